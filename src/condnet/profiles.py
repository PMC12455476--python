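"""Spatial and temporal organization of condensate microstructure.

Radial mass-density profiles about the dense-phase center of mass, logistic
interface fits with the 95%/5% interfacial bounds, radial distributions of
hub and clique chains normalized by the dilute-side boundary, role
lifetimes over continuous trajectory windows, and instantaneous chain
displacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import AMU_PER_A3_TO_G_PER_CM3
from .forcefield import EnergyModel, R0_BOND
from .network import CliqueSet, HubSet
from .trajio import Configuration, Trajectory, all_chain_coms


class InterfaceFitError(RuntimeError):
    """Sigmoid interface fit failed or the profile has no dense plateau."""


@dataclass
class CondensateProfile:
    bin_edges: np.ndarray          # Å
    density: np.ndarray            # g/cm^3 per shell
    rho_dense: float | None = None
    rho_dilute: float | None = None
    r_mid: float | None = None     # logistic midpoint, Å
    width: float | None = None     # logistic width, Å
    r95: float | None = None       # inner interfacial bound, Å
    r05: float | None = None       # outer (dilute-side) bound, Å

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def has_fit(self) -> bool:
        return self.r95 is not None


@dataclass
class RoleTimeline:
    """Per-chain hub/clique flags over a contiguous frame window."""

    chain_ids: list[int]
    hub_flags: np.ndarray      # (n_frames, n_chains) bool
    clique_flags: np.ndarray
    window_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.hub_flags.shape != self.clique_flags.shape:
            raise ValueError("flag arrays must agree in shape")
        if self.hub_flags.shape[1] != len(self.chain_ids):
            raise ValueError("flag columns must match chain ids")


def dense_phase_com(conf: Configuration, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted center of the dense phase.

    The droplet configurations analysed here keep the dense phase compact
    and interior to the box, so the plain mass-weighted bead center is used.
    """
    m = masses[:, None]
    return (conf.positions * m).sum(axis=0) / masses.sum()


def radial_density_profile(
    traj: Trajectory, model: EnergyModel, bin_width: float = 5.0,
    r_max: float | None = None,
) -> CondensateProfile:
    """Frame-averaged radial mass density about the dense-phase COM."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    masses = model.masses_for(traj[0])
    if r_max is None:
        r_max = float(traj[0].box.min()) / 2
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    acc = np.zeros(len(edges) - 1)
    for frame in traj.frames:
        com = dense_phase_com(frame, masses)
        r = np.linalg.norm(frame.positions - com, axis=1)
        hist, _ = np.histogram(r, bins=edges, weights=masses)
        acc += hist
    density = acc / len(traj) / shell_vol * AMU_PER_A3_TO_G_PER_CM3
    return CondensateProfile(bin_edges=edges, density=density)


def _logistic(r, rho_dil, rho_dense, r_mid, w):
    arg = np.clip((np.asarray(r, float) - r_mid) / w, -500.0, 500.0)
    return rho_dil + (rho_dense - rho_dil) / (1.0 + np.exp(arg))


def fit_interface(profile: CondensateProfile) -> CondensateProfile:
    """Fit a logistic sigmoid to the radial profile and attach the 95%/5%
    interfacial bounds (fractions of the dense-phase plateau value)."""
    r = profile.bin_centers
    rho = profile.density
    if not np.any(rho > 0):
        raise InterfaceFitError("profile is empty")
    rho_dense0 = float(np.mean(rho[: max(2, len(rho) // 8)]))
    rho_dil0 = float(np.mean(rho[-max(2, len(rho) // 8):]))
    if rho_dense0 < 2 * max(rho_dil0, 1e-12):
        raise InterfaceFitError("no dense plateau at least twice the dilute level")
    r_mid0 = float(r[np.argmin(np.abs(rho - 0.5 * (rho_dense0 + rho_dil0)))])
    rho_max = float(rho.max())
    try:
        popt, _ = curve_fit(
            _logistic, r, rho,
            p0=[max(rho_dil0, 1e-9), rho_dense0, r_mid0, max(2.0, (r[1] - r[0]))],
            bounds=([0.0, 0.0, 0.0, 1e-3],
                    [rho_max, 2 * rho_max, float(r[-1]), float(r[-1])]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise InterfaceFitError(f"sigmoid fit did not converge: {exc}") from exc
    rho_dil, rho_dense, r_mid, w = (float(v) for v in popt)
    if rho_dense <= rho_dil or w <= 0:
        raise InterfaceFitError("fitted profile is inverted or degenerate")

    def crossing(frac: float) -> float:
        target = frac * rho_dense
        if target <= rho_dil:
            raise InterfaceFitError(
                f"{frac:.0%} of the plateau lies below the dilute baseline"
            )
        return r_mid + w * np.log((rho_dense - rho_dil) / (target - rho_dil) - 1.0)

    r95, r05 = crossing(0.95), crossing(0.05)
    if not r95 < r05:
        raise InterfaceFitError("interfacial bounds are inverted")
    return CondensateProfile(
        bin_edges=profile.bin_edges, density=profile.density,
        rho_dense=rho_dense, rho_dilute=rho_dil,
        r_mid=r_mid, width=w, r95=r95, r05=r05,
    )


def radial_feature_distribution(
    traj: Trajectory,
    hubs_per_frame: list[HubSet],
    cliques_per_frame: list[CliqueSet],
    profile: CondensateProfile,
    model: EnergyModel,
    bin_width: float = 0.05,
    r_norm_max: float = 1.5,
):
    """Unit-area histograms of hub-chain and clique-chain COM radial
    distances, normalized by the dilute-side interfacial bound r05."""
    if not profile.has_fit:
        raise ValueError("profile has no interface fit")
    masses = model.masses_for(traj[0])
    edges = np.arange(0.0, r_norm_max + bin_width, bin_width)
    hub_r, clique_r = [], []
    for frame, hubs, cliques in zip(traj.frames, hubs_per_frame, cliques_per_frame):
        com = dense_phase_com(frame, masses)
        coms = all_chain_coms(frame, masses)
        for c in hubs.hubs:
            hub_r.append(np.linalg.norm(coms[c] - com) / profile.r05)
        for grp in cliques.cliques:
            for c in grp:
                clique_r.append(np.linalg.norm(coms[c] - com) / profile.r05)
    out = {}
    for name, values in (("hub", hub_r), ("clique", clique_r)):
        hist, _ = np.histogram(values, bins=edges, density=True)
        out[name] = {"edges": edges, "density": hist, "values": np.array(values)}
    return out


def build_role_timeline(
    hubs_per_frame: list[HubSet],
    cliques_per_frame: list[CliqueSet],
    chain_ids: list[int],
    window_ns: float = 0.0,
) -> RoleTimeline:
    n_frames = len(hubs_per_frame)
    idx = {c: k for k, c in enumerate(chain_ids)}
    hub = np.zeros((n_frames, len(chain_ids)), bool)
    cli = np.zeros_like(hub)
    for t, (hs, cs) in enumerate(zip(hubs_per_frame, cliques_per_frame)):
        for c in hs.hubs:
            hub[t, idx[c]] = True
        for grp in cs.cliques:
            for c in grp:
                cli[t, idx[c]] = True
    return RoleTimeline(list(chain_ids), hub, cli, window_ns)


def role_lifetimes(timeline: RoleTimeline):
    """Per-chain fraction of window frames spent as a hub / in a clique."""
    n = timeline.hub_flags.shape[0]
    if n == 0:
        raise ValueError("empty window")
    return {
        "chain_ids": timeline.chain_ids,
        "hub_fraction": timeline.hub_flags.mean(axis=0),
        "clique_fraction": timeline.clique_flags.mean(axis=0),
    }


def displacement(
    traj: Trajectory, frame_index: int, model: EnergyModel, offset: int = 1
):
    """Instantaneous chain displacements at a sampled frame.

    |dr_i| is the mean of the two leg lengths |r(t) - r(t-dt)| and
    |r(t+dt) - r(t)|; the normalized value divides by the chain's fully
    extended contour length (n-1) * 3.81 Å.
    """
    if not (offset <= frame_index < len(traj) - offset):
        raise IndexError(
            f"frame {frame_index} has no +-{offset} neighbours; sample interior frames"
        )
    masses = model.masses_for(traj[0])
    prev_c = all_chain_coms(traj[frame_index - offset], masses)
    curr_c = all_chain_coms(traj[frame_index], masses)
    next_c = all_chain_coms(traj[frame_index + offset], masses)
    out = {}
    conf = traj[frame_index]
    for cid in conf.chain_labels:
        leg1 = np.linalg.norm(curr_c[cid] - prev_c[cid])
        leg2 = np.linalg.norm(next_c[cid] - curr_c[cid])
        dr = 0.5 * (leg1 + leg2)
        n = conf.chain_slice(cid).stop - conf.chain_slice(cid).start
        norm = dr / ((n - 1) * R0_BOND) if n > 1 else float("nan")
        out[cid] = (dr, norm)
    return out
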