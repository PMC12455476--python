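"""Material and packing properties: surface tension, coexistence densities,
critical-point fitting, excluded volume, and effective packing density.

Surface tension comes in two routes that must agree on well-behaved slabs:

* mechanical (Kirkwood-Buff): ``gamma = (L_z/2) (<P_zz> - (<P_xx>+<P_yy>)/2)``
  from box-averaged pressure tensors;
* stress-profile: the integral of the normal-tangential anisotropy
  ``sigma_N(z) - sigma_T(z)`` over the two interfacial windows, averaged
  over the two interfaces.

Coexistence densities versus temperature are fitted jointly with the law of
coexisting densities ``rho_d - rho_l = A (1 - T/T_c)^beta`` (beta = 0.325,
3-D Ising, configurable) and the law of rectilinear diameters
``(rho_d + rho_l)/2 = rho_c + s (T_c - T)``.

Packing density: ``phi_rel = rho_n / c*`` with ``c* = N / V_ex``, the
monomer number density inside a single dilute chain's excluded volume;
``V_ex`` sums bead sphere volumes minus the lens-shaped intersections of
bonded neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import AMU_PER_A3_TO_G_PER_CM3, KCAL_PER_MOL_A2_TO_MN_PER_M
from .forcefield import EnergyModel
from .trajio import Trajectory


@dataclass(frozen=True)
class StressProfile:
    z_centers: np.ndarray      # Å
    sigma_n: np.ndarray        # kcal/mol/Å^3
    sigma_t: np.ndarray
    z_left: float              # interface centers, Å
    z_right: float
    window: float              # common window thickness w, Å

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window thickness must be positive")


@dataclass(frozen=True)
class CoexistenceFit:
    t_c: float                 # K
    rho_c: float               # g/cm^3
    amplitude: float
    slope: float
    beta: float


@dataclass(frozen=True)
class PackingDensity:
    rho_n: float               # monomer number density, Å^-3
    v_ex: float                # Å^3
    c_star: float              # Å^-3
    phi_rel: float
    regime: str


def surface_tension_kb(pressure_tensors: np.ndarray, lz: float) -> float:
    """Kirkwood-Buff surface tension (mN/m) from a time series of global
    pressure tensors (kcal/mol/Å^3), slab normal along z."""
    p = np.asarray(pressure_tensors, float)
    if p.ndim == 2:
        p = p[None]
    pzz = p[:, 2, 2].mean()
    ptan = 0.5 * (p[:, 0, 0] + p[:, 1, 1]).mean()
    gamma = 0.5 * lz * (pzz - ptan)  # kcal/mol/Å^2
    return gamma * KCAL_PER_MOL_A2_TO_MN_PER_M


def surface_tension_profile(profile: StressProfile) -> float:
    """Stress-profile surface tension (mN/m): trapezoidal integral of
    sigma_N - sigma_T over the two interfacial windows, averaged."""
    z = profile.z_centers
    half = profile.window / 2
    lo_l, hi_l = profile.z_left - half, profile.z_left + half
    lo_r, hi_r = profile.z_right - half, profile.z_right + half
    if hi_l > lo_r:
        raise ValueError("interfacial windows overlap")
    if lo_l < z[0] - (z[1] - z[0]) or hi_r > z[-1] + (z[1] - z[0]):
        raise ValueError("interfacial windows exceed the profiled region")
    aniso = profile.sigma_n - profile.sigma_t
    total = 0.0
    for lo, hi in ((lo_l, hi_l), (lo_r, hi_r)):
        sel = (z >= lo) & (z <= hi)
        if sel.sum() < 2:
            raise ValueError("window contains fewer than two bins")
        total += np.trapezoid(aniso[sel], z[sel])
    return 0.5 * total * KCAL_PER_MOL_A2_TO_MN_PER_M


def fit_coexistence(
    temperatures: np.ndarray,
    rho_dense: np.ndarray,
    rho_dilute: np.ndarray,
    beta: float = 0.325,
) -> CoexistenceFit:
    """Joint least-squares fit of the coexistence law and rectilinear
    diameters; returns the critical temperature and density."""
    t = np.asarray(temperatures, float)
    rd = np.asarray(rho_dense, float)
    rl = np.asarray(rho_dilute, float)
    if len(t) < 3:
        raise ValueError("need at least three temperatures")
    if np.any(rd <= rl):
        raise ValueError("every temperature must have rho_dense > rho_dilute")

    def residuals(params):
        t_c, a, rho_c, s = params
        red_t = 1.0 - t / t_c
        diff = np.where(red_t > 0, a * np.abs(red_t) ** beta, np.inf)
        mid = rho_c + s * (t_c - t)
        return np.concatenate([(rd - rl) - diff, 0.5 * (rd + rl) - mid])

    t0 = float(t.max()) * 1.05 + 1.0
    p0 = [t0, float((rd - rl).max()), float(0.5 * (rd + rl).mean()), 1e-4]
    fit = least_squares(residuals, p0, method="lm", max_nfev=20000)
    t_c, a, rho_c, s = fit.x
    if not fit.success or not np.isfinite(fit.cost):
        raise RuntimeError("coexistence fit did not converge")
    if t_c <= t.max():
        raise RuntimeError(
            f"fitted T_c = {t_c:.1f} K is not above the largest input temperature"
        )
    return CoexistenceFit(float(t_c), float(rho_c), float(a), float(s), beta)


def z_density_profile(traj: Trajectory, model: EnergyModel, bin_width: float = 5.0):
    """Frame-averaged mass density (g/cm^3) along z."""
    box = traj[0].box
    masses = model.masses_for(traj[0])
    edges = np.arange(0.0, box[2] + bin_width, bin_width)
    slab_vol = box[0] * box[1] * np.diff(edges)
    acc = np.zeros(len(edges) - 1)
    for frame in traj.frames:
        z = np.mod(frame.positions[:, 2], box[2])
        hist, _ = np.histogram(z, bins=edges, weights=masses)
        acc += hist
    rho = acc / len(traj) / slab_vol * AMU_PER_A3_TO_G_PER_CM3
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rho


def slab_coexistence_densities(
    traj: Trajectory, model: EnergyModel, bin_width: float = 5.0,
    interface_pad: float = 10.0,
):
    """Plateau densities (g/cm^3) of the dense interior and dilute exterior
    of a slab, excluding ``interface_pad`` around each interface.

    Interfaces are located from the half-maximum crossings of the folded
    z-profile about the slab's center of mass.
    """
    z, rho = z_density_profile(traj, model, bin_width)
    box = traj[0].box
    masses = model.masses_for(traj[0])
    zc = np.mod((traj[0].positions[:, 2] * masses).sum() / masses.sum(), box[2])
    d = np.abs(z - zc)
    d = np.minimum(d, box[2] - d)  # periodic distance from slab center
    half_max = 0.5 * (rho.max() + rho.min())
    inside = rho > half_max
    if not inside.any() or inside.all():
        raise ValueError("no dense/dilute plateau separation found")
    d_interface = float(np.max(d[inside]))
    dense_sel = d < d_interface - interface_pad
    dilute_sel = d > d_interface + interface_pad
    if dense_sel.sum() < 1 or dilute_sel.sum() < 1:
        raise ValueError("interfacial padding leaves no plateau bins")
    return float(rho[dense_sel].mean()), float(rho[dilute_sel].mean())


def lens_volume(r1: float, r2: float, d: float) -> float:
    """Intersection volume of two spheres of radii r1, r2 at center
    distance d; clamped to the smaller sphere's volume when engulfed."""
    small = min(r1, r2)
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 4.0 / 3.0 * np.pi * small**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def excluded_volume(
    chain_samples: list[np.ndarray], radii: np.ndarray
) -> tuple[float, float]:
    """Single-chain excluded volume (Å^3) with standard error.

    Per sample: sum of bead sphere volumes minus the lens intersection of
    every bonded pair at its sampled separation.  ``radii`` are per-bead
    sphere radii (Å).
    """
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("bead radii must be positive")
    vols = []
    sphere = 4.0 / 3.0 * np.pi * radii**3
    for pos in chain_samples:
        pos = np.asarray(pos, float)
        d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        v = sphere.sum()
        for k, dk in enumerate(d):
            v -= lens_volume(radii[k], radii[k + 1], dk)
        vols.append(v)
    vols = np.array(vols)
    se = float(vols.std(ddof=1) / np.sqrt(len(vols))) if len(vols) > 1 else 0.0
    return float(vols.mean()), se


def dense_phase_number_density(
    traj: Trajectory, model: EnergyModel, sphere_radius: float
) -> tuple[float, float]:
    """Bead number density (Å^-3) inside a sphere of ``sphere_radius``
    centered on the dense-phase COM, averaged over frames, with standard
    error."""
    box = traj[0].box
    if sphere_radius > box.min() / 2:
        raise ValueError("sampling sphere exceeds half the box")
    masses = model.masses_for(traj[0])
    vol = 4.0 / 3.0 * np.pi * sphere_radius**3
    vals = []
    for frame in traj.frames:
        com = (frame.positions * masses[:, None]).sum(axis=0) / masses.sum()
        r = np.linalg.norm(frame.positions - com, axis=1)
        vals.append((r < sphere_radius).sum() / vol)
    vals = np.array(vals)
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), se


def packing_density(rho_n: float, v_ex: float, n_monomers: int) -> PackingDensity:
    """Effective packing density phi_rel = rho_n / c* with c* = N / V_ex."""
    if v_ex <= 0 or n_monomers <= 0 or rho_n < 0:
        raise ValueError("inputs must be positive (rho_n may be zero)")
    c_star = n_monomers / v_ex
    phi = rho_n / c_star
    regime = "dilute-like" if phi < 0.95 else ("overlap onset" if phi <= 1.05 else "semi-dilute/concentrated")
    return PackingDensity(rho_n, v_ex, c_star, phi, regime)
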