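"""Procedural generators standing in for cluster-scale MD production runs.

Everything the analysis pipeline consumes can be generated here at desk
scale: spherical droplet + dilute halo configurations, slab (direct
coexistence) configurations, droplets with *planted* network structure
(clique clusters at the interface, connective core chains at the center),
short Langevin trajectories under the packaged forcefield, synthetic
interfacial stress profiles, and the reference graph families used to
validate the small-world estimators.

All generators are pure functions of their spec and seed.  Chains are grown
as self-avoiding random walks with fixed bond length 3.81 Å; placements
closer than ``min_dist`` to any existing bead are rejected (default
0.8 x mean bead diameter — cheap, and sufficient for analysis fixtures; the
planted generator uses 1.0 x so that every planted contact is net
attractive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .constants import FORCE_TO_ACC, KB
from .forcefield import EnergyModel, R0_BOND, forces_and_energy
from .sequences import ResidueSequence
from .trajio import Configuration, Trajectory


class PackingError(RuntimeError):
    """Raised when self-avoiding placement fails after bounded retries;
    usually means the requested density is too high — enlarge the radius."""


@dataclass(frozen=True)
class DropletSpec:
    n_chains: int
    sequence: ResidueSequence
    radius: float              # dense-phase radius, Å
    box: float                 # cubic box length, Å
    dense_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dense_fraction <= 1.0:
            raise ValueError("dense_fraction must lie in [0, 1]")
        if self.radius >= self.box / 2:
            raise ValueError("dense-phase radius must be below half the box")


@dataclass(frozen=True)
class SlabSpec:
    n_chains: int
    sequence: ResidueSequence
    thickness: float           # slab extent along z, Å
    box: tuple[float, float, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness > self.box[2]:
            raise ValueError("slab thickness must not exceed L_z")

    @property
    def degenerate(self) -> bool:
        """True when the slab fills the box and no dilute region exists."""
        return self.thickness >= self.box[2]


def _grow_chain(
    rng: np.random.Generator,
    n_beads: int,
    center: np.ndarray,
    local_radius: float,
    occupied: np.ndarray,
    min_dist: float,
    max_restarts: int = 40,
    z_bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Grow one self-avoiding chain confined to a ball around ``center``
    (and optionally to a z-slab)."""

    def outside(p: np.ndarray) -> bool:
        if np.linalg.norm(p - center) > local_radius:
            return True
        return z_bounds is not None and not (z_bounds[0] <= p[2] <= z_bounds[1])

    for _ in range(max_restarts):
        pos = np.empty((n_beads, 3))
        for _ in range(60):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            start = center + u * local_radius * 0.6 * rng.random() ** (1 / 3)
            if outside(start):
                continue
            if occupied.size and np.min(np.linalg.norm(occupied - start, axis=1)) < min_dist:
                continue
            break
        else:
            continue
        pos[0] = start
        ok = True
        for i in range(1, n_beads):
            placed = False
            for _ in range(60):
                step = rng.normal(size=3)
                step *= R0_BOND / np.linalg.norm(step)
                cand = pos[i - 1] + step
                if outside(cand):
                    continue
                if i > 1:
                    # the direct predecessor is bonded and exempt from avoidance
                    d = np.linalg.norm(pos[: i - 1] - cand, axis=1)
                    if d.min() < min_dist:
                        continue
                if occupied.size and np.min(np.linalg.norm(occupied - cand, axis=1)) < min_dist:
                    continue
                pos[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise PackingError(
        f"could not place a {n_beads}-bead chain near {center}; "
        "try a larger radius or fewer chains"
    )


def _assemble(spec_seq: ResidueSequence, chain_positions: list[np.ndarray], box: np.ndarray,
              time_ns: float = 0.0) -> Configuration:
    n = len(spec_seq)
    positions = np.concatenate(chain_positions)
    residues = np.tile(np.array(list(spec_seq.residues)), len(chain_positions))
    chain_ids = np.repeat(np.arange(len(chain_positions)), n)
    return Configuration(box=box, positions=positions, residues=residues,
                         chain_ids=chain_ids, time_ns=time_ns)


def _min_dist(model: EnergyModel | None, factor: float) -> float:
    sigma = 5.9 if model is None else float(model.sigma.mean())
    return factor * sigma


def generate_droplet_config(
    spec: DropletSpec, model: EnergyModel | None = None, min_dist_factor: float = 0.8
) -> Configuration:
    """Spherical droplet of self-avoiding chains plus a dilute halo.

    Dense-phase chains have their growth centers uniform in the sphere of
    ``spec.radius`` about the box center; the remaining chains are placed in
    the dilute region outside.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.full(3, float(spec.box))
    center = box / 2
    n_beads = len(spec.sequence)
    local_r = max(14.0, 1.3 * R0_BOND * np.sqrt(n_beads))
    min_dist = _min_dist(model, min_dist_factor)
    n_dense = int(round(spec.dense_fraction * spec.n_chains))
    chains: list[np.ndarray] = []
    occupied = np.empty((0, 3))
    for k in range(spec.n_chains):
        if k < n_dense:
            # uniform in the sphere, pulled in so beads stay near the radius
            margin = min(0.35 * spec.radius, local_r / 2)
            u = rng.random() ** (1 / 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            c = center + direction * u * max(spec.radius - margin, 0.0)
        else:
            for _ in range(200):
                c = rng.random(3) * box
                if np.linalg.norm(c - center) > spec.radius + local_r:
                    break
            else:
                raise PackingError("no dilute region available for halo chains")
        pos = _grow_chain(rng, n_beads, c, local_r, occupied, min_dist)
        chains.append(pos)
        occupied = np.concatenate([occupied, pos])
    return _assemble(spec.sequence, chains, box)


def generate_slab_config(
    spec: SlabSpec, model: EnergyModel | None = None, min_dist_factor: float = 0.8
) -> Configuration:
    """Dense slab centered at L_z/2, periodic in x and y, two planar interfaces."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, float)
    n_beads = len(spec.sequence)
    local_r = max(14.0, 1.3 * R0_BOND * np.sqrt(n_beads))
    min_dist = _min_dist(model, min_dist_factor)
    half = spec.thickness / 2
    chains: list[np.ndarray] = []
    occupied = np.empty((0, 3))
    for _ in range(spec.n_chains):
        margin = min(0.4 * half, local_r / 2)
        c = np.array([
            rng.random() * box[0],
            rng.random() * box[1],
            box[2] / 2 + rng.uniform(-(half - margin), half - margin),
        ])
        pos = _grow_chain(rng, n_beads, c, local_r, occupied, min_dist,
                          z_bounds=(box[2] / 2 - half, box[2] / 2 + half))
        chains.append(pos)
        occupied = np.concatenate([occupied, pos])
    return _assemble(spec.sequence, chains, box)


# ---------------------------------------------------------------------------
# Planted-network droplet


@dataclass(frozen=True)
class PlantedDroplet:
    """A droplet whose interaction graph is built geometrically: a connective
    core at the center joined by branch chains to fully connected clusters
    sitting at the interface."""

    trajectory: Trajectory
    core_chain_positions: list[int] = field(default_factory=list)  # template slots
    cluster_members: list[list[int]] = field(default_factory=list)  # chain ids per cluster
    radius: float = 0.0

    @property
    def clique_chain_ids(self) -> list[int]:
        return sorted({c for grp in self.cluster_members for c in grp})


def generate_planted_droplet(
    sequence: ResidueSequence,
    model: EnergyModel,
    seed: int = 0,
    n_clusters: int = 3,
    n_bridges: int = 4,
    n_frames: int = 1,
    contact: float = 7.5,
    box: float = 200.0,
    jitter: float = 0.4,
) -> PlantedDroplet:
    """Droplet with planted hubs and cliques for pipeline validation.

    Chains are straight rods (bond length 3.81 Å) aligned along z, so the
    interaction energy of two chains is controlled exactly by the in-plane
    distance of their axes: axes at ``contact`` are strongly bound (many
    bead pairs near the Wang-Frenkel minimum), axes beyond ~2x ``contact``
    are not.  The planted layout is a star: one connective chain at the
    center, ``n_clusters`` radial branches of ``n_bridges`` bridge chains at
    spacing ``contact``, each ending in a fully connected triangle of three
    chains at the periphery.  Across frames the triangles keep their slots
    (planted cliques persist) while the core + bridge chains are cyclically
    permuted among the core slots, so the identity of the connective hub
    turns over frame to frame.
    """
    rng = np.random.default_rng(seed)
    boxv = np.full(3, float(box))
    center = boxv / 2
    n_beads = len(sequence)

    slots = [np.zeros(2)]  # central hub slot, xy offsets from the box center
    cluster_slot_groups: list[list[int]] = []
    for b in range(n_clusters):
        phi = 2 * np.pi * b / n_clusters
        direction = np.array([np.cos(phi), np.sin(phi)])
        ortho = np.array([-np.sin(phi), np.cos(phi)])
        for k in range(1, n_bridges + 1):
            slots.append(direction * (k * contact))
        apex = direction * ((n_bridges + 1) * contact)
        group = []
        # equilateral triangle of side ``contact``; apex vertex closes the branch
        for vert in (apex,
                     apex + direction * (contact * np.sqrt(3) / 2) + ortho * (contact / 2),
                     apex + direction * (contact * np.sqrt(3) / 2) - ortho * (contact / 2)):
            group.append(len(slots))
            slots.append(vert)
        cluster_slot_groups.append(group)
    slots = np.array(slots)
    n_chains = len(slots)
    cluster_ids = {s for g in cluster_slot_groups for s in g}
    core_slots = [i for i in range(n_chains) if i not in cluster_ids]

    rod = np.zeros((n_beads, 3))
    rod[:, 2] = (np.arange(n_beads) - (n_beads - 1) / 2) * R0_BOND
    frames = []
    for t in range(n_frames):
        assignment = np.arange(n_chains)
        shift = t % len(core_slots)
        assignment[core_slots] = np.roll(core_slots, shift)
        chain_positions: list[np.ndarray | None] = [None] * n_chains
        for chain_id in range(n_chains):
            xy = slots[assignment[chain_id]]
            offset = np.array([xy[0], xy[1], 0.0]) + rng.normal(scale=jitter, size=3)
            chain_positions[chain_id] = rod + center + offset
        frames.append(_assemble(sequence, chain_positions, boxv, time_ns=float(t)))
    return PlantedDroplet(
        trajectory=Trajectory(frames),
        core_chain_positions=core_slots,
        cluster_members=cluster_slot_groups,
        radius=(n_bridges + 1.6) * contact,
    )


# ---------------------------------------------------------------------------
# Langevin mini-simulator


def run_langevin(
    conf: Configuration,
    model: EnergyModel,
    temperature: float,
    dt_fs: float = 10.0,
    n_steps: int = 1000,
    seed: int = 0,
    friction: float = 0.01,
    sample_every: int = 100,
) -> Trajectory:
    """BAOAB Langevin dynamics under the packaged forcefield.

    ``friction`` is the thermostat collision rate in fs^-1 (a stand-in
    choice; production thermostats in the emulated engine are configured
    differently).  Frames are emitted every ``sample_every`` steps; the
    input configuration's velocities are used when present, otherwise drawn
    from Maxwell-Boltzmann at ``temperature``.
    """
    if dt_fs > 10.0:
        raise ValueError("dt above 10 fs is unstable for the stiff bond term")
    rng = np.random.default_rng(seed)
    m = model.masses_for(conf)[:, None]
    x = conf.positions.copy()
    if conf.velocities is not None:
        v = conf.velocities.copy()
    else:
        v = rng.normal(size=x.shape) * np.sqrt(KB * temperature * FORCE_TO_ACC / m)
    c1 = np.exp(-friction * dt_fs)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma_v = np.sqrt(KB * temperature * FORCE_TO_ACC / m)
    work = Configuration(box=conf.box, positions=x, residues=conf.residues,
                         chain_ids=conf.chain_ids)
    f, _ = forces_and_energy(work, model)
    frames = []
    for step in range(1, n_steps + 1):
        v += 0.5 * dt_fs * f * FORCE_TO_ACC / m
        x += 0.5 * dt_fs * v
        v = c1 * v + c2 * sigma_v * rng.normal(size=v.shape)
        x += 0.5 * dt_fs * v
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite coordinates at step {step}")
        work.positions = x
        f, _ = forces_and_energy(work, model)
        v += 0.5 * dt_fs * f * FORCE_TO_ACC / m
        if step % sample_every == 0:
            frames.append(
                Configuration(box=conf.box.copy(), positions=x.copy(),
                              residues=conf.residues.copy(), chain_ids=conf.chain_ids.copy(),
                              time_ns=step * dt_fs * 1e-6, velocities=v.copy())
            )
    if not frames:
        frames = [Configuration(box=conf.box.copy(), positions=x.copy(),
                                residues=conf.residues.copy(), chain_ids=conf.chain_ids.copy(),
                                time_ns=n_steps * dt_fs * 1e-6, velocities=v.copy())]
    return Trajectory(frames)


def kinetic_energy_per_dof(frame: Configuration, model: EnergyModel) -> float:
    """Mean kinetic energy per degree of freedom, kcal/mol."""
    if frame.velocities is None:
        raise ValueError("frame carries no velocities")
    m = model.masses_for(frame)
    ke = 0.5 * (m[:, None] * frame.velocities ** 2 / FORCE_TO_ACC).sum()
    return float(ke) / (3 * frame.n_beads)


# ---------------------------------------------------------------------------
# Reference graph families


def generate_reference_graph(family: str, n: int, seed: int = 0, *,
                             degree: int | None = None, p: float | None = None,
                             rewire_p: float = 0.1) -> nx.Graph:
    """Seeded graph generators used to validate the small-world estimators.

    family 'ER': Erdős–Rényi G(n, p); give ``p`` directly or a mean
    ``degree`` (p = degree/(n-1)).  family 'ring_lattice': each node joined
    to its ``degree`` nearest neighbours.  family 'watts_strogatz': ring
    lattice rewired with probability ``rewire_p``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if family == "ER":
        if p is None:
            if degree is None:
                raise ValueError("ER family needs p or degree")
            p = degree / (n - 1)
        if not 0 <= p <= 1:
            raise ValueError("p must lie in [0, 1]")
        return nx.gnp_random_graph(n, p, seed=seed)
    if family == "ring_lattice":
        if degree is None or degree < 2 or degree % 2:
            raise ValueError("ring lattice needs an even degree >= 2")
        return nx.watts_strogatz_graph(n, degree, 0.0, seed=seed)
    if family == "watts_strogatz":
        if degree is None:
            raise ValueError("watts_strogatz needs a degree")
        if not 0 <= rewire_p <= 1:
            raise ValueError("rewire_p must lie in [0, 1]")
        return nx.watts_strogatz_graph(n, degree, rewire_p, seed=seed)
    raise ValueError(f"unknown graph family {family!r}")


# ---------------------------------------------------------------------------
# Synthetic interfacial stress fields


def synthetic_slab_stress_profile(
    n_bins: int, lz: float, z_left: float, z_right: float, width: float,
    amplitude: float, baseline: float = 0.0,
):
    """z-binned normal/tangential stress profiles whose anisotropy is two
    Gaussian dips of the tangential component centred on the interfaces.

    Returns ``(z_centers, sigma_n, sigma_t)`` in kcal/mol/Å^3; the implied
    surface tension per interface is ``amplitude * width * sqrt(2 pi)`` in
    kcal/mol/Å^2 before unit conversion.
    """
    z = (np.arange(n_bins) + 0.5) * (lz / n_bins)
    sigma_n = np.full(n_bins, baseline)
    dip = amplitude * (
        np.exp(-0.5 * ((z - z_left) / width) ** 2)
        + np.exp(-0.5 * ((z - z_right) / width) ** 2)
    )
    sigma_t = baseline - dip
    return z, sigma_n, sigma_t
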