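"""Bead-resolution configurations, trajectories, and LAMMPS-style text I/O.

Conventions: orthorhombic periodic boxes with origin at zero; positions are
stored *unwrapped* in Å; times in ns.  Dump files written here carry an
``element`` column with the residue letter so that round trips are lossless
without a separate topology file; plain dumps from other engines can be read
by supplying the topology from a LAMMPS data file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Configuration:
    """One frame: box, per-bead positions, residue types, and chain ids.

    Beads must be grouped by chain (all beads of a chain contiguous, in
    backbone order); bead index within a chain is its offset in that group.
    """

    box: np.ndarray
    positions: np.ndarray
    residues: np.ndarray
    chain_ids: np.ndarray
    time_ns: float = 0.0
    velocities: np.ndarray | None = None
    images: np.ndarray | None = None
    _chain_slices: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.residues = np.asarray(self.residues, dtype="<U1")
        self.chain_ids = np.asarray(self.chain_ids, dtype=int)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        n = len(self.positions)
        if self.positions.shape != (n, 3) or len(self.residues) != n or len(self.chain_ids) != n:
            raise ValueError("positions, residues and chain_ids must agree in length")
        # chains must be contiguous blocks
        ids, starts = np.unique(self.chain_ids, return_index=True)
        order = np.argsort(starts)
        boundaries = np.flatnonzero(np.diff(self.chain_ids) != 0)
        if len(boundaries) != len(ids) - 1:
            raise ValueError("beads of each chain must be stored contiguously")
        starts = np.concatenate(([0], boundaries + 1, [n]))
        for cid, lo, hi in zip(self.chain_ids[starts[:-1]], starts[:-1], starts[1:]):
            self._chain_slices[int(cid)] = slice(int(lo), int(hi))

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def chain_labels(self) -> list[int]:
        return list(self._chain_slices)

    @property
    def n_chains(self) -> int:
        return len(self._chain_slices)

    def chain_slice(self, chain_id: int) -> slice:
        try:
            return self._chain_slices[int(chain_id)]
        except KeyError:
            raise KeyError(f"no chain {chain_id} in configuration") from None

    def bonds(self) -> np.ndarray:
        """Backbone bond index pairs (i, i+1) within each chain."""
        pairs = []
        for sl in self._chain_slices.values():
            idx = np.arange(sl.start, sl.stop)
            pairs.append(np.column_stack([idx[:-1], idx[1:]]))
        return np.concatenate(pairs) if pairs else np.empty((0, 2), int)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions, self.box)


@dataclass
class Trajectory:
    frames: list[Configuration]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        t = np.array([f.time_ns for f in self.frames])
        if np.any(np.diff(t) <= 0) and len(t) > 1:
            raise ValueError("timestamps must be strictly increasing")
        f0 = self.frames[0]
        for k, f in enumerate(self.frames[1:], 1):
            if f.n_beads != f0.n_beads or not np.array_equal(f.chain_ids, f0.chain_ids):
                raise ValueError(f"frame {k}: bead count or chain topology changed")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def frame_spacing_ns(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[1].time_ns - self.frames[0].time_ns


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shortest periodic displacement vector(s) a - b."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Euclidean distance under the minimum-image convention."""
    d = minimum_image_displacement(a, b, np.asarray(box, float))
    return float(np.linalg.norm(d, axis=-1)) if d.ndim == 1 else np.linalg.norm(d, axis=-1)


def unwrap_chain(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap a chain across periodic boundaries by nearest-image chaining
    along the backbone, anchored at the first bead."""
    steps = minimum_image_displacement(positions[1:], positions[:-1], box)
    out = np.empty_like(positions, dtype=float)
    out[0] = positions[0]
    out[1:] = positions[0] + np.cumsum(steps, axis=0)
    return out


def chain_com(conf: Configuration, chain_id: int, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted center of mass of one chain, beads unwrapped first.

    ``masses`` is per-bead for the whole configuration (equal masses when
    omitted).  Raises if the unwrapped chain still contains a bond longer
    than half the box, which signals broken topology.
    """
    sl = conf.chain_slice(chain_id)
    if conf.images is not None:
        pos = conf.positions[sl] + conf.images[sl] * conf.box
    else:
        pos = unwrap_chain(conf.positions[sl], conf.box)
    bond_len = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    if bond_len.size and bond_len.max() > conf.box.min() / 2:
        raise ValueError(f"chain {chain_id}: bond longer than half the box after unwrapping")
    m = np.ones(len(pos)) if masses is None else np.asarray(masses, float)[sl]
    return (pos * m[:, None]).sum(axis=0) / m.sum()


def all_chain_coms(conf: Configuration, masses: np.ndarray | None = None) -> dict[int, np.ndarray]:
    return {cid: chain_com(conf, cid, masses) for cid in conf.chain_labels}


# ---------------------------------------------------------------------------
# LAMMPS dump (text) I/O


def write_lammps_dump(traj: Trajectory, path: str | Path, dt_fs: float = 10.0) -> None:
    """Write a text dump with columns id mol type element x y z (+ velocities)."""
    letters = sorted(set(np.concatenate([f.residues for f in traj.frames]).tolist()))
    type_of = {r: i + 1 for i, r in enumerate(letters)}
    with open(path, "w") as fh:
        for frame in traj.frames:
            step = int(round(frame.time_ns * 1e6 / dt_fs))
            has_v = frame.velocities is not None
            cols = "id mol type element x y z" + (" vx vy vz" if has_v else "")
            fh.write("ITEM: TIMESTEP\n%d\n" % step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % frame.n_beads)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for L in frame.box:
                fh.write("0.0 %.10g\n" % L)
            fh.write(f"ITEM: ATOMS {cols}\n")
            for i in range(frame.n_beads):
                x, y, z = frame.positions[i]
                row = "%d %d %d %s %.10g %.10g %.10g" % (
                    i + 1, frame.chain_ids[i], type_of[frame.residues[i]],
                    frame.residues[i], x, y, z,
                )
                if has_v:
                    row += " %.10g %.10g %.10g" % tuple(frame.velocities[i])
                fh.write(row + "\n")


def read_lammps_dump(
    path: str | Path,
    topology: dict[int, tuple[int, str]] | None = None,
    dt_fs: float = 10.0,
) -> Trajectory:
    """Read a text dump into a Trajectory.

    ``topology`` maps atom id -> (chain id, residue letter) and is required
    when the dump carries neither ``mol`` nor ``element`` columns.  Scaled
    (xs ys zs) and unscaled (x y z) coordinate dialects are supported, with
    optional image flags (ix iy iz) and velocities.
    """
    frames: list[Configuration] = []
    lines = Path(path).read_text().splitlines()
    i, nframe = 0, 0
    try:
        while i < len(lines):
            if not lines[i].startswith("ITEM: TIMESTEP"):
                raise ValueError(f"frame {nframe}: expected TIMESTEP item")
            step = int(lines[i + 1])
            if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
                raise ValueError(f"frame {nframe}: expected NUMBER OF ATOMS item")
            n = int(lines[i + 3])
            if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
                raise ValueError(f"frame {nframe}: expected BOX BOUNDS item")
            lo_hi = [list(map(float, lines[i + 5 + k].split()[:2])) for k in range(3)]
            box = np.array([hi - lo for lo, hi in lo_hi])
            origin = np.array([lo for lo, _ in lo_hi])
            header = lines[i + 8]
            if not header.startswith("ITEM: ATOMS"):
                raise ValueError(f"frame {nframe}: expected ATOMS item")
            cols = header.split()[2:]
            col = {c: k for k, c in enumerate(cols)}
            if "id" not in col:
                raise ValueError(f"frame {nframe}: dump lacks id column")
            scaled = "xs" in col
            want = ("xs", "ys", "zs") if scaled else ("x", "y", "z")
            if not all(c in col for c in want):
                raise ValueError(f"frame {nframe}: dump lacks coordinate columns {want}")
            body = lines[i + 9 : i + 9 + n]
            if len(body) < n or any(not row.strip() for row in body):
                raise ValueError(f"frame {nframe}: truncated (expected {n} atom rows)")
            raw = [row.split() for row in body]
            ids = np.array([int(r[col["id"]]) for r in raw])
            order = np.argsort(ids, kind="stable")
            xyz = np.array(
                [[float(r[col[c]]) for c in want] for r in raw]
            )[order]
            pos = xyz * box if scaled else xyz - origin
            if all(c in col for c in ("ix", "iy", "iz")):
                img = np.array(
                    [[int(r[col[c]]) for c in ("ix", "iy", "iz")] for r in raw]
                )[order]
            else:
                img = None
            if all(c in col for c in ("vx", "vy", "vz")):
                vel = np.array(
                    [[float(r[col[c]]) for c in ("vx", "vy", "vz")] for r in raw]
                )[order]
            else:
                vel = None
            ids_sorted = ids[order]
            if "element" in col:
                res = np.array([r[col["element"]] for r in raw])[order]
            elif topology is not None:
                res = np.array([topology[a][1] for a in ids_sorted])
            else:
                raise ValueError(
                    f"frame {nframe}: no element column; a topology map is required"
                )
            if topology is not None:
                chains = np.array([topology[a][0] for a in ids_sorted])
            elif "mol" in col:
                chains = np.array([int(r[col["mol"]]) for r in raw])[order]
            else:
                raise ValueError(
                    f"frame {nframe}: no mol column; a topology map is required"
                )
            frames.append(
                Configuration(
                    box=box, positions=pos, residues=res, chain_ids=chains,
                    time_ns=step * dt_fs * 1e-6, velocities=vel, images=img,
                )
            )
            i += 9 + n
            nframe += 1
    except (IndexError, ValueError) as exc:
        if isinstance(exc, ValueError) and str(exc).startswith("frame"):
            raise
        raise ValueError(f"frame {nframe}: malformed dump ({exc})") from exc
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# LAMMPS data file (topology)


def write_lammps_data(conf: Configuration, path: str | Path, masses: dict[str, float]) -> None:
    """Write atoms (full style) + backbone bonds; residue letters are kept as
    comments on the Masses lines so the file round-trips identity."""
    letters = sorted(set(conf.residues.tolist()))
    type_of = {r: i + 1 for i, r in enumerate(letters)}
    bonds = conf.bonds()
    with open(path, "w") as fh:
        fh.write("LAMMPS data file (condnet)\n\n")
        fh.write(f"{conf.n_beads} atoms\n{len(bonds)} bonds\n")
        fh.write(f"{len(letters)} atom types\n1 bond types\n\n")
        for L, ax in zip(conf.box, ("x", "y", "z")):
            fh.write(f"0.0 {L:.10g} {ax}lo {ax}hi\n")
        fh.write("\nMasses\n\n")
        for r in letters:
            fh.write(f"{type_of[r]} {masses[r]:.4f} # {r}\n")
        fh.write("\nAtoms # full\n\n")
        for i in range(conf.n_beads):
            x, y, z = conf.positions[i]
            fh.write(
                "%d %d %d 0.0 %.10g %.10g %.10g\n"
                % (i + 1, conf.chain_ids[i], type_of[conf.residues[i]], x, y, z)
            )
        fh.write("\nBonds\n\n")
        for k, (a, b) in enumerate(bonds, 1):
            fh.write(f"{k} 1 {a + 1} {b + 1}\n")


def read_lammps_data(path: str | Path) -> dict[int, tuple[int, str]]:
    """Read a data file written by this package (or with residue-letter
    comments on Masses lines); returns atom id -> (chain id, residue)."""
    section = None
    residue_of_type: dict[int, str] = {}
    rows: list[tuple[int, int, int]] = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        word = stripped.split()[0]
        if word in ("Masses", "Atoms", "Bonds", "Velocities", "Angles"):
            section = word
            continue
        if section == "Masses":
            parts = stripped.split()
            if "#" in parts:
                residue_of_type[int(parts[0])] = parts[parts.index("#") + 1]
        elif section == "Atoms":
            parts = stripped.split()
            rows.append((int(parts[0]), int(parts[1]), int(parts[2])))
    if not rows:
        raise ValueError(f"{path}: no Atoms section found")
    topo = {}
    for atom_id, mol, atype in rows:
        res = residue_of_type.get(atype)
        if res is None:
            raise ValueError(f"{path}: atom type {atype} has no residue-letter comment")
        topo[atom_id] = (mol, res)
    return topo
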