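"""Mpipi-style coarse-grained potential: harmonic bonds, Wang-Frenkel
short-range pair contacts, and Debye-Hückel screened electrostatics.

E = E_bond + E_elec + E_pair with

* ``E_bond = k (r - r0)^2``, k = 19.2 kcal mol^-1 Å^-2, r0 = 3.81 Å (engine
  convention without the 1/2 factor, matching the printed unit of k; a
  half-factor reading would halve bond energies).
* Wang-Frenkel: ``E_WF = eps * alpha * [(s/r)^(2 mu) - 1] * [(Rc/r)^(2 mu) - 1]^(2 nu)``
  with nu = 1, Rc = 3 s, and alpha normalizing the well depth to exactly -eps.
* Debye-Hückel: ``E_DH = C q_i q_j exp(-r/lambda_D) / (eps_r r)`` with
  eps_r = 80, lambda_D = 7.95 Å, truncated at 35 Å.

Per-pair parameters come from a packaged TSV (geometric-mean combining of
per-residue eps, arithmetic-mean sigma and mu); any TSV in the same layout
can be swapped in via :func:`load_parameter_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import COULOMB, thermal_energy  # noqa: F401  (re-exported)
from .trajio import Configuration

K_BOND = 19.2          # kcal mol^-1 Å^-2
R0_BOND = 3.81         # Å
EPS_R = 80.0
DEBYE_LENGTH = 7.95    # Å
COULOMB_CUTOFF = 35.0  # Å
WF_NU = 1.0
WF_CUTOFF_FACTOR = 3.0  # Rc = 3 sigma


def _wf_alpha(rc_over_s: np.ndarray, mu: np.ndarray, nu: float = WF_NU) -> np.ndarray:
    """Prefactor of the generalized Wang-Frenkel potential that makes the
    well depth exactly -eps."""
    x = rc_over_s ** (2 * mu)
    return 2 * nu * x * ((1 + 2 * nu) / (2 * nu * (x - 1))) ** (2 * nu + 1)


def wang_frenkel(r, eps, sigma, mu, rc=None):
    """Wang-Frenkel pair energy; zero at and beyond the cutoff."""
    r = np.asarray(r, float)
    if rc is None:
        rc = WF_CUTOFF_FACTOR * np.asarray(sigma, float)
    alpha = _wf_alpha(np.asarray(rc, float) / np.asarray(sigma, float), np.asarray(mu, float))
    with np.errstate(divide="ignore", over="ignore"):
        e = eps * alpha * ((sigma / r) ** (2 * mu) - 1) * ((rc / r) ** (2 * mu) - 1) ** (2 * WF_NU)
    return np.where(r < rc, e, 0.0)


def wang_frenkel_force(r, eps, sigma, mu, rc=None):
    """Magnitude of -dE/dr for the Wang-Frenkel term (positive = repulsive)."""
    r = np.asarray(r, float)
    if rc is None:
        rc = WF_CUTOFF_FACTOR * np.asarray(sigma, float)
    alpha = _wf_alpha(np.asarray(rc, float) / np.asarray(sigma, float), np.asarray(mu, float))
    with np.errstate(divide="ignore", over="ignore"):
        a = (sigma / r) ** (2 * mu)
        b = (rc / r) ** (2 * mu)
        # E = eps*alpha*(a-1)*(b-1)^2 ; dE/dr = eps*alpha*[a'(b-1)^2 + 2(a-1)(b-1) b']
        da = -2 * mu * a / r
        db = -2 * mu * b / r
        dedr = eps * alpha * (da * (b - 1) ** 2 + (a - 1) * 2 * (b - 1) * db)
    return np.where(r < rc, -dedr, 0.0)


def debye_huckel(r, qq):
    """Screened-Coulomb pair energy for charge product ``qq`` (e^2)."""
    r = np.asarray(r, float)
    with np.errstate(divide="ignore"):
        e = COULOMB * qq / (EPS_R * r) * np.exp(-r / DEBYE_LENGTH)
    return np.where((r < COULOMB_CUTOFF) & (qq != 0), e, 0.0)


def debye_huckel_force(r, qq):
    r = np.asarray(r, float)
    with np.errstate(divide="ignore"):
        e = COULOMB * qq / (EPS_R * r) * np.exp(-r / DEBYE_LENGTH)
        dedr = -e * (1 / r + 1 / DEBYE_LENGTH)
    return np.where((r < COULOMB_CUTOFF) & (qq != 0), -dedr, 0.0)


def bond_energy(r) -> float:
    """Harmonic backbone bond energy k (r - r0)^2."""
    r = np.asarray(r, float)
    return K_BOND * (r - R0_BOND) ** 2


def bond_force(r):
    """-dE/dr of the harmonic bond."""
    return -2 * K_BOND * (np.asarray(r, float) - R0_BOND)


@dataclass
class EnergyModel:
    """Parameter table over the 20 residues plus the shared constants."""

    residues: list[str]
    mass: np.ndarray       # (20,)
    charge: np.ndarray     # (20,)
    sigma: np.ndarray      # (20,) bead diameter, Å
    eps_pair: np.ndarray   # (20, 20) WF well depth, kcal/mol
    sigma_pair: np.ndarray  # (20, 20) Å
    mu_pair: np.ndarray    # (20, 20)
    rc_pair: np.ndarray = field(init=False)
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.eps_pair < 0) or np.any(self.sigma <= 0) or np.any(self.mass <= 0):
            raise ValueError("invalid parameter table (eps >= 0, sigma > 0, mass > 0 required)")
        self.rc_pair = WF_CUTOFF_FACTOR * self.sigma_pair
        self._index = {r: i for i, r in enumerate(self.residues)}

    def index_of(self, residues: np.ndarray | list[str]) -> np.ndarray:
        try:
            return np.array([self._index[r] for r in residues])
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]!r} not in parameter table") from None

    def masses_for(self, conf: Configuration) -> np.ndarray:
        return self.mass[self.index_of(conf.residues)]

    @property
    def max_cutoff(self) -> float:
        rc = float(self.rc_pair.max())
        return max(rc, COULOMB_CUTOFF) if np.any(self.charge != 0) else rc

    def pair_energy(self, type_i: str, type_j: str, r) -> np.ndarray | float:
        """Wang-Frenkel + screened-Coulomb energy of one bead pair at
        separation(s) r (Å)."""
        i, j = self.index_of([type_i, type_j])
        e = wang_frenkel(r, self.eps_pair[i, j], self.sigma_pair[i, j], self.mu_pair[i, j])
        e = e + debye_huckel(r, self.charge[i] * self.charge[j])
        return float(e) if np.isscalar(r) else e

    def pair_energy_by_index(self, ti: np.ndarray, tj: np.ndarray, r: np.ndarray) -> np.ndarray:
        e = wang_frenkel(r, self.eps_pair[ti, tj], self.sigma_pair[ti, tj], self.mu_pair[ti, tj])
        return e + debye_huckel(r, self.charge[ti] * self.charge[tj])

    def pair_force_by_index(self, ti: np.ndarray, tj: np.ndarray, r: np.ndarray) -> np.ndarray:
        f = wang_frenkel_force(r, self.eps_pair[ti, tj], self.sigma_pair[ti, tj], self.mu_pair[ti, tj])
        return f + debye_huckel_force(r, self.charge[ti] * self.charge[tj])


def load_parameter_table(path: str | Path | None = None) -> EnergyModel:
    """Build an :class:`EnergyModel` from a TSV table (packaged default).

    The TSV carries per-residue rows ``residue mass charge sigma eps mu``;
    optional lines ``pair A B eps [sigma [mu]]`` override individual pairs.
    """
    if path is None:
        text = resources.files("condnet.data").joinpath("mpipi_params.tsv").read_text()
    else:
        text = Path(path).read_text()
    rows, overrides = {}, []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        parts = line.split()
        if parts[0] == "pair":
            overrides.append(parts[1:])
            continue
        res, mass, charge, sigma, eps, mu = parts[:6]
        rows[res] = (float(mass), float(charge), float(sigma), float(eps), float(mu))
    residues = sorted(rows)
    mass = np.array([rows[r][0] for r in residues])
    charge = np.array([rows[r][1] for r in residues])
    sigma = np.array([rows[r][2] for r in residues])
    eps = np.array([rows[r][3] for r in residues])
    mu = np.array([rows[r][4] for r in residues])
    eps_pair = np.sqrt(np.outer(eps, eps))
    sigma_pair = 0.5 * (sigma[:, None] + sigma[None, :])
    mu_pair = 0.5 * (mu[:, None] + mu[None, :])
    model = EnergyModel(residues, mass, charge, sigma, eps_pair, sigma_pair, mu_pair)
    for ov in overrides:
        a, b = model.index_of(ov[:2])
        model.eps_pair[a, b] = model.eps_pair[b, a] = float(ov[2])
        if len(ov) > 3:
            model.sigma_pair[a, b] = model.sigma_pair[b, a] = float(ov[3])
        if len(ov) > 4:
            model.mu_pair[a, b] = model.mu_pair[b, a] = float(ov[4])
    model.rc_pair = WF_CUTOFF_FACTOR * model.sigma_pair
    return model


# ---------------------------------------------------------------------------
# Configuration-level energies, forces, stresses


def chain_pair_energy(conf: Configuration, chain_a: int, chain_b: int, model: EnergyModel) -> float:
    """Total inter-chain nonbonded energy between two chains (minimum image)."""
    if chain_a == chain_b:
        raise ValueError("chain_pair_energy is intermolecular; got identical chains")
    sa, sb = conf.chain_slice(chain_a), conf.chain_slice(chain_b)
    d = minimum_image_all(conf.positions[sa], conf.positions[sb], conf.box)
    ti = model.index_of(conf.residues[sa])
    tj = model.index_of(conf.residues[sb])
    e = model.pair_energy_by_index(
        np.repeat(ti, len(tj)), np.tile(tj, len(ti)), d.ravel()
    )
    return float(e.sum())


def minimum_image_all(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Matrix of minimum-image distances between two bead sets."""
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d ** 2).sum(axis=-1))


def _neighbor_pairs(conf: Configuration, model: EnergyModel):
    """All bead pairs within the largest interaction cutoff, with minimum-image
    distances, via a periodic KD-tree."""
    rmax = model.max_cutoff
    wrapped = conf.wrapped_positions()
    # guard against beads exactly at the box edge after the mod
    wrapped = np.where(wrapped >= conf.box, 0.0, wrapped)
    tree = cKDTree(wrapped, boxsize=conf.box)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if len(pairs) == 0:
        return pairs, np.empty(0), np.empty((0, 3))
    d = wrapped[pairs[:, 0]] - wrapped[pairs[:, 1]]
    d -= conf.box * np.round(d / conf.box)
    r = np.sqrt((d ** 2).sum(axis=1))
    return pairs, r, d


def chain_pair_energy_matrix(conf: Configuration, model: EnergyModel) -> np.ndarray:
    """Symmetric (n_chains, n_chains) matrix of inter-chain nonbonded
    energies, neighbor-list accelerated; diagonal is zero."""
    labels = conf.chain_labels
    pos_of = {cid: k for k, cid in enumerate(labels)}
    pairs, r, _ = _neighbor_pairs(conf, model)
    E = np.zeros((len(labels), len(labels)))
    if len(pairs) == 0:
        return E
    ca = conf.chain_ids[pairs[:, 0]]
    cb = conf.chain_ids[pairs[:, 1]]
    inter = ca != cb
    if not np.any(inter):
        return E
    ti = model.index_of(conf.residues)[pairs[inter, 0]]
    tj = model.index_of(conf.residues)[pairs[inter, 1]]
    e = model.pair_energy_by_index(ti, tj, r[inter])
    ia = np.array([pos_of[c] for c in ca[inter]])
    ib = np.array([pos_of[c] for c in cb[inter]])
    np.add.at(E, (ia, ib), e)
    np.add.at(E, (ib, ia), e)
    return E


def _nonbonded_mask(conf: Configuration, pairs: np.ndarray) -> np.ndarray:
    """True for pairs that are not directly bonded (beads are stored in
    backbone order, so bonded pairs are consecutive indices on one chain)."""
    a, b = pairs[:, 0], pairs[:, 1]
    return ~((np.abs(a - b) == 1) & (conf.chain_ids[a] == conf.chain_ids[b]))


def forces_and_energy(conf: Configuration, model: EnergyModel):
    """Total force on every bead (kcal/mol/Å) and the potential energy.

    Directly bonded (1-2) bead pairs are excluded from the nonbonded terms.
    """
    n = conf.n_beads
    f = np.zeros((n, 3))
    energy = 0.0
    types = model.index_of(conf.residues)
    pairs, r, dvec = _neighbor_pairs(conf, model)
    if len(pairs):
        keep = _nonbonded_mask(conf, pairs)
        pairs, r, dvec = pairs[keep], r[keep], dvec[keep]
    if len(pairs):
        ti, tj = types[pairs[:, 0]], types[pairs[:, 1]]
        energy += float(model.pair_energy_by_index(ti, tj, r).sum())
        fmag = model.pair_force_by_index(ti, tj, r)  # -dE/dr
        fvec = (fmag / r)[:, None] * dvec            # force on bead i (first of pair)
        np.add.at(f, pairs[:, 0], fvec)
        np.add.at(f, pairs[:, 1], -fvec)
    bonds = conf.bonds()
    if len(bonds):
        d = conf.positions[bonds[:, 0]] - conf.positions[bonds[:, 1]]
        d -= conf.box * np.round(d / conf.box)
        rb = np.linalg.norm(d, axis=1)
        energy += float(bond_energy(rb).sum())
        fb = (bond_force(rb) / rb)[:, None] * d
        np.add.at(f, bonds[:, 0], fb)
        np.add.at(f, bonds[:, 1], -fb)
    return f, energy


def per_bead_virial_stress(conf: Configuration, model: EnergyModel) -> np.ndarray:
    """Per-bead symmetric stress tensors in pressure*volume units
    (kcal/mol), from pairwise + bonded virial contributions split equally
    between partners, plus the kinetic term when velocities are present.
    Summing over beads and dividing by the box volume gives the global
    pressure tensor.
    """
    n = conf.n_beads
    s = np.zeros((n, 3, 3))
    types = model.index_of(conf.residues)
    pairs, r, dvec = _neighbor_pairs(conf, model)
    if len(pairs):
        keep = _nonbonded_mask(conf, pairs)
        pairs, r, dvec = pairs[keep], r[keep], dvec[keep]
    if len(pairs):
        ti, tj = types[pairs[:, 0]], types[pairs[:, 1]]
        fmag = model.pair_force_by_index(ti, tj, r)
        fvec = (fmag / r)[:, None] * dvec
        w = 0.5 * np.einsum("ka,kb->kab", dvec, fvec)  # half of r_ij x f_ij per partner
        np.add.at(s, pairs[:, 0], w)
        np.add.at(s, pairs[:, 1], w)
    bonds = conf.bonds()
    if len(bonds):
        d = conf.positions[bonds[:, 0]] - conf.positions[bonds[:, 1]]
        d -= conf.box * np.round(d / conf.box)
        rb = np.linalg.norm(d, axis=1)
        fb = (bond_force(rb) / rb)[:, None] * d
        w = 0.5 * np.einsum("ka,kb->kab", d, fb)
        np.add.at(s, bonds[:, 0], w)
        np.add.at(s, bonds[:, 1], w)
    if conf.velocities is not None:
        m = model.masses_for(conf)
        from .constants import VSQ_TO_KCAL
        s += VSQ_TO_KCAL * m[:, None, None] * np.einsum(
            "ka,kb->kab", conf.velocities, conf.velocities
        )
    return s


def pressure_tensor(conf: Configuration, model: EnergyModel) -> np.ndarray:
    """Global virial pressure tensor (kcal/mol/Å^3)."""
    return per_bead_virial_stress(conf, model).sum(axis=0) / float(np.prod(conf.box))
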