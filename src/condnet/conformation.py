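"""Single-chain shape metrics and centrality scaling fits.

The gyration tensor of a chain is the (mass-weighted) second moment of bead
positions about the chain center of mass; its sorted eigenvalues
``l1 >= l2 >= l3`` give the squared radius of gyration ``Rg^2 = l1+l2+l3``
and the relative shape anisotropy

    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2,

which is 0 for spherically isotropic conformations, 1 for collinear ones,
and ~0.39 for ideal (freely jointed) chains.  Scaling of per-chain metrics
with betweenness centrality is summarized by a least-squares line in
log10-log10 space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajio import Configuration, unwrap_chain


@dataclass(frozen=True)
class ChainShape:
    rg: float                  # Å
    eigenvalues: tuple[float, float, float]  # Å^2, descending
    kappa2: float | None = None


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x_floor: float


def gyration_tensor(positions: np.ndarray, masses: np.ndarray | None = None) -> ChainShape:
    """Eigen-decomposed (mass-weighted) gyration tensor of one chain.

    Coordinates must be unwrapped.  All-coincident beads give the valid
    degenerate result Rg = 0.
    """
    pos = np.asarray(positions, float)
    if len(pos) < 2:
        raise ValueError("need at least two beads")
    m = np.ones(len(pos)) if masses is None else np.asarray(masses, float)
    com = (pos * m[:, None]).sum(axis=0) / m.sum()
    d = pos - com
    s = np.einsum("k,ka,kb->ab", m, d, d) / m.sum()
    lam = np.sort(np.linalg.eigvalsh(s))[::-1]
    lam = np.clip(lam, 0.0, None)
    return ChainShape(rg=float(np.sqrt(lam.sum())), eigenvalues=tuple(float(x) for x in lam))


def shape_anisotropy(l1: float, l2: float, l3: float) -> float:
    """Relative shape anisotropy kappa^2 from gyration-tensor eigenvalues."""
    if min(l1, l2, l3) < 0:
        raise ValueError("eigenvalues must be non-negative")
    tr = l1 + l2 + l3
    if tr == 0:
        raise ValueError("kappa^2 undefined for an all-zero gyration tensor")
    return 1.0 - 3.0 * (l1 * l2 + l2 * l3 + l3 * l1) / tr**2


def chain_shape(conf: Configuration, chain_id: int, masses: np.ndarray | None = None) -> ChainShape:
    """Gyration tensor + kappa^2 of one chain in a configuration."""
    sl = conf.chain_slice(chain_id)
    pos = unwrap_chain(conf.positions[sl], conf.box)
    m = None if masses is None else np.asarray(masses, float)[sl]
    shape = gyration_tensor(pos, m)
    return ChainShape(shape.rg, shape.eigenvalues, shape_anisotropy(*shape.eigenvalues))


def _batch_kappa2(pos: np.ndarray) -> np.ndarray:
    """kappa^2 for a batch of equal-mass chains, shape (n_samples, n_beads, 3)."""
    d = pos - pos.mean(axis=1, keepdims=True)
    s = np.einsum("ska,skb->sab", d, d) / pos.shape[1]
    lam = np.linalg.eigvalsh(s)
    tr = lam.sum(axis=1)
    pair = lam[:, 0] * lam[:, 1] + lam[:, 1] * lam[:, 2] + lam[:, 2] * lam[:, 0]
    return 1.0 - 3.0 * pair / tr**2


def ideal_chain_kappa2(n_bonds: int, n_samples: int = 10_000, seed: int = 0,
                       batch: int = 2000) -> float:
    """Monte-Carlo mean kappa^2 of freely jointed chains of ``n_bonds``
    fixed-length bonds with isotropic random directions."""
    if n_bonds < 10 or n_samples < 1000:
        raise ValueError("need n_bonds >= 10 and n_samples >= 1000")
    rng = np.random.default_rng(seed)
    total, done = 0.0, 0
    while done < n_samples:
        k = min(batch, n_samples - done)
        steps = rng.normal(size=(k, n_bonds, 3))
        steps /= np.linalg.norm(steps, axis=2, keepdims=True)
        pos = np.concatenate(
            [np.zeros((k, 1, 3)), np.cumsum(steps, axis=1)], axis=1
        )
        total += _batch_kappa2(pos).sum()
        done += k
    return total / n_samples


def loglog_power_fit(x: np.ndarray, y: np.ndarray, floor: float = 0.0) -> PowerLawFit:
    """Least-squares line of log10(y) on log10(x), after excluding points
    with x <= floor (zero-centrality chains are undefined under the log)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = (x > floor) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 10:
        raise ValueError(f"only {int(keep.sum())} usable points (need >= 10)")
    res = stats.linregress(np.log10(x[keep]), np.log10(y[keep]))
    return PowerLawFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), n_points=int(keep.sum()), x_floor=floor,
    )
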