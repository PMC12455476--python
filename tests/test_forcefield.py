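"""Potential terms, forces, chain-pair energies, and virial stresses."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from condnet import forcefield as ff
from condnet.trajio import Configuration

from conftest import random_configuration


def test_thermal_energy():
    assert ff.thermal_energy(300.0) == pytest.approx(0.596, abs=1e-3)
    assert ff.thermal_energy(600.0) == pytest.approx(2 * ff.thermal_energy(300.0))
    assert ff.thermal_energy(1e-9) < 1e-10
    with pytest.raises(ValueError):
        ff.thermal_energy(0.0)


def test_bond_energy():
    assert ff.bond_energy(3.81) == 0.0
    assert ff.bond_energy(4.81) == pytest.approx(19.2)
    delta = 0.37
    assert ff.bond_energy(3.81 + delta) == pytest.approx(ff.bond_energy(3.81 - delta))


def test_wang_frenkel_depth_equals_eps_for_every_pair(model):
    """The WF normalization must give well depth exactly -eps for all pairs."""
    for i in range(len(model.residues)):
        for j in range(i, len(model.residues)):
            eps, sig, mu = model.eps_pair[i, j], model.sigma_pair[i, j], model.mu_pair[i, j]
            res = minimize_scalar(
                lambda r: ff.wang_frenkel(r, eps, sig, mu),
                bounds=(0.8 * sig, 3 * sig), method="bounded",
                options={"xatol": 1e-10},
            )
            assert res.fun == pytest.approx(-eps, rel=1e-6)


def test_yy_minimum_is_printed_value(model):
    res = minimize_scalar(lambda r: model.pair_energy("Y", "Y", r),
                          bounds=(5, 19), method="bounded")
    assert res.fun == pytest.approx(-0.42, abs=1e-6)


def test_pair_force_matches_numeric_gradient(model, rng):
    i, j = model.index_of(["R", "E"])  # charged pair exercises both terms
    qq = model.charge[i] * model.charge[j]
    for r in rng.uniform(5.5, 30.0, size=20):
        h = 1e-6
        num = -(model.pair_energy_by_index(np.array([i]), np.array([j]), np.array([r + h]))
                - model.pair_energy_by_index(np.array([i]), np.array([j]), np.array([r - h]))) / (2 * h)
        ana = model.pair_force_by_index(np.array([i]), np.array([j]), np.array([r]))
        assert num[0] == pytest.approx(ana[0], rel=1e-5, abs=1e-10)
    assert qq != 0


def test_pair_energy_cutoffs_and_neutral_pairs(model):
    # neutral-neutral: zero electrostatics at every r (pure WF)
    r = np.linspace(4, 40, 50)
    ss = model.pair_energy("S", "S", r)
    i, = model.index_of(["S"])
    wf = ff.wang_frenkel(r, model.eps_pair[i, i], model.sigma_pair[i, i], model.mu_pair[i, i])
    np.testing.assert_allclose(ss, wf)
    # beyond every cutoff everything vanishes
    assert model.pair_energy("R", "E", 36.0) == 0.0
    assert model.pair_energy("Y", "Y", 25.0) == 0.0
    # near-continuity at the Coulomb cutoff (plain truncation of a screened tail)
    assert abs(model.pair_energy("R", "E", 34.999)) < 5e-3
    with pytest.raises(KeyError):
        model.pair_energy("Z", "Y", 5.0)


def test_parameter_table_override(tmp_path, model):
    src = (tmp_path / "table.tsv")
    base = "residue mass charge sigma eps mu\n"
    rows = "\n".join(
        f"{r} {model.mass[k]} {model.charge[k]} {model.sigma[k]} 0.2 2"
        for k, r in enumerate(model.residues)
    )
    src.write_text(base + rows + "\npair Y Y 0.99\n")
    custom = ff.load_parameter_table(src)
    i, = custom.index_of(["Y"])
    assert custom.eps_pair[i, i] == 0.99
    j, = custom.index_of(["S"])
    assert custom.eps_pair[i, j] == pytest.approx(0.2)


def test_chain_pair_energy_symmetry_and_errors(model, rng):
    conf = random_configuration(rng)
    e_ab = ff.chain_pair_energy(conf, 0, 1, model)
    e_ba = ff.chain_pair_energy(conf, 1, 0, model)
    assert e_ab == pytest.approx(e_ba)
    with pytest.raises(ValueError, match="intermolecular"):
        ff.chain_pair_energy(conf, 2, 2, model)


def test_two_single_bead_chains_at_minimum(model):
    res = minimize_scalar(lambda r: model.pair_energy("Y", "Y", r),
                          bounds=(5, 19), method="bounded")
    conf = Configuration(
        box=[100, 100, 100],
        positions=[[50, 50, 50], [50 + res.x, 50, 50]],
        residues=["Y", "Y"], chain_ids=[0, 1],
    )
    assert ff.chain_pair_energy(conf, 0, 1, model) == pytest.approx(-0.42, abs=1e-6)


def test_far_chains_have_zero_energy(model, y12):
    rod = np.zeros((12, 3))
    rod[:, 2] = np.arange(12) * 3.81
    conf = Configuration(
        box=[300, 300, 300],
        positions=np.vstack([rod + [50, 50, 50], rod + [200, 200, 120]]),
        residues=list(y12.residues) * 2, chain_ids=[0] * 12 + [1] * 12,
    )
    assert ff.chain_pair_energy(conf, 0, 1, model) == 0.0


def test_chain_pair_matrix_matches_brute_force(model, rng):
    """Neighbor-list-accelerated matrix equals the all-pairs double loop."""
    conf = random_configuration(rng, n_chains=5, n_beads=20, box=60.0)
    mat = ff.chain_pair_energy_matrix(conf, model)
    for a in range(5):
        for b in range(a + 1, 5):
            assert mat[a, b] == pytest.approx(
                ff.chain_pair_energy(conf, a, b, model), rel=1e-9, abs=1e-9)
            assert mat[a, b] == mat[b, a]
    assert np.all(np.diag(mat) == 0)


def test_chain_pair_energy_translation_invariance(model, rng):
    conf = random_configuration(rng, n_chains=2, n_beads=15, box=70.0)
    e0 = ff.chain_pair_energy(conf, 0, 1, model)
    for shift in ([5.0, -3.0, 11.0], [69.0, 0.0, 0.0]):  # incl. across the boundary
        moved = Configuration(
            box=conf.box, positions=conf.positions + np.asarray(shift),
            residues=conf.residues, chain_ids=conf.chain_ids,
        )
        assert ff.chain_pair_energy(moved, 0, 1, model) == pytest.approx(e0, rel=1e-9)


def _brute_force_virial(conf, model):
    """Independent O(n^2) double loop over all bead pairs + bonds."""
    n = conf.n_beads
    types = model.index_of(conf.residues)
    w = np.zeros((3, 3))
    bonded = {(int(a), int(b)) for a, b in conf.bonds()}
    for i in range(n):
        for j in range(i + 1, n):
            d = conf.positions[i] - conf.positions[j]
            d -= conf.box * np.round(d / conf.box)
            r = np.linalg.norm(d)
            if (i, j) in bonded:
                fmag = ff.bond_force(r)
            else:
                fmag = float(model.pair_force_by_index(
                    np.array([types[i]]), np.array([types[j]]), np.array([r]))[0])
            w += np.outer(d, (fmag / r) * d)
    return w


def test_per_bead_stress_sums_to_global_virial(model, rng):
    conf = random_configuration(rng, n_chains=5, n_beads=10, box=50.0)
    total = ff.per_bead_virial_stress(conf, model).sum(axis=0)
    np.testing.assert_allclose(total, _brute_force_virial(conf, model),
                               rtol=1e-8, atol=1e-8)


def test_two_beads_at_minimum_zero_virial(model):
    res = minimize_scalar(lambda r: model.pair_energy("Y", "Y", r),
                          bounds=(5, 19), method="bounded")
    conf = Configuration(
        box=[80, 80, 80], positions=[[40, 40, 40], [40 + res.x, 40, 40]],
        residues=["Y", "Y"], chain_ids=[0, 1],
    )
    s = ff.per_bead_virial_stress(conf, model)
    assert np.abs(s).max() < 1e-5


def test_noninteracting_beads_kinetic_only_stress(model):
    conf = Configuration(
        box=[200, 200, 200], positions=[[10, 10, 10], [150, 150, 150]],
        residues=["S", "S"], chain_ids=[0, 1],
        velocities=np.array([[0.001, 0.0, 0.0], [0.0, 0.002, 0.0]]),
    )
    s = ff.per_bead_virial_stress(conf, model)
    from condnet.constants import VSQ_TO_KCAL
    m = model.masses_for(conf)
    assert s[0, 0, 0] == pytest.approx(VSQ_TO_KCAL * m[0] * 0.001**2)
    assert s[1, 1, 1] == pytest.approx(VSQ_TO_KCAL * m[1] * 0.002**2)
    assert s[0, 1, 1] == 0.0
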