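"""Surface tension routes, coexistence fitting, excluded volume, packing."""

import numpy as np
import pytest

from condnet import thermo
from condnet.constants import KCAL_PER_MOL_A2_TO_MN_PER_M
from condnet.synthetic import synthetic_slab_stress_profile
from condnet.trajio import Configuration, Trajectory


def test_surface_tension_kb_examples():
    iso = np.eye(3) * 0.01
    assert thermo.surface_tension_kb(iso, lz=100.0) == 0.0
    p = np.diag([0.001, 0.001, 0.003])
    expected = 0.5 * 100.0 * 0.002 * KCAL_PER_MOL_A2_TO_MN_PER_M
    assert thermo.surface_tension_kb(p, lz=100.0) == pytest.approx(expected)
    assert thermo.surface_tension_kb(p, lz=200.0) == pytest.approx(2 * expected)
    # time series averaging
    series = np.stack([p, 3 * p])
    assert thermo.surface_tension_kb(series, lz=100.0) == pytest.approx(2 * expected)


def _rect_profile(h, d, lz=200.0, n_bins=400):
    z = (np.arange(n_bins) + 0.5) * (lz / n_bins)
    sigma_n = np.zeros(n_bins)
    sigma_t = np.zeros(n_bins)
    z_l, z_r = 60.0, 140.0
    for zc in (z_l, z_r):
        sigma_t[np.abs(z - zc) < d / 2] = -h
    return thermo.StressProfile(z, sigma_n, sigma_t, z_l, z_r, window=30.0)


def test_surface_tension_profile_rectangular_pulse():
    h, d = 0.002, 10.0
    prof = _rect_profile(h, d)
    # each window integrates to h*d; averaged over the two interfaces -> h*d
    expected = h * d * KCAL_PER_MOL_A2_TO_MN_PER_M
    assert thermo.surface_tension_profile(prof) == pytest.approx(expected, rel=0.05)


def test_surface_tension_profile_zero_and_errors():
    z = np.linspace(0.5, 199.5, 200)
    flat = thermo.StressProfile(z, np.zeros(200), np.zeros(200), 60, 140, 30)
    assert thermo.surface_tension_profile(flat) == 0.0
    with pytest.raises(ValueError, match="overlap"):
        thermo.surface_tension_profile(
            thermo.StressProfile(z, np.zeros(200), np.zeros(200), 90, 110, 40))
    with pytest.raises(ValueError, match="exceed"):
        thermo.surface_tension_profile(
            thermo.StressProfile(z, np.zeros(200), np.zeros(200), 10, 190, 40))


def test_surface_tension_routes_agree_on_synthetic_slab():
    """Gaussian interfacial anisotropy confined to the windows: the profile
    integral and the box-averaged mechanical route agree within 2%."""
    lz, n_bins = 300.0, 600
    z, sn, st = synthetic_slab_stress_profile(
        n_bins, lz, z_left=100.0, z_right=200.0, width=4.0, amplitude=0.003)
    prof = thermo.StressProfile(z, sn, st, 100.0, 200.0, window=50.0)
    gamma_prof = thermo.surface_tension_profile(prof)
    # mechanical route from the volume-averaged pressure tensor
    pzz = sn.mean()
    ptan = st.mean()
    p = np.diag([ptan, ptan, pzz])
    gamma_kb = thermo.surface_tension_kb(p, lz)
    assert gamma_prof == pytest.approx(gamma_kb, rel=0.02)
    assert gamma_prof > 0


def _coexistence_data(t_c=400.0, a=0.9, rho_c=0.3, s=4e-4, beta=0.325,
                      temps=(300, 320, 340, 360, 380)):
    t = np.array(temps, float)
    diff = a * (1 - t / t_c) ** beta
    mid = rho_c + s * (t_c - t)
    return t, mid + diff / 2, mid - diff / 2


def test_fit_coexistence_exact_recovery():
    t, rho_d, rho_l = _coexistence_data()
    fit = thermo.fit_coexistence(t, rho_d, rho_l)
    assert fit.t_c == pytest.approx(400.0, rel=1e-3)
    assert fit.rho_c == pytest.approx(0.3, rel=1e-3)


def test_fit_coexistence_noise_robustness(rng):
    recovered = []
    for _ in range(100):
        t, rho_d, rho_l = _coexistence_data()
        rho_d = rho_d * (1 + rng.normal(scale=0.01, size=len(t)))
        rho_l = rho_l * (1 + rng.normal(scale=0.01, size=len(t)))
        if np.any(rho_d <= rho_l):
            continue
        recovered.append(thermo.fit_coexistence(t, rho_d, rho_l).t_c)
    assert np.mean(recovered) == pytest.approx(400.0, rel=0.02)


def test_fit_coexistence_preconditions():
    t, rho_d, rho_l = _coexistence_data()
    with pytest.raises(ValueError, match="rho_dense"):
        thermo.fit_coexistence(t, rho_l, rho_d)
    with pytest.raises(ValueError, match="three"):
        thermo.fit_coexistence(t[:2], rho_d[:2], rho_l[:2])


def _slab_config(rng, rho_dense_beads=6000, rho_dilute_beads=150,
                 box=(60.0, 60.0, 300.0), half=50.0, residue="G"):
    lz = box[2]
    z_dense = lz / 2 + rng.uniform(-half, half, rho_dense_beads)
    xy_dense = rng.random((rho_dense_beads, 2)) * box[:2]
    dense = np.column_stack([xy_dense, z_dense])
    z_dil = np.concatenate([rng.uniform(0, lz / 2 - half - 1, rho_dilute_beads // 2),
                            rng.uniform(lz / 2 + half + 1, lz, rho_dilute_beads // 2)])
    xy_dil = rng.random((len(z_dil), 2)) * box[:2]
    dilute = np.column_stack([xy_dil, z_dil])
    pos = np.vstack([dense, dilute])
    return Configuration(box=np.array(box), positions=pos,
                         residues=[residue] * len(pos),
                         chain_ids=np.arange(len(pos)))


def test_slab_coexistence_densities_recovered(rng, model):
    conf = _slab_config(rng)
    rho_d, rho_l = thermo.slab_coexistence_densities(Trajectory([conf]), model)
    from condnet.constants import AMU_PER_A3_TO_G_PER_CM3
    m = 57.05  # glycine bead
    expected_dense = 6000 * m / (60 * 60 * 100) * AMU_PER_A3_TO_G_PER_CM3
    expected_dilute = 150 * m / (60 * 60 * 200) * AMU_PER_A3_TO_G_PER_CM3
    assert rho_d == pytest.approx(expected_dense, rel=0.1)
    assert rho_l == pytest.approx(expected_dilute, rel=0.5)
    assert rho_d > 10 * rho_l


def test_slab_empty_dilute_region(rng, model):
    conf = _slab_config(rng, rho_dilute_beads=0)
    _, rho_l = thermo.slab_coexistence_densities(Trajectory([conf]), model)
    assert rho_l == 0.0


def test_lens_volume_limits():
    v_sphere = 4 / 3 * np.pi * 2.0**3
    assert thermo.lens_volume(2.0, 2.0, 5.0) == 0.0
    assert thermo.lens_volume(2.0, 2.0, 0.0) == pytest.approx(v_sphere)
    assert thermo.lens_volume(3.0, 1.0, 1.0) == pytest.approx(4 / 3 * np.pi)


def test_excluded_volume_examples_and_mc_oracle(rng):
    sigma = 2.5
    v_sphere = 4 / 3 * np.pi * sigma**3
    # single bead
    v, _ = thermo.excluded_volume([np.zeros((1, 3))], [sigma])
    assert v == pytest.approx(v_sphere)
    # two bonded beads far apart: no overlap
    v, _ = thermo.excluded_volume([np.array([[0, 0, 0], [6.0, 0, 0]])], [sigma, sigma])
    assert v == pytest.approx(2 * v_sphere)
    # fully overlapping
    v, _ = thermo.excluded_volume([np.array([[0, 0, 0], [0, 0, 0.0]])], [sigma, sigma])
    assert v == pytest.approx(v_sphere)
    # intermediate separation vs Monte-Carlo union volume (0.5%)
    d = 3.1
    v, _ = thermo.excluded_volume([np.array([[0, 0, 0], [d, 0, 0]])], [sigma, sigma])
    n_mc = 2_000_000
    lo = np.array([-sigma, -sigma, -sigma])
    hi = np.array([d + sigma, sigma, sigma])
    pts = lo + rng.random((n_mc, 3)) * (hi - lo)
    in_a = (pts**2).sum(axis=1) < sigma**2
    in_b = ((pts - [d, 0, 0]) ** 2).sum(axis=1) < sigma**2
    v_mc = (in_a | in_b).mean() * np.prod(hi - lo)
    assert v == pytest.approx(v_mc, rel=0.005)


def test_excluded_volume_monotone_in_bond_distance():
    sigma = 2.0
    vols = []
    for d in (4.5, 3.5, 2.5, 1.5, 0.5):
        v, _ = thermo.excluded_volume([np.array([[0, 0, 0], [d, 0, 0]])], [sigma, sigma])
        vols.append(v)
    assert all(a >= b for a, b in zip(vols, vols[1:]))


def test_dense_phase_number_density(rng, model):
    n, radius, box = 5000, 40.0, 200.0
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pos = box / 2 + u * (radius * rng.random(n) ** (1 / 3))[:, None]
    conf = Configuration(box=np.full(3, box), positions=pos,
                         residues=["G"] * n, chain_ids=np.arange(n))
    expected = n / (4 / 3 * np.pi * radius**3)
    rho, _ = thermo.dense_phase_number_density(Trajectory([conf]), model, 30.0)
    assert rho == pytest.approx(expected, rel=0.02)
    # brute-force count agreement
    com = pos.mean(axis=0)
    count = (np.linalg.norm(pos - com, axis=1) < 30.0).sum()
    assert rho == pytest.approx(count / (4 / 3 * np.pi * 30.0**3), rel=1e-9)
    with pytest.raises(ValueError, match="half the box"):
        thermo.dense_phase_number_density(Trajectory([conf]), model, 150.0)


def test_packing_density():
    out = thermo.packing_density(rho_n=0.01, v_ex=1000.0, n_monomers=10)
    assert out.c_star == pytest.approx(0.01)
    assert out.phi_rel == pytest.approx(1.0)
    assert out.regime == "overlap onset"
    assert thermo.packing_density(0.0, 1000.0, 10).phi_rel == 0.0
    with pytest.raises(ValueError):
        thermo.packing_density(0.01, -1.0, 10)


def test_packing_density_closed_loop(rng, model):
    """A droplet built at 1.1x the measured c* of its own chains comes back
    with phi_rel ~ 1.1."""
    sigma = np.full(8, 5.0)
    radii = sigma / 2
    rod = np.zeros((8, 3))
    rod[:, 2] = np.arange(8) * 3.81
    v_ex, _ = thermo.excluded_volume([rod], radii)
    c_star = 8 / v_ex
    target_rho = 1.1 * c_star
    n_beads = 4000
    radius = (n_beads / (4 / 3 * np.pi * target_rho)) ** (1 / 3)
    box = 6 * radius
    u = rng.normal(size=(n_beads, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pos = box / 2 + u * (radius * rng.random(n_beads) ** (1 / 3))[:, None]
    conf = Configuration(box=np.full(3, box), positions=pos,
                         residues=["G"] * n_beads, chain_ids=np.arange(n_beads))
    rho_n, _ = thermo.dense_phase_number_density(
        Trajectory([conf]), model, 0.8 * radius)
    out = thermo.packing_density(rho_n, v_ex, 8)
    assert out.phi_rel == pytest.approx(1.1, rel=0.05)
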