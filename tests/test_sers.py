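"""Placzek invariants, dressing, enhancement factors, E^4 estimator, spectra."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import omegafq as o
from omegafq.errors import GeometryError, InputError
from omegafq.response import FieldMap
from omegafq.units import BOHR_PER_ANGSTROM


# ---------------------------------------------------------------------------
# rotational invariants

def test_isotropic_tensor_invariants():
    inv = o.raman_invariants(2.5 * np.eye(3))
    assert inv.a_prime == pytest.approx(2.5)
    assert inv.g_prime2 == pytest.approx(0.0, abs=1e-14)
    assert inv.d_prime2 == pytest.approx(0.0, abs=1e-14)


def test_antisymmetric_tensor_is_traceless():
    A = np.array([[0, 1.0, -2.0], [-1.0, 0, 0.5], [2.0, -0.5, 0]])
    inv = o.raman_invariants(A)
    assert inv.a_prime == 0
    assert inv.g_prime2 == pytest.approx(0.0, abs=1e-14)
    assert inv.d_prime2 > 0


def test_invariants_match_rotational_average_oracle(rng):
    """45 a'^2 + 7 g'^2 + 5 d'^2 must reproduce the brute-force orientation
    average of the 90-degree perpendicular-polarized intensity."""
    rots = Rotation.random(20000, random_state=5).as_matrix()
    for _ in range(100):
        A = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        inv = o.raman_invariants(A)
        Ar = np.einsum("nij,jk,nlk->nil", rots, A, rots)
        mc = np.mean(np.abs(Ar[:, 2, 2]) ** 2 + np.abs(Ar[:, 0, 2]) ** 2)
        formula = (45 * inv.a_prime2 + 7 * inv.g_prime2 + 5 * inv.d_prime2) / 45
        assert formula == pytest.approx(mc, rel=0.05)   # MC tolerance


def test_two_frequency_invariants_reduce_at_equal_frequencies(rng):
    for _ in range(20):
        A = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        A = A + A.T   # linear-response molecular tensors are symmetric
        single = o.raman_invariants(A)
        mixed = o.raman_invariants(A, dalpha_dq_scattered=A)
        assert mixed.a_prime2 == pytest.approx(single.a_prime2, rel=1e-12)
        assert mixed.g_prime2 == pytest.approx(single.g_prime2, rel=1e-12)
        assert mixed.d_prime2 == pytest.approx(0.0, abs=1e-12)
        I_full = o.placzek_intensity(mixed, 2.0, 1000.0)
        I_eq = o.placzek_intensity(single, 2.0, 1000.0)
        assert I_full == pytest.approx(I_eq, rel=1e-12)


def test_placzek_isotropic_limit():
    inv = o.raman_invariants(3.0 * np.eye(3))
    from omegafq.units import HARTREE_PER_CM1, HARTREE_PER_EV
    w = 2.0 * HARTREE_PER_EV
    wk = 1000.0 * HARTREE_PER_CM1
    expected = (w - wk) ** 4 / (2 * wk) * (45 * 9.0) / 45
    assert o.placzek_intensity(inv, 2.0, 1000.0) == pytest.approx(expected, rel=1e-12)


def test_placzek_frequency_prefactor_factorizes():
    inv = o.raman_invariants(np.diag([1.0, 2.0, 4.0]))
    from omegafq.units import HARTREE_PER_CM1, HARTREE_PER_EV
    w = 2.5 * HARTREE_PER_EV
    i1 = o.placzek_intensity(inv, 2.5, 600.0)
    i2 = o.placzek_intensity(inv, 2.5, 1500.0)
    pref = lambda wk_cm: (w - wk_cm * HARTREE_PER_CM1) ** 4 / (
        2 * wk_cm * HARTREE_PER_CM1)
    assert i1 / i2 == pytest.approx(pref(600.0) / pref(1500.0), rel=1e-12)


def test_placzek_rejects_anti_stokes():
    inv = o.raman_invariants(np.eye(3))
    with pytest.raises(NotImplementedError):
        o.placzek_intensity(inv, 0.05, 1000.0)   # 0.05 eV < 1000 cm^-1


# ---------------------------------------------------------------------------
# dressed polarizability

def test_dressing_without_substrate_is_identity(molecule3):
    out = o.dressed_polarizability(molecule3.alpha_eq, None)
    assert np.array_equal(out, molecule3.alpha_eq)


def test_dressing_decouples_at_large_distance(silver_material, tip55):
    site = np.array([0.0, tip55.positions[:, 1].max() + 1.0e4, 0.0])
    c = o.SubstrateCoupling.from_substrate(tip55, silver_material, 3.3, site,
                                           model="wfqfmu")
    alpha = np.diag([5.0, 6.0, 7.0]).astype(complex)
    out = o.dressed_polarizability(alpha, c)
    assert np.allclose(out, alpha, rtol=1e-8)


def test_dressing_matches_two_dipole_closed_form(silver_material):
    """Isotropic molecule + one dipole-only substrate atom: analytic
    self-consistent two-point-dipole solution along each principal axis."""
    atom = o.single_atom()
    w = 2.0
    a_s = silver_material.interband(w)
    sep_ang = 20.0   # far beyond the Gaussian widths: point-dipole kernels
    site = np.array([0.0, sep_ang, 0.0])
    c = o.SubstrateCoupling.from_substrate(atom, silver_material, w, site,
                                           model="wfqfmu")
    rb = sep_ang * BOHR_PER_ANGSTROM
    alpha_m = 7.0 + 0.5j
    dressed = o.dressed_polarizability(alpha_m * np.eye(3), c)
    for axis, t in ((0, -1.0 / rb**3), (1, 2.0 / rb**3), (2, -1.0 / rb**3)):
        closed = (1 + a_s * t) * alpha_m * (1 + t * a_s) / (1 - alpha_m * a_s * t * t)
        assert dressed[axis, axis] == pytest.approx(closed, rel=1e-9)
    off = dressed - np.diag(np.diag(dressed))
    assert np.abs(off).max() < 1e-12 * np.abs(dressed).max()


def test_molecule_inside_vdw_envelope_rejected(silver_material, tip55):
    site = np.array([0.0, tip55.positions[:, 1].max() + 0.5, 0.0])
    with pytest.raises(GeometryError):
        o.SubstrateCoupling.from_substrate(tip55, silver_material, 3.3, site)


def test_emission_operator_obeys_reciprocity(silver_material, tip55):
    site = np.array([0.0, tip55.positions[:, 1].max() + 3.0, 0.0])
    c = o.SubstrateCoupling.from_substrate(tip55, silver_material, 3.3, site,
                                           model="wfqfmu")
    S = c.local_field - np.eye(3)
    assert np.allclose(c.emission, S.T, rtol=1e-8)


# ---------------------------------------------------------------------------
# mode derivatives

def test_mode_derivative_exact_for_linear_alpha():
    h = 0.001
    slope = np.arange(9, dtype=float).reshape(3, 3) + 1.0
    hb = h * BOHR_PER_ANGSTROM
    mol = o.MoleculeRamanModel(
        site=np.zeros(3), mode_freqs_cm=[1000.0], alpha_eq=np.eye(3),
        displaced=[(np.eye(3) + slope * hb, np.eye(3) - slope * hb)],
        step_ang=h)
    d = o.mode_derivatives(mol)[0]
    assert np.allclose(d, slope, rtol=1e-10)


def test_mode_derivative_error_scales_as_h_squared():
    spec_h = o.SyntheticRamanSet(n_modes=1, step_ang=0.02, cubic_scale=1.0)
    spec_h2 = o.SyntheticRamanSet(n_modes=1, step_ang=0.01, cubic_scale=1.0)
    m1 = o.generate_synthetic_tensors(spec_h, seed=9)
    m2 = o.generate_synthetic_tensors(spec_h2, seed=9)
    e1 = np.abs(o.mode_derivatives(m1)[0] - m1.planted_derivatives[0]).max()
    e2 = np.abs(o.mode_derivatives(m2)[0] - m2.planted_derivatives[0]).max()
    assert e1 / e2 == pytest.approx(4.0, rel=0.05)


def test_default_differentiation_step_is_one_milliangstrom():
    m = o.generate_synthetic_tensors(o.SyntheticRamanSet(n_modes=1), seed=0)
    assert m.step_ang == 0.001


def test_missing_displacement_names_mode(molecule3):
    molecule3.displaced[1] = (molecule3.displaced[1][0], None)
    with pytest.raises(InputError, match="mode 1"):
        o.mode_derivatives(molecule3)


# ---------------------------------------------------------------------------
# E^4 estimator

def _uniform_map(factor, n=5):
    pts = np.random.default_rng(0).uniform(-1, 1, (n, 3))
    e_ext = np.array([0, 0, 1.0], complex)
    return FieldMap(pts, np.tile(factor * e_ext, (n, 1)), e_ext)


def test_upsilon_uniform_field_limits():
    assert o.upsilon_vol4(_uniform_map(1.0)) == pytest.approx(1.0)
    assert o.upsilon_vol4(_uniform_map(2.0)) == pytest.approx(16.0)


def test_upsilon_zero_external_field_rejected():
    fm = _uniform_map(1.0)
    fm.e_ext = np.zeros(3, complex)
    with pytest.raises(o.OmegaFQError):
        o.upsilon_vol4(fm)


def test_upsilon_trapezoid_matches_monte_carlo(rng):
    lo, hi = np.array([-1.0, -1.0, -1.0]), np.array([1.0, 1.0, 1.0])

    def smooth_field(p):
        return np.stack([
            1.0 + 0.3 * np.sin(1.3 * p[:, 0]) * np.cos(0.7 * p[:, 1]),
            0.2 * np.cos(0.9 * p[:, 2]),
            1.0 + 0.4 * np.sin(0.5 * p[:, 0] + 0.8 * p[:, 2]),
        ], axis=-1).astype(complex)

    pts, shape, _ = o.box_grid(lo, hi, spacing=0.05)
    fm = FieldMap(pts, smooth_field(pts), np.array([1, 0, 1.0], complex) /
                  np.sqrt(2), grid_shape=shape)
    quad = o.upsilon_vol4(fm)
    mc_pts = rng.uniform(lo, hi, (200000, 3))
    fm_mc = FieldMap(mc_pts, smooth_field(mc_pts),
                     np.array([1, 0, 1.0], complex) / np.sqrt(2))
    mc = o.upsilon_vol4(fm_mc)
    assert quad == pytest.approx(mc, rel=5e-3)


def test_e4_identity_uniform_local_field(molecule3):
    """Isotropic local-field enhancement, back-action off: every mode's EF
    equals the site E^4 ratio exactly."""
    ell = 1.8 - 0.35j
    coupling = o.SubstrateCoupling.uniform(ell)
    w = 2.0
    i_vac, i_ps = [], []
    for k, dA in enumerate(o.mode_derivatives(molecule3)):
        i_vac.append(o.placzek_intensity(o.raman_invariants(dA), w,
                                         molecule3.mode_freqs_cm[k]))
    for k, dA in enumerate(o.mode_derivatives(molecule3, coupling,
                                              reflected=False)):
        i_ps.append(o.placzek_intensity(o.raman_invariants(dA), w,
                                        molecule3.mode_freqs_cm[k]))
    rep = o.enhancement_report(i_ps, i_vac, molecule3.mode_freqs_cm)
    e_ext = np.array([0, 0, 1.0], complex)
    fm = FieldMap(np.zeros((1, 3)), (ell * e_ext)[None, :], e_ext)
    ups_site = o.upsilon_vol4(fm)
    assert np.allclose(rep.ef, ups_site, rtol=1e-10)
    assert rep.aef == pytest.approx(ups_site, rel=1e-10)


# ---------------------------------------------------------------------------
# enhancement factors

def test_enhancement_report_identity_and_scaling():
    rep = o.enhancement_report([1.0, 2.0], [1.0, 2.0])
    assert np.allclose(rep.ef, 1.0) and rep.aef == 1.0 and rep.mef == 1.0
    rep = o.enhancement_report([100.0], [1.0])
    assert rep.ef[0] == rep.aef == rep.mef == 100.0


def test_enhancement_report_worked_example():
    # AEF is the ratio of summed intensities = intensity-weighted mean EF
    rep = o.enhancement_report([10.0, 300.0], [1.0, 3.0])
    assert rep.aef == pytest.approx(310.0 / 4.0)
    assert rep.mef == pytest.approx(100.0)


def test_enhancement_report_excludes_zero_gas_phase(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="omegafq.sers"):
        rep = o.enhancement_report([10.0, 5.0], [1.0, 0.0])
    assert "zero gas-phase" in caplog.text
    assert np.isnan(rep.ef[1])
    assert rep.aef == pytest.approx(10.0)


def test_enhancement_ordering_invariant(rng):
    for _ in range(25):
        i_vac = rng.uniform(0.1, 5.0, 6)
        i_ps = rng.uniform(0.1, 500.0, 6)
        rep = o.enhancement_report(i_ps, i_vac)
        assert rep.mef >= rep.aef >= np.nanmin(rep.ef)
        assert rep.mef == np.nanmax(rep.ef)


# ---------------------------------------------------------------------------
# spectra

def test_lorentzian_stick_shape():
    grid, y = o.convolve_spectrum([(1000.0, 2.0)], fwhm_cm1=4.0,
                                  grid_cm=np.linspace(950, 1050, 20001))
    assert grid[np.argmax(y)] == pytest.approx(1000.0, abs=0.01)
    half = y.max() / 2
    above = grid[y >= half]
    assert (above[-1] - above[0]) == pytest.approx(4.0, abs=0.02)


def test_two_separated_sticks_have_equal_maxima():
    grid, y = o.convolve_spectrum([(800.0, 1.0), (1600.0, 1.0)],
                                  grid_cm=np.linspace(700, 1700, 40001))
    m1 = y[(grid > 700) & (grid < 1200)].max()
    m2 = y[(grid > 1200) & (grid < 1700)].max()
    assert m1 == pytest.approx(m2, rel=1e-6)


def test_convolution_conserves_integrated_intensity():
    sticks = [(900.0, 1.5), (1100.0, 3.0), (1300.0, 0.5)]
    grid = np.linspace(400, 1800, 50001)
    _, y = o.convolve_spectrum(sticks, fwhm_cm1=4.0, grid_cm=grid)
    integral = np.trapezoid(y, grid)
    assert integral == pytest.approx(5.0, rel=5e-3)


def test_empty_stick_list_warns(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="omegafq.sers"):
        grid, y = o.convolve_spectrum([])
    assert len(grid) == 0 and len(y) == 0
    assert "no sticks" in caplog.text


# ---------------------------------------------------------------------------
# end-to-end behavior

def test_gas_phase_pipeline_reproduces_raman_bitwise(molecule3):
    r1 = o.compute_sers(None, None, molecule3, 2.0)
    r2 = o.compute_sers(None, None, molecule3, 2.0)
    assert np.array_equal(r1.intensity_vac, r2.intensity_vac)
    assert np.array_equal(r1.intensity_ps, r1.intensity_vac)
    assert np.all(r1.ef == 1.0)


def test_aef_decreases_with_molecule_distance(silver_material, tip55):
    ytop = tip55.positions[:, 1].max()
    aefs = []
    for d in (3.0, 5.0, 7.0, 10.0):
        site = (0.0, ytop + d, 0.0)
        mol = o.generate_synthetic_tensors(
            o.SyntheticRamanSet(n_modes=3, site=site), seed=13)
        res = o.compute_sers(tip55, silver_material, mol, 3.3, model="wfqfmu",
                             with_upsilon=True)
        aefs.append((res.aef, res.upsilon4))
    a = [x[0] for x in aefs]
    u = [x[1] for x in aefs]
    assert all(a[i] > a[i + 1] for i in range(3))
    assert all(u[i] > u[i + 1] for i in range(3))


def test_upsilon_at_point_matches_manual_field_ratio(silver_material, tip55):
    from omegafq.sers import upsilon_at_point
    site = np.array([0.0, tip55.positions[:, 1].max() + 3.0, 0.0])
    pol = np.array([0.0, 1.0, 0.0])
    ups = upsilon_at_point(tip55, silver_material, 3.3, site, pol, model="wfqfmu")
    sol = o.assemble(tip55, silver_material, "wfqfmu").solve(
        3.3, pol.astype(complex))
    fm = o.induced_field(sol, tip55, silver_material, site[None, :])
    manual = (np.sum(np.abs(fm.e_total[0]) ** 2) / 1.0) ** 2
    assert ups == pytest.approx(manual, rel=1e-12)
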