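"""Angular-spectrum propagator, PSF stacking and focal metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import j1

from chiplens import design as D
from chiplens import propagation as P


def _field(values, dx=100.0, lam=500.0, n=1.0):
    return P.ScalarField(values.astype(complex), dx, lam, n)


# -- propagator --------------------------------------------------------------

def test_plane_wave_phase_advance():
    U = np.ones((128, 128))
    f = _field(U)
    out = P.angular_spectrum_propagate(f, 3.0)
    expect = np.exp(1j * 2 * np.pi * 1.0 * 3000.0 / 500.0)
    assert np.allclose(out.values, expect, atol=1e-12)
    assert out.power == pytest.approx(f.power, rel=1e-12)


def test_zero_distance_identity():
    rng = np.random.default_rng(0)
    U = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
    f = _field(U)
    out = P.angular_spectrum_propagate(f, 0.0)
    assert np.array_equal(out.values, f.values)


def test_energy_conserved_without_evanescent_content():
    """Band-limited propagation conserves power to 1e-10 relative."""
    x = (np.arange(256) - 127.5) * 100.0
    X, Y = np.meshgrid(x, x)
    U = np.exp(-(X**2 + Y**2) / 3000.0**2)  # smooth: negligible evanescence
    f = _field(U)
    out = P.angular_spectrum_propagate(f, 5.0)
    assert out.power == pytest.approx(f.power, rel=1e-10)


def test_energy_nonincreasing_with_evanescent_content():
    rng = np.random.default_rng(1)
    U = rng.normal(size=(128, 128))  # white noise: strong evanescent content
    f = _field(U)
    p_prev = f.power
    for dz in (0.05, 0.2, 1.0):
        p = P.angular_spectrum_propagate(f, dz).power
        assert p <= p_prev * (1 + 1e-12)
        p_prev = p


def test_gaussian_beam_divergence_oracle():
    """Beam width vs z matches the closed-form Gaussian-beam solution."""
    w0 = 1000.0  # nm
    lam, n = 500.0, 1.0
    x = (np.arange(512) - 255.5) * 50.0
    X, Y = np.meshgrid(x, x)
    f = _field(np.exp(-(X**2 + Y**2) / w0**2), dx=50.0, lam=lam, n=n)
    zr = np.pi * w0**2 * n / lam
    for z_um in (2.0, 5.0, 10.0):
        out = P.angular_spectrum_propagate(f, z_um)
        I = np.abs(out.values)**2
        var = float((I * X**2).sum() / I.sum())
        w_meas = 2.0 * np.sqrt(var)  # 1/e^2 radius = 2 sigma for a Gaussian
        w_true = w0 * np.sqrt(1 + (z_um * 1e3 / zr)**2)
        assert w_meas == pytest.approx(w_true, rel=0.01)


def test_grid_aliasing_guard():
    with pytest.raises(P.AliasingError):
        _field(np.ones((32, 32)), dx=200.0, lam=500.0, n=1.33)


# -- stack propagation -------------------------------------------------------

def _converging_field(f_um, lam, n_design, dx=50.0, n_grid=512, w_ap=6000.0):
    x = (np.arange(n_grid) - (n_grid - 1) / 2) * dx
    X, Y = np.meshgrid(x, x)
    f_nm = f_um * 1e3
    phase = 2 * np.pi * n_design / lam * (f_nm - np.sqrt(f_nm**2 + X**2 + Y**2))
    amp = np.exp(-(X**2 + Y**2) / w_ap**2)
    return P.ScalarField(amp * np.exp(1j * phase), dx, lam, n_design)


def test_stack_degenerates_to_pure_water():
    lam = 550.0
    f = _converging_field(6.0, lam, 1.334)
    v0 = P.propagate_stack(f, h_sog_um=0.0, z_min_um=4.0, z_max_um=8.0,
                           n_water=1.334, crop_half_um=2.0)
    # reference: plain single-medium propagation
    direct = []
    for z in v0.z_um:
        direct.append(np.abs(P.angular_spectrum_propagate(f, z).values)**2)
    direct = np.stack(direct)
    keep = np.abs(f.axis_nm) <= 2000.0 + 1e-9
    direct = direct[:, keep][:, :, keep]
    assert np.allclose(v0.intensity * v0.peak_raw, direct, rtol=1e-9,
                       atol=1e-12 * direct.max())


def test_sog_layer_shifts_focus_deeper():
    """Paraxial oracle: a higher-index slab shifts the focus by
    h*(1 - n_water/n_sog) toward larger z."""
    lam, n_w, n_s = 550.0, 1.334, 1.46
    f = _converging_field(6.0, lam, n_w, w_ap=3000.0)  # gentle NA: paraxial
    v_water = P.propagate_stack(f, h_sog_um=0.0, z_min_um=4.0, z_max_um=8.0,
                                n_water=n_w, crop_half_um=1.5)
    v_stack = P.propagate_stack(f, h_sog_um=2.0, z_min_um=4.0, z_max_um=8.0,
                                n_sog=n_s, n_water=n_w, crop_half_um=1.5)
    z0 = P.psf_metrics(v_water).z_focus_um
    z1 = P.psf_metrics(v_stack).z_focus_um
    shift = z1 - z0
    expect = 2.0 * (1.0 - n_w / n_s)
    assert shift == pytest.approx(expect, abs=0.05)


def test_designed_focus_forms_near_seven_micron(reference_designs):
    ref = reference_designs["atto490ls"]
    assert 6.5 <= ref["metrics1"].z_focus_um <= 7.6
    assert 6.5 <= ref["metrics2"].z_focus_um <= 7.6


def test_aperture_phase_matches_lens_phase_at_atoms(reference_designs):
    """At the design wavelength the synthesized aperture phase equals the
    lens phase at every atom of the matching segment family."""
    ref = reference_designs["atto490ls"]
    d = ref["design"]
    lam = 500.0
    field = P.synthesize_aperture_field(d, lam)
    sel = d.atoms["segment_lambda_nm"] == lam
    xa = d.atoms.loc[sel, "x_nm"].to_numpy()
    ya = d.atoms.loc[sel, "y_nm"].to_numpy()
    axis = field.axis_nm
    ix = np.round((xa - axis[0]) / field.dx_nm).astype(int)
    iy = np.round((ya - axis[0]) / field.dx_nm).astype(int)
    # each blob carries a constant phase, so the field phase at the nearest
    # grid node is the atom's phi_wg up to small neighbor-blob interference
    got = np.angle(field.values[iy, ix])
    want = D.wrap_phase(D.lens_phase(xa, ya, lam, d.lens))
    err = np.abs(D.wrap_phase(got - want))
    assert np.percentile(err, 90) < 0.15


def test_single_and_periodic_atoms():
    lens = D.LensPhaseSpec.from_focal(5.0, 1.7, 500.0, 660.0)
    beta = 0.02
    period = 2 * np.pi / beta
    atoms = pd.DataFrame({
        "x_nm": [0.0, period],
        "y_nm": [0.0, 0.0],
        "diameter_nm": 200.0, "height_nm": 500.0,
        "segment_lambda_nm": 500.0,
    })
    d = D.MetalensDesign(lens, D.SegmentLayout(5.0, 1), atoms,
                         lambda lam: beta)
    f = P.synthesize_aperture_field(d, 500.0, extent_um=8.0)
    i0 = f.n_grid // 2
    assert np.angle(f.values[i0, i0]) == pytest.approx(0.0, abs=1e-9)
    ix = i0 + int(round(period / f.dx_nm))
    # both atoms carry equal phase (one guided period apart)
    assert abs(np.angle(f.values[i0, ix])) < 0.02
    # empty design -> zero field
    empty = D.MetalensDesign(lens, D.SegmentLayout(5.0, 1),
                             pd.DataFrame(columns=D.ATOM_COLUMNS),
                             lambda lam: beta)
    fe = P.synthesize_aperture_field(empty, 500.0, extent_um=8.0)
    assert np.all(fe.values == 0)


def test_detection_psf_equals_focusing_psf(reference_designs):
    """Reciprocity proxy: the detection PSF at lambda2 is the focusing PSF
    at lambda2 (one volume serves both directions)."""
    ref = reference_designs["alexa555"]
    d = ref["design"]
    again = P.propagate_stack(P.synthesize_aperture_field(d, 570.0))
    assert np.array_equal(again.intensity, ref["vol2"].intensity)


# -- metrics -----------------------------------------------------------------

def test_gaussian_fwhm_closed_form():
    sigma = 300.0  # nm
    x = (np.arange(161) - 80) * 25.0
    X, Y = np.meshgrid(x, x)
    plane = np.exp(-(X**2 + Y**2) / (2 * sigma**2))
    intensity = np.stack([0.4 * plane, plane, 0.4 * plane])
    vol = P.PSFVolume(intensity / intensity.max(), x, x,
                      np.array([4.9, 5.0, 5.1]), 500.0)
    m = P.psf_metrics(vol)
    expect = 2.355 * sigma
    assert m.fwhm_x_nm == pytest.approx(expect, rel=5e-3)
    assert m.fwhm_y_nm == pytest.approx(expect, rel=5e-3)


def test_airy_fwhm_oracle():
    """FWHM of an ideal Airy pattern matches 0.514*lambda/NA within 2%."""
    lam, na = 500.0, 1.1
    x = (np.arange(401) - 200) * 10.0
    X, Y = np.meshgrid(x, x)
    v = 2 * np.pi / lam * na * np.sqrt(X**2 + Y**2)
    v[v == 0] = 1e-9
    airy = (2 * j1(v) / v) ** 2
    intensity = np.stack([0.3 * airy, airy, 0.3 * airy])
    vol = P.PSFVolume(intensity / intensity.max(), x, x,
                      np.array([6.9, 7.0, 7.1]), lam)
    m = P.psf_metrics(vol)
    assert m.fwhm_x_nm == pytest.approx(0.514 * lam / na, rel=0.02)


def test_focus_on_boundary_detected():
    x = (np.arange(21) - 10) * 50.0
    intensity = np.zeros((3, 21, 21))
    intensity[0, 10, 10] = 1.0  # max on the z boundary
    vol = P.PSFVolume(intensity, x, x, np.array([5.0, 5.1, 5.2]), 500.0)
    with pytest.raises(P.FocusNotContainedError):
        P.psf_metrics(vol)


def test_overlap_self_is_perfect(reference_designs):
    vol = reference_designs["atto490ls"]["vol1"]
    ov = P.focal_overlap(vol, vol)
    assert ov.dz_um == 0.0
    assert ov.lateral_offset_nm == 0.0
    assert ov.overlap_integral == 1.0
    with pytest.raises(ValueError):
        P.focal_overlap(vol, reference_designs["atto490ls"]["vol2"]
                        if False else _mismatched(vol))


def _mismatched(vol):
    return P.PSFVolume(vol.intensity[:, :-1, :-1], vol.x_nm[:-1],
                       vol.y_nm[:-1], vol.z_um, vol.wavelength_nm)


def test_hdf5_round_trip(tmp_path, reference_designs):
    vol = reference_designs["alexa555"]["vol1"]
    path = tmp_path / "psf.h5"
    vol.to_hdf5(path, design="alexa555")
    back = P.PSFVolume.from_hdf5(path)
    assert np.allclose(back.intensity, vol.intensity)
    assert np.allclose(back.z_um, vol.z_um)
    assert back.wavelength_nm == vol.wavelength_nm
    assert back.aperture_power == pytest.approx(vol.aperture_power)
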