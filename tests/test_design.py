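"""Lens phase, segment tiling, meta-atom placement and layout export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chiplens import design as D
from chiplens import materials as M


@pytest.fixture(scope="module")
def toy_lens():
    return D.LensPhaseSpec.from_focal(5.0, 1.7, 500.0, 660.0)


# -- NA / focal relation -----------------------------------------------------

def test_focal_length_45_degree_marginal_ray():
    n = 1.33
    na = n * np.sin(np.pi / 4)
    assert D.focal_length_from_na(na, 20.0, n) == pytest.approx(10.0)


def test_na_from_reference_geometry():
    assert D.na_from_focal(7.0, 20.0, 1.33) == pytest.approx(1.0896, abs=2e-4)
    assert D.focal_length_from_na(1.1, 20.0, 1.33) == pytest.approx(6.8, abs=0.1)


def test_na_inverse_consistency_and_errors():
    f = D.focal_length_from_na(0.9, 12.0, 1.33)
    assert D.na_from_focal(f, 12.0, 1.33) == pytest.approx(0.9, rel=1e-12)
    with pytest.raises(ValueError):
        D.focal_length_from_na(1.4, 20.0, 1.33)


def test_lens_spec_consistency_enforced():
    with pytest.raises(ValueError):
        D.LensPhaseSpec(20.0, 7.0, 0.8, 500.0, 660.0)
    spec = D.LensPhaseSpec.from_na(20.0, 1.1, 500.0, 660.0)
    assert D.na_from_focal(spec.f_um, spec.d_um, spec.n_design) == \
        pytest.approx(spec.na, abs=1e-9)
    with pytest.raises(ValueError):
        D.LensPhaseSpec.from_na(20.0, 1.1, 500.0, 500.0)


# -- lens phase --------------------------------------------------------------

def test_lens_phase_center_zero_and_negative(toy_lens):
    assert D.lens_phase(0.0, 0.0, 500.0, toy_lens) == 0.0
    xs = np.linspace(-2500, 2500, 41)
    phi = D.lens_phase(xs, 100.0, 500.0, toy_lens)
    assert np.all(phi <= 0)


def test_lens_phase_radial_symmetry(toy_lens):
    rng = np.random.default_rng(7)
    for _ in range(20):
        x, y = rng.uniform(-2000, 2000, 2)
        a = D.lens_phase(x, y, 660.0, toy_lens)
        assert a == pytest.approx(D.lens_phase(-x, -y, 660.0, toy_lens))
        assert a == pytest.approx(D.lens_phase(y, x, 660.0, toy_lens))


def test_lens_phase_direct_arithmetic(toy_lens):
    """Independent evaluation of the hyperbolic phase at random points."""
    rng = np.random.default_rng(11)
    n_w = M.water().n_at(500.0)
    f_nm = 1.7e3
    for _ in range(20):
        x, y = rng.uniform(-2500, 2500, 2)
        expect = (2 * np.pi * n_w / 500.0
                  * (f_nm - np.hypot(f_nm, np.hypot(x, y))))
        assert D.lens_phase(x, y, 500.0, toy_lens) == pytest.approx(expect)


def test_waveguide_phase_basics():
    beta = 0.02
    assert D.waveguide_phase(0.0, 0.0, 500.0, beta) == 0.0
    assert D.waveguide_phase(2 * np.pi / beta, 0.0, 500.0, beta) == \
        pytest.approx(2 * np.pi)
    cyl = D.CylindricalInput(r_um=40.0)
    assert D.waveguide_phase(123.0, 0.0, 500.0, beta, cyl) == \
        pytest.approx(beta * 123.0)  # on-axis reference
    y = 5000.0
    expect = beta * (np.hypot(40e3, y) - 40e3)
    assert cyl(y, 500.0, beta) == pytest.approx(expect)


# -- segment tiling ----------------------------------------------------------

def test_selector_complementary_tiling():
    layout = D.SegmentLayout(d_um=20.0, n_pairs=5)
    y = np.linspace(-9999.0, 9999.0, 2001)
    loc1 = D.segment_selector(y, layout, 1)
    loc2 = D.segment_selector(y, layout, 2)
    assert np.all(loc1 + loc2 == 1)
    assert layout.stripe_width_um == pytest.approx(2.0)


def test_selector_boundary_half_open():
    layout = D.SegmentLayout(d_um=20.0, n_pairs=5)
    # stripe boundaries at multiples of 2 um from -D/2; boundary points
    # belong to the +y stripe
    assert layout.family(0.0) == layout.family(500.0)
    assert layout.family(-1.0) != layout.family(0.0)
    with pytest.raises(ValueError):
        D.segment_selector(10001.0, layout, 1)
    with pytest.raises(ValueError):
        D.segment_selector(0.0, layout, 3)


# -- placement ---------------------------------------------------------------

def _dense_scan_roots(y, lam, beta, lens, input_phase, step=0.5):
    """Brute-force oracle: sign changes of the wrapped phase mismatch."""
    half = lens.d_um * 500.0
    xs = np.arange(-half, half + step / 2, step)
    g = D.waveguide_phase(xs, y, lam, beta, input_phase) \
        - D.lens_phase(xs, y, lam, lens)
    w = D.wrap_phase(g)
    roots = []
    for i in range(len(xs) - 1):
        if w[i] == 0.0:
            roots.append(xs[i])
        elif w[i] < 0 < w[i + 1] and abs(w[i]) < np.pi / 2:
            roots.append(xs[i] - w[i] * step / (w[i + 1] - w[i]))
    return np.asarray(roots)


def test_placement_matches_dense_scan_oracle():
    """Root-finding placement equals a 0.5 nm dense-grid scan (toy lens)."""
    wg = M.WaveguideSpec()
    lens = D.LensPhaseSpec.from_focal(5.0, 1.7, 500.0, 660.0)
    layout = D.SegmentLayout(d_um=5.0, n_pairs=2)
    cyl = D.CylindricalInput(r_um=40.0)
    b1, b2 = wg.beta(500.0), wg.beta(660.0)
    atoms = D.place_meta_atoms(lens, layout, b1, b2, cyl,
                               diameter_nm=0.0)  # no thinning for the oracle
    assert len(atoms) > 50
    for y in np.unique(atoms["y_nm"])[:6]:
        row = atoms[atoms["y_nm"] == y].sort_values("x_nm")
        lam = row["segment_lambda_nm"].iloc[0]
        beta = b1 if lam == 500.0 else b2
        oracle = _dense_scan_roots(y, lam, beta, lens, cyl)
        assert len(row) == len(oracle)
        assert np.allclose(row["x_nm"].to_numpy(), oracle, atol=1.0)


def test_central_root_and_guided_period_spacing():
    """x = 0 is a root on the y = 0 row; local spacing -> 2*pi/beta."""
    wg = M.WaveguideSpec()
    # 15 row pitches across the aperture -> odd row count -> a y = 0 row
    lens = D.LensPhaseSpec.from_focal(5.475, 1.85, 500.0, 660.0)
    layout = D.SegmentLayout(d_um=5.475, n_pairs=1)
    b1, b2 = wg.beta(500.0), wg.beta(660.0)
    atoms = D.place_meta_atoms(lens, layout, b1, b2, None, row_pitch_nm=365.0,
                               diameter_nm=0.0)
    ys = np.unique(atoms["y_nm"])
    y0 = ys[np.argmin(np.abs(ys))]
    assert y0 == pytest.approx(0.0, abs=1e-9)
    row = atoms[atoms["y_nm"] == y0].sort_values("x_nm")
    x = row["x_nm"].to_numpy()
    i0 = np.argmin(np.abs(x))
    assert abs(x[i0]) < 1e-6
    lam = row["segment_lambda_nm"].iloc[0]
    beta = b1 if lam == 500.0 else b2
    # the lens-phase slope is odd in x, so the mean of the spacings on both
    # sides of x = 0 approaches the guided period to second order
    mean_spacing = (x[i0 + 1] - x[i0 - 1]) / 2.0
    assert mean_spacing == pytest.approx(2 * np.pi / beta, rel=0.05)


def test_placed_atoms_satisfy_phase_matching(reference_designs):
    for ref in reference_designs.values():
        res = ref["design"].phase_residuals()
        assert np.max(np.abs(res)) <= 1e-3
        assert ref["design"].validate()


def test_minimum_atom_spacing_enforced(reference_designs):
    atoms = reference_designs["atto490ls"]["design"].atoms
    for y in np.unique(atoms["y_nm"]):
        x = np.sort(atoms.loc[atoms["y_nm"] == y, "x_nm"].to_numpy())
        if x.size > 1:
            assert np.min(np.diff(x)) >= 200.0 - 1e-9


def test_atom_columns_mirror_symmetric_in_y():
    """phi_input even in y => the atom pattern mirrors about y = 0.

    Checked on a single-family design: in a segmented lens the half-open
    stripe tiling maps family 1 onto family 2 under y -> -y, so only the
    per-wavelength root pattern (not the full atom set) is mirror-even.
    """
    atoms = D.make_design(d_um=8.0, f_um=2.8, lambda1_nm=500.0,
                          lambda2_nm=660.0, segmented=False).atoms
    up = atoms[atoms["y_nm"] > 0]
    key = lambda df: df.sort_values(["y_nm", "x_nm"])[
        ["x_nm", "y_nm"]].to_numpy()
    down = atoms[atoms["y_nm"] < 0].copy()
    down["y_nm"] = -down["y_nm"]
    a, b = key(up), key(down)
    assert a.shape == b.shape
    assert np.allclose(a, b, atol=1e-6)


def test_degenerate_design_error():
    wg = M.WaveguideSpec()
    lens = D.LensPhaseSpec.from_focal(5.0, 1.7, 500.0, 660.0)
    layout = D.SegmentLayout(d_um=5.0, n_pairs=1)
    with pytest.raises(M.DegenerateDesignError):
        D.place_meta_atoms(lens, layout, 1e-3, 1e-3, None)


@settings(derandomize=True, max_examples=10, deadline=None)
@given(f_um=st.floats(1.5, 4.0), lam1=st.floats(480.0, 560.0))
def test_placement_residual_property(f_um, lam1):
    wg = M.WaveguideSpec()
    lens = D.LensPhaseSpec.from_focal(4.0, f_um, lam1, lam1 + 120.0)
    layout = D.SegmentLayout(d_um=4.0, n_pairs=2)
    atoms = D.place_meta_atoms(lens, layout, wg.beta(lam1),
                               wg.beta(lam1 + 120.0),
                               D.CylindricalInput(30.0))
    d = D.MetalensDesign(lens, layout, atoms, wg.beta,
                         D.CylindricalInput(30.0))
    assert np.max(np.abs(d.phase_residuals())) <= 1e-3


# -- export ------------------------------------------------------------------

def test_layout_csv_round_trip(tmp_path, reference_designs):
    d = reference_designs["alexa555"]["design"]
    path = tmp_path / "layout.csv"
    D.export_layout(d, path)
    back = D.read_layout(path)
    assert list(back.columns) == D.ATOM_COLUMNS
    assert np.allclose(back.to_numpy(), d.atoms.to_numpy())


def test_empty_design_header_only(tmp_path):
    lens = D.LensPhaseSpec.from_focal(5.0, 1.7, 500.0, 660.0)
    layout = D.SegmentLayout(d_um=5.0, n_pairs=1)
    empty = D.MetalensDesign(lens, layout,
                             pd.DataFrame(columns=D.ATOM_COLUMNS),
                             lambda lam: 0.02)
    path = tmp_path / "empty.csv"
    D.export_layout(empty, path)
    assert len(D.read_layout(path)) == 0


def test_gds_export_record_structure(tmp_path):
    """The GDSII stream holds one BOUNDARY record per atom."""
    atoms = pd.DataFrame({
        "x_nm": [0.0, 400.0, -400.0],
        "y_nm": [0.0, 0.0, 365.0],
        "diameter_nm": 200.0,
        "height_nm": 500.0,
        "segment_lambda_nm": 500.0,
    })
    lens = D.LensPhaseSpec.from_focal(5.0, 1.7, 500.0, 660.0)
    d = D.MetalensDesign(lens, D.SegmentLayout(5.0, 1), atoms,
                         lambda lam: 0.02)
    path = tmp_path / "lens.gds"
    D.export_layout(d, tmp_path / "lens.csv", gds_path=path)
    data = path.read_bytes()
    tags = []
    i = 0
    while i < len(data):
        size = int.from_bytes(data[i:i + 2], "big")
        tags.append(int.from_bytes(data[i + 2:i + 4], "big"))
        i += size
    assert tags[0] == 0x0002          # HEADER
    assert tags.count(0x0800) == 3    # one BOUNDARY per atom
    assert tags[-1] == 0x0400         # ENDLIB
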