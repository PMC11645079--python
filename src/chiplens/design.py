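"""Segmented dual-wavelength metalens design.

A guided TE0 wave accumulates phase phi_wg(x, y) = beta(lambda)*x +
phi_input(y, lambda) while travelling under the metalens aperture.  A
hyperbolic lens phase phi_lens(x, y) = (2*pi*n/lambda)*(F - sqrt(F^2 + x^2 +
y^2)) focuses light at height F in the focal medium.  Meta-atoms (SiN
cylinders) are placed wherever the two phases agree modulo 2*pi, so each
scatterer launches free-space light with exactly the local lens phase.  The
aperture is tiled into alternating stripes along y; stripes of family 1
implement the condition at lambda1, family 2 at lambda2, which is what makes
the lens focus both wavelengths at the same spot.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import DegenerateDesignError, WaveguideSpec, water

TWO_PI = 2.0 * np.pi


def wrap_phase(phi):
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


# ---------------------------------------------------------------------------
# Lens phase specification
# ---------------------------------------------------------------------------

def focal_length_from_na(na, d_um, n):
    """F = D / (2*tan(arcsin(NA/n))) from NA = n*sin(arctan(D/2F))."""
    if not 0.0 < na < n:
        raise ValueError(f"NA must lie in (0, n={n:g})")
    return d_um / (2.0 * np.tan(np.arcsin(na / n)))


def na_from_focal(f_um, d_um, n):
    """Inverse of :func:`focal_length_from_na`."""
    if f_um <= 0 or d_um <= 0:
        raise ValueError("F and D must be positive")
    return n * np.sin(np.arctan(d_um / (2.0 * f_um)))


@dataclass(frozen=True)
class LensPhaseSpec:
    """Lens size D, focal distance F, NA and the two design wavelengths.

    ``n_focus`` maps wavelength (nm) to the refractive index of the medium
    in which the focus forms (water by default); ``n_design`` is the single
    index used in the NA <-> F relation.
    """

    d_um: float
    f_um: float
    na: float
    lambda1_nm: float
    lambda2_nm: float
    n_design: float = 1.33
    n_focus: object = field(default_factory=water)

    def __post_init__(self):
        if self.d_um <= 0:
            raise ValueError("D must be positive")
        if self.lambda1_nm == self.lambda2_nm:
            raise ValueError("design wavelengths must differ")
        na_chk = na_from_focal(self.f_um, self.d_um, self.n_design)
        if abs(na_chk - self.na) > 1e-6:
            raise ValueError(
                f"inconsistent NA/F/D: NA from F is {na_chk:.8f}, "
                f"stored {self.na:.8f}"
            )

    @classmethod
    def from_na(cls, d_um, na, lambda1_nm, lambda2_nm, n_design=1.33,
                n_focus=None):
        f = focal_length_from_na(na, d_um, n_design)
        return cls(d_um, f, na, lambda1_nm, lambda2_nm, n_design,
                   n_focus or water())

    @classmethod
    def from_focal(cls, d_um, f_um, lambda1_nm, lambda2_nm, n_design=1.33,
                   n_focus=None):
        na = na_from_focal(f_um, d_um, n_design)
        return cls(d_um, f_um, na, lambda1_nm, lambda2_nm, n_design,
                   n_focus or water())


def lens_phase(x_nm, y_nm, wavelength_nm, spec: LensPhaseSpec):
    """Hyperbolic focusing phase, <= 0 everywhere, radially symmetric."""
    x = np.asarray(x_nm, dtype=float)
    y = np.asarray(y_nm, dtype=float)
    f_nm = spec.f_um * 1e3
    n = spec.n_focus(wavelength_nm)
    phi = (TWO_PI * n / wavelength_nm
           * (f_nm - np.sqrt(f_nm ** 2 + x ** 2 + y ** 2)))
    return float(phi) if phi.ndim == 0 else phi


def _dlens_dx(x, y, wavelength_nm, spec):
    f_nm = spec.f_um * 1e3
    n = spec.n_focus(wavelength_nm)
    return -TWO_PI * n / wavelength_nm * x / np.sqrt(f_nm ** 2 + x ** 2 + y ** 2)


# ---------------------------------------------------------------------------
# Input phase models
# ---------------------------------------------------------------------------

class ZeroInput:
    """phi_input identically zero (plane-wave feed)."""

    def __call__(self, y_nm, wavelength_nm, beta):
        return np.zeros_like(np.asarray(y_nm, dtype=float)) + 0.0


@dataclass(frozen=True)
class CylindricalInput:
    """Cylindrical wavefront from an effective source R behind the lens edge.

    phi_input(y, lambda) = beta(lambda) * (sqrt(R^2 + y^2) - R) models the
    curved wavefront the taper delivers to the first meta-atom column.
    """

    r_um: float = 40.0

    def __call__(self, y_nm, wavelength_nm, beta):
        y = np.asarray(y_nm, dtype=float)
        r_nm = self.r_um * 1e3
        return beta * (np.sqrt(r_nm ** 2 + y ** 2) - r_nm)


@dataclass(frozen=True)
class TabulatedInput:
    """User-supplied phi_input(y) table, applied at every wavelength."""

    y_nm: np.ndarray
    phi_rad: np.ndarray

    def __call__(self, y_nm, wavelength_nm, beta):
        return np.interp(np.asarray(y_nm, dtype=float), self.y_nm, self.phi_rad)


def waveguide_phase(x_nm, y_nm, wavelength_nm, beta, input_phase=None):
    """phi_wg = beta*x + phi_input(y, lambda); increasing in x."""
    x = np.asarray(x_nm, dtype=float)
    model = input_phase or ZeroInput()
    phi = beta * x + model(y_nm, wavelength_nm, beta)
    return float(phi) if np.ndim(phi) == 0 else phi


# ---------------------------------------------------------------------------
# Segment layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentLayout:
    """Alternating rectangular stripe tiling of the aperture.

    Stripes run along the propagation direction x and alternate along y.
    ``2*n_pairs*stripe_width == D`` must hold; stripes are half-open
    [y_lo, y_hi) so boundary points belong to the +y stripe.  Stripe index 0
    starts at y = -D/2; even indices are family 1 (lambda1).
    """

    d_um: float = 20.0
    n_pairs: int = 5

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("need at least one stripe pair")

    @property
    def stripe_width_um(self):
        return self.d_um / (2 * self.n_pairs)

    def stripe_index(self, y_nm):
        y = np.asarray(y_nm, dtype=float)
        half = self.d_um * 500.0  # D/2 in nm
        if np.any(y < -half) or np.any(y > half):
            raise ValueError("y outside the aperture")
        w_nm = self.stripe_width_um * 1e3
        idx = np.floor((y + half) / w_nm).astype(int)
        return np.clip(idx, 0, 2 * self.n_pairs - 1)

    def family(self, y_nm):
        """1 for lambda1 stripes (even index), 2 for lambda2 stripes."""
        idx = self.stripe_index(y_nm)
        return np.where(idx % 2 == 0, 1, 2) if np.ndim(idx) else (1 if idx % 2 == 0 else 2)


def segment_selector(y_nm, layout: SegmentLayout, family):
    """Loc_i(y): 1 inside family-i stripes, 0 outside; Loc1 + Loc2 == 1."""
    if family not in (1, 2):
        raise ValueError("family must be 1 or 2")
    fam = layout.family(y_nm)
    out = (np.asarray(fam) == family).astype(int)
    return int(out) if np.ndim(y_nm) == 0 else out


# ---------------------------------------------------------------------------
# Meta-atom placement
# ---------------------------------------------------------------------------

ATOM_COLUMNS = ["x_nm", "y_nm", "diameter_nm", "height_nm", "segment_lambda_nm"]


def _row_roots(y_nm, wavelength_nm, beta, lens: LensPhaseSpec, input_phase,
               tol, x_half_nm, n_coarse=4096):
    """All x with wrap(phi_wg - phi_lens) = 0 on one atom row.

    The mismatch g(x) = phi_wg - phi_lens is strictly increasing when
    beta exceeds the lens-phase slope everywhere (checked); each 2*pi branch
    then holds exactly one root, located by inverse interpolation on a coarse
    grid and polished by Newton iterations with the analytic derivative.
    """
    xs = np.linspace(-x_half_nm, x_half_nm, n_coarse)
    model = input_phase or ZeroInput()
    phi_in = float(np.asarray(model(y_nm, wavelength_nm, beta)))

    def g(x):
        return (beta * x + phi_in
                - lens_phase(x, y_nm, wavelength_nm, lens))

    def dg(x):
        return beta - _dlens_dx(x, y_nm, wavelength_nm, lens)

    slopes = dg(xs)
    if np.min(slopes) <= 0.0:
        raise DegenerateDesignError(
            "beta does not exceed the lens phase slope; guided phase cannot "
            "intersect every 2*pi branch"
        )
    gs = g(xs)
    k_lo = int(np.ceil(gs[0] / TWO_PI))
    k_hi = int(np.floor(gs[-1] / TWO_PI))
    if k_hi < k_lo:
        return np.empty(0)
    targets = TWO_PI * np.arange(k_lo, k_hi + 1)
    x = np.interp(targets, gs, xs)
    for _ in range(4):
        x = x - (g(x) - targets) / dg(x)
    x = np.clip(x, -x_half_nm, x_half_nm)
    ok = np.abs(wrap_phase(g(x))) <= tol
    return x[ok]


def place_meta_atoms(lens: LensPhaseSpec, layout: SegmentLayout, beta1, beta2,
                     input_phase=None, row_pitch_nm=365.0, tol=1e-3,
                     diameter_nm=200.0, height_nm=500.0, segmented=True):
    """Place meta-atoms at phase-matching positions, row by row.

    Rows are spaced by ``row_pitch_nm`` along y; each row inherits the design
    wavelength of its host stripe (all rows use lambda1 when
    ``segmented=False``, the chromatic control design).  Within a row, roots
    closer than one atom diameter are thinned by dropping the later root.

    Returns a DataFrame with columns x_nm, y_nm, diameter_nm, height_nm,
    segment_lambda_nm.
    """
    if row_pitch_nm <= 0:
        raise ValueError("row pitch must be positive")
    half_nm = lens.d_um * 500.0
    n_rows = int(np.floor(lens.d_um * 1e3 / row_pitch_nm))
    ys = (np.arange(n_rows) - (n_rows - 1) / 2.0) * row_pitch_nm
    rows = []
    for y in ys:
        fam = layout.family(y) if segmented else 1
        lam = lens.lambda1_nm if fam == 1 else lens.lambda2_nm
        beta = beta1 if fam == 1 else beta2
        x = _row_roots(y, lam, beta, lens, input_phase, tol, half_nm)
        if x.size == 0:
            continue
        keep = [0]
        for i in range(1, x.size):
            if x[i] - x[keep[-1]] >= diameter_nm:
                keep.append(i)
        x = x[keep]
        rows.append(pd.DataFrame({
            "x_nm": x,
            "y_nm": np.full(x.size, y),
            "diameter_nm": diameter_nm,
            "height_nm": height_nm,
            "segment_lambda_nm": float(lam),
        }))
    if not rows:
        return pd.DataFrame(columns=ATOM_COLUMNS)
    return pd.concat(rows, ignore_index=True)[ATOM_COLUMNS]


@dataclass
class MetalensDesign:
    """Complete design: lens spec, stripe layout, atom table, phase models.

    ``beta`` is a callable lambda_nm -> beta (rad/nm), valid at any
    wavelength in the dispersion range, so the same design can be evaluated
    off its design wavelengths (detection bands, chromatic controls).
    """

    lens: LensPhaseSpec
    layout: SegmentLayout
    atoms: pd.DataFrame
    beta: object
    input_phase: object = None
    segmented: bool = True

    def phase_residuals(self):
        """wrap(phi_wg - phi_lens) at every atom, at its segment wavelength."""
        res = np.empty(len(self.atoms))
        for lam in np.unique(self.atoms["segment_lambda_nm"]):
            sel = self.atoms["segment_lambda_nm"] == lam
            x = self.atoms.loc[sel, "x_nm"].to_numpy()
            y = self.atoms.loc[sel, "y_nm"].to_numpy()
            b = self.beta(lam)
            phi_wg = waveguide_phase(x, y, lam, b, self.input_phase)
            res[sel.to_numpy()] = wrap_phase(
                phi_wg - lens_phase(x, y, lam, self.lens))
        return res

    def validate(self, tol=1e-3):
        r = self.phase_residuals()
        if r.size and np.max(np.abs(r)) > tol:
            raise ValueError(
                f"phase-matching violated: max residual {np.max(np.abs(r)):.2e}"
            )
        half = self.lens.d_um * 500.0
        if np.any(np.abs(self.atoms[["x_nm", "y_nm"]].to_numpy()) > half + 1e-9):
            raise ValueError("atom outside the aperture")
        return True


def make_design(waveguide: WaveguideSpec = None, d_um=20.0, na=1.1,
                f_um=None, lambda1_nm=500.0, lambda2_nm=660.0, n_pairs=5,
                row_pitch_nm=365.0, tol=1e-3, diameter_nm=200.0,
                height_nm=500.0, input_phase="cylindrical", r_um=None,
                segmented=True, n_design=None, beta_table=None):
    """Build a full metalens design from the waveguide stack and lens targets.

    ``beta_table``, when given as (wavelength_nm, beta) arrays, overrides the
    slab-derived propagation constant.  ``input_phase`` may be "cylindrical"
    (default, effective source at R = L_taper), "zero", or any callable
    (y_nm, lambda_nm, beta) -> rad.
    """
    wg = waveguide or WaveguideSpec()
    n_focus = water()
    n_design = n_design if n_design is not None else 1.33
    if f_um is None:
        lens = LensPhaseSpec.from_na(d_um, na, lambda1_nm, lambda2_nm,
                                     n_design, n_focus)
    else:
        lens = LensPhaseSpec.from_focal(d_um, f_um, lambda1_nm, lambda2_nm,
                                        n_design, n_focus)
    layout = SegmentLayout(d_um=d_um, n_pairs=n_pairs)
    if beta_table is not None:
        wl_tab, b_tab = (np.asarray(a, dtype=float) for a in beta_table)
        beta = lambda lam: float(np.interp(lam, wl_tab, b_tab))
    else:
        beta = wg.beta
    if input_phase == "cylindrical":
        model = CylindricalInput(r_um if r_um is not None else wg.L_taper_um)
    elif input_phase in ("zero", None):
        model = ZeroInput()
    else:
        model = input_phase
    atoms = place_meta_atoms(lens, layout, beta(lambda1_nm), beta(lambda2_nm),
                             model, row_pitch_nm, tol, diameter_nm, height_nm,
                             segmented=segmented)
    return MetalensDesign(lens, layout, atoms, beta, model, segmented)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_layout(design: MetalensDesign, csv_path, gds_path=None,
                  n_vertices=64):
    """Write the atom table as CSV and optionally a GDSII cell of circles."""
    design.atoms.to_csv(csv_path, index=False)
    if gds_path is not None:
        _write_gds(design.atoms, gds_path, n_vertices)


def read_layout(csv_path):
    df = pd.read_csv(csv_path)
    missing = [c for c in ATOM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"layout CSV missing columns {missing}")
    return df[ATOM_COLUMNS]


def _gds_record(tag, data=b""):
    return struct.pack(">HH", len(data) + 4, tag) + data


def _gds_real8(value):
    """GDSII 8-byte real: sign, excess-64 base-16 exponent, 56-bit mantissa."""
    if value == 0:
        return b"\x00" * 8
    sign = 0x80 if value < 0 else 0
    v = abs(value)
    exp = 0
    while v >= 1.0:
        v /= 16.0
        exp += 1
    while v < 1.0 / 16.0:
        v *= 16.0
        exp -= 1
    mant = int(round(v * (1 << 56)))
    if mant >= 1 << 56:  # rounding overflow
        mant >>= 4
        exp += 1
    return bytes([sign | (exp + 64)]) + mant.to_bytes(7, "big")


def _write_gds(atoms: pd.DataFrame, path, n_vertices=64):
    """Minimal GDSII stream: one cell, one 64-gon boundary per atom, 1 nm db."""
    recs = [
        _gds_record(0x0002, struct.pack(">h", 600)),            # HEADER v600
        _gds_record(0x0102, struct.pack(">12h", *([0] * 12))),  # BGNLIB
        _gds_record(0x0206, b"CHIPLENS\0"),                     # LIBNAME
        # UNITS: db unit = 1e-3 user units (um), 1e-9 m
        _gds_record(0x0305, _gds_real8(1e-3) + _gds_real8(1e-9)),
        _gds_record(0x0502, struct.pack(">12h", *([0] * 12))),  # BGNSTR
        _gds_record(0x0606, b"METALENS"),                       # STRNAME
    ]
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    for _, a in atoms.iterrows():
        r = a["diameter_nm"] / 2.0
        xs = np.round(a["x_nm"] + r * np.cos(ang)).astype(np.int32)
        ys = np.round(a["y_nm"] + r * np.sin(ang)).astype(np.int32)
        xy = np.empty(2 * (n_vertices + 1), dtype=">i4")
        xy[0:-2:2], xy[1:-1:2] = xs, ys
        xy[-2], xy[-1] = xs[0], ys[0]
        recs += [
            _gds_record(0x0800),                                 # BOUNDARY
            _gds_record(0x0D02, struct.pack(">h", 1)),           # LAYER
            _gds_record(0x0E02, struct.pack(">h", 0)),           # DATATYPE
            _gds_record(0x1003, xy.tobytes()),                   # XY
            _gds_record(0x1100),                                 # ENDEL
        ]
    recs += [_gds_record(0x0700), _gds_record(0x0400)]           # ENDSTR/ENDLIB
    with open(path, "wb") as fh:
        fh.write(b"".join(recs))
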