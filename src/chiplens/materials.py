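"""Refractive-index dispersion, slab waveguide modes, and taper geometry.

The feeding waveguide of the on-chip metalens is a thin (100 nm) silicon
nitride layer clad in silica-on-glass (SOG).  Everything downstream of the
design needs three quantities from this module: the material index n(lambda)
of each layer, the TE0 effective index of the loaded slab (which sets the
guided propagation constant beta), and the taper half-width profile that
expands the narrow single-mode section to the metalens aperture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq


class DispersionRangeError(ValueError):
    """Wavelength outside the tabulated dispersion grid."""


class SlabCutoffError(ValueError):
    """No guided TE solution for the requested slab mode."""


class EvanescentOrderError(ValueError):
    """Grating equation yields |sin theta| > 1 (evanescent diffraction order)."""


class DegenerateDesignError(ValueError):
    """Waveguide phase slope does not exceed the lens phase slope."""


# ---------------------------------------------------------------------------
# Material dispersion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialDispersion:
    """Tabulated refractive index n(lambda) of one material.

    Parameters
    ----------
    name : str
        Material label.
    wavelength_nm : ndarray
        Strictly increasing wavelength grid in nm, covering at least
        450-800 nm for the packaged materials.
    n : ndarray
        Refractive index at each grid point, all >= 1.
    """

    name: str
    wavelength_nm: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        nn = np.asarray(self.n, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if nn.shape != wl.shape:
            raise ValueError("n and wavelength grids must have equal length")
        if np.any(nn < 1.0):
            raise ValueError("refractive index must be >= 1 everywhere")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "n", nn)

    def n_at(self, wavelength_nm):
        """Linear interpolation of n on the table; errors outside the grid."""
        lam = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise DispersionRangeError(
                f"{self.name}: wavelength outside table range "
                f"[{lo:g}, {hi:g}] nm"
            )
        out = np.interp(lam, self.wavelength_nm, self.n)
        return float(out) if np.isscalar(wavelength_nm) else out

    def __call__(self, wavelength_nm):
        return self.n_at(wavelength_nm)

    @classmethod
    def from_csv(cls, path, name=None):
        """Read a two-column CSV (wavelength_nm, n); header required."""
        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        if "wavelength_nm" not in cols or "n" not in cols:
            raise ValueError("material CSV needs 'wavelength_nm' and 'n' columns")
        df.columns = cols
        df = df.sort_values("wavelength_nm")
        return cls(name or str(path), df["wavelength_nm"].to_numpy(),
                   df["n"].to_numpy())

    def to_csv(self, path):
        pd.DataFrame({"wavelength_nm": self.wavelength_nm, "n": self.n}
                     ).to_csv(path, index=False)

    @classmethod
    def from_formula(cls, name, fn, lo_nm=380.0, hi_nm=900.0, step_nm=1.0):
        wl = np.arange(lo_nm, hi_nm + step_nm / 2, step_nm)
        return cls(name, wl, np.asarray([fn(w) for w in wl], dtype=float))


def _sellmeier(lam_um2, terms):
    s = 0.0
    for b, c in terms:
        s += b * lam_um2 / (lam_um2 - c)
    return np.sqrt(1.0 + s)


def silicon_nitride():
    """Stoichiometric Si3N4, Philipp (1973) single-term Sellmeier fit."""
    def n_of(wl_nm):
        l2 = (wl_nm * 1e-3) ** 2
        return _sellmeier(l2, [(2.8939, 0.13967 ** 2)])
    return MaterialDispersion.from_formula("Si3N4", n_of)


def silica():
    """Fused silica / SOG cladding, Malitson (1965) three-term Sellmeier."""
    terms = [(0.6961663, 0.0684043 ** 2),
             (0.4079426, 0.1162414 ** 2),
             (0.8974794, 9.896161 ** 2)]
    def n_of(wl_nm):
        return _sellmeier((wl_nm * 1e-3) ** 2, terms)
    return MaterialDispersion.from_formula("SiO2", n_of)


def water():
    """Water at 21.5 C, Daimon & Masumura (2007) four-term Sellmeier."""
    terms = [(5.684027565e-1, 5.101829712e-3),
             (1.726177391e-1, 1.821153936e-2),
             (2.086189578e-2, 2.620722293e-2),
             (1.130748688e-1, 1.069792721e1)]
    def n_of(wl_nm):
        return _sellmeier((wl_nm * 1e-3) ** 2, terms)
    return MaterialDispersion.from_formula("water", n_of)


def vacuum():
    wl = np.array([380.0, 900.0])
    return MaterialDispersion("vacuum", wl, np.ones(2))


def refractive_index(material: MaterialDispersion, wavelength_nm):
    """n(lambda) by linear interpolation on the material table."""
    return material.n_at(wavelength_nm)


# ---------------------------------------------------------------------------
# Slab modes and V parameter
# ---------------------------------------------------------------------------

def slab_te_index(wavelength_nm, thickness_nm, n_core, n_substrate,
                  n_cladding, mode=0, tol=1e-9):
    """TE effective index of an asymmetric three-layer slab.

    Solves the transcendental dispersion relation

        k0*t*sqrt(nc^2 - ne^2) = atan(sqrt((ne^2-ns^2)/(nc^2-ne^2)))
                               + atan(sqrt((ne^2-ncl^2)/(nc^2-ne^2))) + m*pi

    by bracketed root finding.  Raises :class:`SlabCutoffError` when the
    requested mode is not guided (distinct from a numerical failure).
    """
    if thickness_nm <= 0:
        raise ValueError("thickness must be positive")
    n_hi = max(n_substrate, n_cladding)
    if n_core <= n_hi:
        raise SlabCutoffError("core index does not exceed the claddings")
    k0t = 2.0 * np.pi / wavelength_nm * thickness_nm
    nc2, ns2, ncl2 = n_core ** 2, n_substrate ** 2, n_cladding ** 2

    def resid(ne):
        ne2 = ne * ne
        kap = np.sqrt(max(nc2 - ne2, 1e-300))
        t1 = np.arctan(np.sqrt(max(ne2 - ns2, 0.0)) / kap)
        t2 = np.arctan(np.sqrt(max(ne2 - ncl2, 0.0)) / kap)
        return k0t * kap - t1 - t2 - mode * np.pi

    eps = 1e-12 * n_core
    lo, hi = n_hi + eps, n_core - eps
    if resid(lo) <= 0.0:
        raise SlabCutoffError(
            f"TE{mode} below cutoff for t={thickness_nm} nm at "
            f"{wavelength_nm} nm"
        )
    # resid is monotone decreasing in ne over (n_hi, n_core); resid(hi) -> -m*pi
    # minus positive atan terms < 0 for any guided configuration.
    if resid(hi) >= 0.0:
        raise SlabCutoffError("no root bracketed (degenerate slab)")
    return brentq(resid, lo, hi, xtol=tol)


@dataclass(frozen=True)
class WaveguideSpec:
    """Planar SiN waveguide with taper.

    w1/w2 are the narrow/wide taper widths, w_h the SiN layer thickness,
    L_taper the taper length, m the taper shape exponent and h_SOG the
    upper-cladding thickness.  Defaults follow the 600 nm / 100 nm / 20 um
    geometry of the reference device.
    """

    w1_nm: float = 600.0
    w2_um: float = 20.0
    w_h_nm: float = 100.0
    L_taper_um: float = 40.0
    m: float = 1.15
    h_sog_um: float = 2.0
    core: MaterialDispersion = field(default_factory=silicon_nitride)
    substrate: MaterialDispersion = field(default_factory=silica)
    cladding: MaterialDispersion = field(default_factory=silica)

    def __post_init__(self):
        if not self.w1_nm < self.w2_um * 1e3:
            raise ValueError("w1 must be smaller than w2")
        if self.w_h_nm <= 0 or self.m <= 0 or self.h_sog_um < 0:
            raise ValueError("w_h > 0, m > 0, h_SOG >= 0 required")

    def effective_index(self, wavelength_nm, mode=0):
        """TE effective index of the w_h slab (substrate/core/SOG stack)."""
        return slab_te_index(
            wavelength_nm, self.w_h_nm,
            self.core.n_at(wavelength_nm),
            self.substrate.n_at(wavelength_nm),
            self.cladding.n_at(wavelength_nm),
            mode=mode,
        )

    def beta(self, wavelength_nm):
        """Propagation constant beta = 2*pi*n_eff/lambda in rad/nm."""
        return 2.0 * np.pi * self.effective_index(wavelength_nm) / wavelength_nm


def v_parameter(wavelength_nm, spec: WaveguideSpec):
    """Normalized frequency of the narrow rectangular feeding waveguide.

    V = (2*pi/lambda) * w * sqrt(n_wg^2 - n_clad^2) with the effective width
    w = sqrt(w1 * w_h) (geometric mean of the cross-section) and n_wg the TE0
    effective index of the w_h slab.  Single-mode operation requires
    V < 2.405.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    n_wg = spec.effective_index(wavelength_nm)
    n_clad = spec.cladding.n_at(wavelength_nm)
    w = np.sqrt(spec.w1_nm * spec.w_h_nm)
    contrast = n_wg ** 2 - n_clad ** 2
    return 2.0 * np.pi / wavelength_nm * w * np.sqrt(max(contrast, 0.0))


# ---------------------------------------------------------------------------
# Grating relation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GratingModel:
    """Outcoupling grating linking beta to the far-field angle.

    beta(lambda) = (2*pi*n_top/lambda)*sin(theta) + 2*pi/Lambda, with Lambda
    the grating period and n_top the refractive index of the top cladding.
    """

    period_nm: float = 365.0
    n_top: float = 1.46

    def __post_init__(self):
        if self.period_nm <= 0:
            raise ValueError("grating period must be positive")


def propagation_constant(wavelength_nm, theta_rad, grating: GratingModel):
    """beta in rad/nm from the measured outcoupling angle theta."""
    return (2.0 * np.pi * grating.n_top / wavelength_nm * np.sin(theta_rad)
            + 2.0 * np.pi / grating.period_nm)


def outcoupling_angle(beta_rad_nm, wavelength_nm, grating: GratingModel):
    """Inverse grating relation: theta from beta; errors when evanescent."""
    s = ((beta_rad_nm - 2.0 * np.pi / grating.period_nm) * wavelength_nm
         / (2.0 * np.pi * grating.n_top))
    if abs(s) > 1.0:
        raise EvanescentOrderError(f"|sin theta| = {abs(s):.3f} > 1")
    return float(np.arcsin(s))


# ---------------------------------------------------------------------------
# Taper profile
# ---------------------------------------------------------------------------

def taper_half_width(x_um, spec: WaveguideSpec):
    """Half-width y(x) of the taper in um.

    y = alpha*(L/2 - x)^m + w2/2 with alpha = (w1 - w2)/(2*L^m); x runs from
    -L/2 (narrow end, y = w1/2) to +L/2 (wide end, y = w2/2).
    """
    x = np.asarray(x_um, dtype=float)
    L = spec.L_taper_um
    if np.any(x < -L / 2 - 1e-12) or np.any(x > L / 2 + 1e-12):
        raise ValueError("x outside [-L_taper/2, L_taper/2]")
    w1, w2 = spec.w1_nm * 1e-3, spec.w2_um
    alpha = (w1 - w2) / (2.0 * L ** spec.m)
    y = alpha * np.clip(L / 2 - x, 0.0, None) ** spec.m + w2 / 2
    return float(y) if np.isscalar(x_um) else y
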