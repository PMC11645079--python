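"""Molecule detection efficiency, effective volume and photon budget.

Epi-fluorescence detection through the metalens multiplies the normalized
excitation point-spread function by the collection efficiency function (CEF),
the spectrum-weighted average of the detection PSFs over the emission band,
scaled by P_max, the peak fraction of an isotropic emitter's photons coupled
into the waveguide mode.  Because collection happens through a single TE0
mode, P_max can never exceed 1/3.  The resulting molecule detection
efficiency map MDE(x, y, z) = I_exc * CEF yields the effective detection
volume V_eff = pi^(3/2) * w_xy^2 * w_z and, together with the two-level
emission model N_F = MDE * psi * S1 * k_fl, the per-molecule count rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

from .propagation import PSFVolume

P_MAX_TE0 = 1.0 / 3.0


# ---------------------------------------------------------------------------
# Fluorophores and detection bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluorophoreSpec:
    """Fluorophore photophysics: spectra, quantum yield and lifetime.

    Spectra are tables (wavelength_nm, relative intensity >= 0), normalized
    to unit peak on construction.  ``quantum_yield`` is psi in (0, 1];
    ``lifetime_ns`` is tau_fl, with k_fl = 1/tau_fl.
    """

    name: str
    absorption: pd.DataFrame
    emission: pd.DataFrame
    quantum_yield: float
    lifetime_ns: float

    def __post_init__(self):
        for tag, df in (("absorption", self.absorption),
                        ("emission", self.emission)):
            if not {"wavelength_nm", "intensity"} <= set(df.columns):
                raise ValueError(f"{tag} table needs wavelength_nm, intensity")
            if (df["intensity"] < 0).any():
                raise ValueError(f"{tag} spectrum must be non-negative")
        if not 0.0 < self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must lie in (0, 1]")
        if self.lifetime_ns <= 0:
            raise ValueError("lifetime must be positive")
        for df in (self.absorption, self.emission):
            peak = df["intensity"].max()
            if peak > 0:
                df["intensity"] = df["intensity"] / peak
        if self.emission_peak_nm <= self.absorption_peak_nm:
            raise ValueError("Stokes shift must be positive")

    @property
    def k_fl(self):
        """Fluorescence rate constant in 1/s."""
        return 1.0 / (self.lifetime_ns * 1e-9)

    @property
    def absorption_peak_nm(self):
        i = int(self.absorption["intensity"].idxmax())
        return float(self.absorption.loc[i, "wavelength_nm"])

    @property
    def emission_peak_nm(self):
        i = int(self.emission["intensity"].idxmax())
        return float(self.emission.loc[i, "wavelength_nm"])

    @property
    def stokes_shift_nm(self):
        return self.emission_peak_nm - self.absorption_peak_nm

    def emission_at(self, wavelength_nm):
        df = self.emission
        return np.interp(np.asarray(wavelength_nm, dtype=float),
                         df["wavelength_nm"], df["intensity"],
                         left=0.0, right=0.0)

    @classmethod
    def from_csv(cls, path, name=None, quantum_yield=None, lifetime_ns=None):
        """Load spectra from a CSV with wavelength_nm, absorbance, emission.

        Either spectral column may be blank per row.  psi and tau_fl come
        from keyword arguments or a YAML sidecar (same stem, .yaml) with
        keys quantum_yield and lifetime_ns.
        """
        path = Path(path)
        df = pd.read_csv(path)
        if quantum_yield is None or lifetime_ns is None:
            sidecar = path.with_suffix(".yaml")
            meta = yaml.safe_load(sidecar.read_text())
            quantum_yield = quantum_yield or meta["quantum_yield"]
            lifetime_ns = lifetime_ns or meta["lifetime_ns"]
        ab = df[["wavelength_nm", "absorbance"]].dropna().rename(
            columns={"absorbance": "intensity"})
        em = df[["wavelength_nm", "emission"]].dropna().rename(
            columns={"emission": "intensity"})
        return cls(name or path.stem, ab.reset_index(drop=True),
                   em.reset_index(drop=True), quantum_yield, lifetime_ns)


@dataclass(frozen=True)
class DetectionBand:
    """Collection band around the detection wavelength."""

    center_nm: float
    half_width_nm: float = 20.0
    n_samples: int = 5

    def __post_init__(self):
        if self.half_width_nm < 0 or self.n_samples < 1:
            raise ValueError("invalid detection band")

    def wavelengths(self):
        if self.n_samples == 1 or self.half_width_nm == 0:
            return np.array([self.center_nm])
        return np.linspace(self.center_nm - self.half_width_nm,
                           self.center_nm + self.half_width_nm,
                           self.n_samples)


# ---------------------------------------------------------------------------
# CEF and MDE
# ---------------------------------------------------------------------------

@dataclass
class MDEMap:
    """Molecule-detection-efficiency grid aligned with the PSF volumes."""

    values: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    z_um: np.ndarray
    p_max: float

    def __post_init__(self):
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("MDE must lie in [0, 1]")

    @property
    def peak(self):
        return float(self.values.max())

    @property
    def peak_percent(self):
        return 100.0 * self.peak

    def peak_index(self):
        return np.unravel_index(int(np.argmax(self.values)),
                                self.values.shape)

    def to_hdf5(self, path, **attrs):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("intensity", data=self.values,
                              compression="gzip")
            ax = fh.create_group("axes")
            ax.create_dataset("x", data=self.x_nm)
            ax.create_dataset("y", data=self.y_nm)
            ax.create_dataset("z", data=self.z_um * 1e3)
            fh.attrs["P_max"] = self.p_max
            for k, v in attrs.items():
                fh.attrs[k] = v


def collection_efficiency(det_psfs: dict, fluor: FluorophoreSpec, p_max):
    """Spectrum-weighted CEF grid from detection PSFs over the band.

    ``det_psfs`` maps wavelength (nm) to a normalized :class:`PSFVolume`;
    the average uses trapezoidal quadrature with weights F(lambda) from the
    emission spectrum, then scales by P_max in (0, 1/3].
    """
    if not det_psfs:
        raise ValueError("need at least one detection PSF")
    if not 0.0 < p_max <= P_MAX_TE0 + 1e-12:
        raise ValueError("P_max must lie in (0, 1/3]")
    lams = np.array(sorted(det_psfs))
    weights = fluor.emission_at(lams)
    if weights.max() <= 1e-12:  # peak-normalized spectra
        raise ValueError("detection band outside the emission spectrum")
    shapes = {det_psfs[l].intensity.shape for l in lams}
    if len(shapes) != 1:
        raise ValueError("detection PSFs must share one grid")
    if lams.size == 1:
        avg = det_psfs[float(lams[0])].intensity
    else:
        stack = np.stack([det_psfs[float(l)].intensity for l in lams])
        num = np.trapezoid(weights[:, None, None, None] * stack, lams, axis=0)
        avg = num / np.trapezoid(weights, lams)
    return p_max * avg


def mde(i_exc: PSFVolume, cef: np.ndarray):
    """Pointwise product MDE = I_exc * CEF on the shared grid."""
    if i_exc.intensity.shape != cef.shape:
        raise ValueError("excitation PSF and CEF grids differ")
    p_max = float(cef.max())
    return MDEMap(i_exc.intensity * cef, i_exc.x_nm, i_exc.y_nm, i_exc.z_um,
                  p_max=p_max)


def p_max_proxy(det_metrics_encircled, cap=P_MAX_TE0):
    """Default P_max: (1/3) x encircled focal fraction at the detection
    wavelength, by reciprocity of outcoupling and collection."""
    return min(cap * det_metrics_encircled, cap)


# ---------------------------------------------------------------------------
# Effective volume
# ---------------------------------------------------------------------------

def _gauss(r, a, r0, w):
    return a * np.exp(-2.0 * (r - r0) ** 2 / w ** 2)


def _fit_waist(coords, profile, i_peak, floor=0.01):
    """1/e^2 radius of the main lobe through the peak."""
    peak = profile[i_peak]
    lo = i_peak
    while lo > 0 and profile[lo - 1] > floor * peak:
        lo -= 1
    hi = i_peak
    while hi < len(profile) - 1 and profile[hi + 1] > floor * peak:
        hi += 1
    c = np.asarray(coords[lo:hi + 1], dtype=float)
    p = np.asarray(profile[lo:hi + 1], dtype=float)
    sigma0 = max(np.sqrt(np.sum(p * (c - coords[i_peak]) ** 2) / np.sum(p)),
                 (c[1] - c[0]))
    popt, _ = curve_fit(_gauss, c, p,
                        p0=[peak, coords[i_peak], 2.0 * sigma0],
                        maxfev=10000)
    return abs(popt[2])


def effective_volume(mde_map: MDEMap, method="gaussian_fit"):
    """Effective detection volume in femtoliters.

    "gaussian_fit": V_eff = pi^(3/2) * w_xy^2 * w_z from 1/e^2 radii fitted
    to the axis profiles through the MDE peak (w_xy averages x and y).
    "integral": (integral MDE)^2 / integral MDE^2, exact for a Gaussian.
    On a fit failure the integral value is returned with a warning.
    """
    iz, iy, ix = mde_map.peak_index()
    dx_um = (mde_map.x_nm[1] - mde_map.x_nm[0]) * 1e-3
    dy_um = (mde_map.y_nm[1] - mde_map.y_nm[0]) * 1e-3
    dz_um = mde_map.z_um[1] - mde_map.z_um[0]
    v = mde_map.values
    integral = (float(v.sum()) ** 2 / float((v ** 2).sum())
                * dx_um * dy_um * dz_um)
    if method == "integral":
        return integral
    if method != "gaussian_fit":
        raise ValueError("method must be 'gaussian_fit' or 'integral'")
    try:
        wx = _fit_waist(mde_map.x_nm * 1e-3, v[iz, iy, :], ix)
        wy = _fit_waist(mde_map.y_nm * 1e-3, v[iz, :, ix], iy)
        wz = _fit_waist(mde_map.z_um, v[:, iy, ix], iz)
    except RuntimeError:
        import warnings
        warnings.warn("Gaussian waist fit failed; using integral V_eff")
        return integral
    w_xy = 0.5 * (wx + wy)
    return float(np.pi ** 1.5 * w_xy ** 2 * wz)


# ---------------------------------------------------------------------------
# Two-level photon budget
# ---------------------------------------------------------------------------

def excited_state_population(k_ex, k_fl):
    """Steady-state singlet population S1 = k_ex / (k_fl + k_ex)."""
    if k_ex <= 0 or k_fl <= 0:
        raise ValueError("rates must be positive")
    return k_ex / (k_fl + k_ex)


def count_rate(mde_peak, fluor: FluorophoreSpec, k_ex):
    """Detected photons per second per molecule at the MDE peak.

    N_F = MDE * psi * S1(k_ex, k_fl) * k_fl under the low-saturation
    two-level emission model (no photobleaching, no triplet shelving).
    """
    if not 0.0 < mde_peak <= 1.0:
        raise ValueError("MDE peak must lie in (0, 1]")
    s1 = excited_state_population(k_ex, fluor.k_fl)
    return mde_peak * fluor.quantum_yield * s1 * fluor.k_fl
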