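"""Synthetic fluorophore fixtures and design presets.

The three model fluorophores are emulated as Gaussian band profiles pinned to
their published peak positions: ATTO 490LS (absorption 496 nm, emission
661 nm, a 165 nm Stokes shift), Alexa Fluor 555 (absorption peaks at 520 and
553 nm, emission 568 nm) and the APC-Cy7 tandem (absorption 651 nm, emission
779 nm).  Quantum yields and lifetimes are nominal literature values; real
measured spectra can be loaded instead via FluorophoreSpec.from_csv.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .photophysics import FluorophoreSpec

# name -> (absorption peaks (nm, rel. height), emission peak nm, psi, tau_ns)
_FLUOROPHORES = {
    "atto490ls": ([(496.0, 1.0)], 661.0, 0.30, 2.6),
    "alexa555": ([(520.0, 0.6), (553.0, 1.0)], 568.0, 0.10, 0.3),
    "apc_cy7": ([(651.0, 1.0)], 779.0, 0.30, 1.0),
}

# name -> (excitation design wavelength, detection design wavelength)
DESIGN_WAVELENGTHS = {
    "atto490ls": (500.0, 660.0),
    "alexa555": (520.0, 570.0),
    "apc_cy7": (650.0, 780.0),
}

# published single-molecule FWHM / count-rate context for the three designs
FLUOROPHORE_NAMES = tuple(_FLUOROPHORES)


def _gaussian_bands(grid, peaks, sigma):
    """Envelope (element-wise max) of Gaussian bands.

    The max keeps every stated peak position a genuine local maximum even
    when bands overlap, which a plain sum would merge.
    """
    out = np.zeros_like(grid)
    for center, height in peaks:
        band = height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        out = np.maximum(out, band)
    return out / out.max()


def generate_fluorophore(name, sigma_abs_nm=25.0, sigma_em_nm=30.0,
                         lo_nm=380.0, hi_nm=950.0, step_nm=1.0):
    """Synthetic Gaussian-band FluorophoreSpec for a known model fluorophore.

    Raises a ValueError listing the available fixtures for unknown names.
    """
    key = name.lower().replace("-", "_").replace(" ", "")
    if key not in _FLUOROPHORES:
        raise ValueError(
            f"unknown fluorophore {name!r}; available: "
            + ", ".join(sorted(_FLUOROPHORES))
        )
    abs_peaks, em_peak, psi, tau = _FLUOROPHORES[key]
    grid = np.arange(lo_nm, hi_nm + step_nm / 2, step_nm)
    ab = pd.DataFrame({"wavelength_nm": grid,
                       "intensity": _gaussian_bands(grid, abs_peaks,
                                                    sigma_abs_nm)})
    em = pd.DataFrame({"wavelength_nm": grid,
                       "intensity": _gaussian_bands(grid, [(em_peak, 1.0)],
                                                    sigma_em_nm)})
    return FluorophoreSpec(key, ab, em, psi, tau)


def available_fluorophores():
    return sorted(_FLUOROPHORES)
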