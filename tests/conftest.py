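"""Shared fixtures: the three reference designs and their PSF volumes.

Full-aperture propagations are expensive, so everything downstream of the
design stage is built once per session and shared between the unit and
acceptance tests.
"""

import time

import numpy as np
import pytest

from chiplens import design as dsn
from chiplens import fixtures as fx
from chiplens import photophysics as ph
from chiplens import propagation as prop


@pytest.fixture(scope="session")
def reference_designs():
    """name -> dict(design, vol1, vol2, metrics1, metrics2, overlap)."""
    out = {}
    for name, (lam1, lam2) in fx.DESIGN_WAVELENGTHS.items():
        d = dsn.make_design(lambda1_nm=lam1, lambda2_nm=lam2)
        vols = {}
        elapsed = {}
        for lam in (lam1, lam2):
            t0 = time.perf_counter()
            f = prop.synthesize_aperture_field(d, lam)
            vols[lam] = prop.propagate_stack(f)
            elapsed[lam] = time.perf_counter() - t0
        out[name] = {
            "design": d,
            "lambdas": (lam1, lam2),
            "vol1": vols[lam1],
            "vol2": vols[lam2],
            "metrics1": prop.psf_metrics(vols[lam1]),
            "metrics2": prop.psf_metrics(vols[lam2]),
            "overlap": prop.focal_overlap(vols[lam1], vols[lam2]),
            "elapsed_s": elapsed,
        }
    return out


@pytest.fixture(scope="session")
def control_bundle():
    """Unsegmented (single-wavelength) 500 nm design evaluated at 500/660."""
    d = dsn.make_design(lambda1_nm=500.0, lambda2_nm=660.0, segmented=False)
    vols = {}
    for lam in (500.0, 660.0):
        f = prop.synthesize_aperture_field(d, lam)
        vols[lam] = prop.propagate_stack(f, z_min_um=4.0)
    return {
        "design": d,
        "vol1": vols[500.0],
        "vol2": vols[660.0],
        "metrics1": prop.psf_metrics(vols[500.0]),
        "overlap": prop.focal_overlap(vols[500.0], vols[660.0]),
    }


@pytest.fixture(scope="session")
def alexa_mde_bundle(reference_designs):
    """MDE chain for the 520/570 nm design with the Alexa 555 fixture."""
    ref = reference_designs["alexa555"]
    d = ref["design"]
    fluor = fx.generate_fluorophore("alexa555")
    band = ph.DetectionBand(570.0)
    dets = {}
    for lam in band.wavelengths():
        lam = float(lam)
        if np.isclose(lam, 570.0):
            dets[lam] = ref["vol2"]
        else:
            f = prop.synthesize_aperture_field(d, lam)
            dets[lam] = prop.propagate_stack(f)
    p_max = ph.p_max_proxy(ref["metrics2"].encircled_fraction)
    cef = ph.collection_efficiency(dets, fluor, p_max)
    mde_map = ph.mde(ref["vol1"], cef)
    return {
        "design": d,
        "fluor": fluor,
        "band": band,
        "p_max": p_max,
        "mde": mde_map,
        "v_eff_gauss_fl": ph.effective_volume(mde_map, "gaussian_fit"),
        "v_eff_integral_fl": ph.effective_volume(mde_map, "integral"),
    }


@pytest.fixture(scope="session")
def design_p_max(reference_designs):
    """P_max proxy per design (reciprocity: encircled fraction at lambda2)."""
    return {name: ph.p_max_proxy(ref["metrics2"].encircled_fraction)
            for name, ref in reference_designs.items()}
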