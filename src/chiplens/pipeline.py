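"""End-to-end orchestration: design -> PSFs -> MDE -> photon budget -> FCS.

A single YAML config drives the whole chain; every stage writes its
artifacts under the output directory and contributes to a machine-readable
summary JSON.  Given the same config and seed the summary is byte-identical
between runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import design as dsn
from . import fcs as fcsmod
from . import photophysics as ph
from . import propagation as prop
from .fixtures import DESIGN_WAVELENGTHS, generate_fluorophore
from .materials import WaveguideSpec

log = logging.getLogger("chiplens")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

_SCHEMA = {
    "seed": (int, 1),
    "output_dir": (str, "chiplens_out"),
    "log_level": (str, "INFO"),
    "fluorophore": (str, "alexa555"),
    "waveguide": (dict, {}),
    "design": (dict, {}),
    "propagation": (dict, {}),
    "detection_band": (dict, {}),
    "photophysics": (dict, {}),
    "fcs": (dict, {}),
}

_WAVEGUIDE_KEYS = {"w1_nm": 600.0, "w2_um": 20.0, "w_h_nm": 100.0,
                   "L_taper_um": 40.0, "m": 1.15, "h_sog_um": 2.0}
_DESIGN_KEYS = {"D_um": 20.0, "NA": 1.1, "F_um": None, "lambda1_nm": None,
                "lambda2_nm": None, "n_pairs": 5, "row_pitch_nm": 365.0,
                "atom_diameter_nm": 200.0, "atom_height_nm": 500.0,
                "segmented": True, "tol_rad": 1e-3,
                "input_phase": {"model": "cylindrical", "R_um": None}}
_PROP_KEYS = {"dx_nm": 50.0, "extent_um": 30.0, "z_min_um": 5.0,
              "z_max_um": 9.0, "z_step_nm": 25.0, "crop_half_um": 4.0}
_BAND_KEYS = {"center_nm": None, "half_width_nm": 20.0, "n_samples": 5}
_PHOTO_KEYS = {"k_ex_ratio": 0.1, "p_max": None}
_FCS_KEYS = {"enabled": True, "n_molecules": 300, "box_um": 2.4,
             "cell_nm": 50.0, "D_um2_s": 100.0, "dt_s": 1e-6,
             "bin_s": 2e-6, "duration_s": 30.0, "m": 16, "n_stages": 12,
             "n_blocks": 16}


def _merge(defaults, given, section):
    out = dict(defaults)
    for k, v in (given or {}).items():
        if k not in defaults:
            raise ConfigError(f"unknown key {k!r} in section {section!r}")
        if isinstance(defaults[k], dict) and isinstance(v, dict):
            out[k] = {**defaults[k], **v}
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring)."""

    seed: int = 1
    output_dir: str = "chiplens_out"
    log_level: str = "INFO"
    fluorophore: str = "alexa555"
    waveguide: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    propagation: dict = field(default_factory=dict)
    detection_band: dict = field(default_factory=dict)
    photophysics: dict = field(default_factory=dict)
    fcs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.waveguide = _merge(_WAVEGUIDE_KEYS, self.waveguide, "waveguide")
        self.design = _merge(_DESIGN_KEYS, self.design, "design")
        self.propagation = _merge(_PROP_KEYS, self.propagation, "propagation")
        self.detection_band = _merge(_BAND_KEYS, self.detection_band,
                                     "detection_band")
        self.photophysics = _merge(_PHOTO_KEYS, self.photophysics,
                                   "photophysics")
        self.fcs = _merge(_FCS_KEYS, self.fcs, "fcs")
        if self.design["lambda1_nm"] is None:
            lam1, lam2 = DESIGN_WAVELENGTHS[self.fluorophore]
            self.design["lambda1_nm"] = lam1
            if self.design["lambda2_nm"] is None:
                self.design["lambda2_nm"] = lam2
        if self.design["lambda2_nm"] is None:
            raise ConfigError("lambda2_nm must be set when lambda1_nm is")
        for sec in (self.waveguide, self.design, self.propagation,
                    self.detection_band, self.photophysics, self.fcs):
            for k, v in sec.items():
                if isinstance(v, (int, float)) and not isinstance(v, bool) \
                        and v is not None and k not in ("p_max",) and v < 0:
                    raise ConfigError(f"negative value for {k}")

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs = {}
        for key, (typ, default) in _SCHEMA.items():
            val = raw.get(key, default)
            if not isinstance(val, typ):
                raise ConfigError(f"{key} must be of type {typ.__name__}")
            kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path=None):
        d = {k: getattr(self, k) for k in _SCHEMA}
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def build_design(cfg: PipelineConfig):
    wgd = {k: v for k, v in cfg.waveguide.items()}
    wg = WaveguideSpec(w1_nm=wgd["w1_nm"], w2_um=wgd["w2_um"],
                       w_h_nm=wgd["w_h_nm"], L_taper_um=wgd["L_taper_um"],
                       m=wgd["m"], h_sog_um=wgd["h_sog_um"])
    d = cfg.design
    ipm = d["input_phase"]
    model = ipm.get("model", "cylindrical")
    return wg, dsn.make_design(
        waveguide=wg, d_um=d["D_um"], na=d["NA"], f_um=d["F_um"],
        lambda1_nm=d["lambda1_nm"], lambda2_nm=d["lambda2_nm"],
        n_pairs=d["n_pairs"], row_pitch_nm=d["row_pitch_nm"],
        tol=d["tol_rad"], diameter_nm=d["atom_diameter_nm"],
        height_nm=d["atom_height_nm"], input_phase=model,
        r_um=ipm.get("R_um"), segmented=d["segmented"],
    )


def propagate_design(design, cfg: PipelineConfig, wavelength_nm):
    p = cfg.propagation
    f = prop.synthesize_aperture_field(design, wavelength_nm,
                                       dx_nm=p["dx_nm"],
                                       extent_um=p["extent_um"])
    return prop.propagate_stack(f, h_sog_um=cfg.waveguide["h_sog_um"],
                                z_min_um=p["z_min_um"], z_max_um=p["z_max_um"],
                                z_step_nm=p["z_step_nm"],
                                crop_half_um=p["crop_half_um"])


def mde_stage(design, cfg: PipelineConfig, exc_vol=None):
    """Detection PSFs over the band, CEF, MDE map and effective volume."""
    fluor = generate_fluorophore(cfg.fluorophore)
    lam2 = cfg.design["lambda2_nm"]
    band = ph.DetectionBand(cfg.detection_band["center_nm"] or lam2,
                            cfg.detection_band["half_width_nm"],
                            cfg.detection_band["n_samples"])
    exc = exc_vol or propagate_design(design, cfg, cfg.design["lambda1_nm"])
    dets = {}
    for lam in band.wavelengths():
        dets[float(lam)] = (exc if np.isclose(lam, exc.wavelength_nm)
                            else propagate_design(design, cfg, float(lam)))
    lam_det = float(band.wavelengths()[len(band.wavelengths()) // 2])
    det_center = dets[lam_det]
    p_max = cfg.photophysics["p_max"]
    if p_max is None:
        p_max = ph.p_max_proxy(prop.psf_metrics(det_center).encircled_fraction)
    cef = ph.collection_efficiency(dets, fluor, p_max)
    mde_map = ph.mde(exc, cef)
    return {
        "fluorophore": fluor,
        "band": band,
        "exc": exc,
        "detection_psfs": dets,
        "p_max": p_max,
        "mde": mde_map,
        "v_eff_gauss_fl": ph.effective_volume(mde_map, "gaussian_fit"),
        "v_eff_integral_fl": ph.effective_volume(mde_map, "integral"),
    }


def mde_to_lattice(mde_map: ph.MDEMap, fcs_cfg: fcsmod.DiffusionSimConfig):
    """Resample the MDE map onto the FCS box lattice, centered on its peak."""
    n = fcs_cfg.n_cells
    cell = fcs_cfg.cell_nm
    iz, iy, ix = mde_map.peak_index()
    cx = (np.arange(n) - (n - 1) / 2.0) * cell + mde_map.x_nm[ix]
    cy = (np.arange(n) - (n - 1) / 2.0) * cell + mde_map.y_nm[iy]
    cz = (np.arange(n) - (n - 1) / 2.0) * cell * 1e-3 + mde_map.z_um[iz]
    jx = np.clip(np.round((cx - mde_map.x_nm[0])
                          / (mde_map.x_nm[1] - mde_map.x_nm[0])), 0,
                 mde_map.x_nm.size - 1).astype(int)
    jy = np.clip(np.round((cy - mde_map.y_nm[0])
                          / (mde_map.y_nm[1] - mde_map.y_nm[0])), 0,
                 mde_map.y_nm.size - 1).astype(int)
    jz = np.clip(np.round((cz - mde_map.z_um[0])
                          / (mde_map.z_um[1] - mde_map.z_um[0])), 0,
                 mde_map.z_um.size - 1).astype(int)
    vals = mde_map.values[np.ix_(jz, jy, jx)]  # (z, y, x)
    out_of_z = (cz < mde_map.z_um[0]) | (cz > mde_map.z_um[-1])
    vals[out_of_z, :, :] = 0.0
    return np.ascontiguousarray(np.transpose(vals, (2, 1, 0)))  # (x, y, z)


def fcs_stage(mde_map, peak_rate, cfg: PipelineConfig):
    f = cfg.fcs
    sim = fcsmod.DiffusionSimConfig(
        n_molecules=f["n_molecules"], box_um=f["box_um"], cell_nm=f["cell_nm"],
        d_um2_s=f["D_um2_s"], dt_s=f["dt_s"], duration_s=f["duration_s"],
        bin_s=f["bin_s"], seed=cfg.seed,
    )
    lattice = mde_to_lattice(mde_map, sim)
    trace = fcsmod.simulate_intensity_trace(sim, lattice, peak_rate)
    curve = fcsmod.autocorrelate(trace, m=f["m"], n_stages=f["n_stages"],
                                 n_blocks=f["n_blocks"])
    fit = fcsmod.fit_3d_diffusion(curve)
    return sim, trace, curve, fit


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir=None):
    """Execute all stages; returns the summary dict and writes artifacts.

    A stage failure aborts with the stage name in the exception while
    artifacts of completed stages stay on disk.
    """
    out = Path(outdir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    summary = {"config": yaml.safe_load(cfg.to_yaml()), "stages": {}}
    stage = "design"
    try:
        t0 = time.perf_counter()
        wg, design = build_design(cfg)
        design.validate(cfg.design["tol_rad"])
        dsn.export_layout(design, out / "layout.csv")
        summary["stages"]["design"] = {
            "n_atoms": int(len(design.atoms)),
            "F_um": round(design.lens.f_um, 6),
            "NA": round(design.lens.na, 6),
        }
        log.info("design: %d atoms (%.1f s)", len(design.atoms),
                 time.perf_counter() - t0)

        stage = "propagation"
        t0 = time.perf_counter()
        lam1, lam2 = cfg.design["lambda1_nm"], cfg.design["lambda2_nm"]
        vol1 = propagate_design(design, cfg, lam1)
        vol2 = propagate_design(design, cfg, lam2)
        vol1.to_hdf5(out / f"psf_{int(lam1)}nm.h5")
        vol2.to_hdf5(out / f"psf_{int(lam2)}nm.h5")
        m1, m2 = prop.psf_metrics(vol1), prop.psf_metrics(vol2)
        ov = prop.focal_overlap(vol1, vol2)
        summary["stages"]["propagation"] = {
            "fwhm_x_nm": {str(int(lam1)): round(m1.fwhm_x_nm, 2),
                          str(int(lam2)): round(m2.fwhm_x_nm, 2)},
            "fwhm_y_nm": {str(int(lam1)): round(m1.fwhm_y_nm, 2),
                          str(int(lam2)): round(m2.fwhm_y_nm, 2)},
            "z_focus_um": {str(int(lam1)): round(m1.z_focus_um, 4),
                           str(int(lam2)): round(m2.z_focus_um, 4)},
            "dz_focus_nm": round(ov.dz_um * 1e3, 2),
            "lateral_offset_nm": round(ov.lateral_offset_nm, 2),
            "overlap_integral": round(ov.overlap_integral, 4),
        }
        log.info("propagation: dz=%.1f nm (%.1f s)", ov.dz_um * 1e3,
                 time.perf_counter() - t0)

        stage = "mde"
        t0 = time.perf_counter()
        res = mde_stage(design, cfg, exc_vol=vol1 if np.isclose(
            lam1, cfg.design["lambda1_nm"]) else None)
        mde_map = res["mde"]
        mde_map.to_hdf5(out / "mde.h5", V_eff_fl=res["v_eff_gauss_fl"])
        fluor = res["fluorophore"]
        k_ex = cfg.photophysics["k_ex_ratio"] * fluor.k_fl
        n_f = ph.count_rate(mde_map.peak, fluor, k_ex)
        summary["stages"]["mde"] = {
            "p_max": round(res["p_max"], 6),
            "peak_mde_percent": round(mde_map.peak_percent, 5),
            "v_eff_gauss_fl": round(res["v_eff_gauss_fl"], 5),
            "v_eff_integral_fl": round(res["v_eff_integral_fl"], 5),
            "count_rate_kcps": round(n_f / 1e3, 3),
            "s1_bar": round(ph.excited_state_population(k_ex, fluor.k_fl), 6),
        }
        log.info("mde: V_eff=%.3f fl, N_F=%.2f kcps",
                 res["v_eff_gauss_fl"], n_f / 1e3)

        if cfg.fcs["enabled"]:
            stage = "fcs"
            t0 = time.perf_counter()
            sim, trace, curve, fit = fcs_stage(mde_map, n_f, cfg)
            trace.to_csv(out / "trace.csv")
            curve.to_csv(out / "correlation.csv")
            (out / "fcs_fit.json").write_text(fit.to_json())
            summary["stages"]["fcs"] = {
                "concentration_nM": round(fcsmod.concentration_nM(sim), 3),
                "mean_rate_cps": round(trace.mean_rate, 1),
                "fit_n": round(fit.n, 4),
                "fit_tau_d_us": round(fit.tau_d_s * 1e6, 3),
                "fit_success": fit.success,
            }
            log.info("fcs: N=%.2f tau_D=%.1f us", fit.n, fit.tau_d_s * 1e6)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    # deterministic serialization: fixed key order, fixed float rounding
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary
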