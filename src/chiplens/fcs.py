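"""Monte Carlo diffusion FCS through the metalens detection volume.

Molecules hop on a cubic lattice (50 nm cells) inside a periodic box,
emulating isotropic Brownian diffusion; each hop direction occurs with
probability p = D*dt/cell^2 per axis per step, so the per-axis displacement
variance is the Einstein 2*D*dt.  Photon counts per time bin are Poisson
draws around the sum of per-molecule brightness, peak rate times the
normalized detection efficiency at the molecule's cell.  Intensity traces
are autocorrelated with a multi-tau scheme and fitted with the 3D-diffusion
FCS model

    G(tau) = G_inf + (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(s^2*tau_D))^-1/2

yielding the mean occupancy N and diffusion time tau_D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import lmfit
import numpy as np
import pandas as pd
from numba import njit

AVOGADRO = 6.02214076e23


class TimeStepError(ValueError):
    """Hop probability p = D*dt/cell^2 exceeds the physical 0.25 bound."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionSimConfig:
    """Monte Carlo FCS experiment settings.

    Defaults reproduce the reference simulation conditions: 300 molecules in
    a periodic (2.4 um)^3 box of 50 nm unit cells observed for 30 s.  The
    diffusion coefficient (100 um^2/s, a small free dye) and the 1 us step /
    2 us bin are configurable model choices.
    """

    n_molecules: int = 300
    box_um: float = 2.4
    cell_nm: float = 50.0
    d_um2_s: float = 100.0
    dt_s: float = 1e-6
    duration_s: float = 30.0
    bin_s: float = 2e-6
    seed: int = 1

    def __post_init__(self):
        n_cells = self.box_um * 1e3 / self.cell_nm
        if abs(n_cells - round(n_cells)) > 1e-9:
            raise ValueError("box edge must be an integer number of cells")
        if self.hop_p > 0.25:
            raise TimeStepError(
                f"p = D*dt/cell^2 = {self.hop_p:.3f} > 0.25; reduce dt"
            )
        if self.bin_s < self.dt_s:
            raise ValueError("bin time must be >= dt")
        spb = self.bin_s / self.dt_s
        if abs(spb - round(spb)) > 1e-9:
            raise ValueError("bin time must be an integer multiple of dt")
        if self.n_bins < 1e4:
            raise ValueError("need at least 1e4 bins for correlation analysis")

    @property
    def n_cells(self):
        return int(round(self.box_um * 1e3 / self.cell_nm))

    @property
    def hop_p(self):
        """Per-direction hop probability per axis per step."""
        return self.d_um2_s * self.dt_s / (self.cell_nm * 1e-3) ** 2

    @property
    def n_steps(self):
        return int(round(self.duration_s / self.dt_s))

    @property
    def steps_per_bin(self):
        return int(round(self.bin_s / self.dt_s))

    @property
    def n_bins(self):
        return self.n_steps // self.steps_per_bin


def concentration_nM(cfg: DiffusionSimConfig):
    """Molar concentration of the box in nanomoles per liter."""
    vol_l = (cfg.box_um * 1e-6) ** 3 * 1e3  # m^3 -> L
    return cfg.n_molecules / (vol_l * AVOGADRO) * 1e9


def _molecule_seed(master_seed, mol):
    """Independent per-molecule stream seed (stable under n_molecules)."""
    return (int(master_seed) * 1000003 + 7919 * mol + 12345) % 2147483647


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

_U53 = 1.0 / (1 << 53)


@njit(cache=True)
def _splitmix64(state):
    """One splitmix64 output and the advanced state (seeding helper)."""
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(-1)
    z = state
    z = ((z ^ (z >> np.uint64(30)))
         * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(-1)
    z = ((z ^ (z >> np.uint64(27)))
         * np.uint64(0x94D049BB133111EB)) & np.uint64(-1)
    return z ^ (z >> np.uint64(31)), state


@njit(cache=True)
def _xs128p(s0, s1):
    """xorshift128+ step: returns (u in [0,1), new s0, new s1)."""
    r = (s0 + s1) & np.uint64(-1)
    t = s1 ^ ((s1 << np.uint64(23)) & np.uint64(-1))
    new_s1 = t ^ s0 ^ (t >> np.uint64(17)) ^ (s0 >> np.uint64(26))
    return (r >> np.uint64(11)) * _U53, s1, new_s1


def _hop_tables(p):
    """Cumulative thresholds and displacements of the 26 moving outcomes.

    A single uniform decides the joint (dx, dy, dz) hop: the all-stay
    outcome occupies [0, (1-2p)^3) as a fast path; the remainder is decoded
    against the conditional cumulative table, ordered most-probable-first.
    """
    q = 1.0 - 2.0 * p
    outcomes = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                prob = 1.0
                for d in (dx, dy, dz):
                    prob *= q if d == 0 else p
                outcomes.append((prob, dx, dy, dz))
    outcomes.sort(key=lambda t: (-t[0], t[1:]))
    probs = np.array([o[0] for o in outcomes])
    total = probs.sum()  # == 1 - q^3
    cum = np.cumsum(probs / total)
    cum[-1] = 1.0 + 1e-12
    d = np.array([o[1:] for o in outcomes], dtype=np.int64)
    return q ** 3, cum, d[:, 0].copy(), d[:, 1].copy(), d[:, 2].copy()


@njit(cache=True)
def _init_molecule(seed, n_cells):
    s0, st = _splitmix64(np.uint64(seed))
    s1, st = _splitmix64(st)
    u, s0, s1 = _xs128p(s0, s1)
    x = np.int64(u * n_cells)
    u, s0, s1 = _xs128p(s0, s1)
    y = np.int64(u * n_cells)
    u, s0, s1 = _xs128p(s0, s1)
    z = np.int64(u * n_cells)
    return s0, s1, x, y, z


@njit(cache=True)
def _trajectory_kernel(seed, n_steps, p_stay3, cum, dxs, dys, dzs, n_cells,
                       store_every, out):
    s0, s1, x, y, z = _init_molecule(seed, n_cells)
    k = 0
    for s in range(n_steps):
        u, s0, s1 = _xs128p(s0, s1)
        if u >= p_stay3:
            w = (u - p_stay3) / (1.0 - p_stay3)
            i = 0
            while w > cum[i]:
                i += 1
            x += dxs[i]
            y += dys[i]
            z += dzs[i]
        if (s + 1) % store_every == 0:
            out[k, 0] = x
            out[k, 1] = y
            out[k, 2] = z
            k += 1
    return k


@njit(cache=True)
def _photon_kernel(seed, n_bins, steps_per_bin, p_stay3, cum, dxs, dys, dzs,
                   n_cells, mde, rate_dt, expected):
    """One molecule's expected-count contribution, accumulated per bin.

    Positions wrap periodically; the (wrapped) lattice cell indexes the
    normalized MDE grid, which spans the whole box.
    """
    s0, s1, x, y, z = _init_molecule(seed, n_cells)
    x %= n_cells
    y %= n_cells
    z %= n_cells
    for b in range(n_bins):
        acc = 0.0
        for _ in range(steps_per_bin):
            u, s0, s1 = _xs128p(s0, s1)
            if u >= p_stay3:
                w = (u - p_stay3) / (1.0 - p_stay3)
                i = 0
                while w > cum[i]:
                    i += 1
                x += dxs[i]
                y += dys[i]
                z += dzs[i]
                if x < 0:
                    x += n_cells
                elif x >= n_cells:
                    x -= n_cells
                if y < 0:
                    y += n_cells
                elif y >= n_cells:
                    y -= n_cells
                if z < 0:
                    z += n_cells
                elif z >= n_cells:
                    z -= n_cells
            acc += mde[x, y, z]
        expected[b] += rate_dt * acc


# ---------------------------------------------------------------------------
# Trajectories and photon traces
# ---------------------------------------------------------------------------

def simulate_trajectories(cfg: DiffusionSimConfig, store_every=1,
                          wrap=True):
    """Lattice random-walk positions, (n_molecules, n_stored, 3), in cells.

    With ``wrap=False`` the unwrapped coordinates are returned (for
    mean-square-displacement analysis); photon generation always uses the
    periodic box.  Each molecule runs on its own seeded stream, so adding
    molecules never reshuffles existing trajectories.
    """
    n_stored = cfg.n_steps // store_every
    p_stay3, cum, dxs, dys, dzs = _hop_tables(cfg.hop_p)
    out = np.empty((cfg.n_molecules, n_stored, 3), dtype=np.int64)
    buf = np.empty((n_stored, 3), dtype=np.int64)
    for mol in range(cfg.n_molecules):
        _trajectory_kernel(_molecule_seed(cfg.seed, mol), cfg.n_steps,
                           p_stay3, cum, dxs, dys, dzs, cfg.n_cells,
                           store_every, buf)
        out[mol] = buf
    if wrap:
        out %= cfg.n_cells
    return out


@dataclass(frozen=True)
class IntensityTrace:
    bin_s: float
    counts: np.ndarray

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def mean_rate(self):
        return float(self.counts.mean() / self.bin_s)

    def to_csv(self, path):
        t = np.arange(self.counts.size) * self.bin_s
        pd.DataFrame({"time_s": t, "counts": self.counts}
                     ).to_csv(path, index=False)


def _normalize_mde_lattice(mde_lattice, n_cells):
    g = np.ascontiguousarray(np.asarray(mde_lattice, dtype=np.float64))
    if g.shape != (n_cells,) * 3:
        raise ValueError(
            f"MDE lattice must be {(n_cells,)*3}, got {g.shape}"
        )
    peak = g.max()
    if peak <= 0:
        raise ValueError("MDE lattice must have positive peak")
    return g / peak


def photon_trace(trajectories, mde_lattice, peak_rate, cfg: DiffusionSimConfig):
    """Poisson photon counts per bin from explicit (wrapped) trajectories.

    ``trajectories`` must be sampled every step (shape (n_mol, n_steps, 3));
    per-bin expected counts sum peak_rate * MDE_norm(cell) * dt over
    molecules and steps.
    """
    if cfg.bin_s < cfg.dt_s:
        raise ValueError("bin time must be >= dt")
    g = _normalize_mde_lattice(mde_lattice, cfg.n_cells)
    pos = np.asarray(trajectories) % cfg.n_cells
    per_step = g[pos[..., 0], pos[..., 1], pos[..., 2]].sum(axis=0)
    n_full = (per_step.size // cfg.steps_per_bin) * cfg.steps_per_bin
    expected = (peak_rate * cfg.dt_s
                * per_step[:n_full].reshape(-1, cfg.steps_per_bin).sum(axis=1))
    rng = np.random.default_rng((cfg.seed * 2654435761 + 97) % 2**31)
    return IntensityTrace(cfg.bin_s, rng.poisson(expected))


def simulate_intensity_trace(cfg: DiffusionSimConfig, mde_lattice, peak_rate):
    """Streamed end-to-end photon trace at full scale (no stored paths).

    Equivalent to simulate_trajectories + photon_trace but O(1) in memory;
    per-molecule streams are identical to the trajectory path.
    """
    g = _normalize_mde_lattice(mde_lattice, cfg.n_cells)
    p_stay3, cum, dxs, dys, dzs = _hop_tables(cfg.hop_p)
    expected = np.zeros(cfg.n_bins, dtype=np.float64)
    for mol in range(cfg.n_molecules):
        _photon_kernel(_molecule_seed(cfg.seed, mol), cfg.n_bins,
                       cfg.steps_per_bin, p_stay3, cum, dxs, dys, dzs,
                       cfg.n_cells, g, peak_rate * cfg.dt_s, expected)
    rng = np.random.default_rng((cfg.seed * 2654435761 + 97) % 2**31)
    return IntensityTrace(cfg.bin_s, rng.poisson(expected))


# ---------------------------------------------------------------------------
# Multi-tau autocorrelation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationCurve:
    lag_s: np.ndarray
    g: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lags must be strictly increasing")

    def to_csv(self, path):
        pd.DataFrame({"lag_s": self.lag_s, "G": self.g, "se": self.se}
                     ).to_csv(path, index=False)


def _multitau_single(x, bin_s, m, n_stages):
    """Multi-tau G(tau) of one trace with symmetric normalization."""
    x = np.asarray(x, dtype=np.float64)
    lags, gs = [], []
    level_bin = bin_s
    for stage in range(n_stages):
        ks = range(1, m + 1) if stage == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            n = x.size - k
            if n < 2:
                break
            left = x[:n]
            right = x[k:]
            denom = left.mean() * right.mean()
            if denom == 0:
                raise ZeroDivisionError(
                    "zero-mean trace: correlation normalization undefined"
                )
            lags.append(k * level_bin)
            gs.append(float(left @ right) / n / denom - 1.0)
        n_pairs = x.size // 2
        if n_pairs < 2 * m:
            break
        x = 0.5 * (x[: 2 * n_pairs : 2] + x[1 : 2 * n_pairs : 2])
        level_bin *= 2.0
    return np.asarray(lags), np.asarray(gs)


def autocorrelate(trace: IntensityTrace, m=16, n_stages=12, n_blocks=16):
    """Multi-tau autocorrelation with block-averaged standard errors.

    The trace is rebinned by 2 at every stage beyond the first, giving
    quasi-logarithmic lag spacing; G(tau) = <dI(t) dI(t+tau)>/<I>^2.
    Standard errors come from the scatter of per-block correlations over
    ``n_blocks`` contiguous trace segments.
    """
    counts = np.asarray(trace.counts, dtype=np.float64)
    if counts.size < 2 * m:
        raise ValueError("trace too short for the correlator")
    if counts.mean() == 0:
        raise ZeroDivisionError("zero-mean trace: normalization undefined")
    lag, g = _multitau_single(counts, trace.bin_s, m, n_stages)
    se = np.full(lag.size, np.nan)
    blk = counts.size // n_blocks
    if blk >= 2 * m and n_blocks >= 2:
        bg = []
        for b in range(n_blocks):
            seg = counts[b * blk:(b + 1) * blk]
            if seg.mean() == 0:
                continue
            bl, bgv = _multitau_single(seg, trace.bin_s, m, n_stages)
            bg.append((bl, bgv))
        if len(bg) >= 2:
            n_common = min(len(b[1]) for b in bg)
            mat = np.stack([b[1][:n_common] for b in bg])
            se[:n_common] = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return CorrelationCurve(lag, g, se)


# ---------------------------------------------------------------------------
# 3D diffusion model fit
# ---------------------------------------------------------------------------

def g_diffusion_3d(lag_s, n, tau_d, s_ratio, g_inf=0.0):
    """3D free-diffusion FCS model."""
    tau = np.asarray(lag_s, dtype=float)
    return (g_inf + (1.0 / n) / (1.0 + tau / tau_d)
            / np.sqrt(1.0 + tau / (s_ratio ** 2 * tau_d)))


@dataclass
class FCSFit:
    n: float
    tau_d_s: float
    s_ratio: float
    g_inf: float
    covar: np.ndarray
    success: bool
    message: str
    residual_rms: float

    def to_json(self, path=None):
        d = asdict(self)
        d["covar"] = None if self.covar is None else np.asarray(
            self.covar).tolist()
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_3d_diffusion(curve: CorrelationCurve, init=None, vary_s=False,
                     max_lag_s=None, weights="uniform"):
    """Nonlinear least-squares fit of the 3D diffusion model.

    ``init`` may provide n, tau_d_s, s_ratio, g_inf starting values; missing
    entries are seeded from the curve (amplitude and half-decay lag).  The
    axial/lateral aspect s is fixed by default, as is standard when it is
    known from the detection-volume calibration.  ``weights`` is "uniform"
    (default) or "se": block-averaged errors of a multi-tau curve are
    strongly cross-correlated at the long rebinned lags, and weighting by
    them systematically drags tau_D down, so they are reported but not used
    unless requested.  Non-convergence is reported on the returned object,
    never silently replaced.
    """
    sel = np.isfinite(curve.g)
    if max_lag_s is not None:
        sel &= curve.lag_s <= max_lag_s
    lag, g = curve.lag_s[sel], curve.g[sel]
    if lag.size < 10:
        raise ValueError("need >= 10 lags to fit the 3D diffusion model")
    if weights == "se":
        se = curve.se[sel]
        w = np.where(np.isfinite(se) & (se > 0),
                     1.0 / np.where(se > 0, se, 1.0), 0.0)
        if not np.any(w > 0):
            w = np.ones_like(lag)
    elif weights == "uniform":
        w = np.ones_like(lag)
    else:
        raise ValueError("weights must be 'uniform' or 'se'")
    init = dict(init or {})
    g0 = max(float(np.mean(g[:3])), 1e-6)
    n0 = init.get("n", 1.0 / g0)
    half = g0 / 2.0
    below = np.nonzero(g < half)[0]
    tau0 = init.get("tau_d_s", lag[below[0]] if below.size else lag[-1] / 10)
    params = lmfit.Parameters()
    params.add("n", value=n0, min=1e-6)
    params.add("tau_d", value=tau0, min=1e-12)
    params.add("s_ratio", value=init.get("s_ratio", 5.0), min=1.0,
               vary=vary_s)
    params.add("g_inf", value=init.get("g_inf", 0.0))

    def resid(p):
        model = g_diffusion_3d(lag, p["n"].value, p["tau_d"].value,
                               p["s_ratio"].value, p["g_inf"].value)
        return (g - model) * w

    res = lmfit.minimize(resid, params, method="leastsq")
    model = g_diffusion_3d(lag, res.params["n"].value,
                           res.params["tau_d"].value,
                           res.params["s_ratio"].value,
                           res.params["g_inf"].value)
    rms = float(np.sqrt(np.mean((g - model) ** 2)))
    return FCSFit(
        n=float(res.params["n"].value),
        tau_d_s=float(res.params["tau_d"].value),
        s_ratio=float(res.params["s_ratio"].value),
        g_inf=float(res.params["g_inf"].value),
        covar=res.covar,
        success=bool(res.success),
        message=res.message,
        residual_rms=rms,
    )


# ---------------------------------------------------------------------------
# SNR vs brightness
# ---------------------------------------------------------------------------

def snr_vs_brightness(cfg: DiffusionSimConfig, mde_lattice, rates,
                      fit_init=None, max_lag_s=None):
    """Correlation-noise table across per-molecule brightness values.

    Re-runs the identical seeded simulation for each peak rate and reports
    the rms residual of G about its 3D-diffusion fit; shot-noise-limited
    correlation noise scales inversely with the count rate.
    """
    rates = list(rates)
    if len(rates) < 2:
        raise ValueError("need at least two rates")
    rows = []
    for rate in rates:
        if rate <= 0:
            raise ValueError("rates must be positive (zero rate degenerate)")
        trace = simulate_intensity_trace(cfg, mde_lattice, rate)
        curve = autocorrelate(trace)
        fit = fit_3d_diffusion(curve, init=fit_init, max_lag_s=max_lag_s)
        rows.append({"peak_rate_cps": rate,
                     "mean_rate_cps": trace.mean_rate,
                     "g_noise_rms": fit.residual_rms,
                     "fit_n": fit.n, "fit_tau_d_s": fit.tau_d_s})
    return pd.DataFrame(rows)


def gaussian_mde_lattice(cfg: DiffusionSimConfig, w_xy_um, w_z_um):
    """Synthetic 3D-Gaussian detection volume on the box lattice.

    1/e^2 radii w_xy (lateral) and w_z (axial); V_eff = pi^1.5*w_xy^2*w_z.
    """
    n = cfg.n_cells
    c = (np.arange(n) - (n - 1) / 2.0) * cfg.cell_nm * 1e-3
    r2 = c[:, None, None] ** 2 + c[None, :, None] ** 2
    g = np.exp(-2.0 * r2 / w_xy_um ** 2
               - 2.0 * c[None, None, :] ** 2 / w_z_um ** 2)
    return g
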