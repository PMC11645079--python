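# chiplens

Design and evaluation toolkit for **dual-wavelength on-chip metalenses** used
for epi-fluorescence single-molecule sensing. A metalens here is an array of
silicon nitride nanoposts standing on a planar SiN waveguide: each post
scatters the guided TE0 wave into free space, and posts are placed where the
accumulated guided phase equals a focusing lens phase, so the lens focuses
light out of the chip into the sample. Because both the excitation and the
fluorescence travel through the same lens, single-molecule detection needs
the focal volumes at the two wavelengths of a fluorophore — excitation and
emission — to overlap, which a single-phase on-chip lens cannot achieve:
the wavelength-dependent propagation constant shifts the focus laterally as
well as axially. `chiplens` implements the segmented remedy: the aperture
is tiled into alternating stripes, one family phase-matched at λ₁, the
other at λ₂, producing a common focus for both.

The package covers the full evaluation chain a designer needs:

1. **Waveguide optics** — material dispersion (SiN/SiO₂/water), TE0
   effective slab index, propagation constant β(λ) (with the
   grating-relation cross-check β = (2πn/λ)sinθ + 2π/Λ), single-mode
   V parameter, taper profile.
2. **Metalens design** — lens phase φ_lens = (2πn/λ)(F − √(F² + x² + y²))
   with NA = n·sin(arctan(D/2F)); meta-atom placement at the roots of
   wrap(φ_wg − φ_lens) per stripe; CSV/GDSII export.
3. **Scalar PSFs** — band-limited angular-spectrum propagation of the
   synthesized aperture field through the SOG cladding into water; focal
   FWHM, focal height, encircled fraction, dual-wavelength overlap.
4. **Molecule detection efficiency** — MDE = I_exc · CEF with the
   spectrum-weighted collection efficiency over a detection band (Eq.-level
   P_max ≤ 1/3 for a single TE0 mode); effective volume
   V_eff = π^{3/2} w_xy² w_z; photon budget N_F = MDE·ψ·S̄₁·k_fl with
   S̄₁ = k_ex/(k_fl + k_ex).
5. **FCS simulation** — Monte Carlo lattice diffusion (300 molecules,
   (2.4 µm)³ periodic box, 50 nm cells), Poisson photon traces, multi-tau
   autocorrelation, and 3D-diffusion model fits
   G(τ) = G_inf + (1/N)(1 + τ/τ_D)⁻¹(1 + τ/(s²τ_D))^{−1/2}.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Design the Alexa 555 lens (520/570 nm), check its focus, and run a 2 s FCS
simulation through its detection volume:

```python
import chiplens as cl

design = cl.make_design(lambda1_nm=520, lambda2_nm=570)   # D=20 um, NA=1.1
print(len(design.atoms), round(design.lens.f_um, 2))      # 3203 6.8

field = cl.synthesize_aperture_field(design, 520)
vol520 = cl.propagate_stack(field)                        # 2 um SOG + water
vol570 = cl.propagate_stack(cl.synthesize_aperture_field(design, 570))
m = cl.psf_metrics(vol520)
ov = cl.focal_overlap(vol520, vol570)
print(round(m.fwhm_x_nm), round(m.fwhm_y_nm), round(m.z_focus_um, 2))
#   243 216 7.08   <- lateral FWHM (nm) and focal height (um) at 520 nm
print(round(ov.dz_um * 1e3, 1), round(ov.lateral_offset_nm, 1))
#   10.5 1.6       <- the two foci coincide to ~10 nm axially, ~2 nm laterally

cfg = cl.DiffusionSimConfig(duration_s=2.0, seed=1)       # 300 molecules, 36 nM
lattice = cl.gaussian_mde_lattice(cfg, w_xy_um=0.197, w_z_um=0.787)  # 0.17 fl
trace = cl.simulate_intensity_trace(cfg, lattice, peak_rate=5.4e3)
fit = cl.fit_3d_diffusion(cl.autocorrelate(trace), init={"s_ratio": 4.0})
print(round(fit.n, 2), round(fit.tau_d_s * 1e6, 1))
#   4.03 112.2     <- ~3.7 molecules expected in the volume, tau_D ~ 97 us
```

On this short 2 s trace the fit scatters around the expectations
36 nM × 0.17 fl × N_A ≈ 3.7 and τ_D = w_xy²/4D ≈ 97 µs; at the full 30 s
acquisition both are recovered within a few percent — the FCS read-out recovers concentration and
diffusion properties of the simulated molecules.

A thin CLI wraps the same stages:

```sh
chiplens design  --out layout.csv --gds lens.gds
chiplens propagate --wavelength-nm 520 --out psf.h5
chiplens mde     --out mde.h5
chiplens run     --config myconfig.yaml --seed 1 --out results/
chiplens fixtures --out spectra/
```

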