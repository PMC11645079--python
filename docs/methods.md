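# Methods

`chiplens` models an on-chip epi-fluorescence single-molecule sensor: a
dual-wavelength metalens made of silicon nitride nanoposts standing on a
planar SiN waveguide, focusing guided light into water and collecting the
fluorescence of molecules diffusing through the focus. The chain runs
design → scalar PSFs → molecule detection efficiency → photon budget →
Monte Carlo FCS. This note records the models, the parameters that matter,
and the choices made where the design space was genuinely open.

## Waveguide and materials

The feeding waveguide is a 100 nm SiN slab (narrow section width
w₁ = 600 nm) clad in silica-on-glass (SOG), expanding through a taper of
shape y = α(L/2 − x)^m + w₂/2 with m = 1.15, α = (w₁ − w₂)/(2L^m), to the
20 µm aperture. Packaged dispersion: Si₃N₄ after Philipp (1973), fused
silica after Malitson (1965), water after Daimon & Masumura (2007, 21.5 °C),
tabulated 380–900 nm; users may substitute two-column CSV tables.

The guided propagation constant β(λ) = 2π n_eff/λ comes from the TE0
solution of the asymmetric-slab dispersion relation, solved by bracketed
root finding (`brentq`, tolerance 1e-9 in n_eff); mode cutoff raises a
distinct signal. The grating relation β = (2πn_top/λ)sinθ + 2π/Λ with
Λ = 365 nm serves as a consistency check (the slab β corresponds to
near-vertical outcoupling, θ ≈ 14° at 500 nm); a user-supplied β table
overrides the slab model.

Single-mode operation is assessed with V = (2π/λ)·w·√(n_wg² − n_clad²),
reading the effective width as the geometric mean w = √(w₁·w_h) and n_wg as
the TE0 effective slab index. **Known limitation:** with stoichiometric
Si₃N₄ dispersion this gives V(500 nm) ≈ 2.76, above the 2.405 single-mode
bound; V < 2.4 holds from roughly 550 nm upward. Reaching V < 2.4 at 500 nm
would require a lower-index (silicon-poor PECVD-type) nitride,
n(500) ≲ 1.93. The package reports the computed value rather than the
claim.

## Metalens design

Each segment family i implements phase matching between the accumulated
guided phase φ_wg = β(λᵢ)x + φ_input(y, λᵢ) and the hyperbolic lens phase
φ_lens = (2πn/λᵢ)(F − √(F² + x² + y²)), with n the water index at λᵢ and F
fixed by NA = n·sin(arctan(D/2F)) (defaults D = 20 µm, NA = 1.1 → F = 6.80
µm with n = 1.33). Meta-atoms (200 nm diameter, 500 nm tall cylinders) sit
where wrap(φ_wg − φ_lens) = 0.

Choices where the source design was silent:

- **Stripes.** The aperture is tiled into 2·n_pairs half-open stripes of
  equal width running along the propagation direction, alternating families
  along y; default 5 pairs → 10 stripes of 2 µm. Boundary points belong to
  the +y stripe; stripe 0 starts at y = −D/2 and carries family 1.
- **Rows.** Atom rows are spaced by the grating period (365 nm) along y,
  centered on the aperture.
- **Input phase.** φ_input models the curved wavefront delivered by the
  taper as a cylindrical wave from an effective source R behind the lens,
  φ_input = β(λ)(√(R² + y²) − R), R defaulting to the taper length (40 µm);
  a tabulated φ_input(y) may be supplied instead.
- **Root finding.** Within a row the mismatch is strictly increasing in x
  whenever β exceeds the lens-phase slope (checked; violation raises a
  degenerate-design error), so every 2π branch holds exactly one root:
  located by inverse interpolation on a coarse grid and polished with four
  Newton steps (residuals ~1e-13 rad, tolerance 1e-3 rad). Roots closer
  than one atom diameter are thinned by dropping the later one.

Layouts export as CSV (x_nm, y_nm, diameter_nm, height_nm,
segment_lambda_nm) and optionally as a minimal GDSII stream (one 64-vertex
circle per atom, 1 nm database unit).

## Scalar PSFs

The outcoupled field is synthesized as a sum of Gaussian blobs (1/e radius =
atom radius, uniform amplitude, constant phase φ_wg evaluated at the actual
wavelength — atoms of *both* families radiate at every wavelength), then
propagated with the band-limited angular-spectrum method through h_SOG of
SOG (default 2 µm, "a few micrometers" made concrete) and into water,
switching the medium index at the planar interface without Fresnel loss.
Evanescent components decay and are never amplified; the Matsushima band
limit suppresses aliased replicas. Defaults: 50 nm transverse sampling over
a 30 µm extent (≥1.5× the aperture, enforced), z from 5 to 9 µm in 25 nm
steps, volumes stored cropped to ±4 µm laterally.

Focal metrics: the focal plane is the z of maximal in-plane intensity
(parabolic refinement); lateral and axial FWHM by linear interpolation of
the half-maximum crossings; the encircled fraction is the focal-plane power
within 3×FWHM of the peak relative to the aperture power. Dual-wavelength
overlap reports |Δz| of the two focal planes, the lateral offset of the
above-half-max centroids, and a min/max volume-overlap integral.

This scalar chain replaces full-wave solves and carries a 10–15% per-axis
width error budget at NA = 1.1; all downstream tolerances inherit it. It
reproduces lateral focal widths and dual-wavelength overlap well, but
underestimates the focal *volume*: see Limitations.

## Molecule detection efficiency and photon budget

MDE(x,y,z) = I_exc · CEF with both factors on one grid. CEF is the
emission-spectrum-weighted trapezoidal average of peak-normalized detection
PSFs over the band (default: centered on λ₂, half-width 20 nm, 5 samples),
scaled by P_max — the peak fraction of an isotropic emitter's photons
coupled into the waveguide, bounded by 1/3 for a single TE0 mode. Because
the dipole-coupling factor of the reference device is not tabulated, the
default P_max proxy is (1/3) × (encircled focal fraction at λ₂), by
reciprocity of outcoupling and collection; a measured P_max can be passed
instead. The proxy omits the guided-wave outcoupling efficiency and the
collection solid angle, so absolute MDE and count rates are upper bounds by
roughly two orders of magnitude; relative comparisons between designs
remain meaningful.

Effective volume: V_eff = π^{3/2}·w_xy²·w_z from 1/e² radii fitted to the
MDE profiles through the peak (w_xy averages x and y), with
(∫MDE)²/∫MDE² as the integral alternative (exact for a Gaussian; inflated
by diffuse background on real maps). Photon budget per molecule:
N_F = MDE·ψ·S̄₁·k_fl with S̄₁ = k_ex/(k_fl + k_ex), evaluated by default at
k_ex = 0.1·k_fl.

Fluorophore fixtures are Gaussian band envelopes (σ_abs = 25 nm, σ_em =
30 nm, element-wise max so overlapping bands keep their stated peaks):
ATTO 490LS (abs 496 / em 661 nm, ψ = 0.30, τ = 2.6 ns), Alexa 555 (abs
520 + 553 / em 568 nm, ψ = 0.10, τ = 0.3 ns), APC-Cy7 tandem (abs 651 / em
779 nm, ψ = 0.30, τ = 1.0 ns nominal). ψ and τ are nominal literature
values; measured CSV spectra with a YAML sidecar are accepted.

## Monte Carlo FCS

Molecules hop on a cubic lattice: per axis and step, ±cell with probability
p = D·dt/cell² each way (variance 2D·dt, the Einstein relation; p ≤ 0.25
enforced), periodic at the box faces. Defaults follow the reference
experiment — 300 molecules (36 nM), (2.4 µm)³ box, 50 nm cells, 30 s — plus
model choices the source leaves open: D = 100 µm²/s (small free dye),
dt = 1 µs, bin = 2 µs. Each molecule runs an independent
splitmix64-seeded xorshift128+ stream (hand-inlined in the numba kernel;
per-step calls cannot go through a numpy Generator at 10¹⁰ steps), so
changing the molecule count never reshuffles existing trajectories; Poisson
photon draws use a separate numpy PCG64 stream. Brightness is nearest-cell
MDE lookup times the peak count rate; a 30 s acquisition streams in ~100 s
on one CPU.

The multi-tau correlator uses 16 linear channels per stage and 12 stages,
halving the time resolution per stage; G(τ) = ⟨δI δI⟩/⟨I⟩² with symmetric
normalization, standard errors from 16 contiguous trace blocks. Stage-0
lags coincide exactly with the plain direct estimator.

The 3D diffusion model G(τ) = G_inf + (1/N)(1 + τ/τ_D)⁻¹(1 +
τ/(s²τ_D))^{−1/2} is fitted by least squares (lmfit), aspect s fixed by
default to the calibrated w_z/w_xy. **Numerical choice:** residuals are
*unweighted* by default. Block-averaged errors at long, heavily rebinned
lags are strongly cross-correlated; 1/se weighting overcounts the tail and
drags τ_D down by 12–17% at the default scale, while the unweighted fit
recovers τ_D of the exact (spectrally computed) lattice ACF to ~1%.
se-weighting remains available (`weights="se"`).

What the synthetic experiment does not emulate: triplet blinking,
photobleaching, dipole orientation, detector afterpulsing/dead time,
flow or anomalous diffusion. Passing tests therefore validate the
diffusion + shot-noise statistics chain, not detector- or
photophysics-limited real traces.

## Verification scale and limitations

- Parameter-recovery checks run at the full reference scale (300 molecules,
  30 s, five seeds); noise-scaling checks use shorter 2–5 s traces, where
  the inverse-brightness law is already clean.
- The scalar stand-in reproduces lateral FWHM (222/230/281 nm vs the
  published 220/250/276 nm) and achromatic overlap (|Δz| ≈ 10 nm, offsets
  of a few nm vs ≈3 µm for the chromatic control), but its focal volumes
  are tighter than the full-wave reference: the Gaussian-fit V_eff of the
  Alexa-design MDE computes to ≈0.066 fl against the published ≈0.17 fl.
  Since V_eff compounds three fitted radii, the ~10–15% per-axis scalar
  bias cannot close that gap; treat absolute V_eff (and everything built on
  absolute MDE, e.g. count rates under the P_max proxy) as order-of-scale.
- The V-parameter single-mode claim at 500 nm does not hold under the
  documented effective-index reading with stoichiometric Si₃N₄ (see above).
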