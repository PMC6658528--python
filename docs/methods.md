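# Methods

## Photocycle model

The channel is a continuous-time Markov chain over spectroscopic states.
The canonical four-state cycle is D →(hν)→ K → L → M → D with only L
conducting and only D photoactive: light drives D → K at rate σ·I (σ a
cross-section-like coefficient per arbitrary intensity unit), and all other
transitions are first-order thermal steps. The master equation
`dp/dt = G(I) p` has a column-sum-zero generator, so total occupancy is
conserved exactly. Light protocols are piecewise constant; inside each
constant-intensity span the solution is the matrix exponential of the span
generator, evaluated through a single eigendecomposition per span and
applied to all grid times in that span at once (a per-time `expm` fallback
covers near-defective generators). A helper discretizes smooth ramps into
0.1 ms steps when needed. A delta flash models ns-laser single-turnover
excitation as an instantaneous transfer of an `excited_fraction` of the
ground-state population to the photo target; occupancy reported exactly at
the flash time is the post-flash value when the flash coincides with the
start of the grid, otherwise the left limit.

Assumptions and limitations: rate constants are voltage- and
temperature-independent; photocurrent conversion is ohmic
(`I = g·f_open·(V − E_rev)`, no Goldman–Hodgkin–Katz rectification); M is
not photoactivatable (no light-driven shortcut back to D); closing is
mono-exponential (the minor slow closing phase seen in real recordings is
not represented); no parallel/syn photocycle. Stochastic single-channel
behaviour is out of scope — occupancies are ensemble fractions.

### Packaged parameter sets

Two MerMAID1 fixtures are deliberately kept separate because the electrical
and spectroscopic experiments report different apparent constants and the
package does not attempt to reconcile them:

* `mermaid1_ephys` — apparent closing τ = 2.7 ms, paired-pulse recovery
  τ = 1.21 s, and an effective opening lifetime **calibrated, not assumed**:
  for a flash-fed two-step chain the open-state occupancy is
  ∝ e^(−k₂t) − e^(−k₁t) with peak at t* = ln(k₁/k₂)/(k₁−k₂); requiring
  t* = 350 µs (the measured conductance peak delay) with k₂ = 1/2.7 ms and
  root-finding for k₁ gives an opening lifetime of 103.09 µs. The reversal
  potential is the Cl⁻ Nernst potential at 150 mM external / 120 mM internal
  and 24 °C (−5.71 mV); conductance scale (10 pA/mV) and σ (1 per intensity
  unit) are free scaling parameters, since no absolute photon-flux
  calibration exists.
* `mermaid1_spectro` — sequential lifetimes 173 ns (K), 6 ms (L→M), 1.2 s
  (M→D); dark band at 502 nm (Gaussian, σ = 28 nm); K red-shifted (530 nm);
  L slightly blue-shifted and broadened (488 nm, σ = 36 nm); M as three
  narrow sub-bands at 346/364/384 nm (σ = 5–6 nm — narrow enough that the
  three sub-maxima are resolved at their nominal positions, which is what
  "fine-structured" means operationally here); titration pK 9.8 with Hill
  slope 1 over pH 7.8–10.4; action-spectrum Weibull shape k = 2 and scale
  β = 150 nm with the location solved from λ_max = λ₀ + β((k−1)/k)^(1/k) so
  the analytic peak is exactly 502 nm.
* `mermaid6_ephys` — recovery τ = 6 s, otherwise as MerMAID1.

A three-state reduction (C → O → D_st → C, direct light-driven opening) is
provided for analytics: its stationary open fraction has the closed form
O_ss = (a/k_c)/(1 + a/k_c + a/k_r), approaching k_r/(k_r + k_c) ≈ 2.2×10⁻³
at saturating light — the ~0.2% stationary current that makes these channels
"desensitize to 1%". Saturating-light summaries use this reduction because
the four-state chain's 103 µs feed step caps its transient open-state peak
at ≈0.88 even at infinite intensity, while the reduction reaches >0.9 and
isolates the stationary/peak ratio from the feed kinetics; both variants
give stationary/peak ≈ 0.23–0.25%.

## Global lifetime analysis

Time-resolved data are wavelength (or wavenumber) × time matrices of ΔA on
isologarithmic grids (geometric spacing, fixed points per decade; 10 ns to
100 s at 10/decade gives the standard 101-point grid). The sequential model
A₁ → A₂ → … → Aₙ → ground has closed-form Bateman concentrations
c_m(t) = Σ_l A[m,l]·e^(−k_l t); rates closer than 1e−9 relative are jittered
by 1e−6 to avoid the confluent form (error far below fit tolerances).
Lifetimes are fitted by trust-region least squares (`scipy` TRF) in
log₁₀-lifetime space — they span ten decades — with the amplitude spectra
solved exactly by linear least squares at every iterate (variable
projection). The EADS (spectra of the evolving compartments) and DADS
(amplitudes of the pure exponentials) are related by the exact linear map
DADS = EADS·A with A the Bateman coefficient matrix; both reconstruct the
data identically and the round trip is an identity to machine precision.
Weighting is uniform; masked axis intervals (laser-scatter regions) are
dropped before SVD and fitting. No instrument response function is
modelled: the fit starts at the first grid point and treats the flash as a
delta at t = 0. Non-convergence is flagged on the result object, never
silent.

SVD truncation keeps the best rank-n approximation; the automatic rank rule
takes the smallest n that either captures 99.9% of the squared singular
values or whose first discarded temporal vector is noise-like (lag-1
autocorrelation < 0.5) — under measurement noise the energy criterion alone
would absorb arbitrarily many noise components. The FTIR decomposition
truncates to rank n, fits the retained temporal vectors globally with a
shared sum of n exponentials (optionally plus a constant for
continuous-illumination plateaus), and rotates the spectral vectors by the
fitted amplitude matrix into kinetic component spectra, fast component
first. Continuous illumination is only represented through that optional
plateau basis function, not a driven-kinetics source term.

## Electrophysiology rules

Peak current is the signed extremum (max |I|) inside the light window, on
raw samples (no smoothing; callers may pre-filter). Stationary current is
the trapezoidal mean of the last 50 ms of illumination (exact for linear
drifts), and desensitization extent is 1 − |I_stat/I_peak|, clipped to
[0, 1]. Kinetic constants come from lmfit least-squares fits of
offset + Σ aᵢe^(−t/τᵢ) (order 1 or 2, caller crops the monotone segment);
the apparent constant of a biphasic fit is amplitude-weighted,
Σ|aᵢ|τᵢ/Σ|aᵢ|. Reversal potentials interpolate linearly inside the first
sign-changing pair scanning from negative voltages; with no crossing, the
line through the two voltage-adjacent points of smallest |I| is
extrapolated (interpreting the "two points most adjacent to 0 pA" rule as
smallest-magnitude currents; ties break toward the pair containing the
global minimum). Paired-pulse recovery is fitted as
R(Δt) = 1 − e^(−Δt/τ_rec); a near-saturated series is flagged degenerate.

Action spectra are max-normalized and fitted with the three-parameter
Weibull density shape in wavelength (location λ₀, scale β, shape k > 1),
amplitude fixed by the normalization; λ_max is analytic,
λ₀ + β((k−1)/k)^(1/k), and agrees with the numeric argmax of the fitted
curve. Because large-k/large-β ridges of that surface mimic Gaussians, the
fit multi-starts over a small grid of shapes and locations and keeps the
best solution; k ≤ 1 (monotone curve) is flagged. The exact peaked
functional form is a package choice validated through λ_max only.

## Solutions, Nernst and Henderson

Nernst: E = (RT/zF)·ln(c_out/c_in) in mV (RT/F = 25.61 mV at 24 °C).
Bi-ionic permeability ratios use P_test/P_ref = exp(z·F·ΔE_rev/RT), with the
sign convention fixed so a more permeant test ion gives a ratio > 1 (for an
anion, a negative reversal shift).

Liquid-junction potentials use the generalized Henderson equation with
mobilities u_i = λ°_i/|z_i| from an embedded table of limiting equivalent
conductivities (standard values for the inorganic ions; gluconate and HEPES
at 0.33 and 0.30 of K⁺, the JPCalc convention; nucleotides, phosphocreatine
and ascorbate assigned a generic large-organic-anion value of 24 S·cm²/eq).
Dissociation rules map salt recipes to free ions (Na₂-ATP → 2Na⁺ + ATP²⁻,
Na₂-phosphocreatine → 2Na⁺ + PCr²⁻, ascorbate as its sodium salt, phosphate
as H₂PO₄⁻); HEPES is partitioned by its pKa (7.5) at the stated pH; glucose
and sub-mM EGTA are neutral spectators. The returned sign follows the
pipette-referenced correction convention (K-gluconate pipette against a
NaCl bath is negative) and the function is antisymmetric under swapping its
arguments. The mobility table and charge assignments dominate the last
~0.5 mV and are declared in `solutions.py` rather than hidden; the packaged
table reproduces the standard K-gluconate/ACSF correction to within a
quarter millivolt. Identical (or exactly mobility-balanced) solution pairs
return 0 by the continuity limit.

## Steady spectra and titrations

Normalization anchors at 280 nm or at the chromophore maximum inside
330–650 nm. Savitzky–Golay smoothing uses an 11-point window with a
5th-order polynomial — the traditional 10-point window rounded up to the
next odd size, since symmetric SG filters require odd windows. Sub-maxima
are strict local maxima refined by a three-point parabola. Titrations are
fitted with the base-10 Boltzmann A(pH) = A₁ + (A₂−A₁)/(1 + 10^{h(pK−pH)});
the Hill slope is fixed at 1 by default (a single-site protonation; with
only three points above the pK in the standard 7.8–10.4 span, a free slope
is poorly conditioned) and can be varied on request. A pK outside the
sampled span is flagged, not silently returned.

## Synthetic data and what passing tests show

Every generator is a pure function of (parameters, seed) with the ground
truth attached to the output. Noise is additive i.i.d. Gaussian only,
with default amplitudes giving SNR ≈ 50–100, matching visually clean
published recordings; real instrument artifacts — baseline drift, laser
scatter beyond a static mask, shot noise, correlated noise, IRF smearing,
series-resistance errors — are not emulated. Round-trip tests therefore
demonstrate the *estimators'* correctness and conditioning under the stated
noise model, not robustness to real-world systematics. Transient-absorption
matrices are ground-truth EADS (Gaussian difference bands) times Bateman
concentrations, scaled by a 25% per-flash turnover; FTIR series are built
in the parallel fast + slow representation that the SVD decomposition
targets.

## Problem sizes and numerical choices

The default test and acceptance workloads use the 101-point isologarithmic
grid with ~40–170 wavelength channels, flash grids of 3×10⁵–2×10⁶ points
(vectorized propagation makes these cheap), 20-seed noise ensembles, and
paired-pulse protocols at 0.2–0.5 ms sampling — sizes chosen to match the
fixtures' dynamic range while keeping the full suite in seconds.
Occupancies are clipped of sub-1e-12 negative round-off and renormalized
before invariant checks; eigendecomposition propagation falls back to
`expm` when the eigenvector condition number exceeds 1e10; fit convergence
flags propagate to results rather than raising.
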