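# Methods

## Scope and model

The package models the two experimental layers of a transient-kinetics
study of dmDcr-2 acting on 52-bp dsRNA with blunt (BLT) or 2 nt
3′-overhanging (3′ovr) termini:

1. **Second-to-minute kinetics** of the catalytic-cycle steps, observed by
   stopped-flow fluorescence under pseudo first-order conditions
   (premixing concentrations 2 µM enzyme, 0.2 µM dsRNA; enzyme in 10-fold
   excess so binding appears exponential).
2. **Nanosecond rotational dynamics** of the Cy3 probe, observed by
   polarization-resolved TCSPC.

Neither instrument's raw records are available, so both layers include a
synthetic-data generator that emulates the instrument from the underlying
physics, and every analysis stage is validated by parameter recovery:
inject a known constant, simulate, fit, compare.

## Reaction schemes (stopped-flow layer)

Each cycle step is a mass-action network integrated with LSODA
(`scipy.integrate.solve_ivp`, rtol 1e-8). The absolute tolerance defaults
to 1e-10 × the largest initial concentration: a fixed absolute tolerance
in molar units is either meaningless or too loose on the micromolar scale
of these assays. Schemes:

- `TWO_STEP_BINDING`: E + R ⇌(k₁,k₋₁) C₁ ⇌(k₂,k₋₂) C₂. Bimolecular
  encounter with the helicase domain followed by a slow nucleotide-
  dependent isomerization (helicase clamping).
- `DISSOCIATION_CHASE`: C₂ →(k₋₂) C₁ →(k₋₁) E + R with rebinding
  disabled. The chase (10-fold excess unlabeled competitor) is modelled as
  a perfect sink for free enzyme, justified by the observation that the
  measured off-rates do not change at higher competitor excess. The
  initial C₁:C₂ split defaults to the forward scheme's equilibrium ratio
  k₋₂:k₂ (`chase_initial_state`), overridable.
- `UNWIND_REWIND`: bound → unwound → rewound; FRET coefficients
  high/low/high so the trace dips and recovers.
- `TRANSLOCATION`: bound → arrived; PIFE high on arrival.
- `CLEAVAGE_RELEASE`: bound → arrived → released; FRET coefficients
  moderate/high/near-zero, producing the rise-then-fall trace of
  PIFE-boosted FRET followed by product release.

`observed_eigenrates` linearizes a scheme with the enzyme held at its
excess concentration and returns the nonzero eigenvalues of the
first-order rate matrix — the theoretical k_obs values of the exponential
phases, used throughout as the analytic oracle for the fitters. For the
bimolecular binding scheme at only 10-fold excess this linearization is
itself an approximation: the enzyme pool depletes by up to 10%, so
fitted k_obs and eigenvalues agree to ~1% there (and to <0.1% for the
strictly first-order schemes).

Observable projection is linear, signal(t) = Σ fᵢ·cᵢ(t) + offset,
normalized to a maximum of 1 as is conventional for stopped-flow records.
The specific coefficient values are generator conventions; only their
ordering (which states are bright) shapes the normalized trace.

**Noise model.** Additive i.i.d. Gaussian noise, default σ = 0.02 of the
normalized dynamic range, seeded explicitly everywhere (no global random
state). Real stopped-flow noise is closer to shot noise plus drift; an
additive Gaussian at 2% is the conventional idealization and matches the
scatter visible in published traces. Replicate averaging (4–10 traces per
condition in the emulated protocol; 5 in the recovery workflows) reduces
it by √n.

## Exponential-phase analysis

`fit_exponentials` fits RFU(t) = Σ Aᵢ exp(−k_obs,i t) + offset (1 or 2
phases) by Levenberg–Marquardt (lmfit). Rates are log-parameterized, so
k_obs > 0 by construction while amplitudes remain free-signed (rising
phases carry negative A). Initialization: offset from the mean of the
final 5% of points; rates seeded from a log-spaced grid spanning the
observation window with several restarts, amplitudes obtained by a linear
solve at each candidate rate set; the best converged restart wins.

Diagnostics: reduced χ² against a supplied noise σ (or one estimated from
first differences, which is insensitive to the smooth trend), and a
Wald–Wolfowitz runs test on residual signs (normal approximation) as the
"randomness of residuals" check.

`select_model` prefers the minimal number of phases: the biphasic fit is
accepted only if it improves the corrected AIC by more than 10, both
amplitudes are at least 5% of the total, and the rates are separated by at
least 3-fold. Ties go to fewer phases.

`kobs_from_halflife` uses ln 2 at full precision; the printed convention
k_obs = 0.693/t½ is treated as a display rounding, not arithmetic, and a
`round_sig` helper reproduces printed significant figures.

## Derived quantities

- Residence time: t_res = ln2 / k_off,slow. With the measured slow
  off-rates this gives 346 s (BLT, 0.002 s⁻¹) and 86 s (3′ovr, 0.008 s⁻¹).
- Eyring: ΔG‡ = −RT ln(k_off·h/(k_B·T)) in kcal/mol. The default constants
  are the low-precision printed values (R = 1.986 cal K⁻¹ mol⁻¹,
  h = 1.58×10⁻³⁴ cal s, k_B = 3.3×10⁻²⁴ cal K⁻¹) so that tabulated output
  is faithful; `ThermoConstants.codata()` provides CODATA-2018 values
  (<1% different). T defaults to 298.15 K (assays at 25 °C).
  A known inconsistency is documented rather than resolved: the reported
  ΔΔG‡ values between termini (1.3 and 1.0 kcal/mol) do not follow from
  the reported off-rate ratios (2.33× and 4×), which give RT·ln-ratio
  values of 0.50 and 0.82 kcal/mol at 298.15 K. The implementation
  computes the thermodynamically consistent values and is not tuned to
  reproduce the printed pair.
- Two-step K_d: K_d,app = (k₋₁/k₁)·k₋₂/(k₂+k₋₂), the standard apparent
  dissociation constant of a binding-then-isomerization mechanism;
  isomerization can only tighten apparent binding, so K_d,app ≤ k₋₁/k₁.
  Validated against equilibrium titrations of the full ODE model
  (half-saturation within 1%).
- `summarize_cycle` tabulates per-step half-lives for both termini,
  3′ovr:BLT fold ratios, and labels the largest half-life rate-limiting
  (cleavage/siRNA release under the study's parameter set).

**Microscopic rate presets.** The study reports observed phases and
off-rates, not microscopic constants. `TWO_STEP_RATES_BLT` is
reverse-engineered: k₋₁, k₋₂ are the measured off-rates; k₁ is set so the
fast eigenvalue k₁[E]+k₋₁ matches the fast binding phase (t½ 0.8 s at
[E] = 2 µM); k₂ is solved from the characteristic polynomial so the slow
eigenvalue is exactly ln2/55.5 s⁻¹ (the naive k₂+k₋₂ mapping is ~12% off
at this 70-fold eigenvalue separation). No consistent 3′ovr set exists:
the reported fast binding phase (t½ 5.5 s → 0.126 s⁻¹) is slower than the
reported fast off-rate (0.28 s⁻¹), while the two-step model requires
k_obs,fast ≥ k₋₁. Per-step presets therefore store the reported
half-lives directly, and the rewinding half-life — not reported as a
number — defaults to 5× the unwinding half-life.

## TCSPC simulator

Photophysics: I_tot(t) = Σ f_j exp(−t/τ_j); r(t) = Σ Aᵢ exp(−t/φᵢ) + r∞
with r₀ = ΣAᵢ + r∞ constrained to (0, 0.4] (one-photon limit); the
polarized components are I∥ = I_tot(1+2r)/3 and I⊥ = I_tot(1−r)/3.

Instrument: one 80 MHz excitation period truncated to 781 whole 16 ps
bins (12.496 ns) without wrap-around — justified because all lifetimes in
scope are ≤ 3 ns — with the IRF peak placed 1.5 ns into the window so a
pre-rise background region exists as in real histograms. The IRF is a
pure Gaussian (default FWHM 60 ps; only the FWHM is known), applied by
4× oversampled convolution. The vertical channel is delayed by the
inter-channel path difference (default 380 ps; integer-bin shift plus
sub-bin linear interpolation on the fine grid), attenuated by the
neutral-density factor (default 10, OD 1.0), and the horizontal channel
carries the detection-efficiency ratio g_true, so the total correction
the analysis must recover is g_true × ND. A uniform dark rate is added to
both channels and counts are independent Poisson draws per bin,
reproducible per seed. No pile-up, afterpulsing, or color shift is
modelled.

Sample models: the Cy3-NHS free-dye control (τ 300 ps, r₀ 0.40, φ 440 ps)
and free BLT 52-dsRNA (φ₁ 0.34 ns at 20% of the decaying anisotropy —
internal probe wobble — and φ₂ 2.6 ns at 80% — local tumbling of the
hydrated duplex; r₀ 0.40 with a small r∞ = 0.02). The free-dsRNA
fluorescence lifetime is not a reported quantity; the generator uses
1.2 ns, typical for Cy3 on nucleic acid, and no recovery target depends
on it.

## TCSPC analysis chain

Order: align → background subtraction → g from the control → Eq-style
algebra → fits.

- **Alignment**: the vertical channel is shifted by the integer-bin lag
  maximizing the cross-correlation of the two rising edges
  (positive-clipped first differences). 380 ps on a 16 ps grid recovers
  24 bins; the ≤ half-bin residual (8 ps) is the dominant systematic of
  the chain (~1% on the channel ratio for a 300 ps lifetime).
- **Background**: per-channel mean of the pre-rise region (bins before
  the first 5%-of-max crossing, minus a safety margin; ≥20 bins
  required), subtracted and floored at zero.
- **g factor**: count-weighted tail ratio Σ I_VH / Σ I_VV of the free-dye
  control over a window starting 2 ns after the peak, where its
  anisotropy has decayed (φ = 440 ps → r < 0.005). The count weighting
  avoids the +1/⟨N⟩ bias of averaging per-bin ratios; the window is kept
  to 1 ns because the zero-floor of the background subtraction inflates
  nearly-empty far-tail bins. One run's control g is applied to all
  samples of the run.
- **Time zero**: the decay origin is the maximum rising slope of I_tot
  (parabolic sub-bin refinement), not the histogram peak — for a 300 ps
  lifetime the peak lags the excitation by ~1.3 IRF widths, which would
  depress the extrapolated r₀ by ~0.04. This is the package's convention
  for the r₀ extrapolation point.
- **Fits**: tail fitting starting 100 ps after the origin instead of IRF
  reconvolution; all reported φ and τ are ≥ 300 ps, five times the IRF
  width, so reconvolution would change results by well under the
  statistical error. Lifetime fits use Poisson (1/√I) weights; anisotropy
  fits use per-bin variances propagated from the counts,
  σ_r² = 9g²·V·H·(V+H)/D⁴. Bins with corrected denominator below 100
  counts are masked (bounds the per-bin anisotropy noise; the threshold
  is a package choice). Model selection (1 vs 2 components) follows the
  same minimal-terms rule as the stopped-flow fits.
- **Fast-phase refit**: the fast anisotropy phase is re-analyzed
  independently with a single exponential on an early window (default
  φ₂/3). The global fit's slow component (A₂, φ₂, r∞) is subtracted
  first: on noiseless composites a plain single-exponential-plus-constant
  fit over any usable window overestimates φ₁ by ~2× because the slow
  phase decays appreciably within it, while the subtracted refit is
  exact. The refit supersedes the global fast-phase values in reports.

## Recovery performance (computed by the test suite and acceptance script)

With 20 seeds (stopped-flow, 2% noise, 2000-point log grids) and 10 seeds
(TCSPC, 10⁷ counts), the median recovered values match the injected
constants to ≤1% for the stopped-flow half-lives and off-rates, ~0.5% for
the control r₀ and φ, and a few percent for the dsRNA correlation times.
These problem sizes are the package's defaults for the recovery
workflows; larger seed sets tighten the medians as expected.

## Limitations

- The synthetic stopped-flow traces are ideal exponentials plus Gaussian
  noise: no mixing dead time, photobleaching, drift, or enzyme
  aggregation. Passing recovery tests demonstrates the correctness of the
  analysis chain, not robustness to those artifacts.
- Pseudo first-order linearity in enzyme concentration is a model
  property here; it was not experimentally verifiable in the emulated
  study because of enzyme aggregation at high concentration.
- The TCSPC simulator draws independent Poisson counts per bin (no
  pile-up/dead-time correlations) and a single excitation period (no
  wrap-around), so it under-represents distortions relevant for lifetimes
  approaching the repetition period.
- Associated (species-linked) anisotropy models, global multi-trace
  fitting, and maximum-entropy lifetime distributions are out of scope.
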