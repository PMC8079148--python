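# dicerkin

Transient-kinetics and time-resolved fluorescence modelling of the
ATP-dependent catalytic cycle of *Drosophila melanogaster* Dicer-2
(dmDcr-2) acting on double-stranded RNA.

dmDcr-2 discriminates viral-like blunt (BLT) dsRNA termini from
cellular-like 2 nt 3′-overhanging (3′ovr) termini. Its catalytic cycle —
two-step binding to the helicase domain, transient terminal unwinding and
rewinding, translocation to the cleavage site ~20 nt away, and
cleavage/siRNA release — plays out on the second-to-minute scale and is
measured by stopped-flow fluorescence (Cy3 intensity, PIFE, Cy3→Cy5 FRET),
while nanosecond conformational dynamics of the helicase and Platform–PAZ
domains are measured by time-resolved fluorescence anisotropy (TCSPC).

`dicerkin` implements both analysis chains as a tested, reusable library,
with synthetic-data generators standing in for the stopped-flow and TCSPC
instruments so that every stage is verifiable end to end.

## What it computes

**Stopped-flow kinetics.** Each cycle step is a mass-action network
(`dicerkin.schemes`) integrated with a stiff-capable ODE solver and
projected onto a fluorescence observable. Averaged, normalized traces are
fit (`dicerkin.fitting`) with one or two exponential phases,

    RFU(t) = Σᵢ Aᵢ exp(−k_obs,i · t) + offset,      k_obs = ln 2 / t½,

by Levenberg–Marquardt least squares with multi-start initialization, a
minimal-phases selection rule (corrected AIC, amplitude and rate-separation
thresholds), reduced-χ² and a Wald–Wolfowitz runs test on residuals.

**Derived quantities** (`dicerkin.thermo`): residence times t½ = ln2/k_off,
Eyring activation free energies

    ΔG‡ = −RT ln(k_off · h / (k_B · T)),

the apparent dissociation constant of the two-step mechanism
E + R ⇌ C₁ ⇌ C₂,

    K_d,app = (k₋₁/k₁) · k₋₂/(k₂ + k₋₂),

and a catalytic-cycle summary table with BLT : 3′ovr fold ratios and the
rate-limiting step.

**TCSPC anisotropy** (`dicerkin.tcspc`): a polarized-decay simulator
(Poisson photon statistics, Gaussian IRF, inter-channel delay,
detection-efficiency mismatch, neutral-density attenuation, dark
background) and the full processing chain — channel alignment, pre-rise
background subtraction, g-factor by tail-matching a free-dye control,

    I_tot(t) = g·I_VV + 2·I_VH,      r(t) = (g·I_VV − I_VH)/(g·I_VV + 2·I_VH),

lifetime tail fits, anisotropy-decay fits r(t) = Σ Aᵢ exp(−t/φᵢ) + r∞
reporting r₀ and Δr = r₀ − r∞, and an independent single-exponential refit
of the fast phase.

## Worked example

Simulate a chase-dissociation experiment for the BLT•enzyme complex
(off-rates 0.12 and 0.002 s⁻¹), average five noisy replicates, and fit a
double exponential:

```python
import dicerkin as dk
from dicerkin import presets

rates = presets.chase_rates("BLT")
scheme = dk.build_scheme("DISSOCIATION_CHASE", rates)
init = dk.chase_initial_state(k2=presets.TWO_STEP_RATES_BLT["k2"],
                              k_minus2=rates["k_minus2"])
traj = dk.simulate(scheme, init, dk.default_tgrid(scheme))
clean = dk.to_trace(traj, dk.default_observable(scheme.name))
reps = [dk.add_noise(clean, 0.02, seed=1000 + i) for i in range(5)]
fit = dk.fit_exponentials(dk.average_traces(reps), n_phases=2,
                          sigma=0.02 / 5**0.5)
for p in fit.phases:
    print(f"k_off = {p.k_obs:.4f} 1/s   t1/2 = {p.t_half:.1f} s   A = {p.amplitude:+.3f}")
print(f"reduced chi2 = {fit.reduced_chi_square:.2f}, runs-test p = {fit.runs_test_p:.2f}")

t_res = dk.residence_time(fit.phases[-1].k_obs)
dg = dk.eyring_dg(fit.phases[0].k_obs).delta_g_dagger
print(f"residence time = {t_res:.0f} s, Eyring dG(fast off) = {dg:.1f} kcal/mol")
```

Output:

```
k_off = 0.1173 1/s   t1/2 = 5.9 s   A = +0.088
k_off = 0.0020 1/s   t1/2 = 345.6 s   A = +0.612
reduced chi2 = 0.98, runs-test p = 0.11
residence time = 346 s, Eyring dG(fast off) = 18.7 kcal/mol
```

The fast phase (C₁ → E + R, 0.12 s⁻¹ injected) and slow phase
(C₂-limited, 0.002 s⁻¹ injected) are recovered from the noisy traces; the
slow off-rate converts to a 346 s residence time of the bound complex.

A command-line interface exposes the same workflows
(`dicerkin simulate-sf | fit-sf | derive | simulate-tcspc | anisotropy |
cycle-report`); see `dicerkin --help`.

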