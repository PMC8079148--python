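"""Parameter-recovery experiments: inject printed constants, fit them back.

Each function simulates the matching synthetic generator at the study
conditions (2% stopped-flow noise, the stated photon budgets) over a list
of seeds, runs the fitting pipeline, and returns per-seed recovered
parameters plus medians.  Both the test suite and the acceptance script
drive these, so the numbers they report are always recomputed end to end.
"""

from __future__ import annotations

import numpy as np

from . import presets
from .fitting import average_traces, fit_exponentials
from .schemes import (
    SchemeName,
    add_noise,
    build_scheme,
    chase_initial_state,
    default_observable,
    default_tgrid,
    simulate,
    simulate_stopped_flow,
    to_trace,
)
from .tcspc.analysis import analyze_run
from .tcspc.sim import InstrumentModel, simulate_decay

__all__ = [
    "chase_recovery",
    "step_recovery",
    "anisotropy_recovery",
    "control_recovery",
]

_STEP_SETUP = {
    "unwinding": (SchemeName.UNWIND_REWIND, presets.unwind_rewind_rates, 2, "fast"),
    "translocation": (SchemeName.TRANSLOCATION, presets.translocation_rates, 1, "single"),
    "cleavage/release": (SchemeName.CLEAVAGE_RELEASE, presets.cleavage_rates, 2, "slow"),
}


def chase_recovery(
    seeds: list[int],
    termini: str = "BLT",
    n_replicates: int = 5,
    noise_sigma: float = 0.02,
) -> dict:
    """Chase-dissociation off-rate recovery.

    Simulates the two-state dissociation chain with the measured off-rates,
    starting from the forward scheme's equilibrium C1:C2 split, averages
    noisy replicates, fits a double exponential, and reports fast/slow
    k_off per seed plus medians.
    """
    rates = presets.chase_rates(termini)
    scheme = build_scheme(SchemeName.DISSOCIATION_CHASE, rates)
    init = chase_initial_state(
        k2=presets.TWO_STEP_RATES_BLT["k2"], k_minus2=rates["k_minus2"]
    )
    tgrid = default_tgrid(scheme)
    omap = default_observable(scheme.name)
    traj = simulate(scheme, init, tgrid)
    clean = to_trace(traj, omap)
    fast, slow = [], []
    for seed in seeds:
        reps = [
            add_noise(clean, noise_sigma, seed * 1000 + i) for i in range(n_replicates)
        ]
        fit = fit_exponentials(average_traces(reps), n_phases=2, sigma=noise_sigma / np.sqrt(n_replicates))
        fast.append(fit.phases[0].k_obs)
        slow.append(fit.phases[1].k_obs)
    return {
        "fast_koff": fast,
        "slow_koff": slow,
        "fast_koff_median": float(np.median(fast)),
        "slow_koff_median": float(np.median(slow)),
        "true_fast": rates["k_minus1"],
        "true_slow": rates["k_minus2"],
    }


def step_recovery(
    step: str,
    seeds: list[int],
    termini: str = "BLT",
    noise_sigma: float = 0.02,
) -> dict:
    """Half-life recovery for the unwinding, translocation, or cleavage step.

    Simulates the step's scheme with the printed half-life as ground truth,
    adds 2% Gaussian noise, fits the prescribed number of exponential
    phases, and reports the step's half-life per seed plus the median.
    """
    scheme_name, rates_fn, n_phases, which = _STEP_SETUP[step]
    rates = rates_fn(termini)
    t_halves = []
    for seed in seeds:
        trace = simulate_stopped_flow(
            scheme_name, rates, seed=seed, noise_sigma=noise_sigma
        )
        fit = fit_exponentials(trace, n_phases=n_phases, sigma=noise_sigma)
        phase = fit.phases[0] if which in ("fast", "single") else fit.phases[-1]
        t_halves.append(phase.t_half)
    truth_key = {"unwinding": "unwinding", "translocation": "translocation", "cleavage/release": "cleavage/release"}[step]
    return {
        "t_half": t_halves,
        "t_half_median": float(np.median(t_halves)),
        "true_t_half": presets.HALF_LIVES_S[(truth_key, termini, "ATP")],
    }


def _control_instrument(total_counts: float = 1e7) -> InstrumentModel:
    return InstrumentModel(background_rate=2.0, total_counts=total_counts)


def anisotropy_recovery(seeds: list[int], total_counts: float = 1e7) -> dict:
    """Full-chain recovery of the free-BLT-dsRNA anisotropy model.

    For each seed, simulates the dsRNA sample and its Cy3-NHS control with
    the full instrument distortions, runs align/background/g/anisotropy
    chain with a forced two-phase fit plus the windowed fast-phase refit,
    and reports the slow correlation time and windowed fast correlation
    time.
    """
    inst = _control_instrument(total_counts)
    phi2, phi1_windowed, phi1_global = [], [], []
    for seed in seeds:
        control = simulate_decay(presets.CY3_NHS_CONTROL, inst, seed=seed * 7 + 1)
        sample = simulate_decay(presets.BLT_DSRNA_ALONE, inst, seed=seed * 7 + 2)
        res = analyze_run(sample, control, n_phases=2)
        phases = res["anisotropy"].phases  # sorted fast -> slow by phi
        phi1_global.append(phases[0][1])
        phi2.append(phases[1][1])
        phi1_windowed.append(res["fast_phase"][1])
    return {
        "phi2_ns": phi2,
        "phi2_ns_median": float(np.median(phi2)),
        "phi1_windowed_ns": phi1_windowed,
        "phi1_windowed_ns_median": float(np.median(phi1_windowed)),
        "phi1_global_ns": phi1_global,
        "true_phi1_ns": presets.BLT_DSRNA_ALONE.anisotropy_components[0][1],
        "true_phi2_ns": presets.BLT_DSRNA_ALONE.anisotropy_components[1][1],
    }


def control_recovery(seeds: list[int], total_counts: float = 1e7) -> dict:
    """Full-chain recovery of the Cy3-NHS control photophysics.

    The control calibrates its own g factor (as in a real run) and its
    anisotropy decay is fit with a single exponential; reports the fitted
    fundamental anisotropy r0 and rotational correlation time per seed.
    """
    inst = _control_instrument(total_counts)
    r0s, phis, taus = [], [], []
    for seed in seeds:
        control = simulate_decay(presets.CY3_NHS_CONTROL, inst, seed=seed * 11 + 3)
        res = analyze_run(control, control, n_phases=1)
        afit = res["anisotropy"]
        r0s.append(afit.r0)
        phis.append(afit.phases[0][1])
        taus.append(res["lifetime"].mean_lifetime)
    return {
        "r0": r0s,
        "r0_median": float(np.median(r0s)),
        "phi_ns": phis,
        "phi_ps_median": float(np.median(phis) * 1000.0),
        "tau_ns": taus,
        "tau_ns_median": float(np.median(taus)),
        "true_r0": presets.CY3_NHS_CONTROL.r0,
        "true_phi_ps": presets.CY3_NHS_CONTROL.anisotropy_components[0][1] * 1000.0,
    }
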