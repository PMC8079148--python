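"""Derived kinetic and thermodynamic quantities.

Residence times of the enzyme-bound dsRNA (ln2 / slow off-rate), Eyring
activation free energies for dissociation,

    dG_dagger = -R*T*ln(k_off * h / (k_B * T)),

the apparent dissociation constant of the two-step binding mechanism
E + R <=> C1 <=> C2,

    Kd_app = (k_minus1 / k1) * k_minus2 / (k2 + k_minus2),

and a catalytic-cycle summary table comparing half-lives for blunt (BLT)
and 2 nt 3'-overhanging (3'ovr) dsRNA termini and labelling the
rate-limiting step.

The default physical constants are the low-precision printed values
(R = 1.986 cal/K/mol, h = 1.58e-34 cal s, k_B = 3.3e-24 cal/K) so that
paper-style output is reproduced exactly; a CODATA preset is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .fitting import LN2, ExponentialFit

__all__ = [
    "ThermoConstants",
    "ActivationEnergy",
    "TwoStepKd",
    "CycleSummary",
    "CYCLE_STEPS",
    "residence_time",
    "eyring_dg",
    "delta_delta_g",
    "two_step_kd",
    "summarize_cycle",
]


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants in calorie units, at temperature T (kelvin)."""

    R: float = 1.986          # gas constant, cal K^-1 mol^-1
    h: float = 1.58e-34       # Planck constant, cal s
    k_B: float = 3.3e-24      # Boltzmann constant, cal K^-1
    T: float = 298.15         # assay temperature (25 C)

    def __post_init__(self) -> None:
        if min(self.R, self.h, self.k_B, self.T) <= 0:
            raise ValueError("all thermodynamic constants must be positive")

    @classmethod
    def codata(cls, T: float = 298.15) -> "ThermoConstants":
        """CODATA-2018 constants converted to calorie units."""
        return cls(
            R=8.31446261815324 / 4.184,
            h=6.62607015e-34 / 4.184,
            k_B=1.380649e-23 / 4.184,
            T=T,
        )


@dataclass(frozen=True)
class ActivationEnergy:
    delta_g_dagger: float  # kcal/mol
    k_off: float           # s^-1
    constants: ThermoConstants


@dataclass(frozen=True)
class TwoStepKd:
    k1: float         # M^-1 s^-1
    k_minus1: float   # s^-1
    k2: float         # s^-1
    k_minus2: float   # s^-1
    kd_app: float     # M

    @property
    def kd_single_step(self) -> float:
        return self.k_minus1 / self.k1


def residence_time(k_off_slow: float) -> float:
    """Half-life of the bound complex, ln2 / k_off_slow (seconds)."""
    if not k_off_slow > 0:
        raise ValueError("k_off_slow must be positive")
    return LN2 / k_off_slow


def eyring_dg(k_off: float, constants: ThermoConstants = ThermoConstants()) -> ActivationEnergy:
    """Eyring activation free energy of a rate constant, in kcal/mol."""
    if not k_off > 0:
        raise ValueError("k_off must be positive")
    dg_cal = -constants.R * constants.T * math.log(k_off * constants.h / (constants.k_B * constants.T))
    return ActivationEnergy(delta_g_dagger=dg_cal / 1000.0, k_off=k_off, constants=constants)


def delta_delta_g(
    k_off_a: float,
    k_off_b: float,
    constants: ThermoConstants = ThermoConstants(),
) -> float:
    """dG_dagger(a) - dG_dagger(b) = R*T*ln(k_off_b / k_off_a), kcal/mol."""
    if not (k_off_a > 0 and k_off_b > 0):
        raise ValueError("rates must be positive")
    return constants.R * constants.T * math.log(k_off_b / k_off_a) / 1000.0


def two_step_kd(k1: float, k_minus1: float, k2: float, k_minus2: float) -> TwoStepKd:
    """Apparent Kd of the two-step binding mechanism E + R <=> C1 <=> C2.

    The isomerization C1 <=> C2 can only tighten apparent binding, so
    kd_app <= k_minus1/k1 always.
    """
    if not k1 > 0:
        raise ValueError("k1 must be positive")
    if min(k_minus1, k2, k_minus2) < 0:
        raise ValueError("rates must be nonnegative")
    if k2 + k_minus2 <= 0:
        raise ValueError("k2 + k_minus2 must be positive")
    kd = (k_minus1 / k1) * k_minus2 / (k2 + k_minus2)
    return TwoStepKd(k1=k1, k_minus1=k_minus1, k2=k2, k_minus2=k_minus2, kd_app=kd)


# ---------------------------------------------------------------------------
# catalytic-cycle summary

CYCLE_STEPS = (
    "binding-fast",
    "isomerization",
    "unwinding",
    "rewinding",
    "translocation",
    "cleavage/release",
)

#: Which exponential phase of a fit carries each step's half-life.
_STEP_PHASE = {
    "binding-fast": "fast",
    "isomerization": "slow",
    "unwinding": "fast",
    "rewinding": "slow",
    "translocation": "single",
    "cleavage/release": "slow",
}

TERMINI = ("BLT", "3ovr")


@dataclass
class CycleSummary:
    """Per-step half-lives for both termini, fold ratios, rate-limiting step."""

    table: pd.DataFrame
    rate_limiting_step: str

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")


def _extract_t_half(value, step: str) -> float:
    if isinstance(value, ExponentialFit):
        which = _STEP_PHASE[step]
        if which == "fast" or which == "single":
            return value.phases[0].t_half
        return value.phases[-1].t_half
    t = float(value)
    if not t > 0:
        raise ValueError(f"half-life for step {step!r} must be positive")
    return t


def summarize_cycle(fits: Mapping[tuple, "ExponentialFit | float"]) -> CycleSummary:
    """Tabulate the catalytic cycle from per-step fits or half-lives.

    ``fits`` maps ``(step, termini)`` or ``(step, termini, nucleotide)`` keys
    to an ExponentialFit (the step's canonical phase is extracted) or a bare
    half-life in seconds.  All six steps are required for both termini; the
    step with the largest half-life is labelled rate-limiting.
    """
    values: dict[tuple[str, str], float] = {}
    for key, val in fits.items():
        step, termini = key[0], key[1]
        if step not in CYCLE_STEPS:
            raise ValueError(f"unknown cycle step {step!r}; expected one of {CYCLE_STEPS}")
        if termini not in TERMINI:
            raise ValueError(f"unknown termini {termini!r}; expected one of {TERMINI}")
        values[(step, termini)] = _extract_t_half(val, step)

    missing = [
        (step, termini)
        for step in CYCLE_STEPS
        for termini in TERMINI
        if (step, termini) not in values
    ]
    if missing:
        raise ValueError(f"missing required step entries: {missing}")

    rows = []
    for step in CYCLE_STEPS:
        blt = values[(step, "BLT")]
        ovr = values[(step, "3ovr")]
        rows.append(
            {
                "step": step,
                "t_half_blt_s": blt,
                "t_half_3ovr_s": ovr,
                "fold_ratio_3ovr_over_blt": ovr / blt,
            }
        )
    table = pd.DataFrame(rows)
    limiting_idx = table[["t_half_blt_s", "t_half_3ovr_s"]].max(axis=1).idxmax()
    return CycleSummary(table=table, rate_limiting_step=table.loc[limiting_idx, "step"])
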