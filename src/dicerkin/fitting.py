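"""Exponential-phase analysis of stopped-flow fluorescence traces.

Averaged, normalized traces are described by one or two exponential phases,

    RFU(t) = sum_i A_i * exp(-k_obs_i * t) + offset,

fit by Levenberg-Marquardt least squares with log-parameterized rates
(k_obs > 0 by construction) and multi-start initialization from a
log-spaced rate grid.  Goodness of fit is reported as the reduced
chi-square against the (supplied or estimated) noise level and a
Wald-Wolfowitz runs test on residual signs.  Half-lives and observed rate
constants interconvert through k_obs = ln2 / t_half; ln 2 is kept at full
precision internally, and only a reporting helper rounds to significant
figures to match the conventional printed "0.693".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.stats import norm

from .schemes import StoppedFlowTrace

__all__ = [
    "ExponentialPhase",
    "ExponentialFit",
    "average_traces",
    "normalize",
    "fit_exponentials",
    "select_model",
    "kobs_from_halflife",
    "halflife_from_kobs",
    "round_sig",
    "runs_test_p",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ExponentialPhase:
    """One exponential phase: signed amplitude, rate, and derived half-life.

    The model amplitude is signed (negative for rising phases); the
    magnitude is the "amplitude of change" reported in summary tables.
    """

    amplitude: float
    k_obs: float
    amplitude_se: float = float("nan")
    k_obs_se: float = float("nan")

    def __post_init__(self) -> None:
        if not self.k_obs > 0:
            raise ValueError("k_obs must be positive")

    @property
    def t_half(self) -> float:
        return LN2 / self.k_obs

    @property
    def t_half_se(self) -> float:
        return LN2 * self.k_obs_se / self.k_obs**2


@dataclass
class ExponentialFit:
    """Result of a 1- or 2-phase exponential fit with diagnostics."""

    phases: list[ExponentialPhase]
    offset: float
    reduced_chi_square: float
    runs_test_p: float
    aicc: float
    sigma: float
    n_points: int
    offset_se: float = float("nan")
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phases = sorted(self.phases, key=lambda p: -p.k_obs)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset)
        for p in self.phases:
            y = y + p.amplitude * np.exp(-p.k_obs * t)
        return y

    def to_record(self) -> dict:
        return {
            "n_phases": self.n_phases,
            "phases": [
                {
                    "A": p.amplitude,
                    "k_obs": p.k_obs,
                    "t_half": p.t_half,
                    "se": {"A": p.amplitude_se, "k_obs": p.k_obs_se},
                }
                for p in self.phases
            ],
            "offset": self.offset,
            "chi2_red": self.reduced_chi_square,
            "runs_p": self.runs_test_p,
        }


# ---------------------------------------------------------------------------
# conversions

def kobs_from_halflife(t_half: float) -> float:
    """k_obs = ln2 / t_half (full-precision ln 2)."""
    if not t_half > 0:
        raise ValueError("t_half must be positive")
    return LN2 / t_half


def halflife_from_kobs(k_obs: float) -> float:
    if not k_obs > 0:
        raise ValueError("k_obs must be positive")
    return LN2 / k_obs


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, for printed-value comparisons."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


# ---------------------------------------------------------------------------
# trace preparation

def average_traces(traces: list[StoppedFlowTrace]) -> StoppedFlowTrace:
    """Pointwise mean of replicate traces sharing a time grid."""
    if not traces:
        raise ValueError("need at least one trace")
    t0 = traces[0].time
    for i, tr in enumerate(traces[1:], start=2):
        if tr.time.shape != t0.shape or not np.allclose(tr.time, t0, rtol=0, atol=1e-12):
            raise ValueError(f"trace {i} has a mismatched time grid")
    mean = np.mean([tr.signal for tr in traces], axis=0)
    meta = dict(traces[0].metadata)
    meta["n_replicates"] = len(traces)
    return StoppedFlowTrace(time=t0.copy(), signal=mean, metadata=meta)


def normalize(trace: StoppedFlowTrace) -> StoppedFlowTrace:
    """Scale so max(signal) = 1; preserves the shape (point ratios)."""
    peak = float(np.max(np.abs(trace.signal)))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero trace")
    scale = float(np.max(trace.signal))
    if scale <= 0:
        raise ValueError("cannot normalize a trace with nonpositive maximum")
    return StoppedFlowTrace(
        time=trace.time.copy(),
        signal=trace.signal / scale,
        metadata=dict(trace.metadata),
    )


# ---------------------------------------------------------------------------
# runs test

def runs_test_p(residuals: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs-test p-value on residual signs.

    Normal approximation to the run-count distribution; ties (exact zeros)
    are dropped.
    """
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n = len(signs)
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0 or n < 2:
        return 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# fitting

def _linear_amplitudes(t, y, ks):
    """Least-squares amplitudes and offset for fixed rates."""
    design = np.column_stack([np.exp(-k * t) for k in ks] + [np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[:-1], coef[-1]


def _estimate_sigma(y: np.ndarray) -> float:
    """Noise level from first differences (robust to smooth trends)."""
    if len(y) < 3:
        return max(1e-6, float(np.std(y)))
    s = float(np.std(np.diff(y)) / math.sqrt(2.0))
    return max(s, 1e-9)


def _initial_rate_sets(t: np.ndarray, n_phases: int) -> list[tuple[float, ...]]:
    t_pos = t[t > 0]
    lo = 0.2 / t_pos[-1]
    hi = 2.0 / t_pos[0]
    grid = np.geomspace(lo, hi, 6)
    if n_phases == 1:
        return [(g,) for g in np.geomspace(lo, hi, 5)]
    pairs = [(0, 2), (1, 3), (2, 4), (3, 5), (0, 4), (1, 5), (0, 5)]
    return [(grid[j], grid[i]) for i, j in pairs]


def fit_exponentials(
    trace: StoppedFlowTrace,
    n_phases: int,
    init: dict | None = None,
    sigma: float | None = None,
) -> ExponentialFit:
    """Levenberg-Marquardt fit of a 1- or 2-phase exponential rate equation.

    Parameters
    ----------
    trace
        The (averaged, normalized) trace to fit.
    n_phases
        1 or 2 exponential phases.
    init
        Optional initial guesses: ``{"k_obs": [..], "amplitudes": [..],
        "offset": x}``; otherwise the offset starts at the mean of the final
        5% of points and rates are seeded from a log-spaced grid with
        multiple restarts.
    sigma
        Noise standard deviation for the reduced chi-square; estimated from
        first differences when omitted.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = trace.time, trace.signal
    n_param = 2 * n_phases + 1
    if len(t) < 5 * n_param:
        raise ValueError(f"need at least {5 * n_param} points for {n_phases} phase(s)")
    if sigma is None:
        sigma = _estimate_sigma(y)

    def residual(params):
        model = np.full_like(t, params["offset"].value)
        for i in range(n_phases):
            model = model + params[f"a{i}"].value * np.exp(-math.exp(params[f"lnk{i}"].value) * t)
        return y - model

    def make_params(ks, amps, offset):
        params = lmfit.Parameters()
        for i, (k, a) in enumerate(zip(ks, amps)):
            params.add(f"lnk{i}", value=math.log(k))
            params.add(f"a{i}", value=float(a))
        params.add("offset", value=float(offset))
        return params

    starts = []
    if init is not None:
        ks = list(init["k_obs"])
        offset = float(init.get("offset", np.mean(y[-max(1, len(y) // 20):])))
        amps = init.get("amplitudes")
        if amps is None:
            amps, offset = _linear_amplitudes(t, y, ks)
        starts.append((ks, list(amps), offset))
    else:
        for ks in _initial_rate_sets(t, n_phases):
            amps, offset = _linear_amplitudes(t, y, ks)
            starts.append((list(ks), list(amps), offset))

    best = None
    for ks, amps, offset in starts:
        try:
            res = lmfit.minimize(residual, make_params(ks, amps, offset), method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("exponential fit failed to converge from any start")

    resid = residual(best.params)
    n = len(t)
    chi2_red = float(np.sum((resid / sigma) ** 2) / max(n - n_param, 1))
    rss = float(np.sum(resid**2))
    aicc = n * math.log(max(rss / n, 1e-300)) + 2 * n_param
    if n - n_param - 1 > 0:
        aicc += 2 * n_param * (n_param + 1) / (n - n_param - 1)

    phases = []
    for i in range(n_phases):
        k = math.exp(best.params[f"lnk{i}"].value)
        lnk_se = best.params[f"lnk{i}"].stderr
        phases.append(
            ExponentialPhase(
                amplitude=float(best.params[f"a{i}"].value),
                k_obs=k,
                amplitude_se=float(best.params[f"a{i}"].stderr or "nan"),
                k_obs_se=float(k * lnk_se) if lnk_se is not None else float("nan"),
            )
        )
    offset_se = best.params["offset"].stderr
    return ExponentialFit(
        phases=phases,
        offset=float(best.params["offset"].value),
        reduced_chi_square=chi2_red,
        runs_test_p=runs_test_p(resid),
        aicc=aicc,
        sigma=float(sigma),
        n_points=n,
        offset_se=float(offset_se) if offset_se is not None else float("nan"),
        converged=bool(best.success),
        metadata=dict(trace.metadata),
    )


def select_model(
    trace: StoppedFlowTrace,
    sigma: float | None = None,
    aicc_margin: float = 10.0,
    min_amplitude_fraction: float = 0.05,
    min_rate_separation: float = 3.0,
) -> ExponentialFit:
    """Minimal-phases model selection between 1 and 2 exponentials.

    The 2-phase fit is returned only when it earns its extra parameters:
    corrected-AIC better by more than ``aicc_margin``, both amplitudes at
    least ``min_amplitude_fraction`` of the total amplitude, and rate
    separation at least ``min_rate_separation``.  Ties go to fewer phases.
    """
    fit1 = fit_exponentials(trace, 1, sigma=sigma)
    try:
        fit2 = fit_exponentials(trace, 2, sigma=sigma)
    except (ValueError, RuntimeError):
        return fit1
    total_amp = sum(abs(p.amplitude) for p in fit2.phases)
    amp_ok = total_amp > 0 and all(
        abs(p.amplitude) >= min_amplitude_fraction * total_amp for p in fit2.phases
    )
    sep_ok = fit2.phases[0].k_obs >= min_rate_separation * fit2.phases[-1].k_obs
    aicc_ok = (fit1.aicc - fit2.aicc) > aicc_margin
    return fit2 if (aicc_ok and amp_ok and sep_ok) else fit1
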