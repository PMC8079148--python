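"""Plain-text file formats and the workflow runner.

Formats
-------
Stopped-flow traces: 2-column CSV ``time_s,signal_rfu`` with ``#``-prefixed
JSON metadata header lines.  TCSPC channels: per-channel 2-column ASCII
``bin_ps<TAB>counts`` plus a JSON metadata sidecar.  Reports: JSON records
with a provenance block (config hash, seed, software version) and flat CSV
summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, presets
from .fitting import average_traces, fit_exponentials, normalize, select_model
from .schemes import (
    StoppedFlowTrace,
    add_noise,
    build_scheme,
    default_init,
    default_observable,
    default_tgrid,
    simulate,
    to_trace,
)
from .tcspc.analysis import analyze_run
from .tcspc.sim import InstrumentModel, PhotophysicsModel, PolarizedDecay, simulate_decay
from .thermo import eyring_dg, residence_time, summarize_cycle, two_step_kd

logger = logging.getLogger("dicerkin")

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_trace_csv",
    "write_trace_csv",
    "read_tcspc_ascii",
    "write_tcspc_ascii",
    "run",
]

WORKFLOWS = (
    "simulate_sf",
    "fit_sf",
    "derive",
    "simulate_tcspc",
    "anisotropy",
    "cycle_report",
)


class ConfigError(ValueError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# trace CSV

def write_trace_csv(trace: StoppedFlowTrace, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key in sorted(trace.metadata):
            fh.write(f"# {key}={json.dumps(trace.metadata[key])}\n")
        fh.write("time_s,signal_rfu\n")
        for t, s in zip(trace.time, trace.signal):
            fh.write(f"{t:.9e},{s:.9e}\n")


def read_trace_csv(path: str | Path) -> StoppedFlowTrace:
    path = Path(path)
    metadata: dict = {}
    times, signals = [], []
    last_t = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        metadata[key.strip()] = json.loads(val)
                    except json.JSONDecodeError:
                        metadata[key.strip()] = val.strip()
                continue
            if line.lower().startswith("time"):
                continue
            parts = line.split(",")
            try:
                t, s = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
            if last_t is not None and t <= last_t:
                raise ValueError(f"{path}:{lineno}: time column not strictly increasing")
            last_t = t
            times.append(t)
            signals.append(s)
    if not times:
        raise ValueError(f"{path}: no data rows")
    return StoppedFlowTrace(np.array(times), np.array(signals), metadata)


# ---------------------------------------------------------------------------
# TCSPC ASCII

def write_tcspc_ascii(decay: PolarizedDecay, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, counts in (("vv", decay.i_vv), ("vh", decay.i_vh)):
        with (directory / f"{name}.txt").open("w") as fh:
            for b, c in zip(decay.bin_ps, counts):
                fh.write(f"{b:.3f}\t{int(round(c))}\n")
    sidecar = dict(decay.metadata)
    sidecar["bin_width_ps"] = decay.bin_width_ps
    (directory / "meta.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_tcspc_ascii(directory: str | Path) -> PolarizedDecay:
    directory = Path(directory)
    channels = {}
    grids = {}
    for name in ("vv", "vh"):
        path = directory / f"{name}.txt"
        data = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                try:
                    b, c = float(parts[0]), float(parts[1])
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
                if c != int(c):
                    raise ValueError(f"{path}:{lineno}: fractional count {c}")
                data.append((b, int(c)))
        grids[name] = np.array([b for b, _ in data])
        channels[name] = np.array([c for _, c in data])
    if grids["vv"].shape != grids["vh"].shape or not np.allclose(grids["vv"], grids["vh"]):
        raise ValueError("channel files have mismatched bin grids")
    meta_path = directory / "meta.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    widths = np.diff(grids["vv"])
    bin_width = float(metadata.get("bin_width_ps", widths[0] if len(widths) else 16.0))
    if len(widths) and not np.allclose(widths, widths[0]):
        raise ValueError("bin grid is not uniform")
    return PolarizedDecay(
        bin_ps=grids["vv"],
        i_vv=channels["vv"],
        i_vh=channels["vh"],
        bin_width_ps=bin_width,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# run configuration / workflows

@dataclass
class RunConfig:
    """A validated workflow configuration.

    Units are explicit in key names inside ``params`` (e.g.
    ``k_minus1_per_s``, ``enzyme_M``); every stochastic workflow requires an
    explicit ``seed``.
    """

    workflow: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    out: Path | None = None

    STOCHASTIC = ("simulate_sf", "simulate_tcspc")

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ConfigError(f"unknown workflow {self.workflow!r}; expected one of {WORKFLOWS}")
        if self.workflow in self.STOCHASTIC and self.seed is None:
            raise ConfigError(f"workflow {self.workflow!r} requires an explicit seed")

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None, out: str | None = None) -> "RunConfig":
        path = Path(path)
        try:
            raw = json.loads(path.read_text())
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config file is not valid JSON: {path}: {exc}") from exc
        if "workflow" not in raw:
            raise ConfigError("config must name a workflow")
        cfg_seed = raw.get("seed", seed)
        if seed is not None:
            cfg_seed = seed
        return cls(
            workflow=raw["workflow"],
            params=raw.get("params", {}),
            seed=cfg_seed,
            out=Path(out) if out else (Path(raw["out"]) if "out" in raw else None),
        )

    def canonical(self) -> str:
        return json.dumps(
            {"workflow": self.workflow, "params": self.params, "seed": self.seed},
            sort_keys=True,
        )

    def digest(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _strip_units(params: dict, suffixes=("_per_s", "_per_M_s", "_M", "_s", "_ns", "_ps")) -> dict:
    out = {}
    for key, val in params.items():
        base = key
        for suf in suffixes:
            if key.endswith(suf):
                base = key[: -len(suf)]
                break
        out[base] = val
    return out


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed, "version": __version__}


def _run_simulate_sf(config: RunConfig) -> dict:
    p = config.params
    rates = _strip_units(p["rates"])
    scheme = build_scheme(p["scheme"], rates)
    enzyme = float(p.get("enzyme_M", 2e-6))
    rna = float(p.get("dsRNA_M", 0.2e-6))
    init = p.get("init_M") or default_init(scheme, enzyme=enzyme, rna=rna)
    tgrid = (
        np.geomspace(p["tgrid"]["start_s"], p["tgrid"]["stop_s"], int(p["tgrid"]["n"]))
        if "tgrid" in p
        else default_tgrid(scheme, excess_conc=enzyme)
    )
    omap = default_observable(scheme.name, **p.get("observable_coefficients", {}))
    traj = simulate(scheme, init, tgrid)
    clean = to_trace(traj, omap, metadata={"enzyme_M": enzyme, "dsRNA_M": rna})
    sigma = float(p.get("noise_sigma", 0.02))
    n_rep = int(p.get("n_replicates", 1))
    paths = []
    for i in range(n_rep):
        noisy = add_noise(clean, sigma, int(config.seed) * 1000 + i)
        if config.out:
            config.out.mkdir(parents=True, exist_ok=True)
            path = config.out / f"trace_{i:02d}.csv"
            write_trace_csv(noisy, path)
            paths.append(str(path))
    logger.info("simulate_sf: scheme=%s replicates=%d sigma=%g", scheme.name.value, n_rep, sigma)
    return {"scheme": scheme.name.value, "n_replicates": n_rep, "traces": paths}


def _run_fit_sf(config: RunConfig) -> dict:
    p = config.params
    traces = [read_trace_csv(path) for path in p["traces"]]
    avg = normalize(average_traces(traces))
    sigma = p.get("noise_sigma")
    n_phases = p.get("n_phases")
    if n_phases is None:
        fit = select_model(avg, sigma=sigma)
    else:
        fit = fit_exponentials(avg, int(n_phases), sigma=sigma)
    logger.info("fit_sf: %d traces, selected %d phase(s)", len(traces), fit.n_phases)
    return {"fit": fit.to_record(), "n_traces": len(traces)}


def _run_derive(config: RunConfig) -> dict:
    p = config.params
    out: dict = {}
    if "k_off_slow_per_s" in p:
        out["residence_time_s"] = residence_time(float(p["k_off_slow_per_s"]))
    if "k_off_per_s" in p:
        ae = eyring_dg(float(p["k_off_per_s"]))
        out["delta_g_dagger_kcal_mol"] = ae.delta_g_dagger
    if "two_step" in p:
        ts = _strip_units(p["two_step"])
        kd = two_step_kd(ts["k1"], ts["k_minus1"], ts["k2"], ts["k_minus2"])
        out["kd_app_M"] = kd.kd_app
    if not out:
        raise ConfigError("derive workflow needs k_off_slow_per_s, k_off_per_s, or two_step")
    return out


def _photophysics_from_params(p: dict) -> PhotophysicsModel:
    if "preset" in p:
        return {
            "cy3_nhs_control": presets.CY3_NHS_CONTROL,
            "blt_dsrna_alone": presets.BLT_DSRNA_ALONE,
        }[p["preset"]]
    return PhotophysicsModel(
        lifetimes=tuple((c["tau_ns"], c["fraction"]) for c in p["lifetimes"]),
        anisotropy_components=tuple(
            (c["A"], c["phi_ns"]) for c in p["anisotropy_components"]
        ),
        r_infinity=float(p.get("r_infinity", 0.0)),
    )


def _run_simulate_tcspc(config: RunConfig) -> dict:
    p = config.params
    model = _photophysics_from_params(p.get("model", p))
    inst = InstrumentModel(**p.get("instrument", {}))
    decay = simulate_decay(model, inst, int(config.seed))
    if config.out:
        write_tcspc_ascii(decay, config.out)
    logger.info("simulate_tcspc: %d bins, %g expected counts", len(decay.bin_ps), inst.total_counts)
    return {
        "n_bins": len(decay.bin_ps),
        "total_counts_vv": int(decay.i_vv.sum()),
        "total_counts_vh": int(decay.i_vh.sum()),
        "out": str(config.out) if config.out else None,
    }


def _run_anisotropy(config: RunConfig) -> dict:
    p = config.params
    sample = read_tcspc_ascii(p["run_dir"])
    control = read_tcspc_ascii(p["control_dir"])
    res = analyze_run(sample, control, n_phases=p.get("n_phases"))
    rec = res["anisotropy"].to_record()
    rec["g"] = res["g"]
    rec["mean_lifetime_ns"] = res["lifetime"].mean_lifetime
    if res["fast_phase"] is not None:
        rec["fast_refit_A1"], rec["fast_refit_phi1_ns"] = res["fast_phase"]
    logger.info("anisotropy: g=%.4f, %d phase(s)", res["g"], rec["n_phases"])
    return rec


def _run_cycle_report(config: RunConfig) -> dict:
    p = config.params
    entries = {}
    for item in p["steps"]:
        entries[(item["step"], item["termini"])] = float(item["t_half_s"])
    summary = summarize_cycle(entries)
    return {
        "table": summary.to_records(),
        "rate_limiting_step": summary.rate_limiting_step,
    }


_RUNNERS = {
    "simulate_sf": _run_simulate_sf,
    "fit_sf": _run_fit_sf,
    "derive": _run_derive,
    "simulate_tcspc": _run_simulate_tcspc,
    "anisotropy": _run_anisotropy,
    "cycle_report": _run_cycle_report,
}


def run(config: RunConfig) -> dict:
    """Execute a workflow; deterministic for a fixed config and seed."""
    report = {"workflow": config.workflow, "provenance": _provenance(config)}
    try:
        report["result"] = _RUNNERS[config.workflow](config)
    except (KeyError, ConfigError):
        raise
    except (ValueError, FileNotFoundError) as exc:
        raise ConfigError(f"workflow {config.workflow}: {exc}") from exc
    if config.out and config.workflow in ("fit_sf", "derive", "anisotropy", "cycle_report"):
        config.out.parent.mkdir(parents=True, exist_ok=True)
        config.out.write_text(json.dumps(report, indent=1, sort_keys=True))
        if config.workflow == "cycle_report":
            pd.DataFrame(report["result"]["table"]).to_csv(
                config.out.with_suffix(".csv"), index=False
            )
    return report
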