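"""High-level experiment drivers chaining model, avalanche, correlation and
response analyses, plus the experiment-path analysis of event recordings.

Seeds: every driver takes one integer seed and derives independent
per-run streams from it with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .avalanches import (
    DEFAULT_DT,
    DEFAULT_TH,
    MODEL_TH,
    EventTable,
    bin_events,
    count_series_from_raster,
    detect_avalanches,
)
from .correlations import (
    MODEL_CORR_BIN_STEPS,
    N_GROUPS,
    channelize_model,
    pairwise_correlations,
)
from .kappa import KappaResult, compute_kappa, fit_power_law_mle
from .network import (
    ModelConfig,
    default_stimulus_levels,
    simulate_ongoing,
    simulate_stimulus_trials,
)
from .response import (
    RESPONSE_WINDOW_S,
    DynamicRangeResult,
    SigmoidFit,
    TrialTable,
    bin_curve,
    dynamic_range,
    extract_responses,
    fit_sigmoid,
    model_response_curve,
)

__all__ = [
    "RunConfig",
    "ExperimentAnalysis",
    "derive_seeds",
    "analyze_recording",
    "model_state_run",
    "state_sweep",
    "dynamic_range_sweep",
    "figure_suite",
    "write_provenance",
]

GAMMA_GRID = (0.0, 0.5, 1.0, 1.5, 3.0)


@dataclass(frozen=True)
class RunConfig:
    """Serializable bundle of analysis and model parameters."""

    # experiment-path analysis parameters
    dt: float = DEFAULT_DT
    th: float = DEFAULT_TH
    kappa_points: int = 10
    reference_exponent: float = -1.5
    n_speed_bins: int = 10
    kappa_bins: int = 13
    recovery_margin_s: float = 1.0
    # model-path analysis parameters
    model_th: float = MODEL_TH
    model_bin_steps: int = 1
    corr_bin_steps: int = MODEL_CORR_BIN_STEPS
    n_groups: int = N_GROUPS
    # model parameters
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig(**d["model"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def derive_seeds(seed: int, n: int) -> list[int]:
    """n reproducible independent integer seeds (< 2**31) from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass
class ExperimentAnalysis:
    """Results of the experiment-path analysis of one recording."""

    kappa: KappaResult | None
    n_avalanches: int
    mean_correlation: float
    correlation_pairs: int
    r_min: float
    sigmoid: SigmoidFit | None
    dynrange: DynamicRangeResult | None
    trials: TrialTable

    def summary(self) -> dict:
        return {
            "kappa": self.kappa.kappa if self.kappa else None,
            "n_avalanches": self.n_avalanches,
            "mean_correlation": self.mean_correlation,
            "r_min": self.r_min,
            "r_max": self.sigmoid.r_max if self.sigmoid else None,
            "b": self.sigmoid.b if self.sigmoid else None,
            "c": self.sigmoid.c if self.sigmoid else None,
            "delta": self.dynrange.delta if self.dynrange else None,
        }


def ongoing_rate_per_window(
    events: EventTable,
    exclusions: Sequence[tuple[float, float]],
    duration_s: float,
    window: float = RESPONSE_WINDOW_S,
) -> float:
    """Mean spike count per ``window`` seconds of unstimulated time."""
    times = events.times
    excluded = np.zeros(times.size, dtype=bool)
    excluded_time = 0.0
    prev_end = 0.0
    for lo, hi in sorted(exclusions):
        lo_c, hi_c = max(lo, prev_end), min(hi, duration_s)
        if hi_c > lo_c:
            excluded_time += hi_c - lo_c
            prev_end = hi_c
        excluded |= (times >= lo) & (times < hi)
    free_time = duration_s - excluded_time
    if free_time <= 0:
        raise ValueError("no unstimulated time to estimate the ongoing rate")
    return float((~excluded).sum()) * window / free_time


def analyze_recording(
    events: EventTable,
    stimulus_log: pd.DataFrame,
    config: RunConfig = RunConfig(),
    duration_s: float | None = None,
    stimulus_duration_s: float = 1.0,
) -> ExperimentAnalysis:
    """Full experiment-path analysis of an event recording.

    Ongoing-activity statistics (kappa, correlations, R_min) use only the
    time outside [onset, onset + stimulus duration + recovery margin) of
    every trial; the response curve uses the 100 ms windows after onsets.
    """
    if duration_s is None:
        duration_s = float(events.times.max()) if events.n_events else 0.0
    width = stimulus_duration_s + config.recovery_margin_s
    exclusions = [(t, t + width) for t in stimulus_log["onset_s"]]

    series = bin_events(events, config.dt, exclusions)
    av = detect_avalanches(series, config.th)
    kap = None
    if av.n_avalanches >= 2 and av.sizes.min() < av.sizes.max():
        kap = compute_kappa(
            av.sizes, m=config.kappa_points, exponent=config.reference_exponent
        )
    corr = pairwise_correlations(
        series.per_channel, series.effective_mask(), bin_duration=config.dt
    )
    r_min = ongoing_rate_per_window(events, exclusions, duration_s)
    trials = extract_responses(events, stimulus_log)
    curve = bin_curve(trials, config.n_speed_bins)
    fit = fit_sigmoid(curve, r_min)
    dr = None
    if fit.converged:
        pos = trials.stimuli[trials.stimuli > 0]
        floor = float(pos.min()) if pos.size else None
        dr = dynamic_range(fit, smallest_positive_stimulus=floor)
    return ExperimentAnalysis(
        kappa=kap,
        n_avalanches=av.n_avalanches,
        mean_correlation=corr.mean_correlation,
        correlation_pairs=corr.n_pairs,
        r_min=r_min,
        sigmoid=fit if fit.converged else fit,
        dynrange=dr,
        trials=trials,
    )


def model_state_run(
    gamma: float,
    n_steps: int,
    seed: int,
    config: RunConfig = RunConfig(),
) -> dict:
    """Simulate ongoing activity at one gamma; return kappa, the ML size
    exponent and the mean pairwise correlation."""
    mc = config.model
    mc = ModelConfig(
        n_neurons=mc.n_neurons,
        inhibitory_fraction=mc.inhibitory_fraction,
        gamma=gamma,
        depression_window=mc.depression_window,
        p_ext_baseline=mc.p_ext_baseline,
        step_duration=mc.step_duration,
    )
    raster = simulate_ongoing(mc, n_steps, seed=seed)
    series = count_series_from_raster(raster, config.model_bin_steps)
    av = detect_avalanches(series, config.model_th)
    kap = np.nan
    expo = np.nan
    if av.n_avalanches >= 2 and av.sizes.min() < av.sizes.max():
        kap = compute_kappa(
            av.sizes, m=config.kappa_points, exponent=config.reference_exponent
        ).kappa
        expo = fit_power_law_mle(av.sizes)
    mat = channelize_model(raster, config.n_groups, config.corr_bin_steps)
    corr = pairwise_correlations(mat)
    return {
        "gamma": gamma,
        "seed": seed,
        "n_steps": n_steps,
        "kappa": kap,
        "size_exponent": expo,
        "n_avalanches": av.n_avalanches,
        "mean_correlation": corr.mean_correlation,
        "corr_iqr": corr.iqr() if not np.all(np.isnan(corr.pair_values)) else np.nan,
    }


def state_sweep(
    gammas: Sequence[float] = GAMMA_GRID,
    n_seeds: int = 3,
    n_steps: int = 200_000,
    seed: int = 0,
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Ongoing-state characterization (kappa, exponent, correlations) over a
    gamma grid; one row per (gamma, seed)."""
    seeds = derive_seeds(seed, n_seeds)
    rows = [
        model_state_run(g, n_steps, s, config) for g in gammas for s in seeds
    ]
    return pd.DataFrame(rows)


def dynamic_range_sweep(
    gammas: Sequence[float] = GAMMA_GRID,
    n_seeds: int = 3,
    seed: int = 0,
    depression_window: int = 80,
    full_range: bool = False,
    reps: int = 20,
    response_window: int = 200,
    inter_trial_gap: int = 1500,
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Dynamic range Delta over a gamma grid.

    ``full_range=False`` limits stimulus drives to 1e-3 (the physiological
    comparison); ``True`` extends the levels up to 0.3 per neuron per step,
    strong enough to saturate the network, and skips the truncation.
    """
    levels = (
        default_stimulus_levels(high=0.3) if full_range else default_stimulus_levels()
    )
    truncate = None if full_range else 1e-3
    mc = config.model
    seeds = derive_seeds(seed, n_seeds)
    rows = []
    for g in gammas:
        for s in seeds:
            cfg = ModelConfig(
                n_neurons=mc.n_neurons,
                inhibitory_fraction=mc.inhibitory_fraction,
                gamma=g,
                depression_window=depression_window,
                p_ext_baseline=mc.p_ext_baseline,
                step_duration=mc.step_duration,
            )
            trialset = simulate_stimulus_trials(
                cfg,
                levels=levels,
                reps=reps,
                response_window=response_window,
                inter_trial_gap=inter_trial_gap,
                seed=s,
            )
            _, dr = model_response_curve(trialset, truncate_at=truncate)
            rows.append(
                {
                    "gamma": g,
                    "seed": s,
                    "depression_window": depression_window,
                    "full_range": full_range,
                    "delta": dr.delta if dr is not None else 0.0,
                    "delta_defined": dr is not None,
                    "r_min": trialset.r_min(),
                }
            )
    return pd.DataFrame(rows)


def figure_suite(
    gammas: Sequence[float] = GAMMA_GRID,
    n_seeds: int = 3,
    n_steps: int = 200_000,
    seed: int = 0,
    reps: int = 20,
    out_dir: str | Path | None = None,
    config: RunConfig = RunConfig(),
) -> dict[str, pd.DataFrame]:
    """Model-side summary tables: ongoing-state statistics per gamma, and
    dynamic range per gamma for the depression/no-depression and
    truncated/full stimulus-range conditions.

    With ``out_dir`` the tables are written as CSV plus a provenance JSON.
    """
    states = state_sweep(gammas, n_seeds, n_steps, seed, config)
    dr_dep_trunc = dynamic_range_sweep(
        gammas, n_seeds, seed, depression_window=80, full_range=False,
        reps=reps, config=config,
    )
    dr_dep_full = dynamic_range_sweep(
        gammas, n_seeds, seed, depression_window=80, full_range=True,
        reps=reps, config=config,
    )
    dr_nodep_full = dynamic_range_sweep(
        gammas, n_seeds, seed, depression_window=0, full_range=True,
        reps=reps, config=config,
    )
    tables = {
        "ongoing_state": states,
        "dynrange_depression_truncated": dr_dep_trunc,
        "dynrange_depression_full": dr_dep_full,
        "dynrange_nodepression_full": dr_nodep_full,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        write_provenance(out / "provenance.json", config, seed)
    return tables


def write_provenance(path: str | Path, config: RunConfig, seed: int) -> None:
    """JSON sidecar naming the config (hash), seed and library versions."""
    import scipy

    payload = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": seed,
        "versions": {
            "critrange": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
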