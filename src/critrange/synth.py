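"""Synthetic 32-channel recordings with known ground truth.

Stands in for an undeposited multielectrode barrel-cortex dataset so the
full experimental analysis path (binning, avalanche detection, kappa,
correlations, response curves, dynamic range) can be exercised end to end
against planted parameters.  Two ongoing-activity sources are available:

* ``parametric`` -- per-channel Poisson spiking whose rate is multiplied by
  a shared two-state (quiet/burst) Markov modulator.  The shared modulator
  creates positive inter-channel correlations and supra-threshold count
  excursions (avalanche-like epochs) with tunable strength.  This is a
  statistical fixture, not a biophysical model.
* ``model`` -- ongoing activity simulated with the spiking network at a
  chosen inhibitory modulation gamma, channelized to ``n_channels`` groups;
  the fidelity option for kappa/correlation recovery studies.

Stimulus trials follow the experimental design: ``n_levels`` puff
intensities, each repeated ``reps`` times in pseudorandom order at
``interval_s`` spacing.  Each trial's whisker speed is its level mean times
a lognormal jitter (repeated identical puffs move the whisker differently),
and the evoked response is Poisson with mean f(speed) - R_min over the
100 ms response window, spread across channels proportionally to their
baseline rates, where f is the planted sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from numpy.random import Generator

from .avalanches import EventTable
from .network import ModelConfig, simulate_ongoing
from .response import RESPONSE_WINDOW_S, SigmoidFit, dynamic_range

__all__ = ["SynthParams", "SyntheticRecording", "generate_recording", "truth_delta"]


@dataclass(frozen=True)
class SynthParams:
    """Design of a synthetic recording (defaults mirror the study design)."""

    n_channels: int = 32
    duration_s: float = 1560.0  # 160 s ongoing lead-in + 200 trials at 7 s
    # --- ongoing-activity source
    mode: str = "parametric"  # or "model"
    gamma: float = 1.0
    model_config: ModelConfig | None = None
    ongoing_rate_hz: float = 20.0  # network-wide; R_min = rate * 0.1 s
    burst_rate_multiplier: float = 8.0
    burst_mean_duration_s: float = 0.05
    quiet_mean_duration_s: float = 0.45
    # --- stimulus design
    n_levels: int = 10
    reps: int = 20
    interval_s: float = 7.0
    stimulus_duration_s: float = 1.0
    lead_in_s: float = 160.0
    speed_min: float = 2.0  # mm/s, mean of weakest puff level
    speed_max: float = 28.0  # mm/s, mean of strongest puff level
    speed_jitter_sigma: float = 0.2  # lognormal sigma of trial-to-trial speed
    # --- planted stimulus-response sigmoid
    r_min: float = 2.0  # ongoing spikes per 100 ms window
    r_max: float = 50.0
    b: float = 0.5
    c: float = 10.0  # mm/s

    def __post_init__(self) -> None:
        if self.mode not in ("parametric", "model"):
            raise ValueError("mode must be 'parametric' or 'model'")
        if self.ongoing_rate_hz < 0 or self.burst_rate_multiplier < 0:
            raise ValueError("rates must be non-negative")
        n_trials = self.n_levels * self.reps
        if self.lead_in_s + n_trials * self.interval_s > self.duration_s:
            raise ValueError(
                "stimulus schedule does not fit in duration_s "
                f"(needs {self.lead_in_s + n_trials * self.interval_s:.0f} s)"
            )
        if self.interval_s < self.stimulus_duration_s:
            raise ValueError("interval_s must exceed stimulus_duration_s")

    @property
    def level_speeds(self) -> np.ndarray:
        """Mean whisker speed of each puff intensity level (mm/s)."""
        return np.linspace(self.speed_min, self.speed_max, self.n_levels)

    def planted_sigmoid(self) -> SigmoidFit:
        return SigmoidFit(
            r_min=self.r_min, r_max=self.r_max, b=self.b, c=self.c, converged=True
        )


@dataclass
class SyntheticRecording:
    """Events plus the per-trial stimulus log and the planted ground truth."""

    events: EventTable
    stimulus_log: pd.DataFrame  # onset_s, speed, expected_evoked
    params: SynthParams
    delta_true: float

    def exclusion_windows(self, recovery_margin_s: float = 1.0) -> list[tuple[float, float]]:
        """Stimulus epochs to exclude from ongoing-activity analysis:
        [onset, onset + stimulus duration + recovery margin)."""
        width = self.params.stimulus_duration_s + recovery_margin_s
        return [(t, t + width) for t in self.stimulus_log["onset_s"]]


def truth_delta(params: SynthParams) -> float:
    """Analytic dynamic range of the planted sigmoid.

    Uses the same S10/S90 inversion and the same S10-clamping rule as the
    analysis path (clamp floor: the weakest level's mean speed), so planted
    truth and pipeline estimate are directly comparable.
    """
    res = dynamic_range(
        params.planted_sigmoid(), smallest_positive_stimulus=params.speed_min
    )
    return res.delta


def _ongoing_parametric(params: SynthParams, rng: Generator) -> tuple[np.ndarray, np.ndarray]:
    """Modulated-Poisson ongoing events; returns (channels, times)."""
    res = 0.005  # 5 ms modulator resolution
    n_bins = int(np.ceil(params.duration_s / res))
    # two-state Markov chain sampled at the modulator resolution
    p_qb = min(res / params.quiet_mean_duration_s, 1.0)
    p_bq = min(res / params.burst_mean_duration_s, 1.0)
    u = rng.random(n_bins)
    state = np.empty(n_bins, dtype=bool)  # True = burst
    cur = False
    for i in range(n_bins):  # cheap: ~3e5 iterations for 26 min
        cur = (not cur and u[i] < p_qb) or (cur and u[i] >= p_bq)
        state[i] = cur
    mult = np.where(state, params.burst_rate_multiplier, 1.0)
    # normalize so the time-averaged network rate equals ongoing_rate_hz
    mult = mult / mult.mean()
    channel_rates = np.full(params.n_channels, params.ongoing_rate_hz / params.n_channels)
    lam = np.outer(channel_rates, mult) * res  # channels x bins
    counts = rng.poisson(lam)
    ch_idx, bin_idx = np.nonzero(counts)
    reps = counts[ch_idx, bin_idx]
    channels = np.repeat(ch_idx, reps)
    bins = np.repeat(bin_idx, reps)
    times = (bins + rng.random(channels.size)) * res
    keep = times < params.duration_s
    return channels[keep], times[keep]


def _ongoing_model(params: SynthParams, rng: Generator) -> tuple[np.ndarray, np.ndarray]:
    """Network-model ongoing events channelized to n_channels groups."""
    from .correlations import group_assignments

    cfg = params.model_config or ModelConfig(gamma=params.gamma)
    if cfg.gamma != params.gamma:
        cfg = ModelConfig(
            n_neurons=cfg.n_neurons,
            inhibitory_fraction=cfg.inhibitory_fraction,
            gamma=params.gamma,
            depression_window=cfg.depression_window,
            p_ext_baseline=cfg.p_ext_baseline,
            step_duration=cfg.step_duration,
        )
    n_steps = int(round(params.duration_s / cfg.step_duration))
    raster = simulate_ongoing(cfg, n_steps, seed=rng)
    groups = group_assignments(cfg.n_neurons, params.n_channels)
    channels = groups[raster.spike_neurons]
    # jitter within the step so events are not lattice-aligned in seconds
    times = (raster.spike_steps + rng.random(channels.size)) * cfg.step_duration
    return channels.astype(np.int64), times


def generate_recording(params: SynthParams, seed: int | Generator | None = None) -> SyntheticRecording:
    """Generate a synthetic recording with planted response ground truth."""
    rng = seed if isinstance(seed, Generator) else np.random.default_rng(seed)
    if params.mode == "parametric":
        channels, times = _ongoing_parametric(params, rng)
    else:
        channels, times = _ongoing_model(params, rng)
    # channel weights for distributing evoked spikes
    baseline = np.bincount(channels, minlength=params.n_channels).astype(float)
    if baseline.sum() == 0:
        baseline[:] = 1.0
    weights = baseline / baseline.sum()

    n_trials = params.n_levels * params.reps
    level_idx = np.repeat(np.arange(params.n_levels), params.reps)
    rng.shuffle(level_idx)
    onsets = params.lead_in_s + np.arange(n_trials) * params.interval_s
    level_speeds = params.level_speeds
    jitter = rng.lognormal(mean=0.0, sigma=params.speed_jitter_sigma, size=n_trials)
    speeds = level_speeds[level_idx] * jitter
    f = params.planted_sigmoid()
    expected = np.maximum(np.asarray(f(speeds)) - params.r_min, 0.0)
    ev_channels, ev_times = [channels], [times]
    for onset, mu in zip(onsets, expected):
        k = rng.poisson(mu)
        if k == 0:
            continue
        ev_channels.append(rng.choice(params.n_channels, size=k, p=weights))
        ev_times.append(onset + rng.random(k) * RESPONSE_WINDOW_S)
    all_ch = np.concatenate(ev_channels)
    all_t = np.concatenate(ev_times)
    order = np.argsort(all_t, kind="stable")
    events = EventTable(all_ch[order], all_t[order], params.n_channels)
    log = pd.DataFrame(
        {"onset_s": onsets, "speed": speeds, "expected_evoked": expected}
    )
    try:
        delta_true = truth_delta(params)
    except ValueError:
        # null or degenerate planted response: no defined dynamic range
        delta_true = float("nan")
    return SyntheticRecording(
        events=events,
        stimulus_log=log,
        params=params,
        delta_true=delta_true,
    )
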