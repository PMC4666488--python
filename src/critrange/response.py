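"""Stimulus-response curves, sigmoid fits and sensory dynamic range.

Dynamic range quantifies the band of stimulus intensities a population can
discriminate:

    Delta = 10 * log10(S90 / S10)

where S10 and S90 are the stimulus values evoking 10% and 90% of the
response range above the ongoing floor, R_p = R_min + p * (R_max - R_min).
On the experiment-like path the response curve (mean multi-unit response in
the 100 ms after stimulus onset, binned over 10 equally spaced stimulus
values) is fit with a sigmoid

    f(x) = R_max / (1 + exp(-b (x - c))) + R_min,

with R_min fixed at the ongoing count per response window, and S10/S90 read
off the fit analytically.  On the model path the mean response per external
drive level is interpolated monotonically on a log-stimulus axis instead of
being fit (model curves are far less noisy), with the stimulus range
truncated at drive 1e-3 by default to stay in the physiologically relevant
regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .avalanches import EventTable
from .network import StimulusTrialSet

__all__ = [
    "TrialTable",
    "ResponseCurve",
    "SigmoidFit",
    "DynamicRangeResult",
    "sigmoid",
    "extract_responses",
    "select_dominant_whisker",
    "bin_curve",
    "fit_sigmoid",
    "dynamic_range",
    "model_response_curve",
]

RESPONSE_WINDOW_S = 0.1
N_STIMULUS_BINS = 10
MODEL_STIMULUS_TRUNCATION = 1e-3


@dataclass
class TrialTable:
    """Per-trial (onset, stimulus value, response count) records."""

    onsets: np.ndarray
    stimuli: np.ndarray
    responses: np.ndarray
    whisker: int | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if not (self.onsets.shape == self.stimuli.shape == self.responses.shape):
            raise ValueError("onsets, stimuli and responses must align")
        if np.any(self.responses < 0) or np.any(self.stimuli < 0):
            raise ValueError("stimuli and responses must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(self.onsets.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets, "stimulus": self.stimuli, "response": self.responses}
        )


@dataclass
class ResponseCurve:
    """Binned stimulus-response pairs (mean response per stimulus bin)."""

    bin_centers: np.ndarray
    mean_responses: np.ndarray
    bin_counts: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.bin_counts > 0

    @property
    def has_empty_bins(self) -> bool:
        return bool(np.any(self.bin_counts == 0))


@dataclass
class SigmoidFit:
    """Fitted sigmoid with fixed floor R_min and diagnostics."""

    r_min: float
    r_max: float
    b: float
    c: float
    converged: bool
    residual_norm: float = float("nan")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return sigmoid(x, self.r_max, self.b, self.c, self.r_min)


@dataclass
class DynamicRangeResult:
    """S10/S90 stimulus levels, the response levels and Delta (dB)."""

    s10: float
    s90: float
    r10: float
    r90: float
    delta: float
    clamped: bool = False


def sigmoid(x, r_max, b, c, r_min):
    """f(x) = R_max / (1 + exp(-b (x - c))) + R_min."""
    return r_max / (1.0 + np.exp(-b * (np.asarray(x, dtype=float) - c))) + r_min


def extract_responses(
    events: EventTable,
    stimulus_log: pd.DataFrame,
    window: float = RESPONSE_WINDOW_S,
    stimulus_column: str = "speed",
) -> TrialTable:
    """Per-trial response: total spikes across channels in [onset, onset+window).

    ``stimulus_log`` needs columns ``onset_s`` and the stimulus column
    (dominant-whisker speed averaged over the same window, or any per-trial
    intensity scalar).  Onsets must be sorted with non-overlapping windows.
    """
    onsets = stimulus_log["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < window):
        raise ValueError("response windows overlap or onsets are unsorted")
    times = np.sort(events.times)
    lo = np.searchsorted(times, onsets, side="left")
    hi = np.searchsorted(times, onsets + window, side="left")
    responses = (hi - lo).astype(float)
    return TrialTable(
        onsets=onsets,
        stimuli=stimulus_log[stimulus_column].to_numpy(dtype=float),
        responses=responses,
    )


def select_dominant_whisker(trial_tables: dict[int, TrialTable]) -> int:
    """Whisker whose trials evoke the largest mean response.

    Exact ties resolve to the lowest whisker id (logged as a warning).
    """
    if not trial_tables:
        raise ValueError("need at least one whisker")
    means = {wid: float(np.mean(tt.responses)) for wid, tt in trial_tables.items()}
    best = max(means.values())
    winners = sorted(wid for wid, m in means.items() if m == best)
    if len(winners) > 1:
        warnings.warn(
            f"dominant-whisker tie among {winners}; choosing lowest index",
            RuntimeWarning,
            stacklevel=2,
        )
    return winners[0]


def bin_curve(trials: TrialTable, n_bins: int = N_STIMULUS_BINS) -> ResponseCurve:
    """Mean response over ``n_bins`` equally spaced stimulus bins.

    Bins span the observed stimulus range; empty bins are flagged (zero
    count) and excluded from subsequent fitting.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = trials.stimuli
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("degenerate stimulus range: all stimuli identical")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = trials.responses[sel].mean()
    return ResponseCurve(bin_centers=centers, mean_responses=means, bin_counts=counts)


def fit_sigmoid(curve: ResponseCurve, r_min: float) -> SigmoidFit:
    """Least-squares sigmoid fit with R_min held fixed.

    Initialization: R_max at the curve's span above R_min, c at the
    half-maximum stimulus, b at 4 / stimulus range; b is constrained to
    (0, 100].  Degenerate or non-converging fits return ``converged=False``
    (dynamic range is then undefined).
    """
    occ = curve.occupied
    x = curve.bin_centers[occ]
    y = curve.mean_responses[occ]
    if x.size < 4:
        raise ValueError("need at least 4 non-empty bins to fit 3 parameters")
    span = float(y.max() - r_min)
    if span <= 0:
        return SigmoidFit(r_min, 0.0, np.nan, np.nan, converged=False)
    half = r_min + 0.5 * span
    c0 = float(x[np.argmin(np.abs(y - half))])
    x_range = float(x.max() - x.min())
    b0 = 4.0 / x_range if x_range > 0 else 1.0
    try:
        popt, _ = curve_fit(
            lambda xx, r_max, b, c: sigmoid(xx, r_max, b, c, r_min),
            x,
            y,
            p0=[span, min(b0, 100.0), c0],
            bounds=([1e-12, 1e-9, -np.inf], [np.inf, 100.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return SigmoidFit(r_min, np.nan, np.nan, np.nan, converged=False)
    r_max, b, c = (float(v) for v in popt)
    resid = float(np.linalg.norm(y - sigmoid(x, r_max, b, c, r_min)))
    # a fit that collapsed the amplitude or pinned the slope bound is no fit
    converged = r_max > 1e-8 and 1e-8 < b < 100.0 - 1e-8
    return SigmoidFit(r_min, r_max, b, c, converged=converged, residual_norm=resid)


def dynamic_range(
    fit: SigmoidFit, smallest_positive_stimulus: float | None = None
) -> DynamicRangeResult:
    """Invert a converged sigmoid fit at R10/R90 and compute Delta.

    S_p = c - (1/b) ln(R_max / (R_p - R_min) - 1).  A shallow sigmoid can
    extrapolate S10 to or below zero stimulus, which is unphysical; in that
    case S10 is clamped to ``smallest_positive_stimulus`` (required then)
    and the result flagged.
    """
    if not fit.converged:
        raise ValueError("dynamic range undefined for a non-converged fit")
    span = fit.r_max - fit.r_min
    if span <= 0:
        raise ValueError("response range is non-positive (R_max <= R_min)")
    r10 = fit.r_min + 0.1 * span
    r90 = fit.r_min + 0.9 * span
    # S_p = c - (1/b) ln(R_max / (R_p - R_min) - 1)
    s10 = fit.c - np.log(fit.r_max / (r10 - fit.r_min) - 1.0) / fit.b
    s90 = fit.c - np.log(fit.r_max / (r90 - fit.r_min) - 1.0) / fit.b
    clamped = False
    if s10 <= 0:
        if smallest_positive_stimulus is None or smallest_positive_stimulus <= 0:
            raise ValueError(
                "S10 extrapolates to a non-positive stimulus; provide "
                "smallest_positive_stimulus to clamp"
            )
        warnings.warn(
            "S10 <= 0; clamped to the smallest positive observed stimulus",
            RuntimeWarning,
            stacklevel=2,
        )
        s10 = smallest_positive_stimulus
        clamped = True
    delta = 10.0 * np.log10(s90 / s10)
    return DynamicRangeResult(
        s10=float(s10), s90=float(s90), r10=float(r10), r90=float(r90),
        delta=float(delta), clamped=clamped,
    )


def _pava_increasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators: best monotone non-decreasing fit."""
    vals: list[float] = []
    wts: list[float] = []
    lens: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(float(yi)); wts.append(float(wi)); lens.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]; lens[-2] += lens[-1]
            vals[-2] = v
            vals.pop(); wts.pop(); lens.pop()
    return np.repeat(vals, lens)


def model_response_curve(
    trialset: StimulusTrialSet,
    truncate_at: float | None = MODEL_STIMULUS_TRUNCATION,
    r_min: float | None = None,
) -> tuple[ResponseCurve, DynamicRangeResult | None]:
    """Response curve and Delta for model stimulus trials (no sigmoid fit).

    The mean response per external-drive level is made monotone by
    pool-adjacent-violators and interpolated piecewise-linearly on the
    log10-stimulus axis to locate S10 and S90.  Levels above ``truncate_at``
    are discarded first (pass None for the full range).  R_min defaults to
    the trial set's matched ongoing count.  Conventions for extreme states:
    if the curve already exceeds a response landmark at the smallest level
    the landmark stimulus clamps there (a fully saturated state has
    Delta = 0); if the curve never reaches R90 the result is None (flagged
    via warning) and Delta undefined.
    """
    levels = trialset.levels
    means = trialset.mean_responses()
    if truncate_at is not None:
        keep = levels <= truncate_at
        levels, means = levels[keep], means[keep]
    if levels.size < 2:
        raise ValueError("need at least 2 stimulus levels after truncation")
    counts = np.array(
        [np.sum(trialset.trial_levels == lv) for lv in levels], dtype=np.int64
    )
    curve = ResponseCurve(bin_centers=levels, mean_responses=means, bin_counts=counts)
    if r_min is None:
        r_min = trialset.r_min()
    r_max = float(means.max())
    if r_max <= r_min:
        warnings.warn(
            "response curve never rises above the ongoing floor; Delta undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return curve, None
    r10 = r_min + 0.1 * (r_max - r_min)
    r90 = r_min + 0.9 * (r_max - r_min)
    mono = _pava_increasing(means, counts.astype(float))
    logx = np.log10(levels)
    if mono[-1] < r90:
        warnings.warn(
            "monotone response curve never reaches R90; Delta undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return curve, None
    clamped = False
    if mono[0] >= r10:
        s10_log = logx[0]
        clamped = True
    else:
        s10_log = float(np.interp(r10, mono, logx))
    if mono[0] >= r90:
        s90_log = logx[0]
        clamped = True
    else:
        s90_log = float(np.interp(r90, mono, logx))
    delta = 10.0 * (s90_log - s10_log)
    return curve, DynamicRangeResult(
        s10=10.0**s10_log, s90=10.0**s90_log, r10=float(r10), r90=float(r90),
        delta=float(delta), clamped=clamped,
    )
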