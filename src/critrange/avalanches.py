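"""Population spike-count binning and neuronal-avalanche detection.

An avalanche is a maximal run of consecutive time bins in which the
population (multi-unit) spike count stays strictly above a threshold TH.
Its *size* is the total spike count over the run, its *duration* the number
of bins, and its *spatial area* the number of channels contributing at least
one spike.  Runs touching the edges of the series, or abutting a masked
(e.g. stimulus) bin, are discarded as truncated: their true extent is
unknown and keeping them would bias the size distribution.

Two data paths share this module: experiment-like event tables binned at
DT ~ 5-20 ms with TH ~ 5-20 spikes, and model rasters binned at one time
step with TH = 10 spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .network import SpikeRaster

__all__ = [
    "EventTable",
    "CountSeries",
    "AvalancheSet",
    "bin_events",
    "count_series_from_raster",
    "detect_avalanches",
]

#: experiment-path defaults (means of the per-recording choices)
DEFAULT_DT = 0.0075
DEFAULT_TH = 11
#: model-path defaults
MODEL_BIN_STEPS = 1
MODEL_TH = 10


@dataclass
class EventTable:
    """Spike events as parallel (channel, time) arrays, times in seconds."""

    channels: np.ndarray
    times: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.channels.shape != self.times.shape:
            raise ValueError("channels and times must have equal length")
        if self.times.size and self.times.min() < 0:
            raise ValueError("event times must be non-negative")
        if self.times.size and self.channels.max() >= self.n_channels:
            raise ValueError("channel id exceeds n_channels")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def sorted_by_time(self) -> "EventTable":
        order = np.argsort(self.times, kind="stable")
        return EventTable(self.channels[order], self.times[order], self.n_channels)

    @classmethod
    def from_raster(cls, raster: SpikeRaster) -> "EventTable":
        """Treat every model neuron as a channel; steps become seconds."""
        return cls(
            channels=raster.spike_neurons.astype(np.int64),
            times=raster.spike_steps * raster.step_duration,
            n_channels=raster.n_neurons,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "time_s": self.times})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_channels: int | None = None) -> "EventTable":
        ch = df["channel"].to_numpy(dtype=np.int64)
        if n_channels is None:
            n_channels = int(ch.max()) + 1 if ch.size else 0
        return cls(ch, df["time_s"].to_numpy(dtype=float), n_channels)

    def write_tsv(self, path: str | Path) -> None:
        # %.17g round-trips float64 exactly
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path, n_channels: int | None = None) -> "EventTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls.from_frame(df, n_channels)


@dataclass
class CountSeries:
    """Binned population spike counts with optional per-channel detail.

    ``mask`` marks excluded bins (stimulus epochs); masked bins keep their
    counts but are skipped by avalanche detection and correlations.
    """

    counts: np.ndarray
    bin_duration: float
    per_channel: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.per_channel is not None:
            self.per_channel = np.asarray(self.per_channel, dtype=np.int64)
            if self.per_channel.shape[1] != self.counts.size:
                raise ValueError("per_channel must have one column per bin")
            if not np.array_equal(self.per_channel.sum(axis=0), self.counts):
                raise ValueError("counts must equal column sums of per_channel")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask must match counts shape")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    def effective_mask(self) -> np.ndarray:
        return self.mask if self.mask is not None else np.zeros(self.n_bins, dtype=bool)


@dataclass
class AvalancheSet:
    """Detected avalanches with size/duration/area and provenance."""

    start_bins: np.ndarray
    durations: np.ndarray
    sizes: np.ndarray
    areas: np.ndarray | None
    threshold: float
    bin_duration: float

    @property
    def n_avalanches(self) -> int:
        return int(self.sizes.size)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "start_bin": self.start_bins,
            "duration_bins": self.durations,
            "size": self.sizes,
        }
        if self.areas is not None:
            data["area_channels"] = self.areas
        return pd.DataFrame(data)


def bin_events(
    events: EventTable,
    dt: float,
    exclusion_windows: Iterable[tuple[float, float]] | None = None,
    n_bins: int | None = None,
) -> CountSeries:
    """Bin events into half-open time bins [k*dt, (k+1)*dt).

    Bins overlapping any exclusion window are masked, not zeroed.  The
    per-channel matrix is retained for spatial-area computation.  An empty
    event table yields an empty series.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if events.n_events == 0 and n_bins is None:
        return CountSeries(np.empty(0, dtype=np.int64), dt, None, None)
    bins = np.floor_divide(events.times, dt).astype(np.int64)
    if n_bins is None:
        n_bins = int(bins.max()) + 1 if bins.size else 0
    keep = bins < n_bins
    bins, ch = bins[keep], events.channels[keep]
    per_channel = np.zeros((events.n_channels, n_bins), dtype=np.int64)
    np.add.at(per_channel, (ch, bins), 1)
    counts = per_channel.sum(axis=0)
    mask = None
    if exclusion_windows is not None:
        mask = np.zeros(n_bins, dtype=bool)
        edges = np.arange(n_bins + 1) * dt
        for lo, hi in exclusion_windows:
            # a bin is excluded if [k*dt,(k+1)*dt) intersects [lo, hi)
            first = max(int(np.floor(lo / dt)), 0)
            last = min(int(np.ceil(hi / dt)), n_bins)
            if first < last:
                mask[first:last] = True
        del edges
    return CountSeries(counts, dt, per_channel, mask)


def count_series_from_raster(
    raster: SpikeRaster,
    bin_steps: int = MODEL_BIN_STEPS,
    per_channel_groups: int | None = None,
) -> CountSeries:
    """Model path: population counts per ``bin_steps`` simulation steps.

    When ``per_channel_groups`` is given the neurons are channelized into
    that many contiguous groups (see :func:`critrange.correlations.group_assignments`)
    and the per-channel matrix is kept.
    """
    if bin_steps < 1:
        raise ValueError("bin_steps must be >= 1")
    n_bins = raster.n_steps // bin_steps
    bins = raster.spike_steps // bin_steps
    keep = bins < n_bins
    bins = bins[keep]
    if per_channel_groups is not None:
        from .correlations import group_assignments

        groups = group_assignments(raster.n_neurons, per_channel_groups)
        ch = groups[raster.spike_neurons[keep]]
        per_channel = np.zeros((per_channel_groups, n_bins), dtype=np.int64)
        np.add.at(per_channel, (ch, bins), 1)
        counts = per_channel.sum(axis=0)
    else:
        per_channel = None
        counts = np.bincount(bins, minlength=n_bins).astype(np.int64)
    return CountSeries(counts, raster.step_duration * bin_steps, per_channel, None)


def detect_avalanches(series: CountSeries, threshold: float = DEFAULT_TH) -> AvalancheSet:
    """Find maximal runs of unmasked bins with count strictly above TH.

    Runs touching the series edges or abutting a masked bin are discarded
    (truncated avalanches have unknown true size).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    counts = series.counts
    mask = series.effective_mask()
    n = counts.size
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return AvalancheSet(empty, empty, empty, None, threshold, series.bin_duration)
    above = (counts > threshold) & ~mask
    padded = np.zeros(n + 2, dtype=np.int8)
    padded[1:-1] = above
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    # discard truncated runs: at series edge or adjacent to a masked bin
    ok = np.ones(starts.size, dtype=bool)
    ok &= starts > 0
    ok &= ends < n
    if series.mask is not None and starts.size:
        left_masked = mask[np.maximum(starts - 1, 0)]
        right_masked = mask[np.minimum(ends, n - 1)]
        ok &= ~left_masked & ~right_masked
    starts, ends = starts[ok], ends[ok]
    cs = np.concatenate(([0], np.cumsum(counts)))
    sizes = cs[ends] - cs[starts]
    durations = ends - starts
    areas = None
    if series.per_channel is not None:
        areas = np.empty(starts.size, dtype=np.int64)
        for i, (a, b) in enumerate(zip(starts, ends)):
            areas[i] = int((series.per_channel[:, a:b].sum(axis=1) > 0).sum())
    return AvalancheSet(
        start_bins=starts,
        durations=durations,
        sizes=sizes,
        areas=areas,
        threshold=threshold,
        bin_duration=series.bin_duration,
    )
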