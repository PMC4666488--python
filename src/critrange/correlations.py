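"""Pairwise-correlation characterization of the network state.

The cortical state is summarized by the zero-lag Pearson correlation between
spike-count time series of channel (electrode) pairs, computed over ongoing
activity only.  For model rasters, the neurons are first channelized into 32
contiguous groups, mirroring a 32-electrode array.  Mean pairwise correlation
rises sigmoidally with kappa, with kappa = 1 separating the weakly from the
strongly correlated regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SpikeRaster

__all__ = [
    "CorrelationResult",
    "group_assignments",
    "channelize_model",
    "pairwise_correlations",
    "summarize_vs_kappa",
]

N_GROUPS = 32
#: default model correlation bin, in simulation steps (~10 ms at 1 ms/step)
MODEL_CORR_BIN_STEPS = 10
KAPPA_BINS = 13


@dataclass
class CorrelationResult:
    """All unordered-pair Pearson coefficients and their mean.

    ``pair_values`` has length n*(n-1)/2 (upper-triangle order); pairs
    involving a zero-variance channel are NaN and excluded from the mean.
    """

    pair_values: np.ndarray
    mean_correlation: float
    n_channels: int
    bin_duration: float | None = None

    @property
    def n_pairs(self) -> int:
        return int(self.pair_values.size)

    def iqr(self) -> float:
        """Interquartile range of the (defined) pair coefficients."""
        vals = self.pair_values[~np.isnan(self.pair_values)]
        q1, q3 = np.percentile(vals, [25, 75])
        return float(q3 - q1)


def group_assignments(n_neurons: int, n_groups: int = N_GROUPS) -> np.ndarray:
    """Map neuron index -> group index using contiguous, near-equal blocks.

    Block sizes differ by at most one (1000 neurons -> 8 groups of 32 and
    24 groups of 31).
    """
    if n_groups > n_neurons:
        raise ValueError("n_groups must not exceed n_neurons")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    base = n_neurons // n_groups
    rem = n_neurons % n_groups
    sizes = np.full(n_groups, base, dtype=np.int64)
    sizes[:rem] += 1
    return np.repeat(np.arange(n_groups), sizes)


def channelize_model(
    raster: SpikeRaster,
    n_groups: int = N_GROUPS,
    bin_steps: int = MODEL_CORR_BIN_STEPS,
) -> np.ndarray:
    """Group spike-count matrix (n_groups x n_bins) from a model raster.

    Neurons are split into contiguous near-equal groups (like electrodes);
    each group's series is the summed spike count of its members per
    ``bin_steps``-step bin.  Total spikes are conserved up to the trailing
    partial bin, which is dropped.
    """
    if bin_steps < 1:
        raise ValueError("bin_steps must be >= 1")
    groups = group_assignments(raster.n_neurons, n_groups)
    n_bins = raster.n_steps // bin_steps
    if n_bins == 0:
        return np.zeros((n_groups, 0), dtype=np.int64)
    bins = raster.spike_steps // bin_steps
    keep = bins < n_bins
    mat = np.zeros((n_groups, n_bins), dtype=np.int64)
    np.add.at(mat, (groups[raster.spike_neurons[keep]], bins[keep]), 1)
    return mat


def pairwise_correlations(
    count_matrix: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    bin_duration: float | None = None,
) -> CorrelationResult:
    """Zero-lag Pearson coefficients for every unordered channel pair.

    ``count_matrix`` is channels x bins; bins flagged True in
    ``exclusion_mask`` (stimulus epochs) are dropped before correlating.
    Channels with zero variance produce NaN pairs, which are excluded from
    the mean; an all-constant matrix yields an all-NaN result with a warning.
    """
    X = np.asarray(count_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("count_matrix must be 2-D with at least 2 channels")
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        X = X[:, ~exclusion_mask]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 unmasked bins")
    n = X.shape[0]
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    degenerate = sd == 0
    C[degenerate, :] = np.nan
    C[:, degenerate] = np.nan
    iu = np.triu_indices(n, k=1)
    pairs = C[iu]
    if np.all(np.isnan(pairs)):
        warnings.warn(
            "all channel pairs undefined (zero-variance channels)",
            RuntimeWarning,
            stacklevel=2,
        )
        mean = float("nan")
    else:
        mean = float(np.nanmean(pairs))
    return CorrelationResult(
        pair_values=pairs,
        mean_correlation=mean,
        n_channels=n,
        bin_duration=bin_duration,
    )


def summarize_vs_kappa(
    records: pd.DataFrame,
    value_columns: list[str] | None = None,
    n_bins: int = KAPPA_BINS,
) -> pd.DataFrame:
    """Bin per-recording records into equal-width kappa bins and summarize.

    ``records`` needs a ``kappa`` column plus one or more value columns
    (e.g. ``mean_correlation``, ``delta``).  Bins partition the observed
    kappa range; for each populated bin the frame reports, per value column,
    the mean, standard error, median and quartiles.  A single record passes
    through as a single bin.
    """
    if len(records) < 1:
        raise ValueError("need at least one record")
    if value_columns is None:
        value_columns = [c for c in records.columns if c != "kappa"]
    kap = records["kappa"].to_numpy(dtype=float)
    lo, hi = kap.min(), kap.max()
    if len(records) == 1 or lo == hi:
        edges = np.array([lo, np.nextafter(hi, np.inf)])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, kap, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in np.unique(idx):
        sel = records.iloc[idx == b]
        row = {
            "kappa_bin_low": edges[b],
            "kappa_bin_high": edges[b + 1],
            "kappa_center": 0.5 * (edges[b] + edges[b + 1]),
            "n_records": len(sel),
        }
        for col in value_columns:
            v = sel[col].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size == 0:
                continue
            row[f"{col}_mean"] = v.mean()
            row[f"{col}_sem"] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
            row[f"{col}_median"] = float(np.median(v))
            row[f"{col}_q1"] = float(np.percentile(v, 25))
            row[f"{col}_q3"] = float(np.percentile(v, 75))
        rows.append(row)
    return pd.DataFrame(rows)
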