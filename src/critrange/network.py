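"""Binary probabilistic network model with activity-dependent depression.

The model is a population of ``N`` binary, probabilistic integrate-and-fire
units with all-to-all random coupling.  At every discrete time step (nominally
1 ms) each neuron fires either because an independent external Bernoulli event
with probability ``p_ext`` succeeds, or because a recurrent Bernoulli event
succeeds with probability

    p_i(t) = clip(I_i(t), 0, 1),     I_i(t) = (sum_{j != i} W_ij s_j(t-1)) / h_i(t),

where ``h_i(t)`` is the neuron's own spike count over the preceding ``T``
steps (set to 1 when the count is zero, and identically 1 when ``T = 0``,
i.e. no depression).  The synaptic matrix ``W`` has uniform [0, 1] entries,
a fraction of all-negative (inhibitory) columns, zero diagonal, and is
rescaled once at construction so its leading eigenvalue is exactly 1 -- the
critical point of the linearized dynamics.  Multiplying the negative entries
by a modulation factor ``gamma`` (0 = inhibition fully blocked, >1 =
inhibition enhanced) then moves the leading eigenvalue above or below 1,
pushing the network into the super- or subcritical regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.random import Generator

__all__ = [
    "ModelConfig",
    "WeightMatrix",
    "NetworkState",
    "SpikeRaster",
    "StimulusTrialSet",
    "build_weight_matrix",
    "apply_inhibitory_modulation",
    "depression_divisor",
    "step",
    "simulate_ongoing",
    "simulate_stimulus_trials",
    "default_stimulus_levels",
]

#: p_ext range used for the stimulus protocol (per-neuron, per-step).
P_EXT_BASELINE = 5e-6
P_EXT_STIM_MAX = 1e-3


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the network model.

    Defaults follow the reference parameterization: 1000 neurons, 20%
    inhibitory, depression window T = 80 steps, baseline external drive
    5e-6 per neuron per 1 ms step (5 externally driven spikes/s network-wide).
    """

    n_neurons: int = 1000
    inhibitory_fraction: float = 0.2
    gamma: float = 1.0
    depression_window: int = 80
    p_ext_baseline: float = P_EXT_BASELINE
    step_duration: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError("inhibitory_fraction must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.depression_window < 0:
            raise ValueError("depression_window must be >= 0")
        if not 0.0 <= self.p_ext_baseline <= 1.0:
            raise ValueError("p_ext_baseline must be a probability")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")


@dataclass(frozen=True)
class WeightMatrix:
    """Signed synaptic coupling matrix with construction metadata.

    ``weights`` has zero diagonal and, at ``gamma_applied = 1``, leading
    eigenvalue of magnitude 1.  ``scale_factor`` is the constant the raw
    uniform matrix was multiplied by at construction.
    """

    weights: np.ndarray
    inhibitory_columns: np.ndarray
    scale_factor: float
    gamma_applied: float = 1.0

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def leading_eigenvalue_magnitude(self) -> float:
        """Numerically recompute |lambda_max| of the current matrix."""
        return abs(_leading_eigenvalue(self.weights))


@dataclass
class NetworkState:
    """Instantaneous state of the simulated network.

    ``s`` is the binary firing vector, ``history_counts[i]`` the number of
    spikes of neuron i over the preceding ``T`` steps (the causal window
    t-T..t-1), and ``external_flags`` marks neurons whose most recent spike
    included a successful external draw.
    """

    s: np.ndarray
    history_counts: np.ndarray
    history_ring: np.ndarray  # (max(T,1), N) circular buffer of past spikes
    ring_pos: int
    external_flags: np.ndarray
    depression_window: int = 80
    t: int = 0

    @classmethod
    def zeros(cls, n_neurons: int, depression_window: int) -> "NetworkState":
        T = max(depression_window, 1)
        return cls(
            s=np.zeros(n_neurons, dtype=bool),
            history_counts=np.zeros(n_neurons, dtype=np.int32),
            history_ring=np.zeros((T, n_neurons), dtype=bool),
            ring_pos=0,
            external_flags=np.zeros(n_neurons, dtype=bool),
            depression_window=depression_window,
        )


@dataclass
class SpikeRaster:
    """Sparse spike raster (neuron x step) from a simulation.

    Spikes are stored as parallel arrays of (step, neuron) with a boolean
    flag marking externally driven events; this keeps long low-rate
    recordings small.  ``to_dense`` materializes the binary matrix.
    """

    n_neurons: int
    n_steps: int
    step_duration: float
    spike_steps: np.ndarray
    spike_neurons: np.ndarray
    external: np.ndarray
    config: ModelConfig | None = None

    @property
    def n_spikes(self) -> int:
        return int(self.spike_steps.size)

    def population_counts(self) -> np.ndarray:
        """Network-wide spike count per time step."""
        return np.bincount(self.spike_steps, minlength=self.n_steps).astype(np.int64)

    def external_count(self) -> int:
        return int(self.external.sum())

    def to_dense(self) -> np.ndarray:
        dense = np.zeros((self.n_neurons, self.n_steps), dtype=bool)
        dense[self.spike_neurons, self.spike_steps] = True
        return dense

    def external_to_dense(self) -> np.ndarray:
        dense = np.zeros((self.n_neurons, self.n_steps), dtype=bool)
        dense[self.spike_neurons[self.external], self.spike_steps[self.external]] = True
        return dense


@dataclass
class StimulusTrialSet:
    """Responses of the model to step increases of the external drive.

    One trial: the external drive steps from baseline up to ``level`` at
    ``onset_step`` and the response is the total network spike count over the
    following ``response_window`` steps.  ``ongoing_counts`` holds, per trial,
    the network spike count over a baseline-drive window of the same length
    immediately preceding the onset (used as the response floor R_min).
    """

    levels: np.ndarray
    repetitions: int
    response_window: int
    trial_levels: np.ndarray
    onset_steps: np.ndarray
    responses: np.ndarray
    ongoing_counts: np.ndarray
    config: ModelConfig | None = None

    @property
    def n_trials(self) -> int:
        return int(self.trial_levels.size)

    def r_min(self, n_warmup_trials: int = 5) -> float:
        """Mean ongoing spike count per response window (baseline drive).

        The first few trials' gaps are discarded as warm-up: a continuous
        session starts from quiescence, and states with a self-sustained
        stationary level (or slow depression build-up) only reach it after
        the initial gaps.  Without the discard a fully saturated state
        appears to rise above its own floor purely through start-up bias.
        """
        counts = self.ongoing_counts
        if counts.size > n_warmup_trials:
            counts = counts[n_warmup_trials:]
        return float(np.mean(counts))

    def mean_responses(self) -> np.ndarray:
        """Mean response at each stimulus level, in ``levels`` order."""
        out = np.empty(self.levels.size)
        for i, lv in enumerate(self.levels):
            out[i] = self.responses[self.trial_levels == lv].mean()
        return out


# ---------------------------------------------------------------------------
# Weight matrix construction


def _leading_eigenvalue(W: np.ndarray) -> complex:
    """Eigenvalue of largest magnitude of a dense square matrix."""
    n = W.shape[0]
    if n >= 64:
        from scipy.sparse.linalg import ArpackNoConvergence, eigs

        try:
            vals = eigs(W, k=1, which="LM", return_eigenvectors=False, maxiter=n * 100)
        except ArpackNoConvergence as exc:  # pragma: no cover - rare
            raise ArithmeticError("leading-eigenvalue iteration did not converge") from exc
        return complex(vals[0])
    vals = np.linalg.eigvals(W)
    return complex(vals[np.argmax(np.abs(vals))])


def build_weight_matrix(
    config: ModelConfig, seed: int | Generator | None = None
) -> WeightMatrix:
    """Construct the default synaptic matrix.

    Entries are uniform on [0, 1]; ``round(N * inhibitory_fraction)`` randomly
    chosen columns are negated; the diagonal is zeroed; the whole matrix is
    rescaled once so the leading eigenvalue magnitude is 1 (tolerance 1e-9).
    The inhibitory modulation ``gamma`` is *not* applied here -- rescaling
    always happens at gamma = 1 so that modulation afterwards moves the
    eigenvalue away from the critical value.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, Generator) else np.random.default_rng(seed)
    n = config.n_neurons
    W = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(W, 0.0)
    n_inh = round(n * config.inhibitory_fraction)
    inhibitory = np.sort(rng.choice(n, size=n_inh, replace=False))
    W[:, inhibitory] *= -1.0
    lam = _leading_eigenvalue(W)
    if abs(lam.imag) > 1e-9 * abs(lam) or lam.real <= 0:
        warnings.warn(
            "leading eigenvalue is not real positive; rescaling by its magnitude",
            RuntimeWarning,
            stacklevel=2,
        )
    scale = 1.0 / abs(lam)
    W *= scale
    return WeightMatrix(
        weights=W,
        inhibitory_columns=inhibitory,
        scale_factor=scale,
        gamma_applied=1.0,
    )


def apply_inhibitory_modulation(wm: WeightMatrix, gamma: float) -> WeightMatrix:
    """Multiply all negative entries of W by ``gamma``.

    ``gamma = 0`` removes inhibition entirely (strong GABA antagonist),
    ``gamma > 1`` strengthens it (GABA agonist).  Positive entries are
    untouched.  Returns a new :class:`WeightMatrix`; the input is not
    modified.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    W = wm.weights.copy()
    neg = W < 0
    W[neg] *= gamma
    return replace(wm, weights=W, gamma_applied=wm.gamma_applied * gamma)


# ---------------------------------------------------------------------------
# Dynamics


def depression_divisor(
    history_counts: np.ndarray | Sequence[int], neuron: int | None = None
) -> float | np.ndarray:
    """Divisive depression factor h from the recent spike-count window.

    Returns the spike count of the neuron over the causal window of the last
    ``T`` steps, replaced by 1 wherever the count is zero (and therefore
    identically 1 when depression is disabled, since the counts stay zero).
    With ``neuron=None`` the whole vector of divisors is returned.
    """
    counts = np.asarray(history_counts)
    if neuron is not None:
        c = int(counts[neuron])
        return float(c) if c > 0 else 1.0
    return np.maximum(counts, 1).astype(float)


class _Simulator:
    """In-place stepping engine shared by all drivers.

    Draw protocol per step (fixed for reproducibility): one uniform draw per
    neuron for the recurrent event, then one per neuron for the external
    event.  A neuron fires if either succeeds.
    """

    def __init__(self, weights: np.ndarray, depression_window: int, rng: Generator):
        self.W = np.ascontiguousarray(weights)
        self.N = weights.shape[0]
        self.T = depression_window
        self.rng = rng
        # switch to a BLAS matvec once this many neurons are active
        self._dense_threshold = max(self.N // 4, 8)
        self.reset()

    def reset(self) -> None:
        self.active = np.empty(0, dtype=np.int64)
        self.counts = np.zeros(self.N, dtype=np.int32)
        self.ring = np.zeros((max(self.T, 1), self.N), dtype=bool)
        self.pos = 0
        self.ext = np.zeros(self.N, dtype=bool)

    def load_state(self, state: NetworkState) -> None:
        self.active = np.flatnonzero(state.s)
        self.counts = state.history_counts.astype(np.int32).copy()
        self.ring = state.history_ring.copy()
        self.pos = state.ring_pos
        self.ext = state.external_flags.copy()

    def advance(self, p_ext: float) -> np.ndarray:
        """Advance one step; returns the indices of neurons firing now."""
        k = self.active
        if k.size == 0:
            p = None
        else:
            if k.size <= self._dense_threshold:
                drive = self.W[:, k].sum(axis=1)
            else:
                sf = np.zeros(self.N)
                sf[k] = 1.0
                drive = self.W @ sf
            if self.T > 0:
                drive /= np.maximum(self.counts, 1)
            p = np.clip(drive, 0.0, 1.0)
        r_rec = self.rng.random(self.N)
        r_ext = self.rng.random(self.N)
        ext = r_ext < p_ext
        if p is None:
            s_new = ext.copy()
        else:
            s_new = (r_rec < p) | ext
        self.ext = ext
        if self.T > 0:
            old = self.ring[self.pos]
            np.subtract(self.counts, old, out=self.counts, casting="unsafe")
            self.ring[self.pos] = s_new
            np.add(self.counts, s_new, out=self.counts, casting="unsafe")
            self.pos = (self.pos + 1) % self.T
        self.active = np.flatnonzero(s_new)
        return self.active


def step(
    state: NetworkState, weights: WeightMatrix, p_ext: float, rng: Generator
) -> NetworkState:
    """Advance the network by one time step (functional form).

    Thin wrapper over the in-place engine used by the simulation drivers, so
    single-step semantics and driver semantics cannot drift apart.
    """
    if state.s.size != weights.n_neurons:
        raise ValueError("state size does not match weight matrix")
    sim = _Simulator(weights.weights, state.depression_window, rng)
    sim.load_state(state)
    active = sim.advance(p_ext)
    s = np.zeros(weights.n_neurons, dtype=bool)
    s[active] = True
    return NetworkState(
        s=s,
        history_counts=sim.counts,
        history_ring=sim.ring,
        ring_pos=sim.pos,
        external_flags=sim.ext,
        depression_window=state.depression_window,
        t=state.t + 1,
    )


def simulate_ongoing(
    config: ModelConfig,
    n_steps: int,
    seed: int | Generator | None = None,
    weights: WeightMatrix | None = None,
) -> SpikeRaster:
    """Simulate ongoing activity at the baseline external drive.

    The weight matrix is built from ``config`` (construction and dynamics
    share one seeded generator, so identical ``(config, seed)`` give
    bit-identical rasters) unless a prebuilt ``weights`` is passed, in which
    case the inhibitory modulation ``config.gamma`` is applied to it.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, Generator) else np.random.default_rng(seed)
    if weights is None:
        weights = build_weight_matrix(config, rng)
    wm = apply_inhibitory_modulation(weights, config.gamma)
    sim = _Simulator(wm.weights, config.depression_window, rng)
    steps_acc: list[np.ndarray] = []
    neurons_acc: list[np.ndarray] = []
    ext_acc: list[np.ndarray] = []
    for t in range(n_steps):
        active = sim.advance(config.p_ext_baseline)
        if active.size:
            steps_acc.append(np.full(active.size, t, dtype=np.int64))
            neurons_acc.append(active.astype(np.int32))
            ext_acc.append(sim.ext[active])
    if steps_acc:
        spike_steps = np.concatenate(steps_acc)
        spike_neurons = np.concatenate(neurons_acc)
        external = np.concatenate(ext_acc)
    else:
        spike_steps = np.empty(0, dtype=np.int64)
        spike_neurons = np.empty(0, dtype=np.int32)
        external = np.empty(0, dtype=bool)
    return SpikeRaster(
        n_neurons=config.n_neurons,
        n_steps=n_steps,
        step_duration=config.step_duration,
        spike_steps=spike_steps,
        spike_neurons=spike_neurons,
        external=external,
        config=config,
    )


def default_stimulus_levels(
    n_levels: int = 10,
    low: float = P_EXT_BASELINE,
    high: float = P_EXT_STIM_MAX,
) -> np.ndarray:
    """Logarithmically spaced external-drive levels for stimulus trials.

    Mirrors the 10 experimental puff intensities; the default range spans the
    baseline drive up to 1e-3 per neuron per step (5 to 1000 externally
    driven spikes/s network-wide).
    """
    levels = np.logspace(np.log10(low), np.log10(high), n_levels)
    levels[0], levels[-1] = low, high  # exact endpoints despite log round-trip
    return levels


def simulate_stimulus_trials(
    config: ModelConfig,
    levels: Sequence[float] | np.ndarray | None = None,
    reps: int = 20,
    response_window: int = 200,
    inter_trial_gap: int = 1500,
    seed: int | Generator | None = None,
    weights: WeightMatrix | None = None,
    reset_between_trials: bool = False,
) -> StimulusTrialSet:
    """Run the step-stimulus protocol and collect windowed responses.

    Each trial the external drive steps up from baseline to the trial's
    level for ``response_window`` steps; the response is the total network
    spike count in that window.  Trials are run in pseudorandom level order.
    ``inter_trial_gap`` baseline-drive steps precede every onset, so response
    windows never overlap.  By default the session is continuous, mirroring
    an experimental recording: the network carries its state across trials,
    so a regime whose stationary state is self-sustained (e.g. no-depression
    supercritical saturation) is measured in that state rather than from an
    artificial quiescent restart.  ``reset_between_trials=True`` instead
    clears the state before each gap, making trials statistically
    independent.  The last ``response_window`` steps of each gap provide the
    matched ongoing count used as R_min.
    """
    if levels is None:
        levels = default_stimulus_levels()
    levels = np.asarray(levels, dtype=float)
    if levels.ndim != 1 or levels.size < 1:
        raise ValueError("levels must be a non-empty 1-D sequence")
    if np.any(levels < config.p_ext_baseline) or np.any(levels > 1.0):
        raise ValueError("stimulus levels must lie in [p_ext_baseline, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if response_window < 1:
        raise ValueError("response_window must be >= 1")
    if inter_trial_gap < response_window:
        raise ValueError(
            "inter_trial_gap must be >= response_window so ongoing and "
            "response windows do not overlap"
        )
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, Generator) else np.random.default_rng(seed)
    if weights is None:
        weights = build_weight_matrix(config, rng)
    wm = apply_inhibitory_modulation(weights, config.gamma)
    sim = _Simulator(wm.weights, config.depression_window, rng)

    order = np.repeat(np.arange(levels.size), reps)
    rng.shuffle(order)
    n_trials = order.size
    responses = np.zeros(n_trials, dtype=np.int64)
    ongoing = np.zeros(n_trials, dtype=np.int64)
    onsets = np.zeros(n_trials, dtype=np.int64)
    t = 0
    tail_start = inter_trial_gap - response_window
    for i, level_idx in enumerate(order):
        if reset_between_trials:
            sim.reset()
        og = 0
        for j in range(inter_trial_gap):
            active = sim.advance(config.p_ext_baseline)
            if j >= tail_start:
                og += active.size
        ongoing[i] = og
        onsets[i] = t + inter_trial_gap
        level = levels[order[i]]
        r = 0
        for _ in range(response_window):
            r += sim.advance(level).size
        responses[i] = r
        t += inter_trial_gap + response_window
    return StimulusTrialSet(
        levels=levels,
        repetitions=reps,
        response_window=response_window,
        trial_levels=levels[order],
        onset_steps=onsets,
        responses=responses,
        ongoing_counts=ongoing,
        config=config,
    )
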