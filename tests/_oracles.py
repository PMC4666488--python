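"""Independent reference implementations used only as test oracles.

These deliberately favor clarity over speed: explicit per-neuron, per-step
loops for the network dynamics and direct summation for the kappa statistic,
so they share no code path with the library implementations they check.
"""

from __future__ import annotations

import numpy as np


def naive_simulate(
    W: np.ndarray,
    depression_window: int,
    p_ext: float,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-neuron, per-step loop simulation; returns the dense raster.

    Draw protocol matches the library: per step, one uniform per neuron for
    the recurrent event, then one per neuron for the external event.
    """
    N = W.shape[0]
    T = depression_window
    s_hist = np.zeros((n_steps + 1, N), dtype=bool)  # row 0: initial state
    raster = np.zeros((N, n_steps), dtype=bool)
    for t in range(1, n_steps + 1):
        r_rec = np.array([rng.random() for _ in range(N)])
        r_ext = np.array([rng.random() for _ in range(N)])
        for i in range(N):
            drive = 0.0
            for j in range(N):
                if j != i and s_hist[t - 1, j]:
                    drive += W[i, j]
            if T > 0:
                h = 0
                for tau in range(max(t - T, 0), t):  # causal window t-T..t-1
                    if s_hist[tau, i]:
                        h += 1
                if h == 0:
                    h = 1
                drive /= h
            p = min(max(drive, 0.0), 1.0)
            fired = (r_rec[i] < p) or (r_ext[i] < p_ext)
            s_hist[t, i] = fired
            raster[i, t - 1] = fired
    return raster


def brute_force_kappa(sizes, m=10, exponent=-1.5) -> float:
    """Direct summation of the m reference-minus-empirical differences."""
    sizes = sorted(float(s) for s in sizes)
    n = len(sizes)
    s_min, s_max = max(sizes[0], 1.0), sizes[-1]
    log_lo, log_hi = np.log10(s_min), np.log10(s_max)
    total = 0.0
    for k in range(m):
        if k == 0:
            beta = s_min
        elif k == m - 1:
            beta = s_max
        else:
            beta = 10.0 ** (log_lo + (log_hi - log_lo) * k / (m - 1))
        e1 = exponent + 1.0
        f_ref = (s_min**e1 - beta**e1) / (s_min**e1 - s_max**e1)
        f_emp = sum(1 for s in sizes if s <= beta) / n
        total += f_ref - f_emp
    return 1.0 + total / m


def power_law_sample_by_quantiles(n, s_min, s_max, exponent=-1.5) -> np.ndarray:
    """n sizes placed at the j/n quantiles of the truncated power law.

    The empirical CDF of this sample matches the reference CDF everywhere to
    within 1/n, so its kappa equals 1 up to that placement error.
    """
    e1 = exponent + 1.0
    q = np.arange(1, n + 1) / n
    # inverse of F(s) = (s_min^e1 - s^e1) / (s_min^e1 - s_max^e1)
    return (s_min**e1 - q * (s_min**e1 - s_max**e1)) ** (1.0 / e1)
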