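"""Maximum-entropy L1 (Laplace) likelihood for replicated time courses.

The only testable information carried forward from the replicates is the
expected magnitude of the residual at each time point; maximum-entropy
considerations then give a double-exponential density rather than a
Gaussian. The per-time normalising constant

    epsilon_t = mean_i |x_{t,i} - mu_t|

is the mean absolute deviation of the replicate observations from the
model prediction ``mu_t``, and the likelihood of the course is the product
over time points of the Laplace density of the median observation:

    p(x | mu, eps) = prod_t (1 / (2 eps_t)) exp(-|median_t - mu_t| / eps_t).

Time points with dissimilar replicates have larger ``epsilon_t`` and so
contribute least. ``epsilon_t`` depends on the prediction and is
recomputed inside every likelihood evaluation; a small floor keeps the
density finite when all replicates coincide with the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LikelihoodContext", "epsilon_t", "log_likelihood", "DEFAULT_EPSILON_FLOOR"]

#: Floor for epsilon_t, in TPM. Prevents an infinite density when the
#: replicates coincide exactly with the prediction.
DEFAULT_EPSILON_FLOOR = 1e-3


def epsilon_t(replicates_at_t, mu_t: float, epsilon_floor: float = DEFAULT_EPSILON_FLOOR) -> float:
    """Per-time Laplace scale: mean |x_i - mu_t| over replicates, floored."""
    x = np.asarray(replicates_at_t, dtype=float)
    if x.size == 0:
        raise ValueError("epsilon_t requires at least one replicate value")
    if not np.isfinite(mu_t):
        raise ValueError(f"model prediction must be finite, got {mu_t!r}")
    eps = float(np.mean(np.abs(x - mu_t)))
    return max(eps, epsilon_floor)


@dataclass
class LikelihoodContext:
    """Replicated observations for one transcript/cluster time course.

    Medians are always recomputed from the replicate values (midpoint
    average for an even count), never stored stale.
    """

    times: np.ndarray
    replicates: list[np.ndarray]
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR
    medians: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D sequence")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.replicates) != self.times.size:
            raise ValueError("one replicate collection required per time point")
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        for t, r in zip(self.times, self.replicates):
            if r.size < 2:
                raise ValueError(f"time point {t} has fewer than 2 replicates")
        self.medians = np.array([float(np.median(r)) for r in self.replicates])

    @property
    def n_times(self) -> int:
        return self.times.size


def log_likelihood(ctx: LikelihoodContext, mu) -> float:
    """Log of the L1 likelihood of the per-time medians under ``mu``.

    ``mu`` supplies one model prediction per time point in ``ctx``. The
    scales ``epsilon_t`` are recomputed from the replicates and ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != ctx.times.shape:
        raise ValueError(
            f"predictions have shape {mu.shape}, expected {ctx.times.shape}"
        )
    total = 0.0
    for reps, med, m in zip(ctx.replicates, ctx.medians, mu):
        eps = epsilon_t(reps, float(m), ctx.epsilon_floor)
        total += -np.log(2.0 * eps) - abs(med - m) / eps
    return float(total)
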