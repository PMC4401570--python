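"""Nested sampling of Bayesian evidence over a unit-cube-mapped prior box.

The marginal likelihood (evidence) Z = ∫ L(θ) π(θ) dθ is estimated by the
classic shell construction: maintain ``n_live`` points drawn from the
prior, repeatedly remove the point of lowest likelihood L* and replace it
with a new prior draw constrained to L >= L*, while the enclosed prior
mass shrinks geometrically. With uniform priors mapped to the unit cube,
evidence is reported on the cube (log Z of the cube), which is the scale
used for model comparison.

Implementation choices:

* prior mass shrinkage uses the deterministic expectation
  ``ln X_i = -i / n_live`` (seed-stable evidence estimates);
* replacement points are found by a Metropolis random walk inside the
  hard likelihood constraint, step size adapted towards ~50% acceptance;
* the run terminates when the largest possible remaining contribution
  ``max(L_live) * X_i`` falls below ``tol`` times the accumulated Z, or at
  ``max_iterations``;
* ``sd(log Z) = sqrt(H / n_live)`` with H the information (KL divergence
  of posterior from prior) accumulated during the run;
* posterior moments come from the dead (and final live) points with the
  standard importance weights ``L_i Δm_i / Z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .signatures import SignatureKind

__all__ = [
    "PriorBox",
    "EvidenceResult",
    "NestedSamplerConfig",
    "nested_sample",
    "posterior_moments",
    "build_priors",
    "SamplingFailureError",
]


class SamplingFailureError(RuntimeError):
    """Raised when the likelihood returns NaN during sampling."""


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform priors: a box in parameter space.

    Maps unit-cube coordinates ``u`` to parameters ``lower + u*(upper-lower)``
    componentwise.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D arrays of equal length")
        if len(self.names) != self.lower.size:
            raise ValueError("one name per parameter required")
        if not np.all(self.lower < self.upper):
            raise ValueError("every prior interval requires lower < upper")

    @property
    def dimension(self) -> int:
        return self.lower.size

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map unit-cube point(s) to parameter space."""
        return self.lower + np.asarray(u, dtype=float) * (self.upper - self.lower)


@dataclass(frozen=True)
class EvidenceResult:
    """Evidence and posterior summaries from one nested-sampling run."""

    log_z: float
    log_z_sd: float
    param_mean: np.ndarray
    param_sd: np.ndarray
    n_iterations: int
    seed: int
    information: float = float("nan")

    def __post_init__(self) -> None:
        if self.log_z_sd < 0:
            raise ValueError("log_z_sd must be >= 0")


@dataclass(frozen=True)
class NestedSamplerConfig:
    """Sampler settings (all exposed in the run configuration file)."""

    n_live: int = 100
    max_iterations: int = 10_000
    termination_tol: float = 1e-3
    walk_steps: int = 20
    initial_step: float = 0.3

    def __post_init__(self) -> None:
        if self.n_live < 10:
            raise ValueError("n_live must be >= 10")
        if self.walk_steps < 1:
            raise ValueError("walk_steps must be >= 1")


def _constrained_walk(
    log_like: Callable[[np.ndarray], float],
    u_start: np.ndarray,
    log_l_star: float,
    step: float,
    n_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """Metropolis walk inside the hard constraint logL >= logL*.

    Returns the final point, its log-likelihood and the adapted step size.
    Proposals outside the unit cube count as rejections.
    """
    u = u_start.copy()
    log_l = log_like(u)
    n_accept = 0
    n_reject = 0
    d = u.size
    for _ in range(n_steps):
        prop = u + step * rng.standard_normal(d)
        if np.all(prop >= 0.0) and np.all(prop <= 1.0):
            log_l_prop = log_like(prop)
            if math.isnan(log_l_prop):
                raise SamplingFailureError(f"likelihood returned NaN at {prop!r}")
            if log_l_prop >= log_l_star:
                u = prop
                log_l = log_l_prop
                n_accept += 1
                continue
        n_reject += 1
    # adapt towards ~50% acceptance (Sivia & Skilling scheme)
    if n_accept > n_reject:
        step *= math.exp(1.0 / max(n_accept, 1))
    elif n_reject > n_accept:
        step /= math.exp(1.0 / max(n_reject, 1))
    step = min(max(step, 1e-6), 1.0)
    return u, log_l, step


def nested_sample(
    log_like: Callable[[np.ndarray], float],
    dimension: int,
    n_live: int = 100,
    seed: int = 0,
    config: NestedSamplerConfig | None = None,
    prior_box: PriorBox | None = None,
) -> EvidenceResult:
    """Estimate log Z over the unit cube for an arbitrary log-likelihood.

    ``log_like`` takes a point in [0,1]^dimension. Posterior moments are
    reported in parameter space when ``prior_box`` is supplied, else in
    cube coordinates. Identical seed and config give identical results.
    """
    if config is None:
        config = NestedSamplerConfig(n_live=n_live)
    elif n_live != config.n_live:
        config = NestedSamplerConfig(
            n_live=n_live,
            max_iterations=config.max_iterations,
            termination_tol=config.termination_tol,
            walk_steps=config.walk_steps,
            initial_step=config.initial_step,
        )
    rng = np.random.default_rng(seed)
    n = config.n_live
    live_u = rng.random((n, dimension))
    live_logl = np.empty(n)
    for i in range(n):
        v = log_like(live_u[i])
        if math.isnan(v):
            raise SamplingFailureError(f"likelihood returned NaN at {live_u[i]!r}")
        live_logl[i] = v

    dead_u: list[np.ndarray] = []
    dead_logl: list[float] = []
    dead_logw: list[float] = []

    log_z = -np.inf
    h = 0.0
    step = config.initial_step
    # ln of per-shell width factor: X_{i-1} - X_i with X_i = e^{-i/n}
    log_width_factor = math.log1p(-math.exp(-1.0 / n))
    log_x = 0.0
    n_iter = 0
    for i in range(1, config.max_iterations + 1):
        worst = int(np.argmin(live_logl))
        log_l_star = float(live_logl[worst])
        log_w = log_x + log_width_factor  # ln(X_{i-1} - X_i), X_{i-1} = e^{log_x}
        log_x = -i / n

        log_z_new = np.logaddexp(log_z, log_l_star + log_w)
        if np.isfinite(log_z_new):
            h = (
                math.exp(log_l_star + log_w - log_z_new) * log_l_star
                + math.exp(log_z - log_z_new) * (h + log_z)
                - log_z_new
            ) if np.isfinite(log_z) else math.exp(log_l_star + log_w - log_z_new) * log_l_star - log_z_new
        log_z = float(log_z_new)

        dead_u.append(live_u[worst].copy())
        dead_logl.append(log_l_star)
        dead_logw.append(log_w)

        # replace the worst point by a constrained walk from a random live point
        start = int(rng.integers(n))
        u_new, logl_new, step = _constrained_walk(
            log_like, live_u[start], log_l_star, step, config.walk_steps, rng
        )
        live_u[worst] = u_new
        live_logl[worst] = logl_new
        n_iter = i

        remaining = float(np.max(live_logl)) + log_x
        if remaining < math.log(config.termination_tol) + log_z:
            break

    # fold in the surviving live points at equal remaining mass X/n
    log_w_live = log_x - math.log(n)
    for j in range(n):
        log_z_new = np.logaddexp(log_z, live_logl[j] + log_w_live)
        h = (
            math.exp(live_logl[j] + log_w_live - log_z_new) * live_logl[j]
            + math.exp(log_z - log_z_new) * (h + log_z)
            - log_z_new
        )
        log_z = float(log_z_new)
        dead_u.append(live_u[j].copy())
        dead_logl.append(float(live_logl[j]))
        dead_logw.append(log_w_live)

    log_z_sd = math.sqrt(max(h, 0.0) / n)
    samples = np.asarray(dead_u)
    if prior_box is not None:
        samples = prior_box.transform(samples)
    mean, sd = posterior_moments(samples, np.asarray(dead_logl), np.asarray(dead_logw), log_z)
    return EvidenceResult(
        log_z=log_z,
        log_z_sd=log_z_sd,
        param_mean=mean,
        param_sd=sd,
        n_iterations=n_iter,
        seed=seed,
        information=h,
    )


def posterior_moments(
    samples: np.ndarray,
    log_l: np.ndarray,
    log_w: np.ndarray,
    log_z: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Importance-weighted mean and sd of dead points.

    Weights are the nested-sampling posterior weights ``L_i Δm_i / Z``
    (``Z`` recomputed from the inputs when not given). Samples may be in
    parameter or cube space; moments are reported in the same space.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    log_l = np.asarray(log_l, dtype=float)
    log_w = np.asarray(log_w, dtype=float)
    if samples.shape[0] != log_l.size or log_l.size != log_w.size:
        raise ValueError("samples, log_l and log_w lengths must match")
    if log_l.size == 0:
        raise ValueError("at least one weighted point required")
    logwts = log_l + log_w
    top = float(np.max(logwts))
    if not np.isfinite(top):
        raise ValueError("degenerate posterior: all weights are zero")
    w = np.exp(logwts - top)
    w_sum = w.sum()
    if w_sum == 0:
        raise ValueError("degenerate posterior: all weights are zero")
    w /= w_sum
    mean = w @ samples
    var = w @ (samples - mean) ** 2
    return mean, np.sqrt(np.maximum(var, 0.0))


def build_priors(timecourse, kind: SignatureKind | str, config=None) -> PriorBox:
    """Data-derived uniform prior box for one signature kind.

    Bounds follow the observed dynamic range of the per-time medians
    (span = max - min): ``p1 in [0, max]``, ``p2 in [0, 2*span]`` for the
    exponential kinds; the linear kind allows signed change,
    ``p1 in [min-span, max+span]``, ``p2 in [-2*span, 2*span]``. Switch
    times split at 240 min: early peak ``t_s in [1, 240]`` (first half of
    the series), late peak ``t_s in [240, T_end]``; dip ``t_s`` and decay
    ``t_h`` range over ``[1, T_end]``.
    """
    kind = SignatureKind(kind)
    times = np.asarray(timecourse.times, dtype=float)
    medians = np.asarray(timecourse.medians, dtype=float)
    if times.size < 3:
        raise ValueError("a time course needs at least 3 time points")
    t_end = float(times[-1])
    med_max = float(np.max(medians))
    span = float(np.max(medians) - np.min(medians))
    # degenerate (flat) courses still need a nonempty box
    span = max(span, 1e-6)
    med_max = max(med_max, 1e-6)

    if kind is SignatureKind.LINEAR:
        lo_p1 = float(np.min(medians)) - span
        return PriorBox(
            ("p1", "p2"),
            np.array([lo_p1, -2.0 * span]),
            np.array([med_max + span, 2.0 * span]),
        )
    p1_b = (0.0, med_max)
    p2_b = (0.0, 2.0 * span)
    if kind is SignatureKind.EARLY_PEAK:
        t_b = (1.0, 240.0)
        t_name = "t_s"
    elif kind is SignatureKind.LATE_PEAK:
        if t_end <= 240.0:
            raise ValueError(
                f"late_peak requires a time course extending past 240 min (T_end={t_end})"
            )
        t_b = (240.0, t_end)
        t_name = "t_s"
    elif kind is SignatureKind.DIP:
        t_b = (1.0, t_end)
        t_name = "t_s"
    else:  # decay
        t_b = (1.0, t_end)
        t_name = "t_h"
    return PriorBox(
        ("p1", "p2", t_name),
        np.array([p1_b[0], p2_b[0], t_b[0]]),
        np.array([p1_b[1], p2_b[1], t_b[1]]),
    )
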