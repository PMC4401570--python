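"""Model/Results interface for kinetic-signature fitting.

``KineticSignatureModel`` wraps one cluster's replicated time course;
``fit()`` runs nested sampling for every applicable signature kind and
returns a ``KineticSignatureResults`` carrying the evidences, posterior
parameter moments, the selected category and a ``summary()`` table, with
``predict`` and ``plot`` for the fitted curves.

    >>> model = KineticSignatureModel(course)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classification import Assignment, ModelFit, NO_DECISION, fit_all, select
from .config import RunConfig
from .io import ExpressionMatrix, TimeCourse, build_time_courses
from .signatures import SignatureKind, SignatureParams, evaluate

__all__ = ["KineticSignatureModel", "KineticSignatureResults"]


class KineticSignatureModel:
    """Kinetic-signature model-selection problem for one time course."""

    def __init__(self, timecourse: TimeCourse, config: RunConfig | None = None):
        self.timecourse = timecourse
        self.config = config if config is not None else RunConfig()

    @classmethod
    def from_dataframe(
        cls,
        matrix: ExpressionMatrix,
        metadata: pd.DataFrame,
        cluster_id: str,
        config: RunConfig | None = None,
    ) -> "KineticSignatureModel":
        """Build the model for one cluster of an expression matrix."""
        courses = {tc.cluster_id: tc for tc in build_time_courses(matrix, metadata)}
        if cluster_id not in courses:
            raise KeyError(f"cluster {cluster_id!r} not in matrix")
        return cls(courses[cluster_id], config)

    def fit(self, seed: int | None = None) -> "KineticSignatureResults":
        """Run nested sampling for all kinds and select a category."""
        config = self.config
        if seed is not None:
            config = RunConfig(
                sampler=config.sampler,
                selection=config.selection,
                filters=config.filters,
                epsilon_floor=config.epsilon_floor,
                engine=config.engine,
                seed=seed,
            )
        fitres = fit_all(self.timecourse, config)
        assignment = select(fitres, config.selection)
        return KineticSignatureResults(self, fitres, assignment, config)


class KineticSignatureResults:
    """Fitted evidences, posterior moments and the selected signature."""

    def __init__(
        self,
        model: KineticSignatureModel,
        fit: ModelFit,
        assignment: Assignment,
        config: RunConfig,
    ):
        self.model = model
        self.fit = fit
        self.assignment = assignment
        self.config = config

    @property
    def category(self) -> str:
        return self.assignment.category

    @property
    def log_z(self) -> dict[str, float]:
        return dict(self.assignment.log_z)

    @property
    def log_z_sd(self) -> dict[str, float]:
        return dict(self.assignment.log_z_sd)

    def params(self, kind: SignatureKind | str | None = None) -> SignatureParams:
        """Posterior-mean SignatureParams for a kind (default: selected)."""
        if kind is None:
            if self.category == NO_DECISION:
                raise ValueError("no signature selected; pass a kind explicitly")
            kind = self.category
        kind = SignatureKind(kind)
        res = self.fit.results[kind]
        box = self.fit.prior_boxes[kind]
        values = dict(zip(box.names, res.param_mean))
        p1 = max(values["p1"], 0.0)
        if kind is SignatureKind.LINEAR:
            return SignatureParams(kind, p1=p1, p2=values["p2"])
        if kind is SignatureKind.DECAY:
            return SignatureParams(kind, p1=p1, p2=max(values["p2"], 0.0), t_h=values["t_h"])
        return SignatureParams(kind, p1=p1, p2=max(values["p2"], 0.0), t_s=values["t_s"])

    def predict(self, t, kind: SignatureKind | str | None = None):
        """Posterior-mean signature curve at time(s) t."""
        return evaluate(self.params(kind), t, t_end=self.model.timecourse.t_end)

    def summary(self) -> str:
        """Human-readable per-kind evidence and parameter table."""
        tc = self.model.timecourse
        lines = [
            "Kinetic signature model selection",
            "=" * 70,
            f"cluster: {tc.cluster_id}   time points: {tc.times.size}"
            f"   T_end: {tc.t_end:g} min   rule: {self.assignment.rule}",
            f"selected category: {self.category}",
            "-" * 70,
            f"{'kind':<12}{'log Z':>10}{'sd':>8}  parameters (posterior mean +/- sd)",
        ]
        for kind in self.fit.fitted_kinds():
            res = self.fit.results[kind]
            box = self.fit.prior_boxes[kind]
            pstr = ", ".join(
                f"{n}={m:.3g}+/-{s:.2g}"
                for n, m, s in zip(box.names, res.param_mean, res.param_sd)
            )
            lines.append(
                f"{kind.value:<12}{res.log_z:>10.2f}{res.log_z_sd:>8.2f}  {pstr}"
            )
        lines.append("=" * 70)
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Data (median filled) with the selected model's posterior-mean curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tc = self.model.timecourse
        for t, reps, med in zip(tc.times, tc.replicates, tc.medians):
            ax.plot([t] * reps.size, reps, "o", mfc="none", color="0.4", ms=5)
            ax.plot([t], [med], "o", color="0.1", ms=5)
        if self.category != NO_DECISION:
            grid = np.linspace(0, tc.t_end, n_grid)
            ax.plot(grid, self.predict(grid), color="tab:blue", label=self.category)
            ax.legend(frameon=False)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("expression (TPM)")
        ax.set_title(tc.cluster_id)
        return ax
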