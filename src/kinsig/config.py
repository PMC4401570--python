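"""Run configuration: sampler, selection rule and filter settings.

All knobs that the method leaves open are collected here so that a run is
fully described by (data, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .likelihood import DEFAULT_EPSILON_FLOOR
from .nested import NestedSamplerConfig

__all__ = ["SelectionConfig", "FilterConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class SelectionConfig:
    """Decision-rule settings.

    ``rule='bayes_factor'`` (default) reads "ten times the evidence" as an
    evidence ratio: an exponential kind needs
    ``log Z_k - log Z_linear > ln(10)`` plus sd-band separation from every
    other exponential kind; linear needs ``log Z_linear - log Z_k > ln(10)``
    against all exponential kinds. ``rule='literal'`` instead applies the
    inequality ``log Z > 10 * log Z_other`` verbatim on the (typically
    negative) unit-cube log evidences; that comparison is vacuously true
    whenever log Z < 0, which strips the rule of its guard against calling
    exponential kinetics on linear data, so it is provided for
    completeness rather than as the default.
    """

    rule: str = "bayes_factor"

    def __post_init__(self) -> None:
        if self.rule not in ("literal", "bayes_factor"):
            raise ValueError(f"unknown selection rule {self.rule!r}")


@dataclass(frozen=True)
class FilterConfig:
    """Expression and QC filter thresholds."""

    min_mapped_tags: int = 500_000
    min_replicates: int = 2
    protein_coding_min_tpm: float = 10.0
    noncoding_min_sum_tpm: float = 3.0
    small_rna_min_sum_reads: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a classification run."""

    sampler: NestedSamplerConfig = field(default_factory=NestedSamplerConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR
    engine: str = "numba"  # "numba" (compiled kernel) or "python" (reference)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.engine not in ("numba", "python"):
            raise ValueError(f"unknown engine {self.engine!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file; missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sampler = NestedSamplerConfig(**raw.get("sampler", {}))
    selection = SelectionConfig(**raw.get("selection", {}))
    filters = FilterConfig(**raw.get("filters", {}))
    extra = {
        k: raw[k] for k in ("epsilon_floor", "engine", "seed") if k in raw
    }
    return RunConfig(sampler=sampler, selection=selection, filters=filters, **extra)
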