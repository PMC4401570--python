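"""Characterisation statistics over assignment tables and annotations.

Gene-set enrichment in signature categories (hypergeometric tests and
odds ratios with BH false-discovery control), switch-time binning,
transcription completion-time contours (an assumed elongation rate of
60 bases/s), gene length vs switch time correlation, the RNAPII
travelling ratio (exon-1 density over gene-body density, a readout of
promoter-proximal pausing), DNaseI read counts in windows around cluster
midpoints, enhancer-to-gene expression averaging and miRNA-target
over-representation in early-peak genes.

The enrichment universe differs between analyses in this design (for
example, clusters with any assigned signature vs all protein-coding
clusters), so every enrichment function takes the background explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "odds_ratio",
    "adjust_fdr",
    "bin_switch_times",
    "completion_time",
    "contour_enrichment",
    "length_ts_correlation",
    "travelling_ratio",
    "compare_groups_ranksum",
    "window_counts",
    "enhancer_gene_means",
    "mirna_target_enrichment",
]

#: Assumed RNA polymerase II elongation rate, bases per second.
DEFAULT_ELONGATION_RATE = 60.0


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 enrichment of a gene set within a category against a background.

    Counts: a = set & category, b = non-set & category, c = set outside
    the category, d = non-set outside the category (a+b+c+d = background).
    """

    set_name: str
    category: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


def hypergeom_enrichment(
    category_genes,
    set_genes,
    background_genes,
    set_name: str = "set",
    category: str = "category",
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation of a set in a category.

    The p-value is P(X >= a) for the overlap a under sampling
    len(category) items without replacement from the background, of which
    len(set) are marked. Category and set are intersected with the
    background first.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("background must be non-empty")
    cat = set(category_genes) & background
    marked = set(set_genes) & background
    n_bg = len(background)
    a = len(cat & marked)
    b = len(cat) - a
    c = len(marked) - a
    d = n_bg - a - b - c
    # P(X >= a): survival function at a-1
    p = float(stats.hypergeom.sf(a - 1, n_bg, len(marked), len(cat)))
    p = min(p, 1.0)
    return EnrichmentResult(set_name, category, a, b, c, d, odds_ratio(a, b, c, d), p)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Standard 2x2 odds ratio (a*d)/(b*c).

    Reads as the odds of set membership inside the category divided by the
    odds outside it. A zero denominator gives inf (or nan for 0/0); callers
    wanting a finite value can apply the Haldane correction via
    ``odds_ratio(a + 0.5, b + 0.5, c + 0.5, d + 0.5)``.
    """
    if b * c == 0:
        if a * d == 0:
            return float("nan")
        return float("inf")
    return (a * d) / (b * c)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bin_switch_times(
    assignments: pd.DataFrame,
    gene_set,
    bin_width: float = 30.0,
    category: str = "early_peak",
) -> pd.DataFrame:
    """Per-bin percentage of clusters whose gene belongs to a set.

    Switch times are binned left-closed right-open ([0,30), [30,60), ...);
    a cluster counts toward a bin's percentage as
    100 * (set members in bin) / (clusters in bin). Empty bins report NA.
    The overall average percentage across the category is included as the
    attribute ``overall_percent``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sub = assignments[assignments["category"] == category].dropna(subset=["ts_or_th_mean"])
    gene_set = set(gene_set)
    ts = sub["ts_or_th_mean"].to_numpy(dtype=float)
    in_set = sub["gene_id"].isin(gene_set).to_numpy()
    if ts.size == 0:
        out = pd.DataFrame(columns=["bin_start", "bin_end", "n_clusters", "n_set", "percent"])
        out.attrs["overall_percent"] = float("nan")
        return out
    n_bins = int(np.floor(ts.max() / bin_width)) + 1
    rows = []
    for i in range(n_bins):
        lo, hi = i * bin_width, (i + 1) * bin_width
        mask = (ts >= lo) & (ts < hi)
        n = int(mask.sum())
        k = int(in_set[mask].sum())
        rows.append(
            {
                "bin_start": lo,
                "bin_end": hi,
                "n_clusters": n,
                "n_set": k,
                "percent": 100.0 * k / n if n else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["overall_percent"] = 100.0 * float(in_set.sum()) / ts.size
    return out


def completion_time(
    t_s: float, gene_length_bp: float, rate_bases_per_s: float = DEFAULT_ELONGATION_RATE
):
    """Projected transcript completion time in minutes.

    The switch time plus the time to transcribe the gene body at the
    assumed elongation rate: ``t_s + length / (rate * 60)``.
    """
    t_s = np.asarray(t_s, dtype=float)
    gene_length_bp = np.asarray(gene_length_bp, dtype=float)
    if np.any(gene_length_bp < 0) or rate_bases_per_s <= 0:
        raise ValueError("length must be >= 0 and rate positive")
    out = t_s + gene_length_bp / (rate_bases_per_s * 60.0)
    return float(out) if out.ndim == 0 else out


def contour_enrichment(
    assignments: pd.DataFrame,
    feature_table: pd.DataFrame,
    contour_minutes: float,
    gene_set,
    category: str = "early_peak",
    rate_bases_per_s: float = DEFAULT_ELONGATION_RATE,
    set_name: str = "set",
) -> EnrichmentResult:
    """Set over-representation inside a completion-time contour.

    Genes in the category are partitioned by completion_time <= contour vs
    beyond it; the inside group is tested for over-representation of the
    set against the category as universe.
    """
    sub = assignments[assignments["category"] == category].dropna(subset=["ts_or_th_mean"])
    merged = sub.merge(feature_table[["gene_id", "gene_length"]], on="gene_id", how="inner")
    ct = completion_time(
        merged["ts_or_th_mean"].to_numpy(), merged["gene_length"].to_numpy(), rate_bases_per_s
    )
    inside = merged.loc[ct <= contour_minutes, "gene_id"]
    return hypergeom_enrichment(
        inside, gene_set, merged["gene_id"], set_name=set_name,
        category=f"{category}<= {contour_minutes:g} min",
    )


def length_ts_correlation(
    assignments: pd.DataFrame,
    feature_table: pd.DataFrame,
    category: str = "early_peak",
) -> tuple[float, float]:
    """Pearson correlation of gene length with switch time in a category."""
    sub = assignments[assignments["category"] == category].dropna(subset=["ts_or_th_mean"])
    merged = sub.merge(feature_table[["gene_id", "gene_length"]], on="gene_id", how="inner")
    if len(merged) < 3:
        raise ValueError("at least 3 paired observations required")
    x = merged["gene_length"].to_numpy(dtype=float)
    y = merged["ts_or_th_mean"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def travelling_ratio(records: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Per-gene exon-1 density over pooled other-exon density.

    ``records`` columns: gene_id, exon_index (1-based), covered_bp,
    read_depth. Density is read_depth / covered_bp; the ratio is exon-1
    density over the pooled (summed depth / summed bases) density of all
    other exons. Genes lacking exon 1 or any covered gene body are
    excluded, with the reason logged.
    """
    excluded: list[str] = []
    ratios = {}
    for gene, grp in records.groupby("gene_id", sort=True):
        first = grp[grp["exon_index"] == 1]
        body = grp[grp["exon_index"] != 1]
        if first.empty or float(first["covered_bp"].sum()) <= 0:
            excluded.append(f"{gene}: no covered exon 1")
            continue
        body_bases = float(body["covered_bp"].sum())
        if body.empty or body_bases <= 0:
            excluded.append(f"{gene}: no covered gene body")
            continue
        d1 = float(first["read_depth"].sum()) / float(first["covered_bp"].sum())
        db = float(body["read_depth"].sum()) / body_bases
        if db == 0:
            excluded.append(f"{gene}: zero gene-body density")
            continue
        ratios[gene] = d1 / db
    return pd.Series(ratios, name="travelling_ratio"), excluded


def compare_groups_ranksum(
    values_a,
    values_b,
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> float:
    """Two-sample Wilcoxon rank-sum p-value.

    Uses the exact null distribution when the combined sample size is at
    most ``exact_max_n`` and the data are tie-free; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= exact_max_n and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)


def window_counts(
    clusters: pd.DataFrame,
    reads: pd.DataFrame,
    window_bp: int = 200,
) -> pd.Series:
    """Reads overlapping a window centred at each cluster midpoint.

    Intervals are 0-based half-open BED-style frames with columns chrom,
    start, end (clusters additionally name, i.e. BED6 ordering). The
    window is [mid - w/2, mid + w/2), clipped at 0; a read counts when it
    overlaps the window by at least one base.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp // 2
    counts = {}
    reads_by_chrom = {c: g for c, g in reads.groupby("chrom")}
    for _, row in clusters.iterrows():
        mid = (int(row["start"]) + int(row["end"])) // 2
        w_lo = max(mid - half, 0)
        w_hi = mid + half
        sub = reads_by_chrom.get(row["chrom"])
        if sub is None:
            n = 0
        else:
            n = int(((sub["start"] < w_hi) & (sub["end"] > w_lo)).sum())
        counts[row["name"]] = n
    return pd.Series(counts, name="window_count")


def enhancer_gene_means(
    enhancer_expr: pd.Series,
    links: pd.DataFrame,
) -> pd.Series:
    """Average linked-enhancer expression per gene.

    ``links`` columns: enhancer_id, gene_id (many-to-many). Genes with no
    linked enhancer are absent from the output (NA on reindexing).
    """
    missing = set(links["enhancer_id"]) - set(enhancer_expr.index)
    if missing:
        raise KeyError(f"enhancers without expression values: {sorted(missing)}")
    merged = links.assign(expr=links["enhancer_id"].map(enhancer_expr))
    return merged.groupby("gene_id")["expr"].mean()


def mirna_target_enrichment(
    dip_mirnas,
    target_table: pd.DataFrame,
    early_peak_genes,
    reference_genes,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Per-miRNA over-representation of targets among early-peak genes.

    The universe is the union of the early-peak and unregulated-reference
    gene sets (which must be disjoint); each down-regulated miRNA's
    targets are tested for enrichment in the early-peak side. miRNAs
    absent from the target table (or with no targets in the universe) are
    skipped with a log entry. q-values are BH-adjusted across the tested
    miRNAs.
    """
    early = set(early_peak_genes)
    ref = set(reference_genes)
    if early & ref:
        raise ValueError("early-peak and reference gene sets must be disjoint")
    universe = early | ref
    by_mirna = target_table.groupby("mirna_id")["gene_id"].apply(set)
    results: list[EnrichmentResult] = []
    log: list[str] = []
    for mirna in dip_mirnas:
        if mirna not in by_mirna.index:
            log.append(f"{mirna}: absent from target table")
            continue
        targets = by_mirna[mirna] & universe
        if not targets:
            log.append(f"{mirna}: no targets in universe")
            continue
        results.append(
            hypergeom_enrichment(early, targets, universe, set_name=mirna, category="early_peak")
        )
    if results:
        q = adjust_fdr([r.p_value for r in results])
        results = [
            EnrichmentResult(
                r.set_name, r.category, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value, float(qi)
            )
            for r, qi in zip(results, q)
        ]
    return results, log
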