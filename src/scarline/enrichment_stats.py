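"""Cross-cutting statistics: Fisher enrichments, BH adjustment, change-change
correlations, hierarchical clustering of multi-mark change profiles,
rule-based chromatin-state assignment, and gene-repeat proximity enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "CorrelationResult",
    "ClusterAssignment",
    "fisher_enrichment",
    "bh_adjust",
    "change_correlation",
    "assign_chromatin_states",
    "cluster_changes",
    "proximity_enrichment",
    "STATE_PRECEDENCE",
]


@dataclass
class EnrichmentResult:
    odds_ratio: float
    pvalue: float
    table: tuple[tuple[int, int], tuple[int, int]]
    direction: str  # enriched / depleted / ns
    label: str = ""
    corrected: bool = False  # Haldane-Anscombe +0.5 applied to the OR

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "odds_ratio": self.odds_ratio,
            "pvalue": self.pvalue,
            "direction": self.direction,
            "table": self.table,
        }


def fisher_enrichment(
    features: np.ndarray,
    hits: np.ndarray,
    label: str = "",
    display_threshold: float = 0.001,
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of a membership mask against a hit mask.

    OR is the cross-product ratio (a*d)/(b*c) with a Haldane-Anscombe +0.5
    correction when any cell is zero; the p-value comes from the exact test
    on the uncorrected table. Direction is enriched iff OR > 1 at the display
    threshold (depleted symmetric).
    """
    f = np.asarray(features, dtype=bool)
    h = np.asarray(hits, dtype=bool)
    if f.shape != h.shape or f.size == 0:
        raise ValueError("feature and hit masks must be equal-length and non-empty")
    a = int(np.sum(f & h))
    b = int(np.sum(f & ~h))
    c = int(np.sum(~f & h))
    d = int(np.sum(~f & ~h))
    _, pvalue = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = min(a, b, c, d) == 0
    if corrected:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    if pvalue < display_threshold:
        direction = "enriched" if odds > 1 else "depleted"
    else:
        direction = "ns"
    return EnrichmentResult(
        odds_ratio=float(odds),
        pvalue=float(pvalue),
        table=((a, b), (c, d)),
        direction=direction,
        label=label,
        corrected=corrected,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationResult:
    r: float
    pvalue: float
    n: int
    x_label: str = "x"
    y_label: str = "y"
    n_dropped: int = 0


def change_correlation(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Pearson correlation of two per-feature change vectors.

    Features missing in either vector are dropped and counted; fewer than 3
    complete pairs is a refusal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("change vectors must be paired (equal length)")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, have {x.size}")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic),
        pvalue=float(res.pvalue),
        n=int(x.size),
        x_label=x_label,
        y_label=y_label,
        n_dropped=n_dropped,
    )


#: Fixed precedence when several rules match.
STATE_PRECEDENCE = ("bivalent", "active", "polycomb", "heterochromatic", "quiescent")


def assign_chromatin_states(
    signals: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    tertile: float = 2.0 / 3.0,
) -> tuple[pd.Series, dict[str, float]]:
    """Rule-based chromatin-state labels from per-feature mark signals.

    Rules: bivalent = H3K4me3 high and H3K27me3 high; active = H3K4me3 high,
    H3K27me3 low; polycomb = H3K27me3 high, H3K4me3 low; heterochromatic =
    H3K9me3 high; quiescent otherwise -- applied in the precedence order
    bivalent > active > polycomb > heterochromatic > quiescent. "High" means
    above the per-mark threshold; by default the upper tertile of each mark's
    signal on the analyzed feature set (scale-free). Returns (labels,
    thresholds used).
    """
    required = ["H3K4me3", "H3K27me3"]
    for col in required:
        if col not in signals.columns:
            raise KeyError(f"missing required mark column {col!r}")
    marks = [c for c in ("H3K4me3", "H3K27me3", "H3K9me3") if c in signals.columns]
    if thresholds is None:
        thresholds = {m: float(np.quantile(signals[m].to_numpy(), tertile)) for m in marks}
    high = {m: signals[m].to_numpy() > thresholds[m] for m in marks}
    k4, k27 = high["H3K4me3"], high["H3K27me3"]
    k9 = high.get("H3K9me3", np.zeros(len(signals), dtype=bool))
    state = np.full(len(signals), "quiescent", dtype=object)
    state[k9] = "heterochromatic"
    state[k27 & ~k4] = "polycomb"
    state[k4 & ~k27] = "active"
    state[k4 & k27] = "bivalent"
    return pd.Series(state, index=signals.index, name="state"), thresholds


@dataclass
class ClusterAssignment:
    labels: pd.Series
    linkage: np.ndarray
    standardized: pd.DataFrame
    dropped_columns: list[str]


def cluster_changes(
    changes: pd.DataFrame,
    k: int | None = None,
    cut_height: float | None = None,
) -> ClusterAssignment:
    """Ward/Euclidean agglomerative clustering of z-scored change profiles.

    Columns are standardized (constant columns dropped with a warning) before
    clustering, so marks on different fold-change scales weigh equally. Give
    either ``k`` clusters or a dendrogram ``cut_height``.
    """
    if len(changes) < 1:
        raise ValueError("need at least one feature")
    if len(changes) == 1:
        return ClusterAssignment(
            labels=pd.Series([1], index=changes.index, name="cluster"),
            linkage=np.empty((0, 4)),
            standardized=changes * 0.0,
            dropped_columns=[],
        )
    sd = changes.std(axis=0, ddof=0)
    dropped = [c for c in changes.columns if sd[c] == 0 or not np.isfinite(sd[c])]
    if dropped:
        warnings.warn(f"dropping constant columns before standardization: {dropped}")
    kept = changes.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("no non-constant columns to cluster on")
    zs = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=0)
    if len(changes) == 1:
        return ClusterAssignment(
            labels=pd.Series([1], index=changes.index, name="cluster"),
            linkage=np.empty((0, 4)),
            standardized=zs,
            dropped_columns=dropped,
        )
    link = hierarchy.linkage(zs.to_numpy(), method="ward", metric="euclidean")
    if k is not None:
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    elif cut_height is not None:
        labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    else:
        raise ValueError("give either k or cut_height")
    return ClusterAssignment(
        labels=pd.Series(labels, index=changes.index, name="cluster"),
        linkage=link,
        standardized=zs,
        dropped_columns=dropped,
    )


def _tss(genes: pd.DataFrame) -> np.ndarray:
    """5' end of each gene interval respecting strand ('.' treated as '+')."""
    minus = genes["strand"].to_numpy() == "-"
    return np.where(minus, genes["end"].to_numpy() - 1, genes["start"].to_numpy())


def proximity_enrichment(
    genes: pd.DataFrame,
    repeats: pd.DataFrame,
    gene_flag: str = "upregulated",
    repeat_flag: str = "derepressed",
    radius: int = 10_000,
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Enrichment of flagged repeats near the TSS of flagged genes.

    A gene is repeat-proximal iff any flagged repeat copy lies within
    ``radius`` bp of its TSS (distance from the TSS point to the repeat
    interval, 0 if the TSS falls inside it). The 2x2 table (gene flagged x
    repeat-proximal) goes through the Fisher enrichment. Returns the
    enrichment plus a per-gene nearest-repeat table.
    """
    genes = genes.reset_index(drop=True)
    flagged = repeats[repeats[repeat_flag].astype(bool)]
    tss = _tss(genes)
    nearest = np.full(len(genes), np.inf)
    for chrom, sub in flagged.groupby("chrom", sort=False):
        gsel = np.flatnonzero(genes["chrom"].to_numpy() == chrom)
        if gsel.size == 0:
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy())]
        for gi in gsel:
            x = tss[gi]
            # distance from point to each interval; small sets, direct scan
            d = np.where(
                (x >= starts) & (x < ends), 0, np.minimum(np.abs(starts - x), np.abs(ends - 1 - x))
            )
            nearest[gi] = min(nearest[gi], float(d.min()))
    proximal = nearest <= radius
    up = genes[gene_flag].to_numpy(dtype=bool)
    enr = fisher_enrichment(up, proximal, label=f"repeat within {radius} bp of TSS")
    per_gene = pd.DataFrame(
        {
            "gene": genes["name"] if "name" in genes else genes.index,
            "tss": tss,
            "nearest_repeat_bp": nearest,
            "repeat_proximal": proximal,
            gene_flag: up,
        }
    )
    return enr, per_gene
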