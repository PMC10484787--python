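"""Repeat-subfamily quantification with explicit multimapping handling.

Transposable-element copies within a subfamily are near-identical, so reads
multimap and must be quantified at the subfamily level. A read aligning to n
candidate copies contributes 1/n to each copy's subfamily (fractional
assignment: deterministic and mass-conserving, unlike random single
assignment). Shares are accumulated as exact fractions so the bookkeeping
identity  sum over subfamilies (unique + multi) + unassigned = reads  holds
exactly, not merely to float tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from . import _nbglm
from .enrichment_stats import bh_adjust

__all__ = [
    "RepeatCounts",
    "aggregate_subfamily_counts",
    "multimapping_fraction",
    "test_repeat_differential",
    "AnnotationError",
]


class AnnotationError(ValueError):
    pass


@dataclass
class RepeatCounts:
    """Per-subfamily unique counts and fractional multimapping mass."""

    counts: pd.DataFrame  # index subfamily; columns unique, multi, total
    unassigned: float
    n_reads: int
    library_size: float  # all mapped reads in the library (>= assigned mass)
    sample: str = ""


def _overlap_copy(annotation: pd.DataFrame, chrom, start, end) -> int | None:
    """Index of the copy with maximal overlap with the alignment, or None."""
    sub = annotation[annotation["chrom"] == chrom]
    if not len(sub):
        return None
    ov = np.minimum(sub["end"].to_numpy(), end) - np.maximum(sub["start"].to_numpy(), start)
    best = int(np.argmax(ov))
    if ov[best] <= 0:
        return None
    return int(sub.index[best])


def aggregate_subfamily_counts(
    alignments: pd.DataFrame,
    annotation: pd.DataFrame,
    library_size: float | None = None,
    sample: str = "",
) -> RepeatCounts:
    """Aggregate alignment records into per-subfamily unique/multi masses.

    ``alignments`` has one row per alignment with columns read_id, chrom,
    start, end; a read's alignment count n is the number of rows sharing its
    read_id. Unique reads (n = 1) add 1 to their copy's subfamily; each
    alignment of a multimapping read adds 1/n of fractional mass. Alignments
    that overlap no annotated copy route their share to an explicit
    "unassigned" sink rather than being dropped silently.
    """
    if "subfamily" not in annotation.columns:
        raise AnnotationError("repeat annotation needs a 'subfamily' column")
    counted = annotation.groupby("subfamily").size()
    if (counted == 0).any():
        raise AnnotationError("subfamily with zero copies in annotation")
    annotation = annotation.reset_index(drop=True)

    subfams = sorted(annotation["subfamily"].unique())
    unique_mass = {sf: Fraction(0) for sf in subfams}
    multi_mass = {sf: Fraction(0) for sf in subfams}
    unassigned = Fraction(0)

    n_by_read = alignments.groupby("read_id").size()
    for row in alignments.itertuples(index=False):
        n = int(n_by_read[row.read_id])
        share = Fraction(1, n)
        copy = _overlap_copy(annotation, row.chrom, row.start, row.end)
        if copy is None:
            unassigned += share
            continue
        sf = annotation.at[copy, "subfamily"]
        if n == 1:
            unique_mass[sf] += share
        else:
            multi_mass[sf] += share

    n_reads = int(n_by_read.size)
    total_mass = sum(unique_mass.values()) + sum(multi_mass.values()) + unassigned
    assert total_mass == n_reads  # exact conservation of read mass
    counts = pd.DataFrame(
        {
            "unique": [float(unique_mass[sf]) for sf in subfams],
            "multi": [float(multi_mass[sf]) for sf in subfams],
        },
        index=pd.Index(subfams, name="subfamily"),
    )
    counts["total"] = counts["unique"] + counts["multi"]
    return RepeatCounts(
        counts=counts,
        unassigned=float(unassigned),
        n_reads=n_reads,
        library_size=float(library_size) if library_size is not None else float(n_reads),
        sample=sample,
    )


def multimapping_fraction(
    multi_mass, library_size: float | None = None
) -> float:
    """Share of a library's reads that multimap.

    Accepts a RepeatCounts (uses its library size) or a raw multimapping mass
    plus an explicit library size. The denominator is all mapped reads in
    the library, not just repeat-overlapping reads (a flagged choice).
    """
    if isinstance(multi_mass, RepeatCounts):
        total_multi = float(multi_mass.counts["multi"].sum())
        lib = multi_mass.library_size
    else:
        total_multi = float(multi_mass)
        lib = library_size
    if lib is None or lib <= 0:
        raise ValueError("library size must be positive")
    return total_multi / lib


def test_repeat_differential(
    counts: pd.DataFrame,
    sample_info: pd.DataFrame,
    conditions: tuple[str, str],
    library_sizes: pd.Series | None = None,
    lfc_threshold: float = 0.58,
    fdr_threshold: float = 0.01,
    n_prior: float = 10.0,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-subfamily NB Wald test with library-size offsets.

    Same statistical core as the binned differential-occupancy test, applied
    to total (unique + fractional multimapping) subfamily mass; pass a
    unique-only matrix for the sensitivity mode. Significance requires BOTH
    q < ``fdr_threshold`` AND |log2FC| > ``lfc_threshold`` (default
    log2 1.5 = 0.58), the conventional gate for subfamily calls.
    """
    ref, alt = conditions
    info = sample_info.set_index("sample") if "sample" in sample_info.columns else sample_info
    cols = [s for s in counts.columns if info.loc[s, "condition"] in (ref, alt)]
    cond = np.array([info.loc[s, "condition"] == alt for s in cols])
    if (~cond).sum() < 2 or cond.sum() < 2:
        raise ValueError("need at least 2 replicates per condition")
    y_full = counts[cols].to_numpy(dtype=float)
    if library_sizes is None:
        libs = y_full.sum(axis=0)
    else:
        libs = library_sizes[cols].to_numpy(dtype=float)
    size_factors = libs / np.exp(np.mean(np.log(libs)))

    nonzero = y_full.sum(axis=1) > 0
    y = y_full[nonzero]
    disp = _nbglm.estimate_dispersions(y, size_factors, cond, n_prior=n_prior)
    res = _nbglm.nb_wald(
        y, size_factors, cond, disp["shrunk"],
        df_total=_nbglm.effective_df(len(cols), n_prior),
    )
    log2fc = np.log2(res["mean_alt"] + pseudocount) - np.log2(res["mean_ref"] + pseudocount)
    qvalue = bh_adjust(res["pvalue"])
    significant = (qvalue < fdr_threshold) & (np.abs(log2fc) > lfc_threshold)
    direction = np.where(log2fc > 0, "up", "down")
    table = pd.DataFrame(
        {
            "mean_ref": res["mean_ref"],
            "mean_alt": res["mean_alt"],
            "log2fc": log2fc,
            "pvalue": res["pvalue"],
            "qvalue": qvalue,
            "significant": significant,
            "direction": direction,
        },
        index=counts.index[nonzero],
    )
    audit = {
        "conditions": [ref, alt],
        "samples": cols,
        "size_factors": dict(zip(cols, np.round(size_factors, 6))),
        "n_tested": int(nonzero.sum()),
        "n_all_zero": int((~nonzero).sum()),
        "lfc_threshold": lfc_threshold,
        "fdr_threshold": fdr_threshold,
    }
    return table, audit
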