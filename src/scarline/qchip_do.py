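"""Spike-in quantitative ChIP-seq comparison.

A fixed proportion of exogenous (spike-in) chromatin in every ChIP makes
between-sample scaling absolute: spike-in read totals depend on sequencing
depth only, so dividing them out recovers genome-wide occupancy changes that
ordinary library-size normalization would erase. The module computes
spike-in scale factors, normalizes binned signal, stratifies bins by peak
overlap and replication timing, runs the empirical-Bayes NB Wald test for
differential occupancy (DO), and classifies mutant-specific changes as
rescued or not in a revertant line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nbglm
from .enrichment_stats import bh_adjust
from .genomics_io import Track, WindowGrid, overlap_windows, stratify_by_timing

__all__ = [
    "BinnedSignal",
    "spikein_scale_factors",
    "normalize_signal",
    "stratify_bins",
    "test_differential_occupancy",
    "classify_rescue",
    "NormalizationError",
]

#: Bin sizes used by convention: 5 kb for histone-PTM comparisons, 2.5 kb for
#: the PRC2-subunit (SUZ12) comparison.
DEFAULT_BIN_SIZES = {"histone": 5_000, "prc2": 2_500}


class NormalizationError(ValueError):
    pass


def spikein_scale_factors(spike_totals: pd.Series, reference: str | None = None) -> pd.Series:
    """Per-sample factor spike_reference / spike_sample.

    Equal-occupancy samples sequenced at different depths equalize after
    multiplying genome counts by their factor. Only ratios matter; the
    reference defaults to the first sample.
    """
    if (spike_totals <= 0).any():
        bad = spike_totals.index[spike_totals <= 0][0]
        raise NormalizationError(f"sample {bad!r} has non-positive spike-in count")
    reference = spike_totals.index[0] if reference is None else reference
    if reference not in spike_totals.index:
        raise NormalizationError(f"reference sample {reference!r} not found")
    return (float(spike_totals[reference]) / spike_totals).rename("factor")


@dataclass
class BinnedSignal:
    """Spike-normalized per-bin signal with the factors used, for audit."""

    normalized: pd.DataFrame
    factors: pd.Series


def normalize_signal(counts: pd.DataFrame, factors: pd.Series) -> BinnedSignal:
    missing = [c for c in counts.columns if c not in factors.index]
    if missing:
        raise NormalizationError(f"no scale factor for samples {missing}")
    return BinnedSignal(normalized=counts * factors[counts.columns], factors=factors)


def stratify_bins(
    grid: WindowGrid,
    peaks: pd.DataFrame,
    rt: Track | None = None,
    min_overlap: int = 1,
) -> dict[str, np.ndarray]:
    """Composable bin strata: in/out of reference-condition peaks x timing.

    Peaks are called in the reference (wild-type) condition; early/late are
    replication-timing quartile strata. Empty strata produce a warning so
    downstream tests can skip them.
    """
    if len(peaks) == 0:
        warnings.warn("no peaks supplied: in_peak stratum is empty")
        in_peak = np.zeros(grid.n, dtype=bool)
    else:
        in_peak = overlap_windows(grid, peaks, min_overlap=min_overlap)
    strata = {"in_peak": in_peak, "out_peak": ~in_peak}
    if rt is not None:
        early = stratify_by_timing(grid, rt, "early")
        late = stratify_by_timing(grid, rt, "late")
        strata.update(
            {
                "early": early,
                "late": late,
                "out_peak_early": ~in_peak & early,
                "out_peak_late": ~in_peak & late,
                "in_peak_early": in_peak & early,
                "in_peak_late": in_peak & late,
            }
        )
    for name, mask in strata.items():
        if not mask.any():
            warnings.warn(f"stratum {name!r} is empty")
    return strata


def test_differential_occupancy(
    counts: pd.DataFrame,
    sample_info: pd.DataFrame,
    factors: pd.Series,
    conditions: tuple[str, str],
    stratum_mask: np.ndarray | None = None,
    fdr_threshold: float = 0.1,
    lfc_threshold: float = 0.0,
    n_prior: float = 10.0,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-bin empirical-Bayes NB Wald test between two conditions.

    Spike-in factors enter as offsets (size factor = 1/factor). BH adjustment
    is applied within the tested stratum. Classes: gain iff q < threshold and
    log2FC > lfc_threshold, loss symmetric, else ns. The reported log2FC is
    moderated with a pseudocount on normalized means; the Wald statistic uses
    the GLM coefficient. Returns (DO table, audit dict).
    """
    ref, alt = conditions
    info = sample_info.set_index("sample") if "sample" in sample_info.columns else sample_info
    cols = [s for s in counts.columns if info.loc[s, "condition"] in (ref, alt)]
    cond = np.array([info.loc[s, "condition"] == alt for s in cols])
    for name, nrep in (("reference", (~cond).sum()), ("alternative", cond.sum())):
        if nrep < 2:
            raise ValueError(
                f"{name} condition has {nrep} replicate(s); at least 2 are required"
            )
    y_full = counts[cols].to_numpy(dtype=float)
    size_factors = (1.0 / factors[cols]).to_numpy(dtype=float)
    size_factors = size_factors / np.exp(np.mean(np.log(size_factors)))

    index = counts.index
    if stratum_mask is not None:
        stratum_mask = np.asarray(stratum_mask, dtype=bool)
        y_full = y_full[stratum_mask]
        index = index[stratum_mask]

    nonzero = y_full.sum(axis=1) > 0
    audit = {
        "conditions": [ref, alt],
        "samples": cols,
        "size_factors": dict(zip(cols, size_factors.round(6))),
        "n_bins_tested": int(nonzero.sum()),
        "n_bins_all_zero": int((~nonzero).sum()),
        "n_prior": n_prior,
    }
    y = y_full[nonzero]
    disp = _nbglm.estimate_dispersions(y, size_factors, cond, n_prior=n_prior)
    res = _nbglm.nb_wald(
        y, size_factors, cond, disp["shrunk"],
        df_total=_nbglm.effective_df(len(cols), n_prior),
    )

    log2fc = np.log2(res["mean_alt"] + pseudocount) - np.log2(res["mean_ref"] + pseudocount)
    qvalue = bh_adjust(res["pvalue"])
    cls = np.where(
        (qvalue < fdr_threshold) & (log2fc > lfc_threshold),
        "gain",
        np.where((qvalue < fdr_threshold) & (log2fc < -lfc_threshold), "loss", "ns"),
    )
    table = pd.DataFrame(
        {
            "mean_ref": res["mean_ref"],
            "mean_alt": res["mean_alt"],
            "log2fc": log2fc,
            "dispersion": disp["shrunk"],
            "stat": res["stat"],
            "pvalue": res["pvalue"],
            "qvalue": qvalue,
            "class": cls,
        },
        index=index[nonzero],
    )
    audit["fdr_threshold"] = fdr_threshold
    audit["lfc_threshold"] = lfc_threshold
    return table, audit


def classify_rescue(
    do_mut_vs_wt: pd.DataFrame,
    do_rescue_vs_wt: pd.DataFrame,
    fdr_threshold: float = 0.1,
    magnitude_ratio: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Flag mutant-significant features whose change reverts in the rescue line.

    A feature significant in mutant-vs-WT is rescued iff it is no longer
    significant in rescue-vs-WT, or its rescue-vs-WT log2FC has shrunk below
    ``magnitude_ratio`` of the mutant log2FC (same sign convention: both
    tables are versus WT). The 50% magnitude rule is an explicit choice,
    exposed as a flag.
    """
    if not do_mut_vs_wt.index.equals(do_rescue_vs_wt.index):
        common = do_mut_vs_wt.index.intersection(do_rescue_vs_wt.index)
        if len(common) != len(do_mut_vs_wt) or len(common) != len(do_rescue_vs_wt):
            raise ValueError("rescue classification requires identical feature sets")
        do_rescue_vs_wt = do_rescue_vs_wt.loc[do_mut_vs_wt.index]
    sig = do_mut_vs_wt["class"] != "ns"
    not_sig_rescue = do_rescue_vs_wt["qvalue"] >= fdr_threshold
    shrunk = (
        do_rescue_vs_wt["log2fc"].abs()
        < magnitude_ratio * do_mut_vs_wt["log2fc"].abs()
    )
    rescued = sig & (not_sig_rescue | shrunk)
    table = pd.DataFrame(
        {
            "mut_log2fc": do_mut_vs_wt["log2fc"],
            "mut_qvalue": do_mut_vs_wt["qvalue"],
            "rescue_log2fc": do_rescue_vs_wt["log2fc"],
            "rescue_qvalue": do_rescue_vs_wt["qvalue"],
            "mut_significant": sig,
            "rescued": rescued,
        }
    )
    n_sig = int(sig.sum())
    fraction = float(rescued.sum() / n_sig) if n_sig else float("nan")
    return table, fraction
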