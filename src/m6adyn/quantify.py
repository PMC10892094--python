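"""Normalization, fold change, polysome occupancy, category statistics.

The differential-abundance stage is a deliberately simplified pipeline:
median-of-ratios size factors (the estimator behind DESeq-style
normalization), log2 fold change of normalized condition means with a
pseudocount, Welch t-tests on log-normalized counts and Benjamini-Hochberg
adjustment.  The category-level comparisons — Wilcoxon rank-sum between
stress-enriched / control-enriched / shared groups, two-sample t-tests for
the ncRNA groups — are implemented exactly as the headline statistics.

Polysome occupancy follows the RPM-ratio definition:
occupancy = log2(polysome RPM / RNA RPM) per condition, and
occupancy change = occupancy_copper - occupancy_control.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix

log = logging.getLogger("m6adyn")

CONDITIONS = ("control", "copper")


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over features of count_ij / (geometric mean of feature
    i across samples), using only features positive in every sample.  If no
    such feature exists, falls back to library-size ratios with a warning.
    """
    if cm.n_samples < 2:
        raise ValueError("size factors need at least two samples")
    counts = cm.counts.astype(float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        log.warning("no all-positive feature; falling back to library-size ratios")
        factors = cm.library_size.astype(float)
    else:
        logc = np.log(counts[allpos])
        logratios = logc - logc.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logratios, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def log2_fold_change(
    cm: CountMatrix,
    factors: np.ndarray | None = None,
    pseudocount: float = 1.0,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-feature copper-vs-control fold change table.

    log2fc = log2((mean normalized copper + pc) / (mean normalized control
    + pc)); p-values from Welch t-tests on log2(normalized + pc); padj by
    Benjamini-Hochberg (or ``adjust='bonferroni'``).  Features with zero
    variance in both groups get p = 1.
    """
    ctrl = cm.columns(condition="control")
    copp = cm.columns(condition="copper")
    if not ctrl or not copp:
        raise ValueError("both conditions need at least one replicate")
    if factors is None:
        factors = size_factors(cm)
    norm = cm.counts / factors
    mean_ctrl = norm[:, ctrl].mean(axis=1)
    mean_copp = norm[:, copp].mean(axis=1)
    lfc = np.log2((mean_copp + pseudocount) / (mean_ctrl + pseudocount))
    logn = np.log2(norm + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            logn[:, copp], logn[:, ctrl], axis=1, equal_var=False
        )
    pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    padj = multipletests(pvals, method=adjust)[1]
    return pd.DataFrame(
        dict(
            transcript_id=cm.feature_ids,
            baseMean=norm.mean(axis=1),
            log2fc=lfc,
            pvalue=pvals,
            padj=padj,
        )
    )


def polysome_occupancy(
    poly: CountMatrix,
    rna: CountMatrix,
    rpm_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-transcript polysome occupancy per condition and its change.

    RPM = count * 1e6 / library size, averaged over replicates within
    assay x condition; occupancy = log2(polysome RPM / RNA RPM);
    occupancy_change = occupancy_copper - occupancy_control.  Transcripts
    with any of the four mean RPM cells below ``rpm_floor`` are excluded
    (logged count).
    """
    if poly.feature_ids != rna.feature_ids:
        raise ValueError("polysome and RNA matrices must share feature ids")
    cells = {}
    for assay, cm in (("polysome", poly), ("rna", rna)):
        rpm = cm.rpm()
        for cond in CONDITIONS:
            cols = cm.columns(condition=cond)
            if not cols:
                raise ValueError(f"missing {assay} replicates for {cond}")
            cells[(assay, cond)] = rpm[:, cols].mean(axis=1)
    keep = np.ones(len(rna.feature_ids), dtype=bool)
    for v in cells.values():
        keep &= v >= rpm_floor
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("occupancy: %d transcripts below RPM floor excluded", n_drop)
    occ = {
        cond: np.log2(cells[("polysome", cond)][keep] / cells[("rna", cond)][keep])
        for cond in CONDITIONS
    }
    ids = np.asarray(rna.feature_ids)[keep]
    return pd.DataFrame(
        dict(
            transcript_id=ids,
            occupancy_control=occ["control"],
            occupancy_copper=occ["copper"],
            occupancy_change=occ["copper"] - occ["control"],
        )
    )


# ----------------------------------------------------------------------
# category-level statistics
# ----------------------------------------------------------------------
def rank_sum_statistic(x, y) -> float:
    """Mann-Whitney U of x vs y (ties counted half), as used in the
    category comparisons."""
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)


def _two_sided_p(x: np.ndarray, y: np.ndarray, test: str) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values tied: no evidence either way
    if test == "wilcoxon":
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    if test == "ttest":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    raise ValueError("test must be 'wilcoxon' or 'ttest'")


def category_comparison(
    values: pd.Series,
    labels: pd.Series,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Pairwise two-sided comparisons of a per-transcript statistic between
    categories.

    ``values`` and ``labels`` are aligned on their index (transcript ids).
    Categories with fewer than two observations are skipped with a warning.
    Returns one row per pair: group medians, sizes and the p-value.
    """
    joined = pd.DataFrame(dict(value=values, label=labels)).dropna()
    groups = {
        lab: g["value"].to_numpy() for lab, g in joined.groupby("label", sort=True)
    }
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    for k in set(groups) - set(usable):
        log.warning("category %s has n < 2; comparison skipped", k)
    if len(usable) < 2:
        raise ValueError("need at least two categories with n >= 2")
    rows = []
    for a, b in itertools.combinations(sorted(usable), 2):
        x, y = usable[a], usable[b]
        rows.append(
            dict(
                group1=a, group2=b, n1=len(x), n2=len(y),
                median1=float(np.median(x)), median2=float(np.median(y)),
                pvalue=_two_sided_p(x, y, test),
            )
        )
    return pd.DataFrame(rows)


def threshold_counts(
    fold_changes: pd.DataFrame,
    transcript_ids: list[str],
    up: float = 1.5,
    down: float = 0.5,
) -> tuple[int, int]:
    """(# >50% increase, # >50% decrease) among the given transcripts.

    A ">50% increase/decrease" is a normalized copper/control ratio > ``up``
    (default 1.5) or < ``down`` (default 0.5).
    """
    sub = fold_changes[fold_changes["transcript_id"].isin(set(transcript_ids))]
    ratio = 2.0 ** sub["log2fc"].to_numpy()
    return int((ratio > up).sum()), int((ratio < down).sum())
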