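"""Swappable data-preprocessing options: the researcher's degrees of freedom.

Each stage of the preprocessing — prefiltering of lowly expressed genes,
removal of duplicated gene IDs after ID conversion, count transformation /
normalization, and differential-expression scoring — is exposed as a family
of named options addressable by a string key (``"total_count:10"``,
``"keep_first"``, ``"log2_cpm:0.5"``, ``"welch_t"``, ...).  The stepwise
optimizer swaps these keys; everything here is deterministic given its
inputs.

The four DE scoring options are self-contained archetypes (Welch t,
signal-to-noise ratio, rank-sum z, variance-shrunk moderated t) standing in
for the heavyweight DE packages (limma/voom, DESeq2, edgeR) a practitioner
would normally reach for.  They are deliberately simple: the optimizer only
needs interchangeable options with genuinely different behavior, not a
faithful re-implementation of those tools.

sklearn-style transformer/estimator facades (:class:`CountPrefilter`,
:class:`DuplicateCollapser`, :class:`CountNormalizer`,
:class:`DifferentialExpression`) wrap the functional core.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import bh_adjust
from .datasets import IdConversionTable, LabelAssignment
from .errors import PipelineError

logger = logging.getLogger(__name__)

__all__ = [
    "prefilter",
    "deduplicate",
    "transform_counts",
    "de_score",
    "make_ranked_list",
    "CountPrefilter",
    "DuplicateCollapser",
    "CountNormalizer",
    "DifferentialExpression",
    "PREFILTER_OPTIONS",
    "DEDUP_OPTIONS",
    "TRANSFORM_OPTIONS",
    "DE_OPTIONS",
    "METRIC_OPTIONS",
]

PREFILTER_OPTIONS = ("none", "total_count:<theta>", "cpm:<c>:<k>")
DEDUP_OPTIONS = ("keep_first", "keep_highest_mean")
TRANSFORM_OPTIONS = ("cpm", "log2_cpm:<pseudocount>", "median_ratio_log")
DE_OPTIONS = ("welch_t", "snr", "wilcoxon_z", "moderated_t")
METRIC_OPTIONS = ("statistic", "log2fc", "signed_logp")

# Moderated t: prior weight (pseudo-observations) pulling per-gene variances
# toward the mean variance; a fixed, documented stand-in for empirical-Bayes
# shrinkage.
_MODERATED_PRIOR_DF = 4.0

# SNR denominator floors, mirroring common GSEA practice.
_SNR_SD_FLOOR_FRACTION = 0.2
_SNR_SD_FLOOR_ABS = 1e-8


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    colsums = counts.sum(axis=0).astype(float)
    if (colsums <= 0).any():
        bad = list(colsums.index[colsums <= 0])
        raise PipelineError("transform", f"all-zero sample column(s): {bad}")
    return counts / colsums * 1e6


def prefilter(counts: pd.DataFrame, option: str) -> pd.DataFrame:
    """Remove lowly expressed genes.

    Options: ``none``; ``total_count:<theta>`` keeps genes with row sum >=
    theta; ``cpm:<c>:<k>`` keeps genes whose CPM exceeds ``c`` in at least
    ``k`` samples.  Removing every gene is an error (an over-aggressive
    filter), never an empty success.
    """
    parts = str(option).split(":")
    kind = parts[0]
    if kind == "none":
        return counts
    if kind == "total_count":
        theta = float(parts[1])
        if theta < 0:
            raise ValueError("total_count threshold must be nonnegative")
        kept = counts[counts.sum(axis=1) >= theta]
    elif kind == "cpm":
        c, k = float(parts[1]), int(parts[2])
        if k > counts.shape[1]:
            raise ValueError("cpm filter requires k <= number of samples")
        cpm = _cpm(counts)
        kept = counts[(cpm > c).sum(axis=1) >= k]
    else:
        raise ValueError(f"unknown prefilter option {option!r}")
    if kept.shape[0] == 0:
        raise PipelineError("prefilter", f"option {option!r} removed all genes")
    return kept


def deduplicate(
    counts: pd.DataFrame, table: IdConversionTable, option: str = "keep_first"
) -> pd.DataFrame:
    """Convert gene IDs through ``table`` and collapse duplicated targets.

    ``keep_first`` keeps the first-occurring source row per target;
    ``keep_highest_mean`` keeps the source row with the largest mean count.
    Source IDs absent from the table are dropped with a warning.
    """
    if option not in DEDUP_OPTIONS:
        raise ValueError(f"unknown deduplication option {option!r}")
    mapping = table.mapping
    present = [g for g in counts.index if g in mapping]
    missing = counts.shape[0] - len(present)
    if missing:
        logger.warning("deduplicate: dropping %d gene(s) absent from the ID table", missing)
    if not present:
        raise PipelineError("deduplicate", "no gene maps through the conversion table")
    sub = counts.loc[present]
    targets = pd.Series([mapping[g] for g in present], index=sub.index, name="target")
    if option == "keep_first":
        keep = ~targets.duplicated(keep="first")
    else:  # keep_highest_mean; ties resolved toward the earlier row
        means = sub.mean(axis=1)
        order = np.lexsort((np.arange(len(sub)), -means.values))
        ranked_sources = sub.index[order]
        winners = set()
        seen: set[str] = set()
        for src in ranked_sources:
            tgt = mapping[src]
            if tgt not in seen:
                seen.add(tgt)
                winners.add(src)
        keep = sub.index.isin(winners)
    out = sub[keep].copy()
    out.index = [mapping[g] for g in out.index]
    return out


def transform_counts(counts: pd.DataFrame, option: str) -> pd.DataFrame:
    """Normalize/transform counts into an expression matrix.

    ``cpm`` scales each sample to one million; ``log2_cpm:<pc>`` applies
    log2(CPM + pc); ``median_ratio_log`` divides samples by median-of-ratios
    size factors (geometric-mean reference over genes with all-nonzero
    counts) and applies log2(x + 1).  When no gene is nonzero in every
    sample, median-of-ratios falls back to column-sum factors with a
    warning.
    """
    parts = str(option).split(":")
    kind = parts[0]
    if kind == "cpm":
        return _cpm(counts)
    if kind == "log2_cpm":
        pc = float(parts[1]) if len(parts) > 1 else 0.5
        return np.log2(_cpm(counts) + pc)
    if kind == "median_ratio_log":
        values = counts.to_numpy(dtype=float)
        colsums = values.sum(axis=0)
        if (colsums <= 0).any():
            raise PipelineError("transform", "all-zero sample column")
        all_nonzero = (values > 0).all(axis=1)
        if not all_nonzero.any():
            logger.warning(
                "median_ratio_log: no gene with all-nonzero counts; "
                "falling back to column-sum size factors"
            )
            sf = colsums / np.exp(np.mean(np.log(colsums)))
        else:
            logs = np.log(values[all_nonzero])
            log_geo = logs.mean(axis=1, keepdims=True)
            sf = np.exp(np.median(logs - log_geo, axis=0))
        return pd.DataFrame(
            np.log2(values / sf[None, :] + 1.0), index=counts.index, columns=counts.columns
        )
    raise ValueError(f"unknown transform option {option!r}")


def _rank_sum_z(values: np.ndarray, ref_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample rank-sum z per gene (normal approximation).

    Uses the exact finite-population variance of the rank sum, which
    accounts for ties without an explicit tie-correction term.
    """
    ranks = stats.rankdata(values, axis=1)
    n = values.shape[1]
    n1 = int(ref_mask.sum())
    w = ranks[:, ref_mask].sum(axis=1)
    rbar = ranks.mean(axis=1)
    pop_var = ((ranks - rbar[:, None]) ** 2).mean(axis=1)
    var = n1 * (n - n1) / (n - 1) * pop_var
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - n1 * rbar) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def de_score(values: pd.DataFrame, labels: LabelAssignment, option: str = "welch_t") -> pd.DataFrame:
    """Per-gene two-group differential scoring.

    The signed statistic is positive when expression is higher in the
    reference level.  ``snr`` has no analytic null and carries ``p = NaN``
    (valid only as a ranking metric); the other options report two-sided
    p-values and BH-adjusted p-values.  The ``log2fc`` column is the
    difference of group means of the provided values, i.e., a log2 fold
    change when the input is on a log2 scale.
    """
    missing = [s for s in labels.sample_ids if s not in values.columns]
    if missing:
        raise ValueError(f"samples absent from the matrix: {missing[:5]}")
    x = values[list(labels.sample_ids)].to_numpy(dtype=float)
    ref = labels.mask()
    n1, n2 = int(ref.sum()), int((~ref).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two samples per condition level")
    a, b = x[:, ref], x[:, ~ref]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)

    if option == "welch_t":
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        stat, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        stat = np.where(np.isfinite(stat), stat, 0.0)
        p = np.where(np.isfinite(p), p, 1.0)
    elif option == "snr":
        s1, s2 = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
        s1 = np.maximum(np.maximum(s1, _SNR_SD_FLOOR_FRACTION * np.abs(m1)), _SNR_SD_FLOOR_ABS)
        s2 = np.maximum(np.maximum(s2, _SNR_SD_FLOOR_FRACTION * np.abs(m2)), _SNR_SD_FLOOR_ABS)
        stat = (m1 - m2) / (s1 + s2)
        p = np.full(stat.shape, np.nan)
    elif option == "wilcoxon_z":
        stat, p = _rank_sum_z(x, ref)
    elif option == "moderated_t":
        v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        df_g = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_g
        prior = pooled.mean()
        shrunk = (_MODERATED_PRIOR_DF * prior + df_g * pooled) / (_MODERATED_PRIOR_DF + df_g)
        se = np.sqrt(shrunk * (1.0 / n1 + 1.0 / n2))
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = (m1 - m2) / se
        stat = np.where(np.isfinite(stat), stat, 0.0)
        p = 2.0 * stats.t.sf(np.abs(stat), df=df_g + _MODERATED_PRIOR_DF)
    else:
        raise ValueError(f"unknown DE option {option!r}")

    return pd.DataFrame(
        {
            "statistic": stat,
            "log2fc": m1 - m2,
            "pval": p,
            "adj_pval": bh_adjust(p),
        },
        index=values.index,
    )


def make_ranked_list(de: pd.DataFrame, metric: str = "statistic") -> pd.Series:
    """Genes sorted by a signed gene-level metric, decreasing.

    ``signed_logp`` is sign(statistic) * -log10(p).  Ties are broken by
    lexicographic gene ID, making the ranking deterministic.  NaN metric
    values are an error naming the offending genes.
    """
    if metric == "statistic":
        m = de["statistic"].astype(float)
    elif metric == "log2fc":
        m = de["log2fc"].astype(float)
    elif metric == "signed_logp":
        p = de["pval"].astype(float).clip(lower=1e-300)
        m = np.sign(de["statistic"].astype(float)) * (-np.log10(p))
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    bad = list(m.index[~np.isfinite(m)])
    if bad:
        raise ValueError(f"non-finite metric for gene(s): {bad[:10]}")
    frame = pd.DataFrame({"metric": m, "gene": m.index})
    frame = frame.sort_values(["metric", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(frame["metric"].to_numpy(), index=frame["gene"].to_numpy(), name="metric")


# ---------------------------------------------------------------------------
# sklearn-style facades


class CountPrefilter(BaseEstimator, TransformerMixin):
    """Transformer facade over :func:`prefilter`."""

    def __init__(self, option: str = "total_count:10"):
        self.option = option

    def fit(self, X: pd.DataFrame, y=None):
        self.n_genes_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return prefilter(X, self.option)


class DuplicateCollapser(BaseEstimator, TransformerMixin):
    """Transformer facade over :func:`deduplicate`."""

    def __init__(self, table: IdConversionTable = None, option: str = "keep_first"):
        self.table = table
        self.option = option

    def fit(self, X: pd.DataFrame, y=None):
        if self.table is None:
            raise ValueError("an IdConversionTable is required")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return deduplicate(X, self.table, self.option)


class CountNormalizer(BaseEstimator, TransformerMixin):
    """Transformer facade over :func:`transform_counts`."""

    def __init__(self, option: str = "log2_cpm:0.5"):
        self.option = option

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return transform_counts(X, self.option)


class DifferentialExpression(BaseEstimator):
    """Estimator facade over :func:`de_score`.

    ``fit(X, y)`` takes an expression matrix (genes x samples) and a
    :class:`LabelAssignment`; results land in ``results_``.
    """

    def __init__(self, option: str = "welch_t"):
        self.option = option

    def fit(self, X: pd.DataFrame, y: LabelAssignment):
        self.results_ = de_score(X, y, self.option)
        return self

    def ranked_list(self, metric: str = "statistic") -> pd.Series:
        return make_ranked_list(self.results_, metric)
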