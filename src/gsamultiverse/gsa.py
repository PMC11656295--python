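"""Gene set analysis method archetypes and their shared statistics.

Four archetypes cover the two method families whose flexibility the study
quantifies:

``ora``
    Overrepresentation analysis: upper-tail hypergeometric test of a DE
    gene list against a configurable universe, BH-adjusted.
``gsea_sample_perm``
    Functional class scoring with the weighted Kolmogorov–Smirnov
    enrichment score; the null ranking is regenerated from sample-label
    permutations (group sizes preserved), the defensible null for
    two-condition designs.
``gsea_preranked``
    The same enrichment-score machinery on a fixed, externally supplied
    ranked list, with a gene-permutation null.  Under inter-gene
    correlation this null is miscalibrated and inflates false discovery
    rates — the reliability failure the study highlights.
``weighted_fcs``
    A PADOG-style score: set-level weighted mean of |moderated t| with
    gene weights inversely related to how often a gene appears across the
    database, standardized against a sample-permutation null.

Results are :class:`GSAResult` objects wrapping a per-set table (size,
statistic, NES, raw p, adjusted p, significance flag) plus the threshold
convention under which significance was declared.  The two published
conventions — BH-adjusted p < 0.05 and q < 0.25 — are both expressible via
:class:`MethodSpec`; the FDR machinery is BH on permutation p-values in
either case, with the convention recorded as metadata.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator

from ._stats import bh_adjust
from .datasets import GeneSetDatabase, LabelAssignment
from .errors import PipelineError
from .preprocessing import de_score, make_ranked_list

logger = logging.getLogger(__name__)

__all__ = [
    "MethodSpec",
    "GSAResult",
    "default_method_specs",
    "bh_adjust",
    "enrichment_score",
    "ora_test",
    "resolve_universe",
    "gsea_sample_perm",
    "gsea_preranked",
    "weighted_fcs",
    "count_degs",
    "relative_rank",
    "ORA",
    "GSEA",
    "WeightedFCS",
]

ARCHETYPES = ("ora", "gsea_sample_perm", "gsea_preranked", "weighted_fcs")


@dataclass(frozen=True)
class MethodSpec:
    """Configuration of one GSA archetype.

    ``threshold_on`` labels the significance convention (``"adj_p"`` for
    BH-adjusted p-values, ``"q"`` for the q-value style of the web GSEA
    tools); in both cases the numeric comparison is against the BH-adjusted
    permutation p-values, so the label is a reporting convention.
    """

    archetype: str
    threshold: float = 0.05
    threshold_on: str = "adj_p"
    p_w: int = 1
    universe: str = "all_measured"
    pvalue_mode: str | None = None  # "sample_perm" | "gene_perm"; None = archetype default
    n_permutations: int = 200
    min_set_size: int = 5
    max_set_size: int = 500

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.p_w not in (0, 1):
            raise ValueError("weight exponent p_w must be 0 or 1")
        if self.threshold_on not in ("adj_p", "q"):
            raise ValueError("threshold_on must be 'adj_p' or 'q'")
        if self.universe not in ("all_measured", "all_annotated", "post_filter"):
            raise ValueError(f"unknown universe option {self.universe!r}")

    def resolved_pvalue_mode(self) -> str:
        if self.pvalue_mode is not None:
            return self.pvalue_mode
        return "gene_perm" if self.archetype == "gsea_preranked" else "sample_perm"


def default_method_specs() -> dict[str, MethodSpec]:
    """The archetypes under their customary significance conventions."""
    return {
        "ora": MethodSpec(archetype="ora", threshold=0.05, threshold_on="adj_p"),
        "gsea_sample_perm": MethodSpec(
            archetype="gsea_sample_perm", threshold=0.05, threshold_on="adj_p"
        ),
        "gsea_preranked": MethodSpec(
            archetype="gsea_preranked", threshold=0.25, threshold_on="q"
        ),
        "weighted_fcs": MethodSpec(archetype="weighted_fcs", threshold=0.05, threshold_on="adj_p"),
    }


@dataclass
class GSAResult:
    """Per-gene-set results table plus the threshold convention applied.

    ``table`` is indexed by set name with columns ``size``, ``statistic``,
    ``nes``, ``pval``, ``adj_pval``, ``significant``.
    """

    table: pd.DataFrame
    method: str
    threshold: float
    threshold_on: str

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="set")


def enrichment_score(ranked: pd.Series, set_members: Iterable[str], p_w: int = 0) -> float:
    """Weighted Kolmogorov–Smirnov enrichment score of one set.

    Walking down the ranked list, member genes ("hits") increment a running
    sum by |metric|^p_w normalized over hits, non-members decrement it by
    1/(N - N_hit); the ES is the signed maximum deviation from zero.
    """
    if p_w not in (0, 1):
        raise ValueError("p_w must be 0 or 1")
    genes = ranked.index.to_numpy()
    members = set(set_members)
    hits = np.isin(genes, list(members))
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("set has no gene in the ranked list")
    if n_hit == len(genes):
        raise ValueError("set covers the entire ranked list (miss denominator zero)")
    weights = np.abs(ranked.to_numpy(dtype=float)) ** p_w
    return float(_es_batch(weights, hits[None, :])[0])


def _es_batch(weights: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Enrichment scores for a (sets x positions) membership matrix.

    ``weights`` are |metric|^p_w in ranked order.  Sets whose hit weights
    sum to zero (all member metrics exactly zero under p_w=1) fall back to
    equal hit weights for that set.
    """
    member = member.astype(bool)
    n = member.shape[1]
    hit_w = member * weights[None, :]
    denom = hit_w.sum(axis=1)
    zero = denom <= 0
    if zero.any():
        hit_w[zero] = member[zero].astype(float)
        denom[zero] = member[zero].sum(axis=1)
    p_hit = np.cumsum(hit_w / denom[:, None], axis=1)
    n_miss = n - member.sum(axis=1)
    p_miss = np.cumsum((~member) / n_miss[:, None], axis=1)
    dev = p_hit - p_miss
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


def resolve_universe(
    option: str,
    measured_genes: Sequence[str],
    filtered_genes: Sequence[str] | None,
    db: GeneSetDatabase,
) -> set[str]:
    """Background gene population an ORA test conditions on.

    ``all_measured`` = every gene in the (deduplicated) count matrix;
    ``post_filter`` = genes surviving prefiltering; ``all_annotated`` =
    measured genes appearing in at least one database set.
    """
    measured = set(measured_genes)
    if option == "all_measured":
        return measured
    if option == "post_filter":
        if filtered_genes is None:
            raise ValueError("post_filter universe requires the filtered gene list")
        return set(filtered_genes)
    if option == "all_annotated":
        return measured & db.all_genes()
    raise ValueError(f"unknown universe option {option!r}")


def ora_test(
    de_genes: Iterable[str],
    db: GeneSetDatabase,
    universe: Iterable[str],
    *,
    min_set_size: int = 5,
    max_set_size: int = 500,
    threshold: float = 0.05,
    threshold_on: str = "adj_p",
) -> GSAResult:
    """Hypergeometric overrepresentation test of a DE gene list.

    For each set, the raw p-value is the upper-tail probability of drawing
    at least the observed overlap when |DE| genes are sampled without
    replacement from the universe.  DE genes outside the universe are
    ignored; sets with empty intersection with the universe are skipped
    with a note, as are sets outside the size bounds.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de = set(de_genes) & universe
    m_univ, n_de = len(universe), len(de)
    rows = []
    for name, members in db.sets.items():
        in_univ = set(members) & universe
        k_set = len(in_univ)
        if k_set == 0:
            logger.info("ora_test: set %r does not intersect the universe; skipped", name)
            continue
        if not (min_set_size <= k_set <= max_set_size):
            continue
        k = len(in_univ & de)
        p = float(hypergeom.sf(k - 1, m_univ, k_set, n_de))
        expected = k_set * n_de / m_univ
        fold = k / expected if expected > 0 else 0.0
        rows.append((name, k_set, fold, p))
    if not rows:
        raise PipelineError("gsa", "set-size bounds exclude every gene set")
    table = pd.DataFrame(rows, columns=["set", "size", "statistic", "pval"]).set_index("set")
    table["nes"] = np.nan
    table["adj_pval"] = bh_adjust(table["pval"])
    table["significant"] = table["adj_pval"] < threshold
    table = table[["size", "statistic", "nes", "pval", "adj_pval", "significant"]]
    return GSAResult(table=table, method="ora", threshold=threshold, threshold_on=threshold_on)


def _membership_matrix(
    genes: Sequence[str], db: GeneSetDatabase, min_size: int, max_size: int
) -> tuple[list[str], np.ndarray]:
    pos = {g: i for i, g in enumerate(genes)}
    names, rows = [], []
    for name, members in db.sets.items():
        idx = [pos[g] for g in members if g in pos]
        if not (min_size <= len(idx) <= max_size):
            continue
        row = np.zeros(len(genes), dtype=bool)
        row[idx] = True
        names.append(name)
        rows.append(row)
    if not names:
        raise PipelineError("gsa", "set-size bounds exclude every gene set")
    return names, np.vstack(rows)


def _permutation_table(
    names: list[str],
    sizes: np.ndarray,
    es_obs: np.ndarray,
    es_null: np.ndarray,
    spec: MethodSpec,
    method: str,
) -> GSAResult:
    """NES, permutation p-values and BH adjustment shared by the FCS paths.

    NES divides each ES by the mean of same-sign null ES; p-values use the
    pseudocount estimator (1 + b)/(1 + B) counting same-sign nulls at least
    as extreme, so they are never exactly zero.
    """
    n_perm = es_null.shape[0]
    nes = np.full(es_obs.shape, np.nan)
    pvals = np.ones(es_obs.shape)
    for s, es in enumerate(es_obs):
        if es == 0:
            continue
        same_sign = es_null[:, s] * np.sign(es) > 0
        if not same_sign.any():
            logger.info("no same-sign null ES for set %r; p set to 1", names[s])
            continue
        null_vals = es_null[same_sign, s]
        b = int(np.sum(np.abs(null_vals) >= abs(es)))
        pvals[s] = (1 + b) / (1 + n_perm)
        nes[s] = es / abs(null_vals.mean())
    adj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "size": sizes,
            "statistic": es_obs,
            "nes": nes,
            "pval": pvals,
            "adj_pval": adj,
            "significant": adj < spec.threshold,
        },
        index=pd.Index(names, name="set"),
    )
    return GSAResult(
        table=table, method=method, threshold=spec.threshold, threshold_on=spec.threshold_on
    )


def _permuted_assignment(labels: LabelAssignment, rng: np.random.Generator, b: int) -> LabelAssignment:
    return LabelAssignment(
        sample_ids=labels.sample_ids,
        labels=tuple(rng.permutation(np.array(labels.labels, dtype=object))),
        reference=labels.reference,
        origin=b + 1,
    )


def gsea_sample_perm(
    expr: pd.DataFrame,
    labels: LabelAssignment,
    db: GeneSetDatabase,
    spec: MethodSpec,
    seed: int,
    *,
    de_option: str = "welch_t",
    metric_option: str = "statistic",
) -> GSAResult:
    """GSEA with a sample-label-permutation null.

    The gene ranking (DE scoring + ranking metric) is regenerated for every
    permutation, so inter-gene correlation present in the data is carried
    into the null distribution — the property that keeps this variant
    calibrated where the gene-permutation null is not.
    """
    if spec.n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    de = de_score(expr, labels, de_option)
    ranked = make_ranked_list(de, metric_option)
    gene_list = list(expr.index)
    names, member = _membership_matrix(gene_list, db, spec.min_set_size, spec.max_set_size)
    sizes = member.sum(axis=1)

    pos = {g: i for i, g in enumerate(gene_list)}
    order_obs = np.array([pos[g] for g in ranked.index])
    weights_obs = np.abs(ranked.to_numpy(dtype=float)) ** spec.p_w
    es_obs = _es_batch(weights_obs, member[:, order_obs])

    es_null = np.empty((spec.n_permutations, len(names)))
    for b in range(spec.n_permutations):
        la = _permuted_assignment(labels, rng, b)
        de_b = de_score(expr, la, de_option)
        ranked_b = make_ranked_list(de_b, metric_option)
        order_b = np.array([pos[g] for g in ranked_b.index])
        weights_b = np.abs(ranked_b.to_numpy(dtype=float)) ** spec.p_w
        es_null[b] = _es_batch(weights_b, member[:, order_b])
    return _permutation_table(names, sizes, es_obs, es_null, spec, "gsea_sample_perm")


def gsea_preranked(
    ranked: pd.Series, db: GeneSetDatabase, spec: MethodSpec, seed: int
) -> GSAResult:
    """Preranked GSEA: fixed ranked list, gene-permutation null.

    The null shuffles set membership over the list positions while the
    metric profile stays fixed — implicitly assuming independent genes.
    """
    if spec.n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    gene_list = list(ranked.index)
    names, member = _membership_matrix(gene_list, db, spec.min_set_size, spec.max_set_size)
    sizes = member.sum(axis=1)
    weights = np.abs(ranked.to_numpy(dtype=float)) ** spec.p_w
    es_obs = _es_batch(weights, member)
    n = len(gene_list)
    es_null = np.empty((spec.n_permutations, len(names)))
    for b in range(spec.n_permutations):
        perm = rng.permutation(n)
        es_null[b] = _es_batch(weights, member[:, perm])
    return _permutation_table(names, sizes, es_obs, es_null, spec, "gsea_preranked")


def _set_frequency_weights(genes: Sequence[str], db: GeneSetDatabase) -> np.ndarray:
    """Gene weights 1 + sqrt((f_max - f_g)/(f_max - f_min)).

    ``f_g`` counts the database sets containing gene ``g``; genes in many
    sets are down-weighted, promoting set-specific genes.  All weights are
    1 when every gene has the same frequency.
    """
    freq = np.zeros(len(genes))
    pos = {g: i for i, g in enumerate(genes)}
    for members in db.sets.values():
        for g in members:
            if g in pos:
                freq[pos[g]] += 1
    f_min, f_max = freq.min(), freq.max()
    if f_max == f_min:
        return np.ones(len(genes))
    return 1.0 + np.sqrt((f_max - freq) / (f_max - f_min))


def weighted_fcs(
    expr: pd.DataFrame,
    labels: LabelAssignment,
    db: GeneSetDatabase,
    spec: MethodSpec,
    seed: int,
) -> GSAResult:
    """Frequency-weighted FCS (PADOG-style) with a sample-permutation null.

    Set score = weighted mean of |moderated t| over member genes; the
    reported statistic is the score standardized against the null.
    """
    if spec.n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    gene_list = list(expr.index)
    names, member = _membership_matrix(gene_list, db, spec.min_set_size, spec.max_set_size)
    sizes = member.sum(axis=1)
    w = _set_frequency_weights(gene_list, db)
    w_member = member * w[None, :]
    w_sums = w_member.sum(axis=1)

    def scores(assignment: LabelAssignment) -> np.ndarray:
        t_abs = np.abs(de_score(expr, assignment, "moderated_t")["statistic"].to_numpy())
        return w_member @ t_abs / w_sums

    obs = scores(labels)
    null = np.empty((spec.n_permutations, len(names)))
    for b in range(spec.n_permutations):
        null[b] = scores(_permuted_assignment(labels, rng, b))
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    z = (obs - mu) / np.maximum(sd, 1e-12)
    b_counts = (null >= obs[None, :]).sum(axis=0)
    pvals = (1 + b_counts) / (1 + spec.n_permutations)
    adj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "size": sizes,
            "statistic": z,
            "nes": np.nan,
            "pval": pvals,
            "adj_pval": adj,
            "significant": adj < spec.threshold,
        },
        index=pd.Index(names, name="set"),
    )
    return GSAResult(
        table=table, method="weighted_fcs", threshold=spec.threshold, threshold_on=spec.threshold_on
    )


def count_degs(result: GSAResult) -> int:
    """Number of differentially enriched gene sets at the result's threshold."""
    return int(result.table["significant"].sum())


def relative_rank(result: GSAResult, target_set: str) -> float:
    """Dense rank of the target set by adjusted p, divided by the max rank.

    Sets sharing an adjusted p-value share a rank, so an adjusted p of 1
    always yields a relative rank of exactly 1.
    """
    if target_set not in result.table.index:
        raise KeyError(f"target set {target_set!r} absent from the results table")
    ranks = result.table["adj_pval"].rank(method="dense", ascending=True)
    return float(ranks.loc[target_set] / ranks.max())


# ---------------------------------------------------------------------------
# sklearn-style facades


class ORA(BaseEstimator):
    """Overrepresentation analysis as a fit-shaped estimator.

    ``fit(X, y)`` takes the expression matrix and labels, derives the DE
    gene list internally (BH-adjusted DE p < ``de_alpha``), and stores the
    per-set table in ``results_``.
    """

    def __init__(
        self,
        db: GeneSetDatabase = None,
        universe: str = "all_measured",
        de_option: str = "welch_t",
        de_alpha: float = 0.05,
        threshold: float = 0.05,
        min_set_size: int = 5,
        max_set_size: int = 500,
    ):
        self.db = db
        self.universe = universe
        self.de_option = de_option
        self.de_alpha = de_alpha
        self.threshold = threshold
        self.min_set_size = min_set_size
        self.max_set_size = max_set_size

    def fit(self, X: pd.DataFrame, y: LabelAssignment):
        if self.db is None:
            raise ValueError("a GeneSetDatabase is required")
        de = de_score(X, y, self.de_option)
        de_genes = set(de.index[de["adj_pval"] < self.de_alpha])
        universe = resolve_universe(self.universe, list(X.index), None, self.db)
        self.de_genes_ = de_genes
        self.results_ = ora_test(
            de_genes,
            self.db,
            universe,
            min_set_size=self.min_set_size,
            max_set_size=self.max_set_size,
            threshold=self.threshold,
        )
        return self


class GSEA(BaseEstimator):
    """Enrichment-score GSA with a configurable null (``"sample"``/``"gene"``)."""

    def __init__(
        self,
        db: GeneSetDatabase = None,
        null: str = "sample",
        p_w: int = 1,
        de_option: str = "welch_t",
        metric_option: str = "statistic",
        threshold: float = 0.05,
        n_permutations: int = 200,
        min_set_size: int = 5,
        max_set_size: int = 500,
        seed: int = 0,
    ):
        self.db = db
        self.null = null
        self.p_w = p_w
        self.de_option = de_option
        self.metric_option = metric_option
        self.threshold = threshold
        self.n_permutations = n_permutations
        self.min_set_size = min_set_size
        self.max_set_size = max_set_size
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: LabelAssignment):
        if self.db is None:
            raise ValueError("a GeneSetDatabase is required")
        archetype = "gsea_sample_perm" if self.null == "sample" else "gsea_preranked"
        spec = MethodSpec(
            archetype=archetype,
            threshold=self.threshold,
            p_w=self.p_w,
            n_permutations=self.n_permutations,
            min_set_size=self.min_set_size,
            max_set_size=self.max_set_size,
        )
        if self.null == "sample":
            self.results_ = gsea_sample_perm(
                X, y, self.db, spec, self.seed,
                de_option=self.de_option, metric_option=self.metric_option,
            )
        else:
            ranked = make_ranked_list(de_score(X, y, self.de_option), self.metric_option)
            self.results_ = gsea_preranked(ranked, self.db, spec, self.seed)
        return self


class WeightedFCS(BaseEstimator):
    """Frequency-weighted FCS facade over :func:`weighted_fcs`."""

    def __init__(
        self,
        db: GeneSetDatabase = None,
        threshold: float = 0.05,
        n_permutations: int = 200,
        min_set_size: int = 5,
        max_set_size: int = 500,
        seed: int = 0,
    ):
        self.db = db
        self.threshold = threshold
        self.n_permutations = n_permutations
        self.min_set_size = min_set_size
        self.max_set_size = max_set_size
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: LabelAssignment):
        if self.db is None:
            raise ValueError("a GeneSetDatabase is required")
        spec = MethodSpec(
            archetype="weighted_fcs",
            threshold=self.threshold,
            n_permutations=self.n_permutations,
            min_set_size=self.min_set_size,
            max_set_size=self.max_set_size,
        )
        self.results_ = weighted_fcs(X, y, self.db, spec, self.seed)
        return self
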