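"""Synthetic RNA-seq data with the dependence structure that matters for GSA.

Everything downstream of this module (preprocessing choices, the GSA
archetypes, the stepwise optimizer) is exercised on data produced here, so
the generator reproduces the statistical features the study's conclusions
hinge on:

* negative-binomial counts with library-size variation,
* block-wise gene–gene correlation, induced by a latent per-block Gaussian
  factor shared across genes of a block (so gene-permutation nulls are
  miscalibrated while sample-permutation nulls remain exact),
* many-to-one gene-ID conversion tables producing duplicated target IDs,
* gene set databases with controlled overlap between consecutive sets,
* optional true enrichment signal in designated sets,
* random sample-label permutations that preserve group sizes.

All distributional choices are synthetic stand-ins: the original study was
run on real benchmark expression data sets, and no generative model is
implied by it.  See ``docs/methods.md`` for what the generator does and does
not emulate.

Counts are plain :class:`pandas.DataFrame` objects (rows = genes, columns =
samples); labels, databases and ID tables are small frozen dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalSet",
    "SimulationSpec",
    "LabelAssignment",
    "GeneSetDatabase",
    "IdConversionTable",
    "SyntheticStudy",
    "simulate_counts",
    "true_labels",
    "permute_labels",
    "simulate_database",
    "block_database",
    "simulate_id_table",
    "make_study_data",
]

# Child-seed offsets: each artifact (counts, database, permutations, ID
# table) gets an independently reproducible stream derived from one master
# seed.  Knuth multiplicative constant keeps the children well separated.
_SEED_COUNTS = 0
_SEED_DATABASE = 1
_SEED_PERMUTATIONS = 2
_SEED_IDTABLE = 3


def child_seed(master: int, offset: int) -> int:
    """Deterministic child seed below 2**31 derived from a master seed."""
    return (int(master) + (offset + 1) * 2654435761) % (2**31)


@dataclass(frozen=True)
class SignalSet:
    """A named gene set carrying true differential signal.

    ``log2_effect`` is the between-group difference of log2 mean expression
    for every member gene (group 1 up by half the effect, group 2 down by
    half).  ``genes`` may be empty when the membership is to be resolved
    later against a generated database (see :func:`make_study_data`).
    """

    name: str
    log2_effect: float
    genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the negative-binomial count generator.

    Attributes
    ----------
    n_genes : number of genes (rows).
    samples_per_group : sizes of the two condition groups.
    nb_mean_log_range : natural-log range of per-gene mean expression;
        means are drawn log-uniformly in this range.
    nb_dispersion : common NB dispersion alpha (variance = mu + alpha*mu^2);
        0 degenerates to Poisson.
    correlation_block_size : genes per correlation block.
    within_block_correlation : latent-factor correlation rho in [0, 1)
        between genes of the same block.
    latent_sd : standard deviation of the latent log-mean perturbation; the
        perturbation is mean-corrected so expected counts are unchanged.
    library_size_factor_range : per-sample depth factors, log-uniform.
    signal_sets : sets of genes with true between-group signal.
    seed : master seed; identical spec implies identical output.
    """

    n_genes: int
    samples_per_group: tuple[int, int]
    nb_mean_log_range: tuple[float, float] = (0.7, 6.5)
    nb_dispersion: float = 0.2
    correlation_block_size: int = 50
    within_block_correlation: float = 0.0
    latent_sd: float = 0.8
    library_size_factor_range: tuple[float, float] = (0.7, 1.3)
    signal_sets: tuple[SignalSet, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        n1, n2 = self.samples_per_group
        if n1 <= 0 or n2 <= 0:
            raise ValueError("both groups need at least one sample")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError("within_block_correlation must lie in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.correlation_block_size <= 0:
            raise ValueError("correlation_block_size must be positive")
        for s in self.signal_sets:
            if not math.isfinite(s.log2_effect):
                raise ValueError(f"non-finite effect size for set {s.name!r}")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_group)

    def gene_ids(self) -> list[str]:
        width = max(5, len(str(self.n_genes)))
        return [f"gene{i + 1:0{width}d}" for i in range(self.n_genes)]

    def sample_ids(self) -> list[str]:
        return [f"sample{j + 1:03d}" for j in range(self.n_samples)]


@dataclass(frozen=True)
class LabelAssignment:
    """Two-level condition labels, either the true ones or a permutation.

    ``origin`` is ``"true"`` for the original assignment or the 1-based
    permutation index.  ``reference`` names the level treated as the
    reference group (positive DE statistics = higher in reference).
    """

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    reference: str
    origin: str | int = "true"

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        levels = set(self.labels)
        if len(levels) != 2:
            raise ValueError(f"expected exactly two levels, got {sorted(levels)}")
        if self.reference not in levels:
            raise ValueError(f"reference level {self.reference!r} absent")

    @property
    def levels(self) -> tuple[str, str]:
        other = next(l for l in self.labels if l != self.reference)
        return (self.reference, other)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the sample belongs to the reference."""
        return np.array([l == self.reference for l in self.labels])

    def group_sizes(self) -> tuple[int, int]:
        m = self.mask()
        return int(m.sum()), int((~m).sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.sample_ids), name="condition")


@dataclass(frozen=True)
class GeneSetDatabase:
    """A named collection of gene sets (GMT-shaped)."""

    name: str
    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {set_name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate gene IDs inside set {set_name!r}")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


@dataclass(frozen=True)
class IdConversionTable:
    """Many-to-one mapping from source gene IDs to target gene IDs."""

    mapping: dict[str, str]

    def targets(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def duplicated_targets(self) -> list[str]:
        counts = pd.Series(list(self.mapping.values())).value_counts()
        return sorted(counts.index[counts >= 2])


def simulate_counts(spec: SimulationSpec) -> pd.DataFrame:
    """Draw a gene x sample count matrix under the generative model.

    Gene ``g`` in sample ``j`` is NB with mean
    ``libsize_j * mu_g * 2^(+-effect/2) * exp(sd*eta - sd^2/2)`` where the
    latent ``eta`` is standard normal with correlation ``rho`` between genes
    of the same block and independence across blocks.  Deterministic for a
    fixed spec.
    """
    rng = np.random.default_rng(child_seed(spec.seed, _SEED_COUNTS))
    g, n = spec.n_genes, spec.n_samples
    n1, _ = spec.samples_per_group

    log_lo, log_hi = spec.nb_mean_log_range
    base_mean = np.exp(rng.uniform(log_lo, log_hi, size=g))

    lo, hi = spec.library_size_factor_range
    if not (0 < lo <= hi):
        raise ValueError("library_size_factor_range must be positive and ordered")
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    rho = spec.within_block_correlation
    sd = spec.latent_sd
    block_of = np.arange(g) // spec.correlation_block_size
    n_blocks = int(block_of[-1]) + 1
    block_factor = rng.standard_normal((n_blocks, n))
    gene_noise = rng.standard_normal((g, n))
    eta = math.sqrt(rho) * block_factor[block_of] + math.sqrt(1.0 - rho) * gene_noise

    mean = base_mean[:, None] * np.exp(sd * eta - 0.5 * sd * sd) * lib[None, :]

    gene_ids = spec.gene_ids()
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    group2 = np.arange(n) >= n1
    for sig in spec.signal_sets:
        idx = [gene_pos[gid] for gid in sig.genes if gid in gene_pos]
        if not idx:
            continue
        up = 2.0 ** (sig.log2_effect / 2.0)
        mean[np.ix_(idx, np.where(~group2)[0])] *= up
        mean[np.ix_(idx, np.where(group2)[0])] /= up

    if spec.nb_dispersion > 0:
        r = 1.0 / spec.nb_dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)

    return pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=spec.sample_ids())


def true_labels(spec: SimulationSpec, levels: tuple[str, str] = ("cond1", "cond2")) -> LabelAssignment:
    """The true group assignment implied by ``samples_per_group``."""
    n1, n2 = spec.samples_per_group
    labels = (levels[0],) * n1 + (levels[1],) * n2
    return LabelAssignment(
        sample_ids=tuple(spec.sample_ids()), labels=labels, reference=levels[0], origin="true"
    )


def permute_labels(truth: LabelAssignment, n_permutations: int, seed: int) -> list[LabelAssignment]:
    """Uniformly random permutations of the label vector, group sizes kept."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(child_seed(seed, _SEED_PERMUTATIONS))
    labels = np.array(truth.labels, dtype=object)
    out = []
    for i in range(n_permutations):
        perm = rng.permutation(labels)
        out.append(
            LabelAssignment(
                sample_ids=truth.sample_ids,
                labels=tuple(perm),
                reference=truth.reference,
                origin=i + 1,
            )
        )
    return out


def simulate_database(
    n_sets: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    overlap_fraction: float = 0.0,
    seed: int = 0,
    name: str = "synthetic_db",
) -> GeneSetDatabase:
    """Random gene sets with a controlled overlap between consecutive sets.

    Set ``i`` shares ``round(overlap_fraction * size_i)`` genes with set
    ``i-1`` and draws the remainder from the universe excluding set ``i-1``
    entirely, so consecutive intersections have exactly the stated size.
    """
    lo, hi = size_range
    universe = list(universe)
    if not 0 < lo <= hi:
        raise ValueError("size_range must be positive and ordered")
    if hi > len(universe):
        raise ValueError("size_range exceeds universe size")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(child_seed(seed, _SEED_DATABASE))
    sets: dict[str, tuple[str, ...]] = {}
    prev: list[str] = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        n_shared = min(int(round(overlap_fraction * size)), len(prev))
        shared = list(rng.choice(prev, size=n_shared, replace=False)) if n_shared else []
        pool = [gid for gid in universe if gid not in set(prev)]
        n_rest = size - n_shared
        if n_rest > len(pool):
            raise ValueError("universe too small for the requested set sizes and overlap")
        rest = list(rng.choice(pool, size=n_rest, replace=False))
        members = shared + rest
        sets[f"set{i + 1:04d}"] = tuple(members)
        prev = members
    return GeneSetDatabase(name=name, sets=sets)


def block_database(
    spec: SimulationSpec,
    n_sets: int,
    id_table: IdConversionTable | None = None,
    name: str = "block_db",
) -> GeneSetDatabase:
    """Gene sets aligned with the generator's correlation blocks.

    Set ``i`` consists of the genes of correlation block ``i`` (translated
    through ``id_table`` when the analysis works on converted IDs).  With
    ``within_block_correlation > 0`` these sets consist of mutually
    correlated genes — the configuration under which gene-permutation nulls
    are known to be miscalibrated.
    """
    gene_ids = spec.gene_ids()
    bs = spec.correlation_block_size
    n_blocks = math.ceil(len(gene_ids) / bs)
    if n_sets > n_blocks:
        raise ValueError(f"only {n_blocks} blocks available, {n_sets} sets requested")
    sets: dict[str, tuple[str, ...]] = {}
    for i in range(n_sets):
        members = gene_ids[i * bs : (i + 1) * bs]
        if id_table is not None:
            seen: dict[str, None] = {}
            for gid in members:
                tgt = id_table.mapping.get(gid)
                if tgt is not None:
                    seen.setdefault(tgt, None)
            members = list(seen)
        sets[f"set{i + 1:04d}"] = tuple(members)
    return GeneSetDatabase(name=name, sets=sets)


def simulate_id_table(
    gene_ids: Sequence[str], duplicate_fraction: float = 0.0, seed: int = 0
) -> IdConversionTable:
    """Many-to-one ID conversion table over the given source IDs.

    ``duplicate_fraction`` is the fraction of *target* IDs that receive two
    source IDs; the remaining targets are hit by exactly one source.  With
    fraction 0 the mapping is a bijection.
    """
    if not 0.0 <= duplicate_fraction < 1.0:
        raise ValueError("duplicate_fraction must lie in [0, 1)")
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    rng = np.random.default_rng(child_seed(seed, _SEED_IDTABLE))
    n_targets = int(round(n / (1.0 + duplicate_fraction)))
    n_targets = max(1, min(n, n_targets))
    n_dup = n - n_targets  # duplicated targets absorb one extra source each
    order = rng.permutation(n)
    width = max(5, len(str(n_targets)))
    target_ids = [f"tgt{i + 1:0{width}d}" for i in range(n_targets)]
    mapping: dict[str, str] = {}
    pos = 0
    for t in range(n_dup):
        mapping[gene_ids[order[pos]]] = target_ids[t]
        mapping[gene_ids[order[pos + 1]]] = target_ids[t]
        pos += 2
    for t in range(n_dup, n_targets):
        mapping[gene_ids[order[pos]]] = target_ids[t]
        pos += 1
    return IdConversionTable(mapping=mapping)


@dataclass(frozen=True)
class SyntheticStudy:
    """One fully wired synthetic data set: counts + labels + databases + IDs."""

    counts: pd.DataFrame
    labels: LabelAssignment
    databases: dict[str, GeneSetDatabase]
    id_table: IdConversionTable | None
    spec: SimulationSpec


def make_study_data(
    spec: SimulationSpec,
    *,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 60),
    overlap_fraction: float = 0.2,
    duplicate_fraction: float = 0.0,
    n_databases: int = 1,
    block_aligned: bool = False,
) -> SyntheticStudy:
    """Generate a coherent study data set.

    The gene set databases live on the *target* ID space of the conversion
    table (the space the analysis works in after duplicate removal), and
    signal sets named in ``spec.signal_sets`` without explicit members are
    resolved against the first database, translated back to source IDs, and
    injected into the count model.
    """
    gene_ids = spec.gene_ids()
    id_table = (
        simulate_id_table(gene_ids, duplicate_fraction, seed=spec.seed)
        if duplicate_fraction > 0
        else None
    )
    if id_table is not None:
        universe = id_table.targets()
        sources_of: dict[str, list[str]] = {}
        for src, tgt in id_table.mapping.items():
            sources_of.setdefault(tgt, []).append(src)
    else:
        universe = gene_ids
        sources_of = {gid: [gid] for gid in gene_ids}

    databases: dict[str, GeneSetDatabase] = {}
    for k in range(n_databases):
        db_name = f"db{k + 1}"
        if block_aligned and k == 0:
            db = block_database(spec, n_sets, id_table, name=db_name)
        else:
            db = simulate_database(
                n_sets,
                set_size_range,
                universe,
                overlap_fraction=overlap_fraction,
                seed=child_seed(spec.seed, 100 + k),
                name=db_name,
            )
        databases[db_name] = db

    primary = next(iter(databases.values()))
    resolved: list[SignalSet] = []
    for sig in spec.signal_sets:
        genes = sig.genes
        if not genes:
            members = primary.sets.get(sig.name)
            if members is None:
                raise ValueError(f"signal set {sig.name!r} not found in {primary.name}")
            genes = tuple(src for tgt in members for src in sources_of.get(tgt, []))
        resolved.append(SignalSet(sig.name, sig.log2_effect, genes))
    counts = simulate_counts(replace(spec, signal_sets=tuple(resolved)))
    return SyntheticStudy(
        counts=counts,
        labels=true_labels(spec),
        databases=databases,
        id_table=id_table,
        spec=spec,
    )
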