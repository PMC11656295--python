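"""GSA archetypes and shared statistics: ES, ORA, BH, ranks, permutation nulls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gsamultiverse as gm
from gsamultiverse.gsa import (
    MethodSpec,
    _set_frequency_weights,
    count_degs,
    enrichment_score,
    gsea_preranked,
    gsea_sample_perm,
    ora_test,
    relative_rank,
    resolve_universe,
    weighted_fcs,
)
from gsamultiverse.preprocessing import de_score, make_ranked_list, transform_counts

from conftest import make_gsa_result


def ranked_series(metrics, genes=None) -> pd.Series:
    genes = genes or [f"g{i}" for i in range(len(metrics))]
    return pd.Series(np.asarray(metrics, dtype=float), index=genes, name="metric")


class TestEnrichmentScore:
    def test_top_gene_set_scores_one(self):
        ranked = ranked_series([3.0, 2.0, 1.0, 0.5])
        assert enrichment_score(ranked, {"g0"}, p_w=0) == pytest.approx(1.0)

    def test_bottom_gene_set_scores_minus_one(self):
        ranked = ranked_series([3.0, 2.0, 1.0, 0.5])
        assert enrichment_score(ranked, {"g3"}, p_w=0) == pytest.approx(-1.0)

    def test_uniform_interleaving_gives_small_magnitude(self):
        n, hits = 40, {f"g{i}" for i in range(0, 40, 4)}
        ranked = ranked_series(np.linspace(3, -3, n))
        assert abs(enrichment_score(ranked, hits, p_w=0)) < 0.25

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_unweighted_es_ignores_metric_magnitudes(self, scale):
        ranked = ranked_series([5.0, 4.0, 1.0, -2.0, -6.0])
        base = enrichment_score(ranked, {"g1", "g3"}, p_w=0)
        scaled = enrichment_score(ranked * scale, {"g1", "g3"}, p_w=0)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_weighted_es_depends_on_magnitudes(self):
        ranked = ranked_series([5.0, 4.0, 1.0, -2.0, -6.0])
        boosted = ranked.copy()
        boosted.iloc[0] = 50.0
        assert enrichment_score(ranked, {"g0", "g2"}, p_w=1) != pytest.approx(
            enrichment_score(boosted, {"g0", "g2"}, p_w=1)
        )

    def test_degenerate_sets_rejected(self):
        ranked = ranked_series([1.0, 0.5])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"g0", "g1"}, p_w=0)  # covers whole list
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"absent"}, p_w=0)


class TestBHAdjust:
    def test_step_up_example(self):
        assert np.allclose(gm.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert gm.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        assert np.allclose(gm.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gm.bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        out = gm.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_monotone_in_input_order(self, pvals):
        adj = gm.bh_adjust(pvals)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestORA:
    universe = [f"g{i}" for i in range(20)]
    db = gm.GeneSetDatabase(
        "toy",
        {
            "overlap4": ("g0", "g1", "g2", "g3", "g10"),
            "whole": tuple(f"g{i}" for i in range(20)),
        },
    )

    def test_hypergeometric_upper_tail(self):
        de = {f"g{i}" for i in range(5)}
        result = ora_test(de, self.db, self.universe, min_set_size=1, max_set_size=50)
        # C(5,4)C(15,1) + C(5,5) over C(20,5), confirmed by exhaustive enumeration.
        assert result.table.loc["overlap4", "pval"] == pytest.approx(76 / 15504, abs=1e-12)

    def test_empty_de_list_gives_unit_pvalues(self):
        result = ora_test(set(), self.db, self.universe, min_set_size=1, max_set_size=50)
        assert (result.table["pval"] == 1.0).all()
        assert count_degs(result) == 0

    def test_set_equal_to_universe_has_unit_p(self):
        result = ora_test(
            {"g0", "g1"}, self.db, self.universe, min_set_size=1, max_set_size=50
        )
        assert result.table.loc["whole", "pval"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_test({"g0"}, self.db, [], min_set_size=1)

    def test_nonintersecting_sets_skipped(self):
        db = gm.GeneSetDatabase("d", {"in": ("g0", "g1"), "out": ("x1", "x2")})
        result = ora_test({"g0"}, db, self.universe, min_set_size=1)
        assert "out" not in result.table.index

    def test_universe_resolution(self):
        measured = ["g0", "g1", "g2", "x9"]
        db = gm.GeneSetDatabase("d", {"s": ("g0", "g2", "far")})
        assert resolve_universe("all_measured", measured, None, db) == set(measured)
        assert resolve_universe("all_annotated", measured, None, db) == {"g0", "g2"}
        assert resolve_universe("post_filter", measured, ["g0"], db) == {"g0"}


def study_inputs(seed=0, rho=0.0, signal=False, n_genes=600, n_sets=12):
    sets = (gm.SignalSet("set0001", 2.0),) if signal else ()
    spec = gm.SimulationSpec(
        n_genes=n_genes,
        samples_per_group=(8, 8),
        within_block_correlation=rho,
        correlation_block_size=50,
        signal_sets=sets,
        seed=seed,
    )
    study = gm.make_study_data(
        spec, n_sets=n_sets, set_size_range=(20, 40), n_databases=1,
        block_aligned=rho > 0,
    )
    expr = transform_counts(study.counts, "log2_cpm:0.5")
    return study, expr


class TestGseaArchetypes:
    spec100 = MethodSpec(archetype="gsea_sample_perm", n_permutations=100)

    def test_sample_perm_deterministic_under_seed(self):
        study, expr = study_inputs(seed=3)
        a = gsea_sample_perm(expr, study.labels, study.databases["db1"], self.spec100, seed=7)
        b = gsea_sample_perm(expr, study.labels, study.databases["db1"], self.spec100, seed=7)
        assert a.table.equals(b.table)

    def test_preranked_deterministic_under_seed(self):
        study, expr = study_inputs(seed=3)
        ranked = make_ranked_list(de_score(expr, study.labels, "welch_t"))
        spec = MethodSpec(archetype="gsea_preranked", n_permutations=100)
        a = gsea_preranked(ranked, study.databases["db1"], spec, seed=7)
        b = gsea_preranked(ranked, study.databases["db1"], spec, seed=7)
        assert a.table.equals(b.table)

    def test_permutation_pvalues_never_zero_nor_above_one(self):
        study, expr = study_inputs(seed=5, signal=True)
        res = gsea_sample_perm(expr, study.labels, study.databases["db1"], self.spec100, seed=1)
        assert (res.table["pval"] > 0).all()
        assert (res.table["pval"] <= 1).all()

    def test_signal_set_detected_by_sample_perm_gsea(self):
        study, expr = study_inputs(seed=11, signal=True)
        res = gsea_sample_perm(expr, study.labels, study.databases["db1"], self.spec100, seed=2)
        assert res.table["adj_pval"].idxmin() == "set0001"
        assert res.table.loc["set0001", "nes"] > 0

    def test_too_few_permutations_rejected(self):
        study, expr = study_inputs(seed=3)
        spec = MethodSpec(archetype="gsea_sample_perm", n_permutations=50)
        with pytest.raises(ValueError):
            gsea_sample_perm(expr, study.labels, study.databases["db1"], spec, seed=0)

    def test_nes_sign_matches_es_sign(self):
        study, expr = study_inputs(seed=9)
        res = gsea_sample_perm(expr, study.labels, study.databases["db1"], self.spec100, seed=3)
        t = res.table.dropna(subset=["nes"])
        assert (np.sign(t["nes"]) == np.sign(t["statistic"])).all()


class TestWeightedFCS:
    def test_uniform_frequency_gives_unit_weights(self):
        db = gm.GeneSetDatabase("d", {"a": ("g0", "g1"), "b": ("g2", "g3")})
        w = _set_frequency_weights(["g0", "g1", "g2", "g3"], db)
        assert np.allclose(w, 1.0)

    def test_weight_formula_extremes(self):
        sets = {f"s{i}": ("hub", f"g{i}") for i in range(5)}
        db = gm.GeneSetDatabase("d", sets)
        w = _set_frequency_weights(["hub", "g0"], db)
        # hub appears in 5 sets (weight 1), g0 in one set (weight 2).
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(2.0)

    def test_runs_and_is_deterministic(self):
        study, expr = study_inputs(seed=4)
        spec = MethodSpec(archetype="weighted_fcs", n_permutations=100)
        a = weighted_fcs(expr, study.labels, study.databases["db1"], spec, seed=5)
        b = weighted_fcs(expr, study.labels, study.databases["db1"], spec, seed=5)
        assert a.table.equals(b.table)
        assert (a.table["pval"] > 0).all() and (a.table["pval"] <= 1).all()

    def test_signal_set_scores_highest(self):
        study, expr = study_inputs(seed=12, signal=True)
        spec = MethodSpec(archetype="weighted_fcs", n_permutations=100)
        res = weighted_fcs(expr, study.labels, study.databases["db1"], spec, seed=5)
        assert res.table["statistic"].idxmax() == "set0001"


class TestCountDegs:
    def test_all_unit_adjusted_p_counts_zero(self):
        assert count_degs(make_gsa_result([1.0, 1.0, 1.0])) == 0

    def test_bh_convention(self):
        assert count_degs(make_gsa_result([0.01, 0.2, 0.9], threshold=0.05)) == 1

    def test_q_value_convention(self):
        result = make_gsa_result([0.19, 0.26], threshold=0.25, threshold_on="q")
        assert count_degs(result) == 1


class TestRelativeRank:
    def test_unit_adjusted_p_gives_unit_rank(self):
        result = make_gsa_result([0.2, 1.0, 0.4])
        assert relative_rank(result, "set0002") == 1.0

    def test_dense_rank_of_best_set(self):
        result = make_gsa_result([0.01, 0.5, 1.0])
        assert relative_rank(result, "set0001") == pytest.approx(1 / 3)

    def test_all_tied_sets_share_unit_rank(self):
        result = make_gsa_result([0.7, 0.7, 0.7, 0.7])
        for name in result.table.index:
            assert relative_rank(result, name) == 1.0

    def test_absent_target_is_an_error(self):
        with pytest.raises(KeyError, match="nosuch"):
            relative_rank(make_gsa_result([0.5]), "nosuch")


class TestEstimatorFacades:
    def test_ora_estimator(self, small_study):
        from gsamultiverse.preprocessing import deduplicate

        counts = deduplicate(small_study.counts, small_study.id_table, "keep_first")
        est = gm.ORA(db=small_study.databases["db1"], min_set_size=2)
        est.fit(transform_counts(counts, "log2_cpm:0.5"), small_study.labels)
        assert {"pval", "adj_pval", "significant"} <= set(est.results_.table.columns)

    def test_gsea_estimator_params_roundtrip(self):
        est = gm.GSEA(null="gene", p_w=0, n_permutations=150)
        params = est.get_params()
        assert params["null"] == "gene" and params["p_w"] == 0
        est.set_params(p_w=1)
        assert est.p_w == 1
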