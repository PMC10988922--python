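import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import insituanno as ia
from insituanno.errors import ValidationError


def _catalog(rows):
    return ia.MarkerCatalog(pd.DataFrame(rows, columns=["gene", "claimed_type", "source"]))


@pytest.fixture(scope="module")
def small_analysis(small_dataset):
    sim, est = ia.analyze(
        small_dataset.cells,
        small_dataset.references,
        small_dataset.truth.marker_catalog(),
    )
    cells = ia.normalize(small_dataset.cells, "logcpm")
    return cells, sim, est


class TestSecondRoundCorrelations:
    def test_output_shape(self, small_dataset, small_analysis):
        _, _, est = small_analysis
        n_markers = len(small_dataset.truth.marker_table)
        n_refs = small_dataset.references.n_samples
        assert est.correlations_.shape == (n_markers, n_refs + 2)  # + gene, source

    def test_marker_equal_to_similarity_column_scores_one(self, small_analysis):
        cells, sim, _ = small_analysis
        ref0 = sim.data.columns[0]
        spiked = cells.values.copy()
        spiked.loc["fake_marker"] = sim.data[ref0].to_numpy()
        cat = _catalog([("fake_marker", "fiber", "demo")])
        est = ia.MarkerConcordance(method="pearson").fit(
            ia.GeneExpressionMatrix(spiked, cells.layer), sim, cat
        )
        assert est.correlations_.loc[0, ref0] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_entries_match_bruteforce_oracle(self, method):
        """Every (marker, reference) entry equals a direct scipy evaluation."""
        ds = ia.simulate_dataset(
            n_genes=120, markers_per_type=4, cells_per_type=17, seed=13
        )
        sim, _ = ia.analyze(ds.cells, ds.references, ds.truth.marker_catalog())
        cells = ia.normalize(ds.cells, "logcpm")
        cat = ds.truth.marker_catalog()
        r = ia.second_round_correlations(sim, cells, cat, method=method)
        oracle = sps.pearsonr if method == "pearson" else sps.spearmanr
        for i, gene in enumerate(cat.genes):
            expr = cells.values.loc[gene].to_numpy()
            for ref in sim.data.columns:
                expected = oracle(expr, sim.data[ref].to_numpy())[0]
                assert r.loc[i, ref] == pytest.approx(expected, abs=1e-10)

    def test_missing_genes_skipped_not_fatal(self, small_analysis):
        cells, sim, _ = small_analysis
        cat = _catalog([
            ("not_a_gene", "fiber", "demo"),
            (cells.gene_ids[0], "fiber", "demo"),
        ])
        est = ia.MarkerConcordance().fit(cells, sim, cat)
        assert list(est.skipped_["gene"]) == ["not_a_gene"]
        assert list(est.skipped_["reason"]) == ["missing"]
        assert len(est.calls_) == 1

    def test_constant_marker_excluded_from_tests(self, small_analysis):
        cells, sim, _ = small_analysis
        flat = cells.values.copy()
        flat.loc["flatgene"] = 3.0
        cat = _catalog([("flatgene", "ray", "demo")])
        est = ia.MarkerConcordance().fit(
            ia.GeneExpressionMatrix(flat, cells.layer), sim, cat
        )
        assert list(est.skipped_["reason"]) == ["constant"]
        assert len(est.calls_) == 0

    def test_cell_id_mismatch_rejected(self, small_analysis):
        cells, sim, _ = small_analysis
        shuffled = ia.GeneExpressionMatrix(
            cells.values.iloc[:, ::-1], cells.layer
        )
        with pytest.raises(ValidationError, match="identical cell ids"):
            ia.MarkerConcordance().fit(shuffled, sim, _catalog([]))

    def test_unknown_claimed_type_rejected(self, small_analysis):
        cells, sim, _ = small_analysis
        cat = _catalog([(cells.gene_ids[0], "phloem", "demo")])
        with pytest.raises(ValidationError, match="phloem"):
            ia.MarkerConcordance().fit(cells, sim, cat)


class TestCallMarkerType:
    def test_clearly_separated_marker_called_uniquely(self):
        call = ia.call_marker_type(
            {
                "fiber": np.array([0.8, 0.82, 0.78]),
                "vessel": np.array([0.1, 0.05, 0.12]),
                "ray": np.array([0.0, -0.02, 0.03]),
            },
            alpha=0.05,
        )
        assert call.status == "unique" and call.call == "fiber"
        # oracle: both pairwise scipy t-tests are well below alpha
        assert sps.ttest_ind([0.8, 0.82, 0.78], [0.1, 0.05, 0.12]).pvalue < 0.05
        assert sps.ttest_ind([0.8, 0.82, 0.78], [0.0, -0.02, 0.03]).pvalue < 0.05

    def test_identical_groups_are_ambiguous(self):
        v = np.array([0.5, 0.6, 0.55])
        call = ia.call_marker_type({"fiber": v, "vessel": v, "ray": v})
        assert call.status == "ambiguous"
        assert set(call.call_set) == {"fiber", "vessel", "ray"}

    def test_nonpositive_maximum_is_no_call(self):
        call = ia.call_marker_type(
            {"fiber": np.array([-0.2, -0.1]), "vessel": np.array([-0.4, -0.5])}
        )
        assert call.status == "none" and call.call_set == ()

    def test_mean_tie_declares_ambiguity(self):
        call = ia.call_marker_type(
            {"fiber": np.array([0.4, 0.6]), "vessel": np.array([0.6, 0.4]),
             "ray": np.array([-0.5, -0.6])}
        )
        assert call.status == "ambiguous"
        assert "fiber" in call.call_set and "vessel" in call.call_set

    def test_validation(self):
        with pytest.raises(ValidationError, match="2 cell types"):
            ia.call_marker_type({"fiber": np.array([0.1, 0.2])})
        with pytest.raises(ValidationError, match="replicate"):
            ia.call_marker_type({"fiber": np.array([0.1]), "ray": np.array([0.1, 0.2])})

    def test_pooled_comparison_mode(self):
        groups = {
            "fiber": np.array([0.8, 0.82, 0.78]),
            "vessel": np.array([0.1, 0.05, 0.12]),
            "ray": np.array([0.0, -0.02, 0.03]),
        }
        call = ia.call_marker_type(groups, comparison="pooled")
        assert call.status == "unique" and call.call == "fiber"


class TestEvaluateCatalog:
    def test_all_consistent_summary(self, study_analysis):
        _, est = study_analysis
        summary = ia.evaluate_catalog(est.result_)
        row = summary.iloc[0]
        assert row["n_markers"] == 60
        assert row["consistent"] == 60
        assert (row[["inconsistent", "ambiguous", "none", "skipped"]] == 0).all()

    def test_mislabeled_markers_flagged_inconsistent(self, study_dataset):
        """5 true markers + 5 markers claimed for the wrong type: the wrong
        claims must be exposed as inconsistent unique calls."""
        ds = study_dataset
        wrong = {"fiber": "vessel", "vessel": "ray", "ray": "fiber"}
        table = ds.truth.marker_catalog().table.iloc[:10].reset_index(drop=True)
        table.loc[5:, "claimed_type"] = table.loc[5:, "claimed_type"].map(wrong)
        _, est = ia.analyze(ds.cells, ds.references, ia.MarkerCatalog(table))
        calls = est.calls_
        assert calls.loc[:4, "consistent"].all()
        assert not calls.loc[5:, "consistent"].any()
        summary = est.summary_
        assert summary.iloc[0]["consistent"] == 5
        assert summary.iloc[0]["inconsistent"] == 5

    def test_empty_catalog_gives_empty_summary(self, small_analysis):
        cells, sim, _ = small_analysis
        est = ia.MarkerConcordance().fit(cells, sim, _catalog([]))
        assert len(est.calls_) == 0
        assert len(est.summary_) == 0


class TestEstimatorOptions:
    def test_get_set_params_roundtrip(self):
        est = ia.MarkerConcordance(alpha=0.01, test="welch")
        params = est.get_params()
        assert params["alpha"] == 0.01 and params["test"] == "welch"
        est.set_params(alpha=0.1)
        assert est.alpha == 0.1

    def test_bh_column_reported_separately(self, small_analysis):
        cells, sim, _ = small_analysis
        cat = _catalog([(cells.gene_ids[i], "fiber", "demo") for i in range(5)])
        est = ia.MarkerConcordance(bh=True).fit(cells, sim, cat)
        assert "p_bh" in est.tests_.columns
        assert (est.tests_["p_bh"] >= est.tests_["p"] - 1e-12).all()

    def test_welch_variant_runs(self, small_analysis):
        cells, sim, _ = small_analysis
        cat = _catalog([(cells.gene_ids[0], "fiber", "demo")])
        est = ia.MarkerConcordance(test="welch").fit(cells, sim, cat)
        assert len(est.tests_) == 2

    def test_averaged_replicate_mode_recovers_planted_markers(self, study_dataset):
        ds = study_dataset
        _, est = ia.analyze(
            ds.cells, ds.references, ds.truth.marker_catalog(),
            replicate_mode="averaged",
        )
        assert len(est.tests_) == 0  # no replicate groups, no t-tests
        assert est.calls_["consistent"].all()
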