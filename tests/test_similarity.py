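import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

import insituanno as ia
from insituanno.errors import ValidationError


class TestCorrelation:
    def test_self_correlation_is_one(self):
        assert ia.correlation([1, 2, 3], [1, 2, 3], "pearson") == pytest.approx(1.0)
        assert ia.correlation([1, 2, 3], [1, 2, 3], "spearman") == pytest.approx(1.0)

    def test_exact_reversal_is_minus_one(self):
        assert ia.correlation([1, 2, 3], [3, 2, 1], "pearson") == pytest.approx(-1.0)

    def test_hand_computed_pearson_half(self):
        # cov = 1, sd*sd = 2 -> r = 0.5
        assert ia.correlation([1, 2, 3], [1, 3, 2], "pearson") == pytest.approx(0.5)

    def test_constant_vector_gives_undefined_signal(self):
        assert np.isnan(ia.correlation([1, 1, 1], [1, 2, 3], "pearson"))

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            ia.correlation([1, 2], [1, 2], "pearson")
        with pytest.raises(ValidationError):
            ia.correlation([1, 2, 3], [1, 2], "pearson")
        with pytest.raises(ValidationError):
            ia.correlation([1, 2, 3], [1, 2, 3], "kendall")

    @pytest.mark.parametrize("method,oracle", [
        ("pearson", lambda x, y: sps.pearsonr(x, y)[0]),
        ("spearman", lambda x, y: sps.spearmanr(x, y)[0]),
    ])
    def test_matches_scipy_on_random_vectors(self, method, oracle):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.normal(size=30)
            y = rng.poisson(3.0, size=30).astype(float)  # ties for mid-ranks
            assert ia.correlation(x, y, method) == pytest.approx(
                oracle(x, y), abs=1e-10
            )

    @settings(deadline=None, max_examples=40)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)),
            min_size=4, max_size=30,
        ),
        scale=st.floats(0.1, 5.0),
        shift=st.floats(-10.0, 10.0),
    )
    def test_spearman_invariant_under_monotone_transform(self, data, scale, shift):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        base = ia.correlation(x, y, "spearman")
        transformed = ia.correlation(np.exp(scale * x / 50.0) + shift, y, "spearman")
        assert transformed == pytest.approx(base, abs=1e-12)


@pytest.fixture(scope="module")
def normalized(small_dataset):
    cells = ia.normalize(small_dataset.cells, "logcpm")
    refs = small_dataset.references.with_matrix(
        ia.normalize(small_dataset.references.matrix, "logcpm")
    )
    return cells, refs


class TestCellSimilarityScorer:
    def test_table_shape_and_bounds(self, normalized):
        cells, refs = normalized
        sim = ia.compute_cell_similarity(cells, refs)
        assert sim.data.shape == (cells.n_samples, refs.n_samples)
        arr = sim.data.to_numpy()
        assert np.nanmin(arr) >= -1.0 and np.nanmax(arr) <= 1.0
        assert sim.n_genes_used == cells.n_genes

    def test_cell_equal_to_reference_scores_one(self, normalized):
        cells, refs = normalized
        spiked = cells.values.copy()
        spiked["clone"] = refs.matrix.values.iloc[:, 0]
        sim = ia.compute_cell_similarity(
            ia.GeneExpressionMatrix(spiked, cells.layer), refs
        )
        assert sim.data.loc["clone"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_every_entry_matches_bruteforce_oracle(self, method):
        rng = np.random.default_rng(1)
        cells = ia.GeneExpressionMatrix(
            pd.DataFrame(
                rng.random((20, 10)) * 100,
                index=[f"g{i}" for i in range(20)],
                columns=[f"c{i}" for i in range(10)],
            ),
            layer="linear",
        )
        refs_values = pd.DataFrame(
            rng.random((20, 4)) * 100,
            index=cells.gene_ids,
            columns=["fiber_r1", "fiber_r2", "vessel_r1", "vessel_r2"],
        )
        meta = pd.DataFrame(
            {"cell_type": ["fiber", "fiber", "vessel", "vessel"],
             "replicate": [1, 2, 1, 2]},
            index=refs_values.columns,
        )
        refs = ia.LcmReferenceSet(
            ia.GeneExpressionMatrix(refs_values, "linear"), meta
        )
        sim = ia.compute_cell_similarity(cells, refs, method=method, min_shared_genes=10)
        oracle = sps.pearsonr if method == "pearson" else sps.spearmanr
        for cell in cells.sample_ids:
            for ref in refs_values.columns:
                # ids are sorted lexicographically during alignment
                x = cells.values.sort_index()[cell]
                y = refs_values.sort_index()[ref]
                assert sim.data.loc[cell, ref] == pytest.approx(
                    oracle(x, y)[0], abs=1e-10
                )

    def test_constant_cell_reported_missing_not_zero(self, normalized):
        cells, refs = normalized
        flat = cells.values.copy()
        flat["flat"] = 1.0
        sim = ia.compute_cell_similarity(
            ia.GeneExpressionMatrix(flat, cells.layer), refs
        )
        assert sim.data.loc["flat"].isna().all()

    def test_layer_mismatch_rejected(self, small_dataset, normalized):
        _, refs = normalized
        with pytest.raises(ValidationError, match="layer"):
            ia.compute_cell_similarity(small_dataset.cells, refs)

    def test_min_shared_genes_enforced(self, normalized):
        cells, refs = normalized
        with pytest.raises(ValidationError, match="shared genes"):
            ia.compute_cell_similarity(cells, refs, min_shared_genes=10**6)

    def test_gene_subset_restricts_computation(self, normalized):
        cells, refs = normalized
        subset = cells.gene_ids[:120]
        sim = ia.compute_cell_similarity(cells, refs, gene_subset=subset,
                                         min_shared_genes=50)
        assert sim.n_genes_used == 120

    def test_estimator_contract(self, normalized):
        cells, refs = normalized
        scorer = ia.CellSimilarityScorer(method="pearson", min_shared_genes=10)
        assert scorer.get_params()["method"] == "pearson"
        cloned = clone(scorer)
        with pytest.raises(NotFittedError):
            cloned.transform(cells)
        table = cloned.set_params(method="spearman").fit(refs).transform(cells)
        assert table.method == "spearman"

    def test_cells_rank_their_own_type_highest(self):
        """Mean first-round similarity of type-T cells peaks at type-T references
        whenever a clear planted effect exists (checked over seeds 1-5)."""
        for seed in range(1, 6):
            ds = ia.simulate_dataset(
                n_genes=800, cells_per_type=100, log2_fold_change=3.0, seed=seed
            )
            sim, _ = ia.analyze(ds.cells, ds.references, ds.truth.marker_catalog())
            by_type = sim.mean_by_type()
            for ctype in ds.truth.type_names:
                means = by_type.loc[ds.cell_labels == ctype].mean()
                assert means.idxmax() == ctype, f"seed {seed}, type {ctype}"

    def test_table_tsv_round_trip(self, normalized, tmp_path):
        cells, refs = normalized
        sim = ia.compute_cell_similarity(cells, refs)
        path = tmp_path / "similarity.tsv"
        sim.to_tsv(path)
        back = ia.CellSimilarityTable.from_tsv(path)
        np.testing.assert_allclose(back.data.to_numpy(), sim.data.to_numpy())
        assert list(back.ref_meta["cell_type"]) == list(sim.ref_meta["cell_type"])
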