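import numpy as np
import pandas as pd
import pytest

from conftest import make_study
from xmeta.manifest_io import ValidationError
from xmeta.preprocess import (
    collapse_probes,
    common_genes,
    knn_impute,
    log2_transform,
    preprocess_collection,
    qc_rle,
    quantile_normalize,
    standardize_genes,
)


def df(values, columns=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=columns or [f"s{j}" for j in range(values.shape[1])],
    )


class TestLog2Transform:
    def test_elementwise_log2(self):
        st_ = make_study([[8, 1], [2, 4]], ["MCAO", "sham"], is_log2=False)
        out = log2_transform(st_)
        np.testing.assert_allclose(out.values.to_numpy(), [[3, 0], [1, 2]])
        assert out.is_log2

    def test_already_log_is_identity(self):
        st_ = make_study([[8, 1], [2, 4]], ["MCAO", "sham"], is_log2=True)
        assert log2_transform(st_) is st_

    def test_nonpositive_value_names_cell(self):
        st_ = make_study([[8, -1], [2, 4]], ["MCAO", "sham"], is_log2=False)
        with pytest.raises(ValidationError, match="G1"):
            log2_transform(st_)

    def test_missing_preserved(self):
        st_ = make_study([[8, np.nan], [2, 4]], ["MCAO", "sham"], is_log2=False)
        out = log2_transform(st_)
        assert np.isnan(out.values.iloc[0, 1])


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        x = df(np.column_stack([[2, 4, 6], [1, 3, 5]]))
        out = quantile_normalize(x)
        expected = np.column_stack([[1.5, 3.5, 5.5]] * 2)
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_identical_columns_fixed_point(self):
        x = df(np.column_stack([[1, 5, 9]] * 3))
        np.testing.assert_allclose(quantile_normalize(x).to_numpy(), x.to_numpy())

    def test_ties_get_mean_of_tied_reference_values(self):
        # sorted columns: (1,1,2) and (0,2,4) -> reference (0.5, 1.5, 3.0);
        # the tied 1s share mean(0.5, 1.5) = 1.0
        x = df(np.column_stack([[1, 1, 2], [0, 2, 4]]))
        out = quantile_normalize(x)
        np.testing.assert_allclose(out.iloc[:, 0].to_numpy(), [1.0, 1.0, 3.0])
        np.testing.assert_allclose(out.iloc[:, 1].to_numpy(), [0.5, 1.5, 3.0])

    def test_single_column_noop(self):
        x = df([[3.0], [1.0]])
        pd.testing.assert_frame_equal(quantile_normalize(x), x)

    def test_columns_share_one_distribution(self):
        rng = np.random.default_rng(0)
        x = df(rng.normal(size=(50, 4)) * [1, 2, 3, 4] + [0, 1, 2, 3])
        out = quantile_normalize(x).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)
        # within-column rank order preserved
        for j in range(4):
            assert (np.argsort(out[:, j]) == np.argsort(x.to_numpy()[:, j])).all()


class TestKnnImpute:
    def test_identical_complete_neighbors(self):
        x = df([[1, np.nan, 3], [1, 5, 3], [1, 5, 3]])
        out = knn_impute(x, k=2)
        assert out.iloc[0, 1] == 5.0

    def test_no_missing_is_identity(self):
        x = df([[1, 2], [3, 4]])
        pd.testing.assert_frame_equal(knn_impute(x, k=2), x)

    def test_nearest_neighbor_wins_at_k1(self):
        x = df([[1, np.nan, 3], [1, 7, 3], [9, 9, 9]])
        out = knn_impute(x, k=1)
        assert out.iloc[0, 1] == 7.0  # distance-0 neighbor, not the far one

    def test_observed_entries_bit_identical(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 6))
        mask = rng.random(values.shape) < 0.1
        values[mask] = np.nan
        x = df(values)
        out = knn_impute(x, k=5)
        obs = ~np.isnan(values)
        assert (out.to_numpy()[obs] == values[obs]).all()
        assert not np.isnan(out.to_numpy()).any()

    def test_fully_missing_row_rejected(self):
        x = df([[np.nan, np.nan], [1, 2]])
        with pytest.raises(ValidationError):
            knn_impute(x, k=1)

    def test_small_pool_warns_and_uses_all(self):
        x = df([[1, np.nan, 3], [1, 4, 3]])
        with pytest.warns(UserWarning, match="fewer than k"):
            out = knn_impute(x, k=10)
        assert out.iloc[0, 1] == 4.0


class TestCollapseProbes:
    def test_mean_of_probes(self):
        st_ = make_study([[1, 1], [3, 3], [2, 5]], ["MCAO", "sham"], level="probe")
        pmap = {"G1": "GENEA", "G2": "GENEA", "G3": "GENEB"}
        out = collapse_probes(st_, pmap)
        assert out.level == "gene"
        np.testing.assert_allclose(out.values.loc["GENEA"].to_numpy(), [2, 2])
        np.testing.assert_allclose(out.values.loc["GENEB"].to_numpy(), [2, 5])

    def test_three_probe_mean(self):
        st_ = make_study([[1, 0], [2, 0], [6, 0]], ["MCAO", "sham"], level="probe")
        out = collapse_probes(st_, {"G1": "X", "G2": "X", "G3": "X"})
        assert out.values.loc["X", "s1"] == 3.0

    def test_one_probe_per_gene_identity(self):
        st_ = make_study([[1.5, 2.5]], ["MCAO", "sham"], level="probe")
        out = collapse_probes(st_, {"G1": "X"})
        np.testing.assert_allclose(out.values.to_numpy(), [[1.5, 2.5]])

    def test_unmapped_probes_dropped_not_fatal(self):
        st_ = make_study([[1, 2], [3, 4]], ["MCAO", "sham"], level="probe")
        out = collapse_probes(st_, {"G1": "X"})
        assert list(out.values.index) == ["X"]


class TestStandardizeGenes:
    def test_hand_example(self):
        out = standardize_genes(df([[1, 2, 3]]))
        np.testing.assert_allclose(out.to_numpy(), [[-1, 0, 1]])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = df(rng.normal(size=(20, 5)))
        once = standardize_genes(x)
        twice = standardize_genes(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValidationError, match="g1"):
            standardize_genes(df([[1, 2, 3], [4, 4, 4]]))

    def test_moments(self):
        rng = np.random.default_rng(3)
        out = standardize_genes(df(rng.normal(size=(10, 8)))).to_numpy()
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.var(axis=1, ddof=1), 1, atol=1e-12)


class TestCommonGenes:
    def _study(self, genes, sid):
        from xmeta.manifest_io import StudyExpression

        samples = list("abcd")
        values = pd.DataFrame(np.ones((len(genes), 4)), index=genes, columns=samples)
        return StudyExpression(
            study_id=sid,
            values=values,
            groups=pd.Series(["MCAO", "MCAO", "sham", "sham"], index=samples),
            level="gene",
        )

    def test_intersection(self):
        studies = [self._study(g, f"S{i}") for i, g in
                   enumerate([["A", "B", "C"], ["B", "C", "D"], ["B", "C"]])]
        assert common_genes(studies) == ["B", "C"]

    def test_identical_sets(self):
        studies = [self._study(["A", "B"], f"S{i}") for i in range(3)]
        assert common_genes(studies) == ["A", "B"]

    def test_empty_intersection_rejected(self):
        studies = [self._study(["A"], "S1"), self._study(["B"], "S2")]
        with pytest.raises(ValidationError):
            common_genes(studies)

    def test_dropout_shrinks_intersection_binomially(self):
        from xmeta.synthetic_data import SimulationConfig, simulate_collection

        cfg = SimulationConfig(n_genes=2000, k_studies=4, frac_deg=0.0,
                               platform_dropout=0.1, missing_rate=0.0,
                               probes_per_gene=1, seed=13)
        studies, _ = simulate_collection(cfg)
        gene_level = [st.with_values(st.values, level="gene") for st in studies]
        n = len(common_genes(gene_level))
        p = 0.9**4
        sd = np.sqrt(2000 * p * (1 - p))
        assert abs(n - 2000 * p) < 3 * sd


class TestQcRle:
    def test_identical_columns_zero(self):
        x = df(np.column_stack([[1, 5, 9]] * 4))
        assert (qc_rle(x)["rle_median"] == 0).all()

    def test_shifted_column_detected(self):
        base = np.array([2.0, 4.0, 6.0, 8.0])
        x = df(np.column_stack([base, base, base + 1.0]))
        rle = qc_rle(x)
        # gene medians equal the unshifted values, so the shifted sample's
        # RLE is exactly +1 and the others 0
        np.testing.assert_allclose(rle["rle_median"].to_numpy(), [0, 0, 1])

    def test_single_gene_all_zero(self):
        x = df([[3, 3, 3]])
        assert (qc_rle(x)["rle_median"] == 0).all()


class TestFullChain:
    def test_permutation_equivariance_in_samples(self, small_collection):
        studies, truth = small_collection
        st_ = studies[0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(st_.values.shape[1])
        permuted = st_.with_values(st_.values.iloc[:, perm])

        out1, _ = preprocess_collection([st_], probe_map=truth.probe_map)
        out2, _ = preprocess_collection([permuted], probe_map=truth.probe_map)
        pd.testing.assert_frame_equal(
            out1[0].gene_values.iloc[:, perm], out2[0].gene_values
        )

    def test_chain_outputs_common_gene_matrices(self, small_preprocessed):
        preprocessed, genes, truth = small_preprocessed
        for ps in preprocessed:
            assert list(ps.gene_values.index) == genes
            assert not ps.gene_values.isna().any().any()
            np.testing.assert_allclose(
                ps.standardized.to_numpy().mean(axis=1), 0, atol=1e-10
            )
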