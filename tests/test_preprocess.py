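import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reaxpot.network import EnzymeDefinition
from reaxpot.preprocess import (
    PreprocessError,
    aggregate_enzyme_activity,
    filter_missing,
    impute_min,
    log_transform,
    pca_summary,
    quantile_normalize,
)

from .conftest import make_matrix


class TestFilterMissing:
    def test_half_missing_boundary(self):
        """With 6 samples, 3 missing values is kept (not 'more than half'),
        4 missing is removed."""
        m = make_matrix(
            [
                [1, 2, 3, np.nan, np.nan, np.nan],
                [1, 2, np.nan, np.nan, np.nan, np.nan],
                [1, 2, 3, 4, 5, 6],
            ],
            ["keep3", "drop4", "full"],
        )
        out = filter_missing(m)
        assert out.feature_ids == ["keep3", "full"]

    def test_all_removed_is_an_error(self):
        m = make_matrix([[np.nan, np.nan, np.nan, 1.0]], ["only"])
        with pytest.raises(PreprocessError):
            filter_missing(m)


class TestImputeMin:
    def test_per_feature_minimum(self, small_matrix):
        out = impute_min(small_matrix)
        assert out.data.loc["M1"].tolist() == [2.0, 4.0, 2.0, 8.0]
        assert out.data.loc["M2"].tolist() == [1.0, 1.0, 1.0, 1.0]
        # a minimum of zero propagates
        assert out.data.loc["M3"].tolist() == [0.0, 0.0, 5.0, 5.0]
        assert not out.data.isna().any().any()


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        col = [5.0, 1.0, 3.0, 2.0]
        m = make_matrix(np.column_stack([col] * 4), list("abcd"))
        out = quantile_normalize(m)
        assert np.allclose(out.data.to_numpy(), np.column_stack([col] * 4))
        assert out.state == "normalized"

    def test_mean_of_order_statistics(self):
        # two distinct column profiles, duplicated to satisfy the design
        m = make_matrix(
            [[1.0, 1.0, 4.0, 4.0], [2.0, 2.0, 5.0, 5.0], [3.0, 3.0, 6.0, 6.0]], list("abc")
        )
        out = quantile_normalize(m)
        expected = np.array([[2.5] * 4, [3.5] * 4, [4.5] * 4])
        assert np.allclose(out.data.to_numpy(), expected)

    def test_ties_get_mean_of_spanned_quantiles(self):
        m = make_matrix(
            [[1.0, 1.0, 10.0, 10.0], [1.0, 1.0, 20.0, 20.0], [5.0, 5.0, 30.0, 30.0]],
            list("abc"),
        )
        out = quantile_normalize(m)
        # first column reference: sorted means are (5.5, 10.5, 17.5);
        # the tied 1.0s span ranks 1-2 -> both get (5.5 + 10.5) / 2 = 8.0
        assert np.allclose(out.data["ref_1"].to_numpy(), [8.0, 8.0, 17.5])

    @given(
        st.lists(
            st.lists(st.floats(0, 1e6, allow_nan=False, width=32), min_size=5, max_size=5),
            min_size=4,
            max_size=4,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_columns_share_sorted_values_and_ranks_preserved(self, cols):
        values = np.array(cols, dtype=float).T  # 5 features x 4 samples
        m = make_matrix(values, [f"f{i}" for i in range(5)])
        out = quantile_normalize(m).data.to_numpy()
        ref = np.sort(values, axis=0).mean(axis=1)
        for j in range(out.shape[1]):
            if len(np.unique(values[:, j])) == values.shape[0]:
                # tie-free columns take exactly the reference distribution
                assert np.allclose(np.sort(out[:, j]), ref, atol=1e-9)
            # tie-averaging always preserves the column sum
            assert np.isclose(out[:, j].sum(), ref.sum(), atol=1e-6)
        # rank order within each sample is preserved (up to ties)
        for j in range(out.shape[1]):
            before, after = values[:, j], out[:, j]
            for a in range(5):
                for b in range(5):
                    if before[a] < before[b]:
                        assert after[a] <= after[b] + 1e-9


class TestLogTransform:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_pseudo_count_values(self, x, expected):
        m = make_matrix([[x] * 4], ["f"])
        assert log_transform(m).data.iloc[0, 0] == pytest.approx(expected)

    def test_negative_values_rejected(self):
        m = make_matrix([[-1.0, 1.0, 1.0, 1.0]], ["f"])
        with pytest.raises(PreprocessError):
            log_transform(m)

    def test_state_transitions_enforced(self, small_matrix):
        logged = log_transform(impute_min(small_matrix))
        with pytest.raises(PreprocessError):
            log_transform(logged)
        with pytest.raises(PreprocessError):
            quantile_normalize(logged)


class TestEnzymeAggregation:
    DEFS = {
        "complex": EnzymeDefinition("complex", (("G1", "G2"),)),
        "isoforms": EnzymeDefinition("isoforms", (("G3",), ("G4",))),
        "unmeasured": EnzymeDefinition("unmeasured", (("G9",),)),
        "partial": EnzymeDefinition("partial", (("G1",), ("G9",))),
    }

    def make_genes(self):
        return make_matrix(
            [[10.0] * 4, [4.0] * 4, [3.0] * 4, [5.0] * 4],
            ["G1", "G2", "G3", "G4"],
        )

    def test_min_over_subunits_and_sum_over_isoenzymes(self):
        out = aggregate_enzyme_activity(self.make_genes(), self.DEFS)
        assert out.data.loc["complex"].tolist() == [4.0] * 4  # min(10, 4)
        assert out.data.loc["isoforms"].tolist() == [8.0] * 4  # 3 + 5

    def test_unmeasured_handling(self):
        out = aggregate_enzyme_activity(self.make_genes(), self.DEFS)
        assert "unmeasured" not in out.data.index
        # isoenzymes with no measured subunit are skipped, not zeroed
        assert out.data.loc["partial"].tolist() == [10.0] * 4

    def test_empty_definitions_rejected(self):
        with pytest.raises(PreprocessError):
            aggregate_enzyme_activity(self.make_genes(), {})

    @given(st.lists(st.floats(0, 1e5, allow_nan=False), min_size=4, max_size=4))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_subunit_abundance(self, base):
        genes = make_matrix([base, [7.0] * 4], ["G1", "G2"])
        defs = {"e": EnzymeDefinition("e", (("G1", "G2"),))}
        lo = aggregate_enzyme_activity(genes, defs).data.loc["e"]
        bumped = make_matrix([[v + 1.0 for v in base], [7.0] * 4], ["G1", "G2"])
        hi = aggregate_enzyme_activity(bumped, defs).data.loc["e"]
        assert (hi >= lo - 1e-12).all()


class TestPCA:
    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(0)
        base = rng.gamma(2, 10, size=20)
        values = np.column_stack([base, base, base + rng.normal(0, 1, 20), base])
        m = make_matrix(values, [f"f{i}" for i in range(20)], state="raw")
        scores, evr = pca_summary(log_transform(m), top_fraction=1.0)
        assert np.allclose(scores.loc["ref_1", ["PC1", "PC2"]].astype(float),
                           scores.loc["ref_2", ["PC1", "PC2"]].astype(float))
        assert evr.sum() <= 1.0 + 1e-9

    def test_top_fraction_selects_most_variable(self):
        rng = np.random.default_rng(1)
        quiet = np.tile([[5.0, 5.0, 5.0, 5.0]], (8, 1))
        loud = rng.normal(50, 20, size=(2, 4)).clip(min=0)
        m = log_transform(make_matrix(np.vstack([quiet, loud]),
                                      [f"q{i}" for i in range(8)] + ["l0", "l1"]))
        full_scores, _ = pca_summary(m, top_fraction=1.0)
        top_scores, _ = pca_summary(m, top_fraction=0.2)  # ceil(0.2*10)=2 loud features
        assert top_scores.shape[0] == full_scores.shape[0]

    def test_too_small_inputs_rejected(self):
        m = log_transform(make_matrix([[1.0] * 4, [2.0] * 4], ["a", "b"]))
        with pytest.raises(PreprocessError):
            pca_summary(m)
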