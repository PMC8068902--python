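import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossclust.preprocess import (
    FilterSpec,
    add_pseudocount,
    clr_transform,
    data_loss_report,
    prevalence_filter,
    relative_abundance,
)
from crossclust.tables import CountTable, MetaboliteTable, ValidationError


def _count_table(rows, samples=None, features=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    features = features or [f"g{j}" for j in range(rows.shape[1])]
    return CountTable(pd.DataFrame(rows, index=samples, columns=features))


class TestRelativeAbundance:
    def test_simple_composition(self):
        rel = relative_abundance(_count_table([[2, 3, 5], [2, 3, 5]]))
        assert np.allclose(rel.iloc[0], [0.2, 0.3, 0.5])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        rel = relative_abundance(_count_table(rng.integers(1, 100, (5, 8))))
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_named(self):
        with pytest.raises(ValidationError, match="s1"):
            relative_abundance(_count_table([[1, 2], [0, 0]]))


class TestPrevalenceFilter:
    def _ten_samples(self, focal_counts):
        """10 samples, total 1000 each; focal feature plus a filler."""
        focal = np.asarray(focal_counts)
        filler = 1000 - focal
        return _count_table(np.column_stack([focal, filler]),
                            features=["focal", "filler"])

    def test_abundant_feature_kept(self):
        t = self._ten_samples([5] * 10)  # 0.5% everywhere
        filtered, report = prevalence_filter(t, FilterSpec(), "genera")
        assert "focal" in filtered.feature_ids
        assert report.n_features_kept + len(report.dropped_ids) == 2

    def test_boundary_prevalence_exactly_10pct_is_kept(self):
        # detected at exactly the 0.1% threshold in exactly 1 of 10 samples
        t = self._ten_samples([1] + [0] * 9)
        filtered, _ = prevalence_filter(t, FilterSpec(), "genera")
        assert "focal" in filtered.feature_ids

    def test_below_boundary_dropped(self):
        t = self._ten_samples([0] * 10)
        filtered, report = prevalence_filter(t, FilterSpec(), "genera")
        assert "focal" not in filtered.feature_ids
        assert "focal" in report.dropped_ids

    def test_all_zero_metabolite_dropped(self):
        m = MetaboliteTable(
            pd.DataFrame({"keep": [1.0] * 10, "zero": [0.0] * 10},
                         index=[f"s{i}" for i in range(10)])
        )
        filtered, report = prevalence_filter(m, FilterSpec(), "metabolites")
        assert filtered.feature_ids == ["keep"]
        assert report.dropped_ids == ["zero"]

    def test_filtering_never_rescales_kept_cells(self):
        rng = np.random.default_rng(2)
        t = _count_table(rng.integers(0, 50, (10, 6)))
        filtered, _ = prevalence_filter(t, FilterSpec(), "genera")
        pd.testing.assert_frame_equal(filtered.data, t.data[filtered.feature_ids])

    def test_sample_and_feature_order_invariance(self):
        rng = np.random.default_rng(3)
        t = _count_table(rng.integers(0, 30, (8, 5)))
        kept1, _ = prevalence_filter(t, FilterSpec(detection=0.05), "genera")
        shuffled = CountTable(t.data.sample(frac=1, axis=0, random_state=0)
                              .sample(frac=1, axis=1, random_state=1))
        kept2, _ = prevalence_filter(shuffled, FilterSpec(detection=0.05), "genera")
        assert set(kept1.feature_ids) == set(kept2.feature_ids)


class TestDataLoss:
    def test_nothing_dropped_zero_loss(self, small_counts):
        report = data_loss_report(small_counts, small_counts.feature_ids)
        assert np.allclose(report.data_loss, 0.0)

    def test_uniform_one_percent_feature(self):
        # dropped feature at exactly 1% relative abundance in every sample
        t = _count_table([[1, 99], [2, 198]], features=["drop", "keep"])
        report = data_loss_report(t, ["keep"])
        assert report.mean_data_loss == pytest.approx(0.01)

    def test_loss_is_one_minus_kept_sum(self):
        rng = np.random.default_rng(4)
        t = _count_table(rng.integers(1, 100, (6, 7)))
        kept = t.feature_ids[:4]
        report = data_loss_report(t, kept)
        rel = relative_abundance(t)
        assert np.allclose(report.data_loss, 1.0 - rel[kept].sum(axis=1))

    def test_phylum_shift_hand_computed(self):
        # phylum B is 40% of each sample; dropping it renormalizes A to 100%
        t = _count_table([[30, 30, 40], [20, 40, 40]], features=["a1", "a2", "b1"])
        tax = {"a1": "A", "a2": "A", "b1": "B"}
        report = data_loss_report(t, ["a1", "a2"], taxonomy=tax)
        assert report.phylum_shift_renormalized_pp["A"] == pytest.approx(40.0)
        assert report.phylum_shift_renormalized_pp["B"] == pytest.approx(-40.0)
        assert report.phylum_shift_raw_pp["A"] == pytest.approx(0.0)


class TestPseudocount:
    def test_hand_computed_shift(self):
        t = _count_table([[0, 9], [0, 9]])
        shifted, max_pp = add_pseudocount(t, 1.0)
        assert np.allclose(shifted.iloc[0], [1.0, 10.0])
        assert max_pp == pytest.approx(100.0 / 11.0, abs=1e-9)

    def test_large_counts_negligible_shift(self):
        t = _count_table(np.full((3, 4), 10**6))
        _, max_pp = add_pseudocount(t, 1.0)
        assert max_pp < 1e-4

    def test_positive_table_shifted_exactly(self):
        t = _count_table([[5, 7], [2, 3]])
        shifted, _ = add_pseudocount(t, 1.0)
        assert np.array_equal(shifted.to_numpy(), t.data.to_numpy() + 1.0)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            add_pseudocount(_count_table([[1, 2], [1, 2]]), 0.0)


class TestClr:
    def test_hand_computed_row(self):
        out = clr_transform(pd.DataFrame([[2.0, 4.0, 8.0]]))
        assert np.allclose(out.data.iloc[0], [-np.log(2), 0.0, np.log(2)])

    def test_constant_row_maps_to_zero(self):
        out = clr_transform(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert np.allclose(out.data.iloc[0], 0.0)

    def test_nonpositive_entry_located(self):
        df = pd.DataFrame([[1.0, 0.0]], index=["s"], columns=["x", "y"])
        with pytest.raises(ValidationError, match="y"):
            clr_transform(df)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=3, max_size=8),
            min_size=1,
            max_size=6,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1),
        st.floats(min_value=0.01, max_value=1000.0),
    )
    def test_zero_sum_and_scale_invariance(self, rows, lam):
        df = pd.DataFrame(rows, dtype=float)
        out = clr_transform(df)
        assert np.abs(out.data.sum(axis=1)).max() < 1e-8
        scaled = clr_transform(df * lam)
        assert np.allclose(out.data, scaled.data, atol=1e-8)
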