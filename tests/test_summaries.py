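from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from crossclust.summaries import (
    contrast_table,
    log2_fold_change,
    mann_whitney,
    stars,
    sum_genera_by_bicluster,
    sum_metabolites_by_bicluster,
)
from crossclust.tables import SampleDesign, ValidationError


def enumeration_oracle(a, b):
    """Brute-force exact Mann-Whitney: enumerate all group assignments.

    Returns (min(U_a, U_b), two-sided p) where p is the null probability
    of a U at least as extreme as the observed one on either side.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_of(indices):
        x = pooled[list(indices)]
        y = np.delete(pooled, list(indices))
        return sum(
            1.0 if xi > yj else (0.5 if xi == yj else 0.0) for xi in x for yj in y
        )

    u_obs = u_of(range(n_a))
    mn = n_a * len(b)
    lo, hi = min(u_obs, mn - u_obs), max(u_obs, mn - u_obs)
    us = [u_of(c) for c in combinations(range(len(pooled)), n_a)]
    p = sum(1 for u in us if u <= lo or u >= hi) / len(us)
    return min(u_obs, mn - u_obs), p


class TestBiclusterSums:
    def test_metabolite_sums_simple(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["s"], columns=list("wxyz"))
        sums = sum_metabolites_by_bicluster(df, [0, 0, 1, 1])
        assert list(sums.iloc[0]) == [3.0, 7.0]

    def test_sums_conserve_per_sample_total(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(size=(6, 9)))
        df.columns = [f"m{j}" for j in range(9)]
        labels = rng.integers(0, 3, 9)
        sums = sum_metabolites_by_bicluster(df, labels, k=3)
        assert np.allclose(sums.sum(axis=1), df.sum(axis=1))

    def test_feature_order_invariance(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["s"], columns=list("abc"))
        labels = [0, 1, 0]
        sums = sum_metabolites_by_bicluster(df, labels)
        perm = [2, 0, 1]
        sums_p = sum_metabolites_by_bicluster(df.iloc[:, perm], np.array(labels)[perm])
        pd.testing.assert_frame_equal(sums, sums_p)

    def test_label_out_of_range_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        with pytest.raises(ValidationError):
            sum_metabolites_by_bicluster(df, [0, 3], k=2)

    def test_genus_clr_of_sums_hand_computed(self):
        rel = pd.DataFrame([[0.2, 0.3, 0.5]], index=["s"], columns=list("abc"))
        out = sum_genera_by_bicluster(rel, [0, 1, 2])
        assert np.allclose(out.iloc[0], [-0.4406, -0.0351, 0.4757], atol=1e-4)
        assert abs(out.iloc[0].sum()) < 1e-8

    def test_equal_block_sums_are_zero(self):
        rel = pd.DataFrame([[0.25, 0.25, 0.25, 0.25]], columns=list("abcd"))
        out = sum_genera_by_bicluster(rel, [0, 0, 1, 1])
        assert np.allclose(out.to_numpy(), 0.0)

    def test_two_blocks_algebraic_identity(self):
        rel = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], columns=list("abcd"))
        out = sum_genera_by_bicluster(rel, [0, 0, 1, 1])
        s1, s2 = 0.3, 0.7
        assert out.iloc[0, 0] == pytest.approx(0.5 * np.log(s1 / s2))
        assert out.iloc[0, 1] == pytest.approx(-0.5 * np.log(s1 / s2))


def _design(n_per_group=3):
    rows = []
    for fat in ("HFD", "LFD"):
        for xos in ("no", "yes"):
            for i in range(n_per_group):
                rows.append((f"{fat}{xos}{i}", fat, xos))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "fat", "xos"]).set_index("sample_id")
    )


class TestLog2FoldChange:
    def test_ratio_of_means(self):
        d = _design()
        v = pd.Series(0.0, index=d.sample_ids)
        v.loc[d.samples_in_group("HFD")] = 8.0
        v.loc[d.samples_in_group("LFD")] = 2.0
        fc, eps = log2_fold_change(v, d, "HFD", "LFD")
        assert fc == pytest.approx(2.0) and not eps

    def test_equal_means_zero(self):
        d = _design()
        v = pd.Series(3.0, index=d.sample_ids)
        v.iloc[0] = 2.0
        v.iloc[-1] = 4.0  # keep groups' means equal but non-constant
        fc, _ = log2_fold_change(v, d, "HFD", "HFD")
        assert fc == pytest.approx(0.0)

    def test_antisymmetry(self):
        d = _design()
        rng = np.random.default_rng(1)
        v = pd.Series(rng.lognormal(size=len(d.sample_ids)), index=d.sample_ids)
        ab, _ = log2_fold_change(v, d, "HFD", "LFD")
        ba, _ = log2_fold_change(v, d, "LFD", "HFD")
        assert ab == pytest.approx(-ba)

    def test_zero_mean_uses_epsilon(self):
        d = _design()
        v = pd.Series(0.0, index=d.sample_ids)
        v.loc[d.samples_in_group("HFD")] = 4.0
        fc, eps = log2_fold_change(v, d, "HFD", "LFD")
        assert eps and fc == pytest.approx(np.log2(4.0 / 2.0))


class TestMannWhitney:
    def test_separated_groups_worked_example(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_interleaved_symmetric_example(self):
        u, p = mann_whitney([1, 4], [2, 3])
        assert u == 2 and p == pytest.approx(1.0)

    def test_identical_groups_p_near_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 4)
        u, p = mann_whitney(a, a)
        assert p > 0.9

    def test_exact_path_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(2)
        for n_a in range(1, 6):
            for n_b in range(1, 11 - n_a):
                for _ in range(3):
                    pool = rng.permutation(20)[: n_a + n_b].astype(float)
                    a, b = pool[:n_a], pool[n_a:]
                    u, p = mann_whitney(a, b)
                    u_ref, p_ref = enumeration_oracle(a, b)
                    assert u == u_ref
                    assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_and_normal_paths_agree_closely(self):
        rng = np.random.default_rng(3)
        from scipy import stats

        for _ in range(200):
            n_a, n_b = rng.integers(8, 11, 2)
            pool = rng.permutation(1000)[: n_a + n_b].astype(float)
            a, b = pool[:n_a], pool[n_a:]
            p_exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            p_norm = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - p_norm) <= 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestContrastTable:
    def test_stars_thresholds(self):
        assert stars(0.049) == "*" and stars(0.009) == "**" and stars(0.06) == ""

    def test_constant_feature(self):
        d = _design()
        df = pd.DataFrame({"flat": 1.0}, index=d.sample_ids)
        out = contrast_table(df, d, pairs=[("HFD", "LFD")])
        assert out.loc[0, "log2fc"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_planted_effect_power(self):
        # latent shift of 1.5 SD between groups, n=10/group
        rng = np.random.default_rng(4)
        d = _design(n_per_group=10)
        hits = 0
        reps = 100
        for _ in range(reps):
            v = pd.Series(rng.normal(size=len(d.sample_ids)), index=d.sample_ids)
            v.loc[d.samples_in_group("HFD")] += 1.5
            v = np.exp(v)  # abundance scale; ranks (and the test) unchanged
            out = contrast_table(v.to_frame("f"), d, pairs=[("HFD", "LFD")])
            hits += (out.loc[0, "p"] < 0.05) and (out.loc[0, "log2fc"] != 0)
        assert hits / reps >= 0.8

    def test_null_feature_star_rate_calibrated(self):
        rng = np.random.default_rng(5)
        d = _design(n_per_group=10)
        reps, hits = 400, 0
        for _ in range(reps):
            v = pd.Series(rng.normal(size=len(d.sample_ids)), index=d.sample_ids)
            out = contrast_table(v.to_frame("f"), d, pairs=[("HFD", "LFD")])
            hits += out.loc[0, "p"] < 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_missing_group_lists_available(self):
        d = _design()
        df = pd.DataFrame({"f": np.arange(len(d.sample_ids), dtype=float)},
                          index=d.sample_ids)
        with pytest.raises(ValidationError, match="available"):
            contrast_table(df, d, pairs=[("HFD", "MFD")])
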