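import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given, settings, strategies as st_

from nichefate.cohortstats import bh_adjust, cliffs_delta, dunn_posthoc, \
    filter_degs, holm_adjust, kruskal_wallis, roi_weighted_proportion, \
    spearman_bootstrap, tost_equivalence, wilcoxon_rank_sum
from nichefate.errors import ConfigError, ValidationError
from nichefate.nichescore import ClassificationResult, GCThresholdRule


# ---------------------------------------------------------------------------
# ROI-weighted donor proportions


def make_classification(flags_by_spot):
    s = pd.Series(flags_by_spot, name="gc_sensitive")
    s.index.name = "spot_id"
    return ClassificationResult(s, GCThresholdRule(), pd.Series(dtype=float))


def make_donor_table(spec):
    """spec: {roi: (n_flagged_fib, n_fib, n_other)} for one donor."""
    rows, flags = [], {}
    i = 0
    for roi, (nf, nfib, noth) in spec.items():
        for k in range(nfib + noth):
            sid = f"s{i}"
            rows.append({"spot_id": sid, "x_um": 0.0, "y_um": 0.0,
                         "donor": "d1", "roi": roi, "group": "G",
                         "stage": "none"})
            flags[sid] = k < nf
            i += 1
        labels_part = ["Fib_myo"] * nfib + ["Other"] * noth
        for sid, lab in zip([r["spot_id"] for r in rows[-(nfib + noth):]],
                            labels_part):
            flags.setdefault(sid, False)
    st = pd.DataFrame(rows)
    lab_vals = []
    for roi, (nf, nfib, noth) in spec.items():
        lab_vals += ["Fib_myo"] * nfib + ["Other"] * noth
    labels = pd.DataFrame({"label": lab_vals, "confidence": 1.0},
                          index=pd.Index(st["spot_id"], name="spot_id"))
    return st, labels, make_classification(flags)


class TestRoiWeightedProportion:
    def test_equal_weight_mean_over_rois(self):
        st, labels, cls = make_donor_table({
            "r1": (1, 10, 0), "r2": (3, 10, 0), "r3": (5, 10, 0)})
        out = roi_weighted_proportion(cls, st, labels, ["Fib_myo"],
                                      ["Fib_myo"])
        assert out["value"].iloc[0] == pytest.approx(0.3)
        assert out["n_rois"].iloc[0] == 3

    def test_identical_rois_give_that_proportion(self):
        st, labels, cls = make_donor_table({
            "r1": (2, 10, 5), "r2": (2, 10, 5)})
        out = roi_weighted_proportion(cls, st, labels, ["Fib_myo"],
                                      ["Fib_myo"])
        assert out["value"].iloc[0] == pytest.approx(0.2)

    def test_small_roi_excluded(self):
        st, labels, cls = make_donor_table({
            "r1": (5, 10, 0), "r2": (3, 3, 0)})     # r2 below min_spots
        out = roi_weighted_proportion(cls, st, labels, ["Fib_myo"],
                                      ["Fib_myo"], min_spots=10)
        assert out["value"].iloc[0] == pytest.approx(0.5)
        assert out.attrs["excluded_rois"] == ["r2"]

    def test_donor_without_eligible_roi_omitted(self):
        st, labels, cls = make_donor_table({"r1": (1, 3, 0)})
        out = roi_weighted_proportion(cls, st, labels, ["Fib_myo"],
                                      ["Fib_myo"], min_spots=10)
        assert out.empty
        assert out.attrs["omitted_donors"] == ["d1"]


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def oracle_exact_kw_p(groups):
    """Independent oracle: scipy H over every labelled partition."""
    vals = [np.asarray(v, float) for v in groups.values()]
    pooled = np.concatenate(vals)
    sizes = [len(v) for v in vals]
    h_obs = ss.kruskal(*vals).statistic
    count = total = 0
    idx = list(range(len(pooled)))

    def partitions(rem, szs):
        if len(szs) == 1:
            yield (tuple(rem),)
            return
        for combo in itertools.combinations(rem, szs[0]):
            rest = [i for i in rem if i not in set(combo)]
            for tail in partitions(rest, szs[1:]):
                yield (combo, *tail)

    for part in partitions(idx, sizes):
        perm_groups = [pooled[list(p)] for p in part]
        if ss.kruskal(*perm_groups).statistic >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis({"a": [1, 1, 1], "b": [1, 1, 1]})
        assert res.statistic == 0.0 and res.p == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = kruskal_wallis(groups)
        assert res.method == "exact_permutation"
        assert res.statistic == pytest.approx(
            ss.kruskal(*groups.values()).statistic, abs=1e-12)
        assert res.p == pytest.approx(oracle_exact_kw_p(groups), abs=0)

    def test_exact_p_with_ties_matches_oracle(self):
        groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0, 4.0],
                  "c": [4.0, 5.0, 5.0]}
        res = kruskal_wallis(groups)
        assert res.p == pytest.approx(oracle_exact_kw_p(groups), abs=0)

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(size=6) for g in "abc"}
        transformed = {g: np.exp(3 * v) for g, v in groups.items()}
        a = kruskal_wallis(groups, exact_max_n=0, perm_max_n=0)
        b = kruskal_wallis(transformed, exact_max_n=0, perm_max_n=0)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_single_donor_group_warns_not_errors(self, caplog):
        with caplog.at_level("WARNING", logger="nichefate.cohortstats"):
            res = kruskal_wallis({"a": [1.0], "b": [2.0, 3.0, 4.0]})
        assert res.extras["low_power"]

    def test_mc_permutation_used_at_donor_scale(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(size=n)
                  for g, n in zip("abcd", (5, 5, 6, 5))}
        res = kruskal_wallis(groups)
        assert res.method == "mc_permutation"
        assert "p_chi2" in res.extras


# ---------------------------------------------------------------------------
# Dunn post hoc


class TestDunn:
    def test_identical_groups_give_z_zero(self):
        res = dunn_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res[0].statistic == pytest.approx(0.0)
        assert res[0].p == pytest.approx(1.0)

    def test_hand_computed_z_on_fully_separated_ranks(self):
        # pooled ranks 1..9; mean ranks 2, 5, 8; no ties.
        # var_base = 9*10/12 = 7.5; se = sqrt(7.5 * 2/3) = sqrt(5)
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = {r.contrast: r for r in dunn_posthoc(groups)}
        z_ac = res[("a", "c")].statistic
        assert z_ac == pytest.approx((2 - 8) / np.sqrt(5.0), abs=1e-12)
        assert abs(z_ac) == max(abs(r.statistic) for r in res.values())

    def test_holm_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(loc=i, size=5)
                  for i, g in enumerate("abcd")}
        for r in dunn_posthoc(groups, adjust="holm"):
            assert r.p_adjusted >= r.p - 1e-15

    def test_bad_adjustment_rejected(self):
        with pytest.raises(ConfigError):
            dunn_posthoc({"a": [1], "b": [2]}, adjust="bonferroni")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum and Cliff's delta


class TestWilcoxon:
    def test_identical_multisets(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)       # nm/2
        assert res.p > 0.9

    def test_exact_enumeration_of_four_values(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_swap_symmetry(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 8.0, 9.0, 3.0]
        r1, r2 = wilcoxon_rank_sum(a, b), wilcoxon_rank_sum(b, a)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)
        assert r1.statistic + r2.statistic == pytest.approx(len(a) * len(b))

    def test_ties_switch_to_asymptotic(self):
        res = wilcoxon_rank_sum([1, 2, 2], [2, 3, 4])
        assert res.method == "asymptotic"


class TestCliffsDelta:
    @pytest.mark.parametrize("a,b,expected", [
        ([2, 2, 2], [2, 2, 2], 0.0),
        ([5, 6], [1, 2], 1.0),
        ([1, 2], [5, 6], -1.0),
        ([1, 2], [1, 3], -0.25),
    ])
    def test_exhaustive_pair_enumeration(self, a, b, expected):
        assert cliffs_delta(a, b) == pytest.approx(expected, abs=1e-15)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=8), rng.normal(size=6)
        assert cliffs_delta(a, b) == pytest.approx(-cliffs_delta(b, a))


# ---------------------------------------------------------------------------
# Spearman with bootstrap


class TestSpearmanBootstrap:
    def test_perfectly_monotone(self):
        res = spearman_bootstrap([1, 2, 3, 4, 5], [10, 20, 30, 40, 50],
                                 n_boot=200, seed=1)
        assert res.rho == pytest.approx(1.0)
        assert res.ci[0] == pytest.approx(1.0, abs=1e-12)
        assert res.ci[1] == pytest.approx(1.0, abs=1e-12)

    def test_exact_permutation_p_at_small_n(self):
        x, y = [1, 2, 3, 4, 5], [10, 20, 30, 40, 50]
        res = spearman_bootstrap(x, y, n_boot=50, seed=1)
        assert res.method == "exact_permutation"
        assert res.p == pytest.approx(2.0 / 120.0, abs=1e-12)

    def test_rho_equals_pearson_of_ranks(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = spearman_bootstrap(x, y, n_boot=50, seed=1)
        want = np.corrcoef(ss.rankdata(x), ss.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(want, abs=1e-12)

    def test_zero_variance_gives_explicit_null(self):
        res = spearman_bootstrap([1, 1, 1, 1], [1, 2, 3, 4], seed=1)
        assert np.isnan(res.rho) and res.message is not None

    def test_too_few_donors_rejected(self):
        with pytest.raises(ValidationError):
            spearman_bootstrap([1, 2, 3], [1, 2, 3])


# ---------------------------------------------------------------------------
# multiplicity adjustment


class TestAdjustment:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)

    def test_bh_step_up_hand_computation(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st_.lists(st_.floats(min_value=0.0, max_value=1.0), min_size=1,
                     max_size=12))
    def test_bh_dominates_holm_and_monotonicity(self, ps):
        bh, holm = bh_adjust(ps), holm_adjust(ps)
        assert np.all(bh <= holm + 1e-12)
        assert np.all(holm >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(bh[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# DEG filter and TOST


class TestFilterDegs:
    def test_empty_table(self):
        t = pd.DataFrame(columns=["gene", "log2fc", "padj"])
        assert filter_degs(t).empty

    def test_joint_threshold_rule(self):
        t = pd.DataFrame({"gene": ["a", "b", "c"],
                          "log2fc": [0.3, 0.1, 1.0],
                          "padj": [0.04, 0.04, 0.2]})
        out = filter_degs(t)
        assert list(out["gene"]) == ["a"]
        assert list(out["direction"]) == ["up"]

    def test_permissive_limits_keep_nonzero_lfc(self):
        t = pd.DataFrame({"gene": ["a", "b"], "log2fc": [0.0, -2.0],
                          "padj": [0.5, 0.9]})
        out = filter_degs(t, padj_max=1.0, lfc_min=0.0)
        assert list(out["gene"]) == ["b"]
        assert list(out["direction"]) == ["down"]


class TestTost:
    def test_identical_cohorts_are_equivalent(self):
        a = list(range(12))
        res = tost_equivalence(a, a, margin=1.0)
        assert res.extras["equivalent"]

    def test_large_shift_is_not_equivalent(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 15)
        b = a + 3.0                          # 3 pooled-SD units away
        res = tost_equivalence(a, b, margin=1.0)
        assert not res.extras["equivalent"]

    def test_shrinking_margin_never_creates_equivalence(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 12)
        b = a + 2.5
        p_wide = tost_equivalence(a, b, margin=1.0).p
        p_narrow = tost_equivalence(a, b, margin=0.2).p
        assert p_narrow >= p_wide - 1e-12

    def test_missing_margin_is_a_config_error(self):
        with pytest.raises(ConfigError, match="margin"):
            tost_equivalence([1, 2], [1, 2], margin=0)
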