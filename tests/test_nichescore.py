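import numpy as np
import pandas as pd
import pytest

from nichefate.errors import ValidationError
from nichefate.nichescore import GCThresholdRule, SignatureScoreMatrix, \
    assign_labels, bootstrap_ci, classify_gc, detection_intensity, \
    nearest_rank_threshold, sensitivity_scan, ucell_score
from nichefate.spotio import CountsMatrix, GeneSetCollection


def brute_force_ucell(expr: np.ndarray, gene_names: list[str],
                      sig_genes: list[str], rmax: int) -> float:
    """Independent oracle: materialise the full rank vector of one spot."""
    order = sorted(range(len(expr)), key=lambda i: -expr[i])
    ranks = [0.0] * len(expr)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and expr[order[j]] == expr[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0          # average of positions i+1 .. j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    pos = {g: i for i, g in enumerate(gene_names)}
    n = len(sig_genes)
    rank_sum = 0.0
    for g in sig_genes:
        r = min(ranks[pos[g]], rmax + 1) if g in pos else rmax + 1
        rank_sum += r
    u = rank_sum - n * (n + 1) / 2.0
    return max(0.0, 1.0 - u / (n * rmax))


def make_counts(matrix, genes=None, spots=None):
    m = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(m.shape[0])]
    spots = spots or [f"s{i}" for i in range(m.shape[1])]
    return CountsMatrix(m, genes, spots)


class TestUcellScore:
    def test_enumerated_toy_two_genes_ranks_3_and_7(self):
        # 10 genes, one spot; expression 10..1 so gene i has rank i+1
        expr = np.arange(10, 0, -1).reshape(10, 1)
        counts = make_counts(expr)
        sets = GeneSetCollection({"sig": ["g2", "g6"]})   # ranks 3 and 7
        score = ucell_score(counts, sets, rmax=10).scores["sig"].iloc[0]
        # U' = (3 + 7) - 3 = 7; score = 1 - 7/20
        assert score == pytest.approx(0.65, abs=1e-12)

    def test_top_ranked_signature_scores_one(self):
        expr = np.arange(10, 0, -1).reshape(10, 1)
        counts = make_counts(expr)
        sets = GeneSetCollection({"sig": ["g0", "g1", "g2"]})
        score = ucell_score(counts, sets, rmax=10).scores["sig"].iloc[0]
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_signature_beyond_rank_cap_hits_the_floor(self):
        # both signature genes rank beyond rmax and are capped at rmax + 1;
        # the score floor is (n - 1) / (2 rmax), effectively zero
        expr = np.arange(10, 0, -1).reshape(10, 1)
        counts = make_counts(expr)
        sets = GeneSetCollection({"sig": ["g8", "g9"]})   # ranks 9 and 10
        score = ucell_score(counts, sets, rmax=8).scores["sig"].iloc[0]
        assert score == pytest.approx((2 - 1) / (2 * 8), abs=1e-12)

    def test_signature_with_no_genes_at_all_is_null(self, caplog):
        counts = make_counts([[1], [2]])
        sets = GeneSetCollection({"gone": ["zz"], "ok": ["g0"]})
        with caplog.at_level("WARNING", logger="nichefate.nichescore"):
            res = ucell_score(counts, sets, rmax=5)
        assert np.isnan(res.scores["gone"].iloc[0])
        assert np.isfinite(res.scores["ok"].iloc[0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n_genes = rng.integers(4, 13)
            n_spots = rng.integers(1, 6)
            expr = rng.integers(0, 6, size=(n_genes, n_spots))
            genes = [f"g{i}" for i in range(n_genes)]
            k = int(rng.integers(1, min(4, n_genes)))
            sig = list(rng.choice(genes, size=k, replace=False))
            rmax = int(rng.integers(k, n_genes + 3))
            counts = make_counts(expr, genes=genes)
            got = ucell_score(counts, GeneSetCollection({"s": sig}),
                              rmax=rmax).scores["s"]
            for j in range(n_spots):
                want = brute_force_ucell(expr[:, j], genes, sig, rmax)
                assert got.iloc[j] == pytest.approx(want, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        expr = rng.integers(0, 20, size=(30, 10)).astype(float)
        counts = make_counts(expr)
        sets = GeneSetCollection({"s": ["g3", "g7", "g11"]})
        a = ucell_score(counts, sets, rmax=30).scores
        b = ucell_score(make_counts(np.exp(expr / 5.0)), sets, rmax=30).scores
        pd.testing.assert_frame_equal(a, b)

    def test_scores_bounded(self, scored_cohort):
        _, scores, _ = scored_cohort
        vals = scores.scores.to_numpy()
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0

    def test_rmax_below_signature_size_rejected(self):
        counts = make_counts([[1], [2]])
        with pytest.raises(ValidationError, match="rmax"):
            ucell_score(counts, GeneSetCollection({"s": ["g0", "g1", "x"]}),
                        rmax=2)


class TestAssignLabels:
    @pytest.mark.parametrize("weights,expected,confidence", [
        ({"A": [1.0], "B": [0.0], "C": [0.0]}, "A", 1.0),
        ({"A": [0.35], "B": [0.33], "C": [0.32]}, "unknown", 0.35),
        ({"A": [0.5], "B": [0.5], "C": [0.0]}, "A", 0.5),
    ])
    def test_rule_application(self, weights, expected, confidence):
        df = pd.DataFrame(weights, index=pd.Index(["s1"], name="spot_id"))
        out = assign_labels(df, min_weight=0.4)
        assert out.loc["s1", "label"] == expected
        assert out.loc["s1", "confidence"] == pytest.approx(confidence)

    def test_tie_logged(self, caplog):
        df = pd.DataFrame({"B": [0.5], "A": [0.5]},
                          index=pd.Index(["s1"], name="spot_id"))
        with caplog.at_level("WARNING", logger="nichefate.nichescore"):
            out = assign_labels(df)
        assert out.loc["s1", "label"] == "A"
        assert any("tie" in r.message for r in caplog.records)


def spot_frame(scores_by_donor):
    rows = []
    for donor, vals in scores_by_donor.items():
        for i, _ in enumerate(vals):
            rows.append({"spot_id": f"{donor}_s{i}", "x_um": float(i),
                         "y_um": 0.0, "donor": donor, "roi": f"{donor}_r",
                         "group": "G", "stage": "none"})
    return pd.DataFrame(rows)


def score_matrix(scores_by_donor, signature="GC_Response"):
    ids, vals = [], []
    for donor, v in scores_by_donor.items():
        ids += [f"{donor}_s{i}" for i in range(len(v))]
        vals += list(v)
    df = pd.DataFrame({signature: np.asarray(vals, float) / 100.0},
                      index=pd.Index(ids, name="spot_id"))
    return SignatureScoreMatrix(df, rmax=100)


class TestClassifyGc:
    def test_nearest_rank_on_eight_values(self):
        data = {"d1": [10, 20, 30, 40, 50, 60, 70, 80]}
        cls = classify_gc(score_matrix(data), spot_frame(data),
                          GCThresholdRule())
        assert cls.thresholds["d1"] == pytest.approx(0.60)
        assert cls.flags.sum() == 3          # 60, 70, 80

    def test_tie_saturation_flags_everything(self):
        data = {"d1": [50.0] * 8}
        cls = classify_gc(score_matrix(data), spot_frame(data),
                          GCThresholdRule())
        assert cls.flags.all()
        assert "d1" in cls.metadata["degenerate_scopes"]

    def test_tie_free_fraction_near_25_percent(self):
        rng = np.random.default_rng(0)
        data = {f"d{i}": rng.uniform(0, 100, 400) for i in range(4)}
        cls = classify_gc(score_matrix(data), spot_frame(data),
                          GCThresholdRule())
        st = spot_frame(data).set_index("spot_id")
        for d, sub in st.groupby("donor"):
            frac = cls.flags.loc[sub.index].mean()
            assert frac == pytest.approx(0.25, abs=1.5 / 400)

    def test_small_scope_marked_unreliable(self):
        data = {"d1": [1, 2, 3], "d2": list(range(20))}
        cls = classify_gc(score_matrix(data), spot_frame(data),
                          GCThresholdRule())
        assert cls.metadata["unreliable_scopes"] == ["d1"]

    def test_zscore_mode_flags_upper_tail(self):
        rng = np.random.default_rng(1)
        data = {"d1": rng.normal(50, 10, 2000).clip(0, 100)}
        cls = classify_gc(score_matrix(data), spot_frame(data),
                          GCThresholdRule(mode="zscore"))
        assert cls.flags.mean() == pytest.approx(0.25, abs=0.03)

    def test_restriction_limits_threshold_and_flags(self):
        data = {"d1": [10, 20, 30, 40, 50, 60, 70, 80]}
        st = spot_frame(data)
        labels = pd.DataFrame(
            {"label": ["T"] * 4 + ["U"] * 4, "confidence": 1.0},
            index=pd.Index(st["spot_id"], name="spot_id"))
        cls = classify_gc(score_matrix(data), st, GCThresholdRule(),
                          restrict_to=["T"], labels=labels)
        # threshold from {10..40}: nearest-rank 75th = 30; only T spots flagged
        assert cls.thresholds["d1"] == pytest.approx(0.30)
        flagged = set(cls.flags[cls.flags].index)
        assert flagged == {"d1_s2", "d1_s3"}


class TestBootstrapCi:
    def test_constant_values_give_degenerate_interval(self):
        lo, hi = bootstrap_ci([2.0, 2.0, 2.0, 2.0], seed=1)
        assert lo == hi == 2.0

    def test_seed_determinism(self):
        v = [1.0, 3.0, 2.0, 5.0, 4.0]
        assert bootstrap_ci(v, seed=7) == bootstrap_ci(v, seed=7)
        assert bootstrap_ci(v, seed=7) != bootstrap_ci(v, seed=8)

    def test_interval_brackets_the_mean(self):
        rng = np.random.default_rng(2)
        v = rng.normal(10, 1, 30)
        lo, hi = bootstrap_ci(v, seed=3)
        assert lo < v.mean() < hi


class TestDetectionIntensity:
    def test_hand_computed_decomposition(self):
        counts = make_counts([[0, 0, 2, 4]], genes=["CTHRC1"])
        det, ppm = detection_intensity(counts, counts.spots, "CTHRC1")
        assert det == pytest.approx(0.5)
        assert ppm == pytest.approx(3.0)

    def test_all_zero_detection(self):
        counts = make_counts([[0, 0, 0]], genes=["CTHRC1"])
        det, ppm = detection_intensity(counts, counts.spots, "CTHRC1")
        assert det == 0.0 and ppm is None

    def test_constant_positive(self):
        counts = make_counts([[7, 7]], genes=["CTHRC1"])
        det, ppm = detection_intensity(counts, counts.spots, "CTHRC1")
        assert det == 1.0 and ppm == pytest.approx(7.0)

    def test_empty_subset_is_an_error(self):
        counts = make_counts([[1]], genes=["CTHRC1"])
        with pytest.raises(ValidationError, match="empty"):
            detection_intensity(counts, [], "CTHRC1")


class TestSensitivityScan:
    def test_flag_sets_are_nested_and_contrast_reported(self, scored_cohort):
        cohort, scores, labels = scored_cohort
        report, cls = sensitivity_scan(
            scores, cohort.spot_table, labels,
            numerator_labels=["Fib_myo"], denominator_labels=["Fib_myo"],
            contrast=("OP", "IPF"), n_boot=100, seed=4)
        assert report.nested(cls)
        t = report.table
        assert set(t["threshold"]) == {"p70", "p75", "p80", "p85", "p90",
                                       "zscore"}
        assert (t["ci_lower"] <= t["estimate"]).all()
        assert (t["estimate"] <= t["ci_upper"]).all()

    def test_quantile_monotonicity_of_nearest_rank(self):
        rng = np.random.default_rng(9)
        v = rng.uniform(size=500)
        thr = [nearest_rank_threshold(v, p) for p in (70, 75, 80, 85, 90)]
        assert all(a <= b for a, b in zip(thr, thr[1:]))
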