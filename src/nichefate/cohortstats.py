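"""Donor-level nonparametric statistics.

Every hypothesis test in the pipeline runs at the donor level: per-donor
statistics are formed as equal-weight means over that donor's eligible
ROIs, then compared across disease groups with Kruskal-Wallis, Dunn or
Wilcoxon rank-sum post hocs under Benjamini-Hochberg or Holm multiplicity
control, Cliff's delta effect sizes, and donor-resampled bootstrap
confidence intervals.  Small-sample paths (exact permutation p-values) are
provided wherever total N makes enumeration feasible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError
from .nichescore import ClassificationResult, SignatureScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """One hypothesis-test outcome row."""

    test: str
    statistic: float
    p: float
    p_adjusted: float | None = None
    adjust_method: str | None = None
    contrast: tuple[str, str] | None = None
    effect_size: float | None = None
    method: str | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ROI-weighted donor summaries


def roi_weighted_proportion(classification: ClassificationResult,
                            spot_table: pd.DataFrame,
                            labels: pd.DataFrame,
                            numerator_labels: Sequence[str],
                            denominator_labels: Sequence[str],
                            min_spots: int = 10,
                            pooled: bool = False) -> pd.DataFrame:
    """Donor-level ROI-weighted flagged-spot proportion.

    Per ROI: proportion = flagged spots carrying a numerator label divided
    by spots carrying a denominator label.  The donor value is the
    equal-weight mean over that donor's ROIs with at least ``min_spots``
    denominator spots (``pooled=True`` instead pools spots across the
    donor's ROIs).  Donors with no eligible ROI are omitted and listed in
    the frame's ``attrs["omitted_donors"]``.
    """
    df = spot_table.join(labels["label"], on="spot_id")
    df = df.join(classification.flags.rename("flag"), on="spot_id")
    df["flag"] = df["flag"].fillna(False)
    denom_mask = df["label"].isin(set(denominator_labels))
    num_mask = df["label"].isin(set(numerator_labels)) & df["flag"]

    rows, omitted, excluded_rois = [], [], []
    for donor, sub in df.groupby("donor", sort=True):
        group = sub["group"].iloc[0]
        props, n_spots = [], 0
        pooled_num = pooled_den = 0
        for roi, roi_sub in sub.groupby("roi", sort=True):
            den = int(denom_mask.loc[roi_sub.index].sum())
            num = int(num_mask.loc[roi_sub.index].sum())
            if den < min_spots:
                excluded_rois.append(str(roi))
                logger.warning("ROI %s: only %d denominator spots (<%d); "
                               "excluded from donor proportion",
                               roi, den, min_spots)
                continue
            props.append(num / den)
            pooled_num += num
            pooled_den += den
            n_spots += den
        if not props:
            omitted.append(str(donor))
            logger.warning("donor %s: no eligible ROI; omitted", donor)
            continue
        value = (pooled_num / pooled_den) if pooled else float(np.mean(props))
        rows.append({"donor": donor, "group": group,
                     "statistic": "gc_sensitive_proportion", "value": value,
                     "n_rois": len(props), "n_spots": n_spots})
    out = pd.DataFrame(rows)
    out.attrs["omitted_donors"] = omitted
    out.attrs["excluded_rois"] = excluded_rois
    return out


def donor_mean_score(scores: SignatureScoreMatrix, spot_table: pd.DataFrame,
                     labels: pd.DataFrame, label_subset: Sequence[str],
                     signature: str,
                     flags: pd.Series | None = None,
                     flag_value: bool | None = None) -> pd.DataFrame:
    """Per-donor mean signature score over a labelled spot subset.

    Donor values are equal-weight means of per-ROI mean scores (matching
    the ROI-weighted design).  ``flags``/``flag_value`` optionally restrict
    to GC-sensitive (True) or GC-low (False) spots.
    """
    df = spot_table.join(labels["label"], on="spot_id")
    df["score"] = scores.scores[signature].reindex(df["spot_id"]).to_numpy()
    keep = df["label"].isin(set(label_subset)) & df["score"].notna()
    if flags is not None and flag_value is not None:
        keep &= flags.reindex(df["spot_id"]).fillna(False).to_numpy() == flag_value
    df = df[keep]
    roi_means = (df.groupby(["donor", "group", "roi"])["score"].mean()
                   .reset_index())
    out = (roi_means.groupby(["donor", "group"])["score"].mean()
           .reset_index().rename(columns={"score": "value"}))
    out["statistic"] = f"mean_{signature}"
    return out


# ---------------------------------------------------------------------------
# Rank helpers


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts ** 3 - counts).sum())


def _kw_h(rank_sums: np.ndarray, sizes: np.ndarray, n: int,
          tie_sum: float) -> float:
    h = 12.0 / (n * (n + 1)) * float((rank_sums ** 2 / sizes).sum()) \
        - 3.0 * (n + 1)
    c = 1.0 - tie_sum / (n ** 3 - n)
    return h / c if c > 0 else 0.0


def _group_partitions(n: int, sizes: Sequence[int]):
    """All assignments of indices 0..n-1 to labelled groups of given sizes."""
    def rec(remaining: tuple[int, ...], sizes_left: Sequence[int]):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in set(combo))
            for tail in rec(rest, sizes_left[1:]):
                yield (combo, *tail)
    yield from rec(tuple(range(n)), list(sizes))


# ---------------------------------------------------------------------------
# Omnibus and post-hoc tests


def kruskal_wallis(groups: Mapping[str, Sequence[float]],
                   exact_max_n: int = 12, perm_max_n: int = 50,
                   n_perm: int = 2000, seed: int = 0) -> TestResult:
    """Kruskal-Wallis H with tie correction.

    The H statistic always carries the pooled-rank tie correction.  The
    reported p depends on total N: exact permutation enumeration for
    N <= ``exact_max_n``; a seeded Monte-Carlo permutation p (``n_perm``
    label shuffles, add-one estimator) for N <= ``perm_max_n``, where the
    chi-square approximation is visibly conservative at donor-level sample
    sizes; the chi-square approximation beyond that.  The chi-square p is
    always attached in ``extras["p_chi2"]``.  A group with a single donor
    triggers a low-power warning, not an error.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    vals = [np.asarray(list(groups[g]), float) for g in names]
    if any(len(v) == 0 for v in vals):
        raise ValidationError("empty group passed to Kruskal-Wallis")
    low_power = any(len(v) < 2 for v in vals)
    if low_power:
        logger.warning("Kruskal-Wallis: a group has a single donor; "
                       "the test is low-powered")
    pooled = np.concatenate(vals)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0,
                          method="degenerate", extras={"low_power": low_power})
    h, p_chi2 = ss.kruskal(*vals)
    extras: dict = {"low_power": low_power, "p_chi2": float(p_chi2)}
    n = len(pooled)
    ranks = ss.rankdata(pooled)
    tie_sum = _tie_term(pooled)
    sizes = np.array([len(v) for v in vals])
    bounds = np.cumsum(np.concatenate([[0], sizes]))
    if n <= exact_max_n:
        count = total = 0
        for part in _group_partitions(n, sizes.tolist()):
            rs = np.array([ranks[list(idx)].sum() for idx in part])
            if _kw_h(rs, sizes, n, tie_sum) >= h - 1e-12:
                count += 1
            total += 1
        extras["p_exact"] = count / total
        return TestResult("kruskal_wallis", float(h), count / total,
                          method="exact_permutation", extras=extras)
    if n <= perm_max_n:
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        rperm = ranks[order]                       # (n_perm, n)
        rs = np.stack([rperm[:, bounds[i]:bounds[i + 1]].sum(axis=1)
                       for i in range(len(sizes))], axis=1)
        c = 1.0 - tie_sum / (n ** 3 - n)
        h_perm = (12.0 / (n * (n + 1)) * (rs ** 2 / sizes[None, :]).sum(axis=1)
                  - 3.0 * (n + 1)) / c
        p_mc = (1 + int((h_perm >= h - 1e-12).sum())) / (1 + n_perm)
        extras["n_perm"] = n_perm
        return TestResult("kruskal_wallis", float(h), float(p_mc),
                          method="mc_permutation", extras=extras)
    return TestResult("kruskal_wallis", float(h), float(p_chi2),
                      method="chi2", extras=extras)


def dunn_posthoc(groups: Mapping[str, Sequence[float]],
                 adjust: str = "holm") -> list[TestResult]:
    """Dunn's z tests on pooled ranks for all pairwise contrasts.

    Two-sided normal p-values with the pooled-rank tie correction,
    adjusted across the contrast family by Holm (default) or BH.
    """
    if adjust not in ("holm", "bh"):
        raise ConfigError(f"unknown adjustment '{adjust}' (use holm or bh)")
    names = list(groups)
    vals = {g: np.asarray(list(groups[g]), float) for g in names}
    pooled = np.concatenate([vals[g] for g in names])
    n = len(pooled)
    ranks = ss.rankdata(pooled)
    offsets = np.cumsum([0] + [len(vals[g]) for g in names])
    mean_ranks = {g: float(ranks[offsets[i]:offsets[i + 1]].mean())
                  for i, g in enumerate(names)}
    tie_sum = _tie_term(pooled)
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))

    results = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(vals[a]), len(vals[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * ss.norm.sf(abs(z))
        results.append(TestResult("dunn", float(z), float(min(p, 1.0)),
                                  contrast=(a, b),
                                  effect_size=cliffs_delta(vals[a], vals[b])))
    raw = [r.p for r in results]
    adj = holm_adjust(raw) if adjust == "holm" else bh_adjust(raw)
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.adjust_method = "Holm" if adjust == "holm" else "BH"
    return results


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact p when min(n, m) <= 8 with no ties; otherwise the normal
    approximation with continuity and tie correction.  The method used is
    recorded on the result.
    """
    av, bv = np.asarray(list(a), float), np.asarray(list(b), float)
    if len(av) == 0 or len(bv) == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([av, bv])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(av), len(bv)) <= 8 and not has_ties) \
        else "asymptotic"
    res = ss.mannwhitneyu(av, bv, alternative="two-sided", method=method,
                          use_continuity=True)
    return TestResult("wilcoxon_rank_sum", float(res.statistic),
                      float(res.pvalue), method=method,
                      effect_size=cliffs_delta(av, bv))


def cliffs_delta(a: Sequence[float], b: Sequence[float]) -> float:
    """Cliff's delta: (#{a > b} - #{a < b}) / (n*m); ties contribute 0."""
    av, bv = np.asarray(list(a), float), np.asarray(list(b), float)
    if len(av) == 0 or len(bv) == 0:
        raise ValidationError("both groups must be nonempty")
    diff = av[:, None] - bv[None, :]
    return float((np.sign(diff)).sum() / (len(av) * len(bv)))


# ---------------------------------------------------------------------------
# Spearman correlation with donor-resampled bootstrap


@dataclass
class SpearmanResult:
    rho: float
    ci: tuple[float, float]
    p: float
    n_boot: int
    method: str
    message: str | None = None


def spearman_bootstrap(x: Sequence[float], y: Sequence[float],
                       n_boot: int = 1000, level: float = 0.95,
                       seed: int = 0) -> SpearmanResult:
    """Donor-level Spearman correlation with a percentile bootstrap CI.

    Ties receive average ranks.  The p-value is exact (full permutation
    enumeration) when n <= 7, otherwise the t approximation.  Zero variance
    in either variable leaves rho undefined (NaN with a message).
    """
    xv, yv = np.asarray(list(x), float), np.asarray(list(y), float)
    if len(xv) != len(yv):
        raise ValidationError("x and y must be paired")
    if len(xv) < 4:
        raise ValidationError("need >= 4 paired donors")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        msg = "zero variance in one variable; Spearman rho undefined"
        logger.warning(msg)
        return SpearmanResult(float("nan"), (float("nan"), float("nan")),
                              float("nan"), n_boot, "undefined", msg)
    rho = float(ss.spearmanr(xv, yv).statistic)
    n = len(xv)
    if n <= 7:
        rx = ss.rankdata(xv)
        ry = ss.rankdata(yv)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = ss.spearmanr(rx, ry[list(perm)]).statistic
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p, method = count / total, "exact_permutation"
    else:
        p, method = float(ss.spearmanr(xv, yv).pvalue), "t_approx"

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = np.full(n_boot, np.nan)
    for i, row in enumerate(idx):
        xb, yb = xv[row], yv[row]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            continue
        reps[i] = ss.spearmanr(xb, yb).statistic
    alpha = (1.0 - level) / 2.0
    valid = reps[np.isfinite(reps)]
    lo, hi = (float(q) for q in np.quantile(valid, [alpha, 1.0 - alpha]))
    return SpearmanResult(rho, (lo, hi), float(p), n_boot, method)


# ---------------------------------------------------------------------------
# Multiplicity adjustment


def _check_p(p: Sequence[float]) -> np.ndarray:
    pv = np.asarray(list(p), float)
    if pv.size and ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return pv


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pv = _check_p(p)
    if pv.size == 0:
        return pv
    return multipletests(pv, method="fdr_bh")[1]


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, input order preserved."""
    pv = _check_p(p)
    if pv.size == 0:
        return pv
    return multipletests(pv, method="holm")[1]


# ---------------------------------------------------------------------------
# DEG threshold filtering


def filter_degs(table: pd.DataFrame, padj_max: float = 0.05,
                lfc_min: float = 0.25) -> pd.DataFrame:
    """Retain genes with adjusted p < padj_max and |log2FC| > lfc_min.

    Adds a ``direction`` column (up/down) by the sign of the fold change.
    Expects columns ``gene``, ``log2fc``, ``padj``.
    """
    for col in ("gene", "log2fc", "padj"):
        if col not in table.columns:
            raise ValidationError(f"DEG table missing column '{col}'")
    keep = (table["padj"] < padj_max) & (table["log2fc"].abs() > lfc_min)
    out = table[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


# ---------------------------------------------------------------------------
# Equivalence testing (TOST)


def tost_equivalence(a: Sequence[float], b: Sequence[float], margin: float,
                     alpha: float = 0.05) -> TestResult:
    """Two one-sided Wilcoxon tests against +/- margin (standardised).

    The margin is expressed in pooled-SD units of the two cohorts; the two
    one-sided rank-sum tests compare cohort A against cohort B shifted by
    -margin and +margin.  Equivalence is declared when both one-sided
    p-values fall below alpha.  The margin must be supplied explicitly.
    """
    if margin is None or not margin > 0:
        raise ConfigError("tost_equivalence requires an explicit margin > 0; "
                          "choose one on the standardised-difference scale")
    av, bv = np.asarray(list(a), float), np.asarray(list(b), float)
    if len(av) < 2 or len(bv) < 2:
        raise ValidationError("both cohorts need >= 2 values")
    na, nb = len(av), len(bv)
    pooled_sd = np.sqrt(((na - 1) * av.var(ddof=1) + (nb - 1) * bv.var(ddof=1))
                        / (na + nb - 2))
    shift = margin * pooled_sd
    p_lower = ss.mannwhitneyu(av, bv - shift, alternative="greater").pvalue
    p_upper = ss.mannwhitneyu(av, bv + shift, alternative="less").pvalue
    p_tost = float(max(p_lower, p_upper))
    return TestResult("tost_equivalence", float("nan"), p_tost,
                      method="wilcoxon_tost",
                      extras={"margin": margin, "alpha": alpha,
                              "p_lower": float(p_lower),
                              "p_upper": float(p_upper),
                              "equivalent": bool(p_lower < alpha
                                                 and p_upper < alpha)})


def test_results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flatten TestResult objects into one tidy table."""
    rows = []
    for r in results:
        rows.append({"test": r.test, "statistic": r.statistic, "p": r.p,
                     "p_adjusted": r.p_adjusted,
                     "adjust_method": r.adjust_method,
                     "contrast": "_vs_".join(r.contrast) if r.contrast else "",
                     "effect_size": r.effect_size, "method": r.method})
    return pd.DataFrame(rows)
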