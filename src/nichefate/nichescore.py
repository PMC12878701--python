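"""Signature scoring and glucocorticoid-sensitive spot classification.

Scores spots with a rank-based (Mann-Whitney U) signature score in [0, 1],
turns deconvolution weights into discrete cell-type labels, flags
GC-sensitive spots by a per-sample percentile (or z-score) rule, and
quantifies the robustness of group contrasts across a threshold scan with
donor-resampled bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .spotio import CountsMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# UCell-style rank-based signature scoring


@dataclass
class SignatureScoreMatrix:
    """Spots x signatures score table with the maximum-rank cap used."""

    scores: pd.DataFrame          # index spot_id, one column per signature
    rmax: int

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValidationError("signature scores must lie in [0, 1]")


def ucell_score(counts: CountsMatrix, sets: GeneSetCollection,
                rmax: int = 1500) -> SignatureScoreMatrix:
    """Rank-based signature score per spot and signature.

    Within each spot, genes are ranked by decreasing expression with
    average ranks for ties; ranks above ``rmax`` are capped at
    ``rmax + 1``, as are signature genes missing from the gene index
    (logged once per signature).  For a signature of size n with capped
    rank sum R, U' = R - n(n+1)/2 and the score is
    ``max(0, 1 - U' / (n * rmax))``: 1 when the signature occupies the top
    n ranks, near 0 when every signature gene is absent or beyond the cap.

    A signature with no genes present in the matrix at all scores NaN for
    every spot, with a warning.
    """
    largest = max(len(g) for g in sets.sets.values())
    if rmax < largest:
        raise ValidationError(
            f"rmax={rmax} is smaller than the largest signature ({largest})")
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValidationError("counts matrix is empty")

    X = counts.dense().astype(float)
    ranks = rankdata(-X, axis=0, method="average")
    np.minimum(ranks, rmax + 1, out=ranks)

    gene_pos = {g: i for i, g in enumerate(counts.genes)}
    out = {}
    for name, genes in sets.items():
        present = [gene_pos[g] for g in genes if g in gene_pos]
        n_absent = len(genes) - len(present)
        if n_absent:
            logger.warning("signature '%s': %d/%d genes absent from the "
                           "matrix (ranked at rmax+1)", name, n_absent,
                           len(genes))
        n = len(genes)
        if not present:
            logger.warning("signature '%s' has no genes in the matrix; "
                           "score is null", name)
            out[name] = np.full(X.shape[1], np.nan)
            continue
        rank_sum = ranks[present].sum(axis=0) + n_absent * (rmax + 1)
        u_prime = rank_sum - n * (n + 1) / 2.0
        out[name] = np.maximum(0.0, 1.0 - u_prime / (n * rmax))
    scores = pd.DataFrame(out, index=pd.Index(counts.spots, name="spot_id"))
    return SignatureScoreMatrix(scores, rmax)


# ---------------------------------------------------------------------------
# Discrete cell-type labels from deconvolution weights


def assign_labels(weights: pd.DataFrame, min_weight: float = 0.4) -> pd.DataFrame:
    """Label each spot by its dominant cell type, or ``"unknown"``.

    The label is the argmax weight when that weight reaches ``min_weight``;
    exact ties break to the lexicographically smallest cell-type name and
    are logged.  Returns a frame indexed by spot_id with columns
    ``label`` and ``confidence`` (the winning weight).
    """
    cols = sorted(weights.columns)
    w = weights[cols].to_numpy(float)
    win = w.argmax(axis=1)                       # first (lexicographic) argmax
    conf = w[np.arange(len(w)), win]
    ties = (w == conf[:, None]).sum(axis=1) > 1
    if ties.any():
        for sid in weights.index[ties][:10]:
            logger.warning("spot %s: tied top weights, lexicographic "
                           "tie-break applied", sid)
    labels = np.array(cols, dtype=object)[win]
    labels[conf < min_weight] = "unknown"
    return pd.DataFrame({"label": labels, "confidence": conf},
                        index=weights.index)


# ---------------------------------------------------------------------------
# GC-sensitive classification


@dataclass(frozen=True)
class GCThresholdRule:
    """Per-scope thresholding rule for GC-sensitive classification.

    ``percentile`` mode flags spots at or above the within-scope
    nearest-rank percentile (default 75, i.e. the top quartile);
    ``zscore`` mode flags spots with within-scope z at or above
    ``z_cutoff`` (default 0.674, the upper-quartile point of a normal).
    ``scope`` is the spot-table column defining the units within which the
    threshold is computed (default ``donor``, i.e. per sample).
    """

    mode: str = "percentile"
    percentile: float = 75.0
    z_cutoff: float = 0.674
    scope: str = "donor"

    def __post_init__(self) -> None:
        if self.mode not in ("percentile", "zscore"):
            raise ValidationError(f"unknown threshold mode '{self.mode}'")
        if not 0.0 < self.percentile < 100.0:
            raise ValidationError("percentile must lie in (0, 100)")


@dataclass
class ClassificationResult:
    """Per-spot GC-sensitive flags plus the thresholds that produced them."""

    flags: pd.Series              # bool, indexed by spot_id
    rule: GCThresholdRule
    thresholds: pd.Series         # per scope unit
    metadata: dict = field(default_factory=dict)


def nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Inclusive nearest-rank empirical quantile (inverse ECDF)."""
    v = np.sort(np.asarray(values, float))
    k = int(np.ceil(percentile / 100.0 * len(v)))
    return float(v[max(k, 1) - 1])


def classify_gc(scores: SignatureScoreMatrix, spot_table: pd.DataFrame,
                rule: GCThresholdRule = GCThresholdRule(),
                signature: str = "GC_Response",
                restrict_to: Sequence[str] | None = None,
                labels: pd.DataFrame | None = None,
                min_scope_spots: int = 4) -> ClassificationResult:
    """Flag GC-sensitive spots by a per-scope threshold on one signature.

    ``restrict_to`` limits both the threshold computation and the flagging
    to spots carrying the given discrete labels (requires ``labels`` from
    :func:`assign_labels`); scope units with fewer than ``min_scope_spots``
    eligible spots, and units where every score ties the threshold range
    degenerately, are flagged in ``metadata`` rather than dropped.
    """
    if signature not in scores.scores.columns:
        raise ValidationError(f"signature '{signature}' not in score matrix")
    if rule.scope not in spot_table.columns:
        raise ValidationError(f"scope column '{rule.scope}' not in spot table")

    st = spot_table.set_index("spot_id")
    s = scores.scores[signature].reindex(st.index)
    eligible = s.notna()
    if restrict_to is not None:
        if labels is None:
            raise ValidationError("restrict_to requires discrete labels")
        lab = labels["label"].reindex(st.index)
        eligible &= lab.isin(list(restrict_to))

    flags = pd.Series(False, index=st.index, name="gc_sensitive")
    thresholds: dict[str, float] = {}
    unreliable: list[str] = []
    degenerate: list[str] = []
    for unit, idx in st.groupby(rule.scope, sort=True).groups.items():
        mask = eligible.loc[idx]
        vals = s.loc[idx][mask].to_numpy(float)
        if len(vals) == 0:
            unreliable.append(str(unit))
            continue
        if len(vals) < min_scope_spots:
            unreliable.append(str(unit))
        if rule.mode == "percentile":
            thr = nearest_rank_threshold(vals, rule.percentile)
            sel = s.loc[idx] >= thr
        else:
            mu, sd = float(vals.mean()), float(vals.std(ddof=0))
            if sd == 0.0:
                degenerate.append(str(unit))
                thr = mu
                sel = s.loc[idx] >= thr          # all tie: all flagged
            else:
                thr = mu + rule.z_cutoff * sd
                sel = (s.loc[idx] - mu) / sd >= rule.z_cutoff
        if rule.mode == "percentile" and np.all(vals == vals[0]):
            degenerate.append(str(unit))
        thresholds[str(unit)] = thr
        flags.loc[idx] = (sel & mask).fillna(False)
    meta = {"unreliable_scopes": unreliable, "degenerate_scopes": degenerate,
            "signature": signature, "restrict_to": list(restrict_to or [])}
    for u in unreliable:
        logger.warning("scope unit '%s': fewer than %d eligible spots",
                       u, min_scope_spots)
    return ClassificationResult(flags, rule,
                                pd.Series(thresholds, name="threshold"), meta)


# ---------------------------------------------------------------------------
# Bootstrap over donors


def bootstrap_ci(values: Sequence[float], n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0,
                 stat: Callable[[np.ndarray], float] | None = None
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI over donor-level values.

    Donors are resampled with replacement ``n_boot`` times; the interval is
    the percentile interval of the statistic (default: mean).  Seeded and
    deterministic.  A constant input yields the degenerate zero-width
    interval (logged).
    """
    v = np.asarray(list(values), float)
    if len(v) < 2:
        raise ValidationError("bootstrap needs at least 2 donor values")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    if stat is None:
        reps = v[idx].mean(axis=1)
    else:
        reps = np.array([stat(v[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    if lo == hi:
        logger.warning("degenerate zero-width bootstrap interval")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Sensitivity scan across thresholds


@dataclass
class SensitivityReport:
    """Group-contrast estimates and bootstrap CIs across threshold rules."""

    table: pd.DataFrame           # threshold, estimate, ci_lower, ci_upper...
    contrast: tuple[str, str]
    n_boot: int

    def nested(self, classifications: dict[str, ClassificationResult]) -> bool:
        """True if lower-percentile flag sets contain higher-percentile ones."""
        keys = sorted(k for k in classifications if k.startswith("p"))
        for lo_k, hi_k in zip(keys, keys[1:]):
            lo = classifications[lo_k].flags
            hi = classifications[hi_k].flags
            if (hi & ~lo).any():
                return False
        return True


def sensitivity_scan(scores: SignatureScoreMatrix, spot_table: pd.DataFrame,
                     labels: pd.DataFrame,
                     numerator_labels: Sequence[str],
                     denominator_labels: Sequence[str],
                     contrast: tuple[str, str] = ("OP", "IPF"),
                     percentiles: Sequence[float] = (70, 75, 80, 85, 90),
                     include_zscore: bool = True,
                     signature: str = "GC_Response",
                     scope: str = "donor",
                     n_boot: int = 1000, seed: int = 0
                     ) -> tuple[SensitivityReport, dict[str, ClassificationResult]]:
    """Scan GC-sensitive thresholds and re-estimate the group contrast.

    For each percentile in the scan (covering the top 10-30% flag rates)
    and optionally the z-score rule, spots are re-classified, donor-level
    ROI-weighted GC-sensitive proportions recomputed, and the difference of
    group means (``contrast[0]`` minus ``contrast[1]``) reported with a
    donor-resampled percentile bootstrap CI.  A group with fewer than two
    donors yields a CI marked unavailable (NaN).
    """
    from .cohortstats import roi_weighted_proportion

    groups = set(spot_table["group"])
    if len(groups & set(contrast)) < 2:
        raise ValidationError(f"contrast groups {contrast} not both present")

    rng = np.random.default_rng(seed)
    rules = [(f"p{int(p)}", GCThresholdRule("percentile", percentile=p,
                                            scope=scope))
             for p in sorted(percentiles)]
    if include_zscore:
        rules.append(("zscore", GCThresholdRule("zscore", scope=scope)))

    rows = []
    classifications: dict[str, ClassificationResult] = {}
    donor_groups = spot_table[["donor", "group"]].drop_duplicates() \
        .set_index("donor")["group"]
    for key, rule in rules:
        cls = classify_gc(scores, spot_table, rule, signature=signature)
        classifications[key] = cls
        summary = roi_weighted_proportion(
            cls, spot_table, labels, numerator_labels, denominator_labels)
        by_donor = summary.set_index("donor")["value"]
        a = by_donor[donor_groups.reindex(by_donor.index) == contrast[0]]
        b = by_donor[donor_groups.reindex(by_donor.index) == contrast[1]]
        est = float(a.mean() - b.mean())
        if len(a) < 2 or len(b) < 2:
            lo = hi = float("nan")
            logger.warning("threshold %s: a contrast group has < 2 donors; "
                           "CI unavailable", key)
        else:
            av, bv = a.to_numpy(), b.to_numpy()
            ia = rng.integers(0, len(av), size=(n_boot, len(av)))
            ib = rng.integers(0, len(bv), size=(n_boot, len(bv)))
            reps = av[ia].mean(axis=1) - bv[ib].mean(axis=1)
            lo, hi = (float(x) for x in np.quantile(reps, [0.025, 0.975]))
        rows.append({"threshold": key, "mode": rule.mode,
                     "percentile": rule.percentile if rule.mode == "percentile"
                     else np.nan,
                     "estimate": est, "ci_lower": lo, "ci_upper": hi,
                     "n_boot": n_boot,
                     "n_donors_a": len(a), "n_donors_b": len(b)})
    report = SensitivityReport(pd.DataFrame(rows), contrast, n_boot)
    return report, classifications


# ---------------------------------------------------------------------------
# Detection / per-positive intensity decomposition


def detection_intensity(counts: CountsMatrix, spot_ids: Sequence[str],
                        gene: str) -> tuple[float, float | None]:
    """Decompose a gene's signal into detection rate and positive-spot mean.

    Returns the fraction of the subset's spots with count > 0 and the mean
    expression among those positive spots (None when nothing is detected).
    """
    if len(spot_ids) == 0:
        raise ValidationError("empty spot subset")
    if gene not in counts.genes:
        raise ValidationError(f"gene '{gene}' not in the counts matrix")
    sub = counts.subset_spots(list(spot_ids))
    row = np.asarray(sub.dense()[sub.genes.index(gene)], float)
    pos = row > 0
    detection = float(pos.mean())
    per_positive = float(row[pos].mean()) if pos.any() else None
    return detection, per_positive
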