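"""Stage-resolved lesion dynamics for the staged (organising-pneumonia) group.

ROIs of the staged group carry early / middle / late labels describing
lesion progression: early inflammatory, middle fibro-inflammatory, late
fibrotic.  This module tracks, per (donor, stage), the composition of the
key classes (AT2 epithelium, the inflammatory aggregate of macrophages +
lymphocytes + neutrophils, and myofibroblasts), the GC-sensitive
myofibroblast fraction, and the apoptosis-score contrast between
GC-sensitive and GC-low myofibroblast spots.

Stage labels are consumed, never inferred; (donor, stage) means are the
observational units for inter-stage comparisons, acknowledging that one
donor may contribute ROIs to several stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohortstats import TestResult, bh_adjust, cliffs_delta, kruskal_wallis, \
    wilcoxon_rank_sum
from .errors import ValidationError
from .nichescore import ClassificationResult, SignatureScoreMatrix

logger = logging.getLogger(__name__)

STAGE_ORDER = ("early", "middle", "late")

# composition classes tracked across stages; the inflammatory aggregate is
# the union of the three innate/adaptive immune label families
DEFAULT_CLASSES: Mapping[str, tuple[str, ...]] = {
    "AT2": ("AT2",),
    "inflammatory": ("Macrophage", "Lymphocyte", "Neutrophil"),
    "Fib_myo": ("Fib_myo",),
}


@dataclass
class StageDynamics:
    """Per-(donor, stage) composition and GC-coupling statistics."""

    composition: pd.DataFrame            # donor, stage, class, proportion
    gc_fraction: pd.DataFrame | None = None   # donor, stage, value
    apoptosis_contrast: pd.DataFrame | None = None
    tests: list[TestResult] = field(default_factory=list)


def _staged(spot_table: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    df = spot_table.join(labels["label"], on="spot_id")
    df = df[df["stage"].isin(STAGE_ORDER)]
    if df.empty:
        raise ValidationError("no ROI carries an early/middle/late stage label")
    return df


def stage_composition(spot_table: pd.DataFrame, labels: pd.DataFrame,
                      classes: Mapping[str, Sequence[str]] = DEFAULT_CLASSES,
                      run_tests: bool = True) -> StageDynamics:
    """Equal-ROI-weight class proportions per (donor, stage).

    Per ROI, each class's proportion is its member-labelled spots over all
    labelled (non-unknown) spots; (donor, stage) values average the donor's
    ROIs in that stage.  Stages with no ROIs are omitted with a warning.
    Cross-stage Kruskal-Wallis tests (BH-adjusted across classes) are
    attached when ``run_tests``.
    """
    df = _staged(spot_table, labels)
    present = set(df["stage"])
    for s in STAGE_ORDER:
        if s not in present:
            logger.warning("stage '%s' has no ROIs; omitted", s)

    known = df[df["label"] != "unknown"]
    rows = []
    for (donor, stage, roi), sub in known.groupby(["donor", "stage", "roi"]):
        total = len(sub)
        for cls, members in classes.items():
            prop = sub["label"].isin(set(members)).sum() / total
            rows.append({"donor": donor, "stage": stage, "roi": roi,
                         "class": cls, "proportion": prop})
    per_roi = pd.DataFrame(rows)
    comp = (per_roi.groupby(["donor", "stage", "class"])["proportion"]
            .mean().reset_index())

    tests: list[TestResult] = []
    if run_tests:
        raw = []
        for cls in classes:
            sub = comp[comp["class"] == cls]
            by_stage = {s: sub.loc[sub["stage"] == s, "proportion"].to_numpy()
                        for s in STAGE_ORDER if s in present}
            if len(by_stage) >= 2 and all(len(v) >= 2 for v in by_stage.values()):
                res = kruskal_wallis(by_stage)
                res.extras["class"] = cls
                tests.append(res)
                raw.append(res.p)
        if raw:
            for res, pa in zip(tests, bh_adjust(raw)):
                res.p_adjusted = float(pa)
                res.adjust_method = "BH"
    return StageDynamics(comp, tests=tests)


def stage_gc_dynamics(classification: ClassificationResult,
                      spot_table: pd.DataFrame, labels: pd.DataFrame,
                      apoptosis_scores: SignatureScoreMatrix,
                      apoptosis_signature: str = "Apoptosis",
                      fib_labels: Sequence[str] = ("Fib_myo",),
                      min_spots: int = 10,
                      run_tests: bool = True) -> StageDynamics:
    """GC-sensitive myofibroblast dynamics across lesion stages.

    Per (donor, stage): the GC-sensitive fraction among myofibroblast
    spots (equal-ROI-weight mean over ROIs with >= ``min_spots`` such
    spots) and the mean apoptosis score of GC-sensitive versus GC-low
    myofibroblast spots.  Cross-stage Kruskal-Wallis on the fraction, plus
    per-stage Wilcoxon contrasts (BH-adjusted) with Cliff's delta on the
    apoptosis coupling, are attached when ``run_tests``.
    """
    df = _staged(spot_table, labels)
    df = df.join(classification.flags.rename("flag"), on="spot_id")
    df["apop"] = apoptosis_scores.scores[apoptosis_signature] \
        .reindex(df["spot_id"]).to_numpy()
    fib = df[df["label"].isin(set(fib_labels))]

    frac_rows, apop_rows = [], []
    for (donor, stage), sub in fib.groupby(["donor", "stage"]):
        fracs = []
        for roi, roi_sub in sub.groupby("roi"):
            if len(roi_sub) < min_spots:
                logger.warning("ROI %s (%s): only %d myofibroblast spots; "
                               "excluded", roi, stage, len(roi_sub))
                continue
            fracs.append(roi_sub["flag"].mean())
        if not fracs:
            continue
        frac_rows.append({"donor": donor, "stage": stage,
                          "value": float(np.mean(fracs)),
                          "n_rois": len(fracs)})
        sens = sub.loc[sub["flag"].fillna(False), "apop"].dropna()
        low = sub.loc[~sub["flag"].fillna(False), "apop"].dropna()
        apop_rows.append({
            "donor": donor, "stage": stage,
            "mean_apoptosis_gc_sensitive": float(sens.mean()) if len(sens)
            else np.nan,
            "mean_apoptosis_gc_low": float(low.mean()) if len(low) else np.nan,
            "n_sensitive": len(sens), "n_low": len(low)})
    gc_fraction = pd.DataFrame(frac_rows)
    apop = pd.DataFrame(apop_rows)

    tests: list[TestResult] = []
    if run_tests and not gc_fraction.empty:
        by_stage = {s: gc_fraction.loc[gc_fraction["stage"] == s, "value"]
                    .to_numpy() for s in STAGE_ORDER
                    if (gc_fraction["stage"] == s).sum() >= 2}
        if len(by_stage) >= 2:
            res = kruskal_wallis(by_stage)
            res.extras["statistic_name"] = "gc_sensitive_fraction"
            tests.append(res)
        wil: list[TestResult] = []
        for s in STAGE_ORDER:
            sub = apop[apop["stage"] == s].dropna(
                subset=["mean_apoptosis_gc_sensitive", "mean_apoptosis_gc_low"])
            if len(sub) < 2:
                continue
            a = sub["mean_apoptosis_gc_sensitive"].to_numpy()
            b = sub["mean_apoptosis_gc_low"].to_numpy()
            res = wilcoxon_rank_sum(a, b)
            res.contrast = ("gc_sensitive", "gc_low")
            res.effect_size = cliffs_delta(a, b)
            res.extras["stage"] = s
            wil.append(res)
        if wil:
            for res, pa in zip(wil, bh_adjust([r.p for r in wil])):
                res.p_adjusted = float(pa)
                res.adjust_method = "BH"
            tests.extend(wil)
    return StageDynamics(pd.DataFrame(), gc_fraction, apop, tests)
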