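"""Self-contained benchmark computations for the pipeline.

Each function runs one calibration or parameter-recovery experiment on
synthetic cohorts and returns the measured quantity.  They are shared by
the acceptance checks and by ``scripts/acceptance.py``; all randomness is
derived from one integer seed.

Problem sizes are chosen so the full battery runs in minutes on one CPU:
recovery experiments use 14 x 14-bin ROIs (196 spots, ~2.3 k spots per
donor) with a 40-gene background panel, which the calibration experiments
show is ample for the planted effect sizes.
"""

from __future__ import annotations

import numpy as np

from .cohortstats import donor_mean_score, kruskal_wallis, \
    roi_weighted_proportion, spearman_bootstrap
from .nichescore import GCThresholdRule, assign_labels, bootstrap_ci, \
    classify_gc, nearest_rank_threshold, sensitivity_scan, ucell_score
from .staging import stage_gc_dynamics
from .synthgrid import CohortConfig, generate_cohort


def _sub_seed(seed: int, stream: int, rep: int = 0) -> int:
    return int(np.random.SeedSequence((seed, stream, rep)).generate_state(1)[0]
               % (2 ** 31))


def small_cohort_config(seed: int, **overrides) -> CohortConfig:
    """Reduced-size study-design config used by the recovery experiments."""
    kwargs = dict(grid_shape=(14, 14), n_background_genes=40, seed=seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def _score_and_classify(cohort, rmax: int | None = None):
    sets = cohort.gene_sets()
    if rmax is None:
        rmax = len(cohort.counts.genes)
    scores = ucell_score(cohort.counts, sets, rmax=rmax)
    labels = assign_labels(cohort.weights)
    cls = classify_gc(scores, cohort.spot_table, GCThresholdRule())
    return scores, labels, cls


# ---------------------------------------------------------------------------
# classification rate under the per-sample 75th-percentile rule


def classification_rate(seed: int, n_samples: int = 21,
                        n_spots: int = 1000) -> float:
    """Mean per-sample flagged percentage for continuous tie-free scores.

    Draws ``n_spots`` uniform scores per sample, applies the default
    per-sample 75th-percentile rule, and returns the mean flagged fraction
    as a percentage (expected: 25%).
    """
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_samples):
        s = rng.uniform(size=n_spots)
        thr = nearest_rank_threshold(s, 75.0)
        fracs.append((s >= thr).mean())
    return float(np.mean(fracs) * 100.0)


def cohort_roi_count(seed: int) -> int:
    """ROI records emitted by the generator under the study's design
    (5/5/6/5 donors, 3 ROIs per donor)."""
    cohort = generate_cohort(small_cohort_config(seed, grid_shape=(6, 6)))
    return int(cohort.spot_table["roi"].nunique())


# ---------------------------------------------------------------------------
# statistical calibration


def kw_type1_error(seed: int, n_rep: int = 2000, alpha: float = 0.05) -> float:
    """Empirical type-I error of the Kruskal-Wallis test under the null.

    Donor layout 5/5/6/5 with iid normal donor values; returns the
    fraction of replications with p < alpha.
    """
    rng = np.random.default_rng(seed)
    sizes = (5, 5, 6, 5)
    hits = 0
    for _ in range(n_rep):
        groups = {f"g{i}": rng.standard_normal(n) for i, n in enumerate(sizes)}
        if kruskal_wallis(groups).p < alpha:
            hits += 1
    return hits / n_rep


def bootstrap_coverage(seed: int, n_rep: int = 500, n_donors: int = 30,
                       n_boot: int = 1000) -> float:
    """Empirical coverage of the 95% percentile bootstrap CI for a mean.

    Donor values are standard normal (true mean 0); returns the percentage
    of replications whose interval covers 0.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for rep in range(n_rep):
        v = rng.standard_normal(n_donors)
        lo, hi = bootstrap_ci(v, n_boot=n_boot, seed=_sub_seed(seed, 10, rep))
        covered += (lo <= 0.0 <= hi)
    return 100.0 * covered / n_rep


# ---------------------------------------------------------------------------
# parameter recovery


def op_recovery_rate(seed: int, n_runs: int = 100,
                     effect: float = 2.5) -> float:
    """Fraction of runs where the group with the planted GC elevation tops
    every other group's median donor-level GC-sensitive proportion."""
    hits = 0
    for rep in range(n_runs):
        cfg = small_cohort_config(_sub_seed(seed, 20, rep))
        cfg.signature_effects[("OP", "Fib_myo", "GC_Response")] = effect
        cohort = generate_cohort(cfg)
        _, labels, cls = _score_and_classify(cohort)
        summary = roi_weighted_proportion(cls, cohort.spot_table, labels,
                                          ["Fib_myo"], ["Fib_myo"])
        med = summary.groupby("group")["value"].median()
        if med["OP"] > med.drop("OP").max():
            hits += 1
    return hits / n_runs


def middle_stage_recovery_rate(seed: int, n_runs: int = 100) -> float:
    """Fraction of runs recovering the middle > early/late GC-sensitive
    pattern across lesion stages (median over donors)."""
    hits = 0
    for rep in range(n_runs):
        cfg = small_cohort_config(_sub_seed(seed, 30, rep),
                                  groups=("OP",), donors_per_group=(6,))
        cohort = generate_cohort(cfg)
        scores, labels, cls = _score_and_classify(cohort)
        dyn = stage_gc_dynamics(cls, cohort.spot_table, labels, scores,
                                run_tests=False)
        med = dyn.gc_fraction.groupby("stage")["value"].median()
        if {"early", "middle", "late"} <= set(med.index) and \
                med["middle"] > med["early"] and med["middle"] > med["late"]:
            hits += 1
    return hits / n_runs


def rho_recovery_rate(seed: int, n_runs: int = 100, rho: float = 0.6,
                      n_boot: int = 1000) -> tuple[float, float]:
    """Recovery of a planted donor-level score correlation.

    For each run the generator plants a rank correlation ``rho`` between
    the glucocorticoid-response and apoptosis programmes; the donor-level
    Spearman of mean myofibroblast scores is estimated with its bootstrap
    CI.  Returns (fraction of runs whose CI covers rho, mean estimate).
    """
    hits = 0
    rhos = []
    for rep in range(n_runs):
        cfg = small_cohort_config(_sub_seed(seed, 40, rep),
                                  score_correlation=rho)
        cohort = generate_cohort(cfg)
        sets = cohort.gene_sets()
        scores = ucell_score(cohort.counts, sets,
                             rmax=len(cohort.counts.genes))
        labels = assign_labels(cohort.weights)
        gc = donor_mean_score(scores, cohort.spot_table, labels,
                              ["Fib_myo"], "GC_Response")
        ap = donor_mean_score(scores, cohort.spot_table, labels,
                              ["Fib_myo"], "Apoptosis")
        merged = gc.merge(ap, on="donor", suffixes=("_gc", "_ap"))
        res = spearman_bootstrap(merged["value_gc"], merged["value_ap"],
                                 n_boot=n_boot,
                                 seed=_sub_seed(seed, 41, rep))
        rhos.append(res.rho)
        if res.ci[0] <= rho <= res.ci[1]:
            hits += 1
    return hits / n_runs, float(np.mean(rhos))


def bcell_proximity_recovery(seed: int, n_runs: int = 20) -> float:
    """Recovery of OP-specific B-cell / myofibroblast co-clustering.

    Cohorts plant the B-cell + myofibroblast plug niche in OP only, with
    myofibroblasts equally sparse in every other group; success means the
    pooled median B-cell -> Fib_myo nearest-neighbour distance in OP
    undercuts every other group's.  Returns the success fraction.
    """
    from .spatialstats import nn_distances
    from .synthgrid import DEFAULT_PRIORS, _default_niches

    priors = {g: dict(v) for g, v in DEFAULT_PRIORS.items()}
    for g in ("CTD-ILD", "IPF"):
        excess = priors[g]["Fib_myo"] - priors["CTRL"]["Fib_myo"]
        priors[g]["Fib_myo"] = priors["CTRL"]["Fib_myo"]
        priors[g]["Fib_alv"] += excess
    niches = {"OP": _default_niches()["OP"]}

    hits = 0
    for rep in range(n_runs):
        cfg = small_cohort_config(_sub_seed(seed, 60, rep),
                                  celltype_priors={g: dict(v)
                                                   for g, v in priors.items()},
                                  niche_specs=niches, stage_fractions={})
        cohort = generate_cohort(cfg)
        labels = assign_labels(cohort.weights)
        dd = nn_distances(cohort.spot_table, labels, "B_cell", "Fib_myo")
        merged = dd.distances.merge(
            cohort.spot_table[["roi", "group"]].drop_duplicates(), on="roi")
        med = merged.groupby("group")["distance_um"].median()
        if med["OP"] < med.drop("OP").min():
            hits += 1
    return hits / n_runs


# ---------------------------------------------------------------------------
# sensitivity-scan robustness


def sensitivity_robustness(seed: int, n_boot: int = 1000) -> dict:
    """Threshold-scan robustness of the planted group contrast.

    Generates one cohort with the default planted elevation in the OP
    group, scans the top 10-30% percentile thresholds plus the z-score
    rule, and returns the minimum contrast estimate and the minimum
    bootstrap CI lower bound across the scan (both should sit above zero
    when the effect is robust).
    """
    cohort = generate_cohort(small_cohort_config(seed, grid_shape=(18, 18)))
    sets = cohort.gene_sets()
    scores = ucell_score(cohort.counts, sets, rmax=len(cohort.counts.genes))
    labels = assign_labels(cohort.weights)
    report, _ = sensitivity_scan(scores, cohort.spot_table, labels,
                                 numerator_labels=["Fib_myo"],
                                 denominator_labels=["Fib_myo"],
                                 contrast=("OP", "IPF"),
                                 n_boot=n_boot, seed=_sub_seed(seed, 50))
    t = report.table
    return {"min_estimate": float(t["estimate"].min()),
            "min_ci_lower": float(t["ci_lower"].min()),
            "n_thresholds": int(len(t))}
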