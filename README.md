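# nichefate

Spatial niche quantification for high-definition spatial transcriptomics
of interstitial lung disease.

Organising pneumonia (OP) is the reversible, glucocorticoid(GC)-responsive
end of the lung-fibrosis spectrum; idiopathic pulmonary fibrosis (IPF) is
the progressive end. A recurring question is whether reversibility has a
spatial signature: do GC-responsive, apoptosis-primed myofibroblasts form
localised niches in OP lesions that progressive disease lacks? This
package implements the quantitative machinery for answering that question
on HD-grid spatial data (8 µm expression bins with x/y coordinates,
grouped into ROIs nested in donors nested in disease groups), and a seeded
synthetic cohort generator that emulates the study design (CTRL / CTD-ILD
/ OP / IPF with 5/5/6/5 donors, three ROIs each), so every stage is
testable end to end without access to restricted tissue data.

## What it computes

- **Rank-based signature scores** (`nichescore.ucell_score`). Per spot and
  gene set, genes are ranked by decreasing expression (average ranks on
  ties, ranks capped at `rmax`); for a signature of size *n* with capped
  rank sum *R*, the Mann–Whitney statistic is *U′ = R − n(n+1)/2* and the
  score is *max(0, 1 − U′/(n·rmax))* ∈ [0, 1].
- **GC-sensitive classification** (`nichescore.classify_gc`). A spot is
  GC-sensitive when its GC-response score is at or above the within-sample
  (per-donor) nearest-rank 75th percentile — the top quartile — with a
  z-score rule and a top 10–30% percentile scan
  (`nichescore.sensitivity_scan`) for robustness, each contrast carrying a
  donor-resampled percentile bootstrap CI.
- **Proximity and density geometry** (`spatialstats`): per-ROI cell-type
  centroids, nearest-neighbour distance distributions between labelled
  spot populations, kernel-density maps of spot subsets, and
  distance-ordering gradients from a reference population.
- **Donor-level statistics** (`cohortstats`): ROI-weighted proportions
  (equal-weight mean of per-ROI proportions), Kruskal–Wallis (exact or
  permutation p at donor-level N), Dunn post hocs with Holm/BH adjustment,
  Wilcoxon rank-sum, Cliff's delta, donor-bootstrap Spearman correlation,
  DEG threshold filtering (adjusted p < 0.05, |log2FC| > 0.25), and a
  Wilcoxon-based TOST equivalence test with an explicit margin.
- **Stage dynamics** (`staging`): early/middle/late lesion composition
  trajectories, the GC-sensitive myofibroblast fraction per stage, and the
  apoptosis-score contrast between GC-sensitive and GC-low spots.
- **Synthetic cohorts** (`synthgrid`): seeded lattice ROIs with clustered
  lesion niches, deconvolution-style weights, negative-binomial counts
  with plantable signature effects, and a Gaussian-copula rank correlation
  between the GC-response and apoptosis programmes.

## Worked example

```sh
cd analysis
python 01_simulate_cohort.py
python 02_score_and_classify.py
```

which prints (seed 0):

```
cohort: 21 donors, 63 ROIs, 36288 spots, 120 genes
...
flagged 25.1% of spots (per-donor top-25% rule on GC_Response)
donor-level GC-sensitive Fib_myo proportion by group:
          mean  median
group
CTD-ILD  0.198   0.171
CTRL     0.310   0.288
IPF      0.175   0.183
OP       0.642   0.647
```

The per-donor flag rate is 25% by construction; the *myofibroblast*
GC-sensitive proportion is not — it rises far above the 25% baseline only
in OP, where the generator plants a 2.5-fold GC-response elevation in
myofibroblasts. `03_sensitivity_scan.py` shows the OP − IPF contrast
stays positive with bootstrap CIs above zero at every threshold in the
top 10–30% scan; `05_donor_statistics.py` runs the Kruskal–Wallis/Dunn
battery (OP vs IPF Holm-adjusted p ≈ 0.003, Cliff's δ = −1) and recovers
the planted GC–apoptosis coupling (donor-level Spearman ρ ≈ 0.79, 95%
bootstrap CI [0.50, 0.94]); `06_stage_dynamics.py` shows the middle-stage
GC-sensitive peak and monotone AT2 recovery. A full config-driven run with
a reproducibility manifest is available as
`nichefate-run --config <yaml> --out-dir <dir>`.

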