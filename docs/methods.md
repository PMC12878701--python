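# Methods

## Data model

A cohort is four nested levels: disease group → donor → ROI → spot. A spot
is one 8 µm expression bin on a square lattice with coordinates in µm
(origin at the ROI's top-left, x rightward, y downward); the pitch is
metadata, never inferred from coordinates. Spots carry a genes × spots
count matrix, per-spot cell-type weights (deconvolution output, consumed
as input, rows summing to 1 within 1e-6), and optional per-ROI lesion
stage labels (early / middle / late), which are consumed, never inferred
from histology. All on-disk formats are plain text: TSV tables,
MatrixMarket counts with one-entry-per-line index files, GMT gene sets,
YAML configs.

## Signature scoring

Scores are rank-based (Mann–Whitney U). Within each spot, genes are ranked
by decreasing expression with average ranks for ties; ranks above the cap
`rmax` — and signature genes absent from the gene index — are set to
`rmax + 1`. For a signature of size n with capped rank sum R,
U′ = R − n(n+1)/2 and score = max(0, 1 − U′/(n·rmax)). The score is 1
exactly when the signature occupies the top n ranks; when every signature
gene is beyond the cap the score reaches its floor (n−1)/(2·rmax)
(≈ 0.002 at n = 8, rmax = 1500), effectively but not identically zero — a
property of the U′ normalisation, preserved here rather than patched. A
signature with no genes in the matrix at all scores NaN with a warning.
`rmax` defaults to 1500 (panel-scale data should set it to the gene count,
as the analysis drivers do; it must be at least the largest signature).
Being rank-based, scores are invariant under any strictly increasing
transform of a spot's expression vector.

## GC-sensitive classification

The threshold rule operates within scope units (default: donor, i.e.
per-sample, for cross-sample comparability; ROI scope is available).
Percentile mode uses the inclusive nearest-rank empirical quantile
(sorted values, index ⌈p/100·n⌉), flagging spots with score ≥ threshold;
this keeps the flag-set definition unambiguous under ties, at the price
that a fully tied scope flags everything (such scopes are marked
degenerate in the metadata, as are scopes with fewer than 4 eligible
spots). The default percentile is 75 (top quartile). Z-score mode
standardises within scope and flags z ≥ 0.674, the upper-quartile point of
a normal, chosen to be comparable to the top-25% rule; the cutoff is
configurable since no canonical value exists. The threshold may be
computed over all scored spots per donor (default) or restricted to a
label subset via `restrict_to`, which restricts both thresholding and
flagging. The default matters: thresholding within the same subset used as
both numerator and denominator would pin every donor's GC-sensitive
proportion at exactly 25% and erase any group contrast; pooling all spots
per donor lets cell types with elevated programme activity capture more
than their share of the top quartile, which is the quantity the donor
comparisons need.

## Donor-level statistics

All hypothesis tests run at the donor level. The donor statistic is
ROI-weighted: each ROI with at least `min_spots` (default 10) denominator
spots contributes its proportion with equal weight, and the donor value is
the mean (a pooled-spots alternative is available behind a flag); ROIs
below the floor and donors with no eligible ROI are excluded with logged
warnings, never silently.

Kruskal–Wallis uses the tie-corrected H. The p-value adapts to N: exact
enumeration of all group assignments for N ≤ 12; a seeded Monte-Carlo
permutation p (2000 label shuffles, add-one estimator) for N ≤ 50; the
chi-square approximation beyond. The chi-square p is conservative at
donor-level sizes (empirical size ≈ 0.037 at α = 0.05 for the 5/5/6/5
layout) and is therefore reported alongside, not used as, the primary p in
that regime; with the permutation p the empirical size is ≈ 0.047–0.052.
Dunn post hocs use pooled-rank z statistics with tie correction, two-sided
normal p-values, Holm (default) or BH adjustment within the contrast
family, and Cliff's delta attached per contrast. Wilcoxon rank-sum is
exact when min(n, m) ≤ 8 without ties, otherwise normal with continuity
and tie correction; the method used is recorded. Spearman correlations use
average ranks, an exact permutation p for n ≤ 7 (t approximation
otherwise), and a donor-resampled percentile bootstrap CI (default 1000
replicates); degenerate resamples (zero variance) are dropped from the
percentile computation, and zero variance in the data itself yields an
explicit undefined result. The bootstrap resamples donors, not spots,
matching the donor-level design. BH and Holm adjustments are delegated to
statsmodels. TOST equivalence runs two one-sided Wilcoxon tests against a
caller-supplied margin in pooled-SD units; no default margin is asserted.

## Spatial geometry

All distances are Euclidean in µm and strictly within-ROI (ROIs are
disjoint tissue fields). Nearest-neighbour search uses a KD-tree with an
exactness contract (checked against an O(n²) oracle); when source and
target are the same population the spot's own location is excluded.
Density maps use an isotropic Gaussian kernel with a scalar bandwidth in
µm, defaulting to Silverman's two-dimensional rule (pooled marginal SD ×
n^(−1/6), floored at half a cell for degenerate clouds); an isotropic
kernel keeps the bandwidth physically interpretable and remains defined
for collinear spot sets, where a full-covariance kernel is singular. The
grid spans the bounding box padded by three bandwidths; in-grid mass is
~1, with [0.95, 1.05] tolerated for edge and discretisation leakage.
Distance orderings assign ascending average ranks per ROI.

## Synthetic cohorts

The generator emulates the study design it is tested against: groups
CTRL / CTD-ILD / OP / IPF with 5/5/6/5 donors, 3 ROIs per donor (63 ROIs),
24 × 24 bins per ROI at 8 µm pitch by default. Group-level cell-type
priors follow the expected biology (CTRL alveolar-rich; OP
myofibroblast- and B-cell-rich; IPF myofibroblast-rich, B-cell-poor;
CTD-ILD transitional). Lesion niches are Poisson-placed centres (at least
one per ROI) with Gaussian composition blending by distance to the nearest
centre — the simplest mechanism that yields clustered cores with
transitional rims: an intra-alveolar plug (myofibroblasts + B cells +
inflammatory cells) in OP, a fibroblast focus in IPF, interstitial
thickening in CTD-ILD. OP ROIs are staged early/middle/late (one of each
per donor under the default equal fractions, by largest-remainder
apportionment then per-donor shuffle) with stage-specific composition:
AT2 rises monotonically (0.08 → 0.12 → 0.26), the inflammatory aggregate
falls (0.38 → 0.26 → 0.15).

Counts are negative binomial with a shared baseline mean (0.3, emulating
sparse 8 µm bins) and dispersion 1.5. Planted effects multiply
signature-gene means per (group, cell type, signature): by default a
2.5-fold GC-response and 2-fold apoptosis elevation in OP myofibroblasts,
collagen elevation in the fibrotic groups, B-cell-programme elevation in
OP B cells, and an extra 1.8-fold GC-response factor in middle-stage OP
myofibroblasts. The GC-response and apoptosis programmes share latent
activities drawn from a Gaussian copula whose Pearson parameter is set
from the target Spearman correlation (r = 2·sin(πρ/6); default ρ = 0.6)
with a donor-level variance share of 0.3, so the planted coupling is
recoverable both across spots and across donor means; latent z-scores
multiply the programme-gene means by exp(0.6·z) within myofibroblast
spots and are recorded in the truth table. Deconvolution-style weights are
Dirichlet draws peaked on the true type (concentration 30, giving winning
weights ≈ 0.8 and a near-zero "unknown" rate, consistent with the
high-confidence deconvolution the pipeline assumes). One integer seed
drives everything; per-ROI and per-donor substreams are split by
seed-sequence spawn keys, so output is bit-identical across runs.

What the generator does **not** emulate: spatial autocorrelation of
expression beyond niche composition, library-size variation across spots,
gene–gene correlation outside the two copula-coupled programmes, segment
boundary effects, and deconvolution error structure. Passing tests
therefore demonstrate that the pipeline recovers what it is pointed at
under a faithful but idealised noise model, not that real-tissue
confounders are handled.

## Calibration and recovery experiments

`nichefate.evaluation` (shared by the test suite and
`scripts/acceptance.py`) fixes the problem sizes: classification rate at
21 samples × 1000 spots; Kruskal–Wallis size at 2000 null replications of
the 5/5/6/5 layout; bootstrap coverage at 500 replications of 30 normal
donor values; recovery experiments at 100 seeded runs each on reduced
14 × 14-bin cohorts with a 40-gene background panel (18 × 18 for the
threshold scan), sizes at which the planted effects are comfortably
detectable and the full battery runs in minutes on one CPU. The B-cell
co-clustering experiment uses 20 runs with the plug niche granted to OP
only and myofibroblast abundance equalised across disease groups, since
with the default abundances the 8 µm lattice pitch saturates the median
nearest-neighbour distance in every myofibroblast-rich group.

## Known limitations

- The permutation/exact p-value regimes make Kruskal–Wallis p-values
  seed-dependent (to bootstrap-like Monte-Carlo error) at donor-level N.
- The nearest-rank threshold guarantees at least one flagged spot per
  scope, so tiny scopes overestimate flag rates; they are marked
  unreliable rather than dropped.
- Stage comparisons treat (donor, stage) means as observations; a donor
  contributing ROIs to several stages induces dependence the rank tests
  ignore.
- The TOST equivalence wrapper operates on the standardised difference
  with a user-chosen margin; it makes no attempt to standardise "pattern
  level" beyond that.
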