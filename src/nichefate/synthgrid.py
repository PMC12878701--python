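"""Seeded generator of synthetic HD-grid cohorts.

Emulates the data structure of a high-definition spatial transcriptomics
study of interstitial lung disease: four disease groups (healthy control,
connective-tissue-disease ILD, organising pneumonia, idiopathic pulmonary
fibrosis) with 5/5/6/5 donors, three regions of interest (ROIs) per donor,
and one square lattice of 8 um expression bins ("spots") per ROI.

Each ROI carries clustered lesion niches (intra-alveolar plugs, fibroblast
foci) produced by Gaussian composition blending around randomly placed
lesion centres; per-spot cell-type identities are drawn from the blended
composition and softened into deconvolution-style weight vectors.  Counts
are negative-binomial with signature-gene means multiplied by configurable
group x cell-type x programme fold effects, and the glucocorticoid-response
and apoptosis programmes share a latent Gaussian copula so their scores
carry a plantable rank correlation at both the spot and the donor level.

All randomness flows from one integer seed; per-ROI and per-donor
substreams are derived by counter-based seed-sequence splitting, so output
is bit-identical across runs and independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .spotio import CountsMatrix, GeneSetCollection, write_celltype_weights, \
    write_counts_mtx, write_gmt, write_spot_table, write_stage_labels

COMPOSITION_TOL = 1e-9

CELL_TYPES = (
    "AT2", "B_cell", "Bronchial_epi", "Endothelial", "Fib_alv",
    "Fib_myo", "Lymphocyte", "Macrophage", "Neutrophil",
)

DEFAULT_GROUPS = ("CTRL", "CTD-ILD", "OP", "IPF")
DEFAULT_DONORS = (5, 5, 6, 5)

DEFAULT_SIGNATURES: dict[str, list[str]] = {
    "GC_Response": ["NR3C1", "FKBP5", "TSC22D3", "KLF9", "ZBTB16", "PER1",
                    "DDIT4", "SGK1"],
    "Apoptosis": ["CASP3", "CASP8", "CASP9", "BCL2L11", "BAX", "TP53BP2",
                  "PMAIP1", "BID"],
    "Collagen_Biosynthesis": ["COL1A1", "COL1A2", "COL3A1", "COL5A1",
                              "CTHRC1", "FN1", "POSTN", "SPARC"],
    "Inflammation": ["IL6", "CXCL8", "CCL2", "TNF", "IL1B", "CXCL9",
                     "CCL19", "PTGS2"],
    "Bcell_Differentiation": ["CD19", "MS4A1", "CD79A", "CD79B", "IGKC",
                              "IGHG3", "JCHAIN", "MZB1"],
}

DEFAULT_PRIORS: dict[str, dict[str, float]] = {
    "CTRL": {"AT2": 0.28, "Fib_alv": 0.20, "Macrophage": 0.12,
             "Endothelial": 0.14, "Bronchial_epi": 0.08, "Lymphocyte": 0.06,
             "B_cell": 0.02, "Neutrophil": 0.03, "Fib_myo": 0.07},
    "CTD-ILD": {"AT2": 0.18, "Fib_alv": 0.14, "Fib_myo": 0.18,
                "Macrophage": 0.14, "Endothelial": 0.12, "Bronchial_epi": 0.07,
                "Lymphocyte": 0.09, "B_cell": 0.04, "Neutrophil": 0.04},
    "OP": {"AT2": 0.12, "Fib_alv": 0.08, "Fib_myo": 0.22, "Macrophage": 0.16,
           "Endothelial": 0.09, "Bronchial_epi": 0.06, "Lymphocyte": 0.10,
           "B_cell": 0.12, "Neutrophil": 0.05},
    "IPF": {"AT2": 0.10, "Fib_alv": 0.06, "Fib_myo": 0.30, "Macrophage": 0.14,
            "Endothelial": 0.10, "Bronchial_epi": 0.14, "Lymphocyte": 0.08,
            "B_cell": 0.03, "Neutrophil": 0.05},
}


@dataclass(frozen=True)
class NicheSpec:
    """A clustered lesion niche: centres with Gaussian composition blending.

    ``centres_per_roi`` is the Poisson mean for the number of lesion
    centres (at least one centre is always placed so a configured niche is
    never silently absent); ``radius_um`` is the Gaussian blending radius.
    """

    name: str
    composition: Mapping[str, float]
    centres_per_roi: float = 2.0
    radius_um: float = 60.0
    anchor_celltypes: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.radius_um <= 0:
            raise ConfigError(f"niche '{self.name}': radius must be > 0")
        total = sum(self.composition.values())
        if abs(total - 1.0) > COMPOSITION_TOL:
            raise ConfigError(
                f"niche '{self.name}': composition sums to {total}, not 1"
            )
        if any(v < 0 for v in self.composition.values()):
            raise ConfigError(f"niche '{self.name}': negative composition")


def _default_niches() -> dict[str, list[NicheSpec]]:
    return {
        "OP": [NicheSpec(
            name="intra_alveolar_plug",
            anchor_celltypes=("Fib_myo", "B_cell"),
            composition={"Fib_myo": 0.40, "B_cell": 0.20, "Macrophage": 0.15,
                         "Lymphocyte": 0.12, "Neutrophil": 0.05, "AT2": 0.03,
                         "Fib_alv": 0.02, "Endothelial": 0.02,
                         "Bronchial_epi": 0.01})],
        "IPF": [NicheSpec(
            name="fibroblast_focus",
            anchor_celltypes=("Fib_myo",),
            composition={"Fib_myo": 0.55, "Fib_alv": 0.05, "Macrophage": 0.10,
                         "Endothelial": 0.05, "Bronchial_epi": 0.15,
                         "AT2": 0.04, "Lymphocyte": 0.03, "B_cell": 0.01,
                         "Neutrophil": 0.02})],
        "CTD-ILD": [NicheSpec(
            name="interstitial_thickening",
            anchor_celltypes=("Fib_myo",),
            composition={"Fib_myo": 0.35, "Fib_alv": 0.15, "Macrophage": 0.15,
                         "Lymphocyte": 0.10, "AT2": 0.10, "Endothelial": 0.08,
                         "B_cell": 0.03, "Bronchial_epi": 0.02,
                         "Neutrophil": 0.02})],
    }


def _default_signature_effects() -> dict[tuple[str, str, str], float]:
    return {
        ("OP", "Fib_myo", "GC_Response"): 2.5,
        ("OP", "Fib_myo", "Apoptosis"): 2.0,
        ("OP", "Fib_myo", "Collagen_Biosynthesis"): 2.0,
        ("OP", "B_cell", "Bcell_Differentiation"): 3.0,
        ("IPF", "Fib_myo", "Collagen_Biosynthesis"): 2.5,
        ("CTD-ILD", "Fib_myo", "Collagen_Biosynthesis"): 1.5,
        ("OP", "Macrophage", "Inflammation"): 2.0,
        ("CTD-ILD", "Macrophage", "Inflammation"): 1.8,
    }


def _default_stage_composition() -> dict[str, dict[str, float]]:
    # Early: B-cell/inflammatory infiltration; middle: myofibroblast plugs;
    # late: AT2 restoration with residual fibrosis.  AT2 rises monotonically,
    # the inflammatory aggregate falls monotonically.
    return {
        "early": {"B_cell": 0.18, "Macrophage": 0.18, "Lymphocyte": 0.12,
                  "Neutrophil": 0.08, "Fib_myo": 0.12, "AT2": 0.08,
                  "Fib_alv": 0.08, "Endothelial": 0.10, "Bronchial_epi": 0.06},
        "middle": {"B_cell": 0.08, "Macrophage": 0.14, "Lymphocyte": 0.08,
                   "Neutrophil": 0.04, "Fib_myo": 0.30, "AT2": 0.12,
                   "Fib_alv": 0.06, "Endothelial": 0.12, "Bronchial_epi": 0.06},
        "late": {"B_cell": 0.03, "Macrophage": 0.08, "Lymphocyte": 0.05,
                 "Neutrophil": 0.02, "Fib_myo": 0.22, "AT2": 0.26,
                 "Fib_alv": 0.10, "Endothelial": 0.16, "Bronchial_epi": 0.08},
    }


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults reproduce the study design being emulated: groups
    CTRL/CTD-ILD/OP/IPF with 5/5/6/5 donors, 3 ROIs per donor, an 8 um bin
    pitch, organising-pneumonia ROIs staged early/middle/late (one of each
    per donor), a glucocorticoid-response elevation in OP myofibroblasts,
    and a target spot/donor-level rank correlation of 0.6 between the
    glucocorticoid-response and apoptosis programmes.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    donors_per_group: tuple[int, ...] = DEFAULT_DONORS
    rois_per_donor: int = 3
    grid_shape: tuple[int, int] = (24, 24)
    bin_pitch: float = 8.0
    celltype_priors: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_PRIORS.items()})
    niche_specs: dict[str, list[NicheSpec]] = field(default_factory=_default_niches)
    signatures: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SIGNATURES.items()})
    n_background_genes: int = 80
    nb_mean: float = 0.3
    nb_dispersion: float = 1.5
    signature_effects: dict[tuple[str, str, str], float] = field(
        default_factory=_default_signature_effects)
    # per-(stage, signature) extra fold applied to stage_effect_celltypes
    stage_signature_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("middle", "GC_Response"): 1.8})
    stage_effect_celltypes: tuple[str, ...] = ("Fib_myo",)
    # latent copula between two programmes, applied within corr_celltypes
    score_correlation: float = 0.6
    corr_signatures: tuple[str, str] = ("GC_Response", "Apoptosis")
    corr_celltypes: tuple[str, ...] = ("Fib_myo",)
    latent_scale: float = 0.6
    donor_var_frac: float = 0.3
    # per-group stage fractions over ROIs; only listed groups are staged
    stage_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"OP": {"early": 1 / 3, "middle": 1 / 3,
                                        "late": 1 / 3}})
    stage_composition: dict[str, dict[str, float]] = field(
        default_factory=_default_stage_composition)
    weight_concentration: float = 30.0
    seed: int = 0

    @property
    def cell_types(self) -> tuple[str, ...]:
        names: set[str] = set()
        for comp in self.celltype_priors.values():
            names.update(comp)
        return tuple(sorted(names))

    @property
    def gene_panel(self) -> list[str]:
        genes: list[str] = []
        for members in self.signatures.values():
            genes.extend(g for g in members if g not in genes)
        genes.extend(f"BG{i:04d}" for i in range(self.n_background_genes))
        return genes

    def validate(self) -> None:
        if len(self.donors_per_group) != len(self.groups):
            raise ConfigError(
                f"donors_per_group has {len(self.donors_per_group)} entries "
                f"for {len(self.groups)} groups")
        if any(n < 0 for n in self.donors_per_group):
            raise ConfigError("donors_per_group entries must be >= 0")
        if self.bin_pitch <= 0:
            raise ConfigError("bin_pitch must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.nb_mean <= 0:
            raise ConfigError("nb_mean must be > 0")
        for g in self.groups:
            if g not in self.celltype_priors:
                raise ConfigError(f"no cell-type prior for group '{g}'")
            total = sum(self.celltype_priors[g].values())
            if abs(total - 1.0) > COMPOSITION_TOL:
                raise ConfigError(
                    f"prior for group '{g}' sums to {total}, not 1")
        for specs in self.niche_specs.values():
            for spec in specs:
                spec.validate()
        for g, fracs in self.stage_fractions.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > COMPOSITION_TOL:
                raise ConfigError(
                    f"stage fractions for group '{g}' sum to {total}, not 1")
        for stage, comp in self.stage_composition.items():
            total = sum(comp.values())
            if abs(total - 1.0) > COMPOSITION_TOL:
                raise ConfigError(
                    f"stage composition '{stage}' sums to {total}, not 1")
        if not -1.0 <= self.score_correlation <= 1.0:
            raise ConfigError("score_correlation must lie in [-1, 1]")


@dataclass
class SyntheticCohort:
    """A generated cohort: spatial backbone, weights, counts and truth.

    ``truth`` records per spot the sampled cell type, the niche membership
    weight, the stage label, and the latent programme activities (z-scores)
    used to modulate signature-gene means.
    """

    spot_table: pd.DataFrame
    weights: pd.DataFrame
    counts: CountsMatrix
    truth: pd.DataFrame
    config: CohortConfig
    # base NB means (pre-latent-modulation) for all signature genes, used
    # when a new score correlation is planted post hoc
    sig_base_means: pd.DataFrame | None = None

    def gene_sets(self) -> GeneSetCollection:
        return GeneSetCollection({k: list(v) for k, v in
                                  self.config.signatures.items()})

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "spot_table": out / "spots.tsv",
            "weights": out / "celltype_weights.tsv",
            "truth": out / "truth.tsv",
            "mtx": out / "counts.mtx",
            "genes": out / "genes.tsv",
            "spots_index": out / "spots_index.tsv",
            "gmt": out / "signatures.gmt",
            "stages": out / "stages.tsv",
        }
        write_spot_table(self.spot_table, paths["spot_table"])
        write_celltype_weights(self.weights, paths["weights"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_counts_mtx(self.counts, paths["mtx"], paths["genes"],
                         paths["spots_index"])
        write_gmt(self.gene_sets(), paths["gmt"])
        stage_df = (self.spot_table[["roi", "stage"]].drop_duplicates()
                    .reset_index(drop=True))
        write_stage_labels(stage_df, paths["stages"])
        return paths


# ---------------------------------------------------------------------------
# internals


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson r giving the requested Spearman rho."""
    return float(np.clip(2.0 * math.sin(math.pi * rho_s / 6.0), -1.0, 1.0))


def _copula_pairs(rng: np.random.Generator, n: int, pearson_r: float) -> np.ndarray:
    """n draws from a standard bivariate normal with correlation r, (n, 2)."""
    z = rng.standard_normal((n, 2))
    a = z[:, 0]
    b = pearson_r * z[:, 0] + math.sqrt(max(0.0, 1.0 - pearson_r ** 2)) * z[:, 1]
    return np.column_stack([a, b])


def _stage_plan(config: CohortConfig, group: str,
                rng: np.random.Generator) -> list[str]:
    """Stage labels for one donor's ROIs, honouring the group's fractions.

    Uses largest-remainder apportionment so a donor with 3 ROIs and equal
    fractions covers early/middle/late exactly once, then shuffles.
    """
    fracs = config.stage_fractions.get(group)
    n = config.rois_per_donor
    if not fracs:
        return ["none"] * n
    stages = list(fracs)
    quotas = np.array([fracs[s] * n for s in stages])
    counts = np.floor(quotas).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quotas - counts))
    for i in range(rem):
        counts[order[i % len(stages)]] += 1
    plan = [s for s, c in zip(stages, counts) for _ in range(int(c))]
    rng.shuffle(plan)
    return plan


def _blend_composition(base: np.ndarray, overrides: list[np.ndarray],
                       weights: list[np.ndarray]) -> np.ndarray:
    """Per-spot composition: Gaussian niche pull toward override mixtures.

    With per-spec spot weights w_i in [0, 1], the niche share is
    t = 1 - prod(1 - w_i) and the niche mixture is the w-weighted mean of
    the override compositions; the result is (1 - t) * base + t * mixture.
    """
    n = weights[0].shape[0] if weights else 0
    if not weights:
        return np.tile(base, (n, 1))
    W = np.column_stack(weights)                      # (spots, specs)
    t = 1.0 - np.prod(1.0 - W, axis=1)                # (spots,)
    denom = W.sum(axis=1)
    denom_safe = np.where(denom > 0, denom, 1.0)
    mix = (W[:, :, None] * np.stack(overrides)[None, :, :]).sum(axis=1)
    mix /= denom_safe[:, None]
    comp = (1.0 - t)[:, None] * base[None, :] + t[:, None] * mix
    comp[denom == 0] = base
    return comp / comp.sum(axis=1, keepdims=True)


def _comp_vector(comp: Mapping[str, float], cell_types: Sequence[str]) -> np.ndarray:
    return np.array([comp.get(c, 0.0) for c in cell_types], dtype=float)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(np.int32)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from one seeded configuration.

    One ROI lattice per (donor, ROI) pair; identical config + seed gives
    bit-identical output.
    """
    config.validate()
    if sum(config.donors_per_group) == 0:
        raise ConfigError("cohort has zero donors in every group")
    rows, cols = config.grid_shape
    if rows * cols == 0:
        raise ConfigError("grid_shape must have positive rows and cols")

    cell_types = config.cell_types
    genes = config.gene_panel
    gene_pos = {g: i for i, g in enumerate(genes)}
    sig_gene_idx = {s: np.array([gene_pos[g] for g in members])
                    for s, members in config.signatures.items()}
    sigA, sigB = config.corr_signatures
    pearson_r = _spearman_to_pearson(config.score_correlation)
    sd_d = math.sqrt(config.donor_var_frac)
    sd_s = math.sqrt(1.0 - config.donor_var_frac)

    all_sig_genes = [g for members in config.signatures.values() for g in members]
    all_sig_rows = np.array([gene_pos[g] for g in all_sig_genes])

    spot_frames, truth_frames = [], []
    weight_blocks, count_blocks, base_mean_blocks = [], [], []

    donor_index = 0
    roi_index = 0
    for gi, group in enumerate(config.groups):
        base_prior = _comp_vector(config.celltype_priors[group], cell_types)
        specs = config.niche_specs.get(group, [])
        for dj in range(config.donors_per_group[gi]):
            donor = f"{group}_D{dj + 1}"
            drng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(2, donor_index)))
            u_donor = _copula_pairs(drng, 1, pearson_r)[0]   # donor-level latents
            stage_plan = _stage_plan(config, group, drng)
            for rk in range(config.rois_per_donor):
                roi = f"{donor}_R{rk + 1}"
                stage = stage_plan[rk]
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=(1, roi_index)))

                # lattice of bin centres, origin top-left, y downward
                rr, cc = np.meshgrid(np.arange(rows), np.arange(cols),
                                     indexing="ij")
                x = cc.ravel() * config.bin_pitch
                y = rr.ravel() * config.bin_pitch
                n_spots = rows * cols
                spot_ids = [f"{roi}_s{i:05d}" for i in range(n_spots)]

                # composition: stage override (if staged) + niche blending
                if stage != "none" and stage in config.stage_composition:
                    base = _comp_vector(config.stage_composition[stage],
                                        cell_types)
                else:
                    base = base_prior
                overrides, wlist, wnames = [], [], []
                for spec in specs:
                    k = max(1, int(rng.poisson(spec.centres_per_roi)))
                    cx = rng.uniform(0, (cols - 1) * config.bin_pitch, size=k)
                    cy = rng.uniform(0, (rows - 1) * config.bin_pitch, size=k)
                    d2 = ((x[:, None] - cx[None, :]) ** 2
                          + (y[:, None] - cy[None, :]) ** 2).min(axis=1)
                    wlist.append(np.exp(-d2 / (2.0 * spec.radius_um ** 2)))
                    overrides.append(_comp_vector(spec.composition, cell_types))
                    wnames.append(spec.name)
                comp = _blend_composition(base, overrides, wlist) if wlist \
                    else np.tile(base, (n_spots, 1))

                # sample true cell types from the per-spot composition
                cdf = np.cumsum(comp, axis=1)
                u = rng.uniform(size=n_spots)
                type_idx = (u[:, None] > cdf).sum(axis=1)
                labels = np.array(cell_types, dtype=object)[type_idx]

                # deconvolution-style weights: Dirichlet peaked on the truth
                alpha = np.ones((n_spots, len(cell_types)))
                alpha[np.arange(n_spots), type_idx] += config.weight_concentration
                gam = rng.gamma(alpha)
                wmat = gam / gam.sum(axis=1, keepdims=True)

                # latent programme activities (copula across the two
                # designated programmes, shared donor component)
                e = _copula_pairs(rng, n_spots, pearson_r)
                lat = sd_d * u_donor[None, :] + sd_s * e
                target = np.isin(labels, config.corr_celltypes)

                # NB mean matrix with signature effects
                mean = np.full((len(genes), n_spots), config.nb_mean,
                               dtype=np.float64)
                for (g_eff, ct, sig), fold in config.signature_effects.items():
                    if g_eff != group or sig not in sig_gene_idx:
                        continue
                    mask = labels == ct
                    if mask.any():
                        mean[np.ix_(sig_gene_idx[sig], mask)] *= fold
                if stage != "none":
                    for (st, sig), fold in config.stage_signature_effects.items():
                        if st != stage or sig not in sig_gene_idx:
                            continue
                        mask = np.isin(labels, config.stage_effect_celltypes)
                        if mask.any():
                            mean[np.ix_(sig_gene_idx[sig], mask)] *= fold

                base_mean_blocks.append(mean[all_sig_rows].astype(np.float32))

                # latent modulation of the two correlated programmes
                for sig, col in ((sigA, 0), (sigB, 1)):
                    if sig in sig_gene_idx and target.any():
                        mod = np.exp(config.latent_scale * lat[target, col])
                        mean[np.ix_(sig_gene_idx[sig], target)] *= mod[None, :]

                count_blocks.append(_nb_sample(rng, mean, config.nb_dispersion))
                weight_blocks.append(wmat)

                if wlist:
                    wstack = np.column_stack(wlist)
                    niche_w = wstack.max(axis=1)
                    best = np.array(wnames, dtype=object)[wstack.argmax(axis=1)]
                    niche_name = np.where(niche_w > 0.5, best, "")
                else:
                    niche_w = np.zeros(n_spots)
                    niche_name = np.full(n_spots, "", dtype=object)
                spot_frames.append(pd.DataFrame({
                    "spot_id": spot_ids, "x_um": x.astype(float),
                    "y_um": y.astype(float), "donor": donor, "roi": roi,
                    "group": group, "stage": stage}))
                truth_frames.append(pd.DataFrame({
                    "spot_id": spot_ids, "celltype": labels,
                    "niche": niche_name, "niche_weight": niche_w,
                    "stage": stage, f"latent_{sigA}": lat[:, 0],
                    f"latent_{sigB}": lat[:, 1], "corr_target": target}))
                roi_index += 1
            donor_index += 1

    spot_table = pd.concat(spot_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    weights = pd.DataFrame(np.vstack(weight_blocks), columns=list(cell_types),
                           index=pd.Index(spot_table["spot_id"], name="spot_id"))
    counts = CountsMatrix(np.hstack(count_blocks), list(genes),
                          list(spot_table["spot_id"]))
    sig_base_means = pd.DataFrame(np.hstack(base_mean_blocks),
                                  index=all_sig_genes,
                                  columns=spot_table["spot_id"])
    return SyntheticCohort(spot_table, weights, counts, truth, config,
                           sig_base_means)


def plant_score_correlation(cohort: SyntheticCohort, sig_a: str, sig_b: str,
                            rho: float, seed: int | None = None) -> SyntheticCohort:
    """Re-plant the latent rank correlation between two programmes.

    Within the cohort's correlation-target spots, latent activities of the
    two programmes are redrawn from a Gaussian copula with the requested
    Spearman correlation (shared donor component plus spot noise, as at
    generation time) and the two programmes' gene counts are re-sampled
    from the modulated negative-binomial means.  Returns a new cohort;
    the input is not modified.
    """
    config = cohort.config
    for sig in (sig_a, sig_b):
        if sig not in config.signatures:
            raise ConfigError(f"unknown signature '{sig}'")
    if not -1.0 <= rho <= 1.0:
        raise ConfigError("rho must lie in [-1, 1]")
    if cohort.sig_base_means is None:
        raise ConfigError("cohort lacks stored base means; regenerate it")

    pearson_r = _spearman_to_pearson(rho)
    sd_d = math.sqrt(config.donor_var_frac)
    sd_s = math.sqrt(1.0 - config.donor_var_frac)
    entropy = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=(3,)))

    truth = cohort.truth.copy()
    target = truth["corr_target"].to_numpy(bool)
    donors = cohort.spot_table["donor"].to_numpy()

    lat = np.empty((len(truth), 2))
    lat[:] = _copula_pairs(rng, len(truth), pearson_r)   # spot-level noise
    for d in pd.unique(donors):
        u = _copula_pairs(rng, 1, pearson_r)[0]
        m = donors == d
        lat[m] = sd_d * u[None, :] + sd_s * lat[m]

    truth[f"latent_{sig_a}"] = lat[:, 0]
    truth[f"latent_{sig_b}"] = lat[:, 1]

    gene_pos = {g: i for i, g in enumerate(cohort.counts.genes)}
    new_counts = cohort.counts.dense().copy()
    for sig, col in ((sig_a, 0), (sig_b, 1)):
        rows_idx = np.array([gene_pos[g] for g in config.signatures[sig]])
        base = cohort.sig_base_means.loc[config.signatures[sig]].to_numpy(float)
        mean = base.copy()
        if target.any():
            mod = np.exp(config.latent_scale * lat[target, col])
            mean[:, target] *= mod[None, :]
        new_counts[rows_idx] = _nb_sample(rng, mean, config.nb_dispersion)

    counts = CountsMatrix(new_counts, list(cohort.counts.genes),
                          list(cohort.counts.spots))
    return SyntheticCohort(cohort.spot_table, cohort.weights, counts, truth,
                           replace(config, score_correlation=rho),
                           cohort.sig_base_means)
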