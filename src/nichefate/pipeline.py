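"""End-to-end pipeline orchestration from a single YAML config.

Stages (each gated on its config block being present) run in dependency
order: simulate -> score -> classify -> sensitivity -> proximity ->
stats -> staging.  Every run emits a machine-readable manifest listing the
config snapshot, the seed, and a SHA-256 checksum per output file; reruns
with an identical config and seed reproduce identical checksums.

A failing stage aborts the run with the stage named; files written by the
failing stage are retained with a ``.partial`` suffix.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohortstats import dunn_posthoc, kruskal_wallis, roi_weighted_proportion, \
    test_results_frame
from .errors import ConfigError, NicheFateError
from .nichescore import GCThresholdRule, assign_labels, classify_gc, \
    sensitivity_scan, ucell_score
from .spatialstats import nn_distances
from .spotio import read_celltype_weights, read_counts_mtx, read_gmt, \
    read_spot_table
from .staging import stage_composition, stage_gc_dynamics
from .synthgrid import CohortConfig, NicheSpec, generate_cohort

logger = logging.getLogger(__name__)


def cohort_config_from_dict(d: dict, seed: int | None = None) -> CohortConfig:
    """Build a CohortConfig from a YAML-style mapping.

    Unknown keys raise a ConfigError naming the key.  Effect tables use
    pipe-joined string keys (``group|celltype|signature`` and
    ``stage|signature``).
    """
    kwargs: dict = {}
    valid = set(CohortConfig.__dataclass_fields__)
    for key, val in d.items():
        if key not in valid:
            raise ConfigError(f"simulate.{key}: unknown cohort option")
        if key in ("groups", "donors_per_group", "grid_shape",
                   "stage_effect_celltypes", "corr_signatures",
                   "corr_celltypes"):
            val = tuple(val)
        elif key == "signature_effects":
            val = {tuple(k.split("|")): float(v) for k, v in val.items()}
        elif key == "stage_signature_effects":
            val = {tuple(k.split("|")): float(v) for k, v in val.items()}
        elif key == "niche_specs":
            val = {g: [NicheSpec(**spec) for spec in specs]
                   for g, specs in val.items()}
        kwargs[key] = val
    if seed is not None:
        kwargs["seed"] = seed
    return CohortConfig(**kwargs)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str
    stages_run: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True,
                                         default=str), encoding="utf-8")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Execute the configured stages and return the run manifest."""
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("pipeline config must be a mapping")
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    collector = _WarningCollector()
    logging.getLogger("nichefate").addHandler(collector)
    manifest = RunManifest(config=config, seed=seed, version=__version__)
    stage_files: list[Path] = []

    def _register(*paths: Path) -> None:
        stage_files.extend(paths)

    def _finish_stage(name: str) -> None:
        for p in stage_files:
            if p.exists():
                manifest.checksums[p.name] = _sha256(p)
        manifest.stages_run.append(name)
        stage_files.clear()

    state: dict = {}
    stage = "config"
    try:
        # ---- simulate or load inputs -----------------------------------
        if "simulate" in config:
            stage = "simulate"
            cc = cohort_config_from_dict(config["simulate"] or {}, seed=seed)
            cohort = generate_cohort(cc)
            paths = cohort.write(out / "cohort")
            _register(*paths.values())
            state.update(spot_table=cohort.spot_table, weights=cohort.weights,
                         counts=cohort.counts, sets=cohort.gene_sets())
            _finish_stage(stage)
        elif "inputs" in config:
            stage = "inputs"
            inp = config["inputs"]
            for key in ("spots", "weights", "counts", "genes", "spots_index"):
                if key not in inp:
                    raise ConfigError(f"inputs.{key}: required path missing")
            state["spot_table"] = read_spot_table(inp["spots"])
            state["weights"] = read_celltype_weights(inp["weights"])
            state["counts"] = read_counts_mtx(inp["counts"], inp["genes"],
                                              inp["spots_index"])
            if "gmt" in inp:
                state["sets"] = read_gmt(inp["gmt"])
            _finish_stage(stage)
        else:
            raise ConfigError("config needs a 'simulate' or 'inputs' block")

        # ---- score -----------------------------------------------------
        if "score" in config:
            stage = "score"
            sc = config["score"] or {}
            if "sets" not in state:
                raise ConfigError("score: no gene sets available; provide "
                                  "inputs.gmt or a simulate block")
            rmax = int(sc.get("rmax", 1500))
            scores = ucell_score(state["counts"], state["sets"], rmax=rmax)
            state["scores"] = scores
            p = out / "signature_scores.tsv"
            scores.scores.to_csv(p, sep="\t")
            _register(p)
            _finish_stage(stage)

        # ---- labels + classification ----------------------------------
        if "classify" in config:
            stage = "classify"
            if "scores" not in state:
                raise ConfigError("classify requires the score stage")
            cl = config["classify"] or {}
            labels = assign_labels(state["weights"],
                                   min_weight=float(cl.get("min_weight", 0.4)))
            state["labels"] = labels
            rule = GCThresholdRule(
                mode=cl.get("mode", "percentile"),
                percentile=float(cl.get("percentile", 75.0)),
                z_cutoff=float(cl.get("z_cutoff", 0.674)),
                scope=cl.get("scope", "donor"))
            cls = classify_gc(state["scores"], state["spot_table"], rule,
                              signature=cl.get("signature", "GC_Response"),
                              restrict_to=cl.get("restrict_to"),
                              labels=labels)
            state["classification"] = cls
            p1, p2 = out / "labels.tsv", out / "classification.tsv"
            labels.to_csv(p1, sep="\t")
            cls_df = cls.flags.to_frame()
            cls_df.to_csv(p2, sep="\t")
            _register(p1, p2)
            _finish_stage(stage)

        # ---- sensitivity scan -----------------------------------------
        if "sensitivity" in config:
            stage = "sensitivity"
            sv = config["sensitivity"] or {}
            report, _ = sensitivity_scan(
                state["scores"], state["spot_table"], state["labels"],
                numerator_labels=sv.get("numerator", ["Fib_myo"]),
                denominator_labels=sv.get("denominator", ["Fib_myo"]),
                contrast=tuple(sv.get("contrast", ("OP", "IPF"))),
                percentiles=sv.get("percentiles", (70, 75, 80, 85, 90)),
                n_boot=int(sv.get("n_boot", 1000)), seed=seed)
            p = out / "sensitivity.tsv"
            report.table.to_csv(p, sep="\t", index=False)
            _register(p)
            _finish_stage(stage)

        # ---- proximity -------------------------------------------------
        if "proximity" in config:
            stage = "proximity"
            px = config["proximity"] or {}
            pairs = px.get("pairs", [["B_cell", "Fib_myo"]])
            frames = []
            for src, tgt in pairs:
                dd = nn_distances(state["spot_table"], state["labels"],
                                  src, tgt)
                t = dd.distances.assign(source=src, target=tgt)
                frames.append(t)
            p = out / "nn_distances.tsv"
            pd.concat(frames, ignore_index=True).to_csv(p, sep="\t",
                                                        index=False)
            _register(p)
            _finish_stage(stage)

        # ---- donor-level stats ----------------------------------------
        if "stats" in config:
            stage = "stats"
            stt = config["stats"] or {}
            summary = roi_weighted_proportion(
                state["classification"], state["spot_table"], state["labels"],
                numerator_labels=stt.get("numerator", ["Fib_myo"]),
                denominator_labels=stt.get("denominator", ["Fib_myo"]),
                min_spots=int(stt.get("min_spots", 10)))
            groups = {g: sub["value"].to_numpy()
                      for g, sub in summary.groupby("group")}
            results = [kruskal_wallis(groups)]
            results += dunn_posthoc(groups, adjust=stt.get("adjust", "holm"))
            p1, p2 = out / "donor_summary.tsv", out / "tests.tsv"
            summary.to_csv(p1, sep="\t", index=False)
            test_results_frame(results).to_csv(p2, sep="\t", index=False)
            _register(p1, p2)
            _finish_stage(stage)

        # ---- staging ---------------------------------------------------
        if "staging" in config:
            stage = "staging"
            comp = stage_composition(state["spot_table"], state["labels"])
            gc = stage_gc_dynamics(state["classification"],
                                   state["spot_table"], state["labels"],
                                   state["scores"])
            p1 = out / "stage_composition.tsv"
            p2 = out / "stage_gc_fraction.tsv"
            p3 = out / "stage_apoptosis.tsv"
            comp.composition.to_csv(p1, sep="\t", index=False)
            gc.gc_fraction.to_csv(p2, sep="\t", index=False)
            gc.apoptosis_contrast.to_csv(p3, sep="\t", index=False)
            _register(p1, p2, p3)
            _finish_stage(stage)
    except NicheFateError as exc:
        for p in stage_files:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise type(exc)(f"stage '{stage}': {exc}") from exc
    finally:
        logging.getLogger("nichefate").removeHandler(collector)

    manifest.warnings = collector.messages
    manifest.write(out / "manifest.json")
    return manifest


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="nichefate-run",
        description="Run the spatial niche quantification pipeline from a "
                    "YAML config")
    parser.add_argument("--config", required=True)
    parser.add_argument("--out-dir", required=True)
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("--log-level", default="INFO")
    args = parser.parse_args(argv)
    logging.basicConfig(level=getattr(logging, args.log_level.upper()))
    manifest = run_pipeline(args.config, args.out_dir, seed=args.seed)
    print(f"pipeline complete: {len(manifest.stages_run)} stages, "
          f"{len(manifest.checksums)} outputs, "
          f"{len(manifest.warnings)} warnings")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
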