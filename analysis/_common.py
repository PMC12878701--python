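"""Shared paths and loaders for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

from nichefate.nichescore import SignatureScoreMatrix
from nichefate.spotio import read_celltype_weights, read_counts_mtx, \
    read_gmt, read_spot_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT = RESULTS / "cohort"
SEED = 0


def load_cohort_files():
    spot_table = read_spot_table(COHORT / "spots.tsv")
    weights = read_celltype_weights(COHORT / "celltype_weights.tsv")
    counts = read_counts_mtx(COHORT / "counts.mtx", COHORT / "genes.tsv",
                             COHORT / "spots_index.tsv")
    sets = read_gmt(COHORT / "signatures.gmt")
    return spot_table, weights, counts, sets


def load_scores() -> SignatureScoreMatrix:
    import json
    df = pd.read_csv(RESULTS / "signature_scores.tsv", sep="\t",
                     index_col="spot_id")
    meta = json.loads((RESULTS / "signature_scores.meta.json").read_text())
    return SignatureScoreMatrix(df, rmax=int(meta["rmax"]))


def load_labels() -> pd.DataFrame:
    return pd.read_csv(RESULTS / "labels.tsv", sep="\t", index_col="spot_id")
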