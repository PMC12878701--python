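"""Score spots, label cell types, and flag GC-sensitive spots.

Reads the cohort written by 01, computes rank-based signature scores for
the five programmes, assigns discrete cell-type labels from the
deconvolution weights, and classifies GC-sensitive spots with the default
per-donor top-25% rule.  Writes scores, labels, the classification and the
donor-level GC-sensitive myofibroblast proportions under results/.
"""

import json

from _common import RESULTS, load_cohort_files

from nichefate.cohortstats import roi_weighted_proportion
from nichefate.nichescore import GCThresholdRule, assign_labels, classify_gc, \
    ucell_score


def main() -> None:
    spot_table, weights, counts, sets = load_cohort_files()
    rmax = len(counts.genes)
    scores = ucell_score(counts, sets, rmax=rmax)
    labels = assign_labels(weights)
    cls = classify_gc(scores, spot_table, GCThresholdRule())

    scores.scores.to_csv(RESULTS / "signature_scores.tsv", sep="\t")
    (RESULTS / "signature_scores.meta.json").write_text(
        json.dumps({"rmax": rmax}))
    labels.to_csv(RESULTS / "labels.tsv", sep="\t")
    cls.flags.to_frame().to_csv(RESULTS / "classification.tsv", sep="\t")

    summary = roi_weighted_proportion(cls, spot_table, labels,
                                      ["Fib_myo"], ["Fib_myo"])
    summary.to_csv(RESULTS / "donor_summary.tsv", sep="\t", index=False)

    print(f"flagged {cls.flags.mean():.1%} of spots "
          f"(per-donor top-25% rule on GC_Response)")
    print(f"unknown labels: {(labels['label'] == 'unknown').mean():.2%}")
    print("donor-level GC-sensitive Fib_myo proportion by group:")
    print(summary.groupby("group")["value"].agg(["mean", "median"]).round(3))


if __name__ == "__main__":
    main()
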