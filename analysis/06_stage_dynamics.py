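"""Stage-resolved lesion dynamics in the organising-pneumonia group.

Tracks composition (AT2, inflammatory aggregate, myofibroblasts) across
early / middle / late lesion stages, the GC-sensitive myofibroblast
fraction per stage, and the apoptosis-score contrast between GC-sensitive
and GC-low myofibroblast spots.
"""

import pandas as pd

from _common import RESULTS, load_cohort_files, load_labels, load_scores

from nichefate.nichescore import ClassificationResult, GCThresholdRule
from nichefate.staging import stage_composition, stage_gc_dynamics


def main() -> None:
    spot_table, _, _, _ = load_cohort_files()
    scores, labels = load_scores(), load_labels()
    flags = pd.read_csv(RESULTS / "classification.tsv", sep="\t",
                        index_col="spot_id")["gc_sensitive"]
    cls = ClassificationResult(flags, GCThresholdRule(),
                               pd.Series(dtype=float))

    comp = stage_composition(spot_table, labels)
    comp.composition.to_csv(RESULTS / "stage_composition.tsv", sep="\t",
                            index=False)
    medians = (comp.composition.groupby(["class", "stage"])["proportion"]
               .median().unstack()[["early", "middle", "late"]].round(3))
    print("median composition by stage (OP ROIs):")
    print(medians)
    for res in comp.tests:
        print(f"  {res.extras['class']}: KW p = {res.p:.4f}, "
              f"p_BH = {res.p_adjusted:.4f}")

    gc = stage_gc_dynamics(cls, spot_table, labels, scores)
    gc.gc_fraction.to_csv(RESULTS / "stage_gc_fraction.tsv", sep="\t",
                          index=False)
    gc.apoptosis_contrast.to_csv(RESULTS / "stage_apoptosis.tsv", sep="\t",
                                 index=False)
    frac = (gc.gc_fraction.groupby("stage")["value"].median()
            [["early", "middle", "late"]].round(3))
    print("median GC-sensitive Fib_myo fraction by stage:")
    print(frac.to_string())
    for res in gc.tests:
        if res.test == "wilcoxon_rank_sum":
            print(f"  apoptosis GC-sensitive vs GC-low "
                  f"({res.extras['stage']}): p_BH = {res.p_adjusted:.4f}, "
                  f"delta = {res.effect_size:+.2f}")


if __name__ == "__main__":
    main()
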