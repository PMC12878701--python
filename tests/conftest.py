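import logging

import pytest

from nichefate.nichescore import assign_labels, ucell_score
from nichefate.synthgrid import CohortConfig, generate_cohort

logging.getLogger("nichefate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """One reduced-size cohort shared by read-only tests."""
    cfg = CohortConfig(grid_shape=(10, 10), n_background_genes=40, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def scored_cohort(small_cohort):
    """The small cohort with scores and discrete labels attached."""
    scores = ucell_score(small_cohort.counts, small_cohort.gene_sets(),
                         rmax=len(small_cohort.counts.genes))
    labels = assign_labels(small_cohort.weights)
    return small_cohort, scores, labels
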