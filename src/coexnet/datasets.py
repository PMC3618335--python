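"""Published summary statistics of the reference study.

The package's default shapes emulate a microarray study of 272 transcripts
under (partial) eQTL control, measured in muscle on 56 half-sib animals with
an ultimate-pH phenotype.  The inferred partial-correlation network had 272
nodes and 4,690 edges, and modularity clustering gave seven clusters; each
cluster was checked against a bibliographic pathway database, which accepted
("called eligible") a subset of each cluster's genes and placed most of them
in a single biological network.  Those printed per-cluster counts are kept
here as reference inputs for arithmetic cross-checks; they are not outputs
of this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "STUDY_N_GENES",
    "STUDY_N_SAMPLES",
    "STUDY_EDGE_COUNT",
    "STUDY_HUB_DEGREE_THRESHOLD",
    "STUDY_BETWEENNESS_THRESHOLD",
    "study_cluster_summary",
]

STUDY_N_GENES = 272
STUDY_N_SAMPLES = 56
STUDY_EDGE_COUNT = 4690
STUDY_HUB_DEGREE_THRESHOLD = 26       # inclusive; 21 hubs in the study
STUDY_BETWEENNESS_THRESHOLD = 350.0   # strict; 25 high-betweenness genes

_CLUSTER_ROWS = [
    # cluster, n_genes, n_eligible, pct_eligible_in_same_network
    (1, 33, 24, 71),
    (2, 44, 28, 93),
    (3, 58, 38, 71),
    (4, 28, 17, 94),
    (5, 41, 30, 80),
    (6, 28, 19, 84),
    (7, 40, 26, 88),
]


def study_cluster_summary() -> pd.DataFrame:
    """Per-cluster gene counts and pathway-eligibility percentages.

    Columns: ``n_genes`` (cluster size), ``n_eligible`` (genes accepted by
    the bibliographic database), ``pct_same_network`` (% of eligible genes
    placed in a single biological network).
    """
    return pd.DataFrame(
        _CLUSTER_ROWS,
        columns=["cluster", "n_genes", "n_eligible", "pct_same_network"],
    ).set_index("cluster")
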