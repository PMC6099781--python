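"""Packaged reference data from the published Olyreae plastome study.

The marker table lists the 20 most variable non-coding loci found across 13
herbaceous-bamboo plastomes, with their unaligned length range, aligned
length L, variable-character count (NS) and parsimony-informative-character
count, plus the printed percentage statistics.  It serves as a desk fixture
for validating the percentage arithmetic and the marker-selection thresholds
without re-running genome downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: published class means of percent variable characters across loci
NONCODING_MEAN_PCT_VC = 12.33
CODING_MEAN_PCT_VC = 6.50

#: published genome metrics (bp) for the two newly sequenced plastomes
PUBLISHED_GENOME_METRICS = {
    "Froesiochloa boutelouoides": {"size": 135905, "lsc": 82935, "ssc": 12984,
                                   "ir": 19993},
    "Rehia nervata": {"size": 136700, "lsc": 80931, "ssc": 13273,
                      "ir": 21248},
}


def load_olyreae_marker_table() -> pd.DataFrame:
    """The 20-locus highly-variable marker table (one row per locus)."""
    ref = resources.files("plastocompare") / "data" / "olyreae_marker_table.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
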