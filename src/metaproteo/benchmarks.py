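"""Published benchmark proportion rows used by the acceptance harness.

Each row holds the eight per-metaproteome proportions (percent) reported
for one taxon across the gel-based and gel-free TAX/NAM/AM/Comb
metaproteomes of the reference seawater study. They are the fixture for
the mean +/- SEM summary statistics.
"""
from __future__ import annotations

import pandas as pd

METAPROTEOME_COLUMNS = [
    "gel_based/TAX", "gel_based/NAM", "gel_based/AM", "gel_based/Comb",
    "gel_free/TAX", "gel_free/NAM", "gel_free/AM", "gel_free/Comb",
]

PHYLUM_PROPORTIONS = {
    "Proteobacteria": [87.2, 92.7, 95.2, 89.8, 87.6, 92.9, 91.5, 90.0],
    "Cyanobacteria": [6.3, 2.9, 2.0, 4.0, 2.6, 4.8, 1.6, 2.0],
    "Bacteroidetes": [4.9, 4.2, 2.4, 5.0, 7.6, 1.4, 6.1, 5.8],
}

CLASS_PROPORTIONS = {
    "Alphaproteobacteria": [73.7, 81.6, 79.9, 74.3, 69.7, 68.4, 68.4, 67.5],
    "Gammaproteobacteria": [12.9, 11.5, 14.8, 14.4, 18.0, 25.7, 24.4, 23.5],
    "Flavobacteriia": [6.5, 3.7, 2.2, 3.9, 6.3, 3.5, 4.9, 4.8],
    "Unclassified Cyanobacteria": [3.9, 2.7, 1.8, 5.3, 2.5, 1.4, 1.2, 2.1],
}


def benchmark_matrix() -> pd.DataFrame:
    """All benchmark rows as one proportion matrix (rows = taxa, columns =
    the eight metaproteomes)."""
    rows = {**PHYLUM_PROPORTIONS, **CLASS_PROPORTIONS}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=METAPROTEOME_COLUMNS)
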