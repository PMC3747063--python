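"""Small reference datasets.

``published_abundance_summary`` returns the published per-group summary of
DNA yields and corrected genome counts from the antibiotic time-course
study this package models (three arms: Control, short-term antibiotics,
continuous antibiotics; rows at baseline, day 15 and day 76).  It is input
data, not computed output: the proportion column of the published table is
deliberately omitted so it can be recomputed from the genome-count columns.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_abundance_summary"]

_ROWS = [
    # group, timepoint, yield_mean, yield_sd, bact_mean, bact_sd, euk_mean, euk_sd
    ("Control", "Baseline", 1.08e3, 4.47e2, 2.17e9, 1.18e9, 2.95e6, 1.25e6),
    ("Control", "Day 15", 6.27e2, 4.02e2, 6.03e8, 5.48e8, 1.98e6, 1.30e6),
    ("Control", "Day 76", 4.50e2, 2.72e2, 6.51e8, 4.97e8, 1.12e6, 9.43e5),
    ("AbxShortTerm", "Baseline", 4.51e2, 1.56e2, 5.79e8, 3.43e8, 7.11e5, 4.43e5),
    ("AbxShortTerm", "Day 15", 1.13e2, 7.42e1, 5.43e4, 4.92e4, 3.56e7, 1.38e7),
    ("AbxShortTerm", "Day 76", 3.94e2, 1.88e2, 3.85e8, 3.12e8, 5.35e5, 4.16e5),
    ("AbxContinuous", "Baseline", 4.39e2, 1.79e2, 5.55e8, 3.68e8, 4.62e5, 1.96e5),
    ("AbxContinuous", "Day 15", 1.48e2, 7.32e1, 9.43e4, 6.53e4, 7.86e7, 3.85e7),
    ("AbxContinuous", "Day 76", 1.08e2, 1.32e1, 2.09e5, 1.86e5, 2.43e7, 7.94e6),
]

_PUBLISHED_PROPORTIONS = {
    ("Control", "Baseline"): 0.001,
    ("Control", "Day 15"): 0.003,
    ("Control", "Day 76"): 0.002,
    ("AbxShortTerm", "Baseline"): 0.001,
    ("AbxShortTerm", "Day 15"): 0.998,
    ("AbxShortTerm", "Day 76"): 0.001,
    ("AbxContinuous", "Baseline"): 0.001,
    ("AbxContinuous", "Day 15"): 0.999,
    ("AbxContinuous", "Day 76"): 0.991,
}


def published_abundance_summary(
    include_published_proportion: bool = False,
) -> pd.DataFrame:
    """Published group-level yields and corrected genome counts.

    With ``include_published_proportion=True`` the table also carries the
    proportion column exactly as printed in the source (3 decimals), for
    comparison against recomputed values.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "group", "timepoint",
            "dna_yield_mean", "dna_yield_sd",
            "bacterial_mean", "bacterial_sd",
            "eukaryote_mean", "eukaryote_sd",
        ],
    )
    if include_published_proportion:
        df["published_proportion"] = [
            _PUBLISHED_PROPORTIONS[(g, t)]
            for g, t in zip(df["group"], df["timepoint"])
        ]
    return df
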