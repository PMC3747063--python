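"""Absolute microbial abundance from qPCR.

Quantitative PCR against rRNA-gene standards reports *apparent gene copies
per ng of template DNA*.  Linking that number to organisms per stool pellet
requires three corrections:

1. **DNA yield** — multiply by the ng of DNA recovered from the pellet, so
   that falling total DNA (e.g. when antibiotics clear the bacteria) does not
   masquerade as fungal proliferation.
2. **rRNA operon multiplicity** — divide by the mean gene copies carried per
   genome (~5 for bacterial 16S; ~100 for fungal 18S, a tentative figure
   given tandem-repeat assembly difficulty).
3. **Detection efficiency** — probe-based (Taqman) 16S assays underestimate
   mixed communities ~11-fold because of probe-site mismatches; the dye-based
   18S assay needs no such correction.

The headline summary statistic is the *microeukaryote proportion*,
``euk / (euk + bact)`` genomes per pellet.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Assay",
    "Group",
    "QpcrMeasurement",
    "CorrectionParams",
    "SampleRecord",
    "AbsoluteAbundance",
    "estimate_genomes_per_pellet",
    "microeukaryote_proportion",
    "abundance_table",
    "group_summary",
]


class Assay(str, enum.Enum):
    """qPCR assay chemistry/target."""

    BACT_16S_TAQMAN = "BACT_16S_TAQMAN"
    EUK_18S_SYBR = "EUK_18S_SYBR"


class Group(str, enum.Enum):
    """Treatment arm."""

    CONTROL = "Control"
    ABX_SHORT_TERM = "AbxShortTerm"
    ABX_CONTINUOUS = "AbxContinuous"


@dataclass(frozen=True)
class QpcrMeasurement:
    """Apparent rRNA-gene copies per ng DNA for one assay on one sample."""

    sample_id: str
    assay: Assay
    apparent_copies_per_ng: float

    def __post_init__(self) -> None:
        if self.apparent_copies_per_ng < 0:
            raise ValueError(
                f"negative copies/ng for sample {self.sample_id!r}: "
                f"{self.apparent_copies_per_ng}"
            )


@dataclass(frozen=True)
class CorrectionParams:
    """Scalars converting apparent gene copies to genomes.

    ``copies_per_genome_fungi = 100`` is tentative: fungal rDNA repeat
    number is highly variable and hard to assemble.
    """

    copies_per_genome_bacteria: float = 5.0
    copies_per_genome_fungi: float = 100.0
    taqman_underestimation_factor: float = 11.0

    def __post_init__(self) -> None:
        for name in (
            "copies_per_genome_bacteria",
            "copies_per_genome_fungi",
            "taqman_underestimation_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class SampleRecord:
    """One stool-pellet observation.

    ``pellet_weight_mg`` is optional metadata only; wet/dry pellet weights
    are treated as equal across arms and never enter the conversion.
    """

    sample_id: str
    mouse_id: str
    cage_id: str
    group: Group
    day: int
    dna_yield_ng_per_pellet: float
    pellet_weight_mg: float | None = None

    def __post_init__(self) -> None:
        if self.dna_yield_ng_per_pellet <= 0:
            raise ValueError(
                f"DNA yield must be positive for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class AbsoluteAbundance:
    """Corrected genomes/pellet for one sample (one Table-style row)."""

    sample_id: str
    bacterial_genomes_per_pellet: float
    eukaryote_genomes_per_pellet: float
    microeukaryote_proportion: float


def estimate_genomes_per_pellet(
    m: QpcrMeasurement, yield_ng: float, params: CorrectionParams | None = None
) -> float:
    """Convert one qPCR measurement to genomes per pellet.

    16S-Taqman: ``copies/ng * yield_ng * taqman_factor / copies_per_genome_bact``.
    18S-SYBR:   ``copies/ng * yield_ng / copies_per_genome_fungi`` (dye-based
    assays need no detection correction).
    """
    params = params or CorrectionParams()
    if yield_ng <= 0:
        raise ValueError("yield_ng must be positive")
    if m.apparent_copies_per_ng < 0:
        raise ValueError("negative copies/ng")
    total_copies = m.apparent_copies_per_ng * yield_ng
    if m.assay == Assay.BACT_16S_TAQMAN:
        return (
            total_copies
            * params.taqman_underestimation_factor
            / params.copies_per_genome_bacteria
        )
    if m.assay == Assay.EUK_18S_SYBR:
        return total_copies / params.copies_per_genome_fungi
    raise ValueError(f"unknown assay: {m.assay!r}")


def microeukaryote_proportion(
    bact: float, euk: float, *, ndigits: int | None = None
) -> float:
    """Eukaryote genomes as a fraction of all genomes, ``euk/(euk+bact)``.

    ``ndigits=3`` reproduces the reporting precision of the published
    per-group table; by default full precision is returned.
    """
    if bact < 0 or euk < 0:
        raise ValueError("genome counts must be nonnegative")
    total = bact + euk
    if total == 0:
        raise ValueError("proportion undefined when both genome counts are zero")
    p = euk / total
    return round(p, ndigits) if ndigits is not None else p


def _index_measurements(
    measurements: Iterable[QpcrMeasurement],
) -> dict[tuple[str, Assay], QpcrMeasurement]:
    out: dict[tuple[str, Assay], QpcrMeasurement] = {}
    for m in measurements:
        out[(m.sample_id, m.assay)] = m
    return out


def abundance_table(
    records: Sequence[SampleRecord],
    measurements: Iterable[QpcrMeasurement],
    params: CorrectionParams | None = None,
) -> list[AbsoluteAbundance]:
    """Per-sample corrected abundances; both assays required per sample."""
    params = params or CorrectionParams()
    idx = _index_measurements(measurements)
    rows: list[AbsoluteAbundance] = []
    for rec in records:
        missing = [
            a.value for a in Assay if (rec.sample_id, a) not in idx
        ]
        if missing:
            raise ValueError(
                f"sample {rec.sample_id!r} lacks assay(s): {', '.join(missing)}"
            )
        bact = estimate_genomes_per_pellet(
            idx[(rec.sample_id, Assay.BACT_16S_TAQMAN)],
            rec.dna_yield_ng_per_pellet,
            params,
        )
        euk = estimate_genomes_per_pellet(
            idx[(rec.sample_id, Assay.EUK_18S_SYBR)],
            rec.dna_yield_ng_per_pellet,
            params,
        )
        rows.append(
            AbsoluteAbundance(
                sample_id=rec.sample_id,
                bacterial_genomes_per_pellet=bact,
                eukaryote_genomes_per_pellet=euk,
                microeukaryote_proportion=microeukaryote_proportion(bact, euk),
            )
        )
    return rows


def group_summary(
    records: Sequence[SampleRecord],
    abundances: Sequence[AbsoluteAbundance],
    *,
    proportion_ndigits: int = 3,
) -> pd.DataFrame:
    """Per-(group, day) means and sample SDs (ddof=1), table-report shaped.

    Columns mirror the published per-pellet summary: DNA yield mean/SD,
    bacterial genomes mean/SD, microeukaryote genomes mean/SD, and the
    microeukaryote proportion of the group-mean genome counts rounded to
    ``proportion_ndigits``.
    """
    by_id = {a.sample_id: a for a in abundances}
    rows = []
    for rec in records:
        a = by_id.get(rec.sample_id)
        if a is None:
            continue
        rows.append(
            {
                "group": rec.group.value,
                "day": rec.day,
                "dna_yield_ng": rec.dna_yield_ng_per_pellet,
                "bacterial_genomes": a.bacterial_genomes_per_pellet,
                "eukaryote_genomes": a.eukaryote_genomes_per_pellet,
            }
        )
    df = pd.DataFrame(rows)
    g = df.groupby(["group", "day"], sort=True)
    out = g.agg(
        dna_yield_mean=("dna_yield_ng", "mean"),
        dna_yield_sd=("dna_yield_ng", lambda s: s.std(ddof=1)),
        bacterial_mean=("bacterial_genomes", "mean"),
        bacterial_sd=("bacterial_genomes", lambda s: s.std(ddof=1)),
        eukaryote_mean=("eukaryote_genomes", "mean"),
        eukaryote_sd=("eukaryote_genomes", lambda s: s.std(ddof=1)),
        n=("bacterial_genomes", "size"),
    ).reset_index()
    out["microeukaryote_proportion"] = [
        microeukaryote_proportion(b, e, ndigits=proportion_ndigits)
        for b, e in zip(out["bacterial_mean"], out["eukaryote_mean"])
    ]
    # single-sample groups have undefined sample SD; report 0 spread
    for c in ("dna_yield_sd", "bacterial_sd", "eukaryote_sd"):
        out[c] = out[c].fillna(0.0)
    return out
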