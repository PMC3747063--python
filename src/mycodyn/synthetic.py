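"""Synthetic longitudinal antibiotic-perturbation cohorts.

Generates stool-pellet observations with the statistical structure the
downstream analysis assumes, so every stage is testable without external
sequence data.  The default cohort is 3 treatment arms (Control, a
short-term arm treated days 0-15, a continuously treated arm) x 2 cages x 5
mice, sampled on 13 days from a week before treatment to day 76.

Model summary (details in docs/methods.md):

* **Bacterial load** sits at a baseline (genomes/pellet), crashes by a
  configurable factor while a group is on antibiotics, and relaxes back to
  baseline after cessation with a configurable half-life (log-scale
  exponential recovery).
* **Surviving bacterial composition** under antibiotics is reweighted
  toward a small antibiotic-tolerant OTU subset; the rest of the community
  is suppressed, so observed richness crashes and recovers.
* **Food-derived 16S signal**: a constant number of contaminant 16S copies
  per pellet (sterile chow DNA), attributed to a *Lactococcus* lineage that
  carries no live-organism mass.  Once live bacteria crash, this transient
  dominates the 16S reads.
* **Fungal load** blooms by a configurable factor under antibiotics and
  relaxes back after cessation.
* **Fungal succession** is piecewise-constant per cage: at each event day a
  single phylotype of the named lineage takes a fixed dominance fraction,
  the residual mass is spread uniformly over the remaining OTUs, and all
  mice in the cage follow the same regime (coprophagia synchronizes
  cage-mates).
* **Reads** are multinomial draws at fixed depth from the true proportions;
  **qPCR** reports true copies per ng with multiplicative lognormal noise,
  and the probe-based 16S assay additionally divided by its detection-bias
  factor.

Randomness is counter-based: every (sample, stream) pair seeds its own
generator from the global seed, so subsetting days or mice never shifts the
draws of other samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import (
    Assay,
    CorrectionParams,
    Group,
    QpcrMeasurement,
    SampleRecord,
)
from .community import OtuTable

__all__ = [
    "SuccessionEvent",
    "LineagePool",
    "SimulationConfig",
    "default_pool",
    "default_config",
    "null_config",
    "TruthTable",
    "truth_table",
    "simulate_experiment",
    "plant_fold_change",
]

DEFAULT_DAYS = (-7, -4, -1, 1, 2, 6, 8, 15, 22, 29, 43, 61, 76)

FOOD_LACTOCOCCUS_OTU = "B_Lactococcus_food"


@dataclass(frozen=True)
class SuccessionEvent:
    """From ``day`` on, one phylotype of ``lineage`` dominates the cage."""

    day: int
    lineage: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("dominance fraction must be in (0, 1]")


@dataclass(frozen=True)
class LineagePool:
    """OTU-level lineage strings and baseline proportions per domain.

    ``bacterial_baseline_proportions`` includes the food-only *Lactococcus*
    OTU at proportion 0 (it carries no live organisms).  ``abx_tolerant``
    names the bacterial OTUs whose relative abundance survives antibiotics.
    """

    bacterial_otu_ids: tuple[str, ...]
    bacterial_lineages: Mapping[str, str]
    bacterial_baseline_proportions: np.ndarray
    fungal_otu_ids: tuple[str, ...]
    fungal_lineages: Mapping[str, str]
    fungal_baseline_proportions: np.ndarray
    abx_tolerant: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for ids, props, label in (
            (self.bacterial_otu_ids, self.bacterial_baseline_proportions, "bacterial"),
            (self.fungal_otu_ids, self.fungal_baseline_proportions, "fungal"),
        ):
            if len(ids) == 0:
                raise ValueError(f"{label} pool is empty")
            if len(props) != len(ids):
                raise ValueError(f"{label} proportions do not match OTU ids")
            if abs(float(np.sum(props)) - 1.0) > 1e-9:
                raise ValueError(f"{label} proportions must sum to 1")
            if np.any(np.asarray(props) < 0):
                raise ValueError(f"{label} proportions must be nonnegative")
        for otu in (*self.bacterial_otu_ids, *self.fungal_otu_ids):
            lineages = (
                self.bacterial_lineages
                if otu in self.bacterial_otu_ids
                else self.fungal_lineages
            )
            if otu not in lineages:
                raise ValueError(f"OTU {otu!r} has no lineage")

    def fungal_otus_of(self, lineage_name: str) -> list[str]:
        return [
            o
            for o in self.fungal_otu_ids
            if lineage_name in self.fungal_lineages[o].split(";")
            or o == lineage_name
        ]


def _geometric(n: int, total: float, decay: float = 0.7) -> np.ndarray:
    w = decay ** np.arange(n)
    return total * w / w.sum()


def default_pool() -> LineagePool:
    """The default community: murine-gut-like bacteria plus chow signal.

    ~60 bacterial OTUs dominated by Lachnospiraceae and Bacteroidales with a
    minority of antibiotic-tolerant OTUs (Enterococcus, Escherichia,
    Paenibacillus), and ~40 fungal OTUs spread over the eight genera that
    dominate cage succession waves.
    """
    bact_groups = [
        # (genus/family leaf, lineage prefix, n OTUs, total baseline share)
        ("Lachnospiraceae", "Bacteria;Firmicutes;Clostridia;Clostridiales", 18, 0.36),
        ("Bacteroidales", "Bacteria;Bacteroidetes;Bacteroidia", 15, 0.30),
        ("Clostridium", "Bacteria;Firmicutes;Clostridia;Clostridiales", 8, 0.10),
        ("Ruminococcaceae", "Bacteria;Firmicutes;Clostridia;Clostridiales", 10, 0.13),
        ("Turicibacter", "Bacteria;Firmicutes;Erysipelotrichia", 3, 0.04),
        ("Enterococcus", "Bacteria;Firmicutes;Bacilli;Lactobacillales", 3, 0.04),
        ("Escherichia", "Bacteria;Proteobacteria;Gammaproteobacteria", 2, 0.02),
        ("Paenibacillus", "Bacteria;Firmicutes;Bacilli;Bacillales", 2, 0.01),
    ]
    tolerant_taxa = {"Enterococcus", "Escherichia", "Paenibacillus"}
    b_ids: list[str] = []
    b_lineages: dict[str, str] = {}
    b_props: list[float] = []
    tolerant: set[str] = set()
    for taxon, prefix, n, share in bact_groups:
        props = _geometric(n, share)
        for k in range(n):
            otu = f"B_{taxon}_{k + 1:02d}"
            b_ids.append(otu)
            b_lineages[otu] = f"{prefix};{taxon}"
            b_props.append(float(props[k]))
            if taxon in tolerant_taxa:
                tolerant.add(otu)
    # food-only contaminant lineage: zero live baseline
    b_ids.append(FOOD_LACTOCOCCUS_OTU)
    b_lineages[FOOD_LACTOCOCCUS_OTU] = (
        "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Lactococcus"
    )
    b_props.append(0.0)

    fung_groups = [
        ("Wickerhamomyces", "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Wickerhamomycetaceae", 5, 0.17),
        ("Debaryomyces", "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Debaryomycetaceae", 5, 0.15),
        ("Candida", "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Debaryomycetaceae", 6, 0.15),
        ("Cyberlindnera", "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Phaffomycetaceae", 5, 0.13),
        ("Clavispora", "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Metschnikowiaceae", 4, 0.12),
        ("Pichia", "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Pichiaceae", 4, 0.10),
        ("Sporopachydermia", "Fungi;Ascomycota;Saccharomycetes;Saccharomycetales;Trichomonascaceae", 3, 0.08),
        ("Eurotiales", "Fungi;Ascomycota;Eurotiomycetes", 8, 0.10),
    ]
    f_ids: list[str] = []
    f_lineages: dict[str, str] = {}
    f_props: list[float] = []
    for taxon, prefix, n, share in fung_groups:
        props = _geometric(n, share, decay=0.8)
        for k in range(n):
            otu = f"F_{taxon}_{k + 1:02d}"
            f_ids.append(otu)
            f_lineages[otu] = f"{prefix};{taxon}"
            f_props.append(float(props[k]))

    return LineagePool(
        bacterial_otu_ids=tuple(b_ids),
        bacterial_lineages=b_lineages,
        bacterial_baseline_proportions=np.asarray(b_props) / np.sum(b_props),
        fungal_otu_ids=tuple(f_ids),
        fungal_lineages=f_lineages,
        fungal_baseline_proportions=np.asarray(f_props) / np.sum(f_props),
        abx_tolerant=frozenset(tolerant),
    )


def _default_succession() -> dict[str, tuple[SuccessionEvent, ...]]:
    """Cage-synchronized fungal waves mimicking the study's six cages."""
    e = SuccessionEvent
    return {
        "Control-cage1": (
            e(15, "Wickerhamomyces", 0.95),
            e(22, "Debaryomyces", 0.95),
            e(76, "Eurotiales", 0.90),
        ),
        "Control-cage2": (
            e(15, "Wickerhamomyces", 0.95),
            e(22, "Debaryomyces", 0.30),
            e(76, "Eurotiales", 0.70),
        ),
        "AbxShortTerm-cage1": (
            e(2, "Clavispora", 0.90),
            e(6, "Cyberlindnera", 0.95),
            e(22, "Sporopachydermia", 0.90),
            e(76, "Candida", 0.40),
        ),
        "AbxShortTerm-cage2": (
            e(2, "Candida", 0.60),
            e(6, "Candida", 0.95),
            e(22, "Candida", 0.90),
            e(76, "Candida", 0.40),
        ),
        "AbxContinuous-cage1": (
            e(2, "Clavispora", 0.90),
            e(6, "Cyberlindnera", 0.95),
            e(22, "Candida", 0.95),
            e(76, "Candida", 1.0),
        ),
        "AbxContinuous-cage2": (
            e(2, "Cyberlindnera", 0.90),
            e(6, "Cyberlindnera", 0.95),
            e(22, "Cyberlindnera", 0.95),
            e(76, "Candida", 1.0),
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generative parameters for one synthetic cohort."""

    groups: tuple[str, ...] = (
        Group.CONTROL.value,
        Group.ABX_SHORT_TERM.value,
        Group.ABX_CONTINUOUS.value,
    )
    mice_per_cage: int = 5
    cages_per_group: int = 2
    days: tuple[int, ...] = DEFAULT_DAYS
    abx_windows: Mapping[str, tuple[int, int] | None] = field(
        default_factory=lambda: {
            Group.CONTROL.value: None,
            Group.ABX_SHORT_TERM.value: (0, 15),
            Group.ABX_CONTINUOUS.value: (0, 76),
        }
    )
    bacterial_baseline: float = 5e8
    bacterial_crash_factor: float = 1e4
    fungal_baseline: float = 7e5
    fungal_bloom_factor: float = 50.0
    food_16s_copies_per_pellet: float = 1.2e5
    succession_events: Mapping[str, tuple[SuccessionEvent, ...]] = field(
        default_factory=_default_succession
    )
    read_depth: int = 500
    qpcr_cv: float = 0.2
    recovery_half_life_days: float = 7.0
    abx_susceptible_weight: float = 1e-3
    dna_yield_floor_ng: float = 100.0
    dna_ng_per_bacterial_genome: float = 5e-7
    dna_ng_per_fungal_genome: float = 1e-6
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_cage <= 0 or self.cages_per_group <= 0:
            raise ValueError("counts must be positive")
        if not self.groups or not self.days:
            raise ValueError("need at least one group and one day")
        if self.bacterial_crash_factor < 1 or self.fungal_bloom_factor < 1:
            raise ValueError("crash/bloom factors must be >= 1")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.qpcr_cv < 0:
            raise ValueError("qpcr_cv must be nonnegative")
        for g in self.groups:
            if g not in self.abx_windows:
                raise ValueError(f"no antibiotic window entry for group {g!r}")

    def cage_ids(self) -> list[str]:
        return [
            f"{g}-cage{c + 1}"
            for g in self.groups
            for c in range(self.cages_per_group)
        ]


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A no-effect cohort: no antibiotic effect, no succession waves.

    All mice are exchangeable across groups — the null for calibration of
    the interval tests.
    """
    groups = overrides.pop("groups", None) or (
        Group.CONTROL.value,
        Group.ABX_SHORT_TERM.value,
        Group.ABX_CONTINUOUS.value,
    )
    return SimulationConfig(
        groups=groups,
        abx_windows={g: None for g in groups},
        bacterial_crash_factor=1.0,
        fungal_bloom_factor=1.0,
        succession_events={},
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# deterministic ground truth


def _abx_intensity(
    window: tuple[int, int] | None, day: int, half_life: float
) -> float:
    """1 while on antibiotics, 0 before, exponentially decaying after."""
    if window is None:
        return 0.0
    start, end = window
    if day < start:
        return 0.0
    if day <= end:
        return 1.0
    return 2.0 ** (-(day - end) / half_life)


def _bacterial_composition(
    config: SimulationConfig, pool: LineagePool, intensity: float
) -> np.ndarray:
    """Live-bacteria relative composition at a given antibiotic intensity."""
    base = np.asarray(pool.bacterial_baseline_proportions, dtype=float)
    if intensity == 0:
        return base
    w = np.array(
        [
            1.0
            if o in pool.abx_tolerant
            else config.abx_susceptible_weight ** intensity
            for o in pool.bacterial_otu_ids
        ]
    )
    comp = base * w
    total = comp.sum()
    return comp / total if total > 0 else base


def _fungal_composition(
    config: SimulationConfig, pool: LineagePool, cage_id: str, day: int
) -> np.ndarray:
    base = np.asarray(pool.fungal_baseline_proportions, dtype=float)
    events = sorted(
        config.succession_events.get(cage_id, ()), key=lambda ev: ev.day
    )
    active = None
    for ev in events:
        if ev.day <= day:
            active = ev
    if active is None:
        return base
    members = pool.fungal_otus_of(active.lineage)
    if not members:
        raise ValueError(
            f"succession event references lineage {active.lineage!r} "
            f"absent from the pool (cage {cage_id})"
        )
    # the bloom is a single phylotype: the most abundant member at baseline
    idx = {o: i for i, o in enumerate(pool.fungal_otu_ids)}
    dominant = max(members, key=lambda o: base[idx[o]])
    comp = np.full(len(base), 0.0)
    others = [i for i in range(len(base)) if i != idx[dominant]]
    comp[idx[dominant]] = active.fraction
    if others:
        comp[others] = (1.0 - active.fraction) / len(others)
    return comp


@dataclass
class TruthTable:
    """Noise-free ground truth aligned 1:1 with the simulated samples.

    ``samples`` has one row per (mouse, day) with the true bacterial and
    fungal genomes/pellet, the *apparent* bacterial genomes (true plus
    food-derived 16S copies expressed as genome equivalents — what an
    ideal noise-free qPCR estimator can recover), and the DNA yield.
    Proportion frames are OTUs x samples.
    """

    samples: pd.DataFrame
    bacterial_proportions: pd.DataFrame
    fungal_proportions: pd.DataFrame


def truth_table(config: SimulationConfig, pool: LineagePool) -> TruthTable:
    rows = []
    bact_cols: dict[str, np.ndarray] = {}
    fung_cols: dict[str, np.ndarray] = {}
    cpg_b = config.correction.copies_per_genome_bacteria
    for group in config.groups:
        window = config.abx_windows[group]
        for cage in range(config.cages_per_group):
            cage_id = f"{group}-cage{cage + 1}"
            for m in range(config.mice_per_cage):
                mouse_id = f"{group}-c{cage + 1}-m{m + 1}"
                for day in config.days:
                    intensity = _abx_intensity(
                        window, day, config.recovery_half_life_days
                    )
                    bact = config.bacterial_baseline * (
                        config.bacterial_crash_factor ** -intensity
                    )
                    fung = config.fungal_baseline * (
                        config.fungal_bloom_factor ** intensity
                    )
                    yield_ng = (
                        config.dna_yield_floor_ng
                        + bact * config.dna_ng_per_bacterial_genome
                        + fung * config.dna_ng_per_fungal_genome
                    )
                    sid = f"{mouse_id}_d{day}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "mouse_id": mouse_id,
                            "cage_id": cage_id,
                            "group": group,
                            "day": day,
                            "bacterial_genomes": bact,
                            "bacterial_genomes_apparent": bact
                            + config.food_16s_copies_per_pellet / cpg_b,
                            "fungal_genomes": fung,
                            "dna_yield_ng": yield_ng,
                        }
                    )
                    live = _bacterial_composition(config, pool, intensity)
                    copies = bact * cpg_b * live
                    idx = pool.bacterial_otu_ids.index(FOOD_LACTOCOCCUS_OTU) if FOOD_LACTOCOCCUS_OTU in pool.bacterial_otu_ids else None
                    copies = copies.copy()
                    if idx is not None:
                        copies[idx] += config.food_16s_copies_per_pellet
                    bact_cols[sid] = copies / copies.sum()
                    fung_cols[sid] = _fungal_composition(
                        config, pool, cage_id, day
                    )
    samples = pd.DataFrame(rows)
    return TruthTable(
        samples=samples,
        bacterial_proportions=pd.DataFrame(
            bact_cols, index=list(pool.bacterial_otu_ids)
        ),
        fungal_proportions=pd.DataFrame(
            fung_cols, index=list(pool.fungal_otu_ids)
        ),
    )


# ---------------------------------------------------------------------------
# stochastic realization

_STREAM_READS_16S = 1
_STREAM_READS_ITS = 2
_STREAM_QPCR_16S = 3
_STREAM_QPCR_18S = 4


def _sample_rng(seed: int, sample_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(sample_index, stream))
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def simulate_experiment(
    config: SimulationConfig, pool: LineagePool | None = None
) -> tuple[list[SampleRecord], list[QpcrMeasurement], OtuTable, OtuTable]:
    """Generate one cohort: metadata, qPCR values, 16S and ITS read tables.

    Every sample draws from its own counter-based substream of the global
    seed, so results are bitwise reproducible and invariant to subsetting.
    """
    pool = pool or default_pool()
    # validate succession references eagerly
    for cage_id, events in config.succession_events.items():
        for ev in events:
            if not pool.fungal_otus_of(ev.lineage):
                raise ValueError(
                    f"succession event references lineage {ev.lineage!r} "
                    f"absent from the pool (cage {cage_id})"
                )
    truth = truth_table(config, pool)
    records: list[SampleRecord] = []
    measurements: list[QpcrMeasurement] = []
    counts_16s: list[np.ndarray] = []
    counts_its: list[np.ndarray] = []
    cpg_b = config.correction.copies_per_genome_bacteria
    cpg_f = config.correction.copies_per_genome_fungi
    taqman = config.correction.taqman_underestimation_factor

    for i, row in truth.samples.iterrows():
        sid = row["sample_id"]
        records.append(
            SampleRecord(
                sample_id=sid,
                mouse_id=row["mouse_id"],
                cage_id=row["cage_id"],
                group=Group(row["group"]),
                day=int(row["day"]),
                dna_yield_ng_per_pellet=float(row["dna_yield_ng"]),
            )
        )
        p16 = truth.bacterial_proportions[sid].to_numpy()
        pits = truth.fungal_proportions[sid].to_numpy()
        rng16 = _sample_rng(config.seed, i, _STREAM_READS_16S)
        rngits = _sample_rng(config.seed, i, _STREAM_READS_ITS)
        counts_16s.append(rng16.multinomial(config.read_depth, p16))
        counts_its.append(rngits.multinomial(config.read_depth, pits))

        total_16s_copies = (
            row["bacterial_genomes"] * cpg_b + config.food_16s_copies_per_pellet
        )
        total_18s_copies = row["fungal_genomes"] * cpg_f
        noise16 = _lognormal_factor(
            _sample_rng(config.seed, i, _STREAM_QPCR_16S), config.qpcr_cv
        )
        noise18 = _lognormal_factor(
            _sample_rng(config.seed, i, _STREAM_QPCR_18S), config.qpcr_cv
        )
        measurements.append(
            QpcrMeasurement(
                sample_id=sid,
                assay=Assay.BACT_16S_TAQMAN,
                apparent_copies_per_ng=total_16s_copies
                / row["dna_yield_ng"]
                / taqman
                * noise16,
            )
        )
        measurements.append(
            QpcrMeasurement(
                sample_id=sid,
                assay=Assay.EUK_18S_SYBR,
                apparent_copies_per_ng=total_18s_copies
                / row["dna_yield_ng"]
                * noise18,
            )
        )

    sample_ids = list(truth.samples["sample_id"])
    table_16s = OtuTable(
        otu_ids=list(pool.bacterial_otu_ids),
        sample_ids=sample_ids,
        counts=np.column_stack(counts_16s),
        lineages=dict(pool.bacterial_lineages),
    )
    table_its = OtuTable(
        otu_ids=list(pool.fungal_otu_ids),
        sample_ids=sample_ids,
        counts=np.column_stack(counts_its),
        lineages=dict(pool.fungal_lineages),
    )
    return records, measurements, table_16s, table_its


def plant_fold_change(
    table: OtuTable,
    records: Sequence[SampleRecord],
    otu_id: str,
    groups: Sequence[str],
    days: Sequence[int],
    fold: float,
) -> OtuTable:
    """Multiply one OTU's counts by ``fold`` in selected group/day samples.

    A controlled effect injection for power studies of the interval tests;
    counts are rounded to integers.
    """
    recs = {r.sample_id: r for r in records}
    counts = table.counts.copy()
    i = table.otu_ids.index(otu_id)
    for j, sid in enumerate(table.sample_ids):
        r = recs[sid]
        if r.group.value in groups and r.day in days:
            counts[i, j] = int(round(counts[i, j] * fold))
    return OtuTable(
        otu_ids=list(table.otu_ids),
        sample_ids=list(table.sample_ids),
        counts=counts,
        lineages=dict(table.lineages),
    )
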