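"""Interval-structured nonparametric tests for longitudinal cohorts.

The study design compares lineage abundances between named intervals of the
time course (baseline, early antibiotics, late antibiotics, recovery, last
day, early-vs-late).  Between-group contrasts use the Mann-Whitney U test;
within-animal contrasts (the same mice measured in two intervals) use the
Friedman test with mice as blocks.  P-values are Bonferroni-corrected over
the lineages actually tested within each comparison.

The Mann-Whitney implementation is exact by enumeration of all
C(n+m, n) group labelings for small samples, which keeps p-values honest
for the tiny per-day group sizes of a caged mouse study.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abundance import Group, SampleRecord
from .community import OtuTable
from .phylodiversity import DistanceMatrix

__all__ = [
    "IntervalComparison",
    "IntervalScheme",
    "LineageTestResult",
    "mann_whitney_u",
    "friedman_test",
    "lineage_interval_tests",
    "distance_group_test",
    "default_scheme",
]

EXACT_ENUMERATION_LIMIT = 12  # n+m above this uses the normal approximation


def _rankdata(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], two_sided: bool = True
) -> tuple[float, float]:
    """Mann-Whitney U with exact small-sample enumeration.

    For n+m <= 12 the p-value is exact: every C(n+m, n) assignment of the
    pooled values to groups is enumerated and the two-sided p is the
    fraction of assignments whose U is at least as far from the null mean
    nm/2 as the observed U (ties handled by midranks, so the enumeration is
    valid with ties).  Larger samples use the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2)

    if n + m <= EXACT_ENUMERATION_LIMIT:
        mid = n * m / 2
        obs_dev = abs(u_x - mid)
        hits = 0
        total = 0
        idx_all = frozenset(range(n + m))
        for combo in itertools.combinations(range(n + m), n):
            u = float(ranks[list(combo)].sum() - n * (n + 1) / 2)
            dev = abs(u - mid)
            if dev >= obs_dev - 1e-9:
                hits += 1
            total += 1
        p = hits / total
        if not two_sided:
            # one-sided: fraction with U >= observed
            hits = sum(
                1
                for combo in itertools.combinations(range(n + m), n)
                if float(ranks[list(combo)].sum() - n * (n + 1) / 2)
                >= u_x - 1e-9
            )
            p = hits / total
        return u_x, min(1.0, p)

    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided" if two_sided else "greater",
        method="asymptotic", use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


EXACT_FRIEDMAN_LIMIT = 20_000  # max k!^n arrangements for the exact path


def _friedman_statistic(ranks: np.ndarray, c: float, n: int, k: int) -> float:
    rsum = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(rsum ** 2)) - 3.0 * n * (k + 1)
    return stat / c


def friedman_test(
    matrix: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Friedman test for a blocks x treatments matrix.

    Values are midranked within each block; the statistic is
    12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1), divided by the standard tie
    correction 1 - sum(t^3 - t)/(n k (k^2 - 1)).  ``method`` selects the
    reference distribution for p:

    * ``"chi2"`` — chi-square with k-1 df (the usual large-sample test);
    * ``"exact"`` — the conditional permutation distribution, enumerating
      all k!^n within-block arrangements (the chi-square approximation is
      badly off for tiny designs — e.g. n=4 blocks can misstate p by >0.1);
    * ``"auto"`` — exact when k!^n is small enough, chi-square otherwise.

    Works for k = 2 treatments (unlike the common k >= 3 restriction).
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2:
        raise ValueError("need a 2-D blocks x treatments matrix")
    n, k = a.shape
    if n < 2 or k < 2:
        raise ValueError("need >=2 blocks and >=2 treatments")
    if np.isnan(a).any():
        raise ValueError("missing cells are not allowed")
    ranks = np.vstack([_rankdata(row) for row in a])
    tie_term = 0.0
    for row in a:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    c = 1.0 - tie_term / (n * k * (k ** 2 - 1))
    if c <= 0:
        return 0.0, 1.0  # every block fully tied
    stat = _friedman_statistic(ranks, c, n, k)

    n_arrangements = math.factorial(k) ** n
    if method == "auto":
        method = "exact" if n_arrangements <= EXACT_FRIEDMAN_LIMIT else "chi2"
    if method == "chi2":
        p = float(sps.chi2.sf(stat, k - 1))
    elif method == "exact":
        # permuting values within a block permutes its midrank vector, and
        # the tie correction is permutation-invariant, so enumerate over
        # products of per-block rank-vector permutations
        per_block = [
            [np.array(p_) for p_ in set(itertools.permutations(row))]
            for row in ranks
        ]
        hits = total = 0
        for combo in itertools.product(*per_block):
            s = _friedman_statistic(np.vstack(combo), c, n, k)
            total += 1
            if s >= stat - 1e-9:
                hits += 1
        p = hits / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


@dataclass(frozen=True)
class IntervalComparison:
    """One named contrast between day-sets of the time course.

    ``paired`` marks within-animal contrasts (same mice in both intervals,
    Friedman with mice as blocks); unpaired contrasts compare groups with
    the Mann-Whitney U test on per-sample values.
    """

    name: str
    groups_a: tuple[str, ...]
    groups_b: tuple[str, ...]
    days_a: tuple[int, ...]
    days_b: tuple[int, ...]
    paired: bool = False


@dataclass
class IntervalScheme:
    comparisons: list[IntervalComparison]

    def restrict_to_days(self, days: set[int]) -> "IntervalScheme":
        """Intersect every comparison's day sets with the observed days.

        Comparisons left with an empty side are dropped; useful when a
        cohort was sampled on a subset of the standard calendar.
        """
        kept = []
        for c in self.comparisons:
            da = tuple(d for d in c.days_a if d in days)
            db = tuple(d for d in c.days_b if d in days)
            if da and db:
                kept.append(
                    IntervalComparison(
                        c.name, c.groups_a, c.groups_b, da, db, c.paired
                    )
                )
        return IntervalScheme(kept)

    def validate(self, groups: set[str], days: set[int]) -> None:
        for c in self.comparisons:
            for g in (*c.groups_a, *c.groups_b):
                if g not in groups:
                    raise ValueError(f"{c.name}: unknown group {g!r}")
            for d in (*c.days_a, *c.days_b):
                if d not in days:
                    raise ValueError(f"{c.name}: day {d} not a study day")
            if not c.days_a or not c.days_b:
                raise ValueError(f"{c.name}: empty day set")


def default_scheme(
    baseline_days: Sequence[int] = (-7, -4, -1),
    early_abx_days: Sequence[int] = (1, 2),
    late_abx_days: Sequence[int] = (6, 8, 15),
    recovery_days: Sequence[int] = (22, 29, 43, 61, 76),
    last_day: int = 76,
) -> IntervalScheme:
    """The six standard comparisons of the study's statistical tables.

    Both antibiotic arms are lumped for the on-treatment contrasts; only
    the short-term arm (which actually stops treatment) enters the recovery
    contrasts.  Control samples are restricted to the same days as the
    treated samples they are compared against.
    """
    abx = (Group.ABX_SHORT_TERM.value, Group.ABX_CONTINUOUS.value)
    ctrl = (Group.CONTROL.value,)
    st = (Group.ABX_SHORT_TERM.value,)
    return IntervalScheme(
        comparisons=[
            IntervalComparison(
                "Baseline", abx, ctrl,
                tuple(baseline_days), tuple(baseline_days),
            ),
            IntervalComparison(
                "Early ABX vs Control", abx, ctrl,
                tuple(early_abx_days), tuple(early_abx_days),
            ),
            IntervalComparison(
                "Late ABX vs Control", abx, ctrl,
                tuple(late_abx_days), tuple(late_abx_days),
            ),
            IntervalComparison(
                "Recovery vs Control", st, ctrl,
                tuple(recovery_days), tuple(recovery_days),
            ),
            IntervalComparison(
                "Last Day Recovery vs Control", st, ctrl,
                (last_day,), (last_day,),
            ),
            IntervalComparison(
                "Early ABX vs Late ABX", abx, abx,
                tuple(early_abx_days), tuple(late_abx_days),
                paired=True,
            ),
        ]
    )


@dataclass(frozen=True)
class LineageTestResult:
    lineage: str
    comparison: str
    test: str              # "Friedman" | "Mann-Whitney" | "n/a"
    statistic: float
    p: float
    p_bonferroni: float
    significant: bool
    applicable: bool = True


def _sample_lookup(records: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}


def lineage_interval_tests(
    table: OtuTable,
    records: Sequence[SampleRecord],
    scheme: IntervalScheme | None = None,
    alpha: float = 0.05,
) -> list[LineageTestResult]:
    """Per-lineage tests for every comparison of the scheme.

    The table should already be rarefied to a common depth and aggregated to
    the testing rank.  For unpaired comparisons each sample contributes its
    count; for paired comparisons each mouse contributes its mean count per
    interval and the Friedman test blocks on mice.  Lineages absent from
    both sides of a comparison are reported not-applicable, and the
    Bonferroni multiplier is the number of lineages actually tested within
    that comparison.
    """
    scheme = scheme or default_scheme()
    recs = _sample_lookup(records)
    meta = {
        sid: recs[sid] for sid in table.sample_ids if sid in recs
    }
    if len(meta) < len(table.sample_ids):
        missing = [s for s in table.sample_ids if s not in recs]
        raise ValueError(f"samples without metadata: {missing[:5]}")
    groups = {r.group.value for r in meta.values()}
    days = {r.day for r in meta.values()}
    scheme.validate(groups, days)

    pos = {sid: j for j, sid in enumerate(table.sample_ids)}
    results: list[LineageTestResult] = []
    for comp in scheme.comparisons:
        per_lineage: list[tuple[str, str, float, float]] = []
        na: list[str] = []
        for i, lineage in enumerate(table.otu_ids):
            row = table.counts[i, :]
            if comp.paired:
                stat_p = _paired_test(table, meta, comp, row, pos)
            else:
                stat_p = _unpaired_test(table, meta, comp, row, pos)
            if stat_p is None:
                na.append(lineage)
            else:
                per_lineage.append((lineage, *stat_p))
        n_tested = len(per_lineage)
        for lineage, test_name, stat, p in per_lineage:
            p_bonf = min(1.0, p * n_tested)
            results.append(
                LineageTestResult(
                    lineage=lineage, comparison=comp.name, test=test_name,
                    statistic=stat, p=p, p_bonferroni=p_bonf,
                    significant=p_bonf < alpha,
                )
            )
        for lineage in na:
            results.append(
                LineageTestResult(
                    lineage=lineage, comparison=comp.name, test="n/a",
                    statistic=float("nan"), p=float("nan"),
                    p_bonferroni=float("nan"), significant=False,
                    applicable=False,
                )
            )
    return results


def _select(
    table: OtuTable,
    meta: dict[str, SampleRecord],
    groups: tuple[str, ...],
    days: tuple[int, ...],
    row: np.ndarray,
    pos: dict[str, int],
) -> tuple[list[str], np.ndarray]:
    ids = [
        sid
        for sid in table.sample_ids
        if meta[sid].group.value in groups and meta[sid].day in days
    ]
    vals = np.array([row[pos[sid]] for sid in ids], dtype=float)
    return ids, vals


def _unpaired_test(table, meta, comp, row, pos):
    ids_a, a = _select(table, meta, comp.groups_a, comp.days_a, row, pos)
    ids_b, b = _select(table, meta, comp.groups_b, comp.days_b, row, pos)
    if len(a) == 0 or len(b) == 0:
        return None
    if a.sum() == 0 and b.sum() == 0:
        return None  # lineage absent from both sides
    u, p = mann_whitney_u(a, b)
    return "Mann-Whitney", u, p


def _paired_test(table, meta, comp, row, pos):
    # mouse -> per-interval mean count
    mice: dict[str, dict[str, list[float]]] = {}
    for interval, days in (("a", comp.days_a), ("b", comp.days_b)):
        for sid in table.sample_ids:
            r = meta[sid]
            if r.group.value in comp.groups_a and r.day in days:
                mice.setdefault(r.mouse_id, {}).setdefault(interval, []).append(
                    float(row[pos[sid]])
                )
    blocks = [
        (np.mean(v["a"]), np.mean(v["b"]))
        for v in mice.values()
        if "a" in v and "b" in v
    ]
    if len(blocks) < 2:
        return None
    m = np.asarray(blocks)
    if m.sum() == 0:
        return None
    stat, p = friedman_test(m)
    return "Friedman", stat, p


def distance_group_test(
    dm: DistanceMatrix,
    records: Sequence[SampleRecord],
    control_group: str,
    treatment_group: str,
    day: int,
) -> tuple[float, str]:
    """Community-displacement test for one day.

    Mann-Whitney U on the within-control pairwise distances versus the
    control-to-treatment pairwise distances among that day's samples.
    Returns (p, direction) with direction "treatment_farther" when the
    between-group distances have the larger rank-sum mean.  The pairwise
    distances entering the test are not independent; the p-value should be
    read as the study's screening heuristic, not an exact error rate.
    """
    recs = _sample_lookup(records)
    ctrl_idx = [
        i for i, sid in enumerate(dm.sample_ids)
        if sid in recs
        and recs[sid].group.value == control_group
        and recs[sid].day == day
    ]
    trt_idx = [
        i for i, sid in enumerate(dm.sample_ids)
        if sid in recs
        and recs[sid].group.value == treatment_group
        and recs[sid].day == day
    ]
    if len(ctrl_idx) < 2 or len(trt_idx) < 1:
        raise ValueError(
            f"need >=2 control and >=1 treatment samples at day {day}"
        )
    within = [
        dm.values[i, j] for i, j in itertools.combinations(ctrl_idx, 2)
    ]
    between = [dm.values[i, j] for i in ctrl_idx for j in trt_idx]
    _, p = mann_whitney_u(within, between)
    direction = (
        "treatment_farther"
        if np.mean(between) > np.mean(within)
        else "treatment_not_farther"
    )
    return p, direction
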