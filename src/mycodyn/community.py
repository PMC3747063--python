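"""OTU-table handling, rarefaction and richness.

Read counts are not comparable across samples at unequal sequencing depth,
so richness is assessed after *rarefaction*: subsampling each sample's reads
without replacement to a common depth (default 200 reads, repeated 10
times), then counting the OTUs observed.  Per OTU the rarefied count is
marginally hypergeometric, so the expected rarefied richness has the closed
form  E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "RichnessResult",
    "rarefy",
    "observed_richness",
    "expected_rarefied_richness",
    "rarefied_richness",
    "aggregate_by_lineage",
    "parse_lineage",
]

LINEAGE_SEP = ";"


def parse_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage string into rank names.

    Whitespace around names is stripped; unnamed intermediate ranks are kept
    as empty strings so rank positions stay aligned.
    """
    return [part.strip() for part in lineage.split(LINEAGE_SEP)]


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix with per-OTU lineage strings.

    ``counts`` is oriented (n_otus, n_samples) to match the on-disk layout
    (OTUs as rows, samples as columns).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lineages: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        missing = [o for o in self.otu_ids if o not in self.lineages]
        if missing:
            raise ValueError(f"OTUs without lineage annotation: {missing[:5]}")

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=self.otu_ids, columns=self.sample_ids
        )
        df.index.name = "otu_id"
        return df

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals
        return np.nan_to_num(rel)


@dataclass(frozen=True)
class RichnessResult:
    """Mean/min/max observed OTU richness over repeated rarefactions."""

    sample_id: str
    depth: int
    reps: int
    mean_richness: float
    min_richness: int
    max_richness: int


def rarefy(
    counts: np.ndarray, depth: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Subsample a count vector without replacement to exactly ``depth`` reads.

    The output is marginally hypergeometric per OTU and sums to ``depth``.
    """
    counts = np.asarray(counts)
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total reads {total}")
    if depth == total:
        return counts.copy()
    rng = np.random.default_rng(rng)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def observed_richness(counts: np.ndarray) -> int:
    """Number of OTUs with at least one read."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form expected richness after rarefying to ``depth`` reads.

    E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d)), the probability that each
    OTU contributes at least one of the d draws.
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError("depth exceeds total reads")
    # P(X_i = 0) for hypergeometric draws of size depth
    p_absent = hypergeom.pmf(0, total, counts, depth)
    return float(np.sum(1.0 - p_absent))


def rarefied_richness(
    table: OtuTable,
    depth: int = 200,
    reps: int = 10,
    rng: np.random.Generator | int | None = None,
) -> list[RichnessResult]:
    """Mean and range of observed richness over repeated rarefactions.

    Samples with fewer than ``depth`` reads are excluded with a logged
    warning rather than raising.
    """
    rng = np.random.default_rng(rng)
    results: list[RichnessResult] = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if int(col.sum()) < depth:
            logger.warning(
                "sample %s has %d reads < rarefaction depth %d; excluded",
                sid, int(col.sum()), depth,
            )
            continue
        rich = [observed_richness(rarefy(col, depth, rng)) for _ in range(reps)]
        results.append(
            RichnessResult(
                sample_id=sid,
                depth=depth,
                reps=reps,
                mean_richness=float(np.mean(rich)),
                min_richness=int(min(rich)),
                max_richness=int(max(rich)),
            )
        )
    return results


def rarefy_table(
    table: OtuTable, depth: int = 200, rng: np.random.Generator | int | None = None
) -> OtuTable:
    """Rarefy every sample of a table to ``depth``; shallow samples dropped."""
    rng = np.random.default_rng(rng)
    keep: list[int] = []
    cols: list[np.ndarray] = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if int(col.sum()) < depth:
            logger.warning(
                "sample %s has %d reads < rarefaction depth %d; excluded",
                sid, int(col.sum()), depth,
            )
            continue
        keep.append(j)
        cols.append(rarefy(col, depth, rng))
    return OtuTable(
        otu_ids=list(table.otu_ids),
        sample_ids=[table.sample_ids[j] for j in keep],
        counts=np.column_stack(cols) if cols else np.zeros((len(table.otu_ids), 0), dtype=int),
        lineages=dict(table.lineages),
    )


def aggregate_by_lineage(table: OtuTable, rank: int) -> OtuTable:
    """Collapse OTUs sharing the same name down to rank level ``rank``.

    ``rank`` is a 0-based depth into the semicolon-delimited lineage;
    lineages shorter than the rank keep their deepest name.  Identity is the
    full name-path prefix, so homonym taxa under different parents stay
    distinct.  Per-sample read totals are conserved.
    """
    if rank < 0:
        raise ValueError("rank must be nonnegative")
    groups: dict[str, list[int]] = {}
    for i, otu in enumerate(table.otu_ids):
        parts = parse_lineage(table.lineages[otu])
        key = LINEAGE_SEP.join(parts[: rank + 1])
        groups.setdefault(key, []).append(i)
    new_ids = list(groups)
    counts = np.vstack(
        [table.counts[idx, :].sum(axis=0) for idx in groups.values()]
    )
    lineages = {key: key for key in groups}
    return OtuTable(
        otu_ids=new_ids,
        sample_ids=list(table.sample_ids),
        counts=counts,
        lineages=lineages,
    )
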