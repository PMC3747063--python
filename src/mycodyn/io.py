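"""TSV and Newick readers/writers.

Dense tab-separated text is the canonical dialect for every table (the
study scale is hundreds of samples and ~100 OTUs).  All writers accept an
optional provenance mapping which is emitted as ``# key=value`` comment
lines; readers skip comment lines.  Floats are serialized with 10
significant digits so write-then-read is an identity to numerical noise.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import Assay, Group, QpcrMeasurement, SampleRecord
from .community import OtuTable
from .phylodiversity import DistanceMatrix, TaxonomyTree, build_taxonomy_tree

__all__ = [
    "write_metadata", "read_metadata",
    "write_qpcr", "read_qpcr",
    "write_otu_table", "read_otu_table",
    "write_distance_matrix", "read_distance_matrix",
    "write_newick", "read_newick",
]

FLOAT_FMT = "%.17g"  # shortest-lossless would also do; 17 digits round-trips


def _write_header(fh, provenance: Mapping[str, object] | None) -> None:
    for key, value in (provenance or {}).items():
        fh.write(f"# {key}={value}\n")


def _open_skipping_comments(path: str | Path) -> _io.StringIO:
    """Return file content with comment lines removed, tracking line offsets."""
    lines = Path(path).read_text().splitlines(keepends=True)
    kept = [ln for ln in lines if not ln.startswith("#")]
    return _io.StringIO("".join(kept))


def write_metadata(
    records: Sequence[SampleRecord],
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write(
            "sample_id\tmouse_id\tcage_id\tgroup\tday\tdna_yield_ng_per_pellet\n"
        )
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.mouse_id}\t{r.cage_id}\t{r.group.value}\t"
                f"{r.day}\t{FLOAT_FMT % r.dna_yield_ng_per_pellet}\n"
            )


def read_metadata(path: str | Path) -> list[SampleRecord]:
    out: list[SampleRecord] = []
    with open(path) as fh:
        lineno = 0
        header: list[str] | None = None
        for raw in fh:
            lineno += 1
            if raw.startswith("#") or not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            row = dict(zip(header, parts))
            try:
                out.append(
                    SampleRecord(
                        sample_id=row["sample_id"],
                        mouse_id=row["mouse_id"],
                        cage_id=row["cage_id"],
                        group=Group(row["group"]),
                        day=int(row["day"]),
                        dna_yield_ng_per_pellet=float(
                            row["dna_yield_ng_per_pellet"]
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_qpcr(
    measurements: Sequence[QpcrMeasurement],
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("sample_id\tassay\tapparent_copies_per_ng\n")
        for m in measurements:
            fh.write(
                f"{m.sample_id}\t{m.assay.value}\t"
                f"{FLOAT_FMT % m.apparent_copies_per_ng}\n"
            )


def read_qpcr(path: str | Path) -> list[QpcrMeasurement]:
    out: list[QpcrMeasurement] = []
    with open(path) as fh:
        lineno = 0
        header: list[str] | None = None
        for raw in fh:
            lineno += 1
            if raw.startswith("#") or not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            row = dict(zip(header, parts))
            try:
                out.append(
                    QpcrMeasurement(
                        sample_id=row["sample_id"],
                        assay=Assay(row["assay"]),
                        apparent_copies_per_ng=float(
                            row["apparent_copies_per_ng"]
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_otu_table(
    table: OtuTable,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """OTUs as rows, samples as columns, lineage string in the last column."""
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("otu_id\t" + "\t".join(table.sample_ids) + "\tlineage\n")
        for i, otu in enumerate(table.otu_ids):
            counts = "\t".join(str(int(c)) for c in table.counts[i, :])
            fh.write(f"{otu}\t{counts}\t{table.lineages[otu]}\n")


def read_otu_table(path: str | Path) -> OtuTable:
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    lineages: dict[str, str] = {}
    sample_ids: list[str] | None = None
    with open(path) as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            if raw.startswith("#") or not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if sample_ids is None:
                if parts[0] != "otu_id" or parts[-1] != "lineage":
                    raise ValueError(
                        f"{path}: line {lineno}: header must start with "
                        "'otu_id' and end with 'lineage'"
                    )
                sample_ids = parts[1:-1]
                continue
            if len(parts) != len(sample_ids) + 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(sample_ids) + 2} "
                    f"fields, got {len(parts)}"
                )
            otu = parts[0]
            try:
                counts = [int(c) for c in parts[1:-1]]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if any(c < 0 for c in counts):
                raise ValueError(
                    f"{path}: line {lineno}: negative count for OTU {otu!r}"
                )
            otu_ids.append(otu)
            rows.append(counts)
            lineages[otu] = parts[-1]
    if sample_ids is None:
        raise ValueError(f"{path}: no header line found")
    return OtuTable(
        otu_ids=otu_ids,
        sample_ids=sample_ids,
        counts=np.asarray(rows, dtype=int)
        if rows
        else np.zeros((0, len(sample_ids)), dtype=int),
        lineages=lineages,
    )


def write_distance_matrix(
    dm: DistanceMatrix,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Square TSV with a header row and a leading id column."""
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("sample_id\t" + "\t".join(dm.sample_ids) + "\n")
        for i, sid in enumerate(dm.sample_ids):
            vals = "\t".join(FLOAT_FMT % v for v in dm.values[i, :])
            fh.write(f"{sid}\t{vals}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(
        _open_skipping_comments(path), sep="\t", index_col=0
    )
    values = df.to_numpy(dtype=float)
    # symmetrize away round-trip noise below the type's own tolerance
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(sample_ids=list(df.columns), values=values)


def write_newick(tree: TaxonomyTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> "object":
    """Read a Newick file into a scikit-bio ``TreeNode``.

    Taxonomy trees are canonically rebuilt from lineage strings; Newick
    import is provided for interoperability and round-trip checks.
    """
    import skbio

    return skbio.TreeNode.read(str(path))
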