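"""Taxonomy-derived trees, UniFrac, PCoA and Procrustes.

De novo phylogenies are infeasible for ITS amplicons (the spacer varies too
much in length to align), so communities are compared on a tree built from
taxonomic lineage strings instead: shared lineage prefixes share internal
nodes, every edge gets length 1, and each OTU hangs as a leaf below its
deepest named taxon.  UniFrac distances over such a tree measure how much
taxonomic "branch length" two communities do not share — unweighted UniFrac
from presence/absence, weighted UniFrac from relative abundances.

Ordination is classical PCoA; agreement between two ordinations of the same
samples (e.g. from the 18S and ITS amplicons) is scored by orthogonal
Procrustes superimposition with a permutation null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes

from .community import LINEAGE_SEP, OtuTable, parse_lineage

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonomyTree",
    "DistanceMatrix",
    "Ordination",
    "build_taxonomy_tree",
    "unweighted_unifrac",
    "weighted_unifrac",
    "unifrac_matrix",
    "pcoa",
    "procrustes_test",
]


@dataclass
class TaxonomyTree:
    """Rooted tree from lineage strings; every edge has length exactly 1.

    Nodes are indexed 0..n-1 with node 0 the synthetic root.  ``parent[i]``
    is the parent index (-1 for the root).  Leaves correspond 1:1 to OTUs.
    Node identity is the full name-path, so homonym taxa under different
    parents remain distinct nodes.
    """

    parent: np.ndarray          # (n_nodes,) parent index, -1 at root
    names: list[str]            # name-path per node ("" for root)
    leaf_index: dict[str, int]  # otu_id -> node index

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def total_branch_length(self) -> float:
        return float(self.n_edges)

    def depth(self, node: int) -> int:
        d = 0
        while self.parent[node] >= 0:
            node = int(self.parent[node])
            d += 1
        return d

    def leaf_proportions(self, otu_ids: list[str], counts: np.ndarray) -> np.ndarray:
        """Spread a per-OTU count vector onto tree nodes (leaves only)."""
        v = np.zeros(self.n_nodes)
        for otu, c in zip(otu_ids, np.asarray(counts, dtype=float)):
            v[self.leaf_index[otu]] = c
        return v

    def descendant_totals(self, leaf_values: np.ndarray) -> np.ndarray:
        """Sum leaf values up the tree: out[i] = total below-or-at node i.

        Nodes are created parent-before-child, so a reverse index sweep
        accumulates children into parents in one pass.
        """
        acc = np.asarray(leaf_values, dtype=float).copy()
        for i in range(self.n_nodes - 1, 0, -1):
            acc[self.parent[i]] += acc[i]
        return acc

    def to_newick(self) -> str:
        """Newick string with unit branch lengths written explicitly."""
        children: dict[int, list[int]] = {}
        for i in range(1, self.n_nodes):
            children.setdefault(int(self.parent[i]), []).append(i)
        node_label = {v: k for k, v in self.leaf_index.items()}

        def fmt(i: int) -> str:
            label = node_label.get(i, self.names[i].split(LINEAGE_SEP)[-1])
            label = label.replace(" ", "_")
            if i in children:
                inner = ",".join(fmt(c) for c in children[i])
                s = f"({inner}){label}"
            else:
                s = label
            return s if self.parent[i] < 0 else f"{s}:1.0"

        return fmt(0) + ";"


def build_taxonomy_tree(lineages: dict[str, str]) -> TaxonomyTree:
    """Build a unit-edge tree from ``otu_id -> lineage string``.

    A synthetic root joins the top-level taxa; each OTU becomes a leaf
    hanging (one edge) below its deepest named taxon.  Empty rank names are
    skipped so sparse annotations do not create anonymous nodes.
    """
    if not lineages:
        raise ValueError("no lineages given")
    parent: list[int] = [-1]
    names: list[str] = [""]
    path_index: dict[str, int] = {"": 0}
    leaf_index: dict[str, int] = {}

    for otu_id, lineage in lineages.items():
        if not lineage.strip():
            raise ValueError(f"empty lineage for OTU {otu_id!r}")
        node = 0
        path_parts: list[str] = []
        for name in parse_lineage(lineage):
            if not name:
                continue
            path_parts.append(name)
            path = LINEAGE_SEP.join(path_parts)
            if path not in path_index:
                path_index[path] = len(names)
                parent.append(node)
                names.append(path)
            node = path_index[path]
        # leaf for the OTU itself, one edge below its deepest taxon
        leaf_index[otu_id] = len(names)
        parent.append(node)
        names.append(names[node] + LINEAGE_SEP + otu_id if node else otu_id)
    return TaxonomyTree(
        parent=np.asarray(parent, dtype=int), names=names, leaf_index=leaf_index
    )


def _branch_coverage(
    tree: TaxonomyTree, otu_ids: list[str], counts: np.ndarray
) -> np.ndarray:
    leaf = tree.leaf_proportions(otu_ids, counts)
    return tree.descendant_totals(leaf)


def unweighted_unifrac(
    tree: TaxonomyTree,
    otu_ids: list[str],
    counts_i: np.ndarray,
    counts_j: np.ndarray,
) -> float:
    """Unique / total covered branch length, from presence (count > 0).

    Returns a distance in [0, 1].  The root's in-edge does not exist, so the
    root node is excluded from the branch sums.
    """
    ai = _branch_coverage(tree, otu_ids, np.asarray(counts_i) > 0) > 0
    aj = _branch_coverage(tree, otu_ids, np.asarray(counts_j) > 0) > 0
    ai, aj = ai[1:], aj[1:]  # one unit-length branch above every non-root node
    union = np.logical_or(ai, aj)
    if not union.any():
        raise ValueError("both samples are empty")
    unique = np.logical_xor(ai, aj)
    return float(unique.sum() / union.sum())


def weighted_unifrac(
    tree: TaxonomyTree,
    otu_ids: list[str],
    counts_i: np.ndarray,
    counts_j: np.ndarray,
    normalized: bool = True,
) -> float:
    """Abundance-weighted UniFrac: sum_b |A_b - B_b| over unit branches.

    A_b/B_b are the fractions of each sample's reads descending through
    branch b.  The normalized variant divides by the maximum attainable
    value for this tree and pair of samples — the same branch sum with each
    sample packed onto its own leaves, i.e. sum_b (A_b + B_b) with no
    sharing, computed from leaf depths — so it lies in [0, 1] and is
    comparable with the unweighted variant.
    """
    ci = np.asarray(counts_i, dtype=float)
    cj = np.asarray(counts_j, dtype=float)
    if ci.sum() <= 0 or cj.sum() <= 0:
        raise ValueError("zero-total sample")
    a = _branch_coverage(tree, otu_ids, ci / ci.sum())[1:]
    b = _branch_coverage(tree, otu_ids, cj / cj.sum())[1:]
    raw = float(np.abs(a - b).sum())
    if not normalized:
        return raw
    depths = np.array(
        [tree.depth(tree.leaf_index[o]) for o in otu_ids], dtype=float
    )
    dmax = float(
        np.dot(depths, ci / ci.sum()) + np.dot(depths, cj / cj.sum())
    )
    return raw / dmax if dmax > 0 else 0.0


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v


def unifrac_matrix(
    tree: TaxonomyTree, table: OtuTable, weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """All pairwise UniFrac distances for the samples of a table.

    Vectorized over samples: the (branches x samples) coverage matrix is
    accumulated once, then pairwise sums reduce to matrix products
    (unweighted) or city-block distances (weighted).  Agrees with the
    pairwise functions to machine precision.
    """
    n = len(table.sample_ids)
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=0)
    if weighted and np.any(totals <= 0):
        raise ValueError("zero-total sample")
    # (n_nodes x n_samples) leaf matrix, then accumulate children into parents
    def coverage(leaf_vals: np.ndarray) -> np.ndarray:
        acc = np.zeros((tree.n_nodes, n))
        for k, otu in enumerate(table.otu_ids):
            acc[tree.leaf_index[otu], :] = leaf_vals[k, :]
        for i in range(tree.n_nodes - 1, 0, -1):
            acc[tree.parent[i]] += acc[i]
        return acc[1:]  # drop root: no branch above it

    if not weighted:
        a = (coverage((counts > 0).astype(float)) > 0).astype(float)
        inter = a.T @ a
        sizes = a.sum(axis=0)
        union = sizes[:, None] + sizes[None, :] - inter
        if np.any(union.diagonal() == 0):
            raise ValueError("empty sample in table")
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (union - inter) / union
        d = np.nan_to_num(d)
    else:
        rel = counts / totals
        a = coverage(rel)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(a.T, metric="cityblock"))
        if normalized:
            depths = np.array(
                [tree.depth(tree.leaf_index[o]) for o in table.otu_ids],
                dtype=float,
            )
            s = depths @ rel
            dmax = s[:, None] + s[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                d = d / dmax
            d = np.nan_to_num(d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(sample_ids=list(table.sample_ids), values=d)


@dataclass
class Ordination:
    """PCoA embedding: centered coordinates, eigenvalues descending."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_axes)
    eigenvalues: np.ndarray  # all eigenvalues incl. negatives, descending


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Classical (metric) multidimensional scaling.

    Double-center -D^2/2, eigendecompose, keep axes with eigenvalues above
    a small positive tolerance; negative eigenvalues (non-Euclidean input)
    are reported in ``eigenvalues`` but contribute no axis.
    """
    d = dm.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-12
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if (evals < -tol).any():
        logger.info(
            "PCoA input not Euclidean: %d negative eigenvalues dropped",
            int((evals < -tol).sum()),
        )
    if coords.size == 0:
        coords = np.zeros((n, 1))
    return Ordination(
        sample_ids=list(dm.sample_ids), coordinates=coords, eigenvalues=evals
    )


def _pad_columns(x: np.ndarray, k: int) -> np.ndarray:
    if x.shape[1] >= k:
        return x[:, :k]
    return np.hstack([x, np.zeros((x.shape[0], k - x.shape[1]))])


def procrustes_test(
    x: Ordination,
    y: Ordination,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Procrustes concordance of two ordinations with a permutation null.

    Both configurations are translated, scaled to unit total variance, and
    optimally rotated (reflections allowed); ``m2`` is the residual sum of
    squares of the superimposition.  The null permutes the sample labels of
    ``y``; p = (#{m2_perm <= m2_obs} + 1) / (n_perm + 1).
    """
    if x.sample_ids != y.sample_ids:
        raise ValueError("ordinations must cover the same samples in order")
    n = len(x.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    k = max(x.coordinates.shape[1], y.coordinates.shape[1])
    xm = _pad_columns(x.coordinates, k)
    ym = _pad_columns(y.coordinates, k)
    _, _, m2 = _scipy_procrustes(xm, ym)
    rng = np.random.default_rng(rng)
    hits = 0
    identity = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        while np.array_equal(perm, identity):
            # the identity is the observed labeling, already counted by +1
            perm = rng.permutation(n)
        _, _, m2p = _scipy_procrustes(xm, ym[perm])
        if m2p <= m2:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(m2), float(p)
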