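"""Distance-based phylogeny of labelled VWD domain sequences.

Trees are built by neighbor joining on pairwise distances computed from a
supplied protein alignment (p-distance or its Poisson correction,
d = -ln(1 - p)), with pairwise deletion of gapped columns.  Branch support
comes from column-resampling bootstrap: the support of each internal
bipartition of the full-data tree is the percentage of replicate trees
containing it.  Trees are dendropy objects throughout, so Newick I/O,
rerooting on an outgroup (the convention here: the fruit-fly Hemolectin
VWD domain) and bipartition bookkeeping use dendropy's machinery.

Neighbor joining is exact on additive distance matrices; ties in the
Q-criterion are broken by the lowest index pair, which makes the whole
construction deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "DomainAlignment",
    "DistanceMatrix",
    "read_alignment_fasta",
    "pairwise_distance",
    "nj_tree",
    "bootstrap_support",
    "root_at",
    "write_newick",
    "read_newick",
]

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}


class DistanceUndefinedError(ValueError):
    """A pairwise distance could not be computed (all-gap overlap or p = 1)."""


@dataclass(frozen=True)
class DomainAlignment:
    """A multiple sequence alignment of (domain) protein sequences."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subsample_columns(self, columns: np.ndarray) -> "DomainAlignment":
        rows = tuple("".join(r[c] for c in columns) for r in self.rows)
        return DomainAlignment(self.ids, rows)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < 0).any():
            raise ValueError("negative distances")


def read_alignment_fasta(path: str | Path) -> DomainAlignment:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return DomainAlignment(tuple(ids), tuple(rows))


def write_alignment_fasta(aln: DomainAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, row in zip(aln.ids, aln.rows):
            fh.write(f">{tid}\n{row}\n")


# ---------------------------------------------------------------------------
# Distances


def pairwise_distance(aln: DomainAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise p- or Poisson-corrected distances with pairwise deletion.

    For each pair, only columns where neither row has a gap contribute:
    p = mismatches / non-gap columns; poisson: d = -ln(1 - p).  A pair with
    no shared non-gap column, or p = 1 under the Poisson model, raises
    :class:`DistanceUndefinedError` naming the pair.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}; expected 'p' or 'poisson'")
    n = aln.n_taxa
    mat = np.zeros((n, n))
    arrs = [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in aln.rows]
    gap_codes = np.array([ord(c) for c in GAP_CHARS], dtype=np.uint8)
    nongap = [~np.isin(a, gap_codes) for a in arrs]
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            overlap = int(both.sum())
            if overlap == 0:
                raise DistanceUndefinedError(
                    f"taxa {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                    f"ungapped column"
                )
            p = float((arrs[i][both] != arrs[j][both]).sum()) / overlap
            if model == "p":
                d = p
            else:
                if p >= 1.0:
                    raise DistanceUndefinedError(
                        f"taxa {aln.ids[i]!r} and {aln.ids[j]!r}: p = 1, "
                        f"Poisson distance undefined"
                    )
                d = -math.log(1.0 - p)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(tuple(aln.ids), mat)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; trifurcating central node).

    Deterministic: the pair minimising the Q-criterion is chosen with ties
    broken by the lowest index pair.  Branch lengths follow the standard NJ
    formulas and are not clamped, so an additive input matrix is reproduced
    exactly by the tree's path lengths.
    """
    n = dist.values.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(dist.ids))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for label in dist.ids:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(label)
        nodes.append(nd)
    D = dist.values.astype(float).copy()

    def argmin_pair(Q: np.ndarray) -> tuple[int, int]:
        m = Q.shape[0]
        best = (0, 1)
        best_val = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] < best_val:
                    best_val = Q[i, j]
                    best = (i, j)
        return best

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = argmin_pair(Q)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three nodes around a central (unrooted) vertex
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    lengths = (
        0.5 * (d_ab + d_ac - d_bc),
        0.5 * (d_ab + d_bc - d_ac),
        0.5 * (d_ac + d_bc - d_ab),
    )
    for nd, ln in zip(nodes, lengths):
        center.add_child(nd)
        nd.edge.length = ln
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap support


def _split_key(edge: dendropy.Edge, all_leaves: frozenset[str]) -> frozenset[str] | None:
    """Canonical key of the bipartition induced by an internal edge.

    The key is the smaller side of the split (ties: the side not containing
    the lexicographically smallest taxon is avoided, i.e. the side that
    contains it is complemented).  Pendant edges and the root edge yield
    None — they carry no support.
    """
    head = edge.head_node
    if head is None or head.is_leaf() or edge.tail_node is None:
        return None
    below = frozenset(lf.taxon.label for lf in head.leaf_iter())
    if len(below) <= 1 or len(below) >= len(all_leaves) - 1:
        return None  # trivial split
    other = all_leaves - below
    anchor = min(all_leaves)
    return below if anchor not in below else other


def _internal_splits(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Edge]:
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset[str], dendropy.Edge] = {}
    for edge in tree.preorder_edge_iter():
        key = _split_key(edge, leaves)
        if key is not None:
            out[key] = edge
    return out


def bootstrap_support(
    aln: DomainAlignment,
    B: int = 100,
    seed: int = 0,
    model: str = "poisson",
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    The alignment's columns are resampled with replacement ``B`` times; the
    support of each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it.  Replicates on which a
    distance is undefined are skipped and logged; the effective replicate
    count is recorded on the returned tree as ``effective_bootstrap_n``.
    Supports are stored as internal node labels (percent strings) and on
    each edge as ``edge.support``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    full_tree = nj_tree(pairwise_distance(aln, model=model))
    target_splits = _internal_splits(full_tree)
    counts = {key: 0 for key in target_splits}
    effective = 0
    for b in range(B):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = aln.subsample_columns(cols)
        try:
            rep_tree = nj_tree(pairwise_distance(rep, model=model))
        except DistanceUndefinedError as exc:
            logger.warning("bootstrap replicate %d skipped: %s", b, exc)
            continue
        effective += 1
        rep_splits = _internal_splits(rep_tree)
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, edge in target_splits.items():
        support = 100.0 * counts[key] / effective if effective else float("nan")
        edge.support = support
        edge.head_node.label = f"{support:g}"
    full_tree.effective_bootstrap_n = effective
    return full_tree


# ---------------------------------------------------------------------------
# Rooting and Newick I/O


def root_at(tree: dendropy.Tree, outgroup_taxon: str) -> dendropy.Tree:
    """Root a (copy of a) tree on the outgroup's pendant edge.

    The pendant edge is split at its midpoint; bootstrap supports stored in
    internal node labels are re-derived from the unrooted bipartitions so
    they stay attached to the same splits.
    """
    support_map = {
        key: getattr(edge, "support", None)
        for key, edge in _internal_splits(tree).items()
    }
    rooted: dendropy.Tree = tree.clone(depth=1)
    leaf = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup_taxon:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup taxon {outgroup_taxon!r} not in tree")
    pendant = leaf.edge.length if leaf.edge.length is not None else 0.0
    rooted.is_rooted = True
    rooted.reroot_at_edge(leaf.edge, length1=pendant / 2.0, length2=pendant / 2.0)
    # restore supports on matching splits
    for node in rooted.preorder_node_iter():
        if not node.is_leaf():
            node.label = None
    for key, edge in _internal_splits(rooted).items():
        support = support_map.get(key)
        if support is not None:
            edge.support = support
            edge.head_node.label = f"{support:g}"
    return rooted


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    text = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if not text.endswith(";"):
        text += ";"
    Path(path).write_text(text + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True)
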