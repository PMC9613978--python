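"""Distance-tree verification that syngen labels form monophyletic clades.

A deliberately lightweight check: p-distances, a deterministic neighbour-
joining tree, a bipartition-based monophyly test, and a column-resampling
bootstrap.  Clade recovery, not branch-length fidelity, is the contract —
model-based likelihood phylogenetics is out of scope here.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import CladePartition, MarkerAlignment, SequenceRecord, UNKNOWN, is_missing

logger = logging.getLogger("syngenmark")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix has a non-zero diagonal")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < 0).any() or (self.d > 1 + 1e-12).any():
            raise ValueError("p-distances must lie in [0, 1]")


@dataclass
class Tree:
    """Unrooted tree with branch lengths, held as dendropy + Newick."""

    newick: str
    dtree: dendropy.Tree

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(newick=newick, dtree=dtree)

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.dtree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def p_distance(aln: MarkerAlignment) -> DistanceMatrix:
    """Pairwise fraction of mismatches over shared determinate columns."""
    if len(aln) < 3:
        raise ValueError("p_distance needs at least 3 records")
    seqs = [rec.seq for rec in aln]
    marker = aln.marker
    n = len(seqs)
    ok = np.array(
        [[not is_missing(c, marker) for c in s] for s in seqs], dtype=bool
    )
    chars = np.array([list(s) for s in seqs])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"records {aln.records[i].id!r} and {aln.records[j].id!r} "
                    "share no determinate column"
                )
            mism = int((chars[i][shared] != chars[j][shared]).sum())
            d[i, j] = d[j, i] = mism / n_shared
    return DistanceMatrix(ids=aln.ids(), d=d)


def concatenate_alignments(alns: list[MarkerAlignment]) -> MarkerAlignment:
    """Column-wise concatenation over the shared id set (order of the first).

    Used to mirror SSU+ITS concatenation; the result is tagged with the first
    alignment's marker (column provenance is the cumulative offset of each
    input's length, logged for reference).
    """
    if not alns:
        raise ValueError("nothing to concatenate")
    common = set(alns[0].ids())
    for aln in alns[1:]:
        common &= set(aln.ids())
    if not common:
        raise ValueError("no record id shared by all alignments")
    ids = [i for i in alns[0].ids() if i in common]
    offset = 0
    for aln in alns:
        logger.info("concatenation: %s occupies columns %d..%d",
                    aln.marker, offset + 1, offset + aln.length)
        offset += aln.length
    records = [
        SequenceRecord(
            id=rid,
            seq="".join(aln.get(rid).seq for aln in alns),
            marker=alns[0].marker,
        )
        for rid in ids
    ]
    return MarkerAlignment(alns[0].marker, records)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining, ties broken by the smallest (i, j) pair.

    Negative branch lengths are clamped to zero (logged).  Returns an unrooted
    tree whose final join is a trifurcation.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor_joining needs at least 3 taxa")

    def bl(x: float) -> float:
        if x < 0:
            logger.info("NJ: clamping negative branch length %.4g to 0", x)
            return 0.0
        return x

    d = dm.d.astype(float).copy()
    # each active node is a newick fragment
    labels = [_quote(l) for l in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) among ties, in current active-index order
        best = None
        qmin = q.min()
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    best = (i, j)
                    break
            if best:
                break
        i, j = best
        gi, gj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = bl(li), bl(lj)
        # distances from the new node u to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        merged = f"({labels[gi]}:{li:.10g},{labels[gj]}:{lj:.10g})"
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k_local, gk in enumerate(active):
            if gk in (gi, gj):
                continue
            duk = 0.5 * (sub[i, k_local] + sub[j, k_local] - dij)
            d[u, gk] = d[gk, u] = max(duk, 0.0)
        labels.append(merged)
        active = [g for g in active if g not in (gi, gj)] + [u]
    # final trifurcation via the three-point formulas
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = bl(0.5 * (dab + dac - dbc))
    lb = bl(0.5 * (dab + dbc - dac))
    lc = bl(0.5 * (dac + dbc - dab))
    newick = (
        f"({labels[a]}:{la:.10g},{labels[b]}:{lb:.10g},{labels[c]}:{lc:.10g});"
    )
    return Tree.from_newick(newick)


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------


def tree_bipartitions(tree: Tree) -> list[frozenset[str]]:
    """Leaf sets under each edge (one side of every bipartition)."""
    sides = []
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.append(leaves)
    return sides


def check_monophyly(tree: Tree, partition: CladePartition) -> dict[str, bool]:
    """Per clade: does some bipartition isolate exactly its labelled members?

    Unlabelled leaves are ignored on both sides; labelled ids missing from the
    tree are an error.
    """
    leaf_labels = tree.leaf_labels()
    clades = partition.clades()
    labelled = set()
    for members in clades.values():
        for m in members:
            if m not in leaf_labels:
                raise ValueError(f"labelled id {m!r} is not a leaf of the tree")
        labelled.update(members)
    all_leaves = frozenset(leaf_labels)
    sides = tree_bipartitions(tree)
    result = {}
    for clade, members in clades.items():
        target = frozenset(members)
        mono = False
        for side in sides:
            for half in (side, all_leaves - side):
                if half & labelled == target:
                    mono = True
                    break
            if mono:
                break
        result[clade] = mono
    return result


def bootstrap_support(
    aln: MarkerAlignment,
    partition: CladePartition,
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of column-resampled NJ trees in which each clade is monophyletic."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    clades = sorted(partition.clades())
    hits = {c: 0 for c in clades}
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        records = [
            SequenceRecord(id=r.id, seq="".join(r.seq[c] for c in cols), marker=aln.marker)
            for r in aln
        ]
        rep_aln = MarkerAlignment(aln.marker, records)
        tree = neighbor_joining(p_distance(rep_aln))
        mono = check_monophyly(tree, partition)
        for c in clades:
            hits[c] += int(mono[c])
    return {c: hits[c] / n_reps for c in clades}
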