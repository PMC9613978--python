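"""Statistical-parsimony haplotype networks with geographic annotation.

Records are collapsed into haplotypes, pairwise mutational step counts are
Hamming distances over mutually determinate columns, and haplotypes are linked
in non-decreasing step order up to a *connection limit* — the largest number
of steps that can still be accepted, at confidence ``alpha`` (default 0.95),
as free of homoplasy.  Components of the resulting graph are the networks;
each node carries the geographic composition of its members.

Connection probability
----------------------
The probability that ``j`` mutational steps over an alignment of ``L``
compared characters are all parsimonious (no site hit twice, hence no hidden
or parallel change) is modelled by placing the ``j`` mutations independently
and uniformly over the ``L`` sites:

    P_j = prod_{i=0}^{j-1} (1 - i/L)  =  L! / ((L-j)! * L**j)

The connection limit J is the largest ``j`` with ``P_j > alpha``.  ``P_0 = 1``
and ``P_j`` is strictly decreasing in ``j``, non-decreasing in ``L``, so J is
non-decreasing in ``L`` and non-increasing in ``alpha``; as ``alpha -> 0``
every connection up to ``L`` steps becomes admissible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .seqio import CladePartition, MarkerAlignment, SequenceRecord, UNKNOWN, is_missing

logger = logging.getLogger("syngenmark")

DEFAULT_ALPHA = 0.95
#: fraction of records that must be determinate at a column for it to count
#: towards the compared-character total L
DEFAULT_COVERAGE = 0.90


@dataclass
class Haplotype:
    hap_id: str
    member_ids: frozenset[str]
    representative_seq: str
    marker: str
    region_counts: dict[str, int] = field(default_factory=dict)

    @property
    def freq(self) -> int:
        return len(self.member_ids)

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"haplotype {self.hap_id}: empty member set")
        if self.region_counts and sum(self.region_counts.values()) != self.freq:
            raise ValueError(f"haplotype {self.hap_id}: region counts do not sum to freq")


@dataclass(frozen=True)
class ConnectionLimit:
    L: int
    alpha: float
    limit_J: int


@dataclass
class HaplotypeNetwork:
    nodes: list[Haplotype]
    edges: list[tuple[str, str, int]]          # (hap_a, hap_b, steps)
    components: list[frozenset[str]]           # partition of hap_ids
    limit: ConnectionLimit

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for hap in self.nodes:
            g.add_node(
                hap.hap_id,
                freq=hap.freq,
                members=",".join(sorted(hap.member_ids)),
                region_counts=json.dumps(hap.region_counts, sort_keys=True),
            )
        for a, b, steps in self.edges:
            g.add_edge(a, b, steps=steps)
        return g


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------


def _compatible(a: str, b: str, marker: str) -> bool:
    """Equal at every column determinate in both sequences."""
    return all(
        x == y or is_missing(x, marker) or is_missing(y, marker)
        for x, y in zip(a, b)
    )


def _n_missing(seq: str, marker: str) -> int:
    return sum(is_missing(c, marker) for c in seq)


def collapse_haplotypes(
    aln: MarkerAlignment,
    meta: pd.DataFrame | None = None,
    missing_policy: str = "strict",
) -> list[Haplotype]:
    """Merge identical records into haplotypes.

    ``strict`` merges exact string matches only; ``infer`` also merges records
    that agree at every column determinate in both (missing states inferred
    from the partner), closing the merge transitively.  The representative is
    the member with the fewest missing characters (ties: smallest id).
    Haplotypes are numbered H1, H2, ... in order of first appearance.
    """
    if missing_policy not in ("strict", "infer"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    region_of = {} if meta is None else dict(zip(meta["id"], meta["region"]))
    records = list(aln)
    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if missing_policy == "strict":
                same = records[i].seq == records[j].seq
            else:
                same = _compatible(records[i].seq, records[j].seq, aln.marker)
            if same:
                parent[find(j)] = find(i)

    groups: dict[int, list[SequenceRecord]] = {}
    order: list[int] = []
    for i, rec in enumerate(records):
        root = find(i)
        if root not in groups:
            groups[root] = []
            order.append(root)
        groups[root].append(rec)

    haplotypes = []
    for n, root in enumerate(order, start=1):
        members = groups[root]
        rep = min(members, key=lambda r: (_n_missing(r.seq, aln.marker), r.id))
        region_counts: dict[str, int] = {}
        for rec in members:
            region = region_of.get(rec.id, UNKNOWN)
            region_counts[region] = region_counts.get(region, 0) + 1
        haplotypes.append(
            Haplotype(
                hap_id=f"H{n}",
                member_ids=frozenset(r.id for r in members),
                representative_seq=rep.seq,
                marker=aln.marker,
                region_counts=region_counts,
            )
        )
    return haplotypes


def pairwise_steps(h1: Haplotype, h2: Haplotype) -> int:
    """Hamming distance over columns determinate in both representatives."""
    marker = h1.marker
    return sum(
        x != y
        for x, y in zip(h1.representative_seq, h2.representative_seq)
        if not is_missing(x, marker) and not is_missing(y, marker)
    )


# ---------------------------------------------------------------------------
# Connection limit (statistical parsimony)
# ---------------------------------------------------------------------------


def parsimony_probability(j: int, L: int) -> float:
    """P that j mutational steps over L compared sites are homoplasy-free.

    Iterative product form; see the module docstring for the model.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if j < 0:
        raise ValueError(f"j must be >= 0, got {j}")
    if j > L:
        return 0.0
    p = 1.0
    for i in range(j):
        p *= 1.0 - i / L
    return p


def connection_limit(L: int, alpha: float = DEFAULT_ALPHA) -> ConnectionLimit:
    """Largest step count J whose parsimony probability exceeds *alpha*."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    j = 0
    while j < L and parsimony_probability(j + 1, L) > alpha:
        j += 1
    logger.info("connection limit: L=%d alpha=%g -> J=%d", L, alpha, j)
    return ConnectionLimit(L=L, alpha=alpha, limit_J=j)


def compared_characters(aln: MarkerAlignment, coverage: float = DEFAULT_COVERAGE) -> int:
    """Number of columns determinate in >= *coverage* of records (default 90%).

    This, not the raw alignment length, is the L used for the connection
    limit: heavily ragged columns do not contribute comparable characters.
    """
    n = len(aln)
    count = 0
    for col in range(1, aln.length + 1):
        determinate = sum(not is_missing(c, aln.marker) for c in aln.column(col))
        if determinate >= coverage * n:
            count += 1
    return max(count, 1)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def build_network(haps: list[Haplotype], limit: ConnectionLimit) -> HaplotypeNetwork:
    """Link haplotypes in non-decreasing step order up to the connection limit.

    Within a tied step count, every candidate edge joining components that
    were disconnected *before* that step class is retained (this is what
    produces reticulations); tied edges internal to an already-connected
    component are dropped.  Deterministic for any input order: candidates are
    sorted by (steps, hap_a, hap_b).
    """
    if not haps:
        raise ValueError("build_network needs at least one haplotype")
    ids = [h.hap_id for h in haps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate hap_ids")
    candidates = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            steps = pairwise_steps(haps[i], haps[j])
            if steps <= limit.limit_J:
                a, b = sorted((haps[i].hap_id, haps[j].hap_id))
                candidates.append((steps, a, b))
    candidates.sort()

    g = nx.Graph()
    g.add_nodes_from(ids)
    edges: list[tuple[str, str, int]] = []
    k = 0
    while k < len(candidates):
        steps = candidates[k][0]
        tier = []
        while k < len(candidates) and candidates[k][0] == steps:
            tier.append(candidates[k])
            k += 1
        # connectivity frozen at the start of the tier
        comp_of: dict[str, int] = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        retained = [(a, b, steps) for _, a, b in tier if comp_of[a] != comp_of[b]]
        edges.extend(retained)
        g.add_edges_from((a, b) for a, b, _ in retained)
    for a, b, steps in edges:
        assert steps <= limit.limit_J
    components = [frozenset(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: min(c))
    return HaplotypeNetwork(nodes=list(haps), edges=edges, components=components, limit=limit)


def network_from_alignment(
    aln: MarkerAlignment,
    meta: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
    missing_policy: str = "strict",
    coverage: float = DEFAULT_COVERAGE,
) -> HaplotypeNetwork:
    """Convenience: collapse -> connection limit -> network for one marker."""
    haps = collapse_haplotypes(aln, meta, missing_policy)
    limit = connection_limit(compared_characters(aln, coverage), alpha)
    return build_network(haps, limit)


# ---------------------------------------------------------------------------
# Biogeography
# ---------------------------------------------------------------------------


def summarize_biogeography(net: HaplotypeNetwork, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-syngen region sets with a Europe-only flag, plus per-component clades.

    Returns a table with one row per syngen observed among the network's
    members: syngen, sorted region list, europe_only flag, record count, and
    the components in which the syngen occurs.
    """
    syngen_of = dict(zip(meta["id"], meta["syngen"]))
    region_of = dict(zip(meta["id"], meta["region"]))
    comp_of_hap = {
        hap_id: ci for ci, comp in enumerate(net.components, start=1) for hap_id in comp
    }
    regions: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    comps: dict[str, set[int]] = {}
    for hap in net.nodes:
        for member in hap.member_ids:
            syngen = syngen_of.get(member, UNKNOWN)
            regions.setdefault(syngen, set()).add(region_of.get(member, UNKNOWN))
            counts[syngen] = counts.get(syngen, 0) + 1
            comps.setdefault(syngen, set()).add(comp_of_hap[hap.hap_id])
    rows = []
    for syngen in sorted(regions):
        observed = regions[syngen]
        known = observed - {UNKNOWN}
        rows.append(
            {
                "syngen": syngen,
                "regions": ",".join(sorted(observed)),
                "europe_only": bool(known) and known == {"Europe"},
                "n_records": counts[syngen],
                "components": ",".join(str(c) for c in sorted(comps[syngen])),
            }
        )
    return pd.DataFrame(rows, columns=["syngen", "regions", "europe_only", "n_records", "components"])


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_graphml(net: HaplotypeNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph(), str(path))


def write_network_tables(net: HaplotypeNetwork, nodes_path: str | Path,
                         edges_path: str | Path) -> None:
    comp_of = {h: ci for ci, comp in enumerate(net.components, start=1) for h in comp}
    node_rows = [
        {
            "hap_id": h.hap_id,
            "freq": h.freq,
            "component": comp_of[h.hap_id],
            "members": ",".join(sorted(h.member_ids)),
            "region_counts": json.dumps(h.region_counts, sort_keys=True),
        }
        for h in net.nodes
    ]
    pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
    edge_rows = [{"hap_a": a, "hap_b": b, "steps": s} for a, b, s in net.edges]
    pd.DataFrame(edge_rows, columns=["hap_a", "hap_b", "steps"]).to_csv(
        edges_path, sep="\t", index=False
    )
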