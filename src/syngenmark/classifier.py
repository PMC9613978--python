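"""Signature-based syngen assignment of (possibly fragmentary) query sequences.

A query is typed by reading its states at the diagnostic columns of the
combined signature.  Unaligned queries are first mapped onto reference
alignment columns by a global pairwise alignment (free end gaps, so partial
GenBank-style fragments map onto the region they cover) against the reference
consensus.

Call semantics, per clade and marker:

* a clade is **excluded** if the query state disagrees with the clade state at
  any evaluable diagnostic column of that clade;
* a clade is **matched** if it has >=1 evaluable diagnostic column and the
  query agrees at all of them;
* a clade with no evaluable diagnostic column is neutral — neither matched
  nor excluded (this is what makes an SSU-only query from the R1/R2 pair come
  out AMBIGUOUS({R1, R2}): neither clade has an SSU synapomorphy to test).

Final call: INSUFFICIENT when fewer than ``min_evaluable`` diagnostic columns
were covered at all (or every clade is neutral).  Otherwise positive evidence
outranks untestable clades: ASSIGNED when exactly one clade matched, AMBIGUOUS
when several matched, AMBIGUOUS over the neutral clades when none matched but
several were untestable, and CONFLICT when every clade is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align

from .diagnostics import CombinedSignature
from .seqio import MarkerAlignment, SequenceRecord, is_missing

logger = logging.getLogger("syngenmark")

ASSIGNED = "ASSIGNED"
AMBIGUOUS = "AMBIGUOUS"
CONFLICT = "CONFLICT"
INSUFFICIENT = "INSUFFICIENT"

#: Pairwise-alignment scoring for consensus mapping (exposed for config).
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_SCORE = -2.0

DEFAULT_MIN_EVALUABLE = 3


@dataclass
class ColumnMapping:
    """Monotone map between ungapped query positions and reference columns."""

    #: 1-based ungapped query position -> 1-based reference alignment column
    query_to_ref: dict[int, int]
    identity: float

    def __post_init__(self) -> None:
        prev_q, prev_r = 0, 0
        for q in sorted(self.query_to_ref):
            r = self.query_to_ref[q]
            if q <= prev_q or r <= prev_r:
                raise ValueError("column mapping is not strictly increasing")
            prev_q, prev_r = q, r
        self.ref_to_query = {r: q for q, r in self.query_to_ref.items()}


@dataclass
class MarkerCall:
    marker: str
    matched: set[str]
    excluded: set[str]
    conflicts: list[tuple[int, str]]          # (reference column, observed state)
    evaluable_by_clade: dict[str, int]
    n_evaluable_columns: int                   # distinct diagnostic columns covered
    identity: float


@dataclass
class ClassificationResult:
    query_id: str
    per_marker_calls: dict[str, MarkerCall]
    status: str                                # ASSIGNED/AMBIGUOUS/CONFLICT/INSUFFICIENT
    clades: tuple[str, ...]                    # the call's clade(s), empty for CONFLICT/INSUFF.

    @property
    def final_call(self) -> str:
        if self.status == ASSIGNED:
            return f"ASSIGNED({self.clades[0]})"
        if self.status == AMBIGUOUS:
            return f"AMBIGUOUS({{{','.join(self.clades)}}})"
        return self.status


def reference_consensus(ref_aln: MarkerAlignment) -> tuple[str, list[int]]:
    """Majority-state consensus of the reference alignment.

    Gap-majority columns are excluded.  Returns the consensus string and, for
    each consensus position, the 1-based reference column it represents.
    Ties are broken alphabetically for determinism.
    """
    consensus: list[str] = []
    columns: list[int] = []
    for col in range(1, ref_aln.length + 1):
        states = ref_aln.column(col)
        counts: dict[str, int] = {}
        for char in states:
            counts[char] = counts.get(char, 0) + 1
        best = max(sorted(counts), key=lambda s: counts[s])
        if best == "-":
            continue
        consensus.append(best)
        columns.append(col)
    if not consensus:
        raise ValueError("reference alignment has no non-gap-majority column")
    return "".join(consensus), columns


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    # free end gaps: GenBank records are typically partial
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    else:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def map_query_to_reference(query: SequenceRecord, ref_aln: MarkerAlignment) -> ColumnMapping:
    """Map ungapped query positions onto reference alignment columns.

    Global alignment (match +1, mismatch -1, gap -2, free end gaps) of the
    gap-stripped query against the reference consensus.
    """
    qseq = query.ungapped()
    if not qseq:
        raise ValueError(f"query {query.id!r} is empty after gap stripping")
    consensus, cons_columns = reference_consensus(ref_aln)
    alignment = _make_aligner().align(consensus, qseq)[0]
    query_to_ref: dict[int, int] = {}
    matches = 0
    aligned_pairs = 0
    target_blocks, query_blocks = alignment.aligned
    for (tstart, tend), (qstart, qend) in zip(target_blocks, query_blocks):
        for offset in range(tend - tstart):
            t, q = tstart + offset, qstart + offset
            query_to_ref[q + 1] = cons_columns[t]
            aligned_pairs += 1
            if consensus[t] == qseq[q]:
                matches += 1
    identity = matches / aligned_pairs if aligned_pairs else 0.0
    return ColumnMapping(query_to_ref=query_to_ref, identity=identity)


def _evaluate_marker(
    query: SequenceRecord,
    sig: CombinedSignature,
    ref_aln: MarkerAlignment,
) -> MarkerCall:
    marker = query.marker
    mapping = map_query_to_reference(query, ref_aln)
    qseq = query.ungapped()
    matched: set[str] = set()
    excluded: set[str] = set()
    conflicts: list[tuple[int, str]] = []
    evaluable_by_clade: dict[str, int] = {}
    covered_columns: set[int] = set()
    for clade in sig.clades:
        triples = [t for t in sig.diagnostics[clade] if t[0] == marker]
        n_evaluable = 0
        ok = True
        for _, column, state in triples:
            qpos = mapping.ref_to_query.get(column)
            if qpos is None:
                continue
            observed = qseq[qpos - 1]
            if is_missing(observed, marker):
                continue
            n_evaluable += 1
            covered_columns.add(column)
            if observed != state:
                ok = False
                conflicts.append((column, observed))
        evaluable_by_clade[clade] = n_evaluable
        if n_evaluable == 0:
            continue  # neutral
        (matched if ok else excluded).add(clade)
    return MarkerCall(
        marker=marker,
        matched=matched,
        excluded=excluded,
        conflicts=conflicts,
        evaluable_by_clade=evaluable_by_clade,
        n_evaluable_columns=len(covered_columns),
        identity=mapping.identity,
    )


def type_query(
    query: SequenceRecord | dict[str, SequenceRecord],
    sig: CombinedSignature,
    ref_alns: dict[str, MarkerAlignment],
    min_evaluable: int = DEFAULT_MIN_EVALUABLE,
) -> ClassificationResult:
    """Assign a query (one record, or {marker: record} for multi-marker strains).

    Markers are combined conservatively: a clade is excluded if excluded in any
    marker, matched if matched in at least one marker and excluded in none.
    """
    if isinstance(query, SequenceRecord):
        queries = {query.marker: query}
    else:
        queries = dict(query)
        for marker, rec in queries.items():
            if rec.marker != marker:
                raise ValueError(f"marker key {marker!r} != record marker {rec.marker!r}")
    query_id = next(iter(queries.values())).id
    calls: dict[str, MarkerCall] = {}
    for marker, rec in queries.items():
        if marker not in sig.tables:
            raise ValueError(f"marker {marker!r} absent from signature")
        if marker not in ref_alns:
            raise ValueError(f"no reference alignment supplied for marker {marker!r}")
        calls[marker] = _evaluate_marker(rec, sig, ref_alns[marker])

    total_evaluable = sum(c.n_evaluable_columns for c in calls.values())
    excluded = set().union(*(c.excluded for c in calls.values()))
    matched = set().union(*(c.matched for c in calls.values())) - excluded
    neutral = set(sig.clades) - matched - excluded

    if total_evaluable < min_evaluable or len(neutral) == len(sig.clades):
        status, clades = INSUFFICIENT, ()
    elif matched:
        # positive evidence outranks untestable (neutral) clades
        if len(matched) == 1:
            status, clades = ASSIGNED, (next(iter(matched)),)
        else:
            status, clades = AMBIGUOUS, tuple(sorted(matched))
    elif neutral:
        if len(neutral) >= 2:
            status, clades = AMBIGUOUS, tuple(sorted(neutral))
        else:
            # a single surviving clade with no positive evidence
            status, clades = INSUFFICIENT, ()
    else:
        status, clades = CONFLICT, ()
    return ClassificationResult(
        query_id=query_id, per_marker_calls=calls, status=status, clades=clades
    )


def batch_type(
    queries: list[SequenceRecord | dict[str, SequenceRecord]],
    sig: CombinedSignature,
    ref_alns: dict[str, MarkerAlignment],
    meta: pd.DataFrame | None = None,
    min_evaluable: int = DEFAULT_MIN_EVALUABLE,
) -> pd.DataFrame:
    """Type every query; per-record errors are recorded, never abort the batch.

    Returns a table of final calls joined with metadata regions (when given),
    suitable as input to the biogeography stage.
    """
    region_of = {} if meta is None else dict(zip(meta["id"], meta["region"]))
    rows = []
    for query in queries:
        qid = query.id if isinstance(query, SequenceRecord) else next(iter(query.values())).id
        try:
            result = type_query(query, sig, ref_alns, min_evaluable)
            rows.append(
                {
                    "id": qid,
                    "status": result.status,
                    "call": result.final_call,
                    "clades": ",".join(result.clades),
                    "markers": ",".join(sorted(result.per_marker_calls)),
                    "region": region_of.get(qid, "UNKNOWN"),
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 — per-record isolation is the contract
            logger.error("typing %s failed: %s", qid, exc)
            rows.append(
                {
                    "id": qid, "status": "ERROR", "call": "ERROR", "clades": "",
                    "markers": "", "region": region_of.get(qid, "UNKNOWN"),
                    "error": str(exc),
                }
            )
    columns = ["id", "status", "call", "clades", "markers", "region", "error"]
    return pd.DataFrame(rows, columns=columns)


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)
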