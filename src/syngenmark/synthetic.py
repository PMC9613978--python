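"""Truth-tracked synthetic datasets for the five-syngen typing workflow.

The generator emulates the statistical structure the analysis assumes: five
clades (R1–R5) whose members share a common root sequence per marker, with

* *planted synapomorphies* — columns where one clade is fixed for a private
  derived state;
* *shared-pair columns* — columns where two clades (by default R1 and R2 in
  the SSU) carry the same derived state, making them indistinguishable in that
  marker alone;
* *within-clade variable columns* — a proper subset of one clade carries a
  derived state, so the column is variable but diagnostic for nobody;
* a COI open reading frame (no internal stops under the configured genetic
  code) whose planted changes are nonsynonymous, so they are visible at the
  amino-acid level;
* a geographic model in which R1 and R5 are Europe-only by construction while
  the other syngens occur on several continents.

Every emitted dataset comes with a :class:`SyntheticTruth` describing exactly
what was planted, so recovery can be asserted instead of eyeballed.  There is
no within-clade branching process: each clade is a star of near-identical
sequences, which is sufficient for the discovery/typing contracts but makes
within-clade tree structure meaningless (documented limitation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codonops import GeneticCode, translate_alignment
from .seqio import (
    REGIONS,
    SYNGENS,
    MarkerAlignment,
    SequenceRecord,
    write_alignment,
    write_metadata,
)

logger = logging.getLogger("syngenmark")

NT = "ACGT"

#: Table 2 strain counts per syngen (48 strains: 11 + 12 + 20 + 4 + 1).
DEFAULT_PER_CLADE_N = (11, 12, 20, 4, 1)

DEFAULT_MARKER_LENGTHS = {"SSU": 1700, "ITS": 500, "COI_nt": 600}

#: R1 and R5 are Europe-only; the rest span several continents.
DEFAULT_REGION_MODEL = {
    "R1": {"Europe": 1.0},
    "R2": {"Europe": 0.7, "Asia": 0.3},
    "R3": {"Europe": 0.25, "Asia": 0.35, "North America": 0.15,
           "South America": 0.15, "Australia": 0.10},
    "R4": {"North America": 0.5, "Europe": 0.25, "South America": 0.25},
    "R5": {"Europe": 1.0},
}


@dataclass
class SimulationConfig:
    clade_labels: tuple[str, ...] = SYNGENS
    per_clade_n: tuple[int, ...] = DEFAULT_PER_CLADE_N
    marker_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_LENGTHS)
    )
    #: (marker, clade) -> number of planted synapomorphic columns.  For the
    #: COI marker the columns are amino-acid columns (planted as codons).
    n_synapomorphies: dict[tuple[str, str], int] = field(default_factory=dict)
    #: marker -> number of within-clade variable columns
    n_within_variable: dict[str, int] = field(default_factory=dict)
    #: (clade_a, clade_b, marker) -> number of columns where both clades share
    #: one derived state (fixed, private to the pair)
    shared_pairs: dict[tuple[str, str, str], int] = field(default_factory=dict)
    transl_table: int = 4
    query_error_rate: float = 0.0
    #: None = full length; else (min_len, max_len) windows for fragments
    fragment_length: tuple[int, int] | None = None
    region_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_MODEL.items()}
    )
    seed: int = 42

    def validate(self) -> None:
        if len(self.per_clade_n) != len(self.clade_labels):
            raise ValueError("per_clade_n and clade_labels disagree in length")
        for marker, length in self.marker_lengths.items():
            reserved = self.reserved_columns(marker)
            budget = length // 3 if marker == "COI_nt" else length
            if reserved > budget:
                raise ValueError(
                    f"{marker}: {reserved} planted columns exceed the {budget} available"
                )
        for clade, dist in self.region_model.items():
            for region in dist:
                if region not in REGIONS:
                    raise ValueError(f"region model for {clade}: unknown region {region!r}")

    def reserved_columns(self, marker: str) -> int:
        syn = sum(v for (m, _), v in self.n_synapomorphies.items() if m == marker)
        shared = sum(v for (_, _, m), v in self.shared_pairs.items() if m == marker)
        within = self.n_within_variable.get(marker, 0)
        return syn + shared + within


def fig3_preset(seed: int = 42, **overrides) -> SimulationConfig:
    """Preset reproducing the published variable-position totals by construction.

    SSU: 30 variable columns — 6 synapomorphies each for R3, R4 and R5,
    6 columns where R1 and R2 share a derived state (so the pair cannot be
    told apart by SSU alone), 6 within-clade variable.  ITS: 23 variable —
    4+4+3+3+3 synapomorphies plus 6 within-clade variable.  COI: 18 variable
    amino-acid columns of which 13 (3+3+3+2+2) are diagnostic.
    """
    cfg = SimulationConfig(
        n_synapomorphies={
            ("SSU", "R3"): 6, ("SSU", "R4"): 6, ("SSU", "R5"): 6,
            ("ITS", "R1"): 4, ("ITS", "R2"): 4, ("ITS", "R3"): 3,
            ("ITS", "R4"): 3, ("ITS", "R5"): 3,
            ("COI_nt", "R1"): 3, ("COI_nt", "R2"): 3, ("COI_nt", "R3"): 3,
            ("COI_nt", "R4"): 2, ("COI_nt", "R5"): 2,
        },
        n_within_variable={"SSU": 6, "ITS": 6, "COI_nt": 5},
        shared_pairs={("R1", "R2", "SSU"): 6},
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    clade_of: dict[str, str]
    region_of: dict[str, str]
    #: (marker, clade) -> set of (column, state); COI entries are amino-acid
    #: columns/states under the configured genetic code.
    planted_synapomorphies: dict[tuple[str, str], set[tuple[int, str]]]
    #: marker -> set of within-clade variable columns (aa columns for COI)
    planted_within_variable: dict[str, set[int]]
    #: (clade_a, clade_b, marker) -> set of shared (column, state)
    planted_shared: dict[tuple[str, str, str], set[tuple[int, str]]]
    transl_table: int

    def europe_only_clades(self) -> set[str]:
        by_clade: dict[str, set[str]] = {}
        for rid, clade in self.clade_of.items():
            by_clade.setdefault(clade, set()).add(self.region_of[rid])
        return {c for c, regions in by_clade.items() if regions == {"Europe"}}

    def to_json(self) -> str:
        payload = {
            "clade_of": self.clade_of,
            "region_of": self.region_of,
            "transl_table": self.transl_table,
            "planted_synapomorphies": {
                f"{m}|{c}": sorted([col, st] for col, st in v)
                for (m, c), v in self.planted_synapomorphies.items()
            },
            "planted_within_variable": {
                m: sorted(v) for m, v in self.planted_within_variable.items()
            },
            "planted_shared": {
                f"{a}|{b}|{m}": sorted([col, st] for col, st in v)
                for (a, b, m), v in self.planted_shared.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimulationResult:
    alignments: dict[str, MarkerAlignment]    # SSU, ITS, COI_nt, COI_aa
    metadata: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignments["SSU"], outdir / "ssu.fasta")
        write_alignment(self.alignments["ITS"], outdir / "its.fasta")
        write_alignment(self.alignments["COI_nt"], outdir / "coi.fasta")
        write_metadata(self.metadata, outdir / "meta.tsv")
        (outdir / "truth.json").write_text(self.truth.to_json() + "\n")


# ---------------------------------------------------------------------------
# Core generator
# ---------------------------------------------------------------------------


def _sample_regions(
    rng: np.random.Generator, clade: str, n: int, model: dict[str, float]
) -> list[str]:
    regions = sorted(model)
    probs = np.array([model[r] for r in regions], dtype=float)
    probs = probs / probs.sum()
    draw = list(rng.choice(regions, size=n, p=probs))
    non_europe = [r for r in regions if r != "Europe"]
    if non_europe and all(r == "Europe" for r in draw):
        # the model says this clade is not Europe-only: guarantee the planted
        # biogeography at every seed
        draw[-1] = non_europe[int(rng.integers(len(non_europe)))]
    return draw


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Generate alignments, metadata and planted truth from a config.

    All randomness flows from ``cfg.seed``; per-marker substreams are spawned
    deterministically, so outputs are byte-identical for identical configs.
    """
    cfg.validate()
    root_rng = np.random.default_rng(cfg.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("SSU", "ITS", "COI_nt", "regions", "queries"),
            root_rng.integers(0, 2**31 - 1, size=5),
        )
    }
    members: dict[str, list[str]] = {}
    ids: list[str] = []
    for clade, n in zip(cfg.clade_labels, cfg.per_clade_n):
        members[clade] = [f"{clade}_s{i:02d}" for i in range(1, n + 1)]
        ids.extend(members[clade])

    planted_syn: dict[tuple[str, str], set[tuple[int, str]]] = {}
    planted_within: dict[str, set[int]] = {}
    planted_shared: dict[tuple[str, str, str], set[tuple[int, str]]] = {}
    alignments: dict[str, MarkerAlignment] = {}

    for marker in ("SSU", "ITS"):
        aln = _simulate_nt_marker(
            cfg, marker, members, streams[marker], planted_syn, planted_within,
            planted_shared,
        )
        alignments[marker] = aln

    code = GeneticCode.from_table(cfg.transl_table)
    coi_nt, coi_aa = _simulate_coi(
        cfg, members, streams["COI_nt"], code, planted_syn, planted_within,
        planted_shared,
    )
    alignments["COI_nt"] = coi_nt
    alignments["COI_aa"] = coi_aa

    region_rng = streams["regions"]
    region_of: dict[str, str] = {}
    for clade in cfg.clade_labels:
        model = cfg.region_model.get(clade, {"Europe": 1.0})
        for rid, region in zip(members[clade],
                               _sample_regions(region_rng, clade, len(members[clade]), model)):
            region_of[rid] = region

    clade_of = {rid: clade for clade, rids in members.items() for rid in rids}
    metadata = pd.DataFrame(
        {
            "id": ids,
            "syngen": [clade_of[r] for r in ids],
            "region": [region_of[r] for r in ids],
            "strain": ids,
            "endosymbiont": ["UNKNOWN"] * len(ids),
        }
    )
    truth = SyntheticTruth(
        clade_of=clade_of,
        region_of=region_of,
        planted_synapomorphies=planted_syn,
        planted_within_variable=planted_within,
        planted_shared=planted_shared,
        transl_table=cfg.transl_table,
    )
    return SimulationResult(alignments=alignments, metadata=metadata, truth=truth, config=cfg)


def _pick_columns(rng: np.random.Generator, pool: list[int], k: int) -> list[int]:
    chosen = sorted(rng.choice(pool, size=k, replace=False).tolist()) if k else []
    for c in chosen:
        pool.remove(c)
    return chosen


def _simulate_nt_marker(
    cfg: SimulationConfig,
    marker: str,
    members: dict[str, list[str]],
    rng: np.random.Generator,
    planted_syn: dict,
    planted_within: dict,
    planted_shared: dict,
) -> MarkerAlignment:
    length = cfg.marker_lengths[marker]
    root = rng.choice(list(NT), size=length)
    seqs = {rid: root.copy() for rids in members.values() for rid in rids}
    pool = list(range(1, length + 1))

    for clade in cfg.clade_labels:
        k = cfg.n_synapomorphies.get((marker, clade), 0)
        cols = _pick_columns(rng, pool, k)
        planted = set()
        for col in cols:
            state = rng.choice([b for b in NT if b != root[col - 1]])
            for rid in members[clade]:
                seqs[rid][col - 1] = state
            planted.add((col, str(state)))
        planted_syn[(marker, clade)] = planted

    for (a, b, m), k in cfg.shared_pairs.items():
        if m != marker:
            continue
        cols = _pick_columns(rng, pool, k)
        planted = set()
        for col in cols:
            state = rng.choice([x for x in NT if x != root[col - 1]])
            for rid in members[a] + members[b]:
                seqs[rid][col - 1] = state
            planted.add((col, str(state)))
        planted_shared[(a, b, marker)] = planted

    k_within = cfg.n_within_variable.get(marker, 0)
    cols = _pick_columns(rng, pool, k_within)
    eligible = [c for c in cfg.clade_labels if len(members[c]) >= 2]
    within = set()
    for col in cols:
        clade = eligible[int(rng.integers(len(eligible)))]
        n = len(members[clade])
        n_mut = int(rng.integers(1, n))  # proper, non-empty subset
        hit = rng.choice(members[clade], size=n_mut, replace=False)
        state = rng.choice([x for x in NT if x != root[col - 1]])
        for rid in hit:
            seqs[rid][col - 1] = state
        within.add(col)
    planted_within[marker] = within

    records = [
        SequenceRecord(id=rid, seq="".join(seqs[rid]), marker=marker)
        for rids in members.values() for rid in rids
    ]
    return MarkerAlignment(marker, records)


def _simulate_coi(
    cfg: SimulationConfig,
    members: dict[str, list[str]],
    rng: np.random.Generator,
    code: GeneticCode,
    planted_syn: dict,
    planted_within: dict,
    planted_shared: dict,
) -> tuple[MarkerAlignment, MarkerAlignment]:
    """COI as an ORF; planted changes are nonsynonymous codons (visible as aa)."""
    length = cfg.marker_lengths["COI_nt"]
    n_codons = length // 3
    sense = code.sense_codons()
    root_codons = ["ATG"] + [
        sense[int(rng.integers(len(sense)))] for _ in range(n_codons - 1)
    ]
    codon_seqs = {rid: list(root_codons) for rids in members.values() for rid in rids}
    pool = list(range(1, n_codons + 1))  # amino-acid columns

    def derived_codon(aa_col: int, forbid: set[str]) -> tuple[str, str]:
        root_aa = code.translate_codon(root_codons[aa_col - 1])
        options = [c for c in sense
                   if code.translate_codon(c) != root_aa
                   and code.translate_codon(c) not in forbid]
        codon = options[int(rng.integers(len(options)))]
        return codon, code.translate_codon(codon)

    for clade in cfg.clade_labels:
        k = cfg.n_synapomorphies.get(("COI_nt", clade), 0)
        cols = _pick_columns(rng, pool, k)
        planted = set()
        for col in cols:
            codon, aa = derived_codon(col, forbid=set())
            for rid in members[clade]:
                codon_seqs[rid][col - 1] = codon
            planted.add((col, aa))
        planted_syn[("COI_aa", clade)] = planted

    for (a, b, m), k in cfg.shared_pairs.items():
        if m != "COI_nt":
            continue
        cols = _pick_columns(rng, pool, k)
        planted = set()
        for col in cols:
            codon, aa = derived_codon(col, forbid=set())
            for rid in members[a] + members[b]:
                codon_seqs[rid][col - 1] = codon
            planted.add((col, aa))
        planted_shared[(a, b, "COI_aa")] = planted

    k_within = cfg.n_within_variable.get("COI_nt", 0)
    cols = _pick_columns(rng, pool, k_within)
    eligible = [c for c in cfg.clade_labels if len(members[c]) >= 2]
    within = set()
    for col in cols:
        clade = eligible[int(rng.integers(len(eligible)))]
        n = len(members[clade])
        n_mut = int(rng.integers(1, n))
        hit = rng.choice(members[clade], size=n_mut, replace=False)
        codon, _aa = derived_codon(col, forbid=set())
        for rid in hit:
            codon_seqs[rid][col - 1] = codon
        within.add(col)
    planted_within["COI_aa"] = within

    records = [
        SequenceRecord(id=rid, seq="".join(codon_seqs[rid]) + "A" * (length - 3 * n_codons),
                       marker="COI_nt")
        for rids in members.values() for rid in rids
    ]
    coi_nt = MarkerAlignment("COI_nt", records)
    coi_aa, _colmap = translate_alignment(coi_nt, code, frame=1)
    return coi_nt, coi_aa


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------


def make_queries(
    result: SimulationResult,
    markers: tuple[str, ...] = ("SSU", "ITS"),
    n_per_clade: int = 2,
    error_rate: float | None = None,
    fragment_length: tuple[int, int] | None = None,
    seed: int | None = None,
) -> tuple[list[dict[str, SequenceRecord]], dict[str, str]]:
    """Sample members and derive (possibly fragmentary, noisy) query records.

    Returns ``(queries, truth_labels)`` where each query is a
    ``{marker: SequenceRecord}`` dict sharing one query id, and
    ``truth_labels`` maps query id to the true clade.
    """
    cfg = result.config
    error_rate = cfg.query_error_rate if error_rate is None else error_rate
    fragment_length = cfg.fragment_length if fragment_length is None else fragment_length
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    clade_members: dict[str, list[str]] = {}
    for rid, clade in result.truth.clade_of.items():
        clade_members.setdefault(clade, []).append(rid)
    queries: list[dict[str, SequenceRecord]] = []
    truth_labels: dict[str, str] = {}
    for clade in sorted(clade_members):
        rids = sorted(clade_members[clade])
        take = min(n_per_clade, len(rids))
        chosen = rng.choice(rids, size=take, replace=False)
        for rid in chosen:
            qid = f"q_{rid}"
            per_marker: dict[str, SequenceRecord] = {}
            for marker in markers:
                seq = result.alignments[marker].get(rid).ungapped()
                if fragment_length is not None:
                    lo, hi = fragment_length
                    flen = min(int(rng.integers(lo, hi + 1)), len(seq))
                    start = int(rng.integers(0, len(seq) - flen + 1))
                    seq = seq[start:start + flen]
                if error_rate > 0:
                    chars = list(seq)
                    for k in range(len(chars)):
                        if rng.random() < error_rate:
                            chars[k] = str(rng.choice([b for b in NT if b != chars[k]]))
                    seq = "".join(chars)
                per_marker[marker] = SequenceRecord(id=qid, seq=seq, marker=marker)
            queries.append(per_marker)
            truth_labels[qid] = clade
    return queries, truth_labels


# ---------------------------------------------------------------------------
# Truth/emission consistency (independent re-check pass)
# ---------------------------------------------------------------------------


def verify_truth(result: SimulationResult) -> None:
    """Assert the emitted alignments actually carry the planted truth."""
    truth = result.truth
    for (marker, clade), planted in truth.planted_synapomorphies.items():
        aln = result.alignments[marker]
        clade_ids = {r for r, c in truth.clade_of.items() if c == clade}
        for col, state in planted:
            for rec in aln:
                char = rec.seq[col - 1]
                if rec.id in clade_ids:
                    assert char == state, (marker, clade, col, rec.id)
                else:
                    assert char != state, (marker, clade, col, rec.id)
    for (a, b, marker), planted in truth.planted_shared.items():
        aln = result.alignments[marker]
        pair_ids = {r for r, c in truth.clade_of.items() if c in (a, b)}
        for col, state in planted:
            for rec in aln:
                char = rec.seq[col - 1]
                assert (char == state) == (rec.id in pair_ids), (marker, col, rec.id)
    for marker, cols in truth.planted_within_variable.items():
        aln = result.alignments[marker]
        for col in cols:
            states = set(aln.column(col))
            assert len(states) == 2, (marker, col, states)
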