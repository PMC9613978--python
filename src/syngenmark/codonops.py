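"""Codon-level operations: translating the COI nucleotide alignment.

COI is a mitochondrial protein-coding gene; the syngen signatures for it are
read at the amino-acid level.  Translation therefore has to preserve column
provenance: every amino-acid column maps back to the triple of nucleotide
alignment columns it came from (:class:`CodonColumnMap`), so that an
amino-acid synapomorphy can always be traced to its codon.

The genetic code is selectable by NCBI translation-table number.  The default
used elsewhere in the package is table 4 (mold/protozoan mitochondrial,
TGA→Trp), the standard choice for ciliate mitochondrial genes; tables 1
(standard) and 6 (ciliate nuclear, TAA/TAG→Gln) are also supported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .seqio import MarkerAlignment, SequenceRecord

logger = logging.getLogger("syngenmark")

SUPPORTED_TABLES = (1, 4, 6)
_BASES = "TCAG"
ALL_CODONS = tuple("".join(c) for c in itertools.product(_BASES, repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid map for one NCBI translation table."""

    table_id: int
    codon_map: dict[str, str] = field(repr=False)
    start_codons: frozenset[str] = field(repr=False)

    @classmethod
    def from_table(cls, table_id: int) -> "GeneticCode":
        if table_id not in SUPPORTED_TABLES:
            raise ValueError(
                f"unsupported translation table {table_id}; supported: {SUPPORTED_TABLES}"
            )
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_map = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_map[stop] = "*"
        assert len(codon_map) == 64 and set(codon_map) == set(ALL_CODONS)
        return cls(
            table_id=table_id,
            codon_map=codon_map,
            start_codons=frozenset(table.start_codons),
        )

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; any gap or ambiguity character yields ``X``."""
        return self.codon_map.get(codon.upper(), "X")

    def is_stop(self, codon: str) -> bool:
        return self.codon_map.get(codon.upper()) == "*"

    def sense_codons(self) -> list[str]:
        return [c for c in ALL_CODONS if self.codon_map[c] != "*"]


@dataclass(frozen=True)
class CodonColumnMap:
    """1-based amino-acid column → (n1, n2, n3) nucleotide columns (in frame)."""

    frame: int
    columns: dict[int, tuple[int, int, int]]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for aa_col, triple in self.columns.items():
            n1, n2, n3 = triple
            if not (n2 == n1 + 1 and n3 == n2 + 1):
                raise ValueError(f"aa column {aa_col}: codon columns {triple} not consecutive")
            if triple in seen:
                raise ValueError(f"codon column triple {triple} mapped twice")
            seen.add(triple)

    def nucleotide_columns(self, aa_col: int) -> tuple[int, int, int]:
        return self.columns[aa_col]


def translate_alignment(
    aln: MarkerAlignment, code: GeneticCode, frame: int = 1
) -> tuple[MarkerAlignment, CodonColumnMap]:
    """Translate a COI nucleotide alignment codon-by-codon.

    A codon containing any gap or ambiguity character translates to ``X``;
    a trailing incomplete codon is dropped.  Returns the peptide alignment and
    the amino-acid → nucleotide column map.
    """
    if aln.marker != "COI_nt":
        raise ValueError(f"translate_alignment expects a COI_nt alignment, got {aln.marker}")
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    n_codons = (aln.length - frame + 1) // 3
    if n_codons < 1:
        raise ValueError(
            f"alignment of length {aln.length} has no complete codon in frame {frame}"
        )
    columns = {
        k + 1: (frame + 3 * k, frame + 3 * k + 1, frame + 3 * k + 2)
        for k in range(n_codons)
    }
    records = []
    for rec in aln:
        aa = "".join(
            code.translate_codon(rec.seq[frame - 1 + 3 * k: frame + 2 + 3 * k])
            for k in range(n_codons)
        )
        records.append(SequenceRecord(id=rec.id, seq=aa, marker="COI_aa",
                                      description=rec.description))
    return MarkerAlignment("COI_aa", records), CodonColumnMap(frame=frame, columns=columns)


def count_internal_stops(aln: MarkerAlignment, code: GeneticCode, frame: int) -> int:
    """Total internal (non-terminal) stop codons across records in a frame."""
    n_codons = (aln.length - frame + 1) // 3
    if n_codons < 1:
        return 0
    stops = 0
    for rec in aln:
        for k in range(n_codons):
            codon = rec.seq[frame - 1 + 3 * k: frame + 2 + 3 * k]
            if code.codon_map.get(codon) == "*" and k < n_codons - 1:
                stops += 1
    return stops


def pick_frame(aln: MarkerAlignment, code: GeneticCode) -> int:
    """Reading frame (1-3) minimising internal stops; ties go to the lower frame."""
    counts = {f: count_internal_stops(aln, code, f) for f in (1, 2, 3)}
    best = min(counts, key=lambda f: (counts[f], f))
    logger.info("pick_frame: internal stop counts %s -> frame %d", counts, best)
    return best
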