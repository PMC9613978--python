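"""Aligned sequence and sample-metadata I/O.

All downstream stages (diagnostic-site discovery, signature typing, haplotype
networks, tree checks) operate on :class:`MarkerAlignment` objects — equal-length
sequence records for a single marker — together with a :class:`CladePartition`
mapping record ids to syngen labels.  Column indices are 1-based in every
user-facing report, matching the convention of published signature tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Nexus import Nexus

logger = logging.getLogger("syngenmark")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Marker names. COI is carried both as a coding-nucleotide alignment and as
#: its translation.
MARKERS = ("SSU", "ITS", "COI_nt", "COI_aa")

NUCLEOTIDE_MARKERS = frozenset({"SSU", "ITS", "COI_nt"})
PEPTIDE_MARKERS = frozenset({"COI_aa"})

#: Syngen (mating-group) labels of the species complex.
SYNGENS = ("R1", "R2", "R3", "R4", "R5")
UNKNOWN = "UNKNOWN"

#: Six-continent geography vocabulary used for haplotype biogeography.
REGIONS = ("Europe", "Asia", "North America", "South America", "Australia", "Africa")

ENDOSYMBIONTS = ("Cvar", "Cvul", "Mcon")

NT_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")
#: Determinate nucleotide states; everything else is "missing" under the
#: default missing-data policy.
NT_STATES = frozenset("ACGT")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBJZUOX-*")
AA_STATES = frozenset("ACDEFGHIKLMNPQRSTVWY*")


def is_missing(char: str, marker: str) -> bool:
    """True if *char* is a gap or an ambiguity code for the marker's alphabet.

    Ambiguity codes never match anything during typing or discovery: an ``R``
    at a column is treated as missing, not as "A or G" (conservative typing).
    """
    if marker in PEPTIDE_MARKERS:
        return char not in AA_STATES
    return char not in NT_STATES


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: unique id, uppercase sequence, marker tag."""

    id: str
    seq: str
    marker: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id {self.id!r} is empty or contains whitespace")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        seq = self.seq.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.marker in NUCLEOTIDE_MARKERS:
            seq = seq.replace("U", "T")
            alphabet = NT_ALPHABET
        else:
            alphabet = AA_ALPHABET
        for col, char in enumerate(seq, start=1):
            if char not in alphabet:
                raise ValueError(
                    f"record {self.id!r}: illegal character {char!r} at column {col}"
                )
        object.__setattr__(self, "seq", seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass
class MarkerAlignment:
    """Equal-length records for one marker; columns are 1-based user-facing."""

    marker: str
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        length = len(self.records[0].seq)
        for rec in self.records:
            if rec.marker != self.marker:
                raise ValueError(
                    f"record {rec.id!r} has marker {rec.marker}, alignment is {self.marker}"
                )
            if len(rec.seq) != length:
                raise ValueError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.seq)}, expected {length}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in alignment: {dup}")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def column(self, col: int) -> str:
        """States of 1-based column *col*, in record order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return "".join(rec.seq[col - 1] for rec in self.records)

    def subset(self, ids: Iterable[str]) -> "MarkerAlignment":
        wanted = set(ids)
        return MarkerAlignment(self.marker, [r for r in self.records if r.id in wanted])


@dataclass(frozen=True)
class SampleMetadata:
    id: str
    syngen: str = UNKNOWN
    region: str = UNKNOWN
    strain: str = ""
    endosymbiont: str = UNKNOWN


@dataclass
class CladePartition:
    """Record id → syngen label (``UNKNOWN`` for unlabelled queries)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for rid, label in self.assignments.items():
            if label not in SYNGENS and label != UNKNOWN:
                raise ValueError(f"record {rid!r}: unknown syngen label {label!r}")

    def label(self, record_id: str) -> str:
        return self.assignments.get(record_id, UNKNOWN)

    def clades(self) -> dict[str, list[str]]:
        """Labelled clades only, as {syngen: [record ids]} in stable order."""
        out: dict[str, list[str]] = {}
        for rid, label in self.assignments.items():
            if label != UNKNOWN:
                out.setdefault(label, []).append(rid)
        return {k: out[k] for k in sorted(out)}

    def unknown_ids(self) -> list[str]:
        return [r for r, l in self.assignments.items() if l == UNKNOWN]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _normalize_syngen(value: str) -> str:
    v = str(value).strip()
    if not v or v.lower() in {"unknown", "nan", "na", "-", "?"}:
        return UNKNOWN
    v = v.upper()
    if v not in SYNGENS:
        raise ValueError(f"unknown syngen label {value!r}; expected R1..R5 or blank")
    return v


def _normalize_region(value: str) -> str:
    v = str(value).strip()
    if not v or v.lower() in {"unknown", "nan", "na", "-", "?"}:
        return UNKNOWN
    for region in REGIONS:
        if v.lower() == region.lower():
            return region
    raise ValueError(f"unknown region {value!r}; expected one of {REGIONS} or blank")


def read_alignment(path: str | Path, marker: str, format: str = "fasta") -> MarkerAlignment:
    """Read a pre-aligned FASTA or NEXUS file into a :class:`MarkerAlignment`.

    Record order is preserved. Sequences are uppercased and, for nucleotide
    markers, U is canonicalised to T. Unequal record lengths raise a
    ragged-alignment error naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        bio_records = list(SeqIO.parse(str(path), "fasta"))
        records = [
            SequenceRecord(
                id=r.id,
                seq=str(r.seq),
                marker=marker,
                description=r.description[len(r.id):].strip(),
            )
            for r in bio_records
        ]
    elif format == "nexus":
        nex = Nexus.Nexus(str(path))
        records = [
            SequenceRecord(id=str(name), seq=str(nex.matrix[name]), marker=marker)
            for name in nex.taxlabels
        ]
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    if not records:
        raise ValueError(f"{path}: no sequence records found")
    return MarkerAlignment(marker=marker, records=records)


def write_alignment(aln: MarkerAlignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for rec in aln:
                header = rec.id if not rec.description else f"{rec.id} {rec.description}"
                fh.write(f">{header}\n{rec.seq}\n")
    elif format == "nexus":
        datatype = "protein" if aln.marker in PEPTIDE_MARKERS else "dna"
        with path.open("w") as fh:
            fh.write("#NEXUS\nbegin data;\n")
            fh.write(f"  dimensions ntax={len(aln)} nchar={aln.length};\n")
            fh.write(f"  format datatype={datatype} missing=? gap=-;\n  matrix\n")
            for rec in aln:
                fh.write(f"    {rec.id}  {rec.seq}\n")
            fh.write("  ;\nend;\n")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata TSV (columns: id, syngen, region[, strain, endosymbiont]).

    Blank/unknown syngen or region map to ``UNKNOWN``; duplicate ids are an
    error.  Returns a DataFrame indexed 0..n-1 with normalised columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "syngen", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing required column(s): {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate id(s) in metadata: {dups}")
    df = df.copy()
    df["syngen"] = df["syngen"].map(_normalize_syngen)
    df["region"] = df["region"].map(_normalize_region)
    if "strain" not in df.columns:
        df["strain"] = ""
    if "endosymbiont" not in df.columns:
        df["endosymbiont"] = UNKNOWN
    else:
        df["endosymbiont"] = df["endosymbiont"].map(
            lambda v: v if v in ENDOSYMBIONTS else UNKNOWN
        )
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("id", "syngen", "region", "strain", "endosymbiont") if c in meta.columns]
    meta.to_csv(path, sep="\t", index=False, columns=cols)


def join_alignment_metadata(
    aln: MarkerAlignment, meta: pd.DataFrame | None, require_all: bool = False
) -> CladePartition:
    """Partition alignment record ids into syngen classes using the metadata.

    Ids absent from the metadata become ``UNKNOWN`` unless *require_all*.
    """
    lookup: Mapping[str, str] = (
        {} if meta is None or meta.empty else dict(zip(meta["id"], meta["syngen"]))
    )
    assignments: dict[str, str] = {}
    for rec in aln:
        if rec.id in lookup:
            assignments[rec.id] = lookup[rec.id]
        elif require_all:
            raise ValueError(f"record {rec.id!r} is missing from the metadata")
        else:
            assignments[rec.id] = UNKNOWN
    return CladePartition(assignments)


def metadata_partition(meta: pd.DataFrame) -> CladePartition:
    """Partition over every id in a metadata table (no alignment needed)."""
    return CladePartition(dict(zip(meta["id"], meta["syngen"])))


def drop_gap_only_columns(aln: MarkerAlignment) -> MarkerAlignment:
    """Remove columns consisting solely of gaps (never applied implicitly).

    Useful after subsetting an alignment to one clade; reported column numbers
    refer to the *new* alignment afterwards, so apply with care.
    """
    keep = [
        c for c in range(1, aln.length + 1)
        if any(rec.seq[c - 1] != "-" for rec in aln)
    ]
    if len(keep) == aln.length:
        return aln
    logger.info("dropping %d gap-only column(s)", aln.length - len(keep))
    records = [
        SequenceRecord(
            id=rec.id,
            seq="".join(rec.seq[c - 1] for c in keep),
            marker=rec.marker,
            description=rec.description,
        )
        for rec in aln
    ]
    return MarkerAlignment(aln.marker, records)
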