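"""Diagnostic-site discovery: variable columns and per-syngen synapomorphies.

The central computation of the package.  Given a marker alignment and a clade
partition, it detects every variable column and classifies it:

``SYNAPOMORPHY``
    some clade is *fixed* for a state carried by no record outside it — a
    private, fixed diagnostic character for that clade (several clades can be
    diagnostic at the same column, each for its own private state);
``WITHIN_CLADE_VARIABLE``
    at least one clade shows two or more states at the column and no clade is
    diagnostic there;
``OTHER_VARIABLE``
    the remaining variable columns, e.g. a fixed state shared by exactly two
    clades (the R1+R2 pattern in the SSU).

Missing-data policy: by default gaps and ambiguity codes (and X in peptides)
are excluded from state sets; a clade is "fixed" if all its non-missing states
are identical and it has at least one non-missing state.  Setting
``missing_policy="as_state"`` instead counts every character as a state.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seqio import SYNGENS, UNKNOWN, CladePartition, MarkerAlignment, is_missing

logger = logging.getLogger("syngenmark")

SYNAPOMORPHY = "SYNAPOMORPHY"
WITHIN_CLADE_VARIABLE = "WITHIN_CLADE_VARIABLE"
OTHER_VARIABLE = "OTHER_VARIABLE"
CATEGORIES = (SYNAPOMORPHY, WITHIN_CLADE_VARIABLE, OTHER_VARIABLE)


@dataclass
class ColumnProfile:
    """Observed states at one alignment column, split by clade.

    ``states_by_clade`` maps each clade label (including ``UNKNOWN`` if
    unlabelled records are present) to a multiset of non-missing states;
    ``n_missing`` counts the records excluded under the missing policy.
    """

    column: int
    states_by_clade: dict[str, Counter]
    n_missing: int

    def n_records(self) -> int:
        return sum(sum(c.values()) for c in self.states_by_clade.values()) + self.n_missing

    def distinct_states(self) -> set[str]:
        out: set[str] = set()
        for counter in self.states_by_clade.values():
            out.update(counter)
        return out


@dataclass
class SignatureEntry:
    column: int
    category: str
    diagnostic_for: frozenset[str]
    state_by_clade: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.category == SYNAPOMORPHY and not self.diagnostic_for:
            raise ValueError(f"column {self.column}: SYNAPOMORPHY with empty diagnostic_for")
        if self.category != SYNAPOMORPHY and self.diagnostic_for:
            raise ValueError(f"column {self.column}: diagnostic_for set on {self.category}")


@dataclass
class SignatureTable:
    """Per-marker table of informative columns (signature-table analog)."""

    marker: str
    clades: tuple[str, ...]
    entries: list[SignatureEntry]

    def by_category(self, category: str) -> list[SignatureEntry]:
        return [e for e in self.entries if e.category == category]

    def diagnostic_triples(self, clade: str) -> set[tuple[str, int, str]]:
        """(marker, column, state) triples diagnostic for *clade*."""
        out = set()
        for e in self.entries:
            if e.category == SYNAPOMORPHY and clade in e.diagnostic_for:
                (state,) = e.state_by_clade[clade]
                out.add((self.marker, e.column, state))
        return out


@dataclass
class CombinedSignature:
    """Union of per-marker signatures plus clade-separability bookkeeping."""

    clades: tuple[str, ...]
    tables: dict[str, SignatureTable]
    #: clade -> set of (marker, column, state) diagnostic triples
    diagnostics: dict[str, set[tuple[str, int, str]]]
    #: clade -> {marker or "combined": separable flag}
    separable: dict[str, dict[str, bool]]

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.tables)

    def separable_combined(self, clade: str) -> bool:
        return self.separable[clade]["combined"]


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------


def find_variable_columns(
    aln: MarkerAlignment,
    partition: CladePartition,
    missing_policy: str = "ignore",
) -> list[ColumnProfile]:
    """Profiles for exactly the variable columns of the alignment.

    A column is variable when it shows >=2 distinct non-missing states
    (``missing_policy="ignore"``, default) or >=2 distinct raw characters
    (``"as_state"``).  Profiles are sorted by column.
    """
    if missing_policy not in ("ignore", "as_state"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if len(aln) < 2:
        raise ValueError("variable-column detection needs at least 2 records")
    profiles: list[ColumnProfile] = []
    for col in range(1, aln.length + 1):
        states_by_clade: dict[str, Counter] = {}
        n_missing = 0
        for rec in aln:
            char = rec.seq[col - 1]
            if missing_policy == "ignore" and is_missing(char, aln.marker):
                n_missing += 1
                continue
            clade = partition.label(rec.id)
            states_by_clade.setdefault(clade, Counter())[char] += 1
        distinct = set()
        for counter in states_by_clade.values():
            distinct.update(counter)
        if len(distinct) >= 2:
            profiles.append(ColumnProfile(col, states_by_clade, n_missing))
    return profiles


def classify_columns(
    profiles: list[ColumnProfile],
    partition: CladePartition,
    min_clade_size: int = 1,
) -> SignatureTable:
    """Classify variable-column profiles into the three signature categories.

    Unlabelled (UNKNOWN) records never define a clade but do count as
    "records outside" every clade, so they can veto privacy of a state.
    Clades smaller than *min_clade_size* are kept but flagged with a warning:
    a single-strain syngen still yields synapomorphies, just weakly supported.
    """
    clades = partition.clades()
    if len(clades) < 2:
        raise ValueError(f"need >=2 labelled clades, got {len(clades)}")
    small = [c for c, ids in clades.items() if len(ids) < min_clade_size]
    if small:
        logger.warning(
            "clade(s) below min_clade_size=%d: %s — their synapomorphies are weakly supported",
            min_clade_size, ", ".join(small),
        )
    clade_order = tuple(c for c in SYNGENS if c in clades) + tuple(
        sorted(set(clades) - set(SYNGENS))
    )
    entries: list[SignatureEntry] = []
    for prof in profiles:
        state_by_clade = {
            clade: frozenset(prof.states_by_clade.get(clade, Counter()))
            for clade in clade_order
        }
        # outside_states[c]: every state observed in any record not in c
        # (other clades and UNKNOWN records alike).
        diagnostic = set()
        for clade in clade_order:
            own = state_by_clade[clade]
            if len(own) != 1:
                continue  # not fixed (or no non-missing member)
            (state,) = own
            outside = set()
            for other, counter in prof.states_by_clade.items():
                if other != clade:
                    outside.update(counter)
            if state not in outside:
                diagnostic.add(clade)
        if diagnostic:
            category = SYNAPOMORPHY
        elif any(len(state_by_clade[c]) >= 2 for c in clade_order):
            category = WITHIN_CLADE_VARIABLE
        else:
            category = OTHER_VARIABLE
        entries.append(
            SignatureEntry(
                column=prof.column,
                category=category,
                diagnostic_for=frozenset(diagnostic),
                state_by_clade=state_by_clade,
            )
        )
    return SignatureTable(marker="", clades=clade_order, entries=entries)


def build_signature(
    aln: MarkerAlignment,
    partition: CladePartition,
    missing_policy: str = "ignore",
    min_clade_size: int = 1,
) -> SignatureTable:
    """Convenience: find_variable_columns + classify_columns for one marker."""
    profiles = find_variable_columns(aln, partition, missing_policy)
    table = classify_columns(profiles, partition, min_clade_size)
    table.marker = aln.marker
    return table


def combine_markers(tables: list[SignatureTable]) -> CombinedSignature:
    """Merge per-marker signatures and record clade separability.

    A clade is *separable* by a marker set when it has at least one diagnostic
    (marker, column, state) triple there — by definition a synapomorphy
    distinguishes its clade from every other clade.
    """
    if not tables:
        raise ValueError("combine_markers needs at least one SignatureTable")
    clade_set = set(tables[0].clades)
    for t in tables[1:]:
        if set(t.clades) != clade_set:
            raise ValueError(
                f"clade sets differ across markers: {sorted(clade_set)} vs {sorted(t.clades)}"
            )
    markers = [t.marker for t in tables]
    if len(set(markers)) != len(markers):
        raise ValueError(f"duplicate marker in combine_markers: {markers}")
    clade_order = tables[0].clades
    diagnostics: dict[str, set[tuple[str, int, str]]] = {c: set() for c in clade_order}
    separable: dict[str, dict[str, bool]] = {c: {} for c in clade_order}
    for table in tables:
        for clade in clade_order:
            triples = table.diagnostic_triples(clade)
            diagnostics[clade] |= triples
            separable[clade][table.marker] = bool(triples)
    for clade in clade_order:
        separable[clade]["combined"] = bool(diagnostics[clade])
        if not diagnostics[clade]:
            logger.warning("clade %s is not separable by any marker", clade)
    return CombinedSignature(
        clades=clade_order,
        tables={t.marker: t for t in tables},
        diagnostics=diagnostics,
        separable=separable,
    )


# ---------------------------------------------------------------------------
# Signature report I/O (tabular analog of the published signature figure)
# ---------------------------------------------------------------------------

_MARKER_ORDER = {"SSU": 0, "ITS": 1, "COI_nt": 2, "COI_aa": 3}


def write_signature_report(sig: CombinedSignature, path: str | Path) -> None:
    """TSV with one row per (marker, column); stable (marker, column) order."""
    rows = []
    for marker in sorted(sig.tables, key=lambda m: _MARKER_ORDER.get(m, 99)):
        table = sig.tables[marker]
        for e in sorted(table.entries, key=lambda e: e.column):
            row = {
                "marker": marker,
                "column": e.column,
                "category": e.category,
                "diagnostic_for": ",".join(sorted(e.diagnostic_for)),
            }
            for clade in sig.clades:
                row[clade] = "/".join(sorted(e.state_by_clade.get(clade, frozenset()))) or "."
            rows.append(row)
    columns = ["marker", "column", "category", "diagnostic_for", *sig.clades]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_signature_report(path: str | Path) -> CombinedSignature:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    fixed = ["marker", "column", "category", "diagnostic_for"]
    clade_order = tuple(c for c in df.columns if c not in fixed)
    tables: dict[str, SignatureTable] = {}
    for marker, group in df.groupby("marker", sort=False):
        entries = []
        for _, row in group.iterrows():
            diag = frozenset(x for x in row["diagnostic_for"].split(",") if x)
            state_by_clade = {
                clade: frozenset() if row[clade] == "." else frozenset(row[clade].split("/"))
                for clade in clade_order
            }
            entries.append(
                SignatureEntry(
                    column=int(row["column"]),
                    category=row["category"],
                    diagnostic_for=diag,
                    state_by_clade=state_by_clade,
                )
            )
        tables[str(marker)] = SignatureTable(str(marker), clade_order, entries)
    return combine_markers(list(tables.values()))
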