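import numpy as np
import pytest

from syngenmark import (
    OTHER_VARIABLE,
    SYNAPOMORPHY,
    WITHIN_CLADE_VARIABLE,
    build_signature,
    classify_columns,
    combine_markers,
    find_variable_columns,
    read_signature_report,
    write_signature_report,
)
from syngenmark.diagnostics import SignatureEntry, SignatureTable

from conftest import make_alignment, make_partition

DET = set("ACGT")  # determinate nucleotide states, for the oracle


# ---------------------------------------------------------------------------
# Independent oracle: direct enumeration over (clade, state, column) triples
# ---------------------------------------------------------------------------


def oracle_signature(seqs: dict[str, str], labels: dict[str, str]):
    """Map column -> (category, diagnostic_for) from the raw definitions."""
    clades = sorted({l for l in labels.values() if l != "UNKNOWN"})
    length = len(next(iter(seqs.values())))
    result = {}
    for col in range(1, length + 1):
        obs = {rid: seq[col - 1] for rid, seq in seqs.items() if seq[col - 1] in DET}
        if len(set(obs.values())) < 2:
            continue
        diagnostic = set()
        for clade in clades:
            for state in DET:
                inside = [s for r, s in obs.items() if labels.get(r) == clade]
                outside = [s for r, s in obs.items() if labels.get(r) != clade]
                if inside and all(s == state for s in inside) and state not in outside:
                    diagnostic.add(clade)
        if diagnostic:
            cat = SYNAPOMORPHY
        elif any(
            len({s for r, s in obs.items() if labels.get(r) == c}) >= 2 for c in clades
        ):
            cat = WITHIN_CLADE_VARIABLE
        else:
            cat = OTHER_VARIABLE
        result[col] = (cat, frozenset(diagnostic))
    return result


def random_case(rng):
    n_records = rng.integers(2, 7)
    n_cols = rng.integers(1, 21)
    n_clades = rng.integers(2, 4)
    alphabet = list("ACGT") + ["-", "N"]
    probs = [0.22, 0.22, 0.22, 0.22, 0.06, 0.06]
    seqs = {
        f"r{i}": "".join(rng.choice(alphabet, size=n_cols, p=probs))
        for i in range(n_records)
    }
    labels = {}
    for i in range(n_records):
        if i < n_clades:
            labels[f"r{i}"] = f"R{i + 1}"  # guarantee every clade is non-empty
        else:
            k = rng.integers(0, n_clades + 1)
            labels[f"r{i}"] = "UNKNOWN" if k == n_clades else f"R{k + 1}"
    return seqs, labels


def run_package(seqs, labels):
    aln = make_alignment(seqs, marker="ITS")
    partition = make_partition(labels)
    table = build_signature(aln, partition)
    return {e.column: (e.category, e.diagnostic_for) for e in table.entries}


class TestOracleEquivalence:
    def test_randomized_corpus(self):
        """Direct-enumeration oracle agreement on 1000 small random alignments."""
        rng = np.random.default_rng(20231001)
        n_checked = 0
        for _ in range(1000):
            seqs, labels = random_case(rng)
            if len({l for l in labels.values() if l != "UNKNOWN"}) < 2:
                continue
            assert run_package(seqs, labels) == oracle_signature(seqs, labels)
            n_checked += 1
        assert n_checked >= 900

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seqs, labels = random_case(rng)
            base = run_package(seqs, labels)
            order = list(seqs)
            rng.shuffle(order)
            shuffled = {k: seqs[k] for k in order}
            assert run_package(shuffled, labels) == base

    def test_adding_a_record_never_creates_foreign_synapomorphies_it_carries(self):
        """A record added to clade c can remove, but never create, another
        clade's synapomorphy whose diagnostic state the new record carries
        (its state there would no longer be private to that clade)."""
        rng = np.random.default_rng(99)

        def foreign_synapomorphies(table, target):
            return {
                (col, clade)
                for col, (cat, diag) in table.items()
                if cat == SYNAPOMORPHY
                for clade in diag
                if clade != target
            }

        def diagnostic_state(seqs, labels, col, clade):
            states = {
                seqs[r][col - 1]
                for r in seqs
                if labels[r] == clade and seqs[r][col - 1] in DET
            }
            (state,) = states
            return state

        for _ in range(100):
            seqs, labels = random_case(rng)
            clades = sorted({l for l in labels.values() if l != "UNKNOWN"})
            target = clades[int(rng.integers(len(clades)))]
            n_cols = len(next(iter(seqs.values())))
            new_seq = "".join(rng.choice(list("ACGT"), size=n_cols))
            seqs2 = {**seqs, "rnew": new_seq}
            labels2 = {**labels, "rnew": target}
            before = foreign_synapomorphies(run_package(seqs, labels), target)
            after = foreign_synapomorphies(run_package(seqs2, labels2), target)
            for col, clade in after - before:
                state = diagnostic_state(seqs2, labels2, col, clade)
                assert new_seq[col - 1] != state, (col, clade)


class TestFindVariableColumns:
    def test_no_variation(self):
        aln = make_alignment({f"s{i}": "ACGT" for i in range(4)})
        part = make_partition({f"s{i}": "R1" for i in range(4)})
        assert find_variable_columns(aln, part) == []

    def test_single_variable_column(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
        part = make_partition({"a": "R1", "b": "R1", "c": "R2"})
        profiles = find_variable_columns(aln, part)
        assert [p.column for p in profiles] == [4]
        assert profiles[0].n_records() == 3

    def test_missing_policy_as_state_counts_gaps(self):
        aln = make_alignment({"a": "A-", "b": "A-", "c": "AA"})
        part = make_partition({"a": "R1", "b": "R1", "c": "R2"})
        assert [p.column for p in find_variable_columns(aln, part, "ignore")] == []
        assert [p.column for p in find_variable_columns(aln, part, "as_state")] == [2]


class TestClassifyColumns:
    def test_mutually_diagnostic_column(self):
        aln = make_alignment({"a1": "AA", "a2": "AA", "b1": "AC", "b2": "AC"})
        part = make_partition({"a1": "R1", "a2": "R1", "b1": "R2", "b2": "R2"})
        table = build_signature(aln, part)
        (entry,) = table.entries
        assert entry.column == 2
        assert entry.category == SYNAPOMORPHY
        assert entry.diagnostic_for == {"R1", "R2"}

    def test_within_clade_variable(self):
        aln = make_alignment({"a1": "AA", "a2": "AC", "b1": "AA", "b2": "AA"})
        part = make_partition({"a1": "R1", "a2": "R1", "b1": "R2", "b2": "R2"})
        (entry,) = build_signature(aln, part).entries
        assert entry.category == WITHIN_CLADE_VARIABLE
        assert entry.diagnostic_for == frozenset()

    def test_shared_fixed_state_is_other_variable(self):
        # R1+R2 share a derived state; R3 keeps the ancestral one -> R3 is
        # diagnostic-free here only if its state also occurs elsewhere
        aln = make_alignment({"a": "C", "b": "C", "c": "A", "d": "A"})
        part = make_partition({"a": "R1", "b": "R2", "c": "R3", "d": "UNKNOWN"})
        (entry,) = build_signature(aln, part).entries
        assert entry.category == OTHER_VARIABLE

    def test_needs_two_labelled_clades(self):
        aln = make_alignment({"a": "AC", "b": "AT"})
        part = make_partition({"a": "R1", "b": "UNKNOWN"})
        with pytest.raises(ValueError, match="clades"):
            build_signature(aln, part)


class TestCombineMarkers:
    @staticmethod
    def _toy_tables():
        # SSU-like: R1 and R2 share every state; ITS-like separates them.
        ssu = make_alignment(
            {"a": "AAT", "b": "AAT", "c": "ACT", "d": "AGT"}, marker="SSU"
        )
        its = make_alignment(
            {"a": "TA", "b": "TC", "c": "TG", "d": "TT"}, marker="ITS"
        )
        part = make_partition({"a": "R1", "b": "R2", "c": "R3", "d": "R4"})
        return [build_signature(ssu, part), build_signature(its, part)], part

    def test_ssu_alone_cannot_separate_shared_pair(self):
        tables, _ = self._toy_tables()
        sig = combine_markers(tables)
        assert not sig.separable["R1"]["SSU"] and not sig.separable["R2"]["SSU"]
        assert sig.separable["R1"]["ITS"] and sig.separable["R2"]["ITS"]
        assert all(sig.separable[c]["combined"] for c in sig.clades)

    def test_single_marker_idempotence(self):
        tables, _ = self._toy_tables()
        solo = combine_markers([tables[1]])
        both = combine_markers(tables)
        for clade in solo.clades:
            its_triples = {t for t in both.diagnostics[clade] if t[0] == "ITS"}
            assert solo.diagnostics[clade] == its_triples

    def test_clade_set_mismatch(self):
        tables, _ = self._toy_tables()
        other = SignatureTable("COI_aa", ("R1", "R5"), [])
        with pytest.raises(ValueError, match="clade sets differ"):
            combine_markers([tables[0], other])

    def test_non_separable_clade_is_flagged(self):
        aln = make_alignment({"a": "A", "b": "A", "c": "C"}, marker="SSU")
        part = make_partition({"a": "R1", "b": "R2", "c": "R3"})
        sig = combine_markers([build_signature(aln, part)])
        assert not sig.separable["R1"]["combined"]
        assert sig.separable["R3"]["combined"]


class TestSignatureReport:
    def test_round_trip(self, tmp_path, fig3_signature):
        path = tmp_path / "sig.tsv"
        write_signature_report(fig3_signature, path)
        back = read_signature_report(path)
        assert back.clades == fig3_signature.clades
        assert back.diagnostics == fig3_signature.diagnostics
        assert back.separable == fig3_signature.separable
        for marker, table in fig3_signature.tables.items():
            got = back.tables[marker]
            assert [(e.column, e.category, e.diagnostic_for) for e in got.entries] == [
                (e.column, e.category, e.diagnostic_for)
                for e in sorted(table.entries, key=lambda e: e.column)
            ]

    def test_empty_signature_is_header_only(self, tmp_path):
        sig = combine_markers(
            [SignatureTable("SSU", ("R1", "R2"), [])]
        )
        path = tmp_path / "sig.tsv"
        write_signature_report(sig, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == [
            "marker", "column", "category", "diagnostic_for", "R1", "R2",
        ]

    def test_state_columns_in_syngen_order(self, tmp_path, fig3_signature):
        path = tmp_path / "sig.tsv"
        write_signature_report(fig3_signature, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header[4:] == ["R1", "R2", "R3", "R4", "R5"]
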