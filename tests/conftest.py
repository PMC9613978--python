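import pytest

from syngenmark import (
    CladePartition,
    MarkerAlignment,
    SequenceRecord,
    build_signature,
    combine_markers,
    fig3_preset,
    join_alignment_metadata,
    simulate,
)


def make_alignment(seqs: dict[str, str], marker: str = "ITS") -> MarkerAlignment:
    """Tiny alignment from an {id: sequence} mapping (insertion order kept)."""
    return MarkerAlignment(
        marker, [SequenceRecord(id=k, seq=v, marker=marker) for k, v in seqs.items()]
    )


def make_partition(labels: dict[str, str]) -> CladePartition:
    return CladePartition(dict(labels))


@pytest.fixture(scope="session")
def fig3_result():
    """The default synthetic five-syngen dataset (planted signature totals)."""
    return simulate(fig3_preset(seed=42))


@pytest.fixture(scope="session")
def fig3_signature(fig3_result):
    tables = []
    for marker in ("SSU", "ITS", "COI_aa"):
        aln = fig3_result.alignments[marker]
        partition = join_alignment_metadata(aln, fig3_result.metadata)
        tables.append(build_signature(aln, partition))
    return combine_markers(tables)


@pytest.fixture(scope="session")
def fig3_refs(fig3_result):
    return {m: fig3_result.alignments[m] for m in ("SSU", "ITS")}
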