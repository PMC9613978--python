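import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from syngenmark import (
    ConnectionLimit,
    Haplotype,
    build_network,
    collapse_haplotypes,
    compared_characters,
    connection_limit,
    network_from_alignment,
    pairwise_steps,
    parsimony_probability,
    summarize_biogeography,
)

from conftest import make_alignment


def hap(hid: str, seq: str, members=None) -> Haplotype:
    members = members or {hid}
    return Haplotype(
        hap_id=hid, member_ids=frozenset(members), representative_seq=seq, marker="ITS"
    )


class TestCollapse:
    def meta(self, rows):
        return pd.DataFrame(rows, columns=["id", "syngen", "region"])

    def test_identical_records_merge_with_region_counts(self):
        aln = make_alignment({f"s{i}": "ACGT" for i in range(4)})
        meta = self.meta(
            [("s0", "R1", "Europe"), ("s1", "R1", "Europe"),
             ("s2", "R1", "Europe"), ("s3", "R1", "Asia")]
        )
        (h,) = collapse_haplotypes(aln, meta)
        assert h.freq == 4
        assert h.region_counts == {"Europe": 3, "Asia": 1}

    def test_distinct_sequences_stay_apart(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA"})
        assert len(collapse_haplotypes(aln)) == 2

    def test_strict_vs_infer_on_ambiguity(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGN"})
        assert len(collapse_haplotypes(aln, missing_policy="strict")) == 2
        (h,) = collapse_haplotypes(aln, missing_policy="infer")
        # representative has the fewest missing characters
        assert h.representative_seq == "ACGT"

    def test_representative_tie_breaks_on_id(self):
        aln = make_alignment({"zz": "ACGT", "aa": "ACGT"})
        (h,) = collapse_haplotypes(aln)
        assert h.representative_seq == "ACGT"
        assert min(h.member_ids) == "aa"

    def test_conservation_of_records(self, fig3_result):
        aln = fig3_result.alignments["ITS"]
        haps = collapse_haplotypes(aln, fig3_result.metadata)
        assert sum(h.freq for h in haps) == len(aln)


class TestPairwiseSteps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0), ("ACGT", "TCGA", 2), ("AC-T", "ACGT", 0), ("ACNT", "ACGA", 1)],
    )
    def test_hamming_over_shared_determinate_columns(self, a, b, expected):
        assert pairwise_steps(hap("h1", a), hap("h2", b)) == expected


def direct_parsimony_probability(j: int, L: int) -> float:
    """Independent closed form: L! / ((L-j)! L^j) via log-gamma."""
    if j > L:
        return 0.0
    return math.exp(math.lgamma(L + 1) - math.lgamma(L - j + 1) - j * math.log(L))


class TestConnectionLimit:
    @pytest.mark.parametrize("L", [50, 100, 300, 600, 1000])
    def test_matches_independent_direct_evaluation(self, L):
        for j in (0, 1, 2, 5, 10, 20, L):
            assert parsimony_probability(j, L) == pytest.approx(
                direct_parsimony_probability(j, L), rel=1e-9
            )
        direct_J = max(
            j for j in range(L + 1) if j == 0 or direct_parsimony_probability(j, L) > 0.95
        )
        assert connection_limit(L, 0.95).limit_J == direct_J

    def test_monte_carlo_check(self):
        # P(no two of j uniform mutations hit the same of L sites)
        rng = np.random.default_rng(2024)
        L, j, reps = 100, 8, 20000
        hits = sum(
            len(set(rng.integers(0, L, size=j))) == j for _ in range(reps)
        )
        assert parsimony_probability(j, L) == pytest.approx(hits / reps, abs=0.01)

    def test_alpha_to_zero_admits_every_connection(self):
        # once alpha drops below P_L (= L!/L^L > 0) every connection is in
        assert connection_limit(10, 1e-9).limit_J == 10
        assert connection_limit(40, 1e-18).limit_J == 40

    def test_l1_equals_direct_formula(self):
        direct = 1 if direct_parsimony_probability(1, 1) > 0.95 else 0
        assert connection_limit(1, 0.95).limit_J == direct

    def test_monotone_in_l_and_alpha(self):
        limits = [connection_limit(L, 0.95).limit_J for L in (10, 50, 200, 600, 2000)]
        assert limits == sorted(limits)
        alphas = [connection_limit(600, a).limit_J for a in (0.5, 0.9, 0.95, 0.99)]
        assert alphas == sorted(alphas, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            connection_limit(0, 0.95)
        with pytest.raises(ValueError):
            connection_limit(100, 1.0)


class TestBuildNetwork:
    def test_single_haplotype(self):
        net = build_network([hap("h1", "ACGT")], ConnectionLimit(4, 0.95, 2))
        assert len(net.nodes) == 1 and net.edges == [] and len(net.components) == 1

    def test_transitive_pair_beats_longer_edge(self):
        # AB=1, BC=1, AC=2: AC is dropped (A and C already connected)
        a, b, c = hap("A", "AAAA"), hap("B", "AAAT"), hap("C", "AATT")
        net = build_network([a, b, c], ConnectionLimit(4, 0.95, 10))
        assert sorted((x, y) for x, y, _ in net.edges) == [("A", "B"), ("B", "C")]

    def test_connection_limit_splits_components(self):
        a = hap("A", "A" * 20)
        b = hap("B", "A" * 8 + "T" * 12)  # 12 steps away
        net = build_network([a, b], ConnectionLimit(20, 0.95, 10))
        assert net.edges == []
        assert len(net.components) == 2

    def test_tied_bridges_are_reticulations(self):
        # B and C are both 1 step from A and 2 from each other; D is 1 step
        # from both B and C: the two (B,D)/(C,D)-style ties bridge components
        a, b, c, d = (
            hap("A", "AAAA"), hap("B", "TAAA"), hap("C", "AAAT"), hap("D", "TAAT")
        )
        net = build_network([a, b, c, d], ConnectionLimit(4, 0.95, 4))
        # every 1-step pair retained: AB, AC, BD, CD -> a 4-cycle (reticulation)
        assert sorted((x, y) for x, y, s in net.edges if s == 1) == [
            ("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"),
        ]
        assert len(net.components) == 1

    def test_oracle_components_and_mst_superset(self):
        """500 random ≤8-haplotype sets vs transitive closure + MST weight."""
        rng = np.random.default_rng(555)
        for _ in range(500):
            n = int(rng.integers(2, 9))
            length = int(rng.integers(4, 12))
            haps = [
                hap(f"h{i}", "".join(rng.choice(list("ACGT"), size=length)))
                for i in range(n)
            ]
            limit = ConnectionLimit(length, 0.95, int(rng.integers(0, length + 1)))
            net = build_network(haps, limit)
            # oracle 1: components == transitive closure over pairs <= J
            g_full = nx.Graph()
            g_full.add_nodes_from(h.hap_id for h in haps)
            for h1, h2 in itertools.combinations(haps, 2):
                steps = pairwise_steps(h1, h2)
                if steps <= limit.limit_J:
                    g_full.add_edge(h1.hap_id, h2.hap_id, weight=steps)
            oracle_comps = {frozenset(c) for c in nx.connected_components(g_full)}
            assert set(net.components) == oracle_comps
            # oracle 2: retained edges contain a minimum spanning forest
            g_net = nx.Graph()
            g_net.add_nodes_from(h.hap_id for h in haps)
            g_net.add_weighted_edges_from((a, b, s) for a, b, s in net.edges)
            mst_full = sum(d["weight"] for *_e, d in
                           nx.minimum_spanning_edges(g_full, data=True))
            mst_net = sum(d["weight"] for *_e, d in
                          nx.minimum_spanning_edges(g_net, data=True))
            assert mst_net == mst_full
            # edge bound holds
            assert all(s <= limit.limit_J for *_ab, s in net.edges)


class TestBiogeography:
    def test_planted_europe_only_clades(self, fig3_result):
        aln = fig3_result.alignments["ITS"]
        net = network_from_alignment(aln, fig3_result.metadata)
        bio = summarize_biogeography(net, fig3_result.metadata)
        europe_only = set(bio.loc[bio["europe_only"], "syngen"])
        assert europe_only == fig3_result.truth.europe_only_clades() == {"R1", "R5"}

    @pytest.mark.parametrize(
        "regions,flag",
        [({"Europe"}, True), ({"Europe", "Asia", "North America"}, False)],
    )
    def test_europe_only_flag(self, regions, flag):
        rows = [(f"s{i}", "R1", r) for i, r in enumerate(sorted(regions))]
        meta = pd.DataFrame(rows, columns=["id", "syngen", "region"])
        aln = make_alignment({rid: "ACGT" for rid, *_ in rows})
        net = network_from_alignment(aln, meta)
        bio = summarize_biogeography(net, meta)
        assert bool(bio.loc[bio["syngen"] == "R1", "europe_only"].iloc[0]) is flag


def test_compared_characters_excludes_ragged_columns():
    # last column is determinate in only half the records -> excluded at 90%
    aln = make_alignment({"a": "ACGTN", "b": "ACGT-", "c": "ACGTA", "d": "ACGTA"})
    assert compared_characters(aln) == 4
    assert compared_characters(aln, coverage=0.5) == 5
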