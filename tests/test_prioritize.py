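"""Prioritization cascade: filters, reciprocal overlap, sharing clusters,
gene annotation/blacklisting, uniqueness, cross-caller consensus."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svprior import (
    ACMGClass,
    GeneIndex,
    SVCall,
    SVCluster,
    SVType,
    annotate_genes,
    cluster_shared,
    cross_caller_consensus,
    filter_by_acmg,
    filter_by_length,
    filter_gene_blacklist,
    reciprocal_overlap,
    severe_unique_genes,
)


def _call(sample, start, end, svtype=SVType.DEL, caller="manta", chrom="1",
          acmg=ACMGClass.UNCERTAIN):
    return SVCall(sample, caller, chrom, start, end, svtype, acmg)


class TestLengthFilter:
    def test_oversize_removed_candidates_survive(self):
        calls = [
            _call("S1", 100_056_545, 100_214_180, SVType.DUP),  # 157,635 bp
            _call("S1", 100_089_053, 100_112_257, SVType.DUP),  # 23,204 bp
        ]
        kept = filter_by_length(calls)
        assert [c.length for c in kept] == [23_204]

    def test_exactly_max_length_retained(self):
        call = _call("S1", 0, 100_000)
        assert filter_by_length([call]) == [call]
        assert filter_by_length([_call("S1", 0, 100_001)]) == []

    def test_empty_input(self):
        assert filter_by_length([]) == []


class TestAcmgFilter:
    def test_default_keep_classes(self):
        calls = [
            _call("S1", 0, 10, acmg=ACMGClass.BENIGN),
            _call("S1", 0, 10, acmg=ACMGClass.UNCERTAIN),
            _call("S1", 0, 10, acmg=ACMGClass.PATHOGENIC),
            _call("S1", 0, 10, acmg=ACMGClass.UNCLASSIFIED),
        ]
        kept = filter_by_acmg(calls)
        assert [c.acmg_class for c in kept] == [ACMGClass.UNCERTAIN, ACMGClass.PATHOGENIC]

    def test_all_benign_empty(self):
        assert filter_by_acmg([_call("S", 0, 9, acmg=ACMGClass.BENIGN)] * 3) == []

    def test_empty_input(self):
        assert filter_by_acmg([]) == []


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        assert reciprocal_overlap(("1", 10, 20), ("1", 10, 20)) == 1.0

    def test_disjoint_intervals(self):
        assert reciprocal_overlap(("1", 10, 20), ("1", 20, 30)) == 0.0

    def test_published_near_copy(self):
        """Candidate deletion vs its population-database near-copy:
        I = 138, RO = min(138/144, 138/138)."""
        ro = reciprocal_overlap(
            ("12", 56_100_028, 56_100_172), ("12", 56_100_029, 56_100_167)
        )
        assert ro == pytest.approx(138 / 144)

    def test_different_chromosomes_zero(self):
        assert reciprocal_overlap(("1", 0, 10), ("2", 0, 10)) == 0.0
        assert reciprocal_overlap(("chr1", 0, 10), ("1", 0, 10)) == 1.0

    def test_zero_length_interval_error(self):
        with pytest.raises(ValueError):
            reciprocal_overlap(("1", 5, 5), ("1", 0, 10))

    @settings(max_examples=300, derandomize=True)
    @given(
        a0=st.integers(0, 1000), la=st.integers(1, 500),
        b0=st.integers(0, 1000), lb=st.integers(1, 500),
        shift=st.integers(-10_000, 10_000),
    )
    def test_symmetry_bounds_translation(self, a0, la, b0, lb, shift):
        a, b = ("1", a0, a0 + la), ("1", b0, b0 + lb)
        ro = reciprocal_overlap(a, b)
        assert 0.0 <= ro <= 1.0
        assert ro == reciprocal_overlap(b, a)
        assert ro == pytest.approx(
            reciprocal_overlap(
                ("1", a0 + shift, a0 + la + shift), ("1", b0 + shift, b0 + lb + shift)
            )
        )
        if ro == 1.0:
            assert (a0, la) == (b0, lb)


def oracle_clusters(calls, min_ro=0.6, min_samples=2):
    """Brute-force all-pairs single-linkage clustering (independent of the
    implementation: explicit graph + connected components)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i, j in itertools.combinations(range(len(calls)), 2):
        a, b = calls[i], calls[j]
        if a.svtype != b.svtype or a.chrom != b.chrom:
            continue
        if reciprocal_overlap(a.interval, b.interval) >= min_ro:
            g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        members = [calls[i] for i in comp]
        if len({c.sample_id for c in members}) >= min_samples:
            out.append(frozenset(id(c) for c in members))
    return set(out)


class TestClusterShared:
    def test_identical_calls_in_two_samples_form_one_cluster(self):
        calls = [_call("I4-40", 100, 915), _call("I4-41", 100, 915)]
        (cluster,) = cluster_shared(calls)
        assert cluster.carrier_samples == {"I4-40", "I4-41"}
        assert (cluster.start, cluster.end) == (100, 915)
        assert cluster.svtype is SVType.DEL

    def test_private_call_discarded(self):
        assert cluster_shared([_call("S1", 100, 900)]) == []

    def test_single_linkage_chains_transitively(self):
        """RO(A,B)=0.7, RO(B,C)=0.7, RO(A,C)=0.49: one chained cluster."""
        a, b, c = _call("S1", 0, 1000), _call("S2", 300, 1300), _call("S3", 600, 1600)
        assert reciprocal_overlap(a.interval, b.interval) == pytest.approx(0.7)
        assert reciprocal_overlap(b.interval, c.interval) == pytest.approx(0.7)
        assert reciprocal_overlap(a.interval, c.interval) < 0.6
        (cluster,) = cluster_shared([a, b, c])
        assert cluster.carrier_samples == {"S1", "S2", "S3"}

    def test_type_mismatch_blocks_edge(self):
        calls = [_call("S1", 0, 1000, SVType.DEL), _call("S2", 0, 1000, SVType.DUP)]
        assert cluster_shared(calls) == []

    def test_representative_is_lower_median(self):
        calls = [
            _call("S1", 100, 1000), _call("S2", 110, 1010),
            _call("S3", 120, 1030), _call("S4", 130, 1040),
        ]
        (cluster,) = cluster_shared(calls)
        assert (cluster.start, cluster.end) == (110, 1010)

    def test_mixed_callers_rejected(self):
        calls = [_call("S1", 0, 100), _call("S2", 0, 100, caller="tiddit")]
        with pytest.raises(ValueError, match="one caller"):
            cluster_shared(calls)

    def test_agrees_with_bruteforce_oracle_on_random_instances(self):
        """>= 500 random instances of <= 12 calls, compared against an
        explicit all-pairs connected-components oracle."""
        for seed in range(500):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(0, 13))
            calls = []
            for _ in range(n):
                start = int(rng.integers(0, 60))
                length = int(rng.integers(1, 60))
                calls.append(
                    _call(
                        f"S{int(rng.integers(1, 5))}", start, start + length,
                        SVType.DEL if rng.random() < 0.7 else SVType.DUP,
                        chrom="1" if rng.random() < 0.8 else "2",
                    )
                )
            got = {
                frozenset(id(c) for c in cl.member_calls)
                for cl in cluster_shared(calls)
            }
            assert got == oracle_clusters(calls), f"disagreement at seed {seed}"

    def test_raising_min_ro_only_refines_clusters(self):
        """A cluster at a stricter threshold is always contained in one
        cluster at a looser threshold (single-linkage refinement)."""
        rng = np.random.default_rng(42)
        calls = []
        for _ in range(40):
            start = int(rng.integers(0, 200))
            calls.append(_call(f"S{int(rng.integers(1, 8))}", start, start + int(rng.integers(20, 120))))
        loose = cluster_shared(calls, min_ro=0.4, min_samples=1)
        strict = cluster_shared(calls, min_ro=0.8, min_samples=1)
        assert len(strict) >= len(loose)
        loose_sets = [set(id(c) for c in cl.member_calls) for cl in loose]
        for cl in strict:
            members = set(id(c) for c in cl.member_calls)
            assert any(members <= ls for ls in loose_sets)


class TestGeneAnnotation:
    def test_published_duplication_hits_seven_genes(self, fixture_gene_model):
        genes = annotate_genes(("7", 100_089_053, 100_112_257), fixture_gene_model)
        assert genes == {"AP4M1", "COPS6", "MCM7", "MIR106B", "MIR25", "MIR93", "TAF6"}

    def test_region_with_no_gene(self, fixture_gene_model):
        assert annotate_genes(("7", 1_000, 2_000), fixture_gene_model) == set()

    def test_region_spanning_two_adjacent_genes(self):
        from svprior import GeneInterval

        model = [
            GeneInterval("A", "1", 100, 200),
            GeneInterval("B", "1", 200, 300),
        ]
        assert annotate_genes(("1", 150, 250), model) == {"A", "B"}

    def test_one_bp_overlap_counts(self):
        from svprior import GeneInterval

        model = [GeneInterval("A", "1", 100, 200)]
        assert annotate_genes(("1", 199, 300), model) == {"A"}
        assert annotate_genes(("1", 200, 300), model) == set()


def _cluster(genes, start=0, end=1000, caller="manta", samples=("S1", "S2")):
    members = [_call(s, start, end, caller=caller) for s in samples]
    return SVCluster(
        member_calls=members, carrier_samples=set(samples), chrom="1",
        start=start, end=end, svtype=SVType.DEL, caller_id=caller,
        gene_symbols=set(genes),
    )


class TestBlacklist:
    def test_blacklisted_row_removed_region_kept(self):
        cl = _cluster({"TTN", "ERBB3"})
        (kept,) = filter_gene_blacklist([cl], flags_list={"TTN"}, olfactory_list=set())
        assert kept.gene_symbols == {"ERBB3"}

    def test_fully_blacklisted_region_dropped(self):
        cl = _cluster({"TTN", "OR4F5"})
        assert filter_gene_blacklist([cl], {"TTN"}, {"OR4F5"}) == []

    def test_empty_blacklists_identity(self):
        cl = _cluster({"ERBB3"})
        (kept,) = filter_gene_blacklist([cl], set(), set())
        assert kept.gene_symbols == {"ERBB3"}


class TestSevereUnique:
    def test_gene_shared_with_nonsevere_excluded(self):
        severe = [_cluster({"ERBB3"})]
        assert severe_unique_genes(severe, nonsevere_gene_set={"ERBB3"}) == []

    def test_gene_only_in_severe_retained(self):
        severe = [_cluster({"ERBB3"})]
        (kept,) = severe_unique_genes(severe, nonsevere_gene_set={"TTN"})
        assert kept.gene_symbols == {"ERBB3"}

    def test_empty_nonsevere_keeps_everything(self):
        severe = [_cluster({"A"}), _cluster({"B"})]
        assert len(severe_unique_genes(severe, set())) == 2


class TestCrossCallerConsensus:
    def test_breakpoint_offsets_one_and_seventy_merge(self):
        """Two callers reporting the same region 1 bp / 70 bp apart yield
        one consensus candidate with two supporting callers."""
        a = _cluster({"ERBB3"}, 100_000, 123_204, caller="manta")
        b = _cluster({"ERBB3"}, 100_001, 123_274, caller="tiddit")
        (cand,) = cross_caller_consensus({"manta": [a], "tiddit": [b]})
        assert cand.supporting_callers == {"manta", "tiddit"}
        assert not cand.type_discordant

    def test_del_dup_conflict_flagged_not_resolved(self):
        a = _cluster({"ERBB3"}, 0, 1000, caller="manta")
        b = _cluster({"ERBB3"}, 0, 1000, caller="tiddit")
        b.svtype = SVType.DUP
        (cand,) = cross_caller_consensus({"manta": [a], "tiddit": [b]})
        assert cand.type_discordant
        assert cand.caller_types == {"manta": SVType.DEL, "tiddit": SVType.DUP}

    def test_single_caller_region_dropped(self):
        a = _cluster({"ERBB3"}, 0, 1000, caller="manta")
        assert cross_caller_consensus({"manta": [a], "tiddit": []}) == []

    def test_breakpoint_tolerance_rescues_skewed_ro(self):
        """Near-identical breakpoints but RO below threshold (tiny interval
        vs tiny shifted interval) still match within the tolerance."""
        a = _cluster(set(), 100, 200, caller="manta")
        b = _cluster(set(), 150, 250, caller="tiddit")  # RO = 0.5 < 0.6
        assert reciprocal_overlap(a.interval, b.interval) == 0.5
        (cand,) = cross_caller_consensus({"manta": [a], "tiddit": [b]})
        assert cand.supporting_callers == {"manta", "tiddit"}
        assert cross_caller_consensus(
            {"manta": [a], "tiddit": [b]}, breakpoint_tol=10
        ) == []

    def test_worst_acmg_and_union_fields(self):
        a = _cluster({"A"}, 0, 1000, caller="manta", samples=("S1", "S2"))
        b = _cluster({"B"}, 0, 1000, caller="tiddit", samples=("S2", "S3"))
        b.member_calls[0] = _call("S2", 0, 1000, caller="tiddit",
                                  acmg=ACMGClass.PATHOGENIC)
        (cand,) = cross_caller_consensus({"manta": [a], "tiddit": [b]})
        assert cand.carrier_samples == {"S1", "S2", "S3"}
        assert cand.gene_symbols == {"A", "B"}
        assert cand.acmg_class is ACMGClass.PATHOGENIC
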