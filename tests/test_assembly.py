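"""De Bruijn graph construction, unitig assembly, N-statistics, the
k-selection/filtering rules and the overlap merge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holotx import assembly
from holotx.seqio import SeqRecord, reverse_complement
from oracles import n_statistic_oracle


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _tile(seq, read_len=20, step=1):
    return [SeqRecord(f"r{i}", seq[i:i + read_len])
            for i in range(0, len(seq) - read_len + 1, step)]


class TestDeBruijn:
    def test_node_count_matches_enumeration(self):
        seq = "ACGTACGGAACGTTACG"
        reads = _tile(seq, read_len=12)
        k = 11
        g = assembly.build_debruijn(reads, k)
        expected = set()
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            expected.add(min(km, reverse_complement(km)))
        assert set(g.nodes) == expected

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            assembly.build_debruijn(_tile("ACGT" * 20), 12)

    def test_k_not_smaller_than_read_length_rejected(self):
        with pytest.raises(ValueError, match="read length"):
            assembly.build_debruijn(_tile("ACGT" * 20, read_len=20), 21)

    def test_count_floor_drops_error_kmers(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 100)
        reads = _tile(seq, read_len=30)
        err = seq[10:40]
        err = err[:15] + ("A" if err[15] != "A" else "C") + err[16:]
        k = 21
        with_err = reads + [SeqRecord("e", err)]
        g1 = assembly.build_debruijn(with_err, k, min_kmer_count=2)
        g_loose = assembly.build_debruijn(with_err, k, min_kmer_count=1)
        novel = {km for km in
                 (min(err[i:i + k], reverse_complement(err[i:i + k]))
                  for i in range(len(err) - k + 1))
                 if km not in assembly.build_debruijn(reads, k).nodes}
        assert novel                              # the substitution made new k-mers
        assert novel & g_loose.nodes == novel     # kept without the floor
        assert not novel & g1.nodes               # dropped by the floor


class TestUnitigs:
    def test_lossless_single_transcript(self):
        rng = np.random.default_rng(1)
        t = _random_seq(rng, 500)
        reads = _tile(t, read_len=40)
        contigs = assembly.assemble_unitigs(assembly.build_debruijn(reads, 31))
        assert len(contigs) == 1
        assert contigs[0].seq in (t, reverse_complement(t))

    def test_internal_repeat_splits_unitig(self):
        rng = np.random.default_rng(2)
        rep = _random_seq(rng, 40)              # repeat longer than k
        t = _random_seq(rng, 150) + rep + _random_seq(rng, 150) + rep \
            + _random_seq(rng, 150)
        reads = _tile(t, read_len=50)
        contigs = assembly.assemble_unitigs(assembly.build_debruijn(reads, 31))
        assert len(contigs) > 1

    def test_empty_graph_empty_output(self):
        g = assembly.DeBruijnGraph(31, {}, set())
        assert assembly.assemble_unitigs(g) == []

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(3)
        t = _random_seq(rng, 400)
        reads = _tile(t, read_len=40)
        rc_reads = [SeqRecord(r.id, reverse_complement(r.seq)) for r in reads]
        fwd = assembly.assemble_unitigs(assembly.build_debruijn(reads, 25))
        rev = assembly.assemble_unitigs(assembly.build_debruijn(rc_reads, 25))
        assert [c.seq for c in fwd] == [c.seq for c in rev]


class TestNStatistic:
    def test_forced_by_definition(self):
        assert assembly.n_statistic([6, 5, 4, 3, 2], 50) == 5

    def test_all_equal(self):
        for x in (10, 50, 90):
            assert assembly.n_statistic([7, 7, 7], x) == 7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assembly.n_statistic([], 50)

    @given(st.lists(st.integers(1, 5000), min_size=1, max_size=60),
           st.sampled_from([10, 25, 50, 75, 90]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exact_rational_oracle(self, lengths, x):
        assert assembly.n_statistic(lengths, x) == n_statistic_oracle(lengths, x)


class TestMultikSelection:
    def test_multik_counts_and_duplicate_k(self):
        rng = np.random.default_rng(4)
        t = _random_seq(rng, 300)
        reads = _tile(t, read_len=40)
        asms = assembly.assemble_multik(reads, [21, 25, 31])
        assert set(asms) == {21, 25, 31}
        with pytest.raises(ValueError, match="duplicate"):
            assembly.assemble_multik(reads, [21, 21])
        single = assembly.assemble_multik(reads, [25])[25]
        direct = assembly.assemble_unitigs(assembly.build_debruijn(reads, 25))
        assert [c.seq for c in single] == [c.seq for c in direct]

    def test_selection_ranks_by_n50_and_median_rule(self):
        def contigs(k, lengths):
            return [assembly.Contig(f"k{k}_c{i}", "A" * n, k)
                    for i, n in enumerate(lengths)]
        # N50s: a=400, b=300, c=200, d=100; medians: a=140, b=400, c=300
        asms = {
            21: contigs(21, [400, 140, 100]),          # N50 400, median 140
            25: contigs(25, [300, 400, 120]),          # N50 300-ish
            31: contigs(31, [200, 300, 260]),
            35: contigs(35, [100, 90, 80]),
        }
        pool = assembly.select_and_filter(asms, top_n=3, min_len=150)
        ks = {c.k_origin for c in pool}
        assert ks == {21, 25, 31}                      # lowest-N50 assembly dropped
        keeper = max(ks, key=lambda k: sorted(len(c) for c in asms[k])[1])
        for c in pool:
            if c.k_origin != keeper:
                assert len(c) >= 150                  # short contigs filtered
        # the longest-median assembly keeps even its short contigs
        assert any(len(c) < 150 and c.k_origin == keeper for c in pool)

    def test_top1_keeps_best_unfiltered(self):
        def contigs(k, lengths):
            return [assembly.Contig(f"k{k}_c{i}", "A" * n, k)
                    for i, n in enumerate(lengths)]
        asms = {21: contigs(21, [500, 10]), 25: contigs(25, [100, 90])}
        pool = assembly.select_and_filter(asms, top_n=1, min_len=150)
        assert sorted(len(c) for c in pool) == [10, 500]


class TestMerge:
    def test_exact_overlap_reconstructs_transcript(self):
        rng = np.random.default_rng(5)
        t = _random_seq(rng, 1000)
        a = assembly.Contig("a", t[:600])
        b = assembly.Contig("b", t[500:])
        merged = assembly.merge_assemblies([a, b], min_overlap=40)
        assert len(merged) == 1
        assert merged[0].seq in (t, reverse_complement(t))
        assert set(merged[0].member_ids) == {"a", "b"}

    def test_reverse_orientation_overlap_merges(self):
        rng = np.random.default_rng(6)
        t = _random_seq(rng, 800)
        a = assembly.Contig("a", t[:500])
        b = assembly.Contig("b", reverse_complement(t[400:]))
        merged = assembly.merge_assemblies([a, b], min_overlap=40)
        assert len(merged) == 1
        assert merged[0].seq in (t, reverse_complement(t))

    def test_duplicate_contig_absorbed(self):
        rng = np.random.default_rng(7)
        t = _random_seq(rng, 300)
        a = assembly.Contig("a", t)
        b = assembly.Contig("b", t)
        merged = assembly.merge_assemblies([a, b])
        assert len(merged) == 1

    def test_short_overlap_stays_unmerged(self):
        rng = np.random.default_rng(8)
        t = _random_seq(rng, 500)
        a = assembly.Contig("a", t[:265])
        b = assembly.Contig("b", t[235:])      # 30 bp true overlap
        merged = assembly.merge_assemblies([a, b], min_overlap=40)
        assert len(merged) == 2

    def test_merge_never_decreases_n50_on_selected_pools(self):
        rng = np.random.default_rng(9)
        transcripts = [_random_seq(rng, int(rng.integers(300, 600)))
                       for _ in range(5)]
        reads = []
        for t in transcripts:
            reads.extend(_tile(t, read_len=50, step=3))
        asms = assembly.assemble_multik(reads, [25, 31, 35])
        pool = assembly.select_and_filter(asms, 3, 150)
        merged = assembly.merge_assemblies(pool)
        assert assembly.compute_nstats(merged).n50 >= \
            assembly.compute_nstats(pool).n50
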