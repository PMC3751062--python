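"""Ground-truth guarantees of the synthetic holobiont generator."""

import numpy as np
import pytest
from scipy.stats import binom

from holotx import simulate
from holotx.orffinder import translate
from holotx.seqio import SeqRecord, reverse_complement


def test_proteome_counts_and_determinism():
    p1, f1 = simulate.simulate_reference_proteome(5, 2, (100, 200), seed=1)
    p2, f2 = simulate.simulate_reference_proteome(5, 2, (100, 200), seed=1)
    assert len(p1) == 10 and len(set(f1.values())) == 5
    assert [(r.id, r.seq) for r in p1] == [(r.id, r.seq) for r in p2]
    assert f1 == f2


def test_proteome_singleton_families_and_identity_structure():
    prot, fam = simulate.simulate_reference_proteome(4, 1, (100, 150), seed=2)
    assert len(prot) == 4 and len(set(fam.values())) == 4
    # paralogs are far closer to each other than cross-family pairs
    prot2, fam2 = simulate.simulate_reference_proteome(3, 2, (120, 120), seed=3)
    def ident(a, b):
        return sum(x == y for x, y in zip(a, b)) / len(a)
    within = ident(prot2[0].seq, prot2[1].seq)
    across = ident(prot2[0].seq, prot2[2].seq)
    assert within > 0.7 > 0.3 > across


def test_proteome_degenerate_length_range():
    with pytest.raises(ValueError):
        simulate.simulate_reference_proteome(3, 2, (50, 40), seed=0)
    with pytest.raises(ValueError):
        simulate.simulate_reference_proteome(3, 2, (30, 50), seed=0)


def test_transcript_counts_and_labels():
    prot, fam = simulate.simulate_reference_proteome(5, 2, (100, 150), seed=4)
    host, symb, pool, info = simulate.simulate_holobiont_transcripts(
        prot, fam, 20, 5, seed=4)
    assert len(host) == 20 and len(symb) == 5
    assert sum(1 for ti in info.values() if ti.origin == "symbiont") == 5


def test_zero_divergence_cds_translates_to_source_protein():
    prot, fam = simulate.simulate_reference_proteome(3, 2, (100, 130), seed=5)
    host, _, _, info = simulate.simulate_holobiont_transcripts(
        prot, fam, 6, 0, host_divergence=0.0, extension_fraction=0.0, seed=5)
    by_id = {p.id: p.seq for p in prot}
    for t in host:
        ti = info[t.id]
        cds = t.seq[ti.cds_start - 1:ti.cds_end]
        assert translate(cds) == ti.peptide == by_id[ti.source_id]
        # CDS flanked by in-frame stops
        assert t.seq[ti.cds_start - 4:ti.cds_start - 1] == "TAA"
        assert t.seq[ti.cds_end:ti.cds_end + 3] == "TAA"


def test_divergence_ordering_validated():
    prot, fam = simulate.simulate_reference_proteome(3, 1, (100, 120), seed=6)
    with pytest.raises(ValueError, match="host_divergence"):
        simulate.simulate_holobiont_transcripts(prot, fam, 2, 2,
                                                host_divergence=0.5,
                                                symbiont_pool_divergence=0.4,
                                                seed=6)


def test_reads_error_free_are_exact_substrings():
    prot, fam = simulate.simulate_reference_proteome(2, 1, (100, 120), seed=7)
    host, _, _, _ = simulate.simulate_holobiont_transcripts(
        prot, fam, 1, 0, seed=7)
    expr = {host[0].id: 1.0}
    m1, m2, origin = simulate.simulate_reads(host, expr, 200, error_rate=0.0,
                                             seed=7)
    seq = host[0].seq
    for r in m1:
        assert r.seq in seq
    for r in m2:
        assert reverse_complement(r.seq) in seq
    assert len(origin) == 200


def test_read_share_tracks_expression_within_binomial_bounds():
    # two equal-length transcripts, 0.9/0.1 expression
    rng = np.random.default_rng(8)
    cds = "".join(rng.choice(list("ACGT"), size=600))
    cds2 = "".join(rng.choice(list("ACGT"), size=600))
    t = [SeqRecord("t1", cds), SeqRecord("t2", cds2)]
    expr = {"t1": 0.9, "t2": 0.1}
    n_pairs = 1000
    _, _, origin = simulate.simulate_reads(t, expr, n_pairs, error_rate=0.0,
                                           seed=1)
    c1 = sum(1 for tid, _, _ in origin.values() if tid == "t1")
    lo, hi = binom.ppf([0.005, 0.995], n_pairs, 0.9)
    assert lo <= c1 <= hi


def test_interior_fully_tiled_at_high_coverage():
    # error-free reads at >=30x tile every interior transcript base; the
    # uniform fragment model leaves only the terminal read-length margins
    # with sub-Poisson coverage
    prot, fam = simulate.simulate_reference_proteome(2, 1, (100, 120), seed=9)
    host, _, _, _ = simulate.simulate_holobiont_transcripts(prot, fam, 2, 0,
                                                            seed=9)
    expr = {t.id: 0.5 for t in host}
    total = sum(len(t.seq) for t in host)
    n_pairs = int(40 * total / 150)
    m1, m2, origin = simulate.simulate_reads(host, expr, n_pairs,
                                             error_rate=0.0, seed=9)
    seqs = {t.id: t.seq for t in host}
    covered = {t.id: np.zeros(len(t.seq), dtype=bool) for t in host}
    for pid, (tid, start, _) in origin.items():
        covered[tid][start:start + 75] = True          # mate 1 span
    for r2, (pid, (tid, start, _)) in zip(m2, origin.items()):
        frag = reverse_complement(r2.seq)              # mate 2 span
        pos = seqs[tid].find(frag)
        assert pos >= 0
        covered[tid][pos:pos + 75] = True
    for tid, mask in covered.items():
        assert mask[75:-75].all(), f"transcript {tid} interior not tiled"
        assert mask.mean() > 0.9


def test_reads_deterministic_given_seed():
    prot, fam = simulate.simulate_reference_proteome(2, 1, (100, 120), seed=10)
    host, _, _, _ = simulate.simulate_holobiont_transcripts(prot, fam, 2, 0,
                                                            seed=10)
    expr = {t.id: 0.5 for t in host}
    a = simulate.simulate_reads(host, expr, 50, seed=42)
    b = simulate.simulate_reads(host, expr, 50, seed=42)
    assert a == b


def test_short_transcripts_excluded_with_warning():
    t = [SeqRecord("long", "ACGT" * 60), SeqRecord("short", "ACGT")]
    expr = {"long": 0.5, "short": 0.5}
    with pytest.warns(UserWarning, match="excluded"):
        m1, _, origin = simulate.simulate_reads(t, expr, 20, seed=1)
    assert all(tid == "long" for tid, _, _ in origin.values())
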