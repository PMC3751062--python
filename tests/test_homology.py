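"""Local alignment vs an exhaustive DP oracle, E-value arithmetic, search
semantics, best-hit tie-breaks, completeness and the pre-cluster graph."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from holotx.homology import (NUCLEOTIDE_SCHEME, PROTEIN_SCHEME, ScoringScheme,
                             align_local, align_score, best_hits,
                             build_precluster_graph, completeness, evalue,
                             search)
from holotx.seqio import SeqRecord
from oracles import sw_affine_score

_LINEAR_NT = ScoringScheme("nucleotide", (3, -3), 0, 2, 1.28, 0.46)
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestAlign:
    def test_textbook_linear_gap_example(self):
        a = align_local("GGTTGACTA", "TGTTACGG", _LINEAR_NT)
        assert round(a.score) == 13

    def test_identical_sequences_identity_one(self):
        pep = "MKTAYIAKQR"
        a = align_local(pep, pep, PROTEIN_SCHEME)
        self_score = sum(float(_BLOSUM62[c, c]) for c in pep)
        assert a.score == self_score
        assert a.identity == 1.0
        assert (a.q_start, a.q_end) == (1, len(pep))

    def test_no_positive_pair_scores_zero(self):
        a = align_local("AAAA", "TTTT", NUCLEOTIDE_SCHEME)
        assert a.score == 0 and a.length == 0

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            align_local("MKTAYI", "ACGT1", PROTEIN_SCHEME)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(aas, size=int(rng.integers(8, 25))))
            b = "".join(rng.choice(aas, size=int(rng.integers(8, 25))))
            assert align_score(a, b) == align_score(b, a)

    def test_matches_exhaustive_dp_oracle_protein(self):
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        fn = lambda x, y: float(_BLOSUM62[x, y])
        for _ in range(50):
            a = "".join(rng.choice(aas, size=int(rng.integers(5, 30))))
            b = "".join(rng.choice(aas, size=int(rng.integers(5, 30))))
            assert align_score(a, b, PROTEIN_SCHEME) == pytest.approx(
                sw_affine_score(a, b, fn, 11, 1))

    def test_matches_exhaustive_dp_oracle_nucleotide(self):
        rng = np.random.default_rng(2)
        fn = lambda x, y: 1.0 if x == y else -2.0
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 40))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 40))))
            assert align_score(a, b, NUCLEOTIDE_SCHEME) == pytest.approx(
                sw_affine_score(a, b, fn, 5, 2))


class TestEvalue:
    def test_closed_form_at_zero_score(self):
        assert evalue(0, 100, 100, PROTEIN_SCHEME) == pytest.approx(410.0)

    def test_monotone_in_score_and_linear_in_n(self):
        e1 = evalue(100, 200, 10000, PROTEIN_SCHEME)
        e2 = evalue(101, 200, 10000, PROTEIN_SCHEME)
        assert e2 < e1
        assert evalue(100, 200, 20000, PROTEIN_SCHEME) == pytest.approx(2 * e1)

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            evalue(-1, 10, 10, PROTEIN_SCHEME)


class TestSearch:
    def test_self_search_self_hits(self, holo):
        truth, _, _ = holo
        db = truth.reference_proteome[:6]
        hits = search(db, db, PROTEIN_SCHEME, evalue_max=1e-5)
        for rec in db:
            mine = hits[(hits["qseqid"] == rec.id)]
            assert not mine.empty
            top = mine.iloc[0]          # sorted ascending E per query
            assert top["sseqid"] == rec.id
            assert top["pident"] == 100.0

    def test_unrelated_sequences_give_empty_table(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        qs = [SeqRecord("q", "".join(rng.choice(aas, size=80)))]
        db = [SeqRecord(f"d{i}", "".join(rng.choice(aas, size=80)))
              for i in range(5)]
        assert search(qs, db, PROTEIN_SCHEME, evalue_max=1e-30).empty

    def test_empty_query_set(self, holo):
        truth, _, _ = holo
        out = search([], truth.reference_proteome, PROTEIN_SCHEME)
        assert out.empty

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            search([SeqRecord("q", "MKTAYI")], [], PROTEIN_SCHEME)

    def test_translated_search_recovers_peptide_subject(self, holo, annotated):
        truth, _, _ = holo
        orfs, peptides, hits = annotated
        pep_best = best_hits(hits)
        expected = dict(zip(pep_best["qseqid"], pep_best["sseqid"]))
        by_id = {o.orf_id: o for o in orfs}
        some = list(expected)[:8]
        cdna = [SeqRecord(i, by_id[i].cdna) for i in some]
        thits = search(cdna, truth.reference_proteome, PROTEIN_SCHEME,
                       evalue_max=2e-30, mode="translated")
        tbest = dict(zip(best_hits(thits)["qseqid"], best_hits(thits)["sseqid"]))
        for i in some:
            assert tbest.get(i) == expected[i]

    def test_seed_filter_reproduces_full_dp_hits(self, holo, annotated):
        truth, _, _ = holo
        _, peptides, hits = annotated
        fast = search(peptides[:20], truth.reference_proteome, PROTEIN_SCHEME,
                      evalue_max=2e-30, seed_filter_word=4)
        full = hits[hits["qseqid"].isin([p.id for p in peptides[:20]])]
        key = ["qseqid", "sseqid", "evalue", "score"]
        assert fast[key].reset_index(drop=True).equals(
            full[key].reset_index(drop=True))


class TestBestHits:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue",
                                           "score"])

    def test_minimum_evalue_wins(self):
        df = self._frame([("q", "a", 1e-35, 100), ("q", "b", 1e-40, 90)])
        assert best_hits(df).iloc[0]["sseqid"] == "b"

    def test_score_breaks_evalue_ties(self):
        df = self._frame([("q", "a", 1e-40, 100), ("q", "b", 1e-40, 120)])
        assert best_hits(df).iloc[0]["sseqid"] == "b"

    def test_subject_id_breaks_full_ties(self):
        df = self._frame([("q", "b", 1e-40, 100), ("q", "a", 1e-40, 100)])
        assert best_hits(df).iloc[0]["sseqid"] == "a"


class TestCompleteness:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue",
                                           "scov"])

    def test_fraction_forced_by_definition(self):
        ref = {f"p{i}": 100 for i in range(10)}
        hits = self._hits([(f"q{i}", f"p{i}", 1e-40, 0.9) for i in range(4)])
        assert completeness(hits, ref) == 40.0

    def test_boundary_coverage_counts(self):
        ref = {"p0": 100, "p1": 100}
        hits = self._hits([("q", "p0", 1e-40, 0.80)])
        assert completeness(hits, ref) == 50.0
        hits2 = self._hits([("q", "p0", 1e-40, 0.799)])
        assert completeness(hits2, ref) == 0.0

    def test_no_hits_and_empty_reference(self):
        ref = {"p0": 100}
        assert completeness(self._hits([]), ref) == 0.0
        with pytest.raises(ValueError):
            completeness(self._hits([]), {})

    def test_monotone_under_added_hits(self):
        ref = {f"p{i}": 100 for i in range(5)}
        rows = [("q0", "p0", 1e-40, 0.9)]
        prev = completeness(self._hits(rows), ref)
        for i in range(1, 5):
            rows.append((f"q{i}", f"p{i}", 1e-40, 0.9))
            cur = completeness(self._hits(rows), ref)
            assert cur >= prev
            prev = cur


class TestPreclusterGraph:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue"])

    def test_weight_is_negative_log10(self):
        g = build_precluster_graph(self._hits([("q", "s", 1e-50)]))
        assert g["q"]["s"]["weight"] == pytest.approx(50.0)

    def test_zero_evalue_capped(self):
        g = build_precluster_graph(self._hits([("q", "s", 0.0)]))
        assert g["q"]["s"]["weight"] == 200.0

    def test_duplicate_pair_keeps_best(self):
        g = build_precluster_graph(self._hits([("q", "s", 1e-40),
                                               ("q", "s", 1e-60)]))
        assert g["q"]["s"]["weight"] == pytest.approx(60.0)
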