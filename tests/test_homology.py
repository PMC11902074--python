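"""Alignment, RBH, chaining, and classification against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeodyn import homology
from homeodyn.homology import (AlignScoring, SimilarityHit, SyntenyAnchor, align_pair,
                               all_vs_all_hits, build_homoeolog_table, chain_anchors,
                               chain_score, classify_genes, confirm_specific, filter_hits,
                               reciprocal_best_hits)
from oracles import best_chain_score_bruteforce, gotoh_local_score, rbh_bruteforce


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignPair:
    def test_identical_sequences_are_perfect(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 100)
        hit = align_pair(seq, seq)
        assert hit.identity == 1.0
        assert hit.coverage == 1.0
        assert hit.score == pytest.approx(200.0)

    def test_half_length_subject_halves_coverage(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 100)
        hit = align_pair(seq, seq[:50])
        assert hit.identity == 1.0
        assert hit.coverage == pytest.approx(0.5)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_gotoh_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s1 = _random_seq(rng, 20)
        s2 = _random_seq(rng, 20)
        expected = gotoh_local_score(s1, s2)
        assert align_pair(s1, s2).score == pytest.approx(expected)


class TestHitsAndRBH:
    def test_disjoint_random_sets_yield_no_hits(self):
        rng = np.random.default_rng(2)
        a = {f"a{i}": _random_seq(rng, 300) for i in range(5)}
        b = {f"b{i}": _random_seq(rng, 300) for i in range(5)}
        assert all_vs_all_hits(a, b) == []

    def test_identical_sets_hit_their_twins_perfectly(self):
        rng = np.random.default_rng(3)
        a = {f"a{i}": _random_seq(rng, 300) for i in range(4)}
        b = {f"b{i}": a[f"a{i}"] for i in range(4)}
        hits = all_vs_all_hits(a, b)
        perfect = {(h.query_id, h.subject_id) for h in hits if h.identity == 1.0}
        assert {(f"a{i}", f"b{i}") for i in range(4)} <= perfect

    def test_below_threshold_identity_is_filtered(self):
        # the published thresholds: identity 0.6 and coverage 0.2
        hits = [SimilarityHit("q", "s", 0.55, 0.9, 50.0),
                SimilarityHit("q", "t", 0.61, 0.19, 50.0),
                SimilarityHit("q", "u", 0.61, 0.21, 50.0)]
        kept = filter_hits(hits, identity_min=0.6, coverage_min=0.2)
        assert [h.subject_id for h in kept] == ["u"]

    def test_raising_identity_threshold_never_adds_pairs(self):
        rng = np.random.default_rng(4)
        a = {f"a{i}": _random_seq(rng, 200) for i in range(6)}
        b = {}
        for i in range(6):
            seq = list(a[f"a{i}"])
            for j in rng.choice(len(seq), size=10, replace=False):
                seq[j] = "ACGT"[(("ACGT".index(seq[j])) + 1) % 4]
            b[f"b{i}"] = "".join(seq)
        n_pairs = []
        for identity_min in (0.6, 0.8, 0.95, 0.999):
            hits = all_vs_all_hits(a, b, identity_min=identity_min)
            n_pairs.append(len(reciprocal_best_hits(hits, a_ids=set(a))))
        assert n_pairs == sorted(n_pairs, reverse=True)

    def test_prefilter_keeps_all_truly_similar_pairs(self, small_sim):
        # at the generator's divergence regime, no pair above the identity
        # threshold may be lost to the k-mer prefilter
        import dataclasses
        from conftest import SMALL_PARAMS
        from homeodyn.synthetic_data import simulate_subgenomes

        p = dataclasses.replace(SMALL_PARAMS, substitution_rate=0.10, genes_per_chrom=20,
                                n_insertions_a=0, n_insertions_b=0, n_deletions_a=0,
                                n_deletions_b=0)
        ann_a, ann_b, truth = simulate_subgenomes(p)
        seqs_a = {g: ann_a.sequence_of(g) for g in ann_a.gene_ids}
        seqs_b = {g: ann_b.sequence_of(g) for g in ann_b.gene_ids}
        hits = all_vs_all_hits(seqs_a, seqs_b)
        found = {(h.query_id, h.subject_id) for h in hits}
        for a, b in truth.homoeolog_pairs:
            direct = align_pair(seqs_a[a], seqs_b[b])
            if direct.identity >= 0.6 and direct.coverage >= 0.2:
                assert (a, b) in found

    def test_rbh_simple_and_broken_reciprocity(self):
        hits = [SimilarityHit("g1", "h1", 0.9, 1.0, 100.0),
                SimilarityHit("h1", "g1", 0.9, 1.0, 100.0)]
        assert reciprocal_best_hits(hits, a_ids={"g1"}) == [("g1", "h1")]
        hits = [SimilarityHit("g1", "h1", 0.9, 1.0, 100.0),
                SimilarityHit("h1", "g2", 0.9, 1.0, 120.0),
                SimilarityHit("h1", "g1", 0.9, 1.0, 100.0),
                SimilarityHit("g2", "h1", 0.9, 1.0, 120.0)]
        assert reciprocal_best_hits(hits, a_ids={"g1", "g2"}) == [("g2", "h1")]

    @pytest.mark.parametrize("seed", range(6))
    def test_rbh_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lefts = [f"a{i}" for i in range(3)]
        rights = [f"b{i}" for i in range(3)]
        table = {}
        hits = []
        for a in lefts:
            for b in rights:
                if rng.random() < 0.8:
                    score = float(rng.integers(10, 40))
                    table[(a, b)] = score
                    hits.append(SimilarityHit(a, b, 0.9, 1.0, score))
                    hits.append(SimilarityHit(b, a, 0.9, 1.0, score))
        got = set(reciprocal_best_hits(hits, a_ids=set(lefts)))
        assert got == rbh_bruteforce(table)

    def test_rbh_is_symmetric_under_role_swap(self):
        rng = np.random.default_rng(9)
        hits = []
        for i in range(4):
            for j in range(4):
                if rng.random() < 0.7:
                    s = float(rng.integers(5, 50))
                    hits.append(SimilarityHit(f"a{i}", f"b{j}", 0.9, 1.0, s))
                    hits.append(SimilarityHit(f"b{j}", f"a{i}", 0.9, 1.0, s))
        fwd = set(reciprocal_best_hits(hits, a_ids={f"a{i}" for i in range(4)}))
        swapped = [SimilarityHit(h.subject_id, h.query_id, h.identity, h.coverage, h.score)
                   for h in hits]
        rev = set(reciprocal_best_hits(swapped, a_ids={f"b{j}" for j in range(4)}))
        assert fwd == {(a, b) for b, a in rev}


class TestChaining:
    def test_perfectly_collinear_pairs_form_one_block(self):
        anchors = [SyntenyAnchor(f"a{i}", f"b{i}", i, i) for i in range(5)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 5
        assert blocks[0].orientation == "same"

    def test_two_crossing_pairs_are_below_min_size(self):
        anchors = [SyntenyAnchor("a0", "b1", 0, 1), SyntenyAnchor("a1", "b0", 1, 0)]
        assert chain_anchors(anchors) == []

    def test_inverted_block_is_found(self):
        anchors = [SyntenyAnchor(f"a{i}", f"b{i}", i, 9 - i) for i in range(4)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    @pytest.mark.parametrize("seed", range(25))
    def test_dp_score_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        anchors = sorted(
            (SyntenyAnchor(f"a{i}", f"b{i}", int(ar), int(br))
             for i, (ar, br) in enumerate(zip(rng.choice(30, n, replace=False),
                                              rng.choice(30, n, replace=False)))),
            key=lambda x: x.a_rank)
        for orientation in ("same", "inverted"):
            brute = best_chain_score_bruteforce(anchors, orientation, 0.5, 0.1, 25, chain_score)
            dp_score, _ = homology._best_chain(anchors, orientation, 0.5, 0.1, 25)
            assert dp_score == pytest.approx(brute)


class TestTableAndClassification:
    def test_synteny_precedence_over_rbh(self):
        anchors = [SyntenyAnchor(f"a{i}", f"b{i}", i, i) for i in range(3)]
        blocks = chain_anchors(anchors)
        hits = [SimilarityHit(f"a{i}", f"b{i}", 0.95, 0.9, 80.0) for i in range(3)]
        table = build_homoeolog_table(blocks, [("a0", "b0")], hits, {"a0", "a1", "a2"})
        assert {r.a_gene: r.evidence for r in table} == {f"a{i}": "synteny" for i in range(3)}

    def test_supplement_pairs_leftovers_by_descending_score(self):
        hits = [SimilarityHit("a0", "b0", 0.9, 0.9, 50.0),
                SimilarityHit("a1", "b0", 0.8, 0.9, 70.0),
                SimilarityHit("a1", "b1", 0.7, 0.9, 30.0)]
        table = build_homoeolog_table([], [], hits, {"a0", "a1"})
        by_a = {r.a_gene: r.b_gene for r in table}
        assert by_a == {"a1": "b0"}  # highest score wins first; a0's only hit is taken

    def test_zero_noise_truth_recovery(self, small_classified):
        _, _, truth, table, specific, summary = small_classified
        pairs = {(r.a_gene, r.b_gene) for r in table}
        assert pairs == truth.homoeolog_pairs
        confirmed = {r.gene_id for r in specific if r.confirmed}
        assert confirmed == set(truth.a_specific) | set(truth.b_specific)
        assert summary.n_unresolved_a == summary.n_unresolved_b == 0

    def test_class_partition_conserves_genes(self, small_classified):
        ann_a, ann_b, _, table, specific, summary = small_classified
        assert (summary.n_homoeolog_pairs + summary.n_a_specific
                + summary.n_unresolved_a == summary.total_a == ann_a.n_genes)
        assert (summary.n_homoeolog_pairs + summary.n_b_specific
                + summary.n_unresolved_b == summary.total_b == ann_b.n_genes)

    def test_inserted_gene_confirmed_with_near_zero_cross_coverage(self, small_classified):
        _, _, truth, _, specific, _ = small_classified
        ins = {g for g, o in truth.a_specific.items() if o == "insertion"}
        for r in specific:
            if r.gene_id in ins:
                assert r.confirmed
                assert r.best_cross_coverage < 0.2

    def test_cross_genome_twin_is_not_confirmed_specific(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 400)
        from homeodyn.io_formats import GeneModel
        gene = GeneModel("orphan", "chrA01", 0, 400, "+", "A")
        records = confirm_specific([gene], {"orphan": seq}, {"twin": seq})
        assert len(records) == 1
        assert not records[0].confirmed
        assert records[0].best_cross_identity == 1.0

    def test_double_classification_raises(self, small_classified):
        ann_a, ann_b, _, table, specific, _ = small_classified
        from homeodyn.homology import SpecificGeneRecord
        bad = specific + [SpecificGeneRecord(table[0].a_gene, "A", True, 0.0, 0.0)]
        with pytest.raises(RuntimeError):
            classify_genes(table, bad, ann_a, ann_b)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 15), st.integers(0, 15)), min_size=1,
                max_size=8, unique_by=lambda t: t))
def test_chain_score_contract_rejects_nonmonotone(pairs):
    """The shared scoring contract only accepts strictly monotone chains."""
    anchors = [SyntenyAnchor(f"a{i}", f"b{i}", ar, br) for i, (ar, br) in enumerate(pairs)]
    s = chain_score(anchors, "same", 0.5, 0.1, 25)
    ok_a = all(q.a_rank > p.a_rank for p, q in zip(anchors, anchors[1:]))
    ok_b = all(q.b_rank > p.b_rank for p, q in zip(anchors, anchors[1:]))
    gaps = all(q.a_rank - p.a_rank <= 25 and q.b_rank - p.b_rank <= 25
               for p, q in zip(anchors, anchors[1:]))
    assert (s is not None) == (ok_a and ok_b and gaps)
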