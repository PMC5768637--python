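"""Markov background, window scores, exact p-values, scanning, operons."""

import itertools
import math

import numpy as np
import pytest

from phorep import motifs, synth
from phorep.io import GeneModel, SequenceRecord
from phorep.motifs import (
    DnaPSSM,
    MarkovBackground,
    UpstreamRegion,
    exact_pvalue_table,
    extract_upstream,
    predict_transcription_units,
    scan_upstream,
    train_markov,
    window_score,
)


class TestTrainMarkov:
    def test_pure_repeat_transition(self):
        bg = train_markov(["A" * 40], order=1, pseudocount=0)
        assert bg.transition[0, 0] == pytest.approx(1.0)

    def test_order0_is_marginal_composition(self):
        bg = train_markov(["ACGTACGTACGTACGTACGT"], order=0, pseudocount=0)
        assert np.allclose(bg.initial, 0.25)

    def test_uniform_iid_corpus_transitions_near_quarter(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        bg = train_markov([seq], order=1)
        assert np.allclose(bg.transition, 0.25, atol=0.01)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_markov([])

    def test_counts_not_pooled_across_boundaries(self):
        # the corpus alternates AC and GT in separate sequences:
        # a C -> G transition could only arise across a boundary
        bg = train_markov(["AC" * 10, "GT" * 10], order=1, pseudocount=0.0001)
        assert bg.transition[1, 2] < 0.01  # C -> G essentially unseen


class TestWindowScore:
    def test_matrix_equal_to_background_scores_zero(self):
        pssm = DnaPSSM("flat", np.full((4, 4), 0.25))
        bg = MarkovBackground(0, np.full(4, 0.25), None)
        assert window_score(pssm, "ACGT", bg) == pytest.approx(0.0)

    def test_two_bp_hand_arithmetic(self):
        # ln(0.7/0.3) + ln(0.4/0.2) = 1.5404
        pssm = DnaPSSM("toy", np.array([[0.7, 0.1, 0.1, 0.1], [0.3, 0.4, 0.2, 0.1]]))
        init = np.array([0.3, 0.3, 0.2, 0.2])
        trans = np.tile([0.4, 0.2, 0.2, 0.2], (4, 1))
        bg = MarkovBackground(1, init, trans)
        expected = math.log(0.7 / 0.3) + math.log(0.4 / 0.2)
        assert window_score(pssm, "AC", bg) == pytest.approx(expected, abs=1e-12)

    def test_n_contributes_zero(self):
        pssm = DnaPSSM("toy", np.array([[0.7, 0.1, 0.1, 0.1], [0.3, 0.4, 0.2, 0.1]]))
        bg = MarkovBackground(0, np.full(4, 0.25), None)
        assert window_score(pssm, "NN", bg) == pytest.approx(0.0)
        assert window_score(pssm, "AN", bg) == pytest.approx(math.log(0.7 / 0.25))

    def test_illegal_symbol_rejected(self):
        pssm = DnaPSSM("toy", np.full((1, 4), 0.25))
        bg = MarkovBackground(0, np.full(4, 0.25), None)
        with pytest.raises(ValueError, match="illegal"):
            window_score(pssm, "Z", bg)


class TestExactPvalues:
    def test_single_column_tail_is_symbol_mass(self):
        # strong-A column: only an A window reaches the top score, so
        # P(S >= score(A)) equals the background mass of A (uniform: 0.25)
        pssm = DnaPSSM("a", np.array([[0.97, 0.01, 0.01, 0.01]]))
        bg = MarkovBackground(0, np.full(4, 0.25), None)
        table = exact_pvalue_table(pssm, bg)
        assert table.pvalue(window_score(pssm, "A", bg)) == pytest.approx(0.25)

    def test_minimum_score_has_probability_one(self):
        pssm = DnaPSSM("a", np.array([[0.97, 0.01, 0.01, 0.01]]))
        bg = MarkovBackground(0, np.full(4, 0.25), None)
        table = exact_pvalue_table(pssm, bg)
        assert table.pvalue(-1e9) == pytest.approx(1.0)

    def test_tail_non_increasing(self):
        pssm = synth.phob_like_matrix()
        bg = synth.at_rich_background()
        table = exact_pvalue_table(pssm, bg)
        assert (np.diff(table.tail) <= 1e-15).all()

    def test_bad_bin_width_rejected(self):
        pssm = DnaPSSM("a", np.full((1, 4), 0.25))
        bg = MarkovBackground(0, np.full(4, 0.25), None)
        with pytest.raises(ValueError, match="bin_width"):
            exact_pvalue_table(pssm, bg, bin_width=0.0)

    def test_dp_equals_brute_force_enumeration_order1(self):
        rng = np.random.default_rng(0)
        L = 5
        pssm = DnaPSSM("toy", rng.dirichlet(np.ones(4) * 2, size=L))
        init = np.array([0.4, 0.1, 0.2, 0.3])
        trans = rng.dirichlet(np.ones(4) * 3, size=4)
        bg = MarkovBackground(1, init, trans)
        bw = 0.01
        table = exact_pvalue_table(pssm, bg, bin_width=bw)
        dist: dict[int, float] = {}
        for win in itertools.product(range(4), repeat=L):
            p = init[win[0]]
            k = round((math.log(pssm.probs[0, win[0]]) - math.log(init[win[0]])) / bw)
            for i in range(1, L):
                p *= trans[win[i - 1], win[i]]
                k += round((math.log(pssm.probs[i, win[i]])
                            - math.log(trans[win[i - 1], win[i]])) / bw)
            dist[k] = dist.get(k, 0.0) + p
        for k in sorted(dist):
            enum_tail = sum(v for kk, v in dist.items() if kk >= k)
            assert table.pvalue(k * bw) == pytest.approx(enum_tail, abs=1e-12)


class TestScanUpstream:
    def test_planted_consensus_recovered(self):
        bg = synth.at_rich_background()
        pssm = synth.phob_like_matrix()
        rng = np.random.default_rng(3)
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)]))
        seq[400 - 96:400 - 80] = list(pssm.consensus())
        hits = scan_upstream(pssm, UpstreamRegion("g", "".join(seq)), bg, 1e-4)
        assert any(h.interval == (-96, -81) and h.strand == "+" for h in hits)

    def test_region_shorter_than_matrix_is_empty(self):
        bg = synth.at_rich_background()
        pssm = synth.phob_like_matrix()
        assert scan_upstream(pssm, UpstreamRegion("g", "ACGT"), bg) == []

    def test_strand_symmetry(self):
        bg = synth.at_rich_background()
        pssm = synth.phob_like_matrix()
        rng = np.random.default_rng(4)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        rc = str(SequenceRecord("x", "", seq, "dna").reverse_complement().residues)
        table = exact_pvalue_table(pssm, bg)
        fwd = scan_upstream(pssm, UpstreamRegion("g", seq), bg, 0.05, table=table)
        rev = scan_upstream(pssm, UpstreamRegion("g", rc), bg, 0.05, table=table)
        plus = sorted(round(h.score, 9) for h in fwd if h.strand == "+")
        minus = sorted(round(h.score, 9) for h in rev if h.strand == "-")
        assert plus == minus

    def test_null_hit_rate_matches_threshold(self):
        # expected false positives = p_threshold per scored window
        bg = synth.at_rich_background()
        pssm = synth.phob_like_matrix()
        table = exact_pvalue_table(pssm, bg)
        rng = np.random.default_rng(5)
        total_hits = total_windows = 0
        for rep in range(10):
            enc = synth._markov_sequence(rng, bg, 10_000)
            seq = "".join(np.array(list("ACGT"))[enc])
            hits = scan_upstream(pssm, UpstreamRegion(f"r{rep}", seq), bg, 1e-4, table=table)
            total_hits += len(hits)
            total_windows += 2 * (10_000 - pssm.length + 1)
        expected = 1e-4 * total_windows
        assert 0.5 <= total_hits / expected <= 2.0


class TestExtractUpstream:
    def make_genome(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return SequenceRecord("g", "", "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)]), "dna")

    def test_forward_gene_simple_gap(self):
        genes = [GeneModel("A", "D", 1, 300), GeneModel("B", "D", 401, 700)]
        genome = self.make_genome()
        region = extract_upstream(genes, "B", genome)
        assert len(region) == 100
        assert region.sequence == genome.residues[300:400]

    def test_zero_intergenic_gap_gives_empty_region(self):
        genes = [GeneModel("A", "D", 1, 300), GeneModel("B", "D", 301, 600)]
        assert len(extract_upstream(genes, "B", self.make_genome(600))) == 0

    def test_reverse_strand_region_is_reverse_complemented(self):
        genes = [GeneModel("A", "R", 300, 101), GeneModel("B", "D", 401, 700)]
        genome = self.make_genome()
        region = extract_upstream(genes, "A", genome)
        expected = str(SequenceRecord("x", "", genome.residues[300:400], "dna")
                       .reverse_complement().residues)
        assert region.sequence == expected

    def test_contig_edge_truncates_with_warning(self):
        genes = [GeneModel("A", "D", 51, 350)]
        with pytest.warns(UserWarning, match="contig edge"):
            region = extract_upstream(genes, "A", self.make_genome(400))
        assert len(region) == 50

    def test_missing_target_rejected(self):
        with pytest.raises(KeyError):
            extract_upstream([GeneModel("A", "D", 1, 9)], "nope", self.make_genome(10))


class TestTranscriptionUnits:
    def test_three_gene_operon_with_published_style_gaps(self):
        # gaps of 74 and 50 nt merge into a single 3-gene unit
        genes = [GeneModel("a", "D", 1, 300), GeneModel("b", "D", 375, 600),
                 GeneModel("c", "D", 651, 900)]
        units = predict_transcription_units(genes)
        assert len(units) == 1 and [g.locus_tag for g in units[0].genes] == ["a", "b", "c"]

    def test_strand_switch_splits(self):
        genes = [GeneModel("a", "D", 1, 300), GeneModel("b", "R", 400, 350)]
        assert len(predict_transcription_units(genes)) == 2

    def test_gap_exactly_max_gap_merges(self):
        genes = [GeneModel("a", "D", 1, 300), GeneModel("b", "D", 451, 600)]
        assert len(predict_transcription_units(genes, max_gap=150)) == 1
        assert len(predict_transcription_units(genes, max_gap=149)) == 2

    def test_reverse_strand_unit_ordered_by_transcription(self):
        genes = [GeneModel("a", "R", 300, 101), GeneModel("b", "R", 500, 351)]
        units = predict_transcription_units(genes)
        assert len(units) == 1
        assert [g.locus_tag for g in units[0].genes] == ["b", "a"]
        assert units[0].first_gene.locus_tag == "b"
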