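"""Profile scanning, calibration, redundancy removal, family assignment."""

import math

import numpy as np
import pytest
from scipy import stats

from phorep import profiles, synth
from phorep.io import GeneModel, SequenceRecord
from phorep.profiles import (
    ProfileHit,
    ProteinPSSM,
    ScanCalibration,
    analytic_lambda,
    assign_family,
    best_score,
    best_ungapped_hits,
    calibrate,
    counts_to_logodds,
    deduplicate_profiles,
    local_alignment_score,
    validate_member,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def hit(acc, begin, end, evalue, qid="ref"):
    return ProfileHit(qid, acc, (begin, end), (1, end - begin + 1), 10.0, evalue)


class TestCountsToLogodds:
    def test_uniform_counts_uniform_background_all_zero(self):
        bg = np.full(20, 0.05)
        pssm = counts_to_logodds(np.full((3, 20), 2.0), bg, pseudocount=1.0)
        assert np.allclose(pssm.weights, 0.0)

    def test_hand_arithmetic_single_column(self):
        # counts (4,0,...,0), uniform bg, pseudocount 1:
        # w = 2*(log2((4+0.05)/5) - log2(0.05)) = 8.036 half-bits
        counts = np.zeros((1, 20))
        counts[0, 0] = 4.0
        pssm = counts_to_logodds(counts, np.full(20, 0.05), pseudocount=1.0)
        assert pssm.weights[0, 0] == pytest.approx(8.036, abs=1e-3)

    def test_doubling_counts_invariant_in_zero_pseudocount_limit(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(5, 20)).astype(float)
        w1 = counts_to_logodds(counts, pseudocount=1e-9).weights
        w2 = counts_to_logodds(2 * counts, pseudocount=1e-9).weights
        assert np.allclose(w1, w2, atol=1e-6)

    def test_zero_background_rejected(self):
        bg = np.full(20, 0.05)
        bg[3] = 0.0
        bg[4] = 0.1
        with pytest.raises(ValueError, match="positive"):
            counts_to_logodds(np.ones((2, 20)), bg)


class TestScanning:
    def test_segment_scores_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        w = rng.normal(0, 2, (12, 20))
        pssm = ProteinPSSM("toy", w)
        q = "".join(np.random.default_rng(2).choice(list(AA), 20))
        best = best_score(pssm, SequenceRecord("q", "", q, "protein"))
        idx = {a: i for i, a in enumerate(AA)}
        brute = -np.inf
        for off in range(-11, 20):
            for i0 in range(12):
                for i1 in range(i0, 12):
                    if i0 + off < 0 or i1 + off >= 20:
                        continue
                    brute = max(brute, sum(w[i, idx[q[i + off]]] for i in range(i0, i1 + 1)))
        assert best == pytest.approx(brute, abs=1e-9)

    def test_consensus_query_spans_full_profile_with_max_score(self, standard_proteome):
        pssm = standard_proteome.family_sets[0].pssms[0]
        query = SequenceRecord("cons", "", pssm.consensus(), "protein")
        cal = ScanCalibration(lam=0.35, K=0.1, method="analytic")
        hits = best_ungapped_hits(pssm, query, cal)
        assert hits[0].profile_interval == (1, pssm.length)
        assert hits[0].score == pytest.approx(float(pssm.weights.max(axis=1).sum()))

    def test_unknown_residues_score_zero(self):
        pssm = ProteinPSSM("toy", np.full((4, 20), -1.0))
        cal = ScanCalibration(lam=0.35, K=0.1, method="analytic")
        assert best_score(pssm, SequenceRecord("q", "", "XXXX", "protein")) == 0.0

    def test_evalue_decreases_with_score(self):
        cal = ScanCalibration(lam=0.3, K=0.1, method="empirical")
        assert cal.evalue(50, 100, 300) < cal.evalue(40, 100, 300)


class TestCalibration:
    def test_deterministic_given_seed(self, standard_proteome):
        pssm = standard_proteome.family_sets[0].pssms[0]
        c1 = calibrate(pssm, n_samples=500, seed=3)
        c2 = calibrate(pssm, n_samples=500, seed=3)
        assert (c1.lam, c1.K) == (c2.lam, c2.K)

    def test_all_zero_pssm_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate(ProteinPSSM("zero", np.zeros((5, 20))), n_samples=500, seed=0)

    def test_analytic_lambda_closed_form_single_column(self):
        # weights +1 on five residues (p+ = their background mass), -1 else:
        # p+ e^l + p- e^-l = 1 has the closed-form root e^l
        w = np.full((1, 20), -1.0)
        w[0, :5] = 1.0
        pssm = ProteinPSSM("pm1", w)
        bg = profiles.DEFAULT_AA_BACKGROUND
        p_plus = bg[:5].sum()
        p_minus = 1 - p_plus
        x = (1 + math.sqrt(1 - 4 * p_plus * p_minus)) / (2 * p_plus)
        assert analytic_lambda(pssm, bg) == pytest.approx(math.log(x), rel=1e-6)

    def test_empirical_lambda_matches_analytic_within_10pct(self, standard_proteome,
                                                            standard_calibrations):
        pssm = standard_proteome.family_sets[0].pssms[0]
        lam_analytic = analytic_lambda(pssm)
        lam_emp = standard_calibrations[pssm.accession].lam
        assert abs(lam_emp - lam_analytic) / lam_analytic < 0.10

    def test_background_best_scores_follow_fitted_gumbel(self, standard_proteome,
                                                         standard_calibrations):
        pssm = standard_proteome.family_sets[0].pssms[0]
        cal = standard_calibrations[pssm.accession]
        rng = np.random.default_rng(99)
        fresh = np.empty(400)
        for k in range(400):
            seq = "".join(rng.choice(list(AA), 300, p=profiles.DEFAULT_AA_BACKGROUND))
            fresh[k] = best_score(pssm, SequenceRecord("r", "", seq, "protein"))
        loc = math.log(cal.K * pssm.length * 300) / cal.lam
        ks = stats.kstest(fresh, stats.gumbel_r(loc=loc, scale=1 / cal.lam).cdf)
        assert ks.statistic < 0.08


class TestDeduplication:
    def test_published_phod_intervals_both_retained(self):
        # overlap 295 of the longer 518-aa hit: coverage 0.57 <= 0.70
        hits = [hit("COG3540", 22, 539, 1e-60), hit("cd07389", 174, 468, 1e-40)]
        assert deduplicate_profiles(hits) == ["COG3540", "cd07389"]

    def test_published_phok_intervals_both_retained(self):
        # overlap 71 of 451: coverage 0.16
        hits = [hit("pfam01663", 44, 494, 1e-80), hit("COG1524", 41, 114, 1e-20)]
        assert deduplicate_profiles(hits) == ["pfam01663", "COG1524"]

    def test_high_coverage_pair_keeps_lowest_evalue(self):
        # overlap 86 of 100: coverage 0.86 > 0.70
        hits = [hit("B", 10, 95, 1e-20), hit("A", 1, 100, 1e-50)]
        assert deduplicate_profiles(hits) == ["A"]

    def test_idempotent_and_rule_respected(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            hits = []
            for k in range(10):
                b = int(rng.integers(1, 400))
                e = b + int(rng.integers(20, 300))
                hits.append(hit(f"p{k}", b, e, float(10.0 ** -rng.integers(5, 60))))
            kept = deduplicate_profiles(hits)
            kept_hits = [h for h in hits if h.pssm_accession in kept]
            assert deduplicate_profiles(kept_hits) == kept
            for i, a in enumerate(kept_hits):
                for b in kept_hits[i + 1:]:
                    assert profiles.mutual_coverage(a.query_interval, b.query_interval) <= 0.70

    def test_empty_input(self):
        assert deduplicate_profiles([]) == []


class TestMembership:
    def family(self, n_pssms):
        pssms = [ProteinPSSM(f"p{i}", np.ones((5, 20))) for i in range(n_pssms)]
        ref = SequenceRecord("ref", "", "M" * 50, "protein")
        return profiles.FamilyReferenceSet("PhoX", ref, pssms)

    def test_all_profiles_below_threshold_is_member(self):
        fam = self.family(2)
        hits = [hit("p0", 1, 10, 1e-12), hit("p1", 1, 10, 1e-15)]
        assert assign_family(hits, fam) is True

    def test_one_profile_above_threshold_is_not_member(self):
        fam = self.family(2)
        hits = [hit("p0", 1, 10, 1e-12), hit("p1", 1, 10, 1e-8)]
        assert assign_family(hits, fam) is False

    def test_membership_monotone_in_threshold(self):
        fam = self.family(2)
        hits = [hit("p0", 1, 10, 1e-12), hit("p1", 1, 10, 1e-8)]
        assert assign_family(hits, fam, e_threshold=1e-8) is True


class TestValidation:
    def test_identical_sequence_validates(self, standard_proteome):
        ref = standard_proteome.family_sets[0].reference_sequence
        assert validate_member(ref, ref) is True

    def test_random_sequences_do_not_validate(self, standard_proteome):
        ref = standard_proteome.family_sets[0].reference_sequence
        rng = np.random.default_rng(11)
        outcomes = [
            validate_member(
                SequenceRecord("r", "", "".join(rng.choice(list(AA), 300)), "protein"), ref
            )
            for _ in range(20)
        ]
        assert not any(outcomes)

    def test_alignment_score_matches_gotoh_dynamic_programming(self):
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")

        def gotoh(a, b, open_=-11.0, ext=-1.0):
            n, m = len(a), len(b)
            M = np.zeros((n + 1, m + 1))
            X = np.full((n + 1, m + 1), -1e9)  # gap in b
            Y = np.full((n + 1, m + 1), -1e9)  # gap in a
            best = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext)
                    Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext)
                    s = blosum[a[i - 1], b[j - 1]]
                    M[i, j] = max(0.0, M[i - 1, j - 1] + s, X[i, j], Y[i, j])
                    best = max(best, M[i, j])
            return best

        rng = np.random.default_rng(5)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), 10))
            b = "".join(rng.choice(list(AA), 10))
            assert local_alignment_score(a, b) == pytest.approx(gotoh(a, b))


class TestAnnotateProteome:
    def test_empty_proteome_empty_annotations(self, standard_proteome, standard_calibrations):
        assert profiles.annotate_proteome([], standard_proteome.family_sets,
                                          standard_calibrations) == []

    def test_synthetic_truth_recovered_exactly(self, standard_proteome, standard_calibrations):
        anns = profiles.annotate_proteome(
            standard_proteome.records, standard_proteome.family_sets, standard_calibrations
        )
        predicted = {(a.protein_id, a.family) for a in anns}
        truth = set(zip(standard_proteome.truth.protein_id, standard_proteome.truth.family))
        assert predicted == truth


@pytest.fixture(scope="module")
def single_implant():
    sp = synth.gen_proteome(synth.ProteomeConfig(seed=1, n_decoys=0, implants=(("PhoX", 1),)))
    cal = {p.accession: calibrate(p, n_samples=500, seed=7)
           for p in sp.family_sets[0].pssms}
    tr = sp.truth.iloc[0]
    domain = sp.records[0].residues[tr["begin"] - 1:tr["end"]]
    codon = {v: k for k, v in profiles._CODON_TABLE.items()}
    return sp.family_sets, cal, "".join(codon[a] for a in domain)


class TestSixFrameScan:
    def make_genome(self, dna_domain, seed=9):
        rng = np.random.default_rng(seed)
        bg = lambda n: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        seq = bg(500) + dna_domain + bg(400) + bg(900)
        genes = [GeneModel("g1", "D", len(seq) - 899, len(seq) - 600)]
        return SequenceRecord("g", "", seq, "dna"), genes

    def test_forward_implant_found_in_correct_frame(self, single_implant):
        family_sets, cal, dna_domain = single_implant
        genome, genes = self.make_genome(dna_domain)
        hits = profiles.scan_noncoding_sixframe(genome, genes, family_sets, cal)
        assert hits and hits[0].frame in (1, 2, 3)
        gb, ge = hits[0].genomic_interval
        assert 501 <= gb and ge <= 500 + len(dna_domain)

    def test_reverse_complement_implant_on_negative_frame(self, single_implant):
        family_sets, cal, dna_domain = single_implant
        genome, genes = self.make_genome(dna_domain)
        rc = genome.reverse_complement()
        n = len(rc)
        rc_genes = [GeneModel("g1", "D", n - g.right + 1, n - g.left + 1) for g in genes]
        hits = profiles.scan_noncoding_sixframe(rc, rc_genes, family_sets, cal)
        assert hits and hits[0].frame in (-1, -2, -3)

    def test_fully_covered_genome_yields_nothing(self, single_implant):
        family_sets, cal, _ = single_implant
        genome = SequenceRecord("g", "", "ACGT" * 300, "dna")
        genes = [GeneModel("g1", "D", 1, 1200)]
        assert profiles.scan_noncoding_sixframe(genome, genes, family_sets, cal) == []
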