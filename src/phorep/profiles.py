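"""Profile-based annotation of non-specific phosphatase families.

A family is described by one reference sequence (a solved-structure protein)
plus a deduplicated set of position-specific scoring matrices (PSSMs). A
query protein is annotated as a family member when every PSSM of the family
set produces at least one hit with E <= 1e-10, and the call is then validated
by a low-stringency local alignment (E <= 1e-3) against the family reference.

Scanning is implemented as ungapped maximal-scoring profile-sequence
segments: for every diagonal offset the best contiguous segment is found
(Kadane recursion), and segment scores are converted to E-values through the
Karlin-Altschul law E = K * m * n * exp(-lambda * S) with (lambda, K) fitted
by maximum likelihood of the Gumbel distribution to best-segment scores on
i.i.d. background sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from Bio import Align
from Bio.Align import substitution_matrices

from .constants import (
    BLOSUM62_GAPPED_K,
    BLOSUM62_GAPPED_LAMBDA,
    PROTEIN_ALPHABET,
    ROBINSON_FREQUENCIES,
)
from .io import GeneModel, MatrixFile, SequenceRecord

_AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}

#: Default amino-acid background (Robinson & Robinson), fixed order.
DEFAULT_AA_BACKGROUND = np.array([ROBINSON_FREQUENCIES[a] for a in PROTEIN_ALPHABET])
DEFAULT_AA_BACKGROUND /= DEFAULT_AA_BACKGROUND.sum()


@dataclass
class ProteinPSSM:
    """Per-position log-odds weights (half-bit units) over the 20 aa."""

    accession: str
    weights: np.ndarray  # (length, 20)
    source_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 20:
            raise ValueError(f"PSSM {self.accession!r}: weights must be (L, 20)")
        if self.weights.shape[0] < 1:
            raise ValueError(f"PSSM {self.accession!r}: empty profile")
        if not np.isfinite(self.weights).all():
            raise ValueError(f"PSSM {self.accession!r}: non-finite weights")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def consensus(self) -> str:
        return "".join(PROTEIN_ALPHABET[j] for j in self.weights.argmax(axis=1))


@dataclass
class ScanCalibration:
    """Karlin-Altschul parameters attached to one PSSM.

    ``lam`` is in nats per (half-bit) score unit; E-values computed with
    these parameters use the per-comparison search space m * n.
    """

    lam: float
    K: float
    method: str  # "analytic" | "empirical"
    n_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("calibration requires lambda > 0 and K > 0")

    def evalue(self, score: float, m: int, n: int) -> float:
        exponent = -self.lam * score
        if exponent > 700:  # avoid float overflow for deeply negative scores
            return math.inf
        return self.K * m * n * math.exp(exponent)


@dataclass
class ProfileHit:
    """A scored ungapped profile-sequence segment (1-based inclusive)."""

    query_id: str
    pssm_accession: str
    query_interval: tuple[int, int]
    profile_interval: tuple[int, int]
    score: float
    evalue: float

    def __post_init__(self) -> None:
        for b, e in (self.query_interval, self.profile_interval):
            if b > e:
                raise ValueError("hit interval begin > end")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class FamilyReferenceSet:
    """One phosphatase family: reference sequence + deduplicated PSSMs."""

    family: str
    reference_sequence: SequenceRecord
    pssms: list[ProteinPSSM]


@dataclass
class FamilyAnnotation:
    protein_id: str
    family: str
    supporting_hits: list[ProfileHit]
    validated: bool


# ---------------------------------------------------------------------------
# PSSM construction
# ---------------------------------------------------------------------------

def counts_to_logodds(
    counts: np.ndarray | MatrixFile,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    accession: str = "pssm",
) -> ProteinPSSM:
    """Build a half-bit log-odds PSSM from a count matrix.

    weight(i, a) = 2 * [log2((c_ia + pc*bg_a) / (N_i + pc)) - log2(bg_a)].
    """
    if isinstance(counts, MatrixFile):
        accession = counts.accession
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if background is None:
        background = DEFAULT_AA_BACKGROUND
    background = np.asarray(background, dtype=float)
    if (background <= 0).any():
        raise ValueError("background frequencies must all be positive")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        probs = (counts + pseudocount * background) / (totals + pseudocount)
        weights = 2.0 * (np.log2(probs) - np.log2(background))
    return ProteinPSSM(accession, weights, source_counts=counts)


def emission_probabilities(pssm: ProteinPSSM, background: np.ndarray | None = None) -> np.ndarray:
    """Per-position emission distribution implied by the half-bit weights."""
    if background is None:
        background = DEFAULT_AA_BACKGROUND
    probs = background * np.power(2.0, pssm.weights / 2.0)
    return probs / probs.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Ungapped segment scanning
# ---------------------------------------------------------------------------

def _encode_protein(residues: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, -1) for a in residues], dtype=np.int64)


def _score_matrix(pssm: ProteinPSSM, encoded: np.ndarray) -> np.ndarray:
    """(m, n) per-position scores; unknown residues (X) score 0."""
    m = pssm.length
    padded = np.concatenate([pssm.weights, np.zeros((m, 1))], axis=1)  # col -1 -> 0
    return padded[:, encoded]


def _diagonal_views(scores: np.ndarray) -> np.ndarray:
    """Stack all diagonals of the (m, n) score matrix into rows.

    Returns D of shape (m + n - 1, m) where D[d, i] is the cell (i, j) with
    j - i = d - (m - 1); cells off the matrix are -inf, so a maximal-segment
    recursion that resets on -inf never crosses them.
    """
    m, n = scores.shape
    D = np.full((m + n - 1, m), -np.inf)
    ii = np.repeat(np.arange(m), n)
    jj = np.tile(np.arange(n), m)
    D[jj - ii + m - 1, ii] = scores.ravel()
    return D


def _kadane_rows(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized maximal-subarray over each row; returns (best, end_index)."""
    nrow, ncol = D.shape
    run = np.zeros(nrow)
    best = np.full(nrow, -np.inf)
    end = np.zeros(nrow, dtype=np.int64)
    for t in range(ncol):
        col = D[:, t]
        valid = np.isfinite(col)
        run = np.where(valid, np.maximum(run, 0.0) + np.where(valid, col, 0.0), 0.0)
        improved = valid & (run > best)
        best[improved] = run[improved]
        end[improved] = t
    return best, end


def _segment_bounds(diag: np.ndarray, end: int) -> tuple[int, int, float]:
    """Recover the start of the maximal segment ending at ``end``."""
    total = 0.0
    best_total = -np.inf
    start = end
    for t in range(end, -1, -1):
        if not np.isfinite(diag[t]):
            break
        total += diag[t]
        if total >= best_total:
            best_total = total
            start = t
    return start, end, best_total


def best_ungapped_hits(
    pssm: ProteinPSSM,
    query: SequenceRecord,
    calibration: ScanCalibration,
    max_hits: int = 5,
    max_evalue: float = 10.0,
) -> list[ProfileHit]:
    """Best non-overlapping ungapped segments of the profile on the query.

    For every diagonal offset the maximal-scoring contiguous segment is
    located; segments are ranked by E-value and greedily retained while they
    do not overlap an already retained hit on the query; at most ``max_hits``
    hits with E <= ``max_evalue`` are reported, sorted ascending by E.
    """
    if query.moltype != "protein":
        raise ValueError("query must be a protein sequence")
    if len(query) < 1:
        raise ValueError("empty query")
    encoded = _encode_protein(query.residues)
    scores = _score_matrix(pssm, encoded)
    D = _diagonal_views(scores)
    best, end_idx = _kadane_rows(D)
    m, n = scores.shape
    order = np.argsort(-best)
    hits: list[ProfileHit] = []
    occupied: list[tuple[int, int]] = []
    for d in order:
        if len(hits) >= max_hits or not np.isfinite(best[d]):
            break
        evalue = calibration.evalue(best[d], m, n)
        if evalue > max_evalue:
            break
        # rows of D index the profile position i; the query column is
        # j = i + offset with offset = d - (m - 1)
        s, e, score = _segment_bounds(D[d], int(end_idx[d]))
        off = d - (m - 1)
        qb, qe = s + off + 1, e + off + 1
        if any(qb <= oe and ob <= qe for ob, oe in occupied):
            continue
        occupied.append((qb, qe))
        hits.append(
            ProfileHit(
                query_id=query.id,
                pssm_accession=pssm.accession,
                query_interval=(qb, qe),
                profile_interval=(s + 1, e + 1),
                score=float(score),
                evalue=float(evalue),
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.score))
    return hits


def best_score(pssm: ProteinPSSM, query: SequenceRecord) -> float:
    """Score of the single best ungapped segment (no E-value attached)."""
    encoded = _encode_protein(query.residues)
    D = _diagonal_views(_score_matrix(pssm, encoded))
    best, _ = _kadane_rows(D)
    return float(best.max())


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def analytic_lambda(pssm: ProteinPSSM, background: np.ndarray | None = None) -> float:
    """Karlin-Altschul lambda solving mean_i sum_a p_a exp(lambda s_ia) = 1."""
    if background is None:
        background = DEFAULT_AA_BACKGROUND
    w = pssm.weights

    def f(lam: float) -> float:
        return float(np.mean(np.sum(background * np.exp(lam * w), axis=1)) - 1.0)

    # f(0) = 0 trivially; the relevant root is the positive one, which exists
    # when the expected score is negative.
    lo, hi = 1e-8, 1e-4
    while f(hi) < 0:
        hi *= 2
        if hi > 1e3:
            raise ValueError("no positive lambda root: expected score non-negative?")
    return float(optimize.brentq(f, lo if f(lo) < 0 else 1e-12, hi))


def calibrate(
    pssm: ProteinPSSM,
    background: np.ndarray | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    sample_length: int = 300,
) -> ScanCalibration:
    """Fit (lambda, K) by Gumbel maximum likelihood on background sequences.

    ``n_samples`` i.i.d. background sequences of ``sample_length`` residues
    are scanned; the best segment scores are fitted with a Gumbel law of
    location mu and scale beta, giving lambda = 1/beta and
    K = exp(mu/beta) / (m * sample_length).
    """
    if n_samples < 500:
        raise ValueError("calibration requires n_samples >= 500")
    if background is None:
        background = DEFAULT_AA_BACKGROUND
    rng = np.random.default_rng(seed)
    m = pssm.length
    alphabet_idx = np.arange(20)
    padded = np.concatenate([pssm.weights, np.zeros((m, 1))], axis=1)
    scores = np.empty(n_samples)
    for k in range(n_samples):
        enc = rng.choice(alphabet_idx, size=sample_length, p=background)
        D = _diagonal_views(padded[:, enc])
        best, _ = _kadane_rows(D)
        scores[k] = best.max()
    if np.ptp(scores) < 1e-12:
        raise ValueError("degenerate score distribution: all best scores equal")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / (m * sample_length)
    return ScanCalibration(lam=lam, K=K, method="empirical", n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------------
# Reference-set construction: the 70% mutual-coverage redundancy rule
# ---------------------------------------------------------------------------

def mutual_coverage(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap of two 1-based inclusive intervals / length of the longer."""
    overlap = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    longer = max(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return overlap / longer


def deduplicate_profiles(
    hits_on_reference: list[ProfileHit], coverage_threshold: float = 0.70
) -> list[str]:
    """Greedy redundancy removal among profile hits on one reference.

    Hits are visited by ascending E-value (ties broken by accession); a hit
    is retained unless its query-interval overlap with an already retained
    hit exceeds ``coverage_threshold`` of the longer of the two intervals.
    Returns retained accessions in retention order.
    """
    if not hits_on_reference:
        return []
    ids = {h.query_id for h in hits_on_reference}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple reference sequences: {sorted(ids)}")
    retained: list[ProfileHit] = []
    for hit in sorted(hits_on_reference, key=lambda h: (h.evalue, h.pssm_accession)):
        if all(
            mutual_coverage(hit.query_interval, kept.query_interval) <= coverage_threshold
            for kept in retained
        ):
            retained.append(hit)
    return [h.pssm_accession for h in retained]


# ---------------------------------------------------------------------------
# Membership and validation
# ---------------------------------------------------------------------------

def assign_family(
    protein_hits: list[ProfileHit],
    family_set: FamilyReferenceSet,
    e_threshold: float = 1e-10,
) -> bool:
    """True iff every PSSM of the family set has a hit with E <= threshold."""
    best_by_pssm: dict[str, float] = {}
    for h in protein_hits:
        best_by_pssm[h.pssm_accession] = min(
            best_by_pssm.get(h.pssm_accession, math.inf), h.evalue
        )
    return all(
        best_by_pssm.get(p.accession, math.inf) <= e_threshold for p in family_set.pssms
    )


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_alignment_score(a: str, b: str) -> float:
    """Smith-Waterman score, BLOSUM62 with affine gaps 11/1."""
    return float(_local_aligner().score(a, b))


def validate_member(
    protein: SequenceRecord,
    reference: SequenceRecord,
    e_threshold: float = 1e-3,
) -> bool:
    """Low-stringency local-alignment validation against the family reference.

    E-values use the standard gapped BLOSUM62/11-1 Karlin-Altschul
    parameters; True iff E <= ``e_threshold``.
    """
    if protein.moltype != "protein" or reference.moltype != "protein":
        raise ValueError("validation requires protein sequences")
    score = local_alignment_score(protein.residues, reference.residues)
    evalue = (
        BLOSUM62_GAPPED_K
        * len(protein)
        * len(reference)
        * math.exp(-BLOSUM62_GAPPED_LAMBDA * score)
    )
    return evalue <= e_threshold


# ---------------------------------------------------------------------------
# Proteome-scale annotation
# ---------------------------------------------------------------------------

def annotate_proteome(
    proteome: list[SequenceRecord],
    family_sets: list[FamilyReferenceSet],
    calibrations: dict[str, ScanCalibration],
    e_threshold: float = 1e-10,
    validation_threshold: float = 1e-3,
) -> list[FamilyAnnotation]:
    """Annotate every protein against every family reference set.

    A protein is annotated for a family when the all-profiles-hit membership
    rule passes at ``e_threshold`` and the local-alignment validation against
    the family reference passes at ``validation_threshold``.
    """
    for fs in family_sets:
        for p in fs.pssms:
            if p.accession not in calibrations:
                raise ValueError(f"no calibration for PSSM {p.accession!r}")
    annotations: list[FamilyAnnotation] = []
    for protein in proteome:
        for fs in family_sets:
            hits: list[ProfileHit] = []
            for pssm in fs.pssms:
                hits.extend(
                    best_ungapped_hits(pssm, protein, calibrations[pssm.accession])
                )
            if not assign_family(hits, fs, e_threshold):
                continue
            validated = validate_member(protein, fs.reference_sequence, validation_threshold)
            if validated:
                annotations.append(
                    FamilyAnnotation(protein.id, fs.family, hits, validated=True)
                )
    return annotations


def annotations_to_tsv(annotations: list[FamilyAnnotation]) -> str:
    lines = ["protein_id\tfamily\tbest_evalue\tn_supporting_hits\tvalidated"]
    for a in annotations:
        best = min((h.evalue for h in a.supporting_hits), default=float("nan"))
        lines.append(
            f"{a.protein_id}\t{a.family}\t{best:.3g}\t{len(a.supporting_hits)}\t{a.validated}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Six-frame scan of intergenic regions
# ---------------------------------------------------------------------------

@dataclass
class SixFrameHit:
    """A profile hit on a translated intergenic span."""

    hit: ProfileHit
    frame: int                     # +1..+3 forward, -1..-3 reverse
    genomic_interval: tuple[int, int]  # 1-based inclusive on the genome


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def _translate(dna: str) -> str:
    aas = []
    for i in range(0, len(dna) - 2, 3):
        aas.append(_CODON_TABLE.get(dna[i:i + 3], "X"))
    return "".join(aas)


def intergenic_spans(genes: list[GeneModel], genome_length: int, min_length: int = 60):
    """Intergenic (left, right) 1-based spans of at least ``min_length`` bp."""
    intervals = sorted((g.left, g.right) for g in genes)
    merged: list[list[int]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    spans = []
    cursor = 1
    for lo, hi in merged + [[genome_length + 1, genome_length + 1]]:
        if lo - cursor >= min_length:
            spans.append((cursor, lo - 1))
        cursor = max(cursor, hi + 1)
    return spans


def scan_noncoding_sixframe(
    genome: SequenceRecord,
    genes: list[GeneModel],
    family_sets: list[FamilyReferenceSet],
    calibrations: dict[str, ScanCalibration],
    e_threshold: float = 1e-10,
    min_span: int = 60,
) -> list[SixFrameHit]:
    """Scan six-frame translations of intergenic spans with all family PSSMs.

    Reports every profile hit with E <= ``e_threshold``; a hit carries its
    reading frame (negative for the reverse strand) and genomic interval.
    """
    if genome.moltype != "dna":
        raise ValueError("genome must be DNA")
    results: list[SixFrameHit] = []
    pssms = [p for fs in family_sets for p in fs.pssms]
    for lo, hi in intergenic_spans(genes, len(genome), min_span):
        segment = genome.residues[lo - 1:hi]
        seglen = len(segment)
        rc = SequenceRecord("rc", "", segment, "dna").reverse_complement().residues
        for strand, seq in ((1, segment), (-1, rc)):
            for phase in range(3):
                aa = _translate(seq[phase:]).replace("*", "X")
                if len(aa) < 5:
                    continue
                rec = SequenceRecord(f"span_{lo}_{hi}", "", aa, "protein")
                for pssm in pssms:
                    for h in best_ungapped_hits(pssm, rec, calibrations[pssm.accession]):
                        if h.evalue > e_threshold:
                            continue
                        ab, ae = h.query_interval
                        if strand == 1:
                            gb = lo + phase + 3 * (ab - 1)
                            ge = lo + phase + 3 * ae - 1
                        else:
                            ge = hi - phase - 3 * (ab - 1)
                            gb = hi - phase - 3 * ae + 1
                        results.append(
                            SixFrameHit(h, strand * (phase + 1), (gb, ge))
                        )
    results.sort(key=lambda r: r.hit.evalue)
    return results
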