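"""Cis-regulatory motif scanning with exact p-values.

Upstream noncoding regions are scanned with transcription-factor PSSMs; each
window is scored as the log-likelihood ratio of the motif model over an
order-1 Markov background trained on the organism's upstream noncoding
sequences, and per-window p-values are computed exactly by dynamic
programming over (position, previous symbol, discretized score).

Hit coordinates follow the convention that position -1 is the base
immediately 5' of the start codon, so a hit interval reads e.g. [-96, -81].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DNA_ALPHABET, DNA_COMPLEMENT
from .io import GeneModel, MatrixFile, SequenceRecord

_NT_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}


@dataclass
class MarkovBackground:
    """Order-0 or order-1 nucleotide background model.

    ``initial`` is the marginal symbol distribution; ``transition[a, b]`` is
    P(b | a) for order 1 (ignored for order 0).
    """

    order: int
    initial: np.ndarray            # (4,)
    transition: np.ndarray | None  # (4, 4) or None for order 0
    trained_on: str = ""

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        self.initial = np.asarray(self.initial, dtype=float)
        if abs(self.initial.sum() - 1.0) > 1e-9 or (self.initial < 0).any():
            raise ValueError("initial probabilities must be >= 0 and sum to 1")
        if self.order == 1:
            self.transition = np.asarray(self.transition, dtype=float)
            if ((np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9).any()
                    or (self.transition < 0).any()):
                raise ValueError("transition rows must be >= 0 and sum to 1")

    def conditional(self, prev: int | None) -> np.ndarray:
        """P(b | prev); the initial distribution when there is no context."""
        if self.order == 0 or prev is None:
            return self.initial
        return self.transition[prev]


@dataclass
class DnaPSSM:
    """A DNA motif as per-position emission probabilities over ACGT."""

    name: str
    probs: np.ndarray  # (length, 4)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("DnaPSSM probs must have shape (L, 4)")
        if (self.probs <= 0).any():
            raise ValueError("DnaPSSM probabilities must be positive (apply a pseudocount)")
        self.probs = self.probs / self.probs.sum(axis=1, keepdims=True)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, matrix: MatrixFile, pseudocount: float = 1.0) -> "DnaPSSM":
        if matrix.alphabet != DNA_ALPHABET:
            raise ValueError("DnaPSSM requires an ACGT matrix")
        return cls(matrix.accession, matrix.counts + pseudocount)

    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[j] for j in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "DnaPSSM":
        return DnaPSSM(self.name, self.probs[::-1, ::-1])


@dataclass
class MotifHit:
    """A significant motif match, positioned relative to the gene start."""

    sequence_id: str
    tf_name: str
    strand: str               # "+" | "-"
    interval: tuple[int, int]  # negative upstream coordinates, begin <= end
    score: float
    pvalue: float

    def __post_init__(self) -> None:
        if not 0 < self.pvalue <= 1:
            raise ValueError("p-value must be in (0, 1]")

    def format_interval(self) -> str:
        return f"[{self.interval[0]}, {self.interval[1]}]"


@dataclass
class TranscriptionUnit:
    """A run of adjacent same-strand genes treated as one operon."""

    genes: list[GeneModel]  # ordered 5' -> 3' in transcription direction

    def __post_init__(self) -> None:
        strands = {g.strand for g in self.genes}
        if len(strands) != 1:
            raise ValueError("transcription unit mixes strands")

    @property
    def strand(self) -> str:
        return self.genes[0].strand

    @property
    def first_gene(self) -> GeneModel:
        return self.genes[0]


# ---------------------------------------------------------------------------
# Background training
# ---------------------------------------------------------------------------

def train_markov(
    sequences: list[SequenceRecord] | list[str],
    order: int = 1,
    pseudocount: float = 1.0,
) -> MarkovBackground:
    """Train the background model on a corpus of noncoding sequences.

    Transition counts are accumulated within each sequence (never across
    boundaries), Laplace-smoothed by ``pseudocount`` and normalized.
    """
    texts = [s.residues if isinstance(s, SequenceRecord) else s for s in sequences]
    texts = [t.upper() for t in texts if t]
    total = sum(len(t) for t in texts)
    if total == 0:
        raise ValueError("empty training corpus")
    if total < 16 * (order + 1):
        raise ValueError(f"corpus too small for order {order}: {total} symbols")
    mono = np.full(4, pseudocount, dtype=float)
    di = np.full((4, 4), pseudocount, dtype=float)
    for t in texts:
        enc = np.array([_NT_INDEX.get(c, -1) for c in t])
        valid = enc >= 0
        np.add.at(mono, enc[valid], 1.0)
        if order == 1 and len(enc) > 1:
            pairs_ok = valid[:-1] & valid[1:]
            np.add.at(di, (enc[:-1][pairs_ok], enc[1:][pairs_ok]), 1.0)
    initial = mono / mono.sum()
    transition = None
    if order == 1:
        row_sums = di.sum(axis=1, keepdims=True)
        # a context symbol never observed (possible with zero pseudocount)
        # gets a uniform row so the matrix stays stochastic
        safe = np.where(row_sums > 0, row_sums, 1.0)
        transition = np.where(row_sums > 0, di / safe, 0.25)
    return MarkovBackground(order, initial, transition,
                            trained_on=f"{len(texts)} sequences, {total} nt")


# ---------------------------------------------------------------------------
# Window scoring
# ---------------------------------------------------------------------------

def window_score(
    pssm: DnaPSSM,
    window: str,
    background: MarkovBackground,
    left_context: str | None = None,
) -> float:
    """Log-likelihood-ratio score of one window.

    score = sum_i [ln P_matrix(w_i | i) - ln P_bg(w_i | w_{i-1})]; the
    background's initial distribution is used when no left context exists.
    Unknown symbols (N) contribute 0.
    """
    window = window.upper()
    if len(window) != pssm.length:
        raise ValueError(f"window length {len(window)} != PSSM length {pssm.length}")
    prev = None
    if left_context:
        if left_context not in "ACGTN":
            raise ValueError(f"illegal context symbol {left_context!r}")
        prev = _NT_INDEX.get(left_context)
    score = 0.0
    for i, ch in enumerate(window):
        if ch == "N":
            prev = None
            continue
        if ch not in _NT_INDEX:
            raise ValueError(f"illegal symbol {ch!r} in window")
        b = _NT_INDEX[ch]
        score += np.log(pssm.probs[i, b]) - np.log(background.conditional(prev)[b])
        prev = b
    return float(score)


# ---------------------------------------------------------------------------
# Exact p-values
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Exact null distribution of window scores, discretized in score bins.

    ``tail[k]`` is P(S >= (min_bin + k) * bin_width) under the background
    model; p-values are reported at the lower edge of the bin containing the
    observed score (conservative).
    """

    bin_width: float
    min_bin: int
    tail: np.ndarray

    def pvalue(self, score: float) -> float:
        k = int(np.floor(score / self.bin_width + 1e-9)) - self.min_bin
        if k < 0:
            return 1.0
        # bins beyond the best reachable outcome have zero mass; a window
        # can still land there through rounding drift, so clamp to the
        # smallest positive tail probability
        floor = float(self.tail[self.tail > 0].min())
        if k >= len(self.tail):
            return floor
        return max(float(self.tail[k]), floor)


def exact_pvalue_table(
    pssm: DnaPSSM,
    background: MarkovBackground,
    bin_width: float = 0.01,
) -> ScoreDistribution:
    """Exact right-tail score distribution by dynamic programming.

    States are (position, previous symbol, discretized score); the first
    window symbol is drawn from (and scored against) the background's
    initial distribution. Total probability mass is conserved to 1e-9.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    L = pssm.length
    # integer bin of the weight for emitting symbol b at position i given prev a
    logp = np.log(pssm.probs)

    def bins(i: int, prev: int | None) -> np.ndarray:
        cond = np.log(background.conditional(prev))
        return np.round((logp[i] - cond) / bin_width).astype(np.int64)

    w_first = bins(0, None)  # (4,)
    w_next = np.empty((max(L - 1, 0), 4, 4), dtype=np.int64)  # (pos-1, prev, emitted)
    for i in range(1, L):
        for a in range(4):
            w_next[i - 1, a] = bins(i, a if background.order == 1 else None)

    lo = int(w_first.min()) + int(w_next.min(axis=(1, 2)).sum()) if L > 1 else int(w_first.min())
    hi = int(w_first.max()) + int(w_next.max(axis=(1, 2)).sum()) if L > 1 else int(w_first.max())
    width = hi - lo + 1

    # dist[a, k]: probability that the window so far ends in symbol a with
    # cumulative score bin (k + lo)
    dist = np.zeros((4, width))
    for b in range(4):
        dist[b, int(w_first[b]) - lo] += background.initial[b]
    for i in range(1, L):
        new = np.zeros((4, width))
        for a in range(4):
            row = dist[a]
            if not row.any():
                continue
            trans = background.conditional(a)
            for b in range(4):
                shift = int(w_next[i - 1, a, b])
                seg = row * trans[b]
                if shift >= 0:
                    new[b, shift:] += seg[:width - shift] if shift else seg
                else:
                    new[b, :shift] += seg[-shift:]
        dist = new
    pooled = dist.sum(axis=0)
    if abs(pooled.sum() - 1.0) > 1e-9:
        raise AssertionError(f"probability mass {pooled.sum()} != 1")
    tail = pooled[::-1].cumsum()[::-1]
    return ScoreDistribution(bin_width=bin_width, min_bin=lo, tail=tail)


# ---------------------------------------------------------------------------
# Region scanning
# ---------------------------------------------------------------------------

@dataclass
class UpstreamRegion:
    """Noncoding sequence 5' of a gene, oriented toward the start codon."""

    gene_id: str
    sequence: str  # 5'->3' in the gene's reading direction; last base = -1

    def __len__(self) -> int:
        return len(self.sequence)


def _window_scores_vectorized(
    pssm: DnaPSSM, sequence: str, background: MarkovBackground
) -> np.ndarray:
    """Scores of all windows of a sequence (N columns contribute 0)."""
    L = pssm.length
    n = len(sequence)
    if n < L:
        return np.empty(0)
    enc = np.array([_NT_INDEX.get(c, -1) for c in sequence.upper()])
    nwin = n - L + 1
    scores = np.zeros(nwin)
    loginit = np.log(background.initial)
    logp = np.log(pssm.probs)
    logtrans = np.log(background.transition) if background.order == 1 else None
    offsets = np.arange(nwin)
    for i in range(L):
        pos = offsets + i
        sym = enc[pos]
        ok = sym >= 0
        symc = np.where(ok, sym, 0)
        term = logp[i, symc]
        if logtrans is not None:
            prev = np.where(pos >= 1, enc[np.maximum(pos - 1, 0)], -1)
            has_ctx = prev >= 0
            prevc = np.where(has_ctx, prev, 0)
            bg = np.where(has_ctx, logtrans[prevc, symc], loginit[symc])
        else:
            bg = loginit[symc]
        scores += np.where(ok, term - bg, 0.0)
    return scores


def scan_upstream(
    pssm: DnaPSSM,
    region: UpstreamRegion,
    background: MarkovBackground,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    table: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan a region on one or both strands, reporting hits with p <= threshold.

    Coordinates are reported relative to the gene start: the base immediately
    5' of the start codon is position -1, so a hit occupying the 16 bases
    ending 81 bp upstream reads [-96, -81].
    """
    if table is None:
        table = exact_pvalue_table(pssm, background)
    L, R = pssm.length, len(region)
    if R < L:
        return []
    hits: list[MotifHit] = []
    seq = region.sequence.upper()
    # the reverse strand is scanned as the forward scan of the reverse
    # complement, so strand symmetry holds by construction
    strands = [("+", seq)] + ([("-", _revcomp(seq))] if both_strands else [])
    for strand, s_seq in strands:
        scores = _window_scores_vectorized(pssm, s_seq, background)
        for j, s in enumerate(scores):
            pv = table.pvalue(float(s))
            if pv <= p_threshold:
                jf = j if strand == "+" else R - L - j  # forward 0-based start
                begin = -(R - jf)
                hits.append(MotifHit(region.gene_id, pssm.name, strand,
                                     (begin, begin + L - 1), float(s), pv))
    hits.sort(key=lambda h: (h.interval[0], h.strand))
    return hits


def hits_to_tsv(hits: list[MotifHit]) -> str:
    lines = ["sequence_id\ttf_name\tstrand\tinterval\tbegin\tend\tscore\tpvalue"]
    for h in hits:
        lines.append(
            f"{h.sequence_id}\t{h.tf_name}\t{h.strand}\t{h.format_interval()}"
            f"\t{h.interval[0]}\t{h.interval[1]}\t{h.score:.3f}\t{h.pvalue:.2e}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Upstream extraction and transcription units
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return "".join(DNA_COMPLEMENT[c] for c in reversed(seq.upper()))


def extract_upstream(
    genes: list[GeneModel],
    target: str | TranscriptionUnit,
    genome: SequenceRecord,
) -> UpstreamRegion:
    """Noncoding span between a gene's 5' end and the nearest feature.

    For a transcription unit the upstream region of its first gene is taken.
    Reverse-strand targets are extracted 3' of the numeric end and
    reverse-complemented, so the returned sequence always reads 5'->3'
    toward the start codon. A target at the contig edge yields a truncated
    region with a warning.
    """
    if isinstance(target, TranscriptionUnit):
        gene = target.first_gene
    else:
        matches = [g for g in genes if g.locus_tag == target]
        if not matches:
            raise KeyError(f"locus_tag {target!r} not found")
        gene = matches[0]
    bounds = sorted((g.left, g.right) for g in genes if g.locus_tag != gene.locus_tag)
    if gene.strand == "D":
        upstream_limit = max((r for l, r in bounds if r < gene.left), default=None)
        lo = (upstream_limit + 1) if upstream_limit is not None else 1
        hi = gene.left - 1
        if upstream_limit is None and lo <= hi:
            warnings.warn(f"{gene.locus_tag}: upstream region truncated at contig edge")
        seq = genome.residues[lo - 1:hi] if hi >= lo else ""
    else:
        downstream_limit = min((l for l, r in bounds if l > gene.right), default=None)
        lo = gene.right + 1
        hi = (downstream_limit - 1) if downstream_limit is not None else len(genome)
        if downstream_limit is None and lo <= hi:
            warnings.warn(f"{gene.locus_tag}: upstream region truncated at contig edge")
        seq = _revcomp(genome.residues[lo - 1:hi]) if hi >= lo else ""
    return UpstreamRegion(gene.locus_tag, seq)


def predict_transcription_units(
    genes: list[GeneModel], max_gap: int = 150
) -> list[TranscriptionUnit]:
    """Distance/strand operon heuristic.

    Consecutive same-strand genes whose intergenic gap is <= ``max_gap`` bp
    (inclusive) are merged into one unit; gene order within a unit follows
    the transcription direction.
    """
    ordered = sorted(genes, key=lambda g: g.left)
    units: list[list[GeneModel]] = []
    for g in ordered:
        if units:
            prev = units[-1][-1]
            gap = g.left - prev.right - 1
            if g.strand == prev.strand and gap <= max_gap:
                units[-1].append(g)
                continue
        units.append([g])
    result = []
    for unit in units:
        if unit[0].strand == "R":
            unit = unit[::-1]  # transcription runs right to left
        result.append(TranscriptionUnit(unit))
    return result
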