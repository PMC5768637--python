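"""Seeded generators for every data regime the pipeline consumes.

Each generator is a pure function of its config (including the seed): a
master seed expands into independent substreams so adding one generator
never perturbs another. Every planted signal is recorded in a truth table.

The defaults emulate the study conditions: a proteome of background decoys
carrying one PhoD-like and four PhoX-like implanted domains; AT-rich
upstream regions over an order-1 Markov chain with implanted transcription-
factor motifs; a coarse helical toy protein with a phosphate ligand and a
metal ion defining the active site; absorbance time series with a linear
initial phase; and a genome collection whose per-family gene counts follow
size-proportional Poisson rates chosen to mirror the prevalence of alkaline
and acid phosphatase families across bacterial genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PROTEIN_ALPHABET
from .geochem import AssayConfig, KineticsSeries
from .io import SequenceRecord
from .motifs import DnaPSSM, MarkovBackground
from .profiles import DEFAULT_AA_BACKGROUND, FamilyReferenceSet, counts_to_logodds
from .structure import Atom, Structure

_STREAMS = {"proteome": 1, "promoters": 2, "structure": 3, "kinetics": 4, "survey": 5}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible random stream for one generator."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],)))


# ---------------------------------------------------------------------------
# Proteome with implanted family domains
# ---------------------------------------------------------------------------

@dataclass
class ProteomeConfig:
    seed: int = 0
    n_decoys: int = 200
    decoy_length_mean: float = 300.0
    decoy_length_sd: float = 60.0
    #: (family name, number of implanted proteins); the default mirrors a
    #: repertoire of one PhoD-like and four PhoX-like phosphatases.
    implants: tuple[tuple[str, int], ...] = (("PhoD", 1), ("PhoX", 4))
    #: expected total ungapped score of one implanted domain against its
    #: family profile, in half-bits; chosen to match the information content
    #: of a real conserved-domain hit. 0 turns implants into background.
    signal_strength: float = 280.0
    profile_length: int = 110


@dataclass
class SyntheticProteome:
    records: list[SequenceRecord]
    truth: pd.DataFrame               # protein_id, family, begin, end
    family_sets: list[FamilyReferenceSet]


def _column_probs(rng: np.random.Generator, length: int, per_column_halfbits: float,
                  nsites: int = 100) -> np.ndarray:
    """Column emission probabilities hitting a target expected score.

    Each column interpolates between the background and a point mass on a
    randomly chosen dominant residue; the mixing weight is solved by
    bisection so the expected half-bit score per column (under the weights
    implied by the column counts) equals the target.
    """
    bg = DEFAULT_AA_BACKGROUND
    cols = np.empty((length, 20))
    dominants = rng.integers(0, 20, size=length)
    for i, dom in enumerate(dominants):
        point = np.zeros(20)
        point[dom] = 1.0

        def expected(alpha: float) -> float:
            p = bg + alpha * (point - bg)
            counts = p[None, :] * nsites
            w = counts_to_logodds(counts, bg, pseudocount=1.0).weights[0]
            return float((p * w).sum())

        if per_column_halfbits <= 0:
            cols[i] = bg
            continue
        lo, hi = 0.0, 1.0 - 1e-9
        if expected(hi) <= per_column_halfbits:
            cols[i] = bg + hi * (point - bg)
            continue
        for _ in range(50):
            mid = (lo + hi) / 2
            if expected(mid) < per_column_halfbits:
                lo = mid
            else:
                hi = mid
        cols[i] = bg + 0.5 * (lo + hi) * (point - bg)
    return cols


def _sample_from_probs(rng: np.random.Generator, probs: np.ndarray) -> str:
    picks = [rng.choice(20, p=row / row.sum()) for row in probs]
    return "".join(PROTEIN_ALPHABET[j] for j in picks)


def _background_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=DEFAULT_AA_BACKGROUND)
    return "".join(PROTEIN_ALPHABET[i] for i in idx)


def _make_family(rng: np.random.Generator, family: str, config: ProteomeConfig):
    """One synthetic family: emission columns, PSSM set and reference."""
    L = config.profile_length
    per_col = config.signal_strength / L
    probs = _column_probs(rng, L, per_col)
    counts = probs * 100
    full = counts_to_logodds(counts, pseudocount=1.0, accession=f"syn_{family}_full")
    pssms = [full]
    if family == "PhoD":
        # a second, partially overlapping profile, like a sub-domain model;
        # its hit covers < 70% of the full-profile hit so both are retained
        sub = counts_to_logodds(counts[19:60], pseudocount=1.0, accession=f"syn_{family}_sub")
        pssms.append(sub)
    consensus = full.consensus()
    flank = 30
    reference = SequenceRecord(
        f"ref_{family}", f"synthetic {family} family reference",
        _background_protein(rng, flank) + consensus + _background_protein(rng, flank),
        "protein",
    )
    return probs, FamilyReferenceSet(family, reference, pssms)


def gen_proteome(config: ProteomeConfig | None = None) -> SyntheticProteome:
    """Decoy proteome with implanted family-specific domains.

    Decoys are i.i.d. draws from the background amino-acid frequencies;
    each implant is sampled from its family profile's emission columns and
    embedded at a random interior position of a background host. The truth
    table lists every implanted protein exactly once.
    """
    config = config or ProteomeConfig()
    rng = substream(config.seed, "proteome")
    family_probs: dict[str, np.ndarray] = {}
    family_sets: list[FamilyReferenceSet] = []
    for family, _ in config.implants:
        probs, fs = _make_family(rng, family, config)
        family_probs[family] = probs
        family_sets.append(fs)

    sequences: list[tuple[str, str, int, int]] = []  # residues, family, begin, end
    for _ in range(config.n_decoys):
        length = max(60, int(rng.normal(config.decoy_length_mean, config.decoy_length_sd)))
        sequences.append((_background_protein(rng, length), "", 0, 0))
    if config.profile_length > config.decoy_length_mean:
        raise ValueError("implant longer than host protein length regime")
    for family, n_copies in config.implants:
        for _ in range(n_copies):
            host_len = max(60, int(rng.normal(config.decoy_length_mean, config.decoy_length_sd)))
            domain = _sample_from_probs(rng, family_probs[family])
            host_len = max(host_len, len(domain))
            pos = int(rng.integers(0, host_len - len(domain) + 1))
            host = _background_protein(rng, host_len)
            residues = host[:pos] + domain + host[pos + len(domain):]
            sequences.append((residues, family, pos + 1, pos + len(domain)))

    order = rng.permutation(len(sequences))
    records, truth_rows = [], []
    for new_idx, old_idx in enumerate(order):
        residues, family, begin, end = sequences[old_idx]
        pid = f"prot_{new_idx + 1:04d}"
        records.append(SequenceRecord(pid, "", residues, "protein"))
        if family:
            truth_rows.append({"protein_id": pid, "family": family,
                               "begin": begin, "end": end})
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "family", "begin", "end"])
    return SyntheticProteome(records, truth, family_sets)


# ---------------------------------------------------------------------------
# Promoters with implanted TF motifs
# ---------------------------------------------------------------------------

def at_rich_background(at_fraction: float = 0.7, persistence: float = 0.1) -> MarkovBackground:
    """Order-1 chain with the AT-rich composition of regulatory regions.

    ``persistence`` adds a same-symbol excess to the transition rows,
    giving mild oligonucleotide structure beyond the marginal composition.
    """
    pa = at_fraction / 2
    pc = (1.0 - at_fraction) / 2
    initial = np.array([pa, pc, pc, pa])
    transition = np.tile(initial, (4, 1)) * (1 - persistence) + persistence * np.eye(4)
    transition /= transition.sum(axis=1, keepdims=True)
    return MarkovBackground(1, initial, transition, trained_on="synthetic AT-rich chain")


def phob_like_matrix(strength: float = 0.85) -> DnaPSSM:
    """A strong 16-bp direct-repeat motif, pho-box-like."""
    consensus = "CTGTCATAAAACTGTC"
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.full((len(consensus), 4), (1 - strength) / 3)
    for i, b in enumerate(consensus):
        probs[i, idx[b]] = strength
    return DnaPSSM("PhoB_like", probs)


@dataclass
class PromoterConfig:
    seed: int = 0
    n_regions: int = 100
    region_length: int = 400
    background: MarkovBackground = field(default_factory=at_rich_background)
    #: (matrix, start position relative to gene start, strand)
    implants: tuple[tuple[DnaPSSM, int, str], ...] = (
        (phob_like_matrix(), -96, "+"),
    )


@dataclass
class SyntheticPromoters:
    records: list[SequenceRecord]
    truth: pd.DataFrame  # region_id, tf, begin, end, strand
    background: MarkovBackground


def _markov_sequence(rng: np.random.Generator, bg: MarkovBackground, length: int) -> np.ndarray:
    seq = np.empty(length, dtype=np.int64)
    seq[0] = rng.choice(4, p=bg.initial)
    if bg.order == 0:
        seq[1:] = rng.choice(4, size=length - 1, p=bg.initial)
    else:
        for i in range(1, length):
            seq[i] = rng.choice(4, p=bg.transition[seq[i - 1]])
    return seq


def gen_promoters(config: PromoterConfig | None = None) -> SyntheticPromoters:
    """Upstream regions from the background chain with implanted motifs.

    Implant positions use the upstream convention (position -1 is the base
    immediately 5' of the start codon); overlapping implants are an error.
    """
    config = config or PromoterConfig()
    rng = substream(config.seed, "promoters")
    R = config.region_length
    intervals = []
    for pssm, begin, strand in config.implants:
        j = R + begin  # 0-based start within the region
        if j < 0 or j + pssm.length > R:
            raise ValueError(f"implant at {begin} does not fit a {R} nt region")
        intervals.append((j, j + pssm.length - 1, pssm, strand, begin))
    intervals.sort()
    for (a, b, *_), (c, d, *_) in zip(intervals, intervals[1:]):
        if c <= b:
            raise ValueError("overlapping implants")

    alphabet = np.array(list("ACGT"))
    records, truth_rows = [], []
    for r in range(config.n_regions):
        seq = _markov_sequence(rng, config.background, R)
        for j, _, pssm, strand, begin in intervals:
            probs = pssm.probs if strand == "+" else pssm.reverse_complement().probs
            inst = np.array([rng.choice(4, p=row) for row in probs])
            seq[j:j + pssm.length] = inst
            truth_rows.append({
                "region_id": f"region_{r + 1:03d}", "tf": pssm.name,
                "begin": begin, "end": begin + pssm.length - 1, "strand": strand,
            })
        records.append(SequenceRecord(
            f"region_{r + 1:03d}", "", "".join(alphabet[seq]), "dna"
        ))
    truth = pd.DataFrame(truth_rows, columns=["region_id", "tf", "begin", "end", "strand"])
    return SyntheticPromoters(records, truth, config.background)


# ---------------------------------------------------------------------------
# Toy structure with a phosphate ligand
# ---------------------------------------------------------------------------

@dataclass
class StructureConfig:
    seed: int = 0
    n_residues: int = 60
    site_residues: tuple[int, ...] = (5, 12, 40)  # 1-based residue numbers
    ligand_distance: float = 3.0                  # A from ligand P to site CA
    include_ion: bool = True
    nonsite_margin: float = 6.5                   # min distance of other CAs to the ligand


@dataclass
class SyntheticStructure:
    structure: Structure
    truth_site: tuple[int, ...]


def gen_toy_structure(config: StructureConfig | None = None) -> SyntheticStructure:
    """Coarse helical CA trace with a phosphate (P + 4 O) near chosen residues.

    Site residues are moved onto a sphere of radius ``ligand_distance``
    around the ligand phosphorus; all other residues are pushed outside
    ``nonsite_margin``. Atom clashes closer than 1 A are an error.
    """
    config = config or StructureConfig()
    if not set(config.site_residues) <= set(range(1, config.n_residues + 1)):
        raise ValueError("site residues outside the residue range")
    rng = substream(config.seed, "structure")
    n = config.n_residues
    # coarse alpha-helix CA path
    turn = np.deg2rad(100.0)
    coords = np.column_stack([
        2.3 * np.cos(turn * np.arange(n)),
        2.3 * np.sin(turn * np.arange(n)),
        1.5 * np.arange(n),
    ])
    ligand_center = np.array([12.0, 0.0, 1.5 * n / 2])
    # spread site CAs on the ligand sphere, away from each other
    site = sorted(config.site_residues)
    for k, resnum in enumerate(site):
        theta = 2 * np.pi * k / max(len(site), 1) + rng.uniform(0, 0.3)
        direction = np.array([np.cos(theta), np.sin(theta), 0.35 * (k - len(site) / 2)])
        direction /= np.linalg.norm(direction)
        coords[resnum - 1] = ligand_center + config.ligand_distance * direction
    # push any other residue out of the detection margin
    for i in range(n):
        if (i + 1) in site:
            continue
        delta = coords[i] - ligand_center
        dist = np.linalg.norm(delta)
        if dist < config.nonsite_margin:
            coords[i] = ligand_center + delta / dist * config.nonsite_margin

    atoms = [
        Atom(i + 1, "CA", "C", "GLY", i + 1, "A", *coords[i], is_hetero=False)
        for i in range(n)
    ]
    serial = n + 1
    atoms.append(Atom(serial, "P", "P", "PO4", n + 1, "A", *ligand_center, is_hetero=True))
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    for k, d in enumerate(tet):
        serial += 1
        atoms.append(Atom(serial, f"O{k + 1}", "O", "PO4", n + 1, "A",
                          *(ligand_center + 1.5 * d), is_hetero=True))
    if config.include_ion:
        serial += 1
        atoms.append(Atom(serial, "CA", "CA", "CA", n + 2, "A",
                          *(ligand_center + np.array([0.0, 0.0, 1.8])), is_hetero=True))
    xyz = np.array([[a.x, a.y, a.z] for a in atoms])
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    if (d2 < 1.0).any():
        raise ValueError("atom clash closer than 1 A in generated structure")
    return SyntheticStructure(Structure(atoms, name="toy_phosphatase"),
                              tuple(site))


# ---------------------------------------------------------------------------
# Kinetics series
# ---------------------------------------------------------------------------

@dataclass
class KineticsConfig:
    seed: int = 0
    slope_pmol_s: float = 1.7
    noise_rel: float = 0.02          # Gaussian sd relative to the final signal
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 310, 15))
    t_sat: float | None = None       # plateau onset, seconds
    assay: AssayConfig = field(default_factory=AssayConfig)
    series_kind: str = "absorbance"


def gen_kinetics(config: KineticsConfig | None = None) -> KineticsSeries:
    """Linear (optionally saturating) release curve with Gaussian noise."""
    config = config or KineticsConfig()
    rng = substream(config.seed, "kinetics")
    t = np.asarray(config.times, dtype=float)
    slope_m_per_s = config.slope_pmol_s * 1e-12 / config.assay.reaction_volume
    eff_t = np.minimum(t, config.t_sat) if config.t_sat is not None else t
    conc = slope_m_per_s * eff_t
    scale = conc.max() if conc.max() > 0 else 1.0
    conc = conc + rng.normal(0.0, config.noise_rel * scale, size=len(t))
    conc = np.clip(conc, 0.0, None)
    if config.series_kind == "absorbance":
        values = conc * config.assay.epsilon * config.assay.path_length
    else:
        values = conc
    return KineticsSeries(t, values, config.series_kind)


# ---------------------------------------------------------------------------
# Genome survey tables
# ---------------------------------------------------------------------------

#: Per-Mb Poisson rates chosen so that, at a typical 4 Mb genome, the
#: fraction of genomes carrying each family matches the prevalence observed
#: across complete bacterial genomes (about 62% with >= 1 alkaline
#: phosphatase, 35% PhoA, 22% PhoX, 17% PhoD, smaller acid-family shares).
DEFAULT_FAMILY_RATES_PER_MB = {
    "PhoA": 0.1065, "PhoK": 0.0128, "AcpA": 0.0209, "PhoD": 0.0466,
    "PhoX": 0.0620, "PhoN": 0.0406, "AphA": 0.0320, "NSAPc": 0.0155,
}


@dataclass
class SurveyConfig:
    seed: int = 0
    n_genomes: int = 500
    n_phyla: int = 33
    size_log_mean: float = float(np.log(4e6))
    size_log_sd: float = 0.35
    genes_per_bp: float = 9e-4
    gene_count_noise_rel: float = 0.05
    family_rates_per_mb: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_RATES_PER_MB))
    include_focal: bool = False  # append a 1 PhoD + 4 PhoX focal genome


def gen_survey(config: SurveyConfig | None = None) -> pd.DataFrame:
    """Synthetic genome survey with a linear size-count relation.

    Genome sizes are lognormal; the total gene count is linear in size with
    multiplicative Gaussian noise; per-family phosphatase counts are Poisson
    with size-proportional rates. Phylum labels are assigned round-robin.
    """
    config = config or SurveyConfig()
    if config.n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    rng = substream(config.seed, "survey")
    sizes = rng.lognormal(config.size_log_mean, config.size_log_sd, config.n_genomes)
    sizes = np.maximum(sizes, 5e5).round().astype(np.int64)
    if config.gene_count_noise_rel > 0:
        noise = rng.normal(1.0, config.gene_count_noise_rel, config.n_genomes)
        total_genes = np.maximum(1, np.rint(config.genes_per_bp * sizes * noise)).astype(np.int64)
    else:
        total_genes = np.rint(config.genes_per_bp * sizes).astype(np.int64)
    rows = {
        "genome_id": [f"genome_{i + 1:04d}" for i in range(config.n_genomes)],
        "phylum": [f"Phylum_{i % config.n_phyla + 1:02d}" for i in range(config.n_genomes)],
        "genome_length": sizes,
        "total_genes": total_genes,
    }
    table = pd.DataFrame(rows)
    for family, rate in config.family_rates_per_mb.items():
        table[family] = rng.poisson(rate * sizes / 1e6)
    if config.include_focal:
        focal = {
            "genome_id": "Rta_like", "phylum": "Proteobacteria",
            "genome_length": 4_070_194,
            "total_genes": int(round(config.genes_per_bp * 4_070_194)),
            **{f: 0 for f in config.family_rates_per_mb},
        }
        focal["PhoD"], focal["PhoX"] = 1, 4
        table = pd.concat([table, pd.DataFrame([focal])], ignore_index=True)
    cols = ["genome_id", "phylum", "genome_length",
            "PhoA", "PhoK", "AcpA", "PhoD", "PhoX", "PhoN", "AphA", "NSAPc",
            "total_genes"]
    return table[cols]
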