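# Methods

This note documents the models, conventions and numerical choices behind
`phorep`, and what the synthetic benchmarks do and do not demonstrate.

## Data model and coordinate conventions

Gene coordinates are 1-based inclusive. Reverse-strand ("R") rows may list
start > end, as annotation tables commonly do; they are normalized
internally to (left, right, strand). The encoded protein length is
(span)/3 − 1, i.e. the stop codon is excluded — this is the convention
that makes coordinate-derived lengths match published precursor lengths.
Unknown residues (X for protein, N for DNA) are accepted everywhere and
score 0 in every scoring operation, the background-expected value.

Motif-hit coordinates are relative to the gene start: position −1 is the
base immediately 5′ of the start codon, so a 16-bp hit ending 81 bp
upstream is written [−96, −81].

## Profile annotation

**Scanning.** RPS-Blast-style profile search is re-implemented as ungapped
maximal-scoring profile–sequence segments: for every diagonal offset the
best contiguous segment is found with the Kadane recursion (vectorized
across diagonals), which is exact — it equals exhaustive enumeration over
all (offset, segment) pairs. Gapped profile extension is deliberately out
of scope; the membership rule only consumes E-value threshold decisions,
which are robust to this simplification for genuine domain-length hits.
An adapter for external RPS-Blast tabular output can feed the same
decision logic when real CDD matrices are used.

**E-values.** E = K·m·n·e^(−λS) with per-comparison search space m·n
(profile length × query length), no database-size correction. (λ, K) are
fitted per PSSM by Gumbel maximum likelihood on the best-segment scores of
1000 i.i.d. background sequences of 300 residues (Robinson–Robinson
frequencies), giving λ = 1/β and K = e^(μ/β)/(m·n₀). For true log-odds
weights in half-bits the analytic λ is ln 2 / 2 ≈ 0.347 per half-bit; the
empirical fits land within a few percent of it, and a test enforces
agreement within 10%. A degenerate score distribution (e.g. an all-zero
PSSM) is an error, not a silent fit.

**Redundancy rule.** Profiles hitting the family reference with mutual
coverage > 70% of the longer hit are collapsed, keeping the lowest
E-value. The greedy pass runs in ascending E-value with ties broken by
accession, which makes the outcome deterministic for more than two
mutually overlapping profiles (behavior the rule alone does not define).
The result is idempotent and no retained pair violates the rule.

**Membership and validation.** A protein joins a family iff every PSSM of
the family set hits it at E ≤ 10⁻¹⁰; the same threshold is used during
reference-set construction (no separate value is defined). Validation is
Smith–Waterman (BLOSUM62, affine gaps 11/1, via Biopython's
PairwiseAligner) with the standard NCBI gapped Karlin–Altschul constants
λ = 0.267, K = 0.041, at E ≤ 10⁻³.

**Six-frame intergenic scan.** A tblastn-style search for missed genes is
replaced by translating all six frames of intergenic spans ≥ 60 bp and
running the same profile scan; hits report frame and genomic interval.

## Motif scanning

The background is an order-0 or order-1 Markov model trained on upstream
noncoding sequences (counts never pooled across sequence boundaries,
Laplace pseudocount 1; a context symbol unseen with a zero pseudocount
falls back to a uniform row). Window scores are
Σᵢ [ln P_matrix(wᵢ|i) − ln P_bg(wᵢ|wᵢ₋₁)], with the initial distribution
used where no left context exists. RegulonDB-style count matrices get a
pseudocount of 1 when converted to probabilities.

P-values are exact under the background model: a dynamic program over
(position, previous symbol, discretized score) with bin width 0.01 yields
the full right-tail distribution; it equals brute-force enumeration over
all 4^L windows to machine precision at the shared discretization.
P-values are reported at the lower bin edge (conservative), and scores
landing above the best reachable bin (possible through rounding drift
between continuous window scores and binned weights) are clamped to the
smallest positive tail mass. Both strands are scanned by default — the
reverse strand as the forward scan of the reverse complement, which makes
strand symmetry exact by construction — and single-strand scanning is a
flag. No multiple-testing correction is applied, matching the raw 10⁻⁴
threshold whose meaning ("one false positive per 10 kb") the null
calibration test verifies directly.

Operons are predicted with a distance/strand heuristic: consecutive
same-strand genes with intergenic gap ≤ 150 bp (inclusive) merge into one
transcription unit. This replaces a database-backed operon method; only
the choice of upstream region depends on the call.

## Protein features

Molecular weight sums average residue masses plus one water (ProtParam's
table); X has no defined mass and is an error. The pI is the unique root
of the Henderson–Hasselbalch net-charge function over the termini and
D, E, C, Y, H, K, R, found by bisection; the default pKa set is
Bjellqvist's (with residue-specific N-terminal values), the EMBOSS set is
selectable. Values are conventionally reported to one decimal (half-up).
Tat export signals are a documented heuristic — the consensus
[ST]-R-R-x-[FGAVML]-[LITMVF] within the first 45 residues, falling back
to a bare RR flagged low-confidence; published signal-peptide lengths are
consumed as annotations, not re-predicted.

## Structure analysis

Active-site residues have ≥ 1 heavy atom within 4.0 Å of any atom of the
phosphate ligand or a metal co-factor (Ca, Mg, Fe, Zn, Mn), excluding the
ligand residues and waters. The 4.0 Å default stands in for unstated
contact-program parameters and is calibrated so reference structures
yield their known 10-residue sites; it is a parameter, not a constant.

SASA is Shrake–Rupley with a 1.4 Å probe, 960 quasi-uniform test points
(golden spiral) and Bondi van der Waals radii; hydrogens are ignored.
Each atom's point grid is expressed in a local frame built from its two
nearest neighbors, so the grid co-rotates with the structure and the
total SASA is rigid-motion invariant to well below 0.1% — a shared global
grid drifts by ~0.15% under rotation at this point count. Accessibility
(the sum of per-residue SASA over site residues) is computed after
removing ligand, co-factors and any signal peptide. Published
accessibility values from other SASA engines are reproducible only to
~10% in absolute terms; orderings are the robust comparison.

Superposition is the Kabsch algorithm (SVD with determinant correction,
proper rotations only); fewer than 3 pairs or collinear points are
errors. A per-residue formal-charge summary near the site is provided as
a simple stand-in for electrostatic surface maps, which are out of scope.

## Geochemistry

Speciation is a documented simplification of a full geochemical code:
phosphate protonation from pKa 2.148 / 7.199 / 12.35 (25 °C), OH⁻ from
Kw = 10⁻¹⁴, single-ion activity coefficients from the Davies equation
(A = 0.509), ionic strength by fixed-point iteration to |ΔI| < 10⁻⁸
(converges from any start in practice; a contraction test checks this).
Ca-phosphate ion pairs (CaHPO₄⁰, CaPO₄⁻) and carbonate equilibria are
neglected: this biases SI upward by ≲ 1 log unit at assay conditions,
which does not affect the ≥ 10 precipitation criterion. SI is undefined
(None) when total Ca or total Pi is at or below its detection limit
(defaults 50 µM and 0.85 µM, the instrumental errors of the assay
measurements). The ideal-solution SI (γ = 1) is an upper bound on the
Davies-corrected value and serves as the hand-computable cross-check
(15.4 for 10 mM Ca, 267 µM Pi, pH 7.5).

Hydrolysis rates: absorbance converts by Beer–Lambert
(ε = 18,000 M⁻¹cm⁻¹, 1 cm path); the rate is the OLS slope of
concentration vs time over the longest prefix (≥ 4 points) with R² ≥ 0.98
— the initial linear phase — times the reaction volume, in pmol s⁻¹. On a
saturating curve this window rule can retain a point or two past the
bend, so recovered slopes on plateau series are accurate to ~5–10%,
versus < 5% on genuinely linear initial phases.

## Genome survey

The alkaline-phosphatase aggregate is PhoA + PhoK + PhoD + PhoX. Density
is genes per Mb (per-1000-genes is available where a total gene count is
present). The size dependence of phosphatase abundance is tested with a
tie-corrected Kruskal–Wallis statistic across genome-size quantile bins
(quintiles by default, configurable — the grouping is a convention);
the implementation is cross-checked against scipy on random tables. A
focal genome's percentile is the fraction of genomes with strictly higher
density.

## Synthetic data: what it emulates, and what passing tests show

One master seed expands into independent substreams (SeedSequence spawn
keys), so adding a generator never perturbs another; every generator is a
pure function of its config and every planted signal is recorded exactly
once in a truth table.

* **Proteome.** Decoys are i.i.d. Robinson–Robinson draws; family
  profiles are sharp synthetic PSSMs whose per-column emission is solved
  by bisection so an implanted domain's expected score is the configured
  `signal_strength` (default 280 half-bits over 110 columns, i.e. the
  information content of a genuine conserved-domain hit — weak implants
  cannot clear an E ≤ 10⁻¹⁰ membership rule, by the E-value algebra
  itself). The PhoD-like family carries a second, partially overlapping
  sub-profile so the two-profile membership rule and the redundancy rule
  are both exercised. What passing shows: the decision logic (scanning,
  calibration, thresholds, validation) separates domain-strength signals
  from background perfectly. What it does not show: performance on remote
  homologs near the threshold, or equality of E-values with RPS-Blast's.
* **Promoters.** Order-1 AT-rich chain (P(A)+P(T) = 0.7, mild
  same-symbol persistence) with motif instances sampled from the matrix
  and implanted at stated upstream positions; a strong 16-bp pho-box-like
  matrix is the default. Recovery ≥ 95% at p ≤ 10⁻⁴ reflects strong
  matrices; weak, information-poor motifs will not reach that.
* **Structure.** A coarse helical CA trace whose designated site
  residues sit exactly `ligand_distance` (3 Å) from a phosphate P atom,
  all others pushed beyond 6.5 Å; a Ca ion sits by the ligand. Real
  active sites have full side chains and ambiguous second shells; the toy
  isolates the contact rule and the SASA bookkeeping, not chemistry.
* **Kinetics.** value(t) = slope·t (+ optional plateau after t_sat) with
  Gaussian noise of 2% of the final signal, 21 points over 5 min.
* **Survey.** Lognormal genome sizes (median 4 Mb, σ = 0.35 in log);
  total genes linear in size (9×10⁻⁴ genes/bp) with 5% multiplicative
  noise; per-family counts Poisson with per-Mb rates chosen so family
  prevalence at a typical 4 Mb genome matches the shares observed across
  complete bacterial genomes (~62% with ≥ 1 alkaline phosphatase, 35%
  PhoA, 22% PhoX, 17% PhoD, smaller acid-family shares); 33 phylum labels
  round-robin; an optional focal genome carries the 1 PhoD + 4 PhoX
  repertoire. Default n = 500 genomes keeps the suite fast while leaving
  binomial noise on recovered fractions within a few percent.

## Problem sizes used by the default suite

Calibrations use 1000 background samples per PSSM; the null-calibration
scan covers 100 kb (10 × 10 kb, both strands); the Monte-Carlo SASA
oracle uses 10⁵ surface points; the survey benchmark uses 500 genomes.
These sizes make every statistical check well-powered while the whole
suite stays interactive.

## Known limitations

* E-values are per-comparison (m·n); database-wide E-values require an
  external search-space correction.
* The exact p-value DP assumes background order ≤ 1.
* Speciation ignores ion pairing and temperature dependence; it is not a
  general geochemical solver.
* Homology model building, model quality assessment, electrostatic maps
  and subcellular-location prediction are consumed as inputs, never
  computed.
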