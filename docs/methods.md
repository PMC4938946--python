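# Methods

`longcap` models and evaluates long-fragment region-specific capture: an
enrichment strategy in which short (20–25 nt) capture primers, tiled at
multi-kilobase intervals across a target region, hybridize to genomic DNA and
are extended with biotinylated nucleotides so that the *entire* original
fragment — typically ~20 kbp — is pulled down on streptavidin beads. Because
one primer site retrieves a whole long fragment, a sparse primer tiling can
cover a multi-megabase region contiguously. This note documents the models,
defaults, and design choices behind each module.

## Capture model (`capture_sim`)

A fragment is pulled down if at least one capture primer hybridizes anywhere
on it. Fragment starts are uniform on the genome; lengths are i.i.d. from a
configurable model, independent of position (DNA quality enters only through
the length distribution). For a random fragment known to cover a primer site,
the chance it also covers a point `d` bases away is proportional to the
expected overhang `E[(L − d)+]`; normalizing at `d = 0` gives the
relative-capture decay

    relative_capture(d) = E[(L − d)+] / E[L],

which is 1 at the site, nonincreasing, and exactly 0 beyond the support of
`L`. Between two primers spaced `s` apart, the flanking primers act as
independent capture opportunities, so the worst-covered point (the midpoint)
carries relative signal `1 − (1 − relative_capture(s/2))²` — exact under the
model because fragments are sampled independently.

Length-model families:

* **fixed** — degenerate at `mean_bp`; exists to enable closed-form tests
  (e.g. `relative_capture(10 kbp) = 0.5` at `L = 20 kbp`).
* **uniform** on `[low_bp, high_bp]` with the obvious closed forms.
* **lognormal** (default) with untruncated mean 20,000 bp and sd 10,000 bp,
  truncated at 60,000 bp. The mean matches the ~20 kbp genomic preparations
  such experiments use; the sd (CV 0.5) is consistent with the 20–40 kbp
  spread typical of bead-based DNA preparation, and the truncation caps
  unphysical tails. `E[(L − d)+]` is computed in closed form from lognormal
  partial expectations (`M(x) = e^{μ+σ²/2} Φ((ln x − μ − σ²)/σ)`), not by
  quadrature; a test verifies the closed form against numeric integration.

Monte-Carlo capture (`simulate_capture`) applies the rule
`P(capture | k sites) = 1 − (1 − per_site_efficiency)^k`, plus an independent
`off_target_rate` per fragment modelling non-specific pulldown. Defaults are
`per_site_efficiency = 1.0` and `off_target_rate = 0.0`; neither quantity is
measured by the experiments the model abstracts, so both are free parameters
calibrated only qualitatively (the observed target:background ratios fall
from ≈35:1 near a primer toward ≈10:1 at 8–9 kbp, which the default length
model reproduces in shape). Fragments may overhang the region end; no
circularity is imposed. `target_ratio_profile` reports probe:reference count
ratios with a log-scale (Katz) confidence interval `exp(±z√(1/a + 1/b))`.

## Primer design (`primer_design`)

The region is split into `n = round(length / spacing)` contiguous tiles
(half-up rounding; lengths differ by ≤1 bp, longer tiles first) and one
primer is sought per tile — e.g. a 4,000,002 bp region at 8,000 bp nominal
spacing gives exactly 500 tiles. Candidates are every window of length
20–25 nt inside the tile that

1. overlaps no masked base — repeat mask, SNP mask, or N (a primer placed on
   a known variant risks allele dropout, so any overlap disqualifies);
2. has GC in [0.40, 0.60];
3. has nearest-neighbor melting temperature within 58 ± 3 °C;
4. passes the hairpin screen (longest self-complementary stem with loop ≥ 3
   below 4 bp) and self-dimer screen;
5. is unique by exact k-mer accounting: the maximum over the candidate's
   16-mers of their occurrence count in the background (both strands,
   excluding the candidate's own locus) must not exceed 1.

Candidates are ranked by distance of their midpoint from the tile center
(ties: larger uniqueness margin, then smaller |Tm − 58|, then leftmost), and
screens are evaluated lazily in that order. Tiles are processed left to
right; a candidate is accepted only if cross-dimer compatible with every
already-accepted primer, otherwise the next-ranked candidate is tried
(drop-and-replace). Tiles with no survivor are reported as unfilled. The
procedure contains no randomness: identical inputs give identical sets.

**Melting temperature** is the two-state nearest-neighbor model with the
SantaLucia-1998 unified parameters, terminal initiation terms, the entropic
salt correction `ΔS += 0.368 (N−1) ln[Na⁺]` at 50 mM monovalent, and
`Tm = ΔH / (ΔS + R ln(C/4)) − 273.15` at C = 0.25 µM total oligo. No
symmetry correction is applied (tiling candidates are effectively never
self-complementary). The implementation is checked against an independent
NN implementation (Biopython's) to 10⁻⁶ °C.

**Uniqueness** replaces an alignment-based homology search with exact 16-mer
counting on both strands, implemented as a sorted 2-bit-encoded k-mer array
over the region. This is deterministic, needs no external binary, and is
strictly checkable against a brute-force substring count. The exclusion of
the candidate's own locus is realized by subtracting occurrences of each
k-mer (and its reverse complement) within the candidate subsequence itself.

**Structure screens** are combinatorial run lengths rather than free-energy
folding: a thresholded screen is conservative for a "minimal structure"
requirement and admits exhaustive-enumeration oracles. `cross_dimer_score`
reports (a) the longest Watson–Crick complementarity run over all ungapped
antiparallel alignments of two oligos — equivalently their longest common
substring with one reverse-complemented — and (b) the longest such run whose
extent includes the 3′-terminal base of *either* oligo.

**Dimer policy of the set-compatibility pass.** Across a set of hundreds of
primers, thresholding the either-end 3′-anchored run at 4 bp would reject
essentially every candidate: each accepted primer contributes ~32 distinct
5-mers to the pool, so a few hundred primers saturate the 1,024-element
5-mer space and any candidate's 3′-terminal 5-mer almost surely complements
*something* already accepted (a birthday-type effect, P(pass) ≈ e^(−0.03 n)
against n accepted primers). The set-level screen therefore applies the
3′ threshold to the **mutual** 3′ overlap — duplexes in which both oligos'
3′-terminal bases are paired (`a[−r:] == revcomp(b)[:r]`), the geometry that
actually enables mutual primer-dimer extension — together with the overall
run threshold (> 8 bp fails) for stability-driven cross-hybridization. Both
statistics remain available per pair via `cross_dimer_score` and
`mutual_three_prime_overlap`. With the defaults this admits full 500-tile
designs on random sequence while still rejecting genuinely extensible dimer
pairs.

Set compatibility is evaluated via precomputed hash sets of 9-mers and
3′-prefixes of the reverse complements of accepted primers, so the
drop-and-replace pass is linear rather than all-pairs-rescoring; a test
verifies the emitted set pair-by-pair against `cross_dimer_score`.

**Strand policy**: plus-strand only by default, with an `alternate` option
flipping odd tiles; both yield identical screen outcomes because every
screen statistic is invariant under reverse complement.

The target-to-primer **coverage ratio** (region bp ÷ summed primer bp) is
reported and a warning — not an error — is raised when it falls to 300 or
below, the regime where a design stops being "sparse" in the sense this
capture chemistry exploits; the consequence of violating it is advisory
only.

## Coverage and enrichment statistics (`coverage_eval`)

The enrichment factor is
`(reads_on_target / reads_total_mapped) / (target_size / haploid_genome_size)` —
scale-invariant in reads and equal to 1 under proportional sampling. Depth
tables are consumed as 2–3 column TSV (chrom?, 1-based position, depth), the
de-facto output of standard depth utilities; absent positions are depth 0
within the declared region. "Bases called" is interpreted as depth ≥ 1,
since called-bases ÷ region-size then reproduces the published percentages
exactly to their printed precision. Threshold fractions use depth ≥ t.
`audit_sites` averages depth over ±window (default 100 bp — the averaging
window is not specified anywhere authoritative, so it is an exposed
parameter) at each primer site and at each inter-primer midpoint
`⌊(p₁+p₂)/2⌋`, truncating windows at profile edges. Correlations are Pearson
product-moment (the published r → R² arithmetic identifies the estimator).
Report rounding is half-up at the printed precision; full precision is kept
internally.

## Variant statistics (`variant_eval`)

Filtering keeps records with depth **strictly** greater than 20 and QUAL
**strictly** greater than 30 ("greater than" is taken literally; boundary
records at depth 20 or QUAL 30 fail). Depth is read from DP (INFO, else the
first sample); records missing DP or QUAL fail conservatively. The same
thresholds are applied to indels and SNVs alike. Variant load is
`region_bp / n_variants`, half-up-rounded to an integer, undefined (None)
for zero variants. Validation classification is defined for a homozygous
cell line: an orthogonally confirmed hom-alt call is a reference-sequence
error (an a/a → b/b switch is implausible in such a line), a confirmed het
is a candidate de novo change, and any call the orthogonal read contradicts
is a sequencing-workflow error; a confirmed hom-alt in a non-homozygous
sample raises instead of guessing.

## Allele typing (`hla_typing`)

Consensus: per pileup column, the majority symbol wins; depth below
`min_depth` or an exact top-count tie emits N; a gap majority deletes the
column. Alignment: Needleman–Wunsch with linear gap penalty, defaults
match +1 / mismatch −1 / gap −1 (the published procedure fixes the
algorithm but not the scoring, so the scoring is configurable). The DP is
row-vectorized: with a constant gap penalty the in-row dependency unrolls to
a prefix maximum, making alignment O(rows) in numpy operations. Traceback
tie order is diagonal, up, left — fully deterministic. N matches nothing: it
scores as a mismatch and never counts toward identity, but its column stays
in the identity denominator. `call_allele` scores every allele of the locus,
breaking score ties by higher identity then lexicographically smaller allele
name, and reports the runner-up. Percent identity is matches ÷ alignment
columns × 100, so 100 % identity occurs iff the consensus equals the called
allele exactly. The IMGT database is not bundled; fixtures generate
IMGT-style FASTA so real database files drop in unchanged.

## Synthetic data (`fixtures`)

`make_genome` alternates unique gaps and repeat tracts whose lengths are
exponential with means calibrated so the masked fraction approaches the
requested value (±2 % at megabase scale); tract content tiles *exact* copies
of a 300 bp motif library so the k-mer uniqueness screen genuinely fails
inside tracts rather than their merely being labeled masked. Defaults:
repeat fraction 0.53 and SNP density 10⁻³/bp, emulating a repeat-rich,
polymorphism-dense target such as the MHC (≈53 % repeats); optional exact
tandem duplications are planted for off-target screening tests.
`make_depth_profile` draws Poisson depths around a uniform, primer-peaked
(expected depth follows the capture model's union signal across primer
sites), or gapped expectation, defaulting to mean 164×. `make_variant_table`
concentrates 40 % of records at the filter boundaries (depth 18–23, QUAL
28–33, integer QUALs so text round-trips are exact). Every generator is
deterministic in its seed and emits a manifest (planted intervals, pass
sets, expected summaries) sufficient to predict downstream results.

What the generators do **not** emulate: real sequence composition (GC
structure, homopolymers), read-level error processes, amplification bias,
alignment artifacts, or paralog-induced miscalls. Passing tests therefore
demonstrate correctness of the computations and the internal consistency of
the capture model — not performance on real sequencing data.

## Problem sizes and numerical choices

The test suite designs a full 4,000,002 bp region (500 tiles, a few seconds
via the vectorized k-mer index), runs Monte-Carlo capture at 200,000
fragments, and uses 1,000 bp synthetic alleles with 100 typing replicates;
oracle-equivalence checks run exhaustive enumeration at ≤25 nt (structure
screens) and ≤8 nt (alignment). Floating-point policy: report rounding is
half-up via `decimal`; monotonicity assertions allow 10⁻¹² slack; GC-window
comparisons use an ε of 10⁻¹² to keep prefix-sum arithmetic from excluding
exact-boundary candidates. Degenerate inputs (empty primer sets, zero
variants, empty reference bins, constant correlation vectors) return
explicit "undefined" markers or raise, as documented per function.

## Known limitations

* The capture model ignores primer-specific efficiency variation, which in
  real data dominates site-to-site depth differences.
* Structure screening by complementarity runs is more conservative than
  free-energy folding for GC-rich stems and blinder to long weak duplexes.
* The k-mer uniqueness screen detects exact repeats only; diverged repeats
  pass it (real designs also rely on the repeat mask for those).
* `variant_eval` classifies but does not detect paralog-misalignment
  artifacts; a `psv_flag` field is reserved for such review.
* Typing resolution is best-score only; no exon-restricted or multi-field
  disambiguation logic is attempted.
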