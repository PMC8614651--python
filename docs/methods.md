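# Methods

## Scope and data model

The package analyzes codon usage bias (CUB) in a set of coding sequences
partitioned into groups (e.g. taxa). A sequence enters the analysis only
if it is a clean CDS: bases in {A,C,G,T} (U is silently normalized to T),
length a multiple of three, ATG start, one terminal stop, no internal
stop. Validation applies these rules in that fixed order and reports the
first failure, so rejection reasons are reproducible. The terminal stop is
kept on the record but excluded from every downstream statistic: ENC,
RSCU, composition and the correspondence analysis all operate on the same
universe of sense codons (the initial ATG, a sense Met codon, is
included). The 59-codon universe of RSCU and the ordination is the 61
sense codons minus the single-codon families Met (ATG) and Trp (TGG).

## Composition

Overall A/T/G/C fractions and positional GC (P1, P2, P3) are computed over
sense codons; P12 = (P1+P2)/2. Because each position contributes equally
many bases, overall GC equals (P1+P2+P3)/3 exactly — this identity is used
as a test invariant. Values are stored as fractions in [0,1]; report
tables multiply the percent-scale metrics by 100. Group summaries report
mean and sample SD (n−1 denominator; SD = 0 for singleton groups).

## Wright's effective number of codons

Per synonymous family with total count n ≥ 2 and within-family frequencies
p̂ᵢ, the homozygosity estimate is F̂ = (nΣp̂ᵢ² − 1)/(n − 1). Conventions:

* families with n < 2 or F̂ ≤ 0 are excluded from their class mean;
* F̂ is floored at 1/k (family size k), i.e. a family never contributes
  more effective codons than it has — without the floor, finite-count
  noise can push per-family effective codons above k and ENC above 61;
* class means over the 9 two-fold, 1 three-fold (Ile), 5 four-fold and 3
  six-fold (Leu/Ser/Arg) families combine as
  ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61;
* a missing three-fold class is imputed as F̄₃ = (F̄₂+F̄₄)/2 (the standard
  recommendation); a missing two-, four- or six-fold class leaves ENC
  undefined (NaN with a warning) — broader imputation would be guesswork;
* if no family reaches n = 2, ENC is an error, not a number.

With these conventions the estimator hits both analytic endpoints exactly:
one codon per amino acid gives every F̂ = 1 and ENC = 20; equal counts for
all 61 sense codons give every floored F̂ = 1/k and ENC = 61. The
implementation is checked against an independently written step-by-step
oracle on random count tables to 1e-9.

The mutation-pressure null is ENC_exp(s) = 2 + s + 29/(s² + (1−s)²) at
s = GC3, and the per-sequence deviation is (ENC_exp − ENC_obs)/ENC_exp,
histogrammed with half-open bins [edge, edge+width) aligned so 0 is always
an edge (default width 0.05, configurable).

ENC and RSCU are computed per sequence; group-level values are means of
per-sequence values (matching a mean ± SD reporting convention), while the
per-group preferred-codon inventory is additionally computed on pooled
group counts where a single representative table is wanted.

## RSCU and classification

RSCUᵢⱼ = xᵢⱼ/((1/kᵢ)Σⱼxᵢⱼ). An unobserved family yields zeros for all its
codons (not NaN). Classification: rare < 1, unbiased = 1, preferred in
(1, 1.6], over-represented > 1.6 — the boundary value 1.6 itself is
preferred, not over-represented.

## Force diagnostics

* PR2: AT bias A3/(A3+T3) vs GC bias G3/(G3+C3) from the third bases of
  all sense codons; a variant restricted to fourfold-degenerate families
  (where the third position is fully synonymous) is available via
  `pr2_mode=fourfold_only`. Zero denominators yield flagged-undefined
  points rather than errors.
* Neutrality: per-group OLS of P12 on P3 (P3 as predictor), with Pearson r
  and its two-sided p-value; requires ≥ 3 points and P3 variance.
* The regression is interpreted, not model-selected: slope near 1 means
  directional mutation pressure moves all positions, near 0 means
  selection constrains P12.

## Correspondence analysis

Implemented from first principles: with P the table divided by its grand
total, row masses r and column masses c, the SVD of
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} gives singular values σ and principal
coordinates F = D_r^{−1/2}UΣ, G = D_c^{−1/2}VΣ. Total inertia Σσ² equals
the chi-square statistic over the grand total — used as the oracle
identity in tests — and per-axis inertia fractions are σ²/Σσ². Singular
values below 1e-10 (relative) are treated as null axes; an
all-identical-rows table yields a zero-inertia result with no axes.
All-zero columns are dropped with a warning (zero-mass points have no
chi-square geometry); two reported axes (f1, f2) by default with the full
spectrum retained. As is conventional in single-gene CUB studies, CA runs
on RSCU values per group by default; counts input and a joint (all-groups)
scope are configuration switches. Axis signs are arbitrary; tests compare
coordinates up to sign and check sign-invariant summaries only. The
implementation is cross-checked against an independent CA implementation
(scikit-bio) in the test suite.

## Protein properties

Translation uses the standard code. GRAVY is the mean Kyte–Doolittle
hydropathy over residues (the universal GRAVY definition) and aromaticity
the relative frequency of Phe+Tyr+Trp, both via Biopython's
ProteinAnalysis.

## Statistics

Spearman rank correlation (average ranks for ties) is the default
everywhere — the method conventionally reported for these small-n,
non-normal composition metrics; Pearson is a configuration switch. Spearman p-values are exact
(full permutation enumeration of the tie-free null, cached per n) for
n ≤ 10 without ties, and the t-approximation otherwise. No
multiple-testing correction is applied; cells are starred at p < 0.05 and
p < 0.01. Zero-variance inputs give flagged-undefined cells, and per-codon
RSCU-vs-GC3 correlations flag invariant codons as "uniform usage".

## Synthetic data generator

The generator emulates the statistical structure of a vertebrate
single-gene ortholog panel so every stage of the pipeline can be tested
without real sequences. What it emulates: CDS lengths around 2,100–2,300
nt (group-specific means/SDs), amino-acid usage enriched in Leu/Gln/Ser,
group-specific GC3 regimes (fish-like ≈ 0.63 with wide spread; bird-,
reptile-, mammal-like ≈ 0.45/0.43/0.49 with narrow spreads), moderate
overall bias (group ENC means in the low 50s), and the preferred-codon
asymmetry (G/C-ending codons preferred in the GC3-high group, A/T-ending
elsewhere).

Mechanism. Amino acids are drawn i.i.d. from the weight vector; within a
family, codon choice is a softmax over three seeded components:

1. a global third-position GC tilt β, solved per sequence by root-finding
   (brentq) so the *expected* GC3 equals the sequence's target exactly;
2. a per-family tilt δ_f = b·(τ·(log w_f − mean log w) + σ_f·z_f): abundant
   residues lean GC-ward, scarce ones AT-ward, plus family-level noise.
   This emulates translational selection acting hardest on high-usage
   families and produces the heterogeneous preferred-codon endings real
   single-gene data show; the GC3 pin (β) re-centers the weighted average;
3. codon-level preference noise scaled by bias_strength b.

Defaults b = 0.45, τ = 0.6, σ_f = 0.55 were chosen once, forward from the
emulation targets above (they land group ENC means at ≈ 52–55); b = 0
recovers uniform synonymous usage (RSCU ≈ 1, ENC → 61) and b → ∞ collapses
each family to one codon (ENC = 20).

Six-fold families are split into their natural sub-blocks (Leu TTR/CTN,
Ser TCN/AGY, Arg CGN/AGR) with block probabilities independent of β, so
first/second-position composition is exactly decoupled from the GC3 tilt.
This is what makes the two regimes clean:

* *selection*: amino-acid weights fixed → expected P12 constant while GC3
  varies between sequences → neutrality slope ≈ 0;
* *mutation*: per-sequence GC3 targets vary over a band (default ± 0.15)
  and the amino-acid weights are linearly mixed toward all-GC12 residues
  (Ala/Pro/Gly) or all-AT12 residues (Lys/Asn/Ile/Phe/Tyr) so that
  expected P12 equals the GC3 target → slope ≈ 1. The P12–P3 coupling via
  amino-acid drift is a modeling device (the genetic code leaves no
  synonymous freedom at positions 1–2 apart from the six-fold blocks), not
  a claim about the biology of any real gene.

Two variance-reduction choices keep the generator's contracts tight at
gene-scale lengths: codon counts within a family are allocated by floors
of n·p plus a weighted draw of the leftovers (realized GC3 within ±0.02 of
target at ~700 codons), and per-sequence GC3 targets with a normal spread
are drawn by stratified quantiles (the group sample mean stays pinned to
the group target even at n = 20). Sequences are i.i.d. given the dataset
parameters — there is no phylogenetic correlation, no indels, no
within-sequence spatial structure, and amino-acid composition varies only
as the regimes dictate. Passing tests on this panel therefore demonstrate
estimator correctness and pipeline behaviour under the stated regimes, not
performance on real, phylogenetically structured data.

All randomness flows from one seeded NumPy generator per dataset; a fixed
seed reproduces byte-identical FASTA output.

## Pipeline and numerics

All tables are TSV (UTF-8, '.' decimal, floats at 6 significant digits)
with fixed column order; the run manifest records an SHA-256 checksum per
output, so identical inputs and configuration give identical manifests.
Problem sizes used by the bundled analyses: 20 sequences per group
(80 total) of ~700 sense codons, the panel size at which the group-level
contracts (GC3 within ±0.03, regime slopes within ±0.1) hold comfortably.

## Known limitations

* ENC variants differ between tools (treatment of rare families, capping);
  values from other software may deviate by a fraction of a unit.
* CA on RSCU treats row-normalized ratios as table entries (the source
  convention); a counts-based CA is available and is the more orthodox
  chi-square geometry.
* The exact Spearman permutation null is enumerated up to n = 10 (10! ≈
  3.6M pairings, cached); ties always fall back to the t-approximation.
* The generator's mutation regime moves P12 through amino-acid
  composition, so protein-level properties co-vary with GC3 there by
  construction.
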