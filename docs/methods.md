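# Methods

## Genotype model and summary inversion

Loci are biallelic insertion/deletion markers; a diploid genotype is the
insertion-allele dosage g ∈ {0,1,2}, missing entries use a dedicated
sentinel and are excluded from per-locus sample sizes. Published panel
reports print, per locus, the insertion frequency and observed
heterozygosity to 4 decimals for n diploids. The inversion used
throughout is: n_ID = round(Ho·n), a = round(F_ins·2n) (both half away
from zero, the convention of printed reports); a − n_ID must be even, and
when rounding breaks parity a is nudged ±1 toward the value whose implied
frequency is closest to the printed one (ties resolved downward);
n_II = (a − n_ID)/2. At n = 262 every row of the bundled summary file
inverts with no parity repair, and a property test confirms the inversion
is the identity on 4-decimal summaries of arbitrary counts at this n.
The inversion can be ambiguous at much larger n (where several integer
counts share a 4-decimal rounding); it raises only on inconsistent
summaries (negative implied counts).

## Forensic parameters

- He uses Nei's unbiased estimator (factor 2n/(2n−1)). The biased form
  1 − p² − q² gives 0.4999 where the published table prints 0.5009; the
  unbiased form reproduces every checked cell, which fixes the choice.
- PM is the sum of squared **observed** genotype frequencies, not
  HWE-expected ones; again fixed by the data (0.3539 at the most diverse
  locus is reproduced only with observed counts).
- PE is the trio exclusion formula h²(1 − 2hH²). The duo form is not
  implemented; the trio form reproduces all checked cells.
- Report rounding is half away from zero at 4 decimals.
- Combined values: CPD = 1 − Π PM and CPE = 1 − Π(1 − PE). PM and PE are
  rational in the counts, so when counts are available the complements
  are accumulated exactly with `fractions.Fraction` and rendered through
  `decimal` at 60-digit precision (29 decimals for CPD, 15 for CPE);
  Σ log₁₀ PM is also reported, and the two routes agree to float
  precision. This matters because Π PM ≈ 3×10⁻²⁴ is below the spacing of
  doubles near 1, so a naive `1 - prod(pm)` collapses to 1.0.

## Hardy–Weinberg testing

The exact conditional test: given allele counts, P(h heterozygotes) =
n!/(n_II! h! n_DD!) · 2^h · n_A! n_B!/(2n)!; the two-sided p-value sums
every parity-consistent h whose probability does not exceed the observed
one (probability-ordering with ties included). Enumeration uses
log-gamma arithmetic with a 1e−9 log-scale tolerance for tie detection;
an exhaustive test checks it against rational-arithmetic enumeration for
all configurations with n ≤ 30. The Monte Carlo variant draws h directly
from the enumerated conditional distribution (equivalent to permuting
allele vectors, but cheaper) and uses the (b+1)/(B+1) estimator so p is
never zero. The published per-locus p-values are consistent with a
1000-draw Monte Carlo run of the original software and are therefore not
asserted numerically; the panel-level claim that no locus deviates after
Bonferroni correction (threshold 0.05/57) is asserted with the exact
test, whose minimum p across the panel is 0.0220.

## Linkage disequilibrium

Haplotype frequencies from unphased two-locus genotype counts by EM:
only the double heterozygote is phase-ambiguous and is split between
coupling and repulsion by the current posterior each iteration;
initialization at linkage equilibrium, convergence at 1e−10 on the
log-likelihood, 1000 iteration cap with a `converged` flag. r² =
D²/(p_A q_A p_B q_B) with D = p_AB − p_A p_B. The EM maximizer is tested
against a grid search over the single free haplotype frequency. The
rebuilt panel's between-locus arrangement is artificial (per-locus
genotype blocks), so LD is validated exclusively on synthetic two-locus
draws at known haplotype frequencies.

## Distances and structure

- Nei DA for biallelic loci: 1 − mean over loci of √(x y) + √((1−x)(1−y)).
- Weir–Cockerham θ: two-population variance components a, b, c summed
  across loci; loci monomorphic in both populations are excluded with a
  warning; negative estimates are reported raw (a clamp flag exists for
  heatmap export). Hudson's estimator with the n−1 bias correction covers
  frequency-only reference panels.
- Neighbor joining: Saitou–Nei with the Q-criterion; ties broken at the
  smallest (row, column) pair; negative branch lengths retained with a
  warning. On additive matrices the tree metric is reproduced to 1e−9
  (verified over random trees with 4–10 leaves).
- PCA: loci centered across populations, no scaling (frequencies share a
  scale); SVD; explained fractions are eigenvalues over total variance
  and sum to 1 at full rank; component signs fixed by making each
  component's largest-magnitude loading positive.
- Admixture: binomial genotype likelihood over K ancestral components,
  maximized by plain EM over Q and F (no quasi-Newton acceleration —
  adequate at the package's scale and with a simple monotone-likelihood
  contract). F is clipped to [1e−6, 1−1e−6]; Q rows renormalize every
  update; 5 random restarts by default, best likelihood kept; label
  switching across fits is resolved by optimal assignment on ancestry-
  column correlations (equivalent to exhaustive search over K!
  permutations).

## Synthetic data: what it emulates and what it does not

Generators produce HWE populations (dosage ~ Binomial(2, p)), admixed
individuals (each allele copy drawn via Q then F), two-locus diploids
assembled from 2n haplotype draws, and reference panels drifted from
founder frequencies under Balding–Nichols Beta(p(1−c)/c, (1−p)(1−c)/c)
with a single F_ST-like drift parameter c per population. All are
deterministic under fixed seeds. They emulate idealized random-mating
structure only: no mutation, no close relatives, no genotyping error,
no real LD backbone, and no attempt to match real reference-panel
frequencies. Tests passing on these generators therefore validate the
estimators' correctness under their own model assumptions, not the
demographic realism of any particular population.

The bundled panel fixture rebuilds the 262 × 57 target-population matrix
from its summary file with per-locus genotype blocks in a fixed order, so
single-locus statistics are exact and fully deterministic; an optional
seeded shuffle exists for procedures that need the blocks broken up.
Figure-level results that depend on external reference-population
frequencies (reference PCA percentages, the 27-population tree topology)
are out of reach without those data; the package substitutes
property-based validation (PCA reconstruction identity and rank-1
recovery, DA/θ monotonicity under increasing drift, admixture parameter
recovery) and accepts user-supplied frequency tables for full runs.

## Numerical and design notes

- Problem sizes in the validation suite are desk-scale by design:
  exhaustive HWE checking to n = 30, LD recovery at n = 10⁴, admixture
  recovery with 100 individuals × 60 loci, NJ over 100 random trees.
- Ancestry-assignment certainty scales with panel information: with ~50
  moderately divergent loci the ML mean per-individual maximum ancestry
  for truly unadmixed individuals sits near 0.94; the near-deterministic
  assignment contract (> 0.95) is exercised at 100 strongly divergent
  loci.
- Degenerate inputs raise rather than guess: all-missing loci, n < 2 for
  unbiased He, monomorphic loci for r², fewer than 3 taxa for NJ,
  constant matrices for PCA, K exceeding the number of individuals.
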