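# indelkit

Forensic statistics and population-structure inference for biallelic
insertion/deletion (InDel) marker panels.

InDel markers combine the short amplicons of SNPs with simple
length-based typing, which makes them attractive for forensic
identification in degraded samples. Evaluating a panel for casework in a
given population requires (i) per-locus efficiency parameters, (ii)
evidence that the loci are in Hardy–Weinberg and linkage equilibrium, and
(iii) an assessment of how the studied population relates to reference
populations. `indelkit` implements that entire battery for panels of
biallelic loci genotyped as insertion-allele dosage (0/1/2), and it can
rebuild exact genotype counts from a published summary table — the
insertion frequency *F*ins and observed heterozygosity *Ho* printed to
4 decimals pin down the integer counts uniquely at realistic sample
sizes — so published panels are analyzable without the raw genotypes.

## Statistics implemented

Per locus, with genotype counts (*n*II, *n*ID, *n*DD) and *p* = *F*ins:

- observed heterozygosity *Ho* = *n*ID/*n*; unbiased expected
  heterozygosity *He* = 2*n*/(2*n*−1) · (1 − *p*² − *q*²)
- polymorphism information content PIC = 1 − (*p*² + *q*²) − 2*p*²*q*²
- match probability PM = Σ (observed genotype frequency)²; power of
  discrimination PD = 1 − PM
- probability of paternity exclusion (trio) PE = *h*²(1 − 2*hH*²),
  *h* = *Ho*, *H* = 1 − *h*
- exact Hardy–Weinberg test by full enumeration of the conditional
  heterozygote distribution (probability-ordered, ties included), plus a
  seeded Monte Carlo variant with the (b+1)/(B+1) correction

Across loci, CPD = 1 − Π PM and CPE = 1 − Π(1 − PE) are accumulated as
exact rationals, because the PM product of a ~60-locus panel (~10⁻²⁴) is
far below the resolution of `1 - x` in double precision.

For multi-population work: EM haplotype-frequency estimation and *r*²
for pairwise LD; Nei's *D*A distance and neighbor-joining trees; Weir–
Cockerham θ and Hudson F_ST; PCA of population × locus frequency
matrices; and an admixture model (binomial genotype likelihood over K
ancestral components) fitted by EM with restarts. A synthetic-data
module generates HWE populations, admixed individuals, two-locus
haplotype draws, and Balding–Nichols drifted reference panels for
validation.

## Worked example

The package bundles the per-locus summary table of a 57-InDel panel
typed in 262 individuals of the Hubei Tujia population. Rebuilding the
genotype matrix and recomputing everything:

```sh
python analysis/01_rebuild_panel.py
python analysis/02_forensic_report.py
```

prints

```
57 loci; PIC range 0.3149-0.3750 (all above 0.3: True)
CPD = 0.99999999999999999999999699822
CPE = 0.999975177214539
```

i.e. every locus is informative (PIC > 0.3, near the biallelic maximum
0.375), and jointly the panel discriminates unrelated individuals with
probability 1 − 3.0×10⁻²⁴ and excludes a random non-father with
probability 0.99998 — adequate for identification and paternity
casework. `analysis/03_equilibrium.py` shows no locus deviates from HWE
after Bonferroni correction (minimum exact p = 0.0220 ≫ 0.05/57 =
0.00087719), and `analysis/04_population_structure.py` runs the
distance/tree/PCA/admixture battery on a synthetic reference panel.

The same reports are available as a CLI: `indelkit summarize`, `hwe`,
`ld`, `distance`, `tree`, `pca`, `admix`, `simulate`.

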