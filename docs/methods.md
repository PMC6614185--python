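# Methods

## The model

The analysis couples two independent data sources through a single
multiplication. Population genetics supplies, per pharmacogene *g*, the
fraction `a_g` of individuals predicted to carry an actionable genotype —
one for which DPWG-style guidelines recommend a therapeutic change.
Drug-utilization data supply, per drug or drug group, the number of
exposures `B` over the study window, where an exposure is a distinct
drug–user pair (repeat prescriptions of one drug to one user count once).
Assuming genotype and prescribing are independent — carriers are neither
more nor less likely to receive the drug, reasonable for pre-emptive
settings where genotype is unknown at prescribing time — the expected
number of exposures involving actionable-genotype carriers ("risky
exposures") for the interaction row of gene *g* is `a_g × B_g`. Gene shares
of the risky-exposure total rank genes for a pre-emptive testing panel, and
the coverage of a panel is the sum of its genes' shares.

## From genotypes to actionable fractions

**Star-allele catalog.** Each gene carries a set of star alleles (or tag
haplotypes), each defined by one or two rsID-keyed variants with a declared
risk allele, a functional status from the closed set {normal, decreased,
inactive, increased, risk-tag, non-carrier}, and a haplotype frequency.
Frequencies are haplotype frequencies, not per-SNP MAFs: where definitions
nest (CYP2D6 \*4 carries both rs3892097 and rs1065852, so \*10 —
rs1065852 alone — keeps the residual 0.23 − 0.21 = 0.02; TPMT \*3B and \*3C
likewise keep the residual after \*3A), the per-SNP MAFs of the reference
cohort emerge as marginals. CYP3A5 is reference-inverted: the inactive \*3
is the reference allele and the expresser \*1 is the tracked variant.

**Calling.** Phased haplotypes are matched exactly against defining-variant
sets; a haplotype matching no catalog allele is a no-call (defining sets
are treated as exhaustive — no novel-allele inference). Unphased dosage
patterns are resolved by enumerating all consistent allele pairs and
choosing by a fixed precedence: fewest distinct non-reference alleles, then
lowest combined activity (inactive/risk-tag 0, decreased 0.5,
normal/non-carrier 1, increased 1.5 — conservative, flags more actionable
carriers), then lexicographic name. Two-SNP HLA tags follow the carrier
rule: both dosages ≥ 1 → Het (both = 2 → Hom); one positive with one zero
dosage is inconsistent → no-call. Missing genotypes at any defining variant
propagate to a no-call; no-calls are excluded from frequency denominators
and contribute zero to carriage counts, and both exclusions are reported.

**Phenotype rules.** The diplotype→phenotype map is a per-gene table over
unordered function pairs, because no single global rule reproduces the
reference phenotype-frequency table. Two families are used:

- *variant-count* (CYP2B6, CYP2C9, DPYD, SLCO1B1, TPMT, CYP3A5 inverted,
  VKORC1 genotype-coded): no variant allele → N, one → I, two → P;
- *activity-score style* (CYP2D6): decreased+normal → N (a \*1/\*41 or
  \*1/\*10 heterozygote is a normal metabolizer), one inactive or two
  decreased → I, two inactive → P; copy number > 2 with at least one
  normal-function allele → U (duplicating an inactive allele never creates
  U). CYP2C19: \*17 without a null allele → U, \*2/\*17 → I.

With the catalog frequencies these tables reproduce the reference
phenotype-frequency structure (e.g. CYP2D6 N = 0.600 closed-form vs 0.599
published; actionable I+P+U = 0.400 vs 0.401) for every gene except the two
documented anomalies below.

**Two documented anomalies.** The published carbamazepine row prints an
actionable fraction of 38.54% that no combination of the HLA-A\*31:01 and
B\*15:02 carrier frequencies yields (≈ 8.4%), and its printed risky count
(96,063) is not even the product of its own printed columns (38.54% ×
245,493 = 94,613). The published CYP2C19 row prints 9.88% "(I+P+U)" while
the phenotype table's I+P+U sums to 32.5%. Both printed values are stored
verbatim, flagged non-derivable, excluded from simulation cross-checks, and
regression-tested to *remain* discrepant.

## Exposure arithmetic

Risky-exposure products are rounded to one decimal and then to the nearest
integer, half away from zero at both steps. This two-stage convention
mirrors the source tables' reporting: it reproduces all four published rows
whose value equals the rounded product of their printed columns (TPMT,
FVL, CYP2C9, HLA-B\*57:01); a single rounding step misses FVL by one
(92,225.484 → 92,225 vs the published 92,226). The remaining rows differ
from print by ≤ 0.1% because the source multiplied with unrounded internal
fractions. The published risky-exposure total (12,380,754) differs from the
sum of the published column (12,456,611); both are carried, the computed
sum is the default denominator for shares, and `use_fixture_total` switches
to the published one. Drug groups (PPI, SSRI, TCA, opioids, statins,
estrogen contraceptives) are atomic rows; a drug listed under two genes
(e.g. imipramine under CYP2C19 and CYP2D6) is counted under each, with no
cross-gene deduplication, matching the source's bookkeeping. Utilization
counts are scaled by the 0.85 European-ancestry fraction of the insured
population before per-user rates are formed, because the genotype
frequencies describe that stratum only.

## Population-genetics checks

MAF estimates are risk-allele dosage sums over twice the non-missing sample
count. Cohort comparison uses a two-proportion chi-square on allele counts
without continuity correction (Fisher's exact on request, and automatically
when an expected cell is empty). The comparison cohort defaults to 349
individuals when unspecified. The source names no test; several of its
printed p-values cannot be recovered from any standard two-proportion test
at the printed frequencies, so printed p-values are carried as reference
metadata only and never asserted. The test's empirical size is checked by
simulation (0.05 ± 0.02 at 2000 null replicates; p-values
Kolmogorov–Smirnov-close to uniform).

## Synthetic cohorts

The generator draws, per gene, two haplotypes per individual independently
from the star-allele frequency vector (reference allele takes the residual
mass) and renders them into per-variant genotypes, so Hardy–Weinberg
equilibrium holds by construction and multi-SNP haplotypes are always
consistent. Defaults are the study conditions: catalog (reference-cohort)
allele frequencies, n = 498 individuals for cohort-scale checks, CYP2D6
duplication fraction 0.02 (chosen so the ultrarapid fraction is ≈ 0.02),
phased output, no missingness. Genes are simulated independently; real
cohorts have LD beyond the encoded haplotype nesting, trio structure and
genotyping error, none of which is emulated — so passing tests demonstrate
internal consistency of the method, not properties of real Dutch data.
Convergence checks run at n = 50,000 (3 binomial SE per phenotype label);
cohort-level comparisons run at the study's own n = 498. The consumption
simulator produces schema-valid tables with log-uniform issuance, the
reference class mix and the reference sex/age margins; it is a smoke-test
generator, not a prescribing model.

## Individual-level quantities

The per-individual actionable-genotype count k counts genes (0–14) whose
phenotype lies in the union of that gene's actionable sets, so two
actionable HLA haplo-groups in one person count twice. Under the catalog
frequencies the closed-form probability of k = 0 is ≈ 2% and simulated
cohorts agree (the source cohort reported 0.6% on real data; the gap is
consistent with the independence assumption and the anomalous CYP2C19
translation). Exact reproduction of the published per-k percentages is
impossible without the individual-level genotypes, which are not
redistributable; simulation-based checks substitute for them.

## Numerical and design choices

- Rounding helpers use decimal arithmetic (`ROUND_HALF_UP` on the absolute
  scale), avoiding binary-float artefacts in reported integers.
- Phenotype frequencies are exact rationals of call counts; frequency-table
  validation tolerates ±0.002 on the unit sum (the print precision of the
  reference table).
- The caller memoizes dosage patterns per gene, making 50k-individual
  cohorts cheap (the pattern space is tiny).
- VKORC1 is genotype-coded (GG→N, GA→I, AA→P) with only P actionable for
  the coumarins; CYP3A5 expressers (N+I) are the actionable class for
  tacrolimus; FVL and HLA rows are actionable as carriers (Het+Hom).
- Interaction rows may span two genes (carbamazepine: HLA-A\*31:01 and
  B\*15:02); cohort-estimated fractions for such rows are
  carrier-of-at-least-one under gene independence.
- The command-line layer is deliberately thin; every report artefact is TSV
  or JSON, and the run manifest hashes outputs so deterministic stages can
  be verified byte-for-byte.

## Known limitations

No suballeles, hybrids or CYP2D6 structural variants beyond a copy-number
integer; no phasing or imputation; no LD within or across genes beyond
defining-variant nesting; no multiple-testing correction across the
variant-comparison table (the source applies none); exposures are taken as
given integers (the source is ambiguous about their exact construction);
HLA haplo-groups are tag-SNP proxies, not typed alleles.
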