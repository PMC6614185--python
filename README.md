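# pgx-exposure

Population-scale pharmacogenetic exposure analysis for the Dutch setting:
how often are patients exposed to drugs whose effect depends on their
genotype, and how many of those exposures involve carriers of *actionable*
genotypes — genotypes for which DPWG (Dutch Pharmacogenetics Working Group)
guidelines recommend a dose change or an alternative drug?

The package is aimed at pharmacoepidemiologists and implementation-science
groups who want to reproduce, stress-test or adapt this kind of
"utilization x genetics" analysis: it couples a star-allele caller and a
DPWG-style phenotype translator to drug-consumption tables, and ships a
synthetic-cohort generator so every stage is testable without access to the
underlying cohort or claims databases.

## What it computes

For each pharmacogene *g* with actionable phenotype set *A(g)* and predicted
phenotype frequencies *f(g)*:

- **Column A** — actionable fraction: `a_g = Σ_{x ∈ A(g)} f_g(x)`
  (e.g. CYP2C9 I+P = 0.309 + 0.042 = 0.351);
- **Column B** — exposures: distinct drug–user pairs over the study window
  (repeat prescriptions of one drug to one user count once);
- **risky exposures** — `round(a_g × B_g)`, their gene shares, and the
  coverage of a candidate pre-emptive testing panel (sum of shares).

Upstream of that sit the genotype stages:

- a diploid cohort (VCF, rsID-keyed bi-allelic SNVs, optional CYP2D6
  copy-number sidecar) is read into a samples × variants matrix;
- star-allele diplotypes are called per gene — phased haplotypes are matched
  exactly against defining-variant sets; unphased dosages are resolved by a
  deterministic precedence (fewest variant alleles, then lowest activity,
  then name); unexplainable patterns are no-calls, never guesses;
- diplotypes translate to phenotypes (N/I/P/U metabolizer classes, VKORC1
  sensitivity coding, Het/Hom for FVL and the HLA tag haplotypes) through
  per-gene rule tables;
- allele frequencies, Hardy–Weinberg expectations `((1−q)², 2q(1−q), q²)`
  and two-cohort MAF comparison tests (two-proportion chi-square on allele
  counts, Fisher fall-back) cover the population-genetics checks.

The packaged catalog transcribes the published reference tables: 14
genes/haplo-groups, 30 star-allele definitions, 13 drug–gene interaction
rows, the 32-row consumption table and the sex × age usage strata.

## Worked example

```python
from pgx_exposure import load_catalog, build_exposure_table
from pgx_exposure.exposure_model import ancestry_adjust, exposures_per_user

catalog = load_catalog()                      # packaged reference tables
table = build_exposure_table(catalog, "printed", use_fixture_total=True)
for e in table:
    if e.row_id in ("CYP2D6", "SLCO1B1", "CYP2C19", "TPMT"):
        print(f"{e.row_id:8s} exposures={e.exposures:>10,} "
              f"risky={e.risky_exposures:>9,} share={e.share_of_risky_pct:5.2f}%")

total = sum(e.exposures for e in table)
users = ancestry_adjust(catalog.reference["insured_population"], 0.85)
print(f"total exposures {total:,}; {users:,} users; "
      f"{exposures_per_user(total, users)} exposures/user")
```

prints

```
CYP2C19  exposures=15,471,291 risky=1,528,564 share=12.35%
CYP2D6   exposures=18,638,754 risky=7,474,140 share=60.37%
SLCO1B1  exposures= 9,226,089 risky=2,723,542 share=22.00%
TPMT     exposures=   193,641 risky=   39,696 share= 0.32%
total exposures 51,304,829; 9,690,000 users; 5.3 exposures/user
```

Over the seven-year window, 51.3 million exposures of 9.7 million insured
European-ancestry patients (5.3 per user) include ~12.4 million involving
actionable-genotype carriers; CYP2D6, SLCO1B1 and CYP2C19 alone account for
~95% of those, which is the case for a three-gene pre-emptive panel.

A full synthetic run — simulate a 498-individual cohort under
Hardy–Weinberg equilibrium at the catalog allele frequencies, call
diplotypes, translate phenotypes, and emit the report bundle (phenotype
frequencies, carriage histogram, exposure tables, class shares,
stratification, run manifest):

```bash
pgx-exposure report --out out/ --simulate-n 498 --seed 1
```

## Layout

| module | role |
| --- | --- |
| `pgx_exposure.catalog` | reference tables, validation, actionable fractions |
| `pgx_exposure.genotypes_io` | VCF + copy-number sidecar I/O (pysam) |
| `pgx_exposure.star_caller` | diplotype calling, phased and unphased |
| `pgx_exposure.phenotyper` | phenotype translation, carriage distribution |
| `pgx_exposure.popgen_stats` | MAF estimation, HWE, two-cohort tests |
| `pgx_exposure.exposure_model` | risky exposures, shares, stratification |
| `pgx_exposure.synthetic_data` | HWE cohort + consumption simulators |
| `pgx_exposure.pipeline` / `cli` | orchestration, report bundle, CLI |

See `docs/methods.md` for the modelling assumptions, rule tables and known
limitations.
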