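"""Synthetic cohorts and consumption tables with the statistical structure
the analysis assumes.

Cohorts are simulated at the star-allele level: each individual receives two
haplotypes per gene, drawn independently from the gene's allele frequency
vector (alleles are mutually exclusive within a gene; the reference allele
takes the residual mass), and haplotypes are rendered into per-variant
genotypes.  This guarantees consistent multi-SNP haplotypes — CYP2D6 *4
carries both of its defining risk alleles, the two-SNP HLA tags are never
half-present — and Hardy-Weinberg equilibrium holds by construction.  Genes
are simulated independently; real cohorts have inter-gene correlation the
generator does not attempt to emulate.

Consumption tables are drawn with log-uniform issuance, therapeutic areas
sampled from the reference class distribution, and sex/age strata shaped
like the reference usage margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import Catalog, load_catalog
from .exposure_model import AGE_BANDS, SEXES
from .genotypes_io import MISSING, CohortGenotypes, write_copy_number, write_vcf

CYP2D6_DUP_DEFAULT = 0.02  # chosen so the ultrarapid fraction is ~0.02


@dataclass
class SimulationConfig:
    n_individuals: int
    seed: int
    maf_overrides: dict[str, float] = field(default_factory=dict)
    cyp2d6_dup_fraction: float = CYP2D6_DUP_DEFAULT
    phased_output: bool = True
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("cyp2d6_dup_fraction", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0,1]")
        for rsid, v in self.maf_overrides.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"override for {rsid} outside [0,1]")


def _allele_frequencies(catalog: Catalog, config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-gene frequency vector over all alleles (reference last residual).

    An override keyed by a defining rsID replaces the frequency of every
    allele whose definition includes that rsID (for multi-SNP alleles the
    first overridden rsID wins).
    """
    out = {}
    for name, gene in catalog.genes.items():
        freqs = []
        for allele in gene.alleles:
            f = allele.frequency
            for v in allele.defining_variants:
                if v.rsid in config.maf_overrides:
                    f = config.maf_overrides[v.rsid]
                    break
            freqs.append(f)
        total = float(np.sum(freqs))
        if total > 1.0 + 1e-9:
            raise ValueError(f"{name}: allele frequencies sum to {total:.4f} > 1")
        out[name] = np.array([max(0.0, 1.0 - total)] + freqs)  # reference first
    return out


def simulate_cohort(
    config: SimulationConfig, catalog: Catalog | None = None
) -> tuple[CohortGenotypes, pd.DataFrame]:
    """Draw a diploid cohort under HWE; returns genotypes plus a truth table.

    The truth table records every drawn diplotype (sample_id, gene,
    allele_1, allele_2, copy_number) and is the oracle for caller
    concordance checks.  Identical config and seed give identical output.
    """
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]
    freqs = _allele_frequencies(catalog, config)

    rsids: list[str] = []
    for gene in catalog.genes.values():
        for r in gene.defining_rsids:
            if r not in rsids:
                rsids.append(r)
    sites = [catalog.sites[r] for r in rsids]
    col = {r: j for j, r in enumerate(rsids)}

    hap1 = np.zeros((n, len(rsids)), dtype=np.int8)
    hap2 = np.zeros((n, len(rsids)), dtype=np.int8)
    copy_number: dict[str, np.ndarray] = {}
    truth_rows = []

    for name, gene in catalog.genes.items():
        p = freqs[name]
        alleles = gene.all_alleles  # reference first, matching p
        idx1 = rng.choice(len(alleles), size=n, p=p)
        idx2 = rng.choice(len(alleles), size=n, p=p)
        if gene.cn_aware:
            cn = np.where(rng.random(n) < config.cyp2d6_dup_fraction, 3, 2)
            copy_number[name] = cn
        else:
            cn = np.full(n, 2, dtype=int)
        for j, allele in enumerate(alleles):
            if allele.is_reference:
                continue
            mask1 = idx1 == j
            mask2 = idx2 == j
            for v in allele.defining_variants:
                hap1[mask1, col[v.rsid]] = 1
                hap2[mask2, col[v.rsid]] = 1
        for i in range(n):
            truth_rows.append(
                {"sample_id": sample_ids[i], "gene": name,
                 "allele_1": alleles[idx1[i]].star_name,
                 "allele_2": alleles[idx2[i]].star_name,
                 "copy_number": int(cn[i])}
            )

    if config.missing_rate > 0.0:
        mask = rng.random(hap1.shape) < config.missing_rate
        hap1[mask] = MISSING
        hap2[mask] = MISSING

    cohort = CohortGenotypes(
        sample_ids=sample_ids, sites=sites, hap1=hap1, hap2=hap2,
        phased=np.full(len(rsids), bool(config.phased_output)),
        copy_number=copy_number,
    )
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


def write_cohort(
    cohort: CohortGenotypes, truth: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write VCF + copy-number sidecar + truth TSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "copy_number": out / "copy_number.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    write_copy_number(cohort, paths["copy_number"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_consumption(
    seed: int,
    n_drugs: int,
    scale: float = 1e4,
    catalog: Catalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic consumption and stratified-usage tables (schema-valid for the
    exposure model, not a forecast of real prescribing)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(seed)

    cons = catalog.consumption
    areas = sorted(set(cons["therapeutic_area"])) if cons is not None else ["other"]
    if cons is not None:
        weights = cons.groupby("therapeutic_area")["items_issued_thousands"].sum()
        w = np.array([weights.get(a, 0.0) for a in areas])
        w = w / w.sum()
    else:
        w = np.full(len(areas), 1.0 / len(areas))

    issuance = np.exp(rng.uniform(np.log(scale * 1e-3), np.log(scale), size=n_drugs))
    drug_areas = rng.choice(areas, size=n_drugs, p=w)
    consumption = pd.DataFrame(
        {"drug": [f"drug_{i:03d}" for i in range(1, n_drugs + 1)],
         "therapeutic_area": drug_areas,
         "items_issued_thousands": np.round(issuance, 3)}
    )

    strata_rows = []
    if n_drugs > 0:
        ref = catalog.strata
        total_users = float(issuance.sum()) * 20.0  # ~users per thousand items
        if ref is not None:
            shape = ref.groupby(["sex", "age_band"])["users"].sum()
            shape = shape / shape.sum()
        else:
            shape = None
        for year in (2015, 2017):
            year_users = total_users * rng.uniform(0.45, 0.55)
            for sex in SEXES:
                for band in AGE_BANDS:
                    frac = float(shape.get((sex, band), 1.0 / 14)) if shape is not None else 1 / 14
                    noise = rng.uniform(0.9, 1.1)
                    strata_rows.append(
                        {"year": year, "sex": sex, "age_band": band,
                         "users": int(round(year_users * frac * noise))}
                    )
    strata = pd.DataFrame(strata_rows, columns=["year", "sex", "age_band", "users"])
    return consumption, strata
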