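"""End-to-end orchestration: catalog -> cohort -> calls -> phenotypes ->
exposure report, with a run manifest.

Every output is plain TSV or JSON.  Deterministic stages produce
byte-identical files on re-run; stochastic stages are reproducible under a
fixed seed.  Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import Catalog, load_catalog
from .exposure_model import (
    ancestry_adjust,
    build_exposure_table,
    class_shares,
    consumption_records,
    exposure_table_frame,
    exposures_per_user,
    gene_shares,
    panel_coverage,
    pgx_prescription_share,
    stratify_usage,
)
from .genotypes_io import CohortGenotypes, read_copy_number, read_vcf
from .phenotyper import (
    carriage_distribution,
    cohort_actionable_fraction,
    no_call_count,
    phenotype_frequencies,
    translate,
)
from .popgen_stats import AlleleFrequencyRecord, comparison_report, estimate_maf
from .star_caller import call_diplotypes
from .synthetic_data import SimulationConfig, simulate_cohort, write_cohort

DEFAULT_PANEL = ("CYP2D6", "SLCO1B1", "CYP2C19")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    out_dir: str | Path
    catalog_dir: str | Path | None = None
    simulate_n: int | None = None
    seed: int = 1
    vcf: str | Path | None = None
    copy_number: str | Path | None = None
    use_fixture_total: bool = False
    phased: bool = True
    missing_rate: float = 0.0
    write_cohort_files: bool = True

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "catalog_dir": str(self.catalog_dir) if self.catalog_dir else None,
            "simulate_n": self.simulate_n,
            "seed": self.seed,
            "vcf": str(self.vcf) if self.vcf else None,
            "copy_number": str(self.copy_number) if self.copy_number else None,
            "use_fixture_total": self.use_fixture_total,
            "phased": self.phased,
            "missing_rate": self.missing_rate,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


@dataclass
class ReportBundle:
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


@_stage("catalog")
def _load_catalog(config: PipelineConfig) -> Catalog:
    return load_catalog(config.catalog_dir)


@_stage("cohort")
def _obtain_cohort(config: PipelineConfig, catalog: Catalog, bundle: ReportBundle):
    if config.simulate_n is not None:
        sim = SimulationConfig(
            n_individuals=config.simulate_n, seed=config.seed,
            phased_output=config.phased, missing_rate=config.missing_rate,
        )
        cohort, truth = simulate_cohort(sim, catalog)
        if config.write_cohort_files:
            paths = write_cohort(cohort, truth, bundle.out_dir / "cohort")
            bundle.files.update({f"cohort_{k}": v for k, v in paths.items()})
        return cohort
    if config.vcf is not None:
        wanted = [r for g in catalog.genes.values() for r in g.defining_rsids]
        cohort = read_vcf(config.vcf, wanted)
        if config.copy_number is not None:
            cohort.copy_number = read_copy_number(config.copy_number, cohort.sample_ids)
        return cohort
    return None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run all stages and emit the report bundle.

    Without a cohort (neither ``simulate_n`` nor ``vcf``) the genotype stages
    are skipped and the report is fixture-driven: the exposure table, class
    shares and stratification recomputed from the packaged tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)

    catalog = _load_catalog(config)
    cohort = _obtain_cohort(config, catalog, bundle)

    phenotypes_by_gene: dict[str, list] = {}
    if cohort is not None:
        _genotype_stages(config, catalog, cohort, bundle, phenotypes_by_gene)

    _exposure_stage(config, catalog, bundle, phenotypes_by_gene)
    _write_manifest(config, bundle)
    return bundle


@_stage("calling")
def _call_stage(catalog: Catalog, cohort: CohortGenotypes) -> dict[str, list]:
    return {name: call_diplotypes(cohort, gene) for name, gene in catalog.genes.items()}


def _genotype_stages(config, catalog, cohort, bundle, phenotypes_by_gene) -> None:
    diplotypes = _call_stage(catalog, cohort)

    rows = []
    for name, calls in diplotypes.items():
        for sample, d in zip(cohort.sample_ids, calls):
            rows.append(
                {"sample_id": sample, "gene": name, "allele_1": d.allele_1 or "",
                 "allele_2": d.allele_2 or "", "copy_number": d.copy_number,
                 "call_quality": d.call_quality}
            )
    _write_tsv(bundle, "diplotypes", pd.DataFrame(rows))

    _phenotype_stage(catalog, cohort, diplotypes, bundle, phenotypes_by_gene)
    _stats_stage(catalog, cohort, bundle)


@_stage("phenotyping")
def _phenotype_stage(catalog, cohort, diplotypes, bundle, phenotypes_by_gene) -> None:
    freq_rows, pheno_rows = [], []
    for name, gene in catalog.genes.items():
        labels = [translate(d, gene) for d in diplotypes[name]]
        phenotypes_by_gene[name] = labels
        for sample, label in zip(cohort.sample_ids, labels):
            pheno_rows.append(
                {"sample_id": sample, "gene": name, "phenotype": label or "no-call"}
            )
        freqs = phenotype_frequencies(labels, gene)
        for label, f in freqs.items():
            freq_rows.append(
                {"gene": name, "phenotype": label, "frequency": round(f, 6),
                 "n_no_call": no_call_count(labels)}
            )
    _write_tsv(bundle, "phenotypes", pd.DataFrame(pheno_rows))
    _write_tsv(bundle, "phenotype_frequencies", pd.DataFrame(freq_rows))

    dist = carriage_distribution(phenotypes_by_gene, catalog)
    carriage = pd.DataFrame(
        [
            {"k": k, "count": c, "fraction": round(c / dist.n_total, 6)}
            for k, c in sorted(dist.counts.items())
        ]
    )
    _write_tsv(bundle, "carriage", carriage)


@_stage("stats")
def _stats_stage(catalog, cohort, bundle) -> None:
    records, ref_records = [], []
    n_ref = int(catalog.reference.get("n_mizzi", 349))
    varref = catalog.variants_reference
    for name, gene in catalog.genes.items():
        for allele in gene.alleles:
            for v in allele.defining_variants:
                if v.rsid not in cohort.variant_index:
                    continue
                try:
                    rec = estimate_maf(cohort, v.rsid, gene=name, star_name=allele.star_name)
                except ValueError:
                    continue
                records.append(rec)
                if varref is not None:
                    hit = varref[varref["rsids"].str.split(";").apply(lambda x: v.rsid in x)]
                    if len(hit) and str(hit.iloc[0]["maf_other"]) != "":
                        ref_records.append(
                            AlleleFrequencyRecord(
                                gene=name, star_name=allele.star_name, rsid=v.rsid,
                                maf=float(hit.iloc[0]["maf_other"]),
                                n_chromosomes=2 * n_ref, source="reference",
                            )
                        )
    maf_df = pd.DataFrame(
        [
            {"gene": r.gene, "allele": r.star_name, "rsid": r.rsid,
             "maf": round(r.maf, 6), "n_chromosomes": r.n_chromosomes}
            for r in records
        ]
    ).drop_duplicates(subset=["gene", "allele", "rsid"])
    _write_tsv(bundle, "maf", maf_df)
    if ref_records:
        report = comparison_report(records, ref_records)
        report["maf_a"] = report["maf_a"].round(6)
        report["p"] = report["p"].round(6)
        _write_tsv(bundle, "maf_comparison", report.drop_duplicates(subset=["gene", "allele"]))


@_stage("exposures")
def _exposure_stage(config, catalog, bundle, phenotypes_by_gene) -> None:
    if catalog.consumption is None:
        raise ValueError("missing consumption table")
    records = consumption_records(catalog.consumption)

    printed = build_exposure_table(catalog, "printed", config.use_fixture_total)
    _write_tsv(bundle, "exposures", exposure_table_frame(printed))
    derived = build_exposure_table(catalog, "derived", config.use_fixture_total)
    _write_tsv(bundle, "exposures_derived", exposure_table_frame(derived))

    if phenotypes_by_gene:
        fractions = {}
        for it in catalog.interactions:
            fractions[it.row_id] = cohort_actionable_fraction(
                phenotypes_by_gene, it.genes, it.actionable_set
            )
        cohort_based = build_exposure_table(catalog, fractions, config.use_fixture_total)
        _write_tsv(bundle, "exposures_cohort", exposure_table_frame(cohort_based))

    shares = class_shares(records)
    _write_tsv(
        bundle, "class_shares",
        pd.DataFrame(
            [{"therapeutic_area": k, "share_pct": round(v, 4)} for k, v in shares.items()]
        ),
    )

    if catalog.strata is not None:
        parts = []
        year_list = sorted(catalog.strata["year"].unique())
        for years in [(y,) for y in year_list] + [tuple(year_list)]:
            s = stratify_usage(catalog.strata, years)
            for sex in s.users_by_sex:
                parts.append(
                    {"years": "+".join(map(str, years)), "margin": "sex", "group": sex,
                     "users": s.users_by_sex[sex], "share_pct": round(s.sex_share_pct[sex], 4)}
                )
            for band in s.users_by_age:
                parts.append(
                    {"years": "+".join(map(str, years)), "margin": "age", "group": band,
                     "users": s.users_by_age[band], "share_pct": round(s.age_share_pct[band], 4)}
                )
            parts.append(
                {"years": "+".join(map(str, years)), "margin": "age", "group": "45+",
                 "users": sum(s.users_by_age[b] for b in ("45-64", "65-74", "75+")),
                 "share_pct": round(s.share_45plus_pct, 4)}
            )
        _write_tsv(bundle, "stratification", pd.DataFrame(parts))

    total_exposures = sum(it.exposures for it in catalog.interactions)
    users = ancestry_adjust(
        catalog.reference.get("insured_population", 0.0),
        catalog.reference.get("european_ancestry_fraction", 0.85),
    )
    risky = {e.row_id: e.risky_exposures for e in printed}
    share_map = gene_shares(
        risky,
        int(catalog.reference["total_risky_printed"]) if config.use_fixture_total else None,
    )
    summary = {
        "total_exposures": total_exposures,
        "users_european_ancestry": users,
        "exposures_per_user": exposures_per_user(total_exposures, users) if users else None,
        "total_risky_computed": sum(risky.values()),
        "total_risky_printed": int(catalog.reference.get("total_risky_printed", 0)),
        "pgx_prescription_share_pct": round(
            pgx_prescription_share(records, catalog.reference["total_prescribed_thousands"]), 4
        ),
        "panel": list(DEFAULT_PANEL),
        "panel_coverage_pct": round(panel_coverage(share_map, DEFAULT_PANEL), 4),
    }
    bundle.summary = summary
    path = bundle.out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    bundle.files["summary"] = path


def _write_tsv(bundle: ReportBundle, name: str, df: pd.DataFrame) -> None:
    path = bundle.out_dir / f"{name}.tsv"
    df.to_csv(path, sep="\t", index=False)
    bundle.files[name] = path


@_stage("manifest")
def _write_manifest(config: PipelineConfig, bundle: ReportBundle) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "version": __version__,
        "python": platform.python_version(),
        "created": datetime.now(timezone.utc).isoformat(),
        "outputs": {
            name: {"path": p.name, "sha256": _sha256(p),
                   "rows": max(0, sum(1 for _ in p.open()) - 1) if p.suffix == ".tsv" else None}
            for name, p in sorted(bundle.files.items())
        },
    }
    path = bundle.out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle.files["manifest"] = path
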