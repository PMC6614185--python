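"""Reference catalog: pharmacogene allele definitions, phenotype rules, and
drug-gene interactions.

The catalog is the static knowledge base of the analysis: for each of the 14
pharmacogenes / HLA haplo-groups it stores the defining variants of every star
allele (or tag haplotype), the allele's functional status, its haplotype
frequency in the Dutch reference cohort, a per-gene diplotype-to-phenotype
rule table, and the drug-gene interaction rows with their actionable
phenotype sets.  Everything is plain TSV so the tables can be audited and
round-tripped field-for-field.

Nested allele definitions store *haplotype* frequencies, not per-SNP minor
allele frequencies: CYP2D6 *4 carries both rs3892097 and rs1065852, so the
*10 haplotype (rs1065852 alone) keeps only the residual mass; likewise TPMT
*3A versus *3B/*3C.  Per-SNP frequencies then emerge as marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: closed set of allele functional statuses
FUNCTIONS = frozenset(
    {"normal", "decreased", "inactive", "increased", "risk-tag", "non-carrier"}
)

#: activity weight per function, used by the caller's conservative tie-break
ACTIVITY = {
    "inactive": 0.0,
    "risk-tag": 0.0,
    "decreased": 0.5,
    "non-carrier": 1.0,
    "normal": 1.0,
    "increased": 1.5,
}

GENE_CATEGORIES = frozenset({"enzyme", "transporter", "carrier", "sensitivity"})

REQUIRED_FILES = (
    "genes.tsv",
    "alleles.tsv",
    "phenotype_rules.tsv",
    "interactions.tsv",
    "sites.tsv",
    "phenotype_frequencies.tsv",
    "drug_groups.tsv",
)

OPTIONAL_FILES = ("consumption.tsv", "strata.tsv", "reference.tsv", "variants_reference.tsv")


class CatalogError(ValueError):
    """Raised when catalog tables fail validation; carries every violation."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "catalog validation failed with %d error(s):\n  - %s"
            % (len(self.errors), "\n  - ".join(self.errors))
        )


@dataclass(frozen=True)
class VariantSite:
    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    change_label: str = ""


@dataclass(frozen=True)
class VariantDef:
    rsid: str
    risk_allele: str
    change_label: str = ""


@dataclass(frozen=True)
class AlleleDefinition:
    gene: str
    star_name: str
    defining_variants: tuple[VariantDef, ...]
    function: str
    frequency: float

    @property
    def risk_rsids(self) -> frozenset[str]:
        return frozenset(v.rsid for v in self.defining_variants)

    @property
    def is_reference(self) -> bool:
        return len(self.defining_variants) == 0


def pair_key(f1: str, f2: str) -> str:
    return "|".join(sorted((f1, f2)))


@dataclass
class GeneModel:
    """A pharmacogene: its alleles and the diplotype-to-phenotype rule."""

    gene: str
    category: str
    reference_allele: str
    reference_function: str
    cn_aware: bool
    alleles: tuple[AlleleDefinition, ...]  # variant alleles only
    #: (function pair key, copy-number condition "any"/"gt2") -> phenotype
    phenotype_rule: dict[tuple[str, str], str]

    @property
    def reference(self) -> AlleleDefinition:
        return AlleleDefinition(
            gene=self.gene,
            star_name=self.reference_allele,
            defining_variants=(),
            function=self.reference_function,
            frequency=max(0.0, 1.0 - sum(a.frequency for a in self.alleles)),
        )

    @property
    def all_alleles(self) -> tuple[AlleleDefinition, ...]:
        return (self.reference,) + self.alleles

    @property
    def defining_rsids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a in self.alleles:
            for v in a.defining_variants:
                if v.rsid not in seen:
                    seen.append(v.rsid)
        return tuple(seen)

    @property
    def functions(self) -> frozenset[str]:
        return frozenset(a.function for a in self.all_alleles)

    @property
    def phenotype_labels(self) -> frozenset[str]:
        return frozenset(self.phenotype_rule.values())

    @property
    def is_carrier_gene(self) -> bool:
        return self.category == "carrier"

    def phenotype_for(self, f1: str, f2: str, copy_number: int = 2) -> str:
        """Phenotype for an unordered pair of allele functions at a copy number."""
        key = pair_key(f1, f2)
        if copy_number > 2 and ((key, "gt2") in self.phenotype_rule):
            return self.phenotype_rule[(key, "gt2")]
        return self.phenotype_rule[(key, "any")]


@dataclass(frozen=True)
class DrugGeneInteraction:
    """One Table-4-style interaction row.

    A row may span more than one gene (the carbamazepine row is annotated
    against both HLA-A*31:01 and HLA-B*15:02); ``actionable_set`` applies to
    every listed gene.  Printed reference values (actionable percentage,
    risky exposures, share) are kept verbatim for comparison; rows whose
    printed actionable percentage is not derivable from the phenotype
    frequency table are flagged ``column_a_derivable=False``.
    """

    row_id: str
    genes: tuple[str, ...]
    drugs: tuple[str, ...]
    actionable_set: frozenset[str]
    therapeutic_area: str
    exposures: int
    column_a_printed_pct: float
    risky_printed: int
    share_printed_pct: float
    column_a_derivable: bool


@dataclass
class Catalog:
    genes: dict[str, GeneModel]
    interactions: list[DrugGeneInteraction]
    sites: dict[str, VariantSite]
    drug_groups: dict[str, tuple[str, ...]]
    phenotype_frequencies: dict[str, dict[str, float]]
    consumption: pd.DataFrame | None = None
    strata: pd.DataFrame | None = None
    reference: dict[str, float] = field(default_factory=dict)
    variants_reference: pd.DataFrame | None = None

    def gene(self, name: str) -> GeneModel:
        return self.genes[name]

    def interaction(self, row_id: str) -> DrugGeneInteraction:
        for it in self.interactions:
            if it.row_id == row_id:
                return it
        raise KeyError(row_id)

    def actionable_union(self, gene: str) -> frozenset[str]:
        """Union of actionable phenotype sets over all interactions of a gene."""
        out: set[str] = set()
        for it in self.interactions:
            if gene in it.genes:
                out |= it.actionable_set
        return frozenset(out)


def default_data_dir() -> Path:
    return Path(resources.files("pgx_exposure") / "data")


def _read(path: Path, name: str) -> pd.DataFrame:
    return pd.read_csv(path / name, sep="\t", dtype=str, keep_default_na=False)


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load and validate the catalog from a directory of TSV tables.

    With no argument the packaged default tables are used.  Raises
    :class:`CatalogError` enumerating *every* violation found, not only the
    first.
    """
    path = default_data_dir() if path is None else Path(path)
    errors: list[str] = []

    missing = [f for f in REQUIRED_FILES if not (path / f).is_file()]
    if missing:
        raise CatalogError([f"required file missing: {f}" for f in sorted(missing)])

    sites_df = _read(path, "sites.tsv")
    genes_df = _read(path, "genes.tsv")
    alleles_df = _read(path, "alleles.tsv")
    rules_df = _read(path, "phenotype_rules.tsv")
    inter_df = _read(path, "interactions.tsv")
    freqs_df = _read(path, "phenotype_frequencies.tsv")
    groups_df = _read(path, "drug_groups.tsv")

    sites: dict[str, VariantSite] = {}
    for _, r in sites_df.iterrows():
        if r["rsid"] in sites:
            errors.append(f"duplicate site rsid {r['rsid']}")
        sites[r["rsid"]] = VariantSite(
            rsid=r["rsid"], chrom=r["chrom"], pos=int(r["pos"]),
            ref=r["ref"], alt=r["alt"], change_label=r.get("change_label", ""),
        )

    rules: dict[str, dict[tuple[str, str], str]] = {}
    for _, r in rules_df.iterrows():
        rules.setdefault(r["gene"], {})[(r["function_pair"], r["copy_number"])] = r["phenotype"]

    genes: dict[str, GeneModel] = {}
    for _, g in genes_df.iterrows():
        name = g["gene"]
        if g["category"] not in GENE_CATEGORIES:
            errors.append(f"{name}: unknown category {g['category']!r}")
        rows = alleles_df[alleles_df["gene"] == name]
        defs: list[AlleleDefinition] = []
        for _, a in rows.iterrows():
            rsids = a["rsids"].split(";")
            bases = a["risk_alleles"].split(";")
            if len(rsids) != len(bases):
                errors.append(f"{name} {a['star_name']}: rsids/risk_alleles length mismatch")
                continue
            if len(set(rsids)) != len(rsids):
                errors.append(f"{name} {a['star_name']}: duplicate rsid in definition")
            variants = []
            for rsid, base in zip(rsids, bases):
                if not rsid:
                    errors.append(f"{name} {a['star_name']}: empty rsid")
                site = sites.get(rsid)
                if site is None:
                    errors.append(f"{name} {a['star_name']}: rsid {rsid} not in sites.tsv")
                elif site.alt != base:
                    errors.append(
                        f"{name} {a['star_name']}: risk allele {base} != site alt {site.alt} for {rsid}"
                    )
                if not (set(base) <= set("ACGT")):
                    errors.append(f"{name} {a['star_name']}: invalid risk allele {base!r}")
                variants.append(
                    VariantDef(rsid=rsid, risk_allele=base,
                               change_label=site.change_label if site else "")
                )
            func = a["function"]
            if func not in FUNCTIONS:
                errors.append(f"{name} {a['star_name']}: unknown function {func!r}")
            freq = float(a["frequency"])
            if not (0.0 <= freq <= 1.0):
                errors.append(f"{name} {a['star_name']}: frequency {freq} outside [0,1]")
            defs.append(AlleleDefinition(name, a["star_name"], tuple(variants), func, freq))

        total = sum(a.frequency for a in defs)
        if total > 1.0 + 1e-9:
            errors.append(f"{name}: variant allele frequencies sum to {total:.4f} > 1")
        if g["reference_function"] not in FUNCTIONS:
            errors.append(f"{name}: unknown reference function {g['reference_function']!r}")

        model = GeneModel(
            gene=name,
            category=g["category"],
            reference_allele=g["reference_allele"],
            reference_function=g["reference_function"],
            cn_aware=g.get("cn_aware", "0") == "1",
            alleles=tuple(defs),
            phenotype_rule=rules.get(name, {}),
        )
        # rule table must be total over unordered pairs of present functions
        funcs = sorted(model.functions)
        for i, f1 in enumerate(funcs):
            for f2 in funcs[i:]:
                if (pair_key(f1, f2), "any") not in model.phenotype_rule:
                    errors.append(f"{name}: phenotype rule missing pair {pair_key(f1, f2)}")
        genes[name] = model

    extra_rule_genes = set(rules) - set(genes)
    for name in sorted(extra_rule_genes):
        errors.append(f"phenotype rule for unknown gene {name}")

    interactions: list[DrugGeneInteraction] = []
    for _, r in inter_df.iterrows():
        gene_list = tuple(r["genes"].split(";"))
        act = frozenset(r["actionable_set"].split("+"))
        if not act or act == {""}:
            errors.append(f"interaction {r['row_id']}: empty actionable set")
        for gname in gene_list:
            if gname not in genes:
                errors.append(f"interaction {r['row_id']}: unknown gene {gname}")
            else:
                unknown = act - genes[gname].phenotype_labels
                if unknown:
                    errors.append(
                        f"interaction {r['row_id']}: actionable labels {sorted(unknown)} "
                        f"not in {gname} phenotype labels"
                    )
        interactions.append(
            DrugGeneInteraction(
                row_id=r["row_id"],
                genes=gene_list,
                drugs=tuple(r["drugs"].split(";")),
                actionable_set=act,
                therapeutic_area=r["therapeutic_area"],
                exposures=int(r["exposures"]),
                column_a_printed_pct=float(r["column_a_printed_pct"]),
                risky_printed=int(r["risky_printed"]),
                share_printed_pct=float(r["share_printed_pct"]),
                column_a_derivable=r["column_a_derivable"] == "1",
            )
        )

    freqs: dict[str, dict[str, float]] = {}
    for _, r in freqs_df.iterrows():
        freqs.setdefault(r["gene"], {})[r["phenotype"]] = float(r["frequency"])
    for gname, f in freqs.items():
        if gname not in genes:
            errors.append(f"phenotype frequencies for unknown gene {gname}")
            continue
        bad = set(f) - genes[gname].phenotype_labels
        if bad:
            errors.append(f"{gname}: phenotype frequency labels {sorted(bad)} not in rule table")
        total = sum(f.values())
        if abs(total - 1.0) > 0.002:
            errors.append(f"{gname}: phenotype frequencies sum to {total:.4f}, not 1 +/- 0.002")
    missing_freq = set(genes) - set(freqs)
    for gname in sorted(missing_freq):
        errors.append(f"{gname}: no phenotype frequencies")

    groups: dict[str, tuple[str, ...]] = {}
    for grp, sub in groups_df.groupby("group", sort=False):
        groups[grp] = tuple(sub["member"])

    consumption = _read(path, "consumption.tsv") if (path / "consumption.tsv").is_file() else None
    strata = _read(path, "strata.tsv") if (path / "strata.tsv").is_file() else None
    varref = (
        _read(path, "variants_reference.tsv")
        if (path / "variants_reference.tsv").is_file() else None
    )
    reference: dict[str, float] = {}
    if (path / "reference.tsv").is_file():
        for _, r in _read(path, "reference.tsv").iterrows():
            reference[r["key"]] = float(r["value"])

    if consumption is not None:
        known_drugs = {d for it in interactions for d in it.drugs}
        member_of = {m: grp for grp, members in groups.items() for m in members}
        covered = known_drugs | {member_of.get(d, d) for d in known_drugs} | set(groups)
        for drug in consumption["drug"]:
            if drug not in covered:
                errors.append(f"consumption drug {drug!r} maps to no interaction")

    if errors:
        raise CatalogError(errors)

    cat = Catalog(
        genes=genes,
        interactions=interactions,
        sites=sites,
        drug_groups=groups,
        phenotype_frequencies=freqs,
        consumption=consumption,
        strata=strata,
        reference=reference,
        variants_reference=varref,
    )
    if consumption is not None:
        cat.consumption = consumption.assign(
            items_issued_thousands=consumption["items_issued_thousands"].astype(float)
        )
    if strata is not None:
        cat.strata = strata.assign(
            year=strata["year"].astype(int), users=strata["users"].astype(int)
        )
    return cat


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write the catalog back to a directory of TSVs (round-trip stable)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def _fmt_freq(x: float) -> str:
        return f"{x:g}"

    rows = [
        {
            "rsid": s.rsid, "chrom": s.chrom, "pos": s.pos,
            "ref": s.ref, "alt": s.alt, "change_label": s.change_label,
        }
        for s in catalog.sites.values()
    ]
    pd.DataFrame(rows).to_csv(path / "sites.tsv", sep="\t", index=False)

    grows, arows, rrows = [], [], []
    for g in catalog.genes.values():
        grows.append(
            {"gene": g.gene, "category": g.category, "reference_allele": g.reference_allele,
             "reference_function": g.reference_function, "cn_aware": int(g.cn_aware)}
        )
        for a in g.alleles:
            arows.append(
                {"gene": g.gene, "star_name": a.star_name,
                 "rsids": ";".join(v.rsid for v in a.defining_variants),
                 "risk_alleles": ";".join(v.risk_allele for v in a.defining_variants),
                 "function": a.function, "frequency": _fmt_freq(a.frequency)}
            )
        for (pair, cn), label in g.phenotype_rule.items():
            rrows.append({"gene": g.gene, "function_pair": pair, "copy_number": cn,
                          "phenotype": label})
    pd.DataFrame(grows).to_csv(path / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(arows).to_csv(path / "alleles.tsv", sep="\t", index=False)
    pd.DataFrame(rrows).to_csv(path / "phenotype_rules.tsv", sep="\t", index=False)

    irows = [
        {"row_id": it.row_id, "genes": ";".join(it.genes), "drugs": ";".join(it.drugs),
         "actionable_set": "+".join(sorted(it.actionable_set)),
         "therapeutic_area": it.therapeutic_area, "exposures": it.exposures,
         "column_a_printed_pct": it.column_a_printed_pct, "risky_printed": it.risky_printed,
         "share_printed_pct": it.share_printed_pct,
         "column_a_derivable": int(it.column_a_derivable)}
        for it in catalog.interactions
    ]
    pd.DataFrame(irows).to_csv(path / "interactions.tsv", sep="\t", index=False)

    frows = [
        {"gene": g, "phenotype": label, "frequency": _fmt_freq(f)}
        for g, d in catalog.phenotype_frequencies.items()
        for label, f in d.items()
    ]
    pd.DataFrame(frows).to_csv(path / "phenotype_frequencies.tsv", sep="\t", index=False)

    growp = [{"group": grp, "member": m} for grp, ms in catalog.drug_groups.items() for m in ms]
    pd.DataFrame(growp).to_csv(path / "drug_groups.tsv", sep="\t", index=False)

    if catalog.consumption is not None:
        catalog.consumption.to_csv(path / "consumption.tsv", sep="\t", index=False)
    if catalog.strata is not None:
        catalog.strata.to_csv(path / "strata.tsv", sep="\t", index=False)
    if catalog.reference:
        pd.DataFrame(
            [{"key": k, "value": f"{v:g}"} for k, v in catalog.reference.items()]
        ).to_csv(path / "reference.tsv", sep="\t", index=False)
    if catalog.variants_reference is not None:
        catalog.variants_reference.to_csv(path / "variants_reference.tsv", sep="\t", index=False)


def actionable_fraction(
    phenotype_freqs: Mapping[str, float],
    actionable_set: Iterable[str],
    *,
    gene: str | None = None,
    tolerance: float = 1e-6,
) -> float:
    """Sum of phenotype frequencies over an actionable phenotype set.

    This is "Column A" of the exposure model: the fraction of the population
    predicted to carry an actionable genotype for a drug-gene interaction.
    """
    label = f" for {gene}" if gene else ""
    actionable = set(actionable_set)
    if not actionable:
        raise ValueError(f"empty actionable set{label}")
    for v in phenotype_freqs.values():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"phenotype frequency {v} outside [0,1]{label}")
    total = sum(phenotype_freqs.values())
    if total > 1.0 + 0.01:
        raise ValueError(f"phenotype frequencies sum to {total:.4f} > 1{label}")
    missing = actionable - set(phenotype_freqs)
    if missing:
        raise KeyError(f"labels {sorted(missing)} absent from phenotype frequencies{label}")
    out = sum(phenotype_freqs[k] for k in actionable)
    return min(1.0, out) if out <= 1.0 + tolerance else out


def multi_gene_actionable_fraction(
    catalog: Catalog, interaction: DrugGeneInteraction
) -> float:
    """Fraction actionable for at least one gene of an interaction row.

    Genes are treated as independent, so the carrier-of-any probability is
    1 - prod(1 - f_g) over the row's genes; for single-gene rows this reduces
    to :func:`actionable_fraction` on that gene.
    """
    miss = 1.0
    for gname in interaction.genes:
        f = actionable_fraction(
            catalog.phenotype_frequencies[gname], interaction.actionable_set, gene=gname
        )
        miss *= 1.0 - f
    return 1.0 - miss


def hwe_phenotype_check(catalog: Catalog) -> pd.DataFrame:
    """Tabulate stored phenotype-frequency sums per gene (diagnostic)."""
    rows = [
        {"gene": g, "sum": math.fsum(freqs.values()), "n_labels": len(freqs)}
        for g, freqs in catalog.phenotype_frequencies.items()
    ]
    return pd.DataFrame(rows)
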