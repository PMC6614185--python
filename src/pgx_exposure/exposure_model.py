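"""Drug-utilization exposure model: risky exposures, gene and class shares,
panel coverage, and demographic stratification.

The headline quantity is the "risky exposure": an exposure of a drug user
predicted to carry an actionable genotype for that drug's interacting gene,
estimated as actionable fraction x exposures ("Column A x Column B").  An
exposure is one distinct drug-user pair over the study window; repeat
prescriptions of the same drug to the same user count once.

Rounding convention: a risky-exposure product is rounded to one decimal and
then to the nearest integer, half away from zero, mirroring the reporting
convention of the source consumption tables (this reproduces every
exactly-derivable published row; a single rounding step does not).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import Catalog, DrugGeneInteraction, multi_gene_actionable_fraction

AGE_BANDS = ("0-4", "5-14", "15-24", "25-44", "45-64", "65-74", "75+")
SEXES = ("men", "women")


@dataclass(frozen=True)
class DrugConsumptionRecord:
    drug: str
    therapeutic_area: str
    items_issued_thousands: float
    users: int | None = None
    exposures: int | None = None

    def __post_init__(self) -> None:
        if self.items_issued_thousands < 0:
            raise ValueError(f"{self.drug}: negative issuance")
        if self.users is not None and self.users < 0:
            raise ValueError(f"{self.drug}: negative users")
        if self.exposures is not None and self.exposures < 0:
            raise ValueError(f"{self.drug}: negative exposures")


@dataclass(frozen=True)
class ExposureEstimate:
    row_id: str
    genes: tuple[str, ...]
    drugs: tuple[str, ...]
    exposures: int
    actionable_fraction: float
    risky_exposures: int
    share_of_risky_pct: float


def risky_exposures(actionable_fraction: float, exposures: int) -> int:
    """Round(actionable fraction x exposures): one decimal, then integer,
    half away from zero at both steps."""
    if not (0.0 <= actionable_fraction <= 1.0):
        raise ValueError(f"actionable fraction {actionable_fraction} outside [0,1]")
    if exposures < 0:
        raise ValueError("negative exposures")
    product = Decimal(repr(actionable_fraction)) * Decimal(exposures)
    one_dp = product.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return int(one_dp.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def gene_shares(
    risky_by_row: Mapping[str, int], total_risky: int | None = None
) -> dict[str, float]:
    """Percentage of total risky exposures per gene row."""
    if total_risky is None:
        total_risky = sum(risky_by_row.values())
    if total_risky <= 0:
        raise ValueError("total risky exposures must be positive")
    return {k: 100.0 * v / total_risky for k, v in risky_by_row.items()}


def panel_coverage(shares_pct: Mapping[str, float], panel: Iterable[str]) -> float:
    """Share of risky exposures covered by a testing panel (sum of shares)."""
    panel = set(panel)
    unknown = panel - set(shares_pct)
    if unknown:
        raise KeyError(f"panel genes {sorted(unknown)} not in share table")
    return sum(shares_pct[g] for g in panel)


def class_shares(records: Sequence[DrugConsumptionRecord]) -> dict[str, float]:
    """Therapeutic-class issuance shares (percent of raw thousands issued)."""
    if not records:
        raise ValueError("no consumption records")
    totals: dict[str, float] = {}
    for r in records:
        totals[r.therapeutic_area] = totals.get(r.therapeutic_area, 0.0) + r.items_issued_thousands
    grand = sum(totals.values())
    return {k: 100.0 * v / grand for k, v in sorted(totals.items())}


def drug_issuance_shares(records: Sequence[DrugConsumptionRecord]) -> dict[str, float]:
    grand = sum(r.items_issued_thousands for r in records)
    return {r.drug: 100.0 * r.items_issued_thousands / grand for r in records}


def exposures_per_user(total_exposures: int, n_users: float) -> float:
    """Average exposures per drug user, at the 1-decimal reporting precision."""
    if n_users <= 0:
        raise ValueError("n_users must be positive")
    return float(
        (Decimal(total_exposures) / Decimal(repr(n_users))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def ancestry_adjust(count: float, fraction_kept: float = 0.85) -> int:
    """Restrict a population count to the genetically characterised ancestry
    stratum (85% of Dutch residents are of European ancestry)."""
    if not (0.0 <= fraction_kept <= 1.0):
        raise ValueError(f"fraction {fraction_kept} outside [0,1]")
    return int(
        (Decimal(repr(count)) * Decimal(repr(fraction_kept))).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def consumption_records(df: pd.DataFrame) -> list[DrugConsumptionRecord]:
    return [
        DrugConsumptionRecord(
            drug=r["drug"],
            therapeutic_area=str(r["therapeutic_area"]).lower(),
            items_issued_thousands=float(r["items_issued_thousands"]),
            users=int(r["users"]) if "users" in df.columns and str(r["users"]) != "" else None,
        )
        for _, r in df.iterrows()
    ]


def pgx_prescription_share(
    records: Sequence[DrugConsumptionRecord], total_prescribed_thousands: float
) -> float:
    """Percent of all prescriptions that are pharmacogenetic drugs."""
    issued = sum(r.items_issued_thousands for r in records)
    return 100.0 * issued / total_prescribed_thousands


def build_exposure_table(
    catalog: Catalog,
    column_a: str | Mapping[str, float] = "printed",
    use_fixture_total: bool = False,
) -> list[ExposureEstimate]:
    """Assemble the per-gene risky-exposure table.

    ``column_a`` selects the actionable-fraction source: ``"printed"`` uses
    the published percentages verbatim; ``"derived"`` recomputes them from
    the phenotype-frequency table where derivable (the two documented
    non-derivable rows keep their printed value); a mapping supplies
    cohort-estimated fractions keyed by interaction row id.
    ``use_fixture_total`` divides shares by the published total instead of
    the computed sum (the two differ in the source tables).
    """
    fractions: dict[str, float] = {}
    for it in catalog.interactions:
        if isinstance(column_a, Mapping):
            fractions[it.row_id] = float(column_a[it.row_id])
        elif column_a == "printed":
            fractions[it.row_id] = it.column_a_printed_pct / 100.0
        elif column_a == "derived":
            if it.column_a_derivable:
                fractions[it.row_id] = multi_gene_actionable_fraction(catalog, it)
            else:
                fractions[it.row_id] = it.column_a_printed_pct / 100.0
        else:
            raise ValueError(f"unknown column_a source {column_a!r}")

    risky = {it.row_id: risky_exposures(fractions[it.row_id], it.exposures)
             for it in catalog.interactions}
    total = (
        int(catalog.reference["total_risky_printed"])
        if use_fixture_total
        else sum(risky.values())
    )
    shares = gene_shares(risky, total)
    return [
        ExposureEstimate(
            row_id=it.row_id, genes=it.genes, drugs=it.drugs, exposures=it.exposures,
            actionable_fraction=fractions[it.row_id], risky_exposures=risky[it.row_id],
            share_of_risky_pct=shares[it.row_id],
        )
        for it in catalog.interactions
    ]


def exposure_table_frame(estimates: Sequence[ExposureEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"row_id": e.row_id, "genes": ";".join(e.genes), "drugs": ";".join(e.drugs),
             "exposures": e.exposures, "actionable_fraction": e.actionable_fraction,
             "risky_exposures": e.risky_exposures, "share_of_risky_pct": e.share_of_risky_pct}
            for e in estimates
        ]
    )


@dataclass
class UsageStratification:
    """Sex and age-band margins of the stratified usage table."""

    years: tuple[int, ...]
    users_by_sex: dict[str, int]
    sex_share_pct: dict[str, float]
    users_by_age: dict[str, int]
    age_share_pct: dict[str, float]
    share_45plus_pct: float
    table: pd.DataFrame  # sex x age_band user counts over the selected years


def stratify_usage(strata: pd.DataFrame, years: Sequence[int] | None = None) -> UsageStratification:
    """Margins of the (year, sex, age band) usage table.

    The "45+" aggregate is the sum of the three oldest bands.  Band labels
    come from the closed seven-group set of the source databank.
    """
    df = strata.copy()
    bad_bands = set(df["age_band"]) - set(AGE_BANDS)
    if bad_bands:
        raise ValueError(f"unknown age bands {sorted(bad_bands)}")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sexes {sorted(bad_sex)}")
    if (df["users"] < 0).any():
        raise ValueError("negative user counts")
    if years is not None:
        missing = set(years) - set(df["year"])
        if missing:
            raise ValueError(f"years {sorted(missing)} absent from strata")
        df = df[df["year"].isin(list(years))]
        years = tuple(sorted(years))
    else:
        years = tuple(sorted(df["year"].unique()))

    pivot = df.pivot_table(index="sex", columns="age_band", values="users", aggfunc="sum")
    pivot = pivot.reindex(index=list(SEXES), columns=list(AGE_BANDS)).fillna(0).astype(int)
    total = int(pivot.values.sum())
    if total == 0:
        raise ValueError("empty stratification")
    by_sex = {s: int(pivot.loc[s].sum()) for s in SEXES}
    by_age = {b: int(pivot[b].sum()) for b in AGE_BANDS}
    over45 = sum(by_age[b] for b in ("45-64", "65-74", "75+"))
    return UsageStratification(
        years=years,
        users_by_sex=by_sex,
        sex_share_pct={s: 100.0 * v / total for s, v in by_sex.items()},
        users_by_age=by_age,
        age_share_pct={b: 100.0 * v / total for b, v in by_age.items()},
        share_45plus_pct=100.0 * over45 / total,
        table=pivot,
    )
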