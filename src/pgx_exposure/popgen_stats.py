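"""Allele-frequency estimation, Hardy-Weinberg expectations, and two-cohort
minor-allele-frequency comparison tests.

The comparison test is a two-proportion chi-square on allele counts (no
continuity correction), with Fisher's exact test as an option and as the
automatic fall-back when a chi-square expected cell is empty.  The original
study names no test and its printed p-values are kept as reference metadata
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes_io import CohortGenotypes


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    gene: str
    star_name: str
    rsid: str
    maf: float
    n_chromosomes: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf {self.maf} outside [0,1]")
        if self.n_chromosomes <= 0 or self.n_chromosomes % 2:
            raise ValueError(f"n_chromosomes {self.n_chromosomes} not even and positive")

    @property
    def allele_count(self) -> int:
        return int(round(self.maf * self.n_chromosomes))


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    method: str  # "chi-square" or "fisher"; fisher may be a noted fall-back
    fell_back: bool = False


def estimate_maf(
    cohort: CohortGenotypes,
    rsid: str,
    gene: str = "",
    star_name: str = "",
    source: str = "cohort",
) -> AlleleFrequencyRecord:
    """Risk-allele frequency: dosage sum over twice the non-missing samples."""
    dos = cohort.dosage(rsid)
    called = dos[dos >= 0]
    if called.size == 0:
        raise ValueError(f"{rsid}: all genotypes missing")
    return AlleleFrequencyRecord(
        gene=gene, star_name=star_name, rsid=rsid,
        maf=float(called.sum()) / (2 * called.size),
        n_chromosomes=2 * int(called.size), source=source,
    )


def hwe_genotype_freqs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype fractions ((1-q)^2, 2q(1-q), q^2).

    Sums to 1 up to one unit in the last place (exactly, at the boundary
    frequencies 0, 1/2 and 1).
    """
    if not (0.0 <= maf <= 1.0):
        raise ValueError(f"maf {maf} outside [0,1]")
    q = maf
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def compare_maf(
    rec_a: AlleleFrequencyRecord,
    rec_b: AlleleFrequencyRecord,
    method: str = "chi-square",
) -> ComparisonResult:
    """Two-proportion test on allele counts between two cohorts.

    Symmetric in its arguments; p-value in [0,1].  With ``chi-square`` and an
    empty expected cell the test falls back to Fisher's exact test and says
    so in the result.
    """
    if method not in ("chi-square", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    a_alt, b_alt = rec_a.allele_count, rec_b.allele_count
    table = np.array(
        [[a_alt, rec_a.n_chromosomes - a_alt], [b_alt, rec_b.n_chromosomes - b_alt]]
    )
    fell_back = False
    if method == "chi-square":
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            method, fell_back = "fisher", True
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
            return ComparisonResult(float(min(p, 1.0)), "chi-square")
    _, p = stats.fisher_exact(table)
    return ComparisonResult(float(min(p, 1.0)), "fisher", fell_back)


def comparison_report(records_a, records_b, method: str = "chi-square"):
    """Pairwise MAF comparison table for records matched on (gene, star, rsid)."""
    import pandas as pd

    index_b = {(r.gene, r.star_name, r.rsid): r for r in records_b}
    rows = []
    for ra in records_a:
        rb = index_b.get((ra.gene, ra.star_name, ra.rsid))
        if rb is None:
            continue
        res = compare_maf(ra, rb, method=method)
        rows.append(
            {"gene": ra.gene, "allele": ra.star_name, "rsid": ra.rsid,
             "maf_a": ra.maf, "maf_b": rb.maf, "p": res.p_value,
             "method": res.method + ("(fallback)" if res.fell_back else "")}
        )
    return pd.DataFrame(rows)
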