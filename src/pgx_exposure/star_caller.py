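"""Assign per-sample star-allele diplotypes from variant genotypes.

Phased data are matched haplotype-by-haplotype against the catalog's
defining-variant sets (exact match or no-call).  Unphased dosages are
resolved by enumerating every allele pair consistent with the observed
risk-allele dosages and applying a deterministic precedence:

1. fewest distinct non-reference alleles,
2. lowest combined allele activity (conservative: flags more actionable
   carriers),
3. lexicographic star-name order.

Defining-variant sets are exhaustive: a dosage pattern no catalog allele
pair explains is a no-call, never a guess.  Missing genotypes at any
defining variant propagate to a no-call.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping, Optional

import numpy as np

from .catalog import ACTIVITY, AlleleDefinition, GeneModel
from .genotypes_io import MISSING, CohortGenotypes

EXACT = "exact"
RESOLVED_UNPHASED = "resolved-unphased"
NO_CALL = "no-call"


@dataclass(frozen=True)
class Diplotype:
    gene: str
    allele_1: Optional[str]
    allele_2: Optional[str]
    copy_number: int = 2
    call_quality: str = EXACT

    @property
    def is_no_call(self) -> bool:
        return self.call_quality == NO_CALL

    def alleles(self) -> tuple[Optional[str], Optional[str]]:
        return (self.allele_1, self.allele_2)


def _pair_dosage(a: AlleleDefinition, b: AlleleDefinition, rsid: str) -> int:
    return int(rsid in a.risk_rsids) + int(rsid in b.risk_rsids)


def _pair_sort_key(
    gene: GeneModel, pair: tuple[AlleleDefinition, AlleleDefinition]
) -> tuple[int, float, tuple[str, str]]:
    nonref = {a.star_name for a in pair if not a.is_reference}
    activity = sum(ACTIVITY[a.function] for a in pair)
    return (len(nonref), activity, tuple(sorted(a.star_name for a in pair)))


def _ordered_names(pair: tuple[AlleleDefinition, AlleleDefinition]) -> tuple[str, str]:
    # non-reference allele first; ties broken lexicographically
    a, b = pair
    if a.is_reference and not b.is_reference:
        a, b = b, a
    elif a.is_reference == b.is_reference and b.star_name < a.star_name:
        a, b = b, a
    return (a.star_name, b.star_name)


def enumerate_consistent_pairs(
    dosages: Mapping[str, int], gene: GeneModel
) -> list[tuple[AlleleDefinition, AlleleDefinition]]:
    """All unordered allele pairs whose summed risk sets equal the dosages."""
    out = []
    for a, b in combinations_with_replacement(gene.all_alleles, 2):
        if all(_pair_dosage(a, b, rsid) == dosages.get(rsid, 0) for rsid in gene.defining_rsids):
            out.append((a, b))
    return out


def resolve_unphased(
    dosages: Mapping[str, int], gene: GeneModel
) -> Optional[tuple[str, str]]:
    """Deterministic allele pair for a complete unphased dosage map.

    Returns None (no-call) when no catalog allele pair explains the
    observed pattern.  Carrier tag haplo-groups defined by two SNPs follow
    the tag rule: both dosages >= 1 is a carrier (Het; Hom when both are 2);
    one positive and one zero dosage is inconsistent, hence no-call.
    """
    if _is_two_snp_tag(gene):
        return _resolve_tag(dosages, gene)
    pairs = enumerate_consistent_pairs(dosages, gene)
    if not pairs:
        return None
    best = min(pairs, key=lambda p: _pair_sort_key(gene, p))
    return _ordered_names(best)


def _is_two_snp_tag(gene: GeneModel) -> bool:
    return (
        gene.is_carrier_gene
        and len(gene.alleles) == 1
        and len(gene.alleles[0].defining_variants) == 2
    )


def _resolve_tag(dosages: Mapping[str, int], gene: GeneModel) -> Optional[tuple[str, str]]:
    tag = gene.alleles[0]
    d = [dosages.get(v.rsid, 0) for v in tag.defining_variants]
    if all(x == 0 for x in d):
        return (gene.reference_allele, gene.reference_allele)
    if all(x >= 1 for x in d):
        if all(x == 2 for x in d):
            return (tag.star_name, tag.star_name)
        return (tag.star_name, gene.reference_allele)
    return None  # e.g. dosage 2 at one tag SNP, 0 at the other


def _match_haplotype(riskset: frozenset[str], gene: GeneModel) -> Optional[AlleleDefinition]:
    for allele in gene.all_alleles:
        if allele.risk_rsids == riskset:
            return allele
    return None


def call_diplotypes(cohort: CohortGenotypes, gene: GeneModel) -> list[Diplotype]:
    """Per-sample diplotype calls for one gene (total over samples).

    Samples whose dosage pattern cannot be explained, or with missing
    genotypes at a defining variant, are returned as no-calls.
    """
    rsids = gene.defining_rsids
    vidx = cohort.variant_index
    present = [r for r in rsids if r in vidx]
    cols = [vidx[r] for r in present]
    n = cohort.n_samples
    cn = cohort.copy_number_for(gene.gene) if gene.cn_aware else np.full(n, 2, dtype=int)

    if not rsids:  # gene with no defining variants: everyone reference
        return [
            Diplotype(gene.gene, gene.reference_allele, gene.reference_allele,
                      int(cn[i]), EXACT)
            for i in range(n)
        ]

    all_present = len(present) == len(rsids)
    phased = all_present and all(bool(cohort.phased[j]) for j in cols)
    h1 = cohort.hap1[:, cols] if cols else np.zeros((n, 0), dtype=np.int8)
    h2 = cohort.hap2[:, cols] if cols else np.zeros((n, 0), dtype=np.int8)

    no_call = Diplotype(gene.gene, None, None, 2, NO_CALL)
    calls: list[Diplotype] = []
    cache: dict[tuple, Optional[tuple[str, str, str]]] = {}

    for i in range(n):
        if not all_present or MISSING in h1[i] or MISSING in h2[i]:
            calls.append(no_call)
            continue
        if phased:
            key = ("p",) + tuple(h1[i]) + tuple(h2[i])
        else:
            key = ("u",) + tuple(int(h1[i, k]) + int(h2[i, k]) for k in range(len(present)))
        if key not in cache:
            cache[key] = _call_pattern(key, present, gene)
        res = cache[key]
        if res is None:
            calls.append(no_call)
        else:
            a1, a2, quality = res
            calls.append(Diplotype(gene.gene, a1, a2, int(cn[i]), quality))
    return calls


def _call_pattern(
    key: tuple, rsids: list[str], gene: GeneModel
) -> Optional[tuple[str, str, str]]:
    if key[0] == "p":
        m = len(rsids)
        hap1 = key[1 : 1 + m]
        hap2 = key[1 + m :]
        s1 = frozenset(r for r, v in zip(rsids, hap1) if v == 1)
        s2 = frozenset(r for r, v in zip(rsids, hap2) if v == 1)
        a1 = _match_haplotype(s1, gene)
        a2 = _match_haplotype(s2, gene)
        if a1 is None or a2 is None:
            return None
        return (a1.star_name, a2.star_name, EXACT)
    dosages = dict(zip(rsids, key[1:]))
    if _is_two_snp_tag(gene):
        pair = _resolve_tag(dosages, gene)
        return None if pair is None else (pair[0], pair[1], RESOLVED_UNPHASED)
    pairs = enumerate_consistent_pairs(dosages, gene)
    if not pairs:
        return None
    quality = EXACT if len(pairs) == 1 else RESOLVED_UNPHASED
    best = min(pairs, key=lambda p: _pair_sort_key(gene, p))
    names = _ordered_names(best)
    return (names[0], names[1], quality)


def diplotype_table(cohort: CohortGenotypes, genes: Mapping[str, GeneModel]):
    """Call every gene; returns a tidy DataFrame (sample, gene, alleles, ...)."""
    import pandas as pd

    rows = []
    for gene in genes.values():
        for sample, d in zip(cohort.sample_ids, call_diplotypes(cohort, gene)):
            rows.append(
                {"sample_id": sample, "gene": gene.gene,
                 "allele_1": d.allele_1 or "", "allele_2": d.allele_2 or "",
                 "copy_number": d.copy_number, "call_quality": d.call_quality}
            )
    return pd.DataFrame(rows)
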