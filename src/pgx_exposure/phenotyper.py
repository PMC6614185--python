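"""Diplotype-to-phenotype translation and actionable-genotype aggregation.

Phenotypes follow the catalog's per-gene rule tables (metabolizer classes
N/I/P/U for enzymes, N/I/P sensitivity coding for VKORC1, N/Het/Hom for the
carrier haplo-groups).  A drug-gene interaction flags a sample actionable
when its predicted phenotype falls in the interaction's actionable set; the
per-individual actionable-genotype count k is the number of genes (0..14)
whose phenotype is actionable for at least one interacting drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .catalog import Catalog, GeneModel
from .star_caller import Diplotype


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    gene: str
    phenotype: Optional[str]  # None for a no-call diplotype
    #: interaction row_id -> actionable flag
    actionable: dict = field(default_factory=dict, hash=False, compare=False)


def translate(diplotype: Diplotype, gene: GeneModel) -> Optional[str]:
    """Phenotype label for a diplotype, or None for a no-call."""
    if diplotype.is_no_call:
        return None
    functions = {a.star_name: a.function for a in gene.all_alleles}
    f1 = functions[diplotype.allele_1]
    f2 = functions[diplotype.allele_2]
    cn = diplotype.copy_number if gene.cn_aware else 2
    return gene.phenotype_for(f1, f2, cn)


def phenotype_calls(
    sample_ids: Sequence[str],
    diplotypes: Sequence[Diplotype],
    gene: GeneModel,
    catalog: Catalog | None = None,
) -> list[PhenotypeCall]:
    interactions = (
        [it for it in catalog.interactions if gene.gene in it.genes] if catalog else []
    )
    out = []
    for sample, d in zip(sample_ids, diplotypes):
        label = translate(d, gene)
        flags = {
            it.row_id: (label is not None and label in it.actionable_set)
            for it in interactions
        }
        out.append(PhenotypeCall(sample, gene.gene, label, flags))
    return out


def phenotype_frequencies(
    labels: Sequence[Optional[str]], gene: GeneModel | None = None
) -> dict[str, float]:
    """Fractions per phenotype over non-missing calls (sums to 1)."""
    called = [x for x in labels if x is not None]
    if not called:
        raise ValueError("no non-missing phenotype calls")
    n = len(called)
    out: dict[str, float] = {}
    for x in called:
        out[x] = out.get(x, 0.0) + 1.0
    freqs = {k: v / n for k, v in sorted(out.items())}
    if gene is not None:
        for label in sorted(gene.phenotype_labels - set(freqs)):
            freqs[label] = 0.0
    return freqs


def no_call_count(labels: Sequence[Optional[str]]) -> int:
    return sum(1 for x in labels if x is None)


@dataclass
class CarriageDistribution:
    """Histogram of per-individual actionable-genotype counts."""

    counts: dict[int, int]
    n_total: int

    def fraction(self, k: int) -> float:
        return self.counts.get(k, 0) / self.n_total

    @property
    def fractions(self) -> dict[int, float]:
        return {k: v / self.n_total for k, v in sorted(self.counts.items())}

    def mean(self) -> float:
        return sum(k * v for k, v in self.counts.items()) / self.n_total


def carriage_distribution(
    phenotypes_by_gene: Mapping[str, Sequence[Optional[str]]],
    catalog: Catalog,
) -> CarriageDistribution:
    """Count, per sample, the genes whose phenotype is actionable for >= 1 drug.

    Samples with no-call genes are retained; a missing gene contributes 0 to
    k.  Genes without any drug interaction never contribute.
    """
    genes = list(phenotypes_by_gene)
    if not genes:
        raise ValueError("no genes supplied")
    n = len(next(iter(phenotypes_by_gene.values())))
    for g in genes:
        if len(phenotypes_by_gene[g]) != n:
            raise ValueError(f"gene {g}: sample count mismatch")
    unions = {g: catalog.actionable_union(g) for g in genes}
    counts: dict[int, int] = {}
    for i in range(n):
        k = sum(
            1
            for g in genes
            if phenotypes_by_gene[g][i] is not None and phenotypes_by_gene[g][i] in unions[g]
        )
        counts[k] = counts.get(k, 0) + 1
    return CarriageDistribution(counts=counts, n_total=n)


def expected_phenotype_freqs(
    gene: GeneModel, dup_fraction: float = 0.0
) -> dict[str, float]:
    """Closed-form phenotype distribution under Hardy-Weinberg equilibrium.

    Haplotypes are drawn independently from the gene's star-allele frequency
    vector (reference allele takes the residual mass); for copy-number aware
    genes a fraction ``dup_fraction`` of individuals carries three copies.
    This is the oracle the synthetic cohorts converge to.
    """
    alleles = gene.all_alleles
    out: dict[str, float] = {}
    for i, a in enumerate(alleles):
        for j, b in enumerate(alleles):
            if j < i:
                continue
            w = a.frequency * b.frequency * (1 if i == j else 2)
            if w == 0.0:
                continue
            if gene.cn_aware and dup_fraction > 0.0:
                lab2 = gene.phenotype_for(a.function, b.function, 2)
                lab3 = gene.phenotype_for(a.function, b.function, 3)
                out[lab2] = out.get(lab2, 0.0) + w * (1.0 - dup_fraction)
                out[lab3] = out.get(lab3, 0.0) + w * dup_fraction
            else:
                lab = gene.phenotype_for(a.function, b.function, 2)
                out[lab] = out.get(lab, 0.0) + w
    total = math.fsum(out.values())
    return {k: v / total for k, v in sorted(out.items())}


def expected_actionable_fraction(
    gene: GeneModel, actionable_set: frozenset[str], dup_fraction: float = 0.0
) -> float:
    freqs = expected_phenotype_freqs(gene, dup_fraction)
    return sum(v for k, v in freqs.items() if k in actionable_set)


def cohort_actionable_fraction(
    phenotypes_by_gene: Mapping[str, Sequence[Optional[str]]],
    genes: Sequence[str],
    actionable_set: frozenset[str],
) -> float:
    """Fraction of samples actionable for at least one of the listed genes.

    Denominator: samples with a call in every listed gene (no-calls for any
    of the row's genes are excluded from the estimate).
    """
    n_hit = n_called = 0
    size = len(phenotypes_by_gene[genes[0]])
    for i in range(size):
        labels = [phenotypes_by_gene[g][i] for g in genes]
        if any(x is None for x in labels):
            continue
        n_called += 1
        if any(x in actionable_set for x in labels):
            n_hit += 1
    if n_called == 0:
        raise ValueError("no fully-called samples for genes %s" % (list(genes),))
    return n_hit / n_called
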