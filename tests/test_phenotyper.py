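import math

import numpy as np
import pytest

from pgx_exposure.catalog import Catalog, actionable_fraction
from pgx_exposure.phenotyper import (
    CarriageDistribution,
    carriage_distribution,
    cohort_actionable_fraction,
    expected_phenotype_freqs,
    phenotype_calls,
    phenotype_frequencies,
    translate,
)
from pgx_exposure.star_caller import Diplotype, call_diplotypes
from pgx_exposure.synthetic_data import SimulationConfig, simulate_cohort
from tests.conftest import SEED


def _d(gene, a1, a2, cn=2, quality="exact"):
    return Diplotype(gene, a1, a2, cn, quality)


@pytest.mark.parametrize(
    "gene, a1, a2, cn, expected",
    [
        ("CYP2D6", "*4", "*4", 2, "P"),
        ("CYP2D6", "*1", "*4", 2, "I"),
        ("CYP2D6", "*1", "*10", 2, "N"),
        ("CYP2D6", "*1", "*1", 3, "U"),
        ("CYP2D6", "*4", "*4", 3, "P"),  # duplicated inactive allele is not U
        ("CYP2C19", "*1", "*17", 2, "U"),
        ("CYP2C19", "*2", "*17", 2, "I"),
        ("CYP2C19", "*2", "*2", 2, "P"),
        ("CYP3A5", "*3", "*3", 2, "P"),
        ("CYP3A5", "*1", "*3", 2, "I"),
        ("VKORC1", "*2", "*2", 2, "P"),
        ("VKORC1", "*1", "*2", 2, "I"),
        ("TPMT", "*2", "*2", 2, "P"),
        ("FVL", "Leiden", "non-carrier", 2, "Het"),
    ],
)
def test_translate_examples(catalog, gene, a1, a2, cn, expected):
    assert translate(_d(gene, a1, a2, cn), catalog.genes[gene]) == expected


def test_translate_no_call_is_missing(catalog):
    d = Diplotype("TPMT", None, None, 2, "no-call")
    assert translate(d, catalog.genes["TPMT"]) is None


def test_phenotype_frequencies_sum_to_one(catalog, cohort498):
    cohort, _ = cohort498
    for name, gene in catalog.genes.items():
        labels = [translate(d, gene) for d in call_diplotypes(cohort, gene)]
        freqs = phenotype_frequencies(labels, gene)
        assert math.fsum(freqs.values()) == pytest.approx(1.0, abs=1e-9)


def test_phenotype_frequencies_trivial_cases(catalog):
    gene = catalog.genes["TPMT"]
    assert phenotype_frequencies(["P"], gene)["P"] == 1.0
    assert phenotype_frequencies(["N"] * 5)["N"] == 1.0
    with pytest.raises(ValueError):
        phenotype_frequencies([None, None])


def test_cyp2c9_frequencies_match_hwe_closed_form(catalog, cohort498):
    """At n=498 the simulated CYP2C9 phenotype mix sits within 3 binomial SE
    of the Hardy-Weinberg expectation from the *2/*3 allele frequencies."""
    cohort, _ = cohort498
    gene = catalog.genes["CYP2C9"]
    labels = [translate(d, gene) for d in call_diplotypes(cohort, gene)]
    obs = phenotype_frequencies(labels, gene)
    exp = expected_phenotype_freqs(gene)
    assert exp["N"] == pytest.approx(0.64) and exp["P"] == pytest.approx(0.04)
    for label, p in exp.items():
        se = math.sqrt(p * (1 - p) / 498)
        assert abs(obs[label] - p) <= 3 * se, label


def test_actionable_two_routes_agree(catalog, cohort498):
    """Mean of per-sample actionable flags equals the actionable fraction
    computed from the phenotype frequency table (two routes, one number)."""
    cohort, _ = cohort498
    for it in catalog.interactions:
        if len(it.genes) != 1:
            continue
        gene = catalog.genes[it.genes[0]]
        diplos = call_diplotypes(cohort, gene)
        calls = phenotype_calls(cohort.sample_ids, diplos, gene, catalog)
        flag_mean = np.mean([c.actionable[it.row_id] for c in calls])
        labels = [c.phenotype for c in calls]
        freq_route = actionable_fraction(
            phenotype_frequencies(labels, gene), it.actionable_set, gene=gene.gene
        )
        assert flag_mean == pytest.approx(freq_route, abs=1e-12)


def test_carriage_all_reference_is_zero(catalog):
    cfg = SimulationConfig(
        n_individuals=40, seed=1,
        maf_overrides={r: 0.0 for g in catalog.genes.values() for r in g.defining_rsids},
        cyp2d6_dup_fraction=0.0,
    )
    cohort, _ = simulate_cohort(cfg, catalog)
    phen = {
        name: [translate(d, gene) for d in call_diplotypes(cohort, gene)]
        for name, gene in catalog.genes.items()
    }
    dist = carriage_distribution(phen, catalog)
    assert dist.counts == {0: 40}


def test_carriage_direct_count(catalog):
    phen = {name: ["N"] for name in ("CYP2C9", "TPMT", "SLCO1B1")}
    phen["CYP2D6"] = ["P"]
    phen["TPMT"] = ["I"]
    dist = carriage_distribution(phen, catalog)
    assert dist.counts == {2: 1}


def test_carriage_no_call_contributes_zero(catalog):
    phen = {"CYP2D6": ["P", None], "TPMT": [None, None]}
    dist = carriage_distribution(phen, catalog)
    assert dist.counts == {1: 1, 0: 1}


def test_carriage_monotone_in_actionable_sets(catalog, cohort498):
    """Adding a phenotype label to a gene's actionable set never lowers k."""
    from pgx_exposure.catalog import DrugGeneInteraction

    cohort, _ = cohort498
    phen = {
        name: [translate(d, gene) for d in call_diplotypes(cohort, gene)]
        for name, gene in catalog.genes.items()
    }
    wider = Catalog(
        genes=catalog.genes,
        interactions=catalog.interactions
        + [
            DrugGeneInteraction(
                row_id="extra", genes=("VKORC1",), drugs=("extra",),
                actionable_set=frozenset({"I"}), therapeutic_area="other",
                exposures=0, column_a_printed_pct=0.0, risky_printed=0,
                share_printed_pct=0.0, column_a_derivable=True,
            )
        ],
        sites=catalog.sites,
        drug_groups=catalog.drug_groups,
        phenotype_frequencies=catalog.phenotype_frequencies,
    )
    base = carriage_distribution(phen, catalog)
    wide = carriage_distribution(phen, wider)
    assert wide.mean() >= base.mean()
    # per-k cumulative dominance: mass shifts to higher counts only
    n = base.n_total
    for k in range(0, 15):
        below_base = sum(c for kk, c in base.counts.items() if kk <= k)
        below_wide = sum(c for kk, c in wide.counts.items() if kk <= k)
        assert below_wide <= below_base


def test_low_zero_carriage_at_reference_frequencies(catalog, cohort498):
    """Almost everyone carries at least one actionable genotype: the
    closed-form product of per-gene non-actionable probabilities is ~2% and
    the simulated cohort agrees (the source cohort reported 0.6%)."""
    cohort, _ = cohort498
    phen = {
        name: [translate(d, gene) for d in call_diplotypes(cohort, gene)]
        for name, gene in catalog.genes.items()
    }
    dist = carriage_distribution(phen, catalog)
    p0 = 1.0
    for name, gene in catalog.genes.items():
        act = catalog.actionable_union(name)
        dup = 0.02 if gene.cn_aware else 0.0
        freqs = expected_phenotype_freqs(gene, dup)
        p0 *= 1.0 - sum(v for k, v in freqs.items() if k in act)
    assert p0 < 0.05
    se = math.sqrt(p0 * (1 - p0) / 498)
    assert dist.fraction(0) <= p0 + 3 * se
    assert dist.fraction(0) < 0.05


def test_carriage_distribution_invariants():
    dist = CarriageDistribution(counts={0: 2, 3: 8}, n_total=10)
    assert sum(dist.fractions.values()) == pytest.approx(1.0)
    assert dist.mean() == pytest.approx(2.4)


def test_cohort_actionable_fraction_multi_gene(catalog):
    phen = {"HLA-A*31:01": ["Het", "N", None], "HLA-B*15:02": ["N", "Het", "N"]}
    f = cohort_actionable_fraction(phen, ("HLA-A*31:01", "HLA-B*15:02"), frozenset({"Het", "Hom"}))
    assert f == pytest.approx(1.0)  # the no-call sample is excluded
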