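"""Synthetic pedigree/cohort generation and its exact transmission oracle."""

import itertools
import math

import numpy as np
import pytest

from mendelsieve.pedigree import Pedigree, Phenotype, Sex, read_ped
from mendelsieve.segregation import InheritanceModel, prioritize, segregation_scan
from mendelsieve.simulate import (
    GENOTYPED_SUBSET,
    SimulationConfig,
    build_canonical_pedigree,
    make_table_fixtures,
    pattern_probability,
    simulate_cohort,
    simulate_records,
)
from mendelsieve.variants import make_fixture_tables, read_vcf

from conftest import make_individual

AD = InheritanceModel.AUTOSOMAL_DOMINANT
XLD = InheritanceModel.X_LINKED_DOMINANT


# -- canonical pedigree ----------------------------------------------------

class TestCanonicalPedigree:
    def test_counts(self, canonical_ped):
        assert len(canonical_ped) == 31
        affected = [i for i in canonical_ped if i.phenotype is Phenotype.AFFECTED]
        assert len(affected) == 9
        subset = canonical_ped.genotyped_subset
        assert len(subset) == 12
        assert len(canonical_ped.genotyped_affected()) == 8
        assert len(canonical_ped.genotyped_unaffected()) == 4

    def test_genotyped_subset_sex_split(self, canonical_ped):
        females = [m for m in GENOTYPED_SUBSET
                   if canonical_ped[m].sex is Sex.FEMALE]
        assert len(females) == 7 and len(GENOTYPED_SUBSET) - len(females) == 5

    def test_four_generations(self, canonical_ped):
        gens = {m.member_id.split("-")[0] for m in canonical_ped}
        assert gens == {"1", "2", "3", "4"}

    def test_dominant_transmission_consistency(self, canonical_ped):
        """Every affected non-founder has an affected parent (AD), every
        affected male has an affected mother and every affected father's
        daughters are affected (XLD) — so a fully penetrant variant can
        segregate exactly with the labels under either model."""
        ped = canonical_ped
        for ind in ped:
            if ind.phenotype is not Phenotype.AFFECTED or ind.is_founder:
                continue
            parents = {ped[ind.father_id].phenotype, ped[ind.mother_id].phenotype}
            assert Phenotype.AFFECTED in parents
            if ind.sex is Sex.MALE:  # XLD: carrier males inherit X from mother
                assert ped[ind.mother_id].phenotype is Phenotype.AFFECTED
        for ind in ped:
            if ind.is_founder:
                continue
            father = ped[ind.father_id]
            if father.phenotype is Phenotype.AFFECTED and ind.sex is Sex.FEMALE:
                assert ind.phenotype is Phenotype.AFFECTED


# -- cohort simulation -----------------------------------------------------

class TestSimulateCohort:
    def test_full_penetrance_carriers_are_exactly_the_affected(self):
        cohort = simulate_records(SimulationConfig(seed=7))
        causal = next(r for r in cohort.records if r.key == cohort.causal_key)
        for m in cohort.pedigree.genotyped_subset:
            affected = cohort.pedigree[m].phenotype is Phenotype.AFFECTED
            assert (causal.genotypes[m].alt_count > 0) == affected

    def test_seeded_runs_are_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_noise_variants=50)
        p1 = simulate_cohort(cfg, tmp_path / "a" / "sim")
        p2 = simulate_cohort(cfg, tmp_path / "b" / "sim")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_cohort(SimulationConfig(seed=1, n_noise_variants=50),
                            tmp_path / "a" / "sim")
        b = simulate_cohort(SimulationConfig(seed=2, n_noise_variants=50),
                            tmp_path / "b" / "sim")
        assert a[0].read_bytes() != b[0].read_bytes()

    def test_mendelian_consistency_exhaustive(self):
        """Every simulated child call is derivable from its parents' calls."""
        cohort = simulate_records(SimulationConfig(
            seed=5, n_noise_variants=100, fraction_x_linked_noise=0.3))
        ped = cohort.pedigree
        for v in cohort.records:
            x = v.is_x_linked
            for ind in ped:
                if ind.is_founder:
                    continue
                child = v.genotypes[ind.member_id].alleles
                fa = v.genotypes[ind.father_id].alleles
                mo = v.genotypes[ind.mother_id].alleles
                # calls are unordered: any parental assignment suffices
                if x and ind.sex is Sex.MALE:
                    assert len(child) == 1 and child[0] in mo
                elif x:
                    assert fa[0] in child
                    rest = list(child)
                    rest.remove(fa[0])
                    assert rest[0] in mo
                else:
                    assert (child[0] in fa and child[1] in mo) or (
                        child[1] in fa and child[0] in mo
                    )

    def test_founder_allele_frequency_recovery(self):
        """Founder alt-allele frequency across many variants tracks the
        configured MAF within 3 standard errors."""
        maf = 0.3
        cohort = simulate_records(SimulationConfig(
            seed=9, n_noise_variants=800, noise_maf_range=(maf, maf),
            fraction_x_linked_noise=0.0))
        founders = [i.member_id for i in cohort.pedigree.founders()]
        draws = [
            a
            for v in cohort.records if v.gene != "CAUSAL1"
            for m in founders
            for a in v.genotypes[m].alleles
        ]
        freq = float(np.mean(draws))
        se = math.sqrt(maf * (1 - maf) / len(draws))
        assert abs(freq - maf) <= 3 * se

    def test_missing_rate_injection(self):
        cohort = simulate_records(SimulationConfig(
            seed=2, n_noise_variants=100, missing_rate=0.1))
        calls = [g for v in cohort.records for g in v.genotypes.values()]
        frac = np.mean([g.missing for g in calls])
        assert 0.05 < frac < 0.15

    def test_reduced_penetrance_relabels_phenotypes(self):
        cohort = simulate_records(SimulationConfig(seed=4, penetrance=0.5,
                                                   n_noise_variants=0))
        causal = cohort.records[-1]
        ped = cohort.pedigree
        for ind in ped:
            if ind.phenotype is Phenotype.AFFECTED:
                assert causal.genotypes[ind.member_id].alt_count > 0

    def test_noise_survival_non_increasing_in_genotyped_members(self):
        """With more genotyped members, fewer noise variants can mimic the
        carrier pattern by chance."""
        cohort = simulate_records(SimulationConfig(
            seed=13, n_noise_variants=3000, noise_maf_range=(0.3, 0.3),
            fraction_x_linked_noise=0.0))
        ped = cohort.pedigree
        noise = [r for r in cohort.records if r.gene != "CAUSAL1"]
        subsets = [
            ("2-2", "2-1", "3-1", "3-4"),
            ("2-2", "2-1", "3-1", "3-4", "2-4", "3-3", "3-6", "4-3"),
            GENOTYPED_SUBSET,
        ]
        counts = []
        for subset in subsets:
            narrowed = Pedigree(list(ped.individuals), frozenset(subset))
            counts.append(len(segregation_scan(noise, narrowed)))
        assert counts[0] >= counts[1] >= counts[2]


# -- worked-example files --------------------------------------------------

class TestTableFixtures:
    def test_round_trip_matches_in_memory_fixture(self, tmp_path):
        vcf, ped_path, annot = make_table_fixtures(tmp_path)
        ped = read_ped(ped_path)
        loaded = read_vcf(vcf, ped, annotations=annot)
        expected = make_fixture_tables()
        assert len(loaded) == 4
        for a, b in zip(sorted(loaded, key=lambda v: v.gene),
                        sorted(expected, key=lambda v: v.gene)):
            assert a.key == b.key
            assert a.genotypes == b.genotypes
            assert a.maf == b.maf
            assert a.impact_class == b.impact_class

    def test_prioritize_on_fixture_files(self, tmp_path):
        vcf, ped_path, annot = make_table_fixtures(tmp_path)
        ped = read_ped(ped_path)
        cands = prioritize(read_vcf(vcf, ped, annotations=annot), ped)
        assert len(cands) == 4
        hccs = [c for c in cands if c.variant.gene == "HCCS"]
        assert hccs[0].variant.is_x_linked and hccs[0].models == {XLD}
        mterf2 = next(c for c in cands if c.variant.gene == "MTERF2")
        assert mterf2.variant.maf_of("ASN") is None


# -- exact pattern probability oracle -------------------------------------

def brute_force_pattern_probability(ped, maf, model):
    """Enumerate founder genotypes × transmission choices exactly."""
    x = model is XLD
    founders = [i for i in ped if i.is_founder]
    nonf = [i for i in ped if not i.is_founder]

    def domains(sex):
        if x and sex is Sex.MALE:
            return [(0,), (1,)]
        return [(0, 0), (0, 1), (1, 0), (1, 1)]

    def prior(g, sex):
        p, q = maf, 1 - maf
        if x and sex is Sex.MALE:
            return q if g == (0,) else p
        return {(0, 0): q * q, (0, 1): p * q, (1, 0): p * q, (1, 1): p * p}[g]

    def ok(ind, g):
        if ind.member_id not in ped.genotyped_subset:
            return True
        if ind.phenotype is Phenotype.AFFECTED:
            return sum(g) == 1
        if ind.phenotype is Phenotype.UNAFFECTED:
            return sum(g) == 0
        return True

    total = 0.0
    for fg in itertools.product(*[domains(f.sex) for f in founders]):
        geno = {f.member_id: g for f, g in zip(founders, fg)}
        base = math.prod(prior(g, f.sex) for f, g in zip(founders, fg))
        for picks in itertools.product(range(4), repeat=len(nonf)):
            g2, w = dict(geno), 1.0
            for ind, pk in zip(nonf, picks):
                fi, mi = divmod(pk, 2)
                fa_g, mo_g = g2[ind.father_id], g2[ind.mother_id]
                mat = mo_g[mi]
                if x:
                    child = (mat,) if ind.sex is Sex.MALE else (fa_g[0], mat)
                else:
                    child = (fa_g[fi], mat)
                g2[ind.member_id] = child
                w *= 0.25
            if all(ok(i, g2[i.member_id]) for i in ped):
                total += base * w
    return total


@pytest.mark.parametrize("model", [AD, XLD])
@pytest.mark.parametrize("maf", [0.05, 0.3, 0.5])
def test_pattern_probability_matches_brute_force(model, maf):
    ped = Pedigree([
        make_individual("f", "M", "U"),
        make_individual("m", "F", "A"),
        make_individual("c1", "M", "A", father="f", mother="m"),
        make_individual("c2", "F", "U", father="f", mother="m"),
        make_individual("c3", "F", "?", father="f", mother="m"),
    ])
    exact = pattern_probability(ped, maf, model)
    brute = brute_force_pattern_probability(ped, maf, model)
    assert exact == pytest.approx(brute, rel=1e-12, abs=1e-15)


def test_pattern_probability_canonical_monte_carlo():
    """Simulated segregation-survival frequency of X-linked noise variants
    agrees with the exact transmission-tree probability within 3 SE."""
    ped = build_canonical_pedigree()
    maf, n = 0.2, 8000
    p = pattern_probability(ped, maf, XLD)
    cohort = simulate_records(SimulationConfig(
        seed=11, n_noise_variants=n, noise_maf_range=(maf, maf),
        fraction_x_linked_noise=1.0))
    noise = [r for r in cohort.records if r.gene != "CAUSAL1"]
    obs = len(segregation_scan(noise, cohort.pedigree))
    se = math.sqrt(n * p * (1 - p))
    assert abs(obs - n * p) <= 3 * se


def test_pattern_probability_edge_frequencies():
    ped = build_canonical_pedigree()
    assert pattern_probability(ped, 0.0, AD) == 0.0  # no alt allele to carry
    p = pattern_probability(ped, 0.001, AD)
    assert 0.0 < p < 1e-5


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(penetrance=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(noise_maf_range=(0.6, 0.4))
    with pytest.raises(ValueError):
        SimulationConfig(n_noise_variants=-1)
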