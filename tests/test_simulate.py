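"""Gene-dropping simulator: structure, allele frequencies, phenotypes, ascertainment."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import beta as beta_dist

from digenic.likelihood import AlleleFrequencies, ModelFamily, PenetranceModel
from digenic.pedigree import Affection, Sex, XInactivation, validate_pedigree
from digenic.simulate import (
    AscertainmentError,
    SimConfig,
    StructureTemplate,
    XiSkewDistribution,
    assign_phenotypes,
    gene_drop,
    make_structure,
    simulate_cohort,
)


class TestMakeStructure:
    def test_two_generation_fixed_sibship_is_nuclear(self):
        t = StructureTemplate(p_three_generations=0.0, sibship=(3, 3))
        ped = make_structure(t, np.random.default_rng(0))
        assert len(ped) == 5
        assert len(ped.founders) == 2

    def test_three_generation_skeleton_is_valid(self):
        t = StructureTemplate(p_three_generations=1.0, sibship=(2, 4), p_marry=1.0)
        ped = make_structure(t, np.random.default_rng(1))
        assert [i for i in validate_pedigree(ped) if i.severity == "error"] == []
        grandchildren = [
            m
            for m in ped.members
            if not m.is_founder
            and not (ped[m.father_id].is_founder and ped[m.mother_id].is_founder)
        ]
        assert grandchildren  # third generation present
        married_in = [m for m in ped.founders if m.id not in ("1", "2")]
        assert len(married_in) >= 2

    def test_identical_seeds_identical_skeletons(self):
        t = StructureTemplate()
        a = make_structure(t, np.random.default_rng(42))
        b = make_structure(t, np.random.default_rng(42))
        assert a == b


class TestGeneDrop:
    def test_degenerate_frequencies_all_wildtype(self):
        t = StructureTemplate(p_three_generations=1.0, sibship=(2, 3), p_marry=1.0)
        ped = make_structure(t, np.random.default_rng(3))
        latent = gene_drop(ped, AlleleFrequencies(q_s=0.0, q_t=0.0), np.random.default_rng(4))
        assert all(st.x_count == 0 and st.a_count == 0 for st in latent.values())

    def test_founder_allele_frequency_recovered(self):
        # 10,000 independent founders: observed T allele frequency within
        # 3 binomial standard errors of the simulating value
        q_t = 0.3
        rng = np.random.default_rng(5)
        t = StructureTemplate(p_three_generations=0.0, sibship=(1, 1))
        n_alleles = n_mut = 0
        for _ in range(5000):
            ped = make_structure(t, rng)
            latent = gene_drop(ped, AlleleFrequencies(q_s=0.0, q_t=q_t), rng)
            for m in ped.founders:
                n_alleles += 2
                n_mut += latent[m.id].a_count
        se = np.sqrt(q_t * (1 - q_t) / n_alleles)
        assert abs(n_mut / n_alleles - q_t) < 3 * se

    def test_carrier_mother_transmits_half(self):
        # forced S/wt mother (boost) passes S to sons with frequency ~1/2
        rng = np.random.default_rng(6)
        t = StructureTemplate(p_three_generations=0.0, sibship=(1, 1))
        sons = carriers = 0
        for _ in range(10_000):
            ped = make_structure(t, rng)
            latent = gene_drop(ped, AlleleFrequencies(q_s=0.0, q_t=0.0), rng, founder_carrier_boost=1.0)
            kid = next(m for m in ped.members if not m.is_founder)
            if kid.sex is Sex.MALE:
                sons += 1
                carriers += latent[kid.id].x_count
        se = np.sqrt(0.25 / sons)
        assert abs(carriers / sons - 0.5) < 3 * se


class TestAssignPhenotypes:
    def test_full_penetrance_zero_phenocopy_affected_are_at_risk(self):
        model = PenetranceModel(family=ModelFamily.DIGENIC_AND, f_m=1.0, f_f_skewed=1.0, eps=0.0)
        cfg = SimConfig(seed=8, n_families=40, model=model)
        cohort = simulate_cohort(cfg)
        for ped, latent in zip(cohort.pedigrees, cohort.latent):
            for m in ped.members:
                if m.affection is Affection.AFFECTED:
                    st = latent[m.id]
                    assert st.x_count >= 1 and st.a_count >= 1
                    if m.sex is Sex.FEMALE:
                        assert m.xi_status is XInactivation.SKEWED_MUT_ACTIVE

    def test_phenocopy_rate_recovered_in_null_risk_cohort(self):
        eps = 0.02
        model = PenetranceModel(family=ModelFamily.DIGENIC_AND, f_m=1.0, eps=eps)
        rng = np.random.default_rng(9)
        t = StructureTemplate(p_three_generations=0.0, sibship=(2, 2))
        n = affected = 0
        for _ in range(2500):
            ped = make_structure(t, rng)
            latent = gene_drop(ped, AlleleFrequencies(q_s=0.0, q_t=0.0), rng)
            ped, latent = assign_phenotypes(ped, latent, model, XiSkewDistribution(), rng)
            n += len(ped)
            affected += sum(m.affection is Affection.AFFECTED for m in ped.members)
        se = np.sqrt(eps * (1 - eps) / n)
        assert abs(affected / n - eps) < 3 * se

    def test_skew_call_rate_matches_numerical_integration(self):
        dist = XiSkewDistribution(alpha=8.0, beta=2.0, threshold=0.75)
        expected, _ = integrate.quad(lambda x: beta_dist.pdf(x, 8.0, 2.0), 0.75, 1.0)
        rng = np.random.default_rng(10)
        t = StructureTemplate(p_three_generations=0.0, sibship=(1, 1))
        model = PenetranceModel(family=ModelFamily.DIGENIC_AND)
        called = total = 0
        for _ in range(4000):
            ped = make_structure(t, rng)
            latent = gene_drop(ped, AlleleFrequencies(q_s=0.0, q_t=0.0), rng, founder_carrier_boost=1.0)
            ped, latent = assign_phenotypes(ped, latent, model, dist, rng)
            for m in ped.members:
                if m.sex is Sex.FEMALE and latent[m.id].x_count > 0:
                    total += 1
                    called += m.xi_status is XInactivation.SKEWED_MUT_ACTIVE
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(called / total - expected) < 3 * se


class TestSimulateCohort:
    def test_no_ascertainment_rejects_nothing(self):
        cohort = simulate_cohort(SimConfig(seed=11, n_families=10, ascertainment="none"))
        assert cohort.n_rejected == 0
        assert all(p.proband is None for p in cohort.pedigrees)

    def test_affected_male_proband_rule(self):
        cohort = simulate_cohort(SimConfig(seed=12, n_families=15))
        for ped, latent in zip(cohort.pedigrees, cohort.latent):
            pro = ped.proband
            assert pro is not None
            assert pro.sex is Sex.MALE and pro.affection is Affection.AFFECTED

    def test_reproducible_given_config(self):
        a = simulate_cohort(SimConfig(seed=13, n_families=8))
        b = simulate_cohort(SimConfig(seed=13, n_families=8))
        assert a.pedigrees == b.pedigrees
        assert a.latent == b.latent
        assert a.n_rejected == b.n_rejected

    def test_hopeless_ascertainment_raises(self):
        cfg = SimConfig(
            seed=14,
            n_families=5,
            freqs=AlleleFrequencies(q_s=0.0, q_t=0.0),
            model=PenetranceModel(family=ModelFamily.DIGENIC_AND, f_m=1.0, eps=0.0),
            founder_carrier_boost=0.0,
            max_rejections=200,
        )
        with pytest.raises(AscertainmentError, match="boost"):
            simulate_cohort(cfg)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="ascertainment"):
            SimConfig(seed=1, ascertainment="first_come_first_served")

    def test_unaffected_brothers_never_carry_both_variants(self):
        """Under full penetrance, a brother carrying both variants cannot
        stay unaffected: unaffected brothers carry one variant or neither."""
        model = PenetranceModel(family=ModelFamily.DIGENIC_AND, f_m=1.0, f_f_skewed=1.0, eps=0.0)
        cohort = simulate_cohort(SimConfig(seed=15, n_families=30, model=model))
        for ped, latent in zip(cohort.pedigrees, cohort.latent):
            for m in ped.members:
                if m.sex is Sex.MALE and m.affection is Affection.UNAFFECTED:
                    st = latent[m.id]
                    assert not (st.x_count >= 1 and st.a_count >= 1)
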