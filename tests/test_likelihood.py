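"""Two-locus engine: priors, transmission, penetrance and exact likelihoods."""

import math
from dataclasses import replace

import numpy as np
import pytest

from digenic.likelihood import (
    AlleleFrequencies,
    EnumerationSizeError,
    JointGenotype,
    ModelFamily,
    PenetranceModel,
    UnsupportedStructureError,
    brute_force_likelihood,
    cohort_log_likelihood,
    founder_prior,
    pedigree_likelihood,
    penetrance,
    state_space,
    transmission_prob,
    transmission_tensor,
)
from digenic.pedigree import (
    Affection,
    Individual,
    Pedigree,
    Sex,
    TObs,
    XInactivation,
    XObs,
)

from conftest import make_trio, random_pedigree

DIGENIC = PenetranceModel(family=ModelFamily.DIGENIC_AND, f_m=1.0, f_f_skewed=1.0, eps=0.0)


class TestFounderPrior:
    def test_degenerate_x_frequency(self):
        pr = founder_prior(Sex.MALE, AlleleFrequencies(q_s=0.0, q_t=0.3))
        states = state_space(Sex.MALE)
        assert all(pr[i] == 0.0 for i, g in enumerate(states) if g.x_count > 0)

    def test_female_hwe_symmetry(self):
        pr = founder_prior(Sex.FEMALE, AlleleFrequencies(q_s=0.5, q_t=0.2))
        x_marginal = [
            sum(pr[i] for i, g in enumerate(state_space(Sex.FEMALE)) if g.x_count == k)
            for k in range(3)
        ]
        assert x_marginal == pytest.approx([0.25, 0.5, 0.25])

    @pytest.mark.parametrize("sex", [Sex.MALE, Sex.FEMALE])
    def test_normalisation(self, sex):
        pr = founder_prior(sex, AlleleFrequencies(q_s=0.123, q_t=0.456))
        assert pr.sum() == pytest.approx(1.0, abs=1e-12)


class TestTransmission:
    def test_daughters_of_hemizygous_father_all_carriers(self):
        father = JointGenotype(1, 0)
        mother = JointGenotype(0, 0)
        assert transmission_prob(JointGenotype(1, 0), Sex.FEMALE, father, mother) == 1.0
        assert transmission_prob(JointGenotype(0, 0), Sex.MALE, father, mother) == 1.0

    def test_carrier_mother_transmits_half(self):
        father, mother = JointGenotype(0, 0), JointGenotype(1, 0)
        assert transmission_prob(JointGenotype(1, 0), Sex.MALE, father, mother) == 0.5

    def test_heterozygous_father_transmits_autosomal_allele_half(self):
        # father T/wt, mother wt/wt: child T/wt with probability 1/2
        assert transmission_prob(
            JointGenotype(0, 1), Sex.MALE, JointGenotype(0, 1), JointGenotype(0, 0)
        ) == pytest.approx(0.5)

    def test_child_distribution_normalises_for_all_parent_pairs(self):
        for sex in (Sex.MALE, Sex.FEMALE):
            T = transmission_tensor(sex)
            assert np.allclose(T.sum(axis=2), 1.0)

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            transmission_prob(JointGenotype(2, 0), Sex.MALE, JointGenotype(0, 0), JointGenotype(0, 0))


class TestPenetrance:
    def test_digenic_male_needs_both_loci(self):
        assert penetrance(JointGenotype(1, 1), Sex.MALE, XInactivation.UNKNOWN, DIGENIC) == 1.0
        assert penetrance(JointGenotype(1, 0), Sex.MALE, XInactivation.UNKNOWN, DIGENIC) == 0.0
        assert penetrance(JointGenotype(0, 1), Sex.MALE, XInactivation.UNKNOWN, DIGENIC) == 0.0

    def test_silenced_mutant_x_protects_carrier_female(self):
        model = replace(DIGENIC, eps=0.02)
        p = penetrance(JointGenotype(1, 1), Sex.FEMALE, XInactivation.SKEWED_MUT_SILENCED, model)
        assert p == 0.02

    def test_female_xi_gating(self):
        model = PenetranceModel(
            family=ModelFamily.DIGENIC_AND, f_m=1.0, f_f_skewed=0.9, f_f_random=0.1, eps=0.0
        )
        g = JointGenotype(1, 1)
        assert penetrance(g, Sex.FEMALE, XInactivation.SKEWED_MUT_ACTIVE, model) == 0.9
        assert penetrance(g, Sex.FEMALE, XInactivation.RANDOM, model) == 0.1
        # unknown X-inactivation is treated as random
        assert penetrance(g, Sex.FEMALE, XInactivation.UNKNOWN, model) == 0.1

    def test_heterogeneity_reduces_to_monogenic_when_branch_off(self):
        het = PenetranceModel(
            family=ModelFamily.HETEROGENEITY_OR, f_m=0.7, f_f_skewed=0.6, f_f_random=0.1,
            f_a=0.0, eps=0.05,
        )
        mono = PenetranceModel(
            family=ModelFamily.MONOGENIC_X, f_m=0.7, f_f_skewed=0.6, f_f_random=0.1, eps=0.05
        )
        for sex in (Sex.MALE, Sex.FEMALE):
            for xi in XInactivation:
                if sex is Sex.MALE and xi is not XInactivation.UNKNOWN:
                    continue
                for g in state_space(sex):
                    assert penetrance(g, sex, xi, het) == pytest.approx(
                        penetrance(g, sex, xi, mono)
                    )


class TestSmallExactValues:
    def test_lone_founder_fully_unknown_has_unit_likelihood(self):
        ped = Pedigree("F", [Individual(id="a", sex=Sex.MALE)])
        res = pedigree_likelihood(ped, DIGENIC, AlleleFrequencies(q_s=0.1, q_t=0.2))
        assert res.log_likelihood == pytest.approx(0.0, abs=1e-12)

    def test_lone_founder_observed_hemizygous_equals_prior(self):
        ped = Pedigree("F", [Individual(id="a", sex=Sex.MALE, s_obs=XObs.HEMI_MUT)])
        res = pedigree_likelihood(ped, DIGENIC, AlleleFrequencies(q_s=0.1, q_t=0.2))
        assert math.exp(res.log_likelihood) == pytest.approx(0.1)

    def test_trio_null_model_phenocopy_only(self):
        ped = make_trio(child_affection=Affection.AFFECTED)
        model = PenetranceModel(family=ModelFamily.NULL, eps=0.3)
        freqs = AlleleFrequencies(q_s=0.1, q_t=0.1)
        for fn in (pedigree_likelihood, brute_force_likelihood):
            assert math.exp(fn(ped, model, freqs).log_likelihood) == pytest.approx(0.3)

    def test_impossible_observations_give_minus_inf_with_diagnostic(self):
        ped = Pedigree(
            "F",
            [
                Individual(id="f", sex=Sex.MALE, s_obs=XObs.WT),
                Individual(id="m", sex=Sex.FEMALE, s_obs=XObs.WT),
                Individual(id="c", father_id="f", mother_id="m", sex=Sex.FEMALE, s_obs=XObs.HET_CARRIER),
            ],
        )
        freqs = AlleleFrequencies(q_s=0.1, q_t=0.1)
        for fn in (pedigree_likelihood, brute_force_likelihood):
            res = fn(ped, DIGENIC, freqs)
            assert res.log_likelihood == -math.inf
            assert res.diagnostic is not None

    def test_loop_raises_unsupported(self):
        members = [
            Individual(id="g1", sex=Sex.MALE),
            Individual(id="g2", sex=Sex.FEMALE),
            Individual(id="a", father_id="g1", mother_id="g2", sex=Sex.MALE),
            Individual(id="b", father_id="g1", mother_id="g2", sex=Sex.FEMALE),
            Individual(id="k", father_id="a", mother_id="b", sex=Sex.MALE),
        ]
        with pytest.raises(UnsupportedStructureError):
            pedigree_likelihood(Pedigree("L", members), DIGENIC, AlleleFrequencies())

    def test_brute_force_size_guard(self):
        members = [Individual(id=f"i{k}", sex=Sex.MALE) for k in range(13)]
        with pytest.raises(EnumerationSizeError):
            brute_force_likelihood(Pedigree("B", members), DIGENIC, AlleleFrequencies())


class TestPeelingProperties:
    def test_peeling_matches_enumeration_on_random_pedigrees(self, rng):
        families = list(ModelFamily)
        n_checked = 0
        for i in range(40):
            ped = random_pedigree(rng)
            model = PenetranceModel(
                family=families[i % 5],
                f_m=rng.uniform(),
                f_f_skewed=rng.uniform(),
                f_f_random=rng.uniform(),
                f_a=rng.uniform(),
                eps=rng.uniform(0, 0.3),
            )
            freqs = AlleleFrequencies(q_s=rng.uniform(0.01, 0.5), q_t=rng.uniform(0.01, 0.5))
            a = pedigree_likelihood(ped, model, freqs).log_likelihood
            b = brute_force_likelihood(ped, model, freqs).log_likelihood
            if math.isinf(a) or math.isinf(b):
                assert a == b
                continue
            assert a == pytest.approx(b, abs=1e-10)
            n_checked += 1
        # random observations are often jointly impossible (both engines
        # must then agree on -inf); require a healthy finite sample too
        assert n_checked >= 12

    def test_marginalisation_over_an_unknown_phenotype(self, rng):
        # fixing one unknown-phenotype member alternately affected and
        # unaffected must sum back to the marginal likelihood
        freqs = AlleleFrequencies(q_s=0.2, q_t=0.2)
        model = PenetranceModel(
            family=ModelFamily.DIGENIC_AND, f_m=0.8, f_f_skewed=0.7, f_f_random=0.1, eps=0.05
        )
        for _ in range(5):
            ped = random_pedigree(rng)
            target = next((m for m in ped.members if m.affection is Affection.UNKNOWN), None)
            if target is None:
                continue
            lik = math.exp(pedigree_likelihood(ped, model, freqs).log_likelihood)
            total = 0.0
            for aff in (Affection.AFFECTED, Affection.UNAFFECTED):
                fixed = Pedigree(
                    ped.family_id,
                    [replace(m, affection=aff) if m.id == target.id else m for m in ped.members],
                )
                total += math.exp(pedigree_likelihood(fixed, model, freqs).log_likelihood)
            assert total == pytest.approx(lik, rel=1e-10)

    def test_likelihood_monotone_in_penetrance_for_fully_at_risk_family(self):
        # all affected members at risk, no unaffected at-risk members:
        # raising f_m can only help when eps = 0
        ped = Pedigree(
            "M",
            [
                Individual(id="f", sex=Sex.MALE, s_obs=XObs.WT, t_obs=TObs.HET_MUT),
                Individual(id="m", sex=Sex.FEMALE, s_obs=XObs.HET_CARRIER, t_obs=TObs.HOM_WT),
                Individual(
                    id="c", father_id="f", mother_id="m", sex=Sex.MALE,
                    s_obs=XObs.HEMI_MUT, t_obs=TObs.HET_MUT, affection=Affection.AFFECTED,
                ),
            ],
        )
        freqs = AlleleFrequencies(q_s=0.01, q_t=0.01)
        lls = [
            cohort_log_likelihood(
                [ped],
                PenetranceModel(family=ModelFamily.DIGENIC_AND, f_m=f, eps=0.0),
                freqs,
            ).log_likelihood
            for f in np.linspace(0.1, 1.0, 10)
        ]
        assert all(b >= a for a, b in zip(lls, lls[1:]))

    def test_zero_autosomal_frequency_kills_models_requiring_t(self):
        ped = make_trio(child_affection=Affection.AFFECTED)
        freqs = AlleleFrequencies(q_s=0.1, q_t=0.0)
        for fam in (ModelFamily.DIGENIC_AND, ModelFamily.MONOGENIC_A):
            model = PenetranceModel(family=fam, f_m=1.0, f_f_skewed=1.0, eps=0.0)
            assert pedigree_likelihood(ped, model, freqs).log_likelihood == -math.inf


class TestConditioning:
    def test_conditioned_equals_difference_of_peels(self, rng):
        freqs = AlleleFrequencies(q_s=0.05, q_t=0.1)
        model = PenetranceModel(
            family=ModelFamily.DIGENIC_AND, f_m=0.9, f_f_skewed=0.8, f_f_random=0.05, eps=0.02
        )
        for _ in range(5):
            ped = random_pedigree(rng)
            affected = [m for m in ped.members if m.affection is not Affection.UNKNOWN]
            if not affected:
                continue
            ped = Pedigree(
                ped.family_id,
                [replace(m, proband=(m.id == affected[0].id)) for m in ped.members],
            )
            full = pedigree_likelihood(ped, model, freqs).log_likelihood
            denom = pedigree_likelihood(
                ped.strip_observations(keep_proband_affection=True), model, freqs
            ).log_likelihood
            cond = pedigree_likelihood(ped, model, freqs, condition_on_proband=True).log_likelihood
            if math.isinf(full):
                assert math.isinf(cond)
            else:
                assert cond == pytest.approx(full - denom, abs=1e-9)

    def test_conditioning_requires_a_proband(self):
        ped = make_trio(child_affection=Affection.AFFECTED)
        with pytest.raises(ValueError, match="proband"):
            pedigree_likelihood(ped, DIGENIC, AlleleFrequencies(), condition_on_proband=True)
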