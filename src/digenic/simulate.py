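"""Gene-dropping simulation of two-locus families with ascertainment.

The generator emulates the study design of a digenic myopathy cohort:
nuclear-to-three-generation families ascertained through an affected male,
segregating a rare X-linked deleterious allele and a ~1%-frequency
truncating autosomal allele, with male penetrance near one and female
expression gated by skewed X-inactivation.  Because an unconditioned
digenic family is astronomically rare at realistic frequencies, the
founding couple can be forced to introduce both alleles
(``founder_carrier_boost``); the boost changes only the generator's founder
draws, never the likelihood model used in analysis.

X-inactivation is simulated as a latent Beta-distributed fraction of cells
with the mutant X active, dichotomised into the categorical calls the
likelihood consumes (mutant-active skew / random / mutant-silenced skew).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .likelihood import (
    AlleleFrequencies,
    JointGenotype,
    ModelFamily,
    PenetranceModel,
    founder_prior,
    penetrance,
    transmission_tensor,
)
from .pedigree import (
    Affection,
    Individual,
    Pedigree,
    Sex,
    TObs,
    XInactivation,
    XObs,
    validate_pedigree,
)


@dataclass(frozen=True)
class StructureTemplate:
    """Family-skeleton template: generations and sibship-size distribution.

    ``p_three_generations`` selects a three-generation family; sibship sizes
    are uniform on the closed ranges given.  In three-generation families
    each second-generation child marries in a spouse with probability
    ``p_marry`` and founds a sibship of its own.
    """

    p_three_generations: float = 0.5
    sibship: tuple[int, int] = (1, 4)
    p_marry: float = 0.5
    sibship_g3: tuple[int, int] = (1, 3)

    def __post_init__(self):
        for lo, hi in (self.sibship, self.sibship_g3):
            if not (1 <= lo <= hi):
                raise ValueError("sibship bounds must satisfy 1 <= lo <= hi")
        for p in (self.p_three_generations, self.p_marry):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class XiSkewDistribution:
    """Beta model for a female carrier's mutant-X-active cell fraction.

    Fractions at or above ``threshold`` are called mutant-active skew, at or
    below ``1 - threshold`` mutant-silenced skew, otherwise random.  The
    default threshold 0.6 treats 80:20 and 65:35 ratios as skewed.
    """

    alpha: float = 2.0
    beta: float = 2.0
    threshold: float = 0.6

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")
        if not (0.5 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0.5, 1]")

    def categorize(self, fraction: float) -> XInactivation:
        if fraction >= self.threshold:
            return XInactivation.SKEWED_MUT_ACTIVE
        if fraction <= 1.0 - self.threshold:
            return XInactivation.SKEWED_MUT_SILENCED
        return XInactivation.RANDOM


@dataclass(frozen=True)
class SimConfig:
    """Study-like defaults: 25 ascertained families, digenic generative model."""

    seed: int
    n_families: int = 25
    structure: StructureTemplate = field(default_factory=StructureTemplate)
    freqs: AlleleFrequencies = field(default_factory=AlleleFrequencies)
    model: PenetranceModel = field(
        default_factory=lambda: PenetranceModel(
            family=ModelFamily.DIGENIC_AND,
            f_m=0.95,
            f_f_skewed=0.9,
            f_f_random=0.01,
            eps=0.01,
        )
    )
    xi_skew_distribution: XiSkewDistribution = field(default_factory=XiSkewDistribution)
    founder_carrier_boost: float = 1.0
    ascertainment: str = "affected_male_proband"  # none | at_least_one_affected | affected_male_proband
    max_rejections: int = 1_000_000

    def __post_init__(self):
        if self.ascertainment not in ("none", "at_least_one_affected", "affected_male_proband"):
            raise ValueError(f"unknown ascertainment rule {self.ascertainment!r}")
        if not (0.0 <= self.founder_carrier_boost <= 1.0):
            raise ValueError("founder_carrier_boost must lie in [0, 1]")


#: latent per-individual state: mutant-allele counts and, for carrier
#: females, the latent mutant-X-active fraction
@dataclass(frozen=True)
class LatentState:
    x_count: int
    a_count: int
    x_active_fraction: float | None = None


@dataclass
class SimulatedCohort:
    pedigrees: list[Pedigree]
    latent: list[dict[str, LatentState]]   # parallel to pedigrees
    provenance: SimConfig
    n_rejected: int


class AscertainmentError(RuntimeError):
    pass


# ---------------------------------------------------------------------------

def make_structure(template: StructureTemplate, rng: np.random.Generator, family_id: str = "SIM") -> Pedigree:
    """Loop-free pedigree skeleton (sexes and parentage only)."""
    members: list[Individual] = []
    counter = [0]

    def new(sex: Sex, father: str = "0", mother: str = "0") -> Individual:
        counter[0] += 1
        ind = Individual(id=str(counter[0]), father_id=father, mother_id=mother, sex=sex)
        members.append(ind)
        return ind

    father = new(Sex.MALE)
    mother = new(Sex.FEMALE)
    three_gen = rng.random() < template.p_three_generations
    n_kids = int(rng.integers(template.sibship[0], template.sibship[1] + 1))
    kids = [new(Sex.MALE if rng.random() < 0.5 else Sex.FEMALE, father.id, mother.id) for _ in range(n_kids)]
    if three_gen:
        for kid in kids:
            if rng.random() < template.p_marry:
                spouse = new(Sex.FEMALE if kid.sex is Sex.MALE else Sex.MALE)
                fa, mo = (kid, spouse) if kid.sex is Sex.MALE else (spouse, kid)
                n_g3 = int(rng.integers(template.sibship_g3[0], template.sibship_g3[1] + 1))
                for _ in range(n_g3):
                    new(Sex.MALE if rng.random() < 0.5 else Sex.FEMALE, fa.id, mo.id)
    ped = Pedigree(family_id, members)
    assert not [i for i in validate_pedigree(ped) if i.severity == "error"]
    return ped


def _sample_state(probs: np.ndarray, rng: np.random.Generator) -> int:
    return int(rng.choice(len(probs), p=probs / probs.sum()))


def gene_drop(
    skeleton: Pedigree,
    freqs: AlleleFrequencies,
    rng: np.random.Generator,
    founder_carrier_boost: float = 0.0,
) -> dict[str, LatentState]:
    """Drop genotypes down the pedigree: founders from Hardy-Weinberg
    priors, non-founders by Mendelian transmission.

    With probability ``founder_carrier_boost`` the founding mother is made
    an S carrier and one random member of the founding couple a T carrier.
    The founding couple is the parental pair whose members are both
    founders and whose ids sort first.
    """
    geno: dict[str, int] = {}
    members = sorted(skeleton.members, key=lambda m: int(m.id) if m.id.isdigit() else m.id)
    for m in members:
        if m.is_founder:
            geno[m.id] = _sample_state(founder_prior(m.sex, freqs), rng)

    founding = None
    for fa, mo, _kids in skeleton.nuclear_units():
        if skeleton[fa].is_founder and skeleton[mo].is_founder:
            founding = (fa, mo)
            break
    if founding is not None:
        fa, mo = founding
        if rng.random() < founder_carrier_boost:
            a_mo = geno[mo] % 3
            geno[mo] = 1 * 3 + a_mo  # S/wt at the X locus
        if rng.random() < founder_carrier_boost:
            who = fa if rng.random() < 0.5 else mo
            x_who = geno[who] // 3
            geno[who] = x_who * 3 + max(geno[who] % 3, 1)  # at least one T allele

    # topological drop: parents before children
    remaining = [m for m in members if not m.is_founder]
    while remaining:
        progressed = False
        for m in list(remaining):
            if m.father_id in geno and m.mother_id in geno:
                T = transmission_tensor(m.sex)
                geno[m.id] = _sample_state(T[geno[m.father_id], geno[m.mother_id]], rng)
                remaining.remove(m)
                progressed = True
        if not progressed:  # pragma: no cover - guarded by validation
            raise RuntimeError("unresolvable parentage ordering")

    return {iid: LatentState(x_count=s // 3, a_count=s % 3) for iid, s in geno.items()}


def assign_phenotypes(
    skeleton: Pedigree,
    latent: dict[str, LatentState],
    model: PenetranceModel,
    xi_dist: XiSkewDistribution,
    rng: np.random.Generator,
) -> tuple[Pedigree, dict[str, LatentState]]:
    """Sample X-inactivation for carrier females, then affection status.

    Returns the pedigree with observable fields filled in (every member's
    two-locus carrier status and, for carrier females, the categorical
    X-inactivation call) alongside the updated latent states.
    """
    out_members: list[Individual] = []
    out_latent: dict[str, LatentState] = {}
    for m in sorted(skeleton.members, key=lambda x: int(x.id) if x.id.isdigit() else x.id):
        st = latent[m.id]
        xi = XInactivation.UNKNOWN
        if m.sex is Sex.FEMALE and st.x_count > 0:
            frac = float(rng.beta(xi_dist.alpha, xi_dist.beta))
            st = replace(st, x_active_fraction=frac)
            xi = xi_dist.categorize(frac)
        p_aff = penetrance(JointGenotype(st.x_count, st.a_count), m.sex, xi, model)
        affection = Affection.AFFECTED if rng.random() < p_aff else Affection.UNAFFECTED

        if m.sex is Sex.MALE:
            s_obs = XObs.HEMI_MUT if st.x_count == 1 else XObs.WT
        elif st.x_count == 0:
            s_obs = XObs.WT
        elif st.x_count == 1:
            s_obs = XObs.HET_CARRIER
        else:  # S/S female not encodable in the observation alphabet
            s_obs = XObs.UNKNOWN
        if st.a_count == 0:
            t_obs = TObs.HOM_WT
        elif st.a_count == 1:
            t_obs = TObs.HET_MUT
        else:  # T/T not encodable
            t_obs = TObs.UNKNOWN

        out_latent[m.id] = st
        out_members.append(
            replace(m, affection=affection, s_obs=s_obs, t_obs=t_obs, xi_status=xi)
        )
    return Pedigree(skeleton.family_id, out_members), out_latent


def _satisfies(ped: Pedigree, rule: str) -> str | None:
    """Proband id when the ascertainment rule holds, else None."""
    if rule == "none":
        return None
    for m in sorted(ped.members, key=lambda x: int(x.id) if x.id.isdigit() else x.id):
        if m.affection is Affection.AFFECTED and (
            rule == "at_least_one_affected" or m.sex is Sex.MALE
        ):
            return m.id
    return None


def simulate_family(config: SimConfig, rng: np.random.Generator, family_id: str) -> tuple[Pedigree, dict[str, LatentState]]:
    skeleton = make_structure(config.structure, rng, family_id)
    latent = gene_drop(skeleton, config.freqs, rng, config.founder_carrier_boost)
    return assign_phenotypes(skeleton, latent, config.model, config.xi_skew_distribution, rng)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Rejection-sample families until the ascertainment rule is satisfied.

    Retained families carry the proband flag (the first affected individual,
    in id order, satisfying the rule); ``n_rejected`` counts discards.
    Identical configs (including the seed) give identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    peds: list[Pedigree] = []
    latents: list[dict[str, LatentState]] = []
    n_rejected = 0
    while len(peds) < config.n_families:
        fid = f"F{len(peds) + 1:03d}"
        ped, latent = simulate_family(config, rng, fid)
        if config.ascertainment == "none":
            peds.append(ped)
            latents.append(latent)
            continue
        proband = _satisfies(ped, config.ascertainment)
        if proband is None:
            n_rejected += 1
            if n_rejected > config.max_rejections:
                raise AscertainmentError(
                    "ascertainment acceptance probability too low; consider raising "
                    "founder_carrier_boost or relaxing the rule"
                )
            continue
        ped = Pedigree(
            ped.family_id,
            [replace(m, proband=(m.id == proband)) for m in ped.members],
        )
        peds.append(ped)
        latents.append(latent)
    return SimulatedCohort(pedigrees=peds, latent=latents, provenance=config, n_rejected=n_rejected)
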