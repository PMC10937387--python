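"""Exact two-locus pedigree likelihoods by Elston-Stewart peeling.

The model couples an X-linked locus (deleterious allele ``S``, frequency
``q_s``) with an unlinked autosomal locus (truncating allele ``T``,
frequency ``q_t``).  Joint genotypes are enumerated as ``x_count * 3 +
a_count`` where ``x_count`` is the number of S alleles (males 0..1, females
0..2) and ``a_count`` the number of T alleles (0..2); males therefore have
6 joint states and females 9.  Founders follow Hardy-Weinberg priors at
both loci; transmission is Mendelian, with sons receiving no paternal X.

Phenotypes enter through a penetrance model: one of five inheritance-model
families (null, X-linked monogenic, autosomal monogenic, locus
heterogeneity, digenic AND) maps each joint genotype, sex and
X-inactivation category to a probability of being affected.  Skewed
X-inactivation with the mutant X active unmasks carrier females; a mutant X
that is silenced protects them (phenocopy rate only).

Likelihoods are exact sums over all joint genotype configurations, computed
by peeling over the tree of nuclear families (loop-free pedigrees only) and
cross-checked by :func:`brute_force_likelihood`, a direct enumeration kept
deliberately independent of the peeling code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Mapping

import numpy as np

from .pedigree import (
    Affection,
    Individual,
    Pedigree,
    PedigreeError,
    Sex,
    TObs,
    XInactivation,
    XObs,
    validate_pedigree,
)

N_MALE_STATES = 6   # x in {0,1} times a in {0,1,2}
N_FEMALE_STATES = 9  # x in {0,1,2} times a in {0,1,2}


@dataclass(frozen=True)
class JointGenotype:
    """Joint two-locus genotype as mutant-allele counts (x: X locus, a: autosomal)."""

    x_count: int
    a_count: int

    def state_index(self) -> int:
        return self.x_count * 3 + self.a_count


def state_space(sex: Sex) -> list[JointGenotype]:
    """Fixed enumeration order: x_count major, a_count minor."""
    n_x = 2 if sex is Sex.MALE else 3
    return [JointGenotype(x, a) for x in range(n_x) for a in range(3)]


def _n_states(sex: Sex) -> int:
    return N_MALE_STATES if sex is Sex.MALE else N_FEMALE_STATES


class ModelFamily(str, Enum):
    NULL = "null_model"
    MONOGENIC_X = "monogenic_x"
    MONOGENIC_A = "monogenic_a"
    HETEROGENEITY_OR = "heterogeneity_or"
    DIGENIC_AND = "digenic_and"


@dataclass(frozen=True)
class AlleleFrequencies:
    """Population frequencies of the two deleterious alleles.

    Defaults: ``q_s`` from 6 hemizygous loss-of-function males among 76,702
    reference males; ``q_t`` such that roughly 2% of the population carries
    a truncating autosomal allele (allele frequency ~1%).
    """

    q_s: float = 6 / 76702
    q_t: float = 0.01

    def __post_init__(self):
        for name, v in (("q_s", self.q_s), ("q_t", self.q_t)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PenetranceModel:
    """Inheritance-model family plus penetrance/phenocopy parameters.

    ``f_m`` is the penetrance of the at-risk genotype in males (and, for the
    autosomal branch, the sex-shared carrier penetrance); ``f_f_skewed`` and
    ``f_f_random`` are female penetrances under mutant-X-active skewing and
    random/unknown X-inactivation respectively; ``f_a`` is the autosomal-branch
    carrier penetrance used by the locus-heterogeneity family (which takes
    the strongest applicable cause, floored by ``eps``); ``eps`` is the
    phenocopy rate.  A carrier female whose mutant X is silenced falls back
    to the phenocopy rate on the X branch.
    """

    family: ModelFamily
    f_m: float = 1.0
    f_f_skewed: float = 1.0
    f_f_random: float = 0.0
    f_a: float = 0.0
    eps: float = 0.0

    def __post_init__(self):
        for name in ("f_m", "f_f_skewed", "f_f_random", "f_a", "eps"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class LikelihoodResult:
    log_likelihood: float
    per_family_terms: dict[str, float]
    conditioned_on_proband: bool = False
    diagnostic: str | None = None


class UnsupportedStructureError(PedigreeError):
    """Pedigree structure the exact engine does not handle (loops)."""


class EnumerationSizeError(ValueError):
    """Brute-force genotype enumeration would be too large."""


# ---------------------------------------------------------------------------
# penetrance

# Each (genotype, sex, XI, model family) maps to a symbolic *term key*; the
# key evaluates to a probability of affection given the four model
# parameters.  Keeping the key symbolic lets model fitting re-evaluate
# likelihood summaries across a parameter grid without re-peeling.
TERM_VALUES: dict[str, Callable[[Mapping[str, np.ndarray | float]], np.ndarray | float]] = {
    "f_m": lambda p: p["f_m"],
    "f_f_skewed": lambda p: p["f_f_skewed"],
    "f_f_random": lambda p: p["f_f_random"],
    "eps": lambda p: p["eps"],
    # locus-heterogeneity terms: the strongest applicable cause determines
    # risk, with the phenocopy rate as a floor; setting one branch's
    # penetrance to zero recovers the corresponding monogenic model exactly
    "het_a": lambda p: np.maximum(p["f_a"], p["eps"]),
    "het_m": lambda p: np.maximum(p["f_m"], p["eps"]),
    "het_s": lambda p: np.maximum(p["f_f_skewed"], p["eps"]),
    "het_r": lambda p: np.maximum(p["f_f_random"], p["eps"]),
    "het_ma": lambda p: np.maximum(np.maximum(p["f_m"], p["f_a"]), p["eps"]),
    "het_sa": lambda p: np.maximum(np.maximum(p["f_f_skewed"], p["f_a"]), p["eps"]),
    "het_ra": lambda p: np.maximum(np.maximum(p["f_f_random"], p["f_a"]), p["eps"]),
}


def _female_x_key(xi: XInactivation) -> str | None:
    """X-branch penetrance key for a carrier female, or None when silenced."""
    if xi is XInactivation.SKEWED_MUT_ACTIVE:
        return "f_f_skewed"
    if xi is XInactivation.SKEWED_MUT_SILENCED:
        return None
    # random and unknown are both treated as random
    return "f_f_random"


def penetrance_key(x_count: int, a_count: int, sex: Sex, xi: XInactivation, family: ModelFamily) -> str:
    x_risk = x_count > 0
    a_risk = a_count > 0
    if family is ModelFamily.NULL:
        return "eps"
    if family is ModelFamily.MONOGENIC_X:
        if not x_risk:
            return "eps"
        if sex is Sex.MALE:
            return "f_m"
        return _female_x_key(xi) or "eps"
    if family is ModelFamily.MONOGENIC_A:
        return "f_m" if a_risk else "eps"
    if family is ModelFamily.DIGENIC_AND:
        if not (x_risk and a_risk):
            return "eps"
        if sex is Sex.MALE:
            return "f_m"
        return _female_x_key(xi) or "eps"
    if family is ModelFamily.HETEROGENEITY_OR:
        xkey = None
        if x_risk:
            xkey = "f_m" if sex is Sex.MALE else _female_x_key(xi)
        branch = {"f_m": "m", "f_f_skewed": "s", "f_f_random": "r", None: None}[xkey]
        if branch and a_risk:
            return f"het_{branch}a"
        if branch:
            return f"het_{branch}"
        if a_risk:
            return "het_a"
        return "eps"
    raise ValueError(f"unknown model family {family}")


def _params_dict(model: PenetranceModel) -> dict[str, float]:
    return {
        "f_m": model.f_m,
        "f_f_skewed": model.f_f_skewed,
        "f_f_random": model.f_f_random,
        "f_a": model.f_a,
        "eps": model.eps,
    }


def penetrance(
    geno: JointGenotype, sex: Sex, xi_status: XInactivation, model: PenetranceModel
) -> float:
    """Probability of being affected for a joint genotype."""
    key = penetrance_key(geno.x_count, geno.a_count, sex, xi_status, model.family)
    return float(TERM_VALUES[key](_params_dict(model)))


def penetrance_vector(sex: Sex, xi: XInactivation, model: PenetranceModel) -> np.ndarray:
    return np.array([penetrance(g, sex, xi, model) for g in state_space(sex)])


# ---------------------------------------------------------------------------
# founder priors and transmission

def founder_prior(sex: Sex, freqs: AlleleFrequencies) -> np.ndarray:
    """Hardy-Weinberg founder prior over the joint genotype states."""
    qs, qt = freqs.q_s, freqs.q_t
    if sex is Sex.MALE:
        px = np.array([1.0 - qs, qs])
    else:
        px = np.array([(1.0 - qs) ** 2, 2.0 * qs * (1.0 - qs), qs**2])
    pa = np.array([(1.0 - qt) ** 2, 2.0 * qt * (1.0 - qt), qt**2])
    return np.outer(px, pa).ravel()


def _allele_from_pair(count: int) -> np.ndarray:
    """P(transmit 0 or 1 mutant allele) from a diploid mutant-allele count."""
    p = count / 2.0
    return np.array([1.0 - p, p])


_TRANS_CACHE: dict[Sex, np.ndarray] = {}


def transmission_tensor(child_sex: Sex) -> np.ndarray:
    """T[father_state, mother_state, child_state] transmission probabilities."""
    if child_sex in _TRANS_CACHE:
        return _TRANS_CACHE[child_sex]
    n_c = _n_states(child_sex)
    T = np.zeros((N_MALE_STATES, N_FEMALE_STATES, n_c))
    for fi, fg in enumerate(state_space(Sex.MALE)):
        for mi, mg in enumerate(state_space(Sex.FEMALE)):
            # X locus: sons draw only from the mother; daughters get the
            # father's single X allele plus one maternal draw
            mom_x = _allele_from_pair(mg.x_count)
            if child_sex is Sex.MALE:
                px = mom_x  # over x_count in {0,1}
            else:
                px = np.zeros(3)
                for k in (0, 1):
                    px[fg.x_count + k] += mom_x[k]
            # autosomal locus: one draw from each parent
            pa = np.zeros(3)
            for j, pj in enumerate(_allele_from_pair(fg.a_count)):
                for k, pk in enumerate(_allele_from_pair(mg.a_count)):
                    pa[j + k] += pj * pk
            for ci, cg in enumerate(state_space(child_sex)):
                T[fi, mi, ci] = px[cg.x_count] * pa[cg.a_count]
    T.setflags(write=False)
    _TRANS_CACHE[child_sex] = T
    return T


def transmission_prob(
    child: JointGenotype, child_sex: Sex, father: JointGenotype, mother: JointGenotype
) -> float:
    """Probability of a child's joint genotype given parental genotypes."""
    for g, sex, who in ((father, Sex.MALE, "father"), (mother, Sex.FEMALE, "mother"), (child, child_sex, "child")):
        n_x = 2 if sex is Sex.MALE else 3
        if not (0 <= g.x_count < n_x and 0 <= g.a_count <= 2):
            raise ValueError(f"invalid genotype {g} for {who} ({sex.value})")
    T = transmission_tensor(child_sex)
    return float(T[father.state_index(), mother.state_index(), child.state_index()])


# ---------------------------------------------------------------------------
# per-individual factors

def _obs_indicator(ind: Individual) -> np.ndarray:
    """Hard 0/1 indicator over states from the genotype observations."""
    ok = np.ones(_n_states(ind.sex))
    for si, g in enumerate(state_space(ind.sex)):
        if ind.s_obs is XObs.WT and g.x_count != 0:
            ok[si] = 0.0
        elif ind.s_obs is XObs.HET_CARRIER and g.x_count != 1:
            ok[si] = 0.0
        elif ind.s_obs is XObs.HEMI_MUT and g.x_count != 1:
            ok[si] = 0.0
        if ind.t_obs is TObs.HOM_WT and g.a_count != 0:
            ok[si] = 0.0
        elif ind.t_obs is TObs.HET_MUT and g.a_count != 1:
            ok[si] = 0.0
    return ok


def _phenotype_factor(ind: Individual, model: PenetranceModel) -> np.ndarray:
    if ind.affection is Affection.UNKNOWN:
        return np.ones(_n_states(ind.sex))
    pen = penetrance_vector(ind.sex, ind.xi_status, model)
    return pen if ind.affection is Affection.AFFECTED else 1.0 - pen


def _individual_factor(
    ind: Individual, model: PenetranceModel, freqs: AlleleFrequencies
) -> np.ndarray:
    phi = _obs_indicator(ind) * _phenotype_factor(ind, model)
    if ind.is_founder:
        phi = phi * founder_prior(ind.sex, freqs)
    return phi


# ---------------------------------------------------------------------------
# peeling

def _check_structure(ped: Pedigree) -> None:
    """Reject structurally invalid pedigrees; observation-level Mendelian
    conflicts pass through and surface as a zero likelihood."""
    errors = [
        i for i in validate_pedigree(ped) if i.severity == "error" and i.kind == "structure"
    ]
    loops = [i for i in errors if "loop" in i.message or "cycle" in i.message]
    if loops:
        raise UnsupportedStructureError(f"family {ped.family_id}: {loops[0].message}")
    if errors:
        raise PedigreeError(f"family {ped.family_id}: " + "; ".join(i.message for i in errors))


def _peel_linear(ped: Pedigree, model: PenetranceModel, freqs: AlleleFrequencies) -> float:
    """Total pedigree likelihood in linear space (exact, loop-free only)."""
    phi = {m.id: _individual_factor(m, model, freqs) for m in ped.members}
    units = ped.nuclear_units()  # deterministic sorted order
    unit_members = {u: (u[0], u[1], *u[2]) for u in units}
    of_ind: dict[str, list] = {m.id: [] for m in ped.members}
    for u in units:
        for iid in unit_members[u]:
            of_ind[iid].append(u)

    memo: dict[tuple, np.ndarray] = {}

    def msg_i2u(iid: str, unit) -> np.ndarray:
        key = ("I", iid, unit)
        if key not in memo:
            out = phi[iid].copy()
            for v in of_ind[iid]:
                if v != unit:
                    out = out * msg_u2i(v, iid)
            memo[key] = out
        return memo[key]

    def msg_u2i(unit, iid: str) -> np.ndarray:
        key = ("U", unit, iid)
        if key in memo:
            return memo[key]
        father, mother, children = unit[0], unit[1], unit[2]
        inc = {j: msg_i2u(j, unit) for j in unit_members[unit] if j != iid}
        # per-child collapse onto the parental joint state
        def child_term(cid: str) -> np.ndarray:
            T = transmission_tensor(ped[cid].sex)
            return np.einsum("fmc,c->fm", T, inc[cid])

        if iid == father or iid == mother:
            other = mother if iid == father else father
            joint = np.outer(np.ones(N_MALE_STATES), inc[other]) if iid == father else np.outer(
                inc[other], np.ones(N_FEMALE_STATES)
            )
            for cid in children:
                joint = joint * child_term(cid)
            res = joint.sum(axis=1) if iid == father else joint.sum(axis=0)
        else:
            joint = np.outer(inc[father], inc[mother])
            for cid in children:
                if cid != iid:
                    joint = joint * child_term(cid)
            T = transmission_tensor(ped[iid].sex)
            res = np.einsum("fm,fmc->c", joint, T)
        memo[key] = res
        return res

    # connected components over the unit-individual bipartite structure
    seen: set[str] = set()
    total = 1.0
    for root in sorted(of_ind):
        if root in seen:
            continue
        # collect the component by flood fill
        comp, stack = {root}, [root]
        while stack:
            cur = stack.pop()
            for u in of_ind[cur]:
                for j in unit_members[u]:
                    if j not in comp:
                        comp.add(j)
                        stack.append(j)
        seen |= comp
        vec = phi[root].copy()
        for u in of_ind[root]:
            vec = vec * msg_u2i(u, root)
        total *= float(vec.sum())
        if total == 0.0:
            return 0.0
    return total


def _zero_diagnostic(ped: Pedigree, model: PenetranceModel, freqs: AlleleFrequencies) -> str:
    for m in ped.members:
        if not np.any(_individual_factor(m, model, freqs) > 0.0):
            return (
                f"family {ped.family_id}: individual {m.id} has no genotype state "
                "consistent with its observations under this model"
            )
    return (
        f"family {ped.family_id}: observations are jointly inconsistent with "
        "Mendelian transmission under this model"
    )


def pedigree_likelihood(
    ped: Pedigree,
    model: PenetranceModel,
    freqs: AlleleFrequencies,
    condition_on_proband: bool = False,
) -> LikelihoodResult:
    """Exact log-likelihood of one pedigree's phenotype and genotype data.

    With ``condition_on_proband`` the likelihood is divided by the marginal
    probability of the proband's observed affection status (classical
    single-ascertainment correction); the pedigree must then carry a proband
    with known affection.
    """
    _check_structure(ped)
    lik = _peel_linear(ped, model, freqs)
    diagnostic = None
    if lik == 0.0:
        loglik = -math.inf
        diagnostic = _zero_diagnostic(ped, model, freqs)
    else:
        loglik = math.log(lik)
    if condition_on_proband:
        pro = ped.proband
        if pro is None or pro.affection is Affection.UNKNOWN:
            raise ValueError(
                f"family {ped.family_id}: conditioning requires a proband with known affection"
            )
        denom = _peel_linear(ped.strip_observations(keep_proband_affection=True), model, freqs)
        loglik -= math.log(denom) if denom > 0.0 else -math.inf
    return LikelihoodResult(
        log_likelihood=loglik,
        per_family_terms={ped.family_id: loglik},
        conditioned_on_proband=condition_on_proband,
        diagnostic=diagnostic,
    )


def cohort_log_likelihood(
    peds: Iterable[Pedigree],
    model: PenetranceModel,
    freqs: AlleleFrequencies,
    condition_on_proband: bool = False,
) -> LikelihoodResult:
    """Summed log-likelihood over independent families."""
    terms: dict[str, float] = {}
    diagnostic = None
    for ped in peds:
        res = pedigree_likelihood(ped, model, freqs, condition_on_proband)
        terms[ped.family_id] = res.log_likelihood
        if diagnostic is None and res.diagnostic is not None:
            diagnostic = res.diagnostic
    return LikelihoodResult(
        log_likelihood=sum(terms.values()),
        per_family_terms=terms,
        conditioned_on_proband=condition_on_proband,
        diagnostic=diagnostic,
    )


# ---------------------------------------------------------------------------
# brute-force oracle

_BRUTE_MAX_MEMBERS = 12
_BRUTE_MAX_CONFIGS = 4_000_000


def _brute_linear(ped: Pedigree, model: PenetranceModel, freqs: AlleleFrequencies) -> float:
    members = sorted(ped.members, key=lambda m: m.id)
    phis = []
    allowed = []
    for m in members:
        phi = _individual_factor(m, model, freqs)
        states = np.nonzero(phi > 0.0)[0]
        if states.size == 0:
            return 0.0
        phis.append(phi)
        allowed.append(states)
    n_configs = math.prod(len(s) for s in allowed)
    if n_configs > _BRUTE_MAX_CONFIGS:
        raise EnumerationSizeError(
            f"family {ped.family_id}: {n_configs} genotype configurations exceed the "
            f"enumeration guard ({_BRUTE_MAX_CONFIGS})"
        )
    grids = np.meshgrid(*allowed, indexing="ij")
    configs = {m.id: g.ravel() for m, g in zip(members, grids)}
    value = np.ones(n_configs)
    for m, phi in zip(members, phis):
        value *= phi[configs[m.id]]
    for m in members:
        if not m.is_founder:
            T = transmission_tensor(m.sex)
            value *= T[configs[m.father_id], configs[m.mother_id], configs[m.id]]
    return float(value.sum())


def brute_force_likelihood(
    ped: Pedigree,
    model: PenetranceModel,
    freqs: AlleleFrequencies,
    condition_on_proband: bool = False,
) -> LikelihoodResult:
    """Likelihood by explicit enumeration of every genotype assignment.

    Verification oracle for the peeling engine; guarded to small pedigrees.
    """
    if len(ped) > _BRUTE_MAX_MEMBERS:
        raise EnumerationSizeError(
            f"family {ped.family_id}: {len(ped)} members exceed the brute-force limit "
            f"({_BRUTE_MAX_MEMBERS})"
        )
    lik = _brute_linear(ped, model, freqs)
    loglik = math.log(lik) if lik > 0.0 else -math.inf
    diagnostic = None if lik > 0.0 else _zero_diagnostic(ped, model, freqs)
    if condition_on_proband:
        pro = ped.proband
        if pro is None or pro.affection is Affection.UNKNOWN:
            raise ValueError(
                f"family {ped.family_id}: conditioning requires a proband with known affection"
            )
        denom = _brute_linear(ped.strip_observations(keep_proband_affection=True), model, freqs)
        loglik -= math.log(denom) if denom > 0.0 else -math.inf
    return LikelihoodResult(
        log_likelihood=loglik,
        per_family_terms={ped.family_id: loglik},
        conditioned_on_proband=condition_on_proband,
        diagnostic=diagnostic,
    )
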