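"""Maximum-likelihood fitting and comparison of inheritance-model families.

Each model family (null, monogenic X, monogenic autosomal, locus
heterogeneity, digenic AND) is fitted to a set of pedigrees by maximizing
the summed per-family log-likelihood over its free penetrance parameters:
a coarse grid (step 0.05) followed by bounded local refinement from the
best grid points.  Families are then ranked by maximized log-likelihood and
compared through pairwise log10 likelihood ratios.

Fitting avoids re-peeling every pedigree at every parameter point: the
phenotype part of the likelihood is a mixture of monomials in the four
penetrance parameters (each genotype configuration contributes a product of
``f``/``1-f`` terms), so each family is summarised once per model family by
enumerating its observation-consistent genotype configurations.  The
summary evaluates across the whole grid with array arithmetic and equals
the peeling likelihood exactly (property-tested); pedigrees whose
configuration space is too large fall back to direct peeling per point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .likelihood import (
    TERM_VALUES,
    AlleleFrequencies,
    ModelFamily,
    PenetranceModel,
    founder_prior,
    pedigree_likelihood,
    penetrance_key,
    state_space,
    transmission_tensor,
    _obs_indicator,
)
from .pedigree import Affection, Pedigree

LN10 = math.log(10.0)

#: free parameters per model family (minimal spaces realising the
#: reduced-penetrance alternatives; the rest stay at their defaults)
FREE_PARAMS: dict[ModelFamily, tuple[str, ...]] = {
    ModelFamily.NULL: ("eps",),
    ModelFamily.MONOGENIC_X: ("f_m", "f_f_skewed", "f_f_random", "eps"),
    ModelFamily.MONOGENIC_A: ("f_m", "eps"),
    ModelFamily.HETEROGENEITY_OR: ("f_m", "f_f_skewed", "f_f_random", "f_a", "eps"),
    ModelFamily.DIGENIC_AND: ("f_m", "f_f_skewed", "f_f_random", "eps"),
}

_PARAM_NAMES = ("f_m", "f_f_skewed", "f_f_random", "f_a", "eps")


class FitError(RuntimeError):
    pass


@dataclass
class FitOptions:
    """Options controlling grid fitting; deterministic given the grid."""

    seed: int = 0
    grid_step: float = 0.05
    eps_max: float = 0.1          # phenocopies of a severe myopathy are rare
    condition_on_proband: bool = False
    refine: bool = True
    n_refine: int = 3
    fixed_params: dict[str, float] = field(default_factory=dict)
    summary_config_cap: int = 20_000


@dataclass
class ModelFit:
    family: ModelFamily
    mle_params: dict[str, float]
    log_likelihood: float
    n_families: int
    converged: bool
    n_restarts_used: int

    @property
    def model(self) -> PenetranceModel:
        return PenetranceModel(family=self.family, **self.mle_params)


@dataclass
class ComparisonResult:
    fits: dict[ModelFamily, ModelFit]
    best_family: ModelFamily
    log10_lr_vs_next_best: float
    pairwise_log10_lr: dict[ModelFamily, dict[ModelFamily, float]]


# ---------------------------------------------------------------------------
# per-family likelihood summaries

@dataclass
class _Summary:
    """Phenotype likelihood of one family as sum_p w_p * prod_k v_k^{n_k}."""

    family_id: str
    patterns: list[tuple[float, tuple[tuple[tuple[str, bool], int], ...]]]
    # ascertainment denominator: proband prior mass per term key, or None
    proband_masses: list[tuple[str, float]] | None
    proband_affected: bool = True


@dataclass
class _PeelFallback:
    family_id: str
    pedigree: Pedigree


def _summarize_family(
    ped: Pedigree,
    family: ModelFamily,
    freqs: AlleleFrequencies,
    condition_on_proband: bool,
    cap: int,
) -> _Summary | _PeelFallback:
    members = sorted(ped.members, key=lambda m: m.id)
    allowed: list[np.ndarray] = []
    bases: list[np.ndarray] = []
    for m in members:
        base = _obs_indicator(m)  # genotype part only; phenotype enters via term keys
        if m.is_founder:
            base = base * founder_prior(m.sex, freqs)
        states = np.nonzero(base > 0.0)[0]
        allowed.append(states)
        bases.append(base)
    n_configs = math.prod(len(s) for s in allowed)
    if n_configs == 0:
        return _Summary(ped.family_id, [], _proband_masses(ped, family, freqs, condition_on_proband))
    if n_configs > cap:
        return _PeelFallback(ped.family_id, ped)

    grids = np.meshgrid(*allowed, indexing="ij")
    cfg = {m.id: g.ravel() for m, g in zip(members, grids)}
    weight = np.ones(n_configs)
    for m, base in zip(members, bases):
        weight *= base[cfg[m.id]]
    for m in members:
        if not m.is_founder:
            T = transmission_tensor(m.sex)
            weight *= T[cfg[m.father_id], cfg[m.mother_id], cfg[m.id]]

    # phenotype term keys per member per state
    key_tables: dict[str, list[tuple[str, bool] | None]] = {}
    for m in members:
        if m.affection is Affection.UNKNOWN:
            key_tables[m.id] = [None] * len(state_space(m.sex))
            continue
        aff = m.affection is Affection.AFFECTED
        key_tables[m.id] = [
            (penetrance_key(g.x_count, g.a_count, m.sex, m.xi_status, family), aff)
            for g in state_space(m.sex)
        ]

    patterns: dict[tuple, float] = {}
    for i in range(n_configs):
        w = weight[i]
        if w == 0.0:
            continue
        counts: dict[tuple[str, bool], int] = {}
        for m in members:
            entry = key_tables[m.id][cfg[m.id][i]]
            if entry is not None:
                counts[entry] = counts.get(entry, 0) + 1
        sig = tuple(sorted(counts.items()))
        patterns[sig] = patterns.get(sig, 0.0) + w
    pat_list = [(w, sig) for sig, w in sorted(patterns.items())]
    return _Summary(
        ped.family_id,
        pat_list,
        _proband_masses(ped, family, freqs, condition_on_proband),
    )


def _proband_masses(
    ped: Pedigree, family: ModelFamily, freqs: AlleleFrequencies, condition: bool
) -> list[tuple[str, float]] | None:
    """Prior mass per penetrance term key for the proband's marginal genotype.

    Under random mating and Hardy-Weinberg founders, every individual's
    marginal joint-genotype distribution is the Hardy-Weinberg product, so
    P(proband's affection status) needs no peeling.
    """
    if not condition:
        return None
    pro = ped.proband
    if pro is None or pro.affection is Affection.UNKNOWN:
        raise FitError(
            f"family {ped.family_id}: conditioning requires a proband with known affection"
        )
    prior = founder_prior(pro.sex, freqs)
    masses: dict[str, float] = {}
    for s, g in enumerate(state_space(pro.sex)):
        key = penetrance_key(g.x_count, g.a_count, pro.sex, pro.xi_status, family)
        masses[key] = masses.get(key, 0.0) + float(prior[s])
    return sorted(masses.items())


def _safe_log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(x > 0.0, np.log(np.maximum(x, 1e-300)), -np.inf)


def _eval_summary(summary: _Summary, theta: Mapping[str, np.ndarray]) -> np.ndarray:
    """Log-likelihood of one family across a batch of parameter points."""
    g_shape = np.broadcast(*(np.asarray(v) for v in theta.values())).shape
    vals: dict[str, np.ndarray] = {}

    def val(key: str) -> np.ndarray:
        if key not in vals:
            vals[key] = np.clip(np.broadcast_to(TERM_VALUES[key](theta), g_shape), 0.0, 1.0)
        return vals[key]

    if not summary.patterns:
        out = np.full(g_shape, -np.inf)
    else:
        logs = np.full((len(summary.patterns),) + g_shape, -np.inf)
        for pi, (w, sig) in enumerate(summary.patterns):
            term = np.full(g_shape, math.log(w))
            for (key, affected), n in sig:
                v = val(key) if affected else 1.0 - val(key)
                term = term + n * _safe_log(v)
            logs[pi] = term
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = np.max(logs, axis=0)
            safe_mx = np.where(np.isfinite(mx), mx, 0.0)
            out = safe_mx + np.log(np.sum(np.exp(logs - safe_mx), axis=0))
            out = np.where(np.isfinite(mx), out, -np.inf)
    if summary.proband_masses is not None:
        denom = np.zeros(g_shape)
        for key, mass in summary.proband_masses:
            p = val(key)
            denom = denom + mass * (p if summary.proband_affected else 1.0 - p)
        # a zero denominator means the proband's status itself is impossible
        # under these parameters; the conditioned likelihood is then zero too
        with np.errstate(invalid="ignore"):
            out = np.where(denom > 0.0, out - _safe_log(np.maximum(denom, 1e-300)), -np.inf)
    return out


# ---------------------------------------------------------------------------
# fitting

def _grid_axes(family: ModelFamily, options: FitOptions) -> dict[str, np.ndarray]:
    axes: dict[str, np.ndarray] = {}
    free = FREE_PARAMS[family]
    defaults = PenetranceModel(family=family)
    for name in _PARAM_NAMES:
        if name in options.fixed_params:
            axes[name] = np.array([float(options.fixed_params[name])])
        elif name in free:
            hi = options.eps_max if name == "eps" else 1.0
            n = int(round(hi / options.grid_step)) + 1
            axes[name] = np.linspace(0.0, hi, n)
        else:
            axes[name] = np.array([getattr(defaults, name)])
    return axes


def _total_loglik(summaries, theta) -> np.ndarray:
    total = None
    for s in summaries:
        if isinstance(s, _Summary):
            term = _eval_summary(s, theta)
        else:  # peeling fallback, scalar theta only
            term = np.asarray(
                _eval_fallback(s, theta)
            )
        total = term if total is None else total + term
    return total


_FALLBACK_CTX: dict[str, object] = {}


def _eval_fallback(fb: _PeelFallback, theta: Mapping[str, np.ndarray]) -> np.ndarray:
    family: ModelFamily = _FALLBACK_CTX["family"]
    freqs: AlleleFrequencies = _FALLBACK_CTX["freqs"]
    condition: bool = _FALLBACK_CTX["condition"]
    arrs = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in theta.items()}
    shape = np.broadcast(*arrs.values()).shape
    flat = {k: np.broadcast_to(v, shape).ravel() for k, v in arrs.items()}
    n = flat["f_m"].size
    out = np.empty(n)
    for i in range(n):
        model = PenetranceModel(
            family=family,
            f_m=float(flat["f_m"][i]),
            f_f_skewed=float(flat["f_f_skewed"][i]),
            f_f_random=float(flat["f_f_random"][i]),
            f_a=float(flat["f_a"][i]),
            eps=float(flat["eps"][i]),
        )
        out[i] = pedigree_likelihood(fb.pedigree, model, freqs, condition).log_likelihood
    return out.reshape(shape) if shape else out[0]


def fit_model(
    peds: Sequence[Pedigree],
    family: ModelFamily,
    freqs: AlleleFrequencies | None = None,
    options: FitOptions | None = None,
    extra_starts: Sequence[Mapping[str, float]] = (),
) -> ModelFit:
    """Fit one inheritance-model family by grid search plus refinement.

    ``extra_starts`` supplies additional refinement starting points (full
    parameter mappings); used by :func:`compare_models` to seed the
    locus-heterogeneity fit from the monogenic optima it nests.
    """
    freqs = freqs or AlleleFrequencies()
    options = options or FitOptions()
    peds = list(peds)
    if not peds:
        raise FitError("no pedigrees supplied")

    _FALLBACK_CTX.update(family=family, freqs=freqs, condition=options.condition_on_proband)
    summaries = [
        _summarize_family(p, family, freqs, options.condition_on_proband, options.summary_config_cap)
        for p in peds
    ]

    axes = _grid_axes(family, options)
    mesh = np.meshgrid(*axes.values(), indexing="ij")
    theta_grid = {name: m.ravel() for name, m in zip(axes, mesh)}
    total = _total_loglik(summaries, theta_grid)

    if not np.any(np.isfinite(total)):
        # name the first family that is impossible everywhere on the grid
        for s in summaries:
            per = (
                _eval_summary(s, theta_grid)
                if isinstance(s, _Summary)
                else _eval_fallback(s, theta_grid)
            )
            if not np.any(np.isfinite(per)):
                raise FitError(
                    f"family {s.family_id}: data have zero likelihood everywhere "
                    f"under {family.value}"
                )
        raise FitError(f"data have zero likelihood everywhere under {family.value}")

    order = np.argsort(-np.where(np.isfinite(total), total, -np.inf), kind="stable")
    best_idx = int(order[0])
    best_ll = float(total[best_idx])
    best_theta = {k: float(v[best_idx]) for k, v in theta_grid.items()}

    free = [n for n in FREE_PARAMS[family] if n not in options.fixed_params]
    n_restarts = 0
    converged = True
    if options.refine and free:
        def objective(x: np.ndarray) -> float:
            theta = dict(best_theta)
            theta.update({n: float(np.clip(xi, 0.0, 1.0)) for n, xi in zip(free, x)})
            arrs = {k: np.asarray(v) for k, v in theta.items()}
            val = float(_total_loglik(summaries, arrs))
            return -val if np.isfinite(val) else 1e12

        bounds = [(0.0, options.eps_max if n == "eps" else 1.0) for n in free]
        starts = []
        for idx in order[: max(options.n_refine, 1)]:
            cand = tuple(float(theta_grid[n][int(idx)]) for n in free)
            if np.isfinite(total[int(idx)]) and cand not in starts:
                starts.append(cand)
        for extra in extra_starts:
            cand = tuple(
                float(np.clip(extra[n], lo, hi)) for n, (lo, hi) in zip(free, bounds)
            )
            if cand not in starts:
                starts.append(cand)
        for x0 in starts:
            n_restarts += 1
            # the start itself counts: nested-model starts must never lose
            val0 = -objective(np.array(x0))
            if val0 > best_ll + 1e-12:
                best_ll = float(val0)
                for n, xi in zip(free, x0):
                    best_theta[n] = float(xi)
            res = minimize(objective, np.array(x0), method="L-BFGS-B", bounds=bounds)
            if -res.fun > best_ll + 1e-12:
                best_ll = float(-res.fun)
                for n, xi in zip(free, res.x):
                    best_theta[n] = float(np.clip(xi, 0.0, 1.0))
            converged = converged and bool(res.success)

    return ModelFit(
        family=family,
        mle_params={n: best_theta[n] for n in _PARAM_NAMES},
        log_likelihood=best_ll,
        n_families=len(peds),
        converged=converged,
        n_restarts_used=n_restarts,
    )


def compare_models(
    peds: Sequence[Pedigree],
    model_space: Iterable[ModelFamily] | None = None,
    freqs: AlleleFrequencies | None = None,
    options: FitOptions | None = None,
) -> ComparisonResult:
    """Fit every family in the model space and rank by log-likelihood.

    Ties at machine precision break toward the family with fewer free
    parameters.  Likelihood ratios are reported in log10 units.
    """
    space = list(model_space) if model_space is not None else list(ModelFamily)
    required = {ModelFamily.MONOGENIC_X, ModelFamily.MONOGENIC_A, ModelFamily.DIGENIC_AND}
    if not required <= set(space):
        raise ValueError("model space must contain monogenic_x, monogenic_a and digenic_and")
    # fit the heterogeneity family last so its refinement can start from the
    # monogenic optima it contains (guaranteeing the nesting inequality)
    ordered = [f for f in space if f is not ModelFamily.HETEROGENEITY_OR]
    fits = {fam: fit_model(peds, fam, freqs, options) for fam in ordered}
    if ModelFamily.HETEROGENEITY_OR in space:
        starts = []
        mx = fits[ModelFamily.MONOGENIC_X]
        starts.append({**mx.mle_params, "f_a": 0.0})
        ma = fits[ModelFamily.MONOGENIC_A]
        starts.append(
            {
                "f_m": 0.0,
                "f_f_skewed": 0.0,
                "f_f_random": 0.0,
                "f_a": ma.mle_params["f_m"],
                "eps": ma.mle_params["eps"],
            }
        )
        fits[ModelFamily.HETEROGENEITY_OR] = fit_model(
            peds, ModelFamily.HETEROGENEITY_OR, freqs, options, extra_starts=starts
        )

    def rank_key(fam: ModelFamily):
        return (-fits[fam].log_likelihood, len(FREE_PARAMS[fam]), fam.value)

    ranked = sorted(space, key=rank_key)
    best = ranked[0]
    # a simpler family within 1e-9 log-units of the top is preferred
    for fam in ranked[1:]:
        if (
            abs(fits[fam].log_likelihood - fits[best].log_likelihood) < 1e-9
            and len(FREE_PARAMS[fam]) < len(FREE_PARAMS[best])
        ):
            best = fam
    next_best = min(
        (f for f in space if f is not best), key=lambda f: -fits[f].log_likelihood
    )
    pairwise = {
        a: {
            b: (fits[a].log_likelihood - fits[b].log_likelihood) / LN10
            for b in space
        }
        for a in space
    }
    return ComparisonResult(
        fits=fits,
        best_family=best,
        log10_lr_vs_next_best=(fits[best].log_likelihood - fits[next_best].log_likelihood) / LN10,
        pairwise_log10_lr=pairwise,
    )
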