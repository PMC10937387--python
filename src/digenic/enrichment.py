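"""Cohort enrichment and co-occurrence statistics.

Carrier counts are compared with a two-sided Fisher exact test; following
Agresti and Coull, two successes and two failures are added to each group
before testing, which stabilises the extreme tables produced by small
cohorts with very high carrier fractions.  P-values come from the exact
hypergeometric distribution (sum of all tables with the observed margins
whose point probability does not exceed the observed table's), never from
an asymptotic approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import binom, hypergeom

from .variants import CohortCounts

#: relative tolerance when comparing point probabilities, absorbing
#: floating-point ties in the two-sided minimum-likelihood rule
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: (a, b) group 1 carriers/non-carriers, (c, d) group 2."""

    a: int
    b: int
    c: int
    d: int
    adjusted: bool = False

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    table: ContingencyTable           # the table actually tested
    p_two_sided: float
    odds_ratio: float
    group1: str = "group1"
    group2: str = "group2"
    raw_table: Optional[ContingencyTable] = None


def agresti_coull_adjust(t: ContingencyTable) -> ContingencyTable:
    """Add two successes and two failures to each group."""
    if t.adjusted:
        raise ValueError("table already carries the add-two adjustment")
    return ContingencyTable(t.a + 2, t.b + 2, t.c + 2, t.d + 2, adjusted=True)


def _odds_ratio(t: ContingencyTable) -> float:
    if t.b * t.c == 0:
        return math.nan if t.a * t.d == 0 else math.inf
    return (t.a * t.d) / (t.b * t.c)


def fisher_exact_two_sided(t: ContingencyTable) -> EnrichmentResult:
    """Two-sided Fisher exact test by the minimum-likelihood rule.

    Sums point hypergeometric probabilities over every table with the
    observed margins that is no more probable than the observed one (up to
    a ``1 + 1e-7`` relative tolerance).  A zero margin makes every
    compatible table equally (trivially) probable; p is then 1 with a
    warning.
    """
    row1, col1, n = t.a + t.b, t.a + t.c, t.n
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        warnings.warn("degenerate 2x2 table with a zero margin; p = 1", stacklevel=2)
        return EnrichmentResult(table=t, p_two_sided=1.0, odds_ratio=_odds_ratio(t))
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = float(hypergeom.pmf(t.a, n, col1, row1))
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return EnrichmentResult(table=t, p_two_sided=min(p, 1.0), odds_ratio=_odds_ratio(t))


def cohort_enrichment(
    case: CohortCounts, control: CohortCounts, adjust: bool = True
) -> EnrichmentResult:
    """Compare truncating-variant carriage between two cohorts.

    Builds the 2x2 table exactly as the counts are given (the units of the
    two groups may differ, e.g. families versus individual patients),
    applies the add-two adjustment when requested, and runs the exact test.
    The result carries both the raw and the tested tables.
    """
    raw = ContingencyTable(
        case.n_ttn_truncating,
        case.n_units - case.n_ttn_truncating,
        control.n_ttn_truncating,
        control.n_units - control.n_ttn_truncating,
    )
    tested = agresti_coull_adjust(raw) if adjust else raw
    res = fisher_exact_two_sided(tested)
    res.raw_table = raw
    res.group1 = case.cohort_id
    res.group2 = control.cohort_id
    return res


@dataclass
class CooccurrenceReport:
    """Expectations for truncating-variant co-occurrence in population males."""

    n_pop_males: int
    n_srpk3_lof: int
    n_lof_with_ttntv: int
    carrier_prob: float
    expected_cocarriers: float
    p_binomial_le_observed: float
    affected_vs_unaffected: Optional[EnrichmentResult] = None


def cooccurrence_analysis(
    n_pop_males: int,
    n_srpk3_lof: int,
    n_lof_with_ttntv: int,
    q_t: float,
    affected: Optional[CohortCounts] = None,
    q_is_carrier_freq: bool = False,
    adjust: bool = True,
) -> CooccurrenceReport:
    """Co-occurrence of X-linked loss-of-function and autosomal truncating alleles.

    Reports the expected number of truncating-carrier males among the
    ``n_srpk3_lof`` hemizygous loss-of-function males, with the exact
    binomial probability of observing at most ``n_lof_with_ttntv``; when
    affected-cohort counts are supplied, adds the adjusted two-sided Fisher
    comparison of truncating-variant carriage between affected and
    unaffected loss-of-function males.

    ``q_t`` is the truncating allele frequency (diploid carrier probability
    ``1-(1-q_t)^2``) unless ``q_is_carrier_freq`` says it is already the
    carrier fraction.
    """
    if not (0 <= n_lof_with_ttntv <= n_srpk3_lof <= n_pop_males):
        raise ValueError("need 0 <= n_lof_with_ttntv <= n_srpk3_lof <= n_pop_males")
    if not (0.0 <= q_t <= 1.0):
        raise ValueError(f"q_t={q_t} outside [0, 1]")
    carrier = q_t if q_is_carrier_freq else 1.0 - (1.0 - q_t) ** 2
    expected = n_srpk3_lof * carrier
    p_le = float(binom.cdf(n_lof_with_ttntv, n_srpk3_lof, carrier))
    fisher = None
    if affected is not None:
        unaffected = CohortCounts(
            cohort_id="unaffected_srpk3_lof_males",
            n_units=n_srpk3_lof,
            n_ttn_truncating=n_lof_with_ttntv,
            unit="individual",
        )
        fisher = cohort_enrichment(affected, unaffected, adjust=adjust)
    return CooccurrenceReport(
        n_pop_males=n_pop_males,
        n_srpk3_lof=n_srpk3_lof,
        n_lof_with_ttntv=n_lof_with_ttntv,
        carrier_prob=carrier,
        expected_cocarriers=expected,
        p_binomial_le_observed=p_le,
        affected_vs_unaffected=fisher,
    )
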