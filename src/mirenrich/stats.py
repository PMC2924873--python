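"""Hypergeometric over/under-representation tests and multiplicity corrections.

The sampling model is the classical urn: a population of ``P`` miRNAs
(every miRNA in the catalog, or a user background) contains ``HP`` input
miRNAs of interest; a category holds ``S`` of the population's miRNAs,
``HS`` of which are inputs.  The chance of observing exactly ``HS``
inputs in the category is

    Pr(X = HS) = C(HP, HS) * C(P - HP, S - HS) / C(P, S)

Over-representation is the upper tail ``sum_{h >= HS} Pr(X = h)`` and
under-representation the lower tail ``sum_{h <= HS} Pr(X = h)``; the
upper-tail sum formally runs to ``S``, with impossible terms ``h > HP``
contributing zero (an over-drawn binomial coefficient).

Two numeric paths are used: exact integer/rational arithmetic for
populations up to 10,000 (the realistic catalog regime — a few hundred
distinct miRNAs), and log-gamma summation above that.  Raw p-values are
adjusted by Bonferroni and Benjamini–Hochberg step-up FDR corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, exp, lgamma
from typing import Sequence

from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

#: Largest population handled by the exact rational path.
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class ContingencyCounts:
    """The four urn counts: population P, input hits HP, set size S, overlap HS."""

    P: int
    HP: int
    S: int
    HS: int

    def __post_init__(self) -> None:
        p, hp, s, hs = self.P, self.HP, self.S, self.HS
        if min(p, hp, s, hs) < 0:
            raise ValidationError("counts must be non-negative")
        if s > p or hp > p:
            raise ValidationError(f"S={s} and HP={hp} must not exceed P={p}")
        if hs > min(s, hp):
            raise ValidationError(f"HS={hs} exceeds min(S={s}, HP={hp})")

    @property
    def support(self) -> range:
        """Attainable overlap values: max(0, S-(P-HP)) .. min(S, HP)."""
        return range(max(0, self.S - (self.P - self.HP)), min(self.S, self.HP) + 1)


def _pmf_fraction(c: ContingencyCounts, h: int) -> Fraction:
    if h < 0 or h > c.S or h > c.HP or c.S - h > c.P - c.HP:
        return Fraction(0)
    return Fraction(comb(c.HP, h) * comb(c.P - c.HP, c.S - h), comb(c.P, c.S))


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _pmf_float(c: ContingencyCounts, h: int) -> float:
    if h < 0 or h > c.S or h > c.HP or c.S - h > c.P - c.HP:
        return 0.0
    return exp(
        _log_comb(c.HP, h)
        + _log_comb(c.P - c.HP, c.S - h)
        - _log_comb(c.P, c.S)
    )


def hypergeom_pmf(c: ContingencyCounts) -> float:
    """Probability of observing exactly ``HS`` input miRNAs in the set."""
    if c.P <= EXACT_LIMIT:
        return float(_pmf_fraction(c, c.HS))
    return _pmf_float(c, c.HS)


def p_over(c: ContingencyCounts) -> float:
    """Over-representation p-value: upper tail from ``HS`` upward."""
    if c.HS == 0:
        return 1.0
    if c.P <= EXACT_LIMIT:
        total = sum((_pmf_fraction(c, h) for h in range(c.HS, c.S + 1)), Fraction(0))
        return float(min(total, Fraction(1)))
    total = sum(_pmf_float(c, h) for h in range(c.HS, c.S + 1))
    return min(total, 1.0)


def p_under(c: ContingencyCounts) -> float:
    """Under-representation p-value: lower tail from 0 up to ``HS``."""
    if c.HS >= min(c.S, c.HP):
        return 1.0
    if c.P <= EXACT_LIMIT:
        total = sum((_pmf_fraction(c, h) for h in range(0, c.HS + 1)), Fraction(0))
        return float(min(total, Fraction(1)))
    total = sum(_pmf_float(c, h) for h in range(0, c.HS + 1))
    return min(total, 1.0)


def _check_pvals(pvals: Sequence[float]) -> None:
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")


def bonferroni_adjust(pvals: Sequence[float]) -> list[float]:
    """Bonferroni family-wise correction: ``min(1, p * m)``, order preserved."""
    _check_pvals(pvals)
    if len(pvals) == 0:
        return []
    return list(multipletests(pvals, method="bonferroni")[1])


def bh_fdr_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, mapped back to input order."""
    _check_pvals(pvals)
    if len(pvals) == 0:
        return []
    return list(multipletests(pvals, method="fdr_bh")[1])
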