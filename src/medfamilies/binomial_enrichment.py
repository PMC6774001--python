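"""Exact binomial over-representation test.

Under the proportional null every species is medicinal independently
with the flora-wide probability q = sum(M) / sum(T), so a family of T
species contributes Binomial(T, q) medicinal species.  The reported
statistic is the upper tail

    p = P(X >= M) = (1 - CDF(M)) + PMF(M),

evaluated through the survival function so that tails far below 1e-30
keep full relative precision.  A family is flagged when p falls strictly
below alpha; no multiple-testing correction is applied by default, to
match the original single-threshold usage (Holm or Benjamini-Hochberg
adjusted flags can be requested on top).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .family_table import AnalysisConfig, FamilyTable


class EmptyTableError(ValueError):
    pass


class InvalidProportionError(ValueError):
    pass


@dataclass(frozen=True)
class BinomialResult:
    family: str
    total_species: int
    observed: int
    null_proportion: float
    expected_count: float  # q * T, unrounded
    p_over: float
    significant: bool


def pooled_proportion(table: FamilyTable) -> float:
    """Flora-wide medicinal proportion q = sum(M) / sum(T)."""
    if len(table) == 0:
        raise EmptyTableError("cannot pool an empty table")
    total = table.total_species_sum()
    if total == 0:
        raise EmptyTableError("table has no species")
    return table.medicinal_species_sum() / total


def binomial_upper_tail(observed: int, trials: int, q: float) -> float:
    """P(X >= observed) for X ~ Binomial(trials, q)."""
    if not 0.0 < q < 1.0:
        raise InvalidProportionError(f"q must lie strictly in (0, 1), got {q}")
    if not 0 <= observed <= trials:
        raise ValueError(f"need 0 <= observed <= trials, got {observed} of {trials}")
    if observed == 0:
        return 1.0
    # sf(k) = P(X > k), so sf(M - 1) = P(X >= M) = (1 - CDF(M)) + PMF(M)
    return float(stats.binom.sf(observed - 1, trials, q))


def run_binomial_stage(table: FamilyTable, config: AnalysisConfig) -> list[BinomialResult]:
    """Tail probability and significance flag for every family."""
    q = pooled_proportion(table)
    if not 0.0 < q < 1.0:
        raise InvalidProportionError(
            f"pooled proportion {q} is degenerate; the test needs 0 < q < 1"
        )
    results = []
    for rec in table.records:
        p = binomial_upper_tail(rec.medicinal_species, rec.total_species, q)
        results.append(
            BinomialResult(
                family=rec.family,
                total_species=rec.total_species,
                observed=rec.medicinal_species,
                null_proportion=q,
                expected_count=q * rec.total_species,
                p_over=p,
                significant=p < config.alpha,
            )
        )
    return results


def adjusted_flags(results: list[BinomialResult], alpha: float, method: str = "holm") -> list[bool]:
    """Optional multiple-testing-corrected flags (off the default path)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.array([r.p_over for r in results])
    reject, *_ = multipletests(pvals, alpha=alpha, method=method)
    return list(map(bool, reject))
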