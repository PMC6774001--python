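"""Consensus MIMF classification and cross-stratum comparison.

A family is a Most Important Medicinal Family (MIMF) under the default
rule only when all three methods agree: its relative regression residual
exceeds the band, its binomial upper-tail probability falls below alpha,
and its credible-interval lower bound exceeds the reference proportion.
Requiring the conjunction trades sensitivity for robustness — each
method has a known bias (the residual favours large families, the two
count-based tests are more sensitive in small ones), and the
intersection is what survives all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .bayesian_enrichment import BayesResult, run_bayesian_stage
from .binomial_enrichment import BinomialResult, run_binomial_stage
from .family_table import AnalysisConfig, FamilyTable, filter_min_size
from .regression_residuals import RegressionFit, ResidualResult, run_regression_stage

RULES = ("all3", "any", "per_method")


class FamilySetMismatchError(ValueError):
    """The three per-method result lists cover different family sets."""


class EmptyAfterFilterError(ValueError):
    """The minimum-size filter removed every family."""


@dataclass(frozen=True)
class FamilyVerdict:
    family: str
    region: str
    r_flag: bool
    binom_flag: bool
    bayes_flag: bool
    mimf: bool


@dataclass(frozen=True)
class StratumComparison:
    """Set algebra over per-stratum MIMF lists."""

    counts: dict[str, int]
    pairwise_overlap: dict[tuple[str, str], int]
    shared_all: frozenset[str]
    union: frozenset[str]
    unique_per_stratum: dict[str, frozenset[str]]


@dataclass(frozen=True)
class PipelineResult:
    """Everything one full run produces, in family order of the input."""

    stratum: str
    fit: RegressionFit
    residuals: tuple[ResidualResult, ...]
    binomials: tuple[BinomialResult, ...]
    bayes: tuple[BayesResult, ...]
    verdicts: tuple[FamilyVerdict, ...]
    config: AnalysisConfig

    @property
    def mimf_families(self) -> tuple[str, ...]:
        return tuple(v.family for v in self.verdicts if v.mimf)

    def method_counts(self) -> dict[str, int]:
        return {
            "regression": sum(v.r_flag for v in self.verdicts),
            "binomial": sum(v.binom_flag for v in self.verdicts),
            "bayesian": sum(v.bayes_flag for v in self.verdicts),
            "consensus": sum(v.mimf for v in self.verdicts),
        }


def combine_verdicts(
    residuals: Sequence[ResidualResult],
    binomials: Sequence[BinomialResult],
    bayes: Sequence[BayesResult],
    rule: str = "all3",
    region: str = "NATIONAL",
) -> list[FamilyVerdict]:
    """Merge the three per-method flags into one verdict per family.

    ``all3`` requires every flag; ``any`` requires at least one;
    ``per_method`` reports the flags with the combined field left False
    (for per-method tabulations).
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}, got {rule!r}")
    res_map = {r.family: r for r in residuals}
    bin_map = {b.family: b for b in binomials}
    bay_map = {b.family: b for b in bayes}
    if not (set(res_map) == set(bin_map) == set(bay_map)):
        raise FamilySetMismatchError(
            "the three stages cover different family sets: "
            f"{sorted(set(res_map) ^ set(bin_map) | set(res_map) ^ set(bay_map))[:5]} ..."
        )
    verdicts = []
    for family in (r.family for r in residuals):  # preserve input order
        flags = (res_map[family].is_mimf, bin_map[family].significant, bay_map[family].significant)
        if rule == "all3":
            mimf = all(flags)
        elif rule == "any":
            mimf = any(flags)
        else:
            mimf = False
        verdicts.append(
            FamilyVerdict(
                family=family,
                region=region,
                r_flag=flags[0],
                binom_flag=flags[1],
                bayes_flag=flags[2],
                mimf=mimf,
            )
        )
    return verdicts


def compare_strata(verdict_sets: Mapping[str, Iterable[str]]) -> StratumComparison:
    """Counts, pairwise overlaps and shared/unique MIMFs across strata."""
    sets = {stratum: frozenset(fams) for stratum, fams in verdict_sets.items()}
    if len(sets) < 2:
        raise ValueError(f"need at least 2 strata, got {len(sets)}")
    shared = frozenset.intersection(*sets.values())
    union = frozenset.union(*sets.values())
    overlap = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(sorted(sets), 2)
    }
    unique = {
        stratum: frozenset(
            members - frozenset.union(*(s for other, s in sets.items() if other != stratum))
        )
        for stratum, members in sets.items()
    }
    return StratumComparison(
        counts={stratum: len(members) for stratum, members in sets.items()},
        pairwise_overlap=overlap,
        shared_all=shared,
        union=union,
        unique_per_stratum=unique,
    )


def run_full_pipeline(
    table: FamilyTable, config: AnalysisConfig | None = None, rule: str = "all3"
) -> PipelineResult:
    """Filter, fit, test and combine: the end-to-end analysis of one stratum."""
    config = config or AnalysisConfig()
    filtered = filter_min_size(table, config.min_family_size)
    if len(filtered) == 0:
        raise EmptyAfterFilterError(
            f"no family in stratum {table.stratum!r} reaches "
            f"{config.min_family_size} species"
        )
    fit, residuals = run_regression_stage(filtered, config)
    binomials = run_binomial_stage(filtered, config)
    bayes = run_bayesian_stage(filtered, config)
    verdicts = combine_verdicts(residuals, binomials, bayes, rule=rule, region=table.stratum)
    return PipelineResult(
        stratum=table.stratum,
        fit=fit,
        residuals=tuple(residuals),
        binomials=tuple(binomials),
        bayes=tuple(bayes),
        verdicts=tuple(verdicts),
        config=config,
    )
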