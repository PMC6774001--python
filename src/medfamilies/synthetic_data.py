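"""Synthetic family tables with known ground truth.

The generator emulates the statistical structure the analysis assumes:
heavy-tailed family sizes (truncated lognormal by default, spanning the
ten-to-eleven-hundred species range seen in a national flora), binomial
medicinal counts at a baseline proportion, and a designated enriched
subset whose odds of a species being medicinal are multiplied by an
effect factor.  Regional tables are produced by binomial thinning of the
national species pool, with an optional fraction of regional totals
marked unknown to exercise the national-substitution rule.

Defaults mirror the national study conditions: 115 families, baseline
proportion 0.227 (the pooled national value), an enriched sixth of the
families, and a threefold odds effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .consensus import FamilyVerdict
from .family_table import REGION_CODES, FamilyRecord, FamilyTable

_MAX_ENRICHED_PROPORTION = 0.99


@dataclass(frozen=True)
class RegionalSpec:
    """How to thin the national pool into regional strata."""

    n_regions: int = 7
    retention: float = 0.5
    missing_total_probability: float = 0.1

    def __post_init__(self) -> None:
        if not 1 <= self.n_regions <= 7:
            raise ValueError("n_regions must be between 1 and 7")
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention must lie in (0, 1]")
        if not 0.0 <= self.missing_total_probability <= 1.0:
            raise ValueError("missing_total_probability must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    n_families: int = 115
    size_distribution: str = "lognormal"  # {"lognormal", "logseries"}
    mu: float = 3.0
    sigma: float = 1.2
    theta: float = 0.98
    size_min: int = 10
    size_max: int = 1200
    baseline_q: float = 0.227
    enriched_fraction: float = 1 / 6
    effect: float = 3.0
    regional: Optional[RegionalSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.size_distribution not in ("lognormal", "logseries"):
            raise ValueError("size_distribution must be 'lognormal' or 'logseries'")
        if not 0.0 < self.baseline_q < 1.0:
            raise ValueError("baseline_q must lie strictly in (0, 1)")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if self.effect < 1.0:
            raise ValueError("effect must be >= 1 (an odds multiplier)")
        if not 1 <= self.size_min <= self.size_max:
            raise ValueError("need 1 <= size_min <= size_max")

    def enriched_proportion(self) -> float:
        """Per-species medicinal probability in enriched families."""
        odds = self.baseline_q / (1.0 - self.baseline_q) * self.effect
        return min(odds / (1.0 + odds), _MAX_ENRICHED_PROPORTION)


@dataclass(frozen=True)
class SyntheticTable:
    table: FamilyTable
    enriched: frozenset[str]

    @property
    def labels(self) -> dict[str, bool]:
        return {rec.family: rec.family in self.enriched for rec in self.table.records}


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    consensus_precision: float
    n_enriched: int
    n_null: int


def _draw_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Family sizes from the chosen distribution, truncated by resampling."""
    sizes = np.empty(spec.n_families, dtype=int)
    filled = 0
    while filled < spec.n_families:
        need = spec.n_families - filled
        if spec.size_distribution == "lognormal":
            draw = np.floor(rng.lognormal(spec.mu, spec.sigma, size=2 * need)).astype(int)
        else:
            draw = rng.logseries(spec.theta, size=2 * need)
        draw = draw[(draw >= spec.size_min) & (draw <= spec.size_max)]
        take = min(need, len(draw))
        sizes[filled : filled + take] = draw[:take]
        filled += take
    return sizes


def generate(spec: SyntheticSpec) -> SyntheticTable:
    """One national-style table with ground-truth enrichment labels."""
    rng = np.random.default_rng(spec.seed)
    sizes = _draw_sizes(spec, rng)
    n_enriched = round(spec.enriched_fraction * spec.n_families)
    enriched_idx = rng.choice(spec.n_families, size=n_enriched, replace=False)
    is_enriched = np.zeros(spec.n_families, dtype=bool)
    is_enriched[enriched_idx] = True
    q_enriched = spec.enriched_proportion()
    props = np.where(is_enriched, q_enriched, spec.baseline_q)
    medicinal = rng.binomial(sizes, props)
    records = tuple(
        FamilyRecord(
            family=f"Fam{i:04d}",
            total_species=int(sizes[i]),
            medicinal_species=int(medicinal[i]),
        )
        for i in range(spec.n_families)
    )
    return SyntheticTable(
        table=FamilyTable(records=records, stratum="NATIONAL"),
        enriched=frozenset(records[i].family for i in range(spec.n_families) if is_enriched[i]),
    )


def generate_regional(spec: SyntheticSpec) -> tuple[SyntheticTable, dict[str, FamilyTable]]:
    """National table plus thinned regional tables (some totals unknown).

    Each regional total is a binomial thinning of the national total and
    the regional medicinal count is drawn hypergeometrically from the
    retained species, so M <= T holds by construction before any total
    is masked.
    """
    if spec.regional is None:
        raise ValueError("spec.regional must be set for regional generation")
    national = generate(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    regions = [code for code in REGION_CODES if code != "NATIONAL"][: spec.regional.n_regions]
    regional_tables: dict[str, FamilyTable] = {}
    for region in regions:
        records = []
        for rec in national.table.records:
            t_nat = rec.total_species
            m_nat = rec.medicinal_species
            t_reg = int(rng.binomial(t_nat, spec.regional.retention))
            m_reg = int(rng.hypergeometric(m_nat, t_nat - m_nat, t_reg)) if t_reg else 0
            total: Optional[int] = t_reg
            if rng.random() < spec.regional.missing_total_probability:
                total = None
            records.append(
                FamilyRecord(
                    family=rec.family,
                    region=region,
                    total_species=total,
                    medicinal_species=m_reg,
                )
            )
        regional_tables[region] = FamilyTable(records=tuple(records), stratum=region)
    return national, regional_tables


def evaluate_recovery(
    synthetic: SyntheticTable, verdicts: list[FamilyVerdict]
) -> RecoveryMetrics:
    """Confusion-matrix metrics of the flags against ground truth."""
    labels = synthetic.labels
    verdict_families = {v.family for v in verdicts}
    if not verdict_families <= set(labels):
        raise ValueError("verdicts cover families absent from the synthetic table")
    flags = {
        "regression": {v.family: v.r_flag for v in verdicts},
        "binomial": {v.family: v.binom_flag for v in verdicts},
        "bayesian": {v.family: v.bayes_flag for v in verdicts},
        "consensus": {v.family: v.mimf for v in verdicts},
    }
    families = [v.family for v in verdicts]
    n_enriched = sum(labels[f] for f in families)
    n_null = len(families) - n_enriched
    sensitivity = {}
    specificity = {}
    for method, flag_map in flags.items():
        tp = sum(flag_map[f] and labels[f] for f in families)
        tn = sum(not flag_map[f] and not labels[f] for f in families)
        sensitivity[method] = tp / n_enriched if n_enriched else float("nan")
        specificity[method] = tn / n_null if n_null else float("nan")
    n_called = sum(flags["consensus"][f] for f in families)
    tp_consensus = sum(flags["consensus"][f] and labels[f] for f in families)
    precision = tp_consensus / n_called if n_called else float("nan")
    return RecoveryMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        consensus_precision=precision,
        n_enriched=n_enriched,
        n_null=n_null,
    )
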