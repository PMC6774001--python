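"""Relative regression residuals.

An ordinary least-squares line of medicinal count M on family size T
describes how many medicinal species a family "should" contribute given
its size.  The relative regression residual

    R = (O - P) / P

scales the deviation of the observed count O from the prediction P by
the prediction, so over-representation in a 20-species family and a
500-species family is measured on the same footing.  R = 0 is a perfect
fit, R = -1 means the family contributes no medicinal species at all,
and values inside a +/- halfwidth band (default 0.5) are treated as
noise.  Families with R above the band are flagged as enriched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .family_table import AnalysisConfig, FamilyTable


class DegenerateRegressionError(ValueError):
    """Fewer than two families, or no variation in family size."""


class NonPositivePredictionError(ValueError):
    """The fitted line predicts a non-positive medicinal count."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of medicinal count on total species count."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, total_species: float) -> float:
        return self.slope * total_species + self.intercept


@dataclass(frozen=True)
class ResidualResult:
    """Per-family residual diagnostics.

    ``band_class`` is ``"over"``, ``"neutral"`` or ``"under"``; ``None``
    with ``valid=False`` marks a family whose prediction was
    non-positive, for which R is undefined.
    """

    family: str
    total_species: int
    observed: int
    predicted: float
    r_value: Optional[float]
    band_class: Optional[str]
    is_mimf: bool
    valid: bool = True


def fit_ols(table: FamilyTable) -> RegressionFit:
    """Least-squares fit of M on T across the table's families."""
    t = np.array([rec.total_species for rec in table.records], dtype=float)
    m = np.array([rec.medicinal_species for rec in table.records], dtype=float)
    if np.any(np.isnan(t)):
        raise DegenerateRegressionError("table contains unresolved unknown totals")
    n = len(t)
    if n < 2:
        raise DegenerateRegressionError(f"need at least 2 families, got {n}")
    if np.ptp(t) == 0:
        raise DegenerateRegressionError("all families have identical total species counts")
    design = np.column_stack([t, np.ones_like(t)])
    (slope, intercept), *_ = np.linalg.lstsq(design, m, rcond=None)
    resid = m - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((m - m.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(slope=float(slope), intercept=float(intercept), r_squared=r_squared, n=n)


def relative_residual(observed: float, predicted: float) -> float:
    """(observed - predicted) / predicted; requires a positive prediction."""
    if predicted <= 0:
        raise NonPositivePredictionError(
            f"model predicts a non-positive medicinal count ({predicted:.4g})"
        )
    return (observed - predicted) / predicted


def classify_band(r_value: float, halfwidth: float) -> str:
    """Strict comparison of the unrounded residual against the band."""
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if r_value > halfwidth:
        return "over"
    if r_value < -halfwidth:
        return "under"
    return "neutral"


def run_regression_stage(
    table: FamilyTable, config: AnalysisConfig
) -> tuple[RegressionFit, list[ResidualResult]]:
    """Fit the line and classify every family's residual."""
    fit = fit_ols(table)
    results = []
    for rec in table.records:
        predicted = fit.predict(rec.total_species)
        if predicted <= 0:
            results.append(
                ResidualResult(
                    family=rec.family,
                    total_species=rec.total_species,
                    observed=rec.medicinal_species,
                    predicted=predicted,
                    r_value=None,
                    band_class=None,
                    is_mimf=False,
                    valid=False,
                )
            )
            continue
        r = relative_residual(rec.medicinal_species, predicted)
        band = classify_band(r, config.r_band_halfwidth)
        results.append(
            ResidualResult(
                family=rec.family,
                total_species=rec.total_species,
                observed=rec.medicinal_species,
                predicted=predicted,
                r_value=r,
                band_class=band,
                is_mimf=(band == "over"),
            )
        )
    return fit, results
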