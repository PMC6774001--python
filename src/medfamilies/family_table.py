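"""Family-level count tables: data model, validation, I/O and the national fixture.

The basic observational unit is a plant family within one stratum (the
national flora or one of seven ethnobotanical regions), carrying two
counts: ``total_species`` (T), the number of species of that family
recorded in the flora of the stratum, and ``medicinal_species`` (M), the
number of those species with at least one medicinal-use citation.

A regional total may be unknown (the regional flora was never compiled
for that family); this is encoded as ``total_species=None``, never as 0,
so that "unknown" and "locally absent" remain distinguishable.  The
conservative substitution rule replaces an unknown regional total with
the corresponding national total.
"""

from __future__ import annotations

import csv
import hashlib
import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

REGION_CODES = ("C", "E", "N", "NE", "P", "SE", "SW", "NATIONAL")

#: sha256 of the packaged national table, fixed at packaging time.
_TABLE1_SHA256 = "b01b55dff82f71e2ff0e91a764d498b8c8ed5a485833b3b49744205d3db1b05e"


class FamilyTableError(ValueError):
    """Base class for table validation failures."""


class MissingColumnError(FamilyTableError):
    """A required header column is absent."""


class DuplicateColumnError(FamilyTableError):
    """The header names a column more than once."""


class NonIntegerCountError(FamilyTableError):
    """A count cell is not a non-negative integer."""


class MedicinalExceedsTotalError(FamilyTableError):
    """A record has more medicinal species than total species."""


class DuplicateFamilyError(FamilyTableError):
    """The same family appears twice within one stratum."""


class UnknownRegionError(FamilyTableError):
    """A region code outside the recognised set."""


class MissingFamilyError(FamilyTableError):
    """A regional family has no national counterpart for substitution."""


class FixtureIntegrityError(FamilyTableError):
    """The packaged fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class FamilyRecord:
    """Counts for one family in one stratum.

    ``total_species is None`` means the stratum-level total is unknown
    (possible for regional strata only; resolved by
    :func:`substitute_missing_regional_totals`).
    """

    family: str
    total_species: Optional[int]
    medicinal_species: int
    region: str = "NATIONAL"

    def __post_init__(self) -> None:
        if not self.family or not self.family.strip():
            raise FamilyTableError("family label must be non-empty")
        object.__setattr__(self, "family", self.family.strip())
        if self.region not in REGION_CODES:
            raise UnknownRegionError(
                f"unknown region code {self.region!r}; expected one of {REGION_CODES}"
            )
        for name in ("total_species", "medicinal_species"):
            v = getattr(self, name)
            if name == "total_species" and v is None:
                continue
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise NonIntegerCountError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total_species is not None and self.medicinal_species > self.total_species:
            raise MedicinalExceedsTotalError(
                f"{self.family}: medicinal exceeds total "
                f"({self.medicinal_species} > {self.total_species})"
            )


@dataclass(frozen=True)
class FamilyTable:
    """An ordered collection of :class:`FamilyRecord` sharing one stratum."""

    records: tuple[FamilyRecord, ...]
    stratum: str = "NATIONAL"

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.stratum not in REGION_CODES:
            raise UnknownRegionError(f"unknown stratum code {self.stratum!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.region != self.stratum:
                raise FamilyTableError(
                    f"record {rec.family!r} has region {rec.region!r}, table stratum is {self.stratum!r}"
                )
            if rec.family in seen:
                raise DuplicateFamilyError(f"duplicate family {rec.family!r} in stratum {self.stratum}")
            seen.add(rec.family)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FamilyRecord]:
        return iter(self.records)

    def __getitem__(self, family: str) -> FamilyRecord:
        for rec in self.records:
            if rec.family == family:
                return rec
        raise KeyError(family)

    def __contains__(self, family: str) -> bool:
        return any(rec.family == family for rec in self.records)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(rec.family for rec in self.records)

    def total_species_sum(self) -> int:
        """Sum of known totals (unknown totals contribute nothing)."""
        return sum(rec.total_species for rec in self.records if rec.total_species is not None)

    def medicinal_species_sum(self) -> int:
        return sum(rec.medicinal_species for rec in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [r.family for r in self.records],
                "region": [r.region for r in self.records],
                "total_species": pd.array(
                    [r.total_species for r in self.records], dtype="Int64"
                ),
                "medicinal_species": [r.medicinal_species for r in self.records],
            }
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the three-way enrichment analysis.

    Defaults replicate the national analysis: families below 10 species
    excluded, a +/-0.5 neutral band on the relative regression residual,
    exact binomial significance at alpha=0.05, uniform Beta(1,1) prior
    with equal-tailed 95% intervals, and the published fixed reference
    proportion 0.2362 for the credible-bound rule.
    """

    min_family_size: int = 10
    r_band_halfwidth: float = 0.5
    alpha: float = 0.05
    ci_level: float = 0.95
    prior_a: float = 1.0
    prior_b: float = 1.0
    bayes_threshold_mode: str = "fixed"  # {"fixed", "computed"}
    bayes_threshold_value: float = 0.2362
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_family_size < 0:
            raise ValueError("min_family_size must be >= 0")
        if self.r_band_halfwidth < 0:
            raise ValueError("r_band_halfwidth must be >= 0")
        for name in ("alpha", "ci_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("prior parameters must be positive")
        if self.bayes_threshold_mode not in ("fixed", "computed"):
            raise ValueError("bayes_threshold_mode must be 'fixed' or 'computed'")


_REQUIRED_COLUMNS = ("family", "total_species", "medicinal_species")


def _parse_count(cell: str, column: str, allow_missing: bool) -> Optional[int]:
    cell = cell.strip()
    if cell in ("", "NA", "na", "None"):
        if allow_missing:
            return None
        raise NonIntegerCountError(f"missing value in required column {column!r}")
    try:
        as_float = float(cell)
    except ValueError as exc:
        raise NonIntegerCountError(f"non-integer {column}: {cell!r}") from exc
    if not as_float.is_integer():
        raise NonIntegerCountError(f"non-integer {column}: {cell!r}")
    return int(as_float)


def read_family_table(path: str | Path, dialect: str = "tsv") -> FamilyTable:
    """Read a validated family table from a TSV or CSV file.

    The header must name ``family``, ``total_species`` and
    ``medicinal_species``; a ``region`` column is optional and defaults
    to ``NATIONAL``.  An empty ``total_species`` cell marks an unknown
    regional total.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise MissingColumnError(f"{path}: empty file, no header row") from None
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise DuplicateColumnError(f"{path}: duplicate columns {dupes}")
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise MissingColumnError(f"{path}: missing column {col!r}")
        idx = {col: header.index(col) for col in header}
        has_region = "region" in idx
        records = []
        stratum: Optional[str] = None
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            family = row[idx["family"]]
            region = row[idx["region"]].strip() if has_region else "NATIONAL"
            total = _parse_count(row[idx["total_species"]], "total_species", allow_missing=True)
            med = _parse_count(row[idx["medicinal_species"]], "medicinal_species", allow_missing=False)
            records.append(
                FamilyRecord(family=family, region=region, total_species=total, medicinal_species=med)
            )
            stratum = region if stratum is None else stratum
    return FamilyTable(records=tuple(records), stratum=stratum or "NATIONAL")


def load_table1_fixture() -> FamilyTable:
    """Load the packaged 115-family national table (T and M per family)."""
    resource = importlib.resources.files("medfamilies.data") / "table1.tsv"
    raw = resource.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise FixtureIntegrityError(
            f"packaged national table is corrupted (sha256 {digest}, expected {_TABLE1_SHA256})"
        )
    with importlib.resources.as_file(resource) as path:
        return read_family_table(path, dialect="tsv")


def filter_min_size(table: FamilyTable, k: int) -> FamilyTable:
    """Keep families whose total species count is at least ``k``.

    Records with an unknown total are retained (they cannot be judged
    until the substitution rule has resolved them); order is preserved.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    kept = tuple(
        rec for rec in table.records if rec.total_species is None or rec.total_species >= k
    )
    return FamilyTable(records=kept, stratum=table.stratum)


def substitute_missing_regional_totals(
    regional: FamilyTable, national: FamilyTable
) -> FamilyTable:
    """Resolve unknown regional totals using the national total for the family."""
    out = []
    for rec in regional.records:
        if rec.total_species is not None:
            out.append(rec)
            continue
        if rec.family not in national:
            raise MissingFamilyError(
                f"{rec.family!r} has an unknown regional total and no national record"
            )
        nat_total = national[rec.family].total_species
        if nat_total is None:
            raise MissingFamilyError(f"{rec.family!r}: national total is itself unknown")
        if rec.medicinal_species > nat_total:
            raise MedicinalExceedsTotalError(
                f"{rec.family!r}: substitution would give medicinal {rec.medicinal_species} "
                f"> total {nat_total}"
            )
        out.append(replace(rec, total_species=nat_total))
    return FamilyTable(records=tuple(out), stratum=regional.stratum)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (spreadsheet style)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_probability(p: float) -> str:
    """Table-style probability cell: scientific with 3 significant digits
    below 1e-3 (e.g. ``1.62E-05``), fixed 3 decimals otherwise."""
    if p < 1e-3:
        return f"{p:.2E}"
    return f"{p:.3f}"


def write_results_table(results, path: str | Path, dialect: str = "tsv") -> None:
    """Write one row per family with counts, per-method statistics and flags.

    ``results`` is a :class:`medfamilies.consensus.PipelineResult`.  The
    (family, region, total_species, medicinal_species) columns round-trip
    through :func:`read_family_table`.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    path = Path(path)
    residual_by_family = {r.family: r for r in results.residuals}
    binom_by_family = {b.family: b for b in results.binomials}
    bayes_by_family = {b.family: b for b in results.bayes}
    header = [
        "family", "region", "total_species", "medicinal_species",
        "P1", "R", "P2", "p_binomial", "ci_low", "ci_high",
        "r_flag", "binom_flag", "bayes_flag", "mimf",
    ]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(header)
        for verdict in results.verdicts:
            res = residual_by_family[verdict.family]
            binom = binom_by_family[verdict.family]
            bayes = bayes_by_family[verdict.family]
            writer.writerow(
                [
                    verdict.family,
                    verdict.region,
                    res.total_species,
                    res.observed,
                    # display rounding only; computations keep unrounded values
                    round_half_away(res.predicted),
                    f"{res.r_value:.2f}" if res.r_value is not None else "NA",
                    round_half_away(binom.expected_count),
                    format_probability(binom.p_over),
                    f"{bayes.ci_low:.4f}",
                    f"{bayes.ci_high:.4f}",
                    verdict.r_flag,
                    verdict.binom_flag,
                    verdict.bayes_flag,
                    verdict.mimf,
                ]
            )
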