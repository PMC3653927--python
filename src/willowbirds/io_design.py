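"""Survey data model: species table ingestion, detection histories, covariates.

The survey design is a fixed panel: points nested in regions, visited a
constant number of times per year.  Counts and detection histories are kept
as dense 4-D arrays (species x point x year x visit) with explicit axis
labels so they round-trip losslessly through long-format CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ASSEMBLAGES = ("WCB", "WGB", "OT")
HABITAT_CATEGORIES = ("heath", "thicket", "flying_over", "meadow", "water")

#: Covariate columns used in the occupancy / abundance models, in model order.
MODEL_COVARIATES = ("area", "edge_density", "willow_height", "willow_density")


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class IntegrityError(ValueError):
    """A file parses but its contents are internally inconsistent."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the species detection table."""

    latin_name: str
    common_name: str
    assemblage: str
    habitat_counts: tuple[int, ...]  # ordered as HABITAT_CATEGORIES
    total: int
    exclude: bool = False  # gulls / shoreline-associated species

    def __post_init__(self):
        if self.assemblage not in ASSEMBLAGES:
            raise IntegrityError(
                f"{self.latin_name}: unknown assemblage {self.assemblage!r}"
            )
        if len(self.habitat_counts) != len(HABITAT_CATEGORIES):
            raise IntegrityError(f"{self.latin_name}: need 5 habitat counts")
        if any(c < 0 for c in self.habitat_counts) or self.total < 0:
            raise IntegrityError(f"{self.latin_name}: negative count")
        if sum(self.habitat_counts) != self.total:
            raise IntegrityError(
                f"{self.latin_name}: habitat counts sum to "
                f"{sum(self.habitat_counts)}, total column says {self.total}"
            )


@dataclass(frozen=True)
class SurveyDesign:
    """Panel layout: regions, points per region, years, visits per year."""

    regions: tuple[str, ...] = ("KO", "VJ", "IF")
    points_per_region: tuple[int, ...] = (12, 13, 12)
    years: tuple[int, ...] = (2005, 2006, 2007, 2008)
    visits_per_year: int = 3

    def __post_init__(self):
        if len(self.regions) != len(self.points_per_region):
            raise ValueError("regions and points_per_region length mismatch")
        if any(n <= 0 for n in self.points_per_region):
            raise ValueError("points_per_region must be positive")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if self.visits_per_year <= 0:
            raise ValueError("visits_per_year must be positive")

    @property
    def n_points(self) -> int:
        return int(sum(self.points_per_region))

    @property
    def n_years(self) -> int:
        return len(self.years)

    def point_ids(self) -> list[str]:
        out = []
        for region, n in zip(self.regions, self.points_per_region):
            out.extend(f"{region}-{i + 1:02d}" for i in range(n))
        return out

    def point_regions(self) -> list[str]:
        out = []
        for region, n in zip(self.regions, self.points_per_region):
            out.extend([region] * n)
        return out


@dataclass
class LabeledArray:
    """Dense species x point x year x visit array with axis labels."""

    values: np.ndarray
    species: list[str]
    points: list[str]
    years: list[int]
    visits: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        expected = (
            len(self.species),
            len(self.points),
            len(self.years),
            len(self.visits),
        )
        if self.values.shape != expected:
            raise ValueError(
                f"array shape {self.values.shape} does not match labels {expected}"
            )

    def to_long_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.species, self.points, self.years, self.visits],
            names=["species", "point", "year", "visit"],
        )
        return pd.DataFrame(
            {self._value_column: self.values.ravel()}, index=idx
        ).reset_index()

    def write_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def _from_long_frame(cls, df: pd.DataFrame):
        for col in ("species", "point", "year", "visit", cls._value_column):
            if col not in df.columns:
                raise FormatError(f"missing column: {col}")
        species = list(pd.unique(df["species"]))
        points = list(pd.unique(df["point"]))
        years = sorted(pd.unique(df["year"]))
        visits = sorted(pd.unique(df["visit"]))
        pivot = df.set_index(["species", "point", "year", "visit"])[
            cls._value_column
        ]
        idx = pd.MultiIndex.from_product(
            [species, points, years, visits],
            names=["species", "point", "year", "visit"],
        )
        try:
            values = pivot.reindex(idx).to_numpy().reshape(
                len(species), len(points), len(years), len(visits)
            )
        except KeyError as exc:  # pragma: no cover
            raise FormatError(f"incomplete long table: {exc}") from exc
        if np.any(pd.isna(values)):
            raise IntegrityError("long table has missing cells")
        return cls(
            values=values.astype(cls._dtype),
            species=species,
            points=points,
            years=[int(y) for y in years],
            visits=[int(v) for v in visits],
        )

    @classmethod
    def read_csv(cls, path):
        return cls._from_long_frame(pd.read_csv(path))


class CountArray(LabeledArray):
    """Nonnegative visit counts y[i, l, j, k]."""

    _value_column = "count"
    _dtype = np.int64

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.values < 0):
            raise IntegrityError("counts must be nonnegative")


class DetectionArray(LabeledArray):
    """Binary detection indicators x[i, l, j, k]."""

    _value_column = "detected"
    _dtype = np.int8

    def __post_init__(self):
        super().__post_init__()
        if not np.isin(self.values, (0, 1)).all():
            raise IntegrityError("detections must be 0/1")


def counts_to_detection(counts: CountArray) -> DetectionArray:
    """Reduce counts to 1/0 detection histories (indicator of count > 0)."""
    if np.any(counts.values < 0):
        raise IntegrityError("counts must be nonnegative")
    return DetectionArray(
        values=(counts.values > 0).astype(np.int8),
        species=list(counts.species),
        points=list(counts.points),
        years=list(counts.years),
        visits=list(counts.visits),
    )


@dataclass
class CovariateTable:
    """Per-point covariates; optionally standardized with moments retained."""

    frame: pd.DataFrame  # indexed by point id
    standardized: bool = False
    #: column -> (mean, sd) recorded at standardization time
    moments: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.standardized and "area" in self.frame.columns:
            area = self.frame["area"].to_numpy(float)
            if np.any((area < 0) | (area > 100)):
                raise IntegrityError("area must be within [0, 100] percent")

    def columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "region"]

    def matrix(self, columns=MODEL_COVARIATES) -> np.ndarray:
        """Design matrix (n_points x len(columns)) in the given column order."""
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise FormatError(f"missing covariate column(s): {missing}")
        return self.frame[list(columns)].to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.frame.rename_axis("point").reset_index().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CovariateTable":
        df = pd.read_csv(path)
        if "point" not in df.columns:
            raise FormatError("missing column: point")
        return cls(frame=df.set_index("point"))


def read_species_table(path, validate_totals: bool = True) -> list[SpeciesRecord]:
    """Read a species detection table (habitat-category counts per species).

    Expected columns: latin_name, common_name, assemblage, the five habitat
    categories, and total.  An optional boolean ``exclude`` column marks
    gull/shoreline species to be removed from analyses.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty species table: {path}") from exc
    required = ["latin_name", "common_name", "assemblage", *HABITAT_CATEGORIES, "total"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    records = []
    for _, row in df.iterrows():
        counts = tuple(int(row[c]) for c in HABITAT_CATEGORIES)
        total = int(row["total"])
        if validate_totals and sum(counts) != total:
            raise IntegrityError(
                f"{row['latin_name']}: habitat counts sum to {sum(counts)}, "
                f"total column says {total}"
            )
        records.append(
            SpeciesRecord(
                latin_name=str(row["latin_name"]),
                common_name=str(row["common_name"]),
                assemblage=str(row["assemblage"]),
                habitat_counts=counts,
                total=total,
                exclude=bool(row.get("exclude", False)),
            )
        )
    return records


def bundled_species_table() -> list[SpeciesRecord]:
    """The species detection table shipped with the package."""
    ref = importlib.resources.files("willowbirds.data") / "table1_species.csv"
    with importlib.resources.as_file(ref) as path:
        return read_species_table(path)


def assemblage_partition(records) -> dict[str, list[SpeciesRecord]]:
    """Partition species records by assemblage label (disjoint, covering)."""
    out: dict[str, list[SpeciesRecord]] = {a: [] for a in ASSEMBLAGES}
    for rec in records:
        if rec.assemblage not in out:
            raise IntegrityError(f"unknown assemblage label: {rec.assemblage!r}")
        out[rec.assemblage].append(rec)
    return out


def standardize_covariates(table: CovariateTable, columns=None) -> CovariateTable:
    """Centre/scale columns to mean 0, SD 1 (sample SD, n-1 denominator).

    Moments are stored on the result so predictions can be back-transformed.
    Idempotent on already-standardized input up to floating point.
    """
    if columns is None:
        columns = table.columns()
    df = table.frame.copy()
    moments = dict(table.moments)
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
        x = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise IntegrityError(f"non-finite values in column {col!r}")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise IntegrityError(f"zero-variance column: {col!r}")
        df[col] = (x - mean) / sd
        moments[col] = (mean, sd)
    return CovariateTable(frame=df, standardized=True, moments=moments)


def unstandardize_covariates(table: CovariateTable) -> CovariateTable:
    """Invert :func:`standardize_covariates` using the stored moments."""
    if not table.standardized:
        return table
    df = table.frame.copy()
    for col, (mean, sd) in table.moments.items():
        if col in df.columns:
            df[col] = df[col].to_numpy(dtype=float) * sd + mean
    return CovariateTable(frame=df, standardized=False, moments={})


def drop_collinear(
    table: CovariateTable,
    threshold: float = 0.7,
    pair: tuple[str, str] = ("patch_density", "edge_density"),
):
    """Drop the first column of ``pair`` when |Pearson r| exceeds threshold.

    Returns ``(table, report)`` where the report records the correlation,
    the decision, and which column was retained.
    """
    a, b = pair
    for col in pair:
        if col not in table.frame.columns:
            raise FormatError(f"missing column: {col}")
    x = table.frame[a].to_numpy(dtype=float)
    y = table.frame[b].to_numpy(dtype=float)
    if len(x) < 3:
        raise IntegrityError("need at least 3 points to assess correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    report = {"pair": pair, "pearson_r": r, "threshold": threshold}
    if abs(r) > threshold:
        new = replace(table, frame=table.frame.drop(columns=[a]))
        report.update(dropped=a, retained=b)
        return new, report
    report.update(dropped=None, retained=None)
    return table, report
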