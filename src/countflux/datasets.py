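"""Reading, validating, aligning and preprocessing the annual series.

The working container is :class:`TimeSeriesDataset`: a complete annual grid
of calendar years with integer conflict and monument counts plus named
real-valued covariate columns.  Subannual proxy records (e.g. a speleothem
d18O series) are resampled to annual means with a cubic spline before they
join the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import CoverageError, SchemaError, ValidationError

__all__ = [
    "TimeSeriesDataset",
    "ProxyRecord",
    "read_dataset",
    "write_dataset",
    "read_proxy",
    "annualize_proxy",
    "mean_center",
    "align_window",
]

_COUNT_COLUMNS = ("conflicts", "monuments")


@dataclass
class TimeSeriesDataset:
    """Aligned annual series: years, counts, exposure and covariates.

    Invariants (enforced on construction): all series share one length;
    years are consecutive integers; conflict and monument counts are
    non-negative integers.  ``covariate_means`` records the means removed
    by :func:`mean_center` so effects can be mapped back to raw units.
    """

    years: np.ndarray
    conflicts: np.ndarray
    monuments: np.ndarray
    covariates: pd.DataFrame
    covariate_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.conflicts = _validate_counts(self.conflicts, "conflicts")
        self.monuments = _validate_counts(self.monuments, "monuments")
        self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
        n = len(self.years)
        if not (len(self.conflicts) == len(self.monuments) == len(self.covariates) == n):
            raise ValidationError("all series must have the same length")
        if n == 0:
            raise ValidationError("dataset is empty")
        dif = np.diff(self.years)
        if np.any(dif <= 0):
            dup = self.years[:-1][dif == 0]
            if dup.size:
                raise ValidationError(f"duplicate years: {dup.tolist()[:10]}")
            raise ValidationError("years must be strictly increasing")
        if np.any(dif != 1):
            missing = []
            for a, d in zip(self.years[:-1], dif):
                if d > 1:
                    missing.extend(range(int(a) + 1, int(a) + int(d)))
            raise ValidationError(
                f"missing years inside the window: {missing[:20]}"
                + ("..." if len(missing) > 20 else "")
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.covariates.columns)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "year": self.years,
                "conflicts": self.conflicts,
                "monuments": self.monuments,
            }
        )
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        return df

    def copy(self) -> "TimeSeriesDataset":
        return TimeSeriesDataset(
            years=self.years.copy(),
            conflicts=self.conflicts.copy(),
            monuments=self.monuments.copy(),
            covariates=self.covariates.copy(),
            covariate_means=dict(self.covariate_means),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeSeriesDataset):
            return NotImplemented
        return (
            np.array_equal(self.years, other.years)
            and np.array_equal(self.conflicts, other.conflicts)
            and np.array_equal(self.monuments, other.monuments)
            and self.covariates.equals(other.covariates)
        )


def _validate_counts(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    farr = arr.astype(float)
    if np.any(~np.isfinite(farr)):
        raise ValidationError(f"{name} contains non-finite values")
    if np.any(farr < 0):
        raise ValidationError(f"{name} contains negative values")
    if np.any(farr != np.floor(farr)):
        raise ValidationError(f"{name} contains non-integer values")
    return farr.astype(np.int64)


def read_dataset(path, column_map: Mapping[str, str] | None = None) -> TimeSeriesDataset:
    """Read an annual dataset from CSV.

    The file needs ``year``, ``conflicts`` and ``monuments`` columns (or a
    ``column_map`` of ``{file_column: canonical_name}`` renames); every
    other column is taken as a covariate.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("year",) + _COUNT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    cov_cols = [c for c in df.columns if c not in ("year",) + _COUNT_COLUMNS]
    return TimeSeriesDataset(
        years=df["year"].to_numpy(),
        conflicts=df["conflicts"].to_numpy(),
        monuments=df["monuments"].to_numpy(),
        covariates=df[cov_cols],
    )


def write_dataset(dataset: TimeSeriesDataset, path) -> Path:
    """Write the dataset as a plain CSV with a header row."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class ProxyRecord:
    """An irregular (possibly subannual) proxy series.

    ``times`` are fractional calendar years, strictly increasing, with at
    least two points; ``values`` are the proxy measurements.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.size < 2:
            raise ValidationError("proxy record needs at least 2 points")
        if self.times.size != self.values.size:
            raise ValidationError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("proxy times must be strictly increasing")


def read_proxy(path) -> ProxyRecord:
    """Read a two-column (time, value) CSV proxy record."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"proxy file {path} needs two columns (time, value)")
    return ProxyRecord(times=df.iloc[:, 0].to_numpy(), values=df.iloc[:, 1].to_numpy())


def annualize_proxy(
    record: ProxyRecord,
    start_year: int,
    end_year: int,
    points_per_year: int | None = None,
) -> np.ndarray:
    """Resample an irregular proxy record to annual means.

    A natural cubic spline is passed through all proxy points and averaged
    over each calendar year Y (the half-open interval [Y, Y+1)).  By
    default the average is the exact integral of the spline over the year
    (the limit of averaging ever-finer regular evaluation grids); passing
    ``points_per_year`` instead averages composite-Simpson evaluations on
    that many subintervals per year, which converges rapidly to the exact
    value as the grid refines.
    """
    if end_year < start_year:
        raise ValidationError("end_year must be >= start_year")
    lo, hi = float(start_year), float(end_year) + 1.0
    if record.times[0] > lo or record.times[-1] < hi:
        raise CoverageError(
            f"proxy record spans [{record.times[0]:g}, {record.times[-1]:g}] "
            f"but the window [{lo:g}, {hi:g}] was requested"
        )
    spline = CubicSpline(record.times, record.values, bc_type="natural")
    n_years = end_year - start_year + 1
    if points_per_year is None:
        return np.array(
            [spline.integrate(lo + i, lo + i + 1) for i in range(n_years)]
        )
    if points_per_year < 2:
        raise ValidationError("points_per_year must be >= 2")
    p = points_per_year + (points_per_year % 2)  # Simpson needs even count
    grid = lo + np.arange(n_years * p + 1) / p
    vals = spline(grid)
    # composite Simpson weights over one year: 1,4,2,4,...,2,4,1 times h/3
    w = np.ones(p + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w /= 3.0 * p
    annual = np.empty(n_years)
    for i in range(n_years):
        annual[i] = w @ vals[i * p : i * p + p + 1]
    return annual


def mean_center(
    dataset: TimeSeriesDataset,
    covariate_names: Sequence[str] | None = None,
) -> TimeSeriesDataset:
    """Subtract each named covariate's mean; keep the means for back-maps.

    Centering makes the intercept the log rate at average covariate
    conditions.  Means accumulate across repeated calls so the original
    scale stays recoverable; centering is idempotent on the values.
    """
    names = tuple(covariate_names) if covariate_names is not None else dataset.covariate_names
    out = dataset.copy()
    for name in names:
        if name not in out.covariates.columns:
            raise ValidationError(f"unknown covariate {name!r}")
        m = float(out.covariates[name].mean())
        out.covariates[name] = out.covariates[name] - m
        out.covariate_means[name] = out.covariate_means.get(name, 0.0) + m
    return out


def clamp_exposure(dataset: TimeSeriesDataset, min_value: int = 1) -> TimeSeriesDataset:
    """Raise every exposure value below ``min_value`` up to it.

    Off by default everywhere: a positive count in a zero-exposure year
    is an impossible observation under the model and normally a data
    error worth surfacing.  This rule exists for real records where a
    dated event can precede the first surviving monument; applying it
    concedes that the exposure series undercounts.
    """
    if min_value < 0:
        raise ValidationError("min_value must be non-negative")
    out = dataset.copy()
    out.monuments = np.maximum(out.monuments, min_value)
    return out


def align_window(
    dataset: TimeSeriesDataset, start_year: int, end_year: int
) -> TimeSeriesDataset:
    """Trim the dataset to [start_year, end_year], inclusive of both ends."""
    missing = [
        y
        for y in range(int(start_year), int(end_year) + 1)
        if y < dataset.start_year or y > dataset.end_year
    ]
    if missing:
        raise CoverageError(
            f"dataset covers {dataset.start_year}-{dataset.end_year}; "
            f"missing years: {missing[:20]}" + ("..." if len(missing) > 20 else "")
        )
    keep = (dataset.years >= start_year) & (dataset.years <= end_year)
    idx = np.flatnonzero(keep)
    return TimeSeriesDataset(
        years=dataset.years[idx],
        conflicts=dataset.conflicts[idx],
        monuments=dataset.monuments[idx],
        covariates=dataset.covariates.iloc[idx],
        covariate_means=dict(dataset.covariate_means),
    )
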