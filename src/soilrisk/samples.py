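"""Soil-sample tables, background sets, descriptive statistics and fixtures.

Concentrations are mg kg⁻¹ of dry soil throughout; Fe is treated like any other
metal despite its magnitude.  The canonical metal set is the eight
metal(loid)s routinely monitored around ferrous-metallurgy sites:
As, Pb, Zn, Fe, Cd, Cu, Cr, Ni.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

METALS: tuple[str, ...] = ("As", "Pb", "Zn", "Fe", "Cd", "Cu", "Cr", "Ni")

STAT_COLUMNS: tuple[str, ...] = (
    "min", "max", "mean", "sd", "cv_percent", "skewness", "kurtosis",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _data_path(name: str):
    return resources.files("soilrisk").joinpath("data", name)


@dataclass(frozen=True)
class BackgroundSet:
    """Per-metal geochemical background concentrations (mg kg⁻¹)."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for metal, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"background {self.name!r}: non-positive value for {metal}: {v}"
                )

    def __getitem__(self, metal: str) -> float:
        return float(self.values[metal])

    def metals(self) -> tuple[str, ...]:
        return tuple(self.values)


@dataclass
class SampleTable:
    """A validated per-sample table of metal concentrations.

    The underlying frame has a ``sample_id`` column, optional ``easting`` /
    ``northing`` coordinate columns and one numeric column per metal.
    """

    df: pd.DataFrame
    metals: tuple[str, ...] = field(default=METALS)

    def __post_init__(self) -> None:
        self.metals = tuple(self.metals)
        df = self.df
        if "sample_id" not in df.columns:
            raise ValidationError("missing required column 'sample_id'")
        unknown = set(self.metals) - set(METALS)
        if unknown:
            raise ValidationError(f"unknown metals: {sorted(unknown)}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id values: {dupes}")
        for metal in self.metals:
            if metal not in df.columns:
                raise ValidationError(f"missing metal column {metal!r}")
            col = pd.to_numeric(df[metal], errors="coerce")
            if col.isna().any():
                row = df.loc[col.isna()].index[0]
                raise ValidationError(
                    f"non-numeric or missing cell at row {row}, column {metal!r}"
                )
            if (col <= 0).any():
                row = df.loc[col <= 0].index[0]
                raise ValidationError(
                    f"non-positive concentration at row {row}, column {metal!r}: "
                    f"{col.loc[row]}"
                )
            self.df[metal] = col.astype(float)

    def __len__(self) -> int:
        return len(self.df)

    def concentrations(self, metal: str) -> np.ndarray:
        return self.df[metal].to_numpy(dtype=float)

    def matrix(self) -> pd.DataFrame:
        """Samples x metals concentration matrix indexed by sample_id."""
        return self.df.set_index("sample_id")[list(self.metals)]


@dataclass(frozen=True)
class SummaryStats:
    """Per-metal descriptive statistics (rows: metals; columns: statistics)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(STAT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"summary table missing columns {sorted(missing)}")
        bad = self.table.index[
            (self.table["min"] > self.table["mean"])
            | (self.table["mean"] > self.table["max"])
        ]
        if len(bad):
            raise ValidationError(f"min <= mean <= max violated for {list(bad)}")

    def metals(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def stat(self, metal: str, which: str) -> float:
        return float(self.table.loc[metal, which])


def read_samples(path: str | Path, metals: Sequence[str] = METALS) -> SampleTable:
    """Read and validate a CSV of per-sample concentrations.

    Expected layout: comma-separated UTF-8, header row, first column
    ``sample_id``, one column per metal; optional ``easting``/``northing``.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    return SampleTable(df, metals=tuple(metals))


def write_samples(table: SampleTable, path: str | Path) -> Path:
    """Write a SampleTable back to CSV (full float precision, round-trips)."""
    path = Path(path)
    cols = ["sample_id"]
    for c in ("easting", "northing"):
        if c in table.df.columns:
            cols.append(c)
    cols += list(table.metals)
    table.df[cols].to_csv(path, index=False, float_format="%.17g")
    return path


def summarize(table: SampleTable) -> SummaryStats:
    """Per-metal min/max/mean/SD/CV%/skewness/excess kurtosis.

    SD uses the n-1 denominator; skewness and kurtosis are the bias-adjusted
    sample estimators; kurtosis is excess (normal = 0).  Requires >= 2 samples.
    """
    if len(table) < 2:
        raise ValidationError("summarize requires at least 2 samples (SD undefined)")
    rows = {}
    for metal in table.metals:
        x = table.concentrations(metal)
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        constant = np.allclose(x, x[0])
        rows[metal] = {
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "mean": mean,
            "sd": sd,
            "cv_percent": 100.0 * sd / mean,
            "skewness": 0.0 if constant else float(sps.skew(x, bias=False)),
            "kurtosis": 0.0 if constant else float(sps.kurtosis(x, bias=False)),
        }
    return SummaryStats(pd.DataFrame.from_dict(rows, orient="index")[list(STAT_COLUMNS)])


def load_background(name: str = "ASV") -> BackgroundSet:
    """Load a packaged background set: 'ASV' (average shale) or 'UCC' (crust)."""
    with resources.as_file(_data_path("backgrounds.csv")) as p:
        df = pd.read_csv(p).set_index("metal")
    if name not in df.columns:
        raise KeyError(f"unknown background set {name!r}; have {list(df.columns)}")
    return BackgroundSet(name, df[name].to_dict())


def load_study_fixture() -> tuple[SummaryStats, BackgroundSet, BackgroundSet]:
    """Published summary statistics for the reference study site.

    Returns the per-metal descriptive statistics of a 20-sample survey of
    agricultural topsoils around a steel smelter, together with the ASV and
    UCC background sets, exactly as published.  These are the packaged inputs
    for the desk-reproducible index computations.
    """
    with resources.as_file(_data_path("study_summary.csv")) as p:
        df = pd.read_csv(p).set_index("metal")
    stats = SummaryStats(df[list(STAT_COLUMNS)].astype(float))
    return stats, load_background("ASV"), load_background("UCC")
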