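"""Geochemical pollution indices: EF, Igeo, CF and PLI.

All four indices compare measured concentrations to a geochemical background
set (average shale by default).  The enrichment factor double-normalizes by a
conservative reference element (Fe); the geo-accumulation index is
log₂(C/(1.5·B)) with the 1.5 factor absorbing lithogenic variability; the
contamination factor is the plain ratio C/B and the pollution load index is the
geometric mean of a sample's contamination factors.

Qualitative class schemes live in ``data/class_schemes.yaml`` (boundaries are
left-closed: a value on a bound belongs to the upper class).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .samples import BackgroundSet, SampleTable, SummaryStats, ValidationError

REFERENCE_ELEMENT = "Fe"  # conservative lithogenic normalizer for EF


def _require_positive(**kwargs: float | np.ndarray) -> None:
    for name, v in kwargs.items():
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValidationError(f"{name} must be strictly positive, got {v}")


def enrichment_factor(c_n, c_ref, b_n, b_ref):
    """EF = (C_n/C_ref)_sample / (B_n/B_ref)_background, Fe as reference."""
    _require_positive(c_n=c_n, c_ref=c_ref, b_n=b_n, b_ref=b_ref)
    return (np.asarray(c_n, float) / c_ref) / (np.asarray(b_n, float) / b_ref)


def geoaccumulation_index(c_n, b_n):
    """Igeo = log₂(C_n / (1.5 · B_n)); negative values mean below background."""
    _require_positive(c_n=c_n, b_n=b_n)
    return np.log2(np.asarray(c_n, float) / (1.5 * np.asarray(b_n, float)))


def contamination_factor(c_metal, c_background):
    """CF = C_metal / C_background."""
    _require_positive(c_metal=c_metal, c_background=c_background)
    return np.asarray(c_metal, float) / np.asarray(c_background, float)


def pollution_load_index(cfs: Iterable[float]) -> float:
    """PLI = (CF₁ · CF₂ · … · CFₙ)^(1/n), the geometric mean of the CFs."""
    arr = np.asarray(list(cfs), dtype=float)
    if arr.size == 0:
        raise ValidationError("PLI needs at least one contamination factor")
    _require_positive(cfs=arr)
    return float(np.exp(np.mean(np.log(arr))))


@dataclass(frozen=True)
class ClassScheme:
    """Ordered left-closed intervals [lower, upper) mapping a value to a label."""

    name: str
    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        ivs = self.intervals
        if not ivs:
            raise ValidationError(f"scheme {self.name!r} has no intervals")
        for (lo, hi, _), (lo2, _, _) in zip(ivs, ivs[1:]):
            if hi != lo2 or not lo < hi:
                raise ValidationError(
                    f"scheme {self.name!r}: intervals must be contiguous and increasing"
                )

    def classify(self, value: float) -> str:
        for lo, hi, label in self.intervals:
            if lo <= value < hi:
                return label
        # value == +inf upper bound of last interval
        return self.intervals[-1][2]


def load_class_schemes() -> dict[str, ClassScheme]:
    """The packaged classification schemes (igeo, ef, cf, pli, hi, tcr)."""
    p = resources.files("soilrisk").joinpath("data", "class_schemes.yaml")
    raw = yaml.safe_load(p.read_text())
    return {
        name: ClassScheme(name, tuple((float(lo), float(hi), str(lab)) for lo, hi, lab in ivs))
        for name, ivs in raw.items()
    }


def classify(value: float, scheme: ClassScheme) -> str:
    """Label of the interval containing ``value`` (bounds go to the upper class)."""
    return scheme.classify(float(value))


@dataclass
class IndexResult:
    """Per-sample/per-metal indices plus per-sample PLI and cross-sample summaries."""

    per_sample: pd.DataFrame   # rows (sample_id, metal): ef, igeo, cf + classes
    pli: pd.DataFrame          # rows sample_id: pli, pli_class
    summary: pd.DataFrame      # rows metal: min/max/mean for ef, igeo, cf
    background: str


def index_report(table: SampleTable, background: BackgroundSet) -> IndexResult:
    """Compute EF, Igeo, CF per (sample, metal), PLI per sample, and summaries."""
    missing = set(table.metals) - set(background.metals())
    if missing:
        raise ValidationError(
            f"background {background.name!r} lacks metals {sorted(missing)}"
        )
    if REFERENCE_ELEMENT not in table.metals:
        raise ValidationError(
            f"EF needs the reference element {REFERENCE_ELEMENT!r} in the table"
        )
    schemes = load_class_schemes()
    c_ref = table.concentrations(REFERENCE_ELEMENT)
    b_ref = background[REFERENCE_ELEMENT]

    rows = []
    cf_by_metal = {}
    for metal in table.metals:
        c = table.concentrations(metal)
        b = background[metal]
        ef = enrichment_factor(c, c_ref, b, b_ref)
        igeo = geoaccumulation_index(c, b)
        cf = contamination_factor(c, b)
        cf_by_metal[metal] = cf
        for sid, e, g, f in zip(table.df["sample_id"], ef, igeo, cf):
            rows.append(
                {
                    "sample_id": sid,
                    "metal": metal,
                    "ef": e,
                    "igeo": g,
                    "cf": f,
                    "ef_class": schemes["ef"].classify(e),
                    "igeo_class": schemes["igeo"].classify(g),
                    "cf_class": schemes["cf"].classify(f),
                }
            )
    per_sample = pd.DataFrame(rows)

    cf_matrix = np.column_stack([cf_by_metal[m] for m in table.metals])
    pli_vals = np.exp(np.mean(np.log(cf_matrix), axis=1))
    pli = pd.DataFrame(
        {
            "sample_id": table.df["sample_id"],
            "pli": pli_vals,
            "pli_class": [schemes["pli"].classify(v) for v in pli_vals],
        }
    )

    summary = (
        per_sample.groupby("metal", sort=False)[["ef", "igeo", "cf"]]
        .agg(["min", "max", "mean"])
    )
    summary.columns = [f"{idx}_{stat}" for idx, stat in summary.columns]
    return IndexResult(per_sample, pli, summary, background.name)


def cf_summary_from_stats(
    stats: SummaryStats, background: BackgroundSet
) -> pd.DataFrame:
    """CF min/max/mean per metal straight from summary statistics.

    CF is linear in concentration, so the minimum, maximum and mean CF of a
    survey equal the summary min/max/mean divided by the background value —
    published summary tables are enough to recover the CF table exactly.
    """
    rows = {}
    for metal in stats.metals():
        b = background[metal]
        rows[metal] = {
            "cf_min": stats.stat(metal, "min") / b,
            "cf_max": stats.stat(metal, "max") / b,
            "cf_mean": stats.stat(metal, "mean") / b,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def igeo_range_from_stats(
    stats: SummaryStats, background: BackgroundSet
) -> pd.DataFrame:
    """Igeo of the per-metal min and max concentrations (log₂ is monotone)."""
    rows = {}
    for metal in stats.metals():
        b = background[metal]
        rows[metal] = {
            "igeo_min": float(geoaccumulation_index(stats.stat(metal, "min"), b)),
            "igeo_max": float(geoaccumulation_index(stats.stat(metal, "max"), b)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
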