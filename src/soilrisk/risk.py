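"""Deterministic USEPA multi-pathway exposure-dose and risk model.

Three pathways (incidental soil ingestion, inhalation of resuspended
particulates, dermal contact) for two receptors (child, adult).  Average daily
intakes (ADI, mg kg⁻¹ day⁻¹):

    ADI_ing  = C · IngR · EF · ED / (BW · AT) · 1e-6
    ADI_inh  = C · InhR · EF · ED / (BW · AT · PEF)
    ADI_derm = C · SA · AF · ABS · EF · ED / (BW · AT) · 1e-6

The 1e-6 converts mg of metal per kg of soil to mg per mg of soil ingested or
adhered; the inhalation route has no such factor because PEF (m³ air per kg
soil) already carries the mass conversion.  Non-carcinogenic hazard quotients
divide ADI (with AT = ED·365) by route-specific reference doses and sum to the
hazard index HI; carcinogenic risks multiply ADI (with a 70-year AT) by route
slope factors and sum to the total cancer risk TCR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .indices import load_class_schemes
from .samples import SampleTable, ValidationError

PATHWAYS = ("ing", "inh", "derm")
RECEPTORS = ("child", "adult")


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor-specific exposure factors (units in data/exposure_defaults.yaml)."""

    receptor: str
    ing_r: float
    inh_r: float
    ef_d: float
    ed: float
    bw: float
    at_nc: float
    at_ca: float
    sa: float
    af: float
    pef: float

    def __post_init__(self) -> None:
        for name in ("ing_r", "inh_r", "ef_d", "ed", "bw", "at_nc", "at_ca",
                     "sa", "af", "pef"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.ef_d > 365:
            raise ValidationError("ef_d cannot exceed 365 days/year")
        if not np.isclose(self.at_nc, self.ed * 365):
            raise ValidationError("at_nc must equal ed * 365 (convention)")
        if self.at_ca < self.at_nc:
            raise ValidationError("at_ca must be >= at_nc")


@dataclass(frozen=True)
class ToxicityEntry:
    """Route-specific reference doses and slope factors for one metal."""

    metal: str
    rfd_ing: float
    rfd_inh: float
    rfd_derm: float
    abs_derm: float
    csf_ing: float | None = None
    csf_inh: float | None = None
    csf_derm: float | None = None
    gi_abs: float = 1.0  # gastrointestinal absorption fraction (dermal extrapolation)
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("rfd_ing", "rfd_inh", "rfd_derm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{self.metal}: {name} must be > 0")
        if not 0 < self.abs_derm <= 1:
            raise ValidationError(f"{self.metal}: abs_derm must be in (0, 1]")
        for name in ("csf_ing", "csf_inh", "csf_derm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{self.metal}: {name} must be > 0 if present")

    @property
    def carcinogenic(self) -> bool:
        return any(
            v is not None for v in (self.csf_ing, self.csf_inh, self.csf_derm)
        )


ToxicityRegistry = Mapping[str, ToxicityEntry]


def default_profiles(path: str | Path | None = None) -> dict[str, ExposureProfile]:
    """Load exposure profiles from YAML (packaged defaults if no path given)."""
    if path is None:
        raw = yaml.safe_load(
            resources.files("soilrisk").joinpath("data", "exposure_defaults.yaml").read_text()
        )
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return {name: ExposureProfile(receptor=name, **vals) for name, vals in raw.items()}


def default_toxicity(path: str | Path | None = None) -> dict[str, ToxicityEntry]:
    """Load the toxicity registry from YAML (packaged defaults if no path given)."""
    if path is None:
        raw = yaml.safe_load(
            resources.files("soilrisk").joinpath("data", "toxicity_defaults.yaml").read_text()
        )
    else:
        raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for metal, vals in raw.items():
        vals = dict(vals)
        vals.pop("csf_derm_note", None)
        out[metal] = ToxicityEntry(metal=metal, **vals)
    return out


def adi_ingestion(c_soil, p: ExposureProfile, at: float):
    """Soil-ingestion dose, mg kg⁻¹ day⁻¹ (c_soil = 0 allowed for linearity)."""
    c = np.asarray(c_soil, dtype=float)
    if np.any(c < 0) or at <= 0:
        raise ValidationError("c_soil must be >= 0 and at > 0")
    return c * p.ing_r * p.ef_d * p.ed / (p.bw * at) * 1e-6


def adi_inhalation(c_soil, p: ExposureProfile, at: float):
    """Particulate-inhalation dose, mg kg⁻¹ day⁻¹ (PEF carries the unit change)."""
    c = np.asarray(c_soil, dtype=float)
    if np.any(c < 0) or at <= 0:
        raise ValidationError("c_soil must be >= 0 and at > 0")
    return c * p.inh_r * p.ef_d * p.ed / (p.bw * at * p.pef)


def adi_dermal(c_soil, p: ExposureProfile, abs_derm: float, at: float):
    """Dermal-contact dose, mg kg⁻¹ day⁻¹."""
    c = np.asarray(c_soil, dtype=float)
    if np.any(c < 0) or at <= 0:
        raise ValidationError("c_soil must be >= 0 and at > 0")
    if not 0 <= abs_derm <= 1:
        raise ValidationError("abs_derm must be in [0, 1]")
    return c * p.sa * p.af * abs_derm * p.ef_d * p.ed / (p.bw * at) * 1e-6


def adi_all(c_soil, p: ExposureProfile, tox: ToxicityEntry, at: float):
    """(ADI_ing, ADI_inh, ADI_derm) at a given averaging time."""
    return (
        adi_ingestion(c_soil, p, at),
        adi_inhalation(c_soil, p, at),
        adi_dermal(c_soil, p, tox.abs_derm, at),
    )


def hazard_quotients(adi_ing, adi_inh, adi_derm, tox: ToxicityEntry):
    """(HQ_ing, HQ_inh, HQ_derm, HI) — ADIs must be computed with AT_nc."""
    hq_ing = np.asarray(adi_ing, float) / tox.rfd_ing
    hq_inh = np.asarray(adi_inh, float) / tox.rfd_inh
    hq_derm = np.asarray(adi_derm, float) / tox.rfd_derm
    return hq_ing, hq_inh, hq_derm, hq_ing + hq_inh + hq_derm


def cancer_risks(adi_ing, adi_inh, adi_derm, tox: ToxicityEntry):
    """(CR_ing, CR_inh, CR_derm, TCR) — ADIs must be computed with AT_ca.

    Routes without a slope factor contribute zero; a metal with no slope
    factor at all raises (callers exclude it from TCR tables with a notice).
    """
    if not tox.carcinogenic:
        raise ValidationError(
            f"{tox.metal} has no cancer slope factor for any route "
            "(non-carcinogenic-only)"
        )
    crs = []
    for adi, csf in (
        (adi_ing, tox.csf_ing),
        (adi_inh, tox.csf_inh),
        (adi_derm, tox.csf_derm),
    ):
        adi = np.asarray(adi, float)
        crs.append(adi * csf if csf is not None else np.zeros_like(adi))
    return crs[0], crs[1], crs[2], crs[0] + crs[1] + crs[2]


def hi_for(c_soil, p: ExposureProfile, tox: ToxicityEntry):
    """Hazard index of a concentration under a profile/toxicity entry."""
    return hazard_quotients(*adi_all(c_soil, p, tox, p.at_nc), tox)[3]


def tcr_for(c_soil, p: ExposureProfile, tox: ToxicityEntry):
    """Total cancer risk of a concentration under a profile/toxicity entry."""
    return cancer_risks(*adi_all(c_soil, p, tox, p.at_ca), tox)[3]


def deterministic_risk_report(
    table: SampleTable,
    profiles: Mapping[str, ExposureProfile] | None = None,
    tox: ToxicityRegistry | None = None,
) -> pd.DataFrame:
    """Full per-(sample, metal, receptor) risk table.

    Columns: the three ADIs (non-carcinogenic AT), HQs, HI and its class, and —
    for carcinogenic metals — CRs and TCR (carcinogenic AT) with class.
    Non-carcinogenic-only metals carry NaN in the CR columns and are flagged.
    """
    profiles = profiles or default_profiles()
    tox = tox or default_toxicity()
    missing = set(table.metals) - set(tox)
    if missing:
        raise ValidationError(f"toxicity registry lacks metals {sorted(missing)}")
    schemes = load_class_schemes()
    rows = []
    for receptor, p in profiles.items():
        for metal in table.metals:
            t = tox[metal]
            c = table.concentrations(metal)
            a_ing, a_inh, a_derm = adi_all(c, p, t, p.at_nc)
            hq_ing, hq_inh, hq_derm, hi = hazard_quotients(a_ing, a_inh, a_derm, t)
            if t.carcinogenic:
                ca = adi_all(c, p, t, p.at_ca)
                cr_ing, cr_inh, cr_derm, tcr = cancer_risks(*ca, t)
            else:
                cr_ing = cr_inh = cr_derm = tcr = np.full_like(hi, np.nan)
            for i, sid in enumerate(table.df["sample_id"]):
                rows.append(
                    {
                        "receptor": receptor,
                        "metal": metal,
                        "sample_id": sid,
                        "adi_ing": a_ing[i],
                        "adi_inh": a_inh[i],
                        "adi_derm": a_derm[i],
                        "hq_ing": hq_ing[i],
                        "hq_inh": hq_inh[i],
                        "hq_derm": hq_derm[i],
                        "hi": hi[i],
                        "hi_class": schemes["hi"].classify(hi[i]),
                        "cr_ing": cr_ing[i],
                        "cr_inh": cr_inh[i],
                        "cr_derm": cr_derm[i],
                        "tcr": tcr[i],
                        "tcr_class": (
                            schemes["tcr"].classify(tcr[i])
                            if t.carcinogenic
                            else "non-carcinogenic-only"
                        ),
                    }
                )
    return pd.DataFrame(rows)


def risk_summary(report: pd.DataFrame) -> pd.DataFrame:
    """P5/P50/P95 of HI and TCR across samples per (receptor, metal)."""
    def q(x, p):
        return float(np.percentile(x.dropna(), p)) if x.notna().any() else np.nan

    rows = []
    for (receptor, metal), grp in report.groupby(["receptor", "metal"], sort=False):
        rows.append(
            {
                "receptor": receptor,
                "metal": metal,
                "hi_p5": q(grp["hi"], 5),
                "hi_p50": q(grp["hi"], 50),
                "hi_p95": q(grp["hi"], 95),
                "tcr_p5": q(grp["tcr"], 5),
                "tcr_p50": q(grp["tcr"], 50),
                "tcr_p95": q(grp["tcr"], 95),
            }
        )
    return pd.DataFrame(rows)
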