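"""Monte Carlo propagation of parameter uncertainty through the risk model.

A simulation is a deterministic risk closure evaluated over named parameter
draws.  Parameter uncertainty is described by :class:`DistributionSpec`
(point / normal / lognormal / triangular / uniform, optionally truncated);
truncation is applied by inverse-CDF restriction so that draws remain exactly
reproducible and stratified transforms (Sobol' sequences) stay stratified.

Default parameterization of the hazard-index model
--------------------------------------------------
* concentration C — truncated normal around the site mean with the standard
  error of the mean (sd/√n), truncated at the observed min/max: the quantity
  propagated is the uncertainty of the chronic site-wide exposure
  concentration, not raw spatial variability;
* soil ingestion rate IngR — triangular (0.25×, 1×, 2×) around the point
  value: soil-ingestion estimates are the most uncertain exposure factor in
  the literature, with central estimates spanning roughly a factor of four;
* InhR, SA, AF — triangular ±30% around the point values;
* BW — truncated normal, SD = BW/6 (child 15 ± 2.5 kg, adult 70 ± 11.7 kg);
* EF, ED, PEF — fixed point values (chronic-scenario constants).

Summaries report P5/P50/P95 (linear interpolation of order statistics) and
exceedance probabilities against risk thresholds (HI > 1, TCR > 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .risk import (
    ExposureProfile,
    ToxicityEntry,
    adi_all,
    cancer_risks,
    default_profiles,
    default_toxicity,
    hazard_quotients,
)
from .samples import SummaryStats, ValidationError

HI_THRESHOLD = 1.0
TCR_THRESHOLD = 1e-4


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric distribution with optional truncation bounds."""

    name: str
    family: str
    params: Mapping[str, float]
    trunc: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("point", "normal", "lognormal", "triangular", "uniform"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.trunc is not None:
            lo, hi = self.trunc
            if not lo < hi:
                raise ValidationError(f"{self.name}: truncation needs low < high")
        self._frozen()  # validate parameters eagerly

    def _frozen(self):
        p = self.params
        try:
            if self.family == "point":
                float(p["value"])
                return None
            if self.family == "normal":
                if p["sd"] <= 0:
                    raise ValidationError(f"{self.name}: sd must be > 0")
                return sps.norm(p["mean"], p["sd"])
            if self.family == "lognormal":
                if p["sigma"] <= 0:
                    raise ValidationError(f"{self.name}: sigma must be > 0")
                return sps.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
            if self.family == "triangular":
                low, mode, high = p["low"], p["mode"], p["high"]
                if not (low <= mode <= high and low < high):
                    raise ValidationError(
                        f"{self.name}: need low <= mode <= high and low < high"
                    )
                return sps.triang(
                    c=(mode - low) / (high - low), loc=low, scale=high - low
                )
            low, high = p["low"], p["high"]
            if not low < high:
                raise ValidationError(f"{self.name}: need low < high")
            return sps.uniform(loc=low, scale=high - low)
        except KeyError as e:
            raise ValidationError(f"{self.name}: missing parameter {e}") from e

    def ppf(self, u):
        """Inverse CDF, with truncation folded in by CDF restriction."""
        u = np.asarray(u, dtype=float)
        if self.family == "point":
            return np.full_like(u, float(self.params["value"]))
        dist = self._frozen()
        if self.trunc is not None:
            lo, hi = self.trunc
            a, b = dist.cdf(lo), dist.cdf(hi)
            u = a + u * (b - a)
        return dist.ppf(u)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValidationError("n must be >= 1")
        return self.ppf(rng.random(n))

    def mean(self) -> float:
        """Analytic mean of the untruncated distribution (tests/diagnostics)."""
        if self.family == "point":
            return float(self.params["value"])
        return float(self._frozen().mean())


def sample(dist: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """n reproducible draws from a distribution spec."""
    return dist.sample(n, np.random.default_rng(seed))


Model = Callable[[Mapping[str, np.ndarray]], np.ndarray | Mapping[str, np.ndarray]]


@dataclass
class MCSummary:
    """Percentiles and exceedance probabilities of a Monte Carlo run."""

    table: pd.DataFrame
    n_iterations: int
    seed: int

    def row(self, output: str) -> pd.Series:
        return self.table.set_index("output").loc[output]


def _draw_params(
    dists: Mapping[str, DistributionSpec], n: int, seed: int
) -> dict[str, np.ndarray]:
    # one independent, reproducible substream per parameter (sorted by name)
    names = sorted(dists)
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: dists[name].sample(n, np.random.default_rng(ss))
        for name, ss in zip(names, children)
    }


def _as_outputs(y) -> dict[str, np.ndarray]:
    if isinstance(y, Mapping):
        return {k: np.asarray(v, dtype=float) for k, v in y.items()}
    return {"output": np.asarray(y, dtype=float)}


def run_simulation(
    model: Model,
    dists: Mapping[str, DistributionSpec],
    n: int = 10_000,
    seed: int = 0,
    thresholds: Mapping[str, float] | float | None = None,
) -> MCSummary:
    """Evaluate the model over n joint draws and summarize the outputs.

    ``thresholds`` maps output names to exceedance thresholds (a scalar applies
    to every output); exceedance is the fraction of draws strictly above the
    threshold.
    """
    params = _draw_params(dists, n, seed)
    outputs = _as_outputs(model(params))
    rows = []
    for name, y in outputs.items():
        if y.shape != (n,):
            raise ValidationError(f"output {name!r}: expected {n} values, got {y.shape}")
        if not np.all(np.isfinite(y)):
            i = int(np.flatnonzero(~np.isfinite(y))[0])
            vals = {k: float(v[i]) for k, v in params.items()}
            raise ValidationError(
                f"model produced non-finite output {name!r} at draw {i}; "
                f"parameters: {vals}"
            )
        if thresholds is None:
            thr = None
        elif isinstance(thresholds, Mapping):
            thr = thresholds.get(name)
        else:
            thr = float(thresholds)
        p5, p50, p95 = np.percentile(y, [5, 50, 95])
        rows.append(
            {
                "output": name,
                "mean": float(np.mean(y)),
                "sd": float(np.std(y, ddof=1)) if n > 1 else 0.0,
                "p5": float(p5),
                "p50": float(p50),
                "p95": float(p95),
                "threshold": np.nan if thr is None else thr,
                "p_exceed": np.nan if thr is None else float(np.mean(y > thr)),
            }
        )
    return MCSummary(pd.DataFrame(rows), n_iterations=n, seed=seed)


TRACKED_STATS = ("mean", "sd", "p5", "p50", "p95")


@dataclass
class ConvergenceResult:
    table: pd.DataFrame
    tolerance: float

    @property
    def passed(self) -> bool:
        return not bool(self.table["flag"].any())


def convergence_check(
    model: Model,
    dists: Mapping[str, DistributionSpec],
    ns: Sequence[int] = (5_000, 10_000, 15_000),
    seed: int = 0,
    tolerance: float = 0.02,
) -> ConvergenceResult:
    """Relative drift of tracked statistics across iteration counts.

    The simulation is run once at the largest n and statistics are evaluated
    at each checkpoint n along the same stream (the estimate a practitioner
    would have stopped with after n iterations); the table reports
    |stat(n) − stat(n_max)| / |stat(n_max)| for mean, SD and the P5/P50/P95
    percentiles of every output, flagging drifts above the tolerance
    (default 2%).
    """
    ns = sorted(ns)
    n_max_total = ns[-1]
    params_full = _draw_params(dists, n_max_total, seed)
    summaries = {}
    for n in ns:
        params = {k: v[:n] for k, v in params_full.items()}
        outputs = _as_outputs(model(params))
        rows = []
        for name, y in outputs.items():
            p5, p50, p95 = np.percentile(y, [5, 50, 95])
            rows.append(
                {
                    "output": name,
                    "mean": float(np.mean(y)),
                    "sd": float(np.std(y, ddof=1)) if n > 1 else 0.0,
                    "p5": float(p5),
                    "p50": float(p50),
                    "p95": float(p95),
                }
            )
        summaries[n] = MCSummary(pd.DataFrame(rows), n_iterations=n, seed=seed)
    n_max = ns[-1]
    ref = summaries[n_max].table.set_index("output")
    rows = []
    for n in ns[:-1]:
        cur = summaries[n].table.set_index("output")
        for output in cur.index:
            # statistics indistinguishable from zero at the output's own scale
            # (fp dust on degenerate inputs) count as exactly converged
            tiny = 1e-10 * max(1.0, abs(float(ref.loc[output, "mean"])))
            for stat in TRACKED_STATS:
                val, rval = float(cur.loc[output, stat]), float(ref.loc[output, stat])
                if abs(val - rval) <= tiny:
                    rel = 0.0
                elif abs(rval) <= tiny:
                    rel = np.inf
                else:
                    rel = abs(val - rval) / abs(rval)
                rows.append(
                    {
                        "output": output,
                        "statistic": stat,
                        "n": n,
                        "n_ref": n_max,
                        "value": val,
                        "ref_value": rval,
                        "rel_diff": rel,
                        "flag": rel > tolerance,
                    }
                )
    return ConvergenceResult(pd.DataFrame(rows), tolerance)


# ---------------------------------------------------------------------------
# Default distribution library for the risk models
# ---------------------------------------------------------------------------

def concentration_dist(
    metal: str, stats: SummaryStats, n_site_samples: int = 20
) -> DistributionSpec:
    """Uncertainty of the site-mean concentration: trunc-normal(mean, sd/√n)."""
    mean = stats.stat(metal, "mean")
    se = stats.stat(metal, "sd") / np.sqrt(n_site_samples)
    return DistributionSpec(
        "C", "normal", {"mean": mean, "sd": se},
        trunc=(stats.stat(metal, "min"), stats.stat(metal, "max")),
    )


def _triangular(name: str, center: float, rel: float) -> DistributionSpec:
    return DistributionSpec(
        name, "triangular",
        {"low": (1 - rel) * center, "mode": center, "high": (1 + rel) * center},
    )


def exposure_dists(profile: ExposureProfile) -> dict[str, DistributionSpec]:
    """Default exposure-factor distributions for one receptor."""
    return {
        "IngR": DistributionSpec(
            "IngR", "triangular",
            {"low": 0.25 * profile.ing_r, "mode": profile.ing_r,
             "high": 2.0 * profile.ing_r},
        ),
        "InhR": _triangular("InhR", profile.inh_r, 0.30),
        "SA": _triangular("SA", profile.sa, 0.30),
        "AF": _triangular("AF", profile.af, 0.30),
        "BW": DistributionSpec(
            "BW", "normal", {"mean": profile.bw, "sd": profile.bw / 6.0},
            trunc=(profile.bw / 2.0, 2.0 * profile.bw),
        ),
    }


def _model_from(profile: ExposureProfile, tox: ToxicityEntry, at: float, kind: str):
    def model(params: Mapping[str, np.ndarray]):
        p = SimpleNamespace(
            ing_r=params["IngR"], inh_r=params["InhR"], sa=params["SA"],
            af=params["AF"], bw=params["BW"],
            ef_d=profile.ef_d, ed=profile.ed, pef=profile.pef,
        )
        adis = adi_all(params["C"], p, tox, at)
        if kind == "hi":
            return hazard_quotients(*adis, tox)[3]
        return cancer_risks(*adis, tox)[3]

    return model


def build_hi_model(
    metal: str,
    receptor: str = "child",
    stats: SummaryStats | None = None,
    profiles: Mapping[str, ExposureProfile] | None = None,
    tox: Mapping[str, ToxicityEntry] | None = None,
    n_site_samples: int = 20,
):
    """(model, dists) for the hazard index of one metal and receptor.

    The model reuses the deterministic dose/HQ code path, so with all-point
    distributions the Monte Carlo output equals the deterministic result.
    """
    if stats is None:
        from .samples import load_study_fixture

        stats, _, _ = load_study_fixture()
    profiles = profiles or default_profiles()
    tox = tox or default_toxicity()
    profile = profiles[receptor]
    dists = {"C": concentration_dist(metal, stats, n_site_samples)}
    dists.update(exposure_dists(profile))
    return _model_from(profile, tox[metal], profile.at_nc, "hi"), dists


def build_tcr_model(
    metal: str,
    receptor: str = "child",
    stats: SummaryStats | None = None,
    profiles: Mapping[str, ExposureProfile] | None = None,
    tox: Mapping[str, ToxicityEntry] | None = None,
    n_site_samples: int = 20,
):
    """(model, dists) for the total cancer risk of one metal and receptor."""
    if stats is None:
        from .samples import load_study_fixture

        stats, _, _ = load_study_fixture()
    profiles = profiles or default_profiles()
    tox = tox or default_toxicity()
    profile = profiles[receptor]
    if not tox[metal].carcinogenic:
        raise ValidationError(f"{metal} has no slope factor; TCR model undefined")
    dists = {"C": concentration_dist(metal, stats, n_site_samples)}
    dists.update(exposure_dists(profile))
    return _model_from(profile, tox[metal], profile.at_ca, "tcr"), dists


def point_dists(dists: Mapping[str, DistributionSpec]) -> dict[str, DistributionSpec]:
    """Collapse every distribution to a point mass at its analytic mean."""
    return {
        name: DistributionSpec(name, "point", {"value": d.mean()})
        for name, d in dists.items()
    }
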