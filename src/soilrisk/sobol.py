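"""Variance-based global sensitivity analysis (Sobol indices).

The evaluation design is the Saltelli scheme: two base matrices A and B of N
joint parameter vectors plus the cross matrices AB_i (A with column i taken
from B) and BA_i, giving N·(2D+2) model evaluations for D parameters when
second-order indices are requested (N·(D+2) otherwise).  The base sample is a
scrambled Sobol' low-discrepancy sequence in [0,1)^{2D}; marginals are mapped
to the target distributions by inverse CDF so the stratification is preserved.

Estimators (chosen for low estimator variance):

* first order   S1_i = E[f_B · (f_{AB_i} − f_A)] / V        (Saltelli 2010)
* total order   ST_i = E[(f_A − f_{AB_i})²] / (2V)          (Jansen 1999)
* second order  S2_ij = E[f_{BA_i}·f_{AB_j} − f_A·f_B]/V − S1_i − S1_j

Negative estimates are reported as-is (they signal estimator noise or
non-convergence; clipping would hide it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .mc import DistributionSpec
from .samples import ValidationError


@dataclass
class SaltelliDesign:
    """Parameter matrix arranged in blocks [A; B; AB_1..AB_D; BA_1..BA_D]."""

    matrix: np.ndarray
    names: tuple[str, ...]
    n_base: int
    second_order: bool

    @property
    def d(self) -> int:
        return len(self.names)

    @property
    def n_evaluations(self) -> int:
        return self.matrix.shape[0]

    def params(self) -> dict[str, np.ndarray]:
        return {name: self.matrix[:, j] for j, name in enumerate(self.names)}

    def evaluate(self, model: Callable[[Mapping[str, np.ndarray]], np.ndarray]):
        return np.asarray(model(self.params()), dtype=float)


def saltelli_sample(
    dists: Mapping[str, DistributionSpec],
    n_base: int = 1024,
    seed: int | None = None,
    second_order: bool = True,
) -> SaltelliDesign:
    """Generate the Saltelli evaluation matrix for the given marginals.

    ``n_base`` should be a power of two (the Sobol' sequence is balanced at
    powers of two; other sizes trigger a warning).
    """
    names = tuple(dists)
    d = len(names)
    if d < 2:
        raise ValidationError("Sobol analysis needs at least 2 parameters")
    if n_base < 2:
        raise ValidationError("n_base must be >= 2")
    if n_base & (n_base - 1):
        warnings.warn(
            f"n_base={n_base} is not a power of two; Sobol' sequence balance "
            "properties are degraded",
            stacklevel=2,
        )
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    u = sampler.random(n_base)
    # clip away exact 0/1 to keep unbounded ppfs finite
    eps = np.finfo(float).tiny
    u = np.clip(u, eps, 1 - np.finfo(float).epsneg)
    a_u, b_u = u[:, :d], u[:, d:]

    blocks = [a_u, b_u]
    for i in range(d):
        ab = a_u.copy()
        ab[:, i] = b_u[:, i]
        blocks.append(ab)
    if second_order:
        for i in range(d):
            ba = b_u.copy()
            ba[:, i] = a_u[:, i]
            blocks.append(ba)
    u_all = np.vstack(blocks)

    x = np.empty_like(u_all)
    for j, name in enumerate(names):
        x[:, j] = dists[name].ppf(u_all[:, j])
    return SaltelliDesign(x, names, n_base, second_order)


@dataclass
class SobolResult:
    """First-, second- and total-order Sobol indices with bootstrap CIs."""

    names: tuple[str, ...]
    s1: np.ndarray
    st: np.ndarray
    s1_conf: np.ndarray
    st_conf: np.ndarray
    s2: pd.DataFrame | None
    n_base: int
    n_evaluations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "s1": self.s1,
                "s1_conf": self.s1_conf,
                "st": self.st,
                "st_conf": self.st_conf,
            }
        )


def _split(y: np.ndarray, n: int, d: int, second_order: bool):
    f_a = y[:n]
    f_b = y[n : 2 * n]
    f_ab = [y[(2 + i) * n : (3 + i) * n] for i in range(d)]
    f_ba = (
        [y[(2 + d + i) * n : (3 + d + i) * n] for i in range(d)]
        if second_order
        else None
    )
    return f_a, f_b, f_ab, f_ba


def _estimate(f_a, f_b, f_ab, f_ba, idx=None):
    if idx is not None:
        f_a, f_b = f_a[idx], f_b[idx]
        f_ab = [f[idx] for f in f_ab]
        f_ba = [f[idx] for f in f_ba] if f_ba is not None else None
    both = np.concatenate([f_a, f_b])
    v = both.var()
    if v == 0.0:
        return None, None, None, 0.0
    # center so the estimators are exactly invariant to output shifts
    mu = both.mean()
    f_a, f_b = f_a - mu, f_b - mu
    f_ab = [f - mu for f in f_ab]
    f_ba = [f - mu for f in f_ba] if f_ba is not None else None
    d = len(f_ab)
    s1 = np.array([np.mean(f_b * (f_ab[i] - f_a)) / v for i in range(d)])
    st = np.array([0.5 * np.mean((f_a - f_ab[i]) ** 2) / v for i in range(d)])
    s2 = None
    if f_ba is not None:
        s2 = np.full((d, d), np.nan)
        for i in range(d):
            for j in range(i + 1, d):
                vij = np.mean(f_ba[i] * f_ab[j] - f_a * f_b) / v
                s2[i, j] = vij - s1[i] - s1[j]
    return s1, st, s2, v


def sobol_indices(
    y: np.ndarray,
    design: SaltelliDesign,
    n_bootstrap: int = 100,
    bootstrap_seed: int = 0,
) -> SobolResult:
    """Estimate S1, ST (and S2 if the design includes BA blocks) from outputs."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n_evaluations:
        raise ValidationError(
            f"expected {design.n_evaluations} outputs, got {y.shape[0]}"
        )
    if not np.all(np.isfinite(y)):
        raise ValidationError("model outputs must be finite")
    n, d = design.n_base, design.d
    f_a, f_b, f_ab, f_ba = _split(y, n, d, design.second_order)
    s1, st, s2, v = _estimate(f_a, f_b, f_ab, f_ba)
    if v == 0.0 or s1 is None:
        raise ValidationError("constant model: output variance is zero")

    rng = np.random.default_rng(bootstrap_seed)
    s1_bs = np.empty((n_bootstrap, d))
    st_bs = np.empty((n_bootstrap, d))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        s1_b, st_b, _, _ = _estimate(f_a, f_b, f_ab, None, idx=idx)
        s1_bs[b], st_bs[b] = s1_b, st_b
    # 95% normal-approximation half-widths
    s1_conf = 1.96 * s1_bs.std(axis=0, ddof=1)
    st_conf = 1.96 * st_bs.std(axis=0, ddof=1)

    s2_frame = None
    if s2 is not None:
        s2_frame = pd.DataFrame(s2, index=list(design.names), columns=list(design.names))
    return SobolResult(
        design.names, s1, st, s1_conf, st_conf, s2_frame,
        n_base=n, n_evaluations=design.n_evaluations,
    )


def rank_parameters(
    result: SobolResult, cutoff: float = 0.1
) -> list[tuple[str, float]]:
    """Parameters with total-order index above the cutoff, most important first."""
    pairs = sorted(zip(result.names, result.st), key=lambda p: -p[1])
    return [(name, float(s)) for name, s in pairs if s > cutoff]


def analyze_model(
    model: Callable[[Mapping[str, np.ndarray]], np.ndarray],
    dists: Mapping[str, DistributionSpec],
    n_base: int = 1024,
    seed: int | None = None,
    second_order: bool = True,
) -> SobolResult:
    """Convenience wrapper: design, evaluate, estimate."""
    design = saltelli_sample(dists, n_base, seed=seed, second_order=second_order)
    return sobol_indices(design.evaluate(model), design)
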