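import numpy as np
import pandas as pd
import pytest

from soilrisk.mc import (
    DistributionSpec,
    build_hi_model,
    build_tcr_model,
    convergence_check,
    run_simulation,
    sample,
)
from soilrisk.risk import hi_for, tcr_for
from soilrisk.samples import ValidationError


def point(name, v):
    return DistributionSpec(name, "point", {"value": v})


def test_point_mass_sampling():
    assert (sample(point("p", 5.0), 3, seed=0) == 5.0).all()


def test_lognormal_median_matches_analytic():
    """Empirical median of e^X, X~N(mu, sigma^2), estimates e^mu."""
    mu, sigma, n = 1.3, 0.7, 1_000_000
    draws = sample(DistributionSpec("c", "lognormal", {"mu": mu, "sigma": sigma}), n, seed=3)
    # SE of the sample median: 1 / (2 f(m) sqrt(n)) with lognormal density at e^mu
    f_med = 1.0 / (np.exp(mu) * sigma * np.sqrt(2 * np.pi))
    se = 1.0 / (2 * f_med * np.sqrt(n))
    assert abs(np.median(draws) - np.exp(mu)) < 3 * se


def test_truncation_bounds_respected():
    d = DistributionSpec("bw", "normal", {"mean": 15.0, "sd": 5.0}, trunc=(10.0, 20.0))
    draws = sample(d, 10_000, seed=1)
    assert draws.min() >= 10.0 and draws.max() <= 20.0


def test_invalid_family_parameters_error():
    with pytest.raises(ValidationError):
        DistributionSpec("x", "normal", {"mean": 0.0, "sd": -1.0})
    with pytest.raises(ValidationError):
        DistributionSpec("x", "triangular", {"low": 2.0, "mode": 1.0, "high": 3.0})
    with pytest.raises(ValidationError):
        DistributionSpec("x", "gamma", {"a": 1.0})


def test_uniform_identity_model_quantiles():
    dists = {"u": DistributionSpec("u", "uniform", {"low": 0.0, "high": 1.0}),
             "v": point("v", 0.0)}
    s = run_simulation(lambda p: p["u"] + p["v"], dists, n=1_000_000, seed=2,
                       thresholds=0.9)
    row = s.table.iloc[0]
    se50 = 0.5 / np.sqrt(1e6)  # 1/(2 f(q) sqrt(n)) with f=1
    assert row["p50"] == pytest.approx(0.5, abs=3 * se50)
    assert row["p_exceed"] == pytest.approx(0.1, abs=3 * np.sqrt(0.1 * 0.9 / 1e6))


def test_sum_model_variance_matches_closed_form():
    dists = {"a": point("a", 2.0),
             "b": DistributionSpec("b", "normal", {"mean": 0.0, "sd": 3.0})}
    s = run_simulation(lambda p: p["a"] + p["b"], dists, n=200_000, seed=4)
    # var of sum = var(b) = 9; SE of sample SD ~ sd/sqrt(2n)
    assert s.table.iloc[0]["sd"] == pytest.approx(3.0, abs=3 * 3 / np.sqrt(2 * 2e5))


def test_degenerate_run_equals_deterministic_hi_and_tcr(profiles, toxicity):
    child = profiles["child"]
    for metal, builder, det_fn in (
        ("Cr", build_hi_model, hi_for),
        ("Cd", build_tcr_model, tcr_for),
    ):
        model, _ = builder(metal, "child")
        pts = {
            "C": point("C", 50.0),
            "IngR": point("IngR", child.ing_r),
            "InhR": point("InhR", child.inh_r),
            "SA": point("SA", child.sa),
            "AF": point("AF", child.af),
            "BW": point("BW", child.bw),
        }
        s = run_simulation(model, pts, n=64, seed=0, thresholds=1.0)
        det = float(det_fn(50.0, child, toxicity[metal]))
        row = s.table.iloc[0]
        for stat in ("p5", "p50", "p95", "mean"):
            assert row[stat] == pytest.approx(det, rel=1e-12)
        assert row["p_exceed"] in (0.0, 1.0)


def test_percentile_monotonicity_and_seed_determinism():
    model, dists = build_hi_model("Pb", "adult")
    a = run_simulation(model, dists, n=5000, seed=11, thresholds=1.0)
    b = run_simulation(model, dists, n=5000, seed=11, thresholds=1.0)
    c = run_simulation(model, dists, n=5000, seed=12)
    pd.testing.assert_frame_equal(a.table, b.table)  # bit-identical
    assert not a.table["p50"].equals(c.table["p50"])
    row = a.table.iloc[0]
    assert row["p5"] <= row["p50"] <= row["p95"]
    assert 0.0 <= row["p_exceed"] <= 1.0


def test_hq_percentiles_scale_linearly_with_concentration():
    model, dists = build_hi_model("Cr", "child")
    base = run_simulation(model, dists, n=20_000, seed=5).table.iloc[0]
    scaled_dists = dict(dists)
    c = dists["C"]
    scaled_dists["C"] = DistributionSpec(
        "C", "normal",
        {"mean": 2 * c.params["mean"], "sd": 2 * c.params["sd"]},
        trunc=(2 * c.trunc[0], 2 * c.trunc[1]),
    )
    scaled = run_simulation(model, scaled_dists, n=20_000, seed=5).table.iloc[0]
    for stat in ("p5", "p50", "p95", "mean"):
        assert scaled[stat] == pytest.approx(2 * base[stat], rel=1e-9)


def test_nonfinite_output_aborts_with_draw_context():
    dists = {"u": DistributionSpec("u", "uniform", {"low": 0.0, "high": 1.0}),
             "w": point("w", 1.0)}

    def bad(p):
        y = p["u"].copy()
        y[7] = np.nan
        return y

    with pytest.raises(ValidationError, match="draw 7"):
        run_simulation(bad, dists, n=50, seed=0)


def test_convergence_point_mass_all_zero():
    model, dists = build_hi_model("Cr", "child")
    pts = {k: point(k, d.mean()) for k, d in dists.items()}
    cc = convergence_check(model, pts, seed=0)
    assert (cc.table["rel_diff"] == 0).all() and cc.passed


def test_convergence_flags_heavy_tail_at_tiny_n():
    heavy = {
        "x": DistributionSpec("x", "lognormal", {"mu": 0.0, "sigma": 2.5}),
        "y": DistributionSpec("y", "lognormal", {"mu": 0.0, "sigma": 2.5}),
    }
    cc = convergence_check(lambda p: p["x"] * p["y"], heavy, ns=(10, 25, 50), seed=1)
    assert cc.table["flag"].any() and not cc.passed
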