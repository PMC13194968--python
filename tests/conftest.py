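import numpy as np
import pandas as pd
import pytest

from soilrisk.samples import METALS, SampleTable, load_study_fixture
from soilrisk.risk import default_profiles, default_toxicity


@pytest.fixture(scope="session")
def study():
    """(SummaryStats, ASV, UCC) packaged study fixture."""
    return load_study_fixture()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def toxicity():
    return default_toxicity()


@pytest.fixture
def small_table():
    """A tiny hand-built two-sample table covering all eight metals."""
    rng = np.random.default_rng(42)
    data = {"sample_id": ["A", "B", "C", "D", "E"]}
    for metal in METALS:
        data[metal] = rng.lognormal(mean=3.0, sigma=0.5, size=5)
    return SampleTable(pd.DataFrame(data))


def ward_bruteforce(X):
    """Greedy Ward agglomeration minimizing the ESS increase at each merge.

    Independent O(n^3) oracle: clusters are merged by globally scanning all
    pairs for the smallest within-cluster variance increase
    dESS = |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2; the reported merge
    height is sqrt(2 * dESS), the Ward distance convention used by standard
    linkage encodings.  Returns the sequence of merge heights.
    """
    X = np.asarray(X, dtype=float)
    clusters = [(1, X[i].copy()) for i in range(X.shape[0])]  # (size, centroid)
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                na, ca = clusters[i]
                nb, cb = clusters[j]
                d_ess = na * nb / (na + nb) * float(np.sum((ca - cb) ** 2))
                if best is None or d_ess < best[0]:
                    best = (d_ess, i, j)
        d_ess, i, j = best
        na, ca = clusters[i]
        nb, cb = clusters[j]
        merged = (na + nb, (na * ca + nb * cb) / (na + nb))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        heights.append(np.sqrt(2.0 * d_ess))
    return np.asarray(heights)


@pytest.fixture(scope="session")
def ward_oracle():
    return ward_bruteforce


@pytest.fixture(scope="session")
def ishigami_problem():
    """(model, marginals, closed-form S1) for the Ishigami benchmark (a=7, b=0.1)."""
    from soilrisk.mc import DistributionSpec

    a, b = 7.0, 0.1

    def fn(p):
        return (
            np.sin(p["x1"]) + a * np.sin(p["x2"]) ** 2
            + b * p["x3"] ** 4 * np.sin(p["x1"])
        )

    dists = {
        n: DistributionSpec(n, "uniform", {"low": -np.pi, "high": np.pi})
        for n in ("x1", "x2", "x3")
    }
    pi = np.pi
    v1 = 0.5 * (1 + b * pi**4 / 5) ** 2
    v2 = a**2 / 8
    v13 = 8 * b**2 * pi**8 / 225
    v = v1 + v2 + v13
    s1_true = np.array([v1 / v, v2 / v, 0.0])
    return fn, dists, s1_true
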