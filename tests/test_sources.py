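import numpy as np
import pandas as pd
import pytest

from soilrisk.samples import METALS, SampleTable, ValidationError
from soilrisk.sources import (
    Dendrogram,
    interpret_loadings,
    pca_varimax,
    ward_cluster,
    zscore,
)
from soilrisk.synth import default_site_spec, generate_site


@pytest.fixture
def site():
    return generate_site(default_site_spec(rng_seed=13))


def test_zscore_contract_and_idempotence(site):
    z = zscore(site)
    assert np.allclose(z.mean(), 0.0, atol=1e-12)
    assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)
    pd.testing.assert_frame_equal(zscore(z), z, atol=1e-10)


def test_zscore_two_sample_forced_values():
    df = pd.DataFrame({"sample_id": ["a", "b"], **{m: [1.0, 2.0] for m in METALS}})
    z = zscore(SampleTable(df))
    assert np.allclose(z.iloc[0], -np.sqrt(0.5)) and np.allclose(z.iloc[1], np.sqrt(0.5))


def test_zscore_constant_column_errors():
    df = pd.DataFrame({"sample_id": list("abc"), **{m: [1.0, 1.0, 1.0] for m in METALS}})
    with pytest.raises(ValidationError, match="constant"):
        zscore(SampleTable(df))


def test_identical_profiles_merge_first_at_height_zero():
    X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [10.0, -4.0, 2.0], [0.0, 8.0, 1.0]])
    dend = ward_cluster(X, labels=("a", "a2", "b", "c"))
    assert dend.heights[0] == pytest.approx(0.0, abs=1e-12)
    assert dend.cut(3)["a"] == dend.cut(3)["a2"]


def test_two_correlated_pairs_recovered_at_k2():
    rng = np.random.default_rng(3)
    base1, base2 = rng.normal(size=40), rng.normal(size=40)
    df = pd.DataFrame(
        {
            "sample_id": [str(i) for i in range(40)],
            "As": np.exp(base1), "Fe": np.exp(base1 + rng.normal(0, 0.05, 40)),
            "Cd": np.exp(base2), "Pb": np.exp(base2 + rng.normal(0, 0.05, 40)),
        }
    )
    table = SampleTable(df, metals=("As", "Fe", "Cd", "Pb"))
    dend = ward_cluster(table, on="metals")
    cut = dend.cut(2)
    assert cut["As"] == cut["Fe"] and cut["Cd"] == cut["Pb"]
    assert cut["As"] != cut["Cd"]


def test_merge_heights_match_bruteforce_on_five_leaves(ward_oracle):
    rng = np.random.default_rng(17)
    X = rng.normal(size=(5, 3))
    dend = ward_cluster(X)
    assert np.allclose(dend.heights, ward_oracle(X), rtol=1e-10)


def test_merge_heights_nondecreasing(site):
    dend = ward_cluster(site, on="metals")
    assert (np.diff(dend.heights) >= -1e-12).all()
    assert set(dend.labels) == set(METALS)


def test_newick_output_parses_and_has_all_leaves(site):
    import io

    from Bio import Phylo

    nwk = ward_cluster(site, on="metals").to_newick()
    tree = Phylo.read(io.StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(METALS)


def test_pca_eigenvalue_trace_and_communalities(site):
    res = pca_varimax(site)
    assert res.eigenvalues.sum() == pytest.approx(len(site.metals), rel=1e-10)
    unrot = pca_varimax(site, rotate=False, n_components=res.retained)
    assert np.allclose(
        res.communalities.sort_index(), unrot.communalities.sort_index(), atol=1e-10
    )


def test_pca_full_reconstruction_of_correlation_matrix(site):
    res = pca_varimax(site, rotate=False, n_components=len(site.metals))
    L = res.loadings.to_numpy()
    corr = np.corrcoef(zscore(site).to_numpy(), rowvar=False)
    assert np.allclose(L @ L.T, corr, atol=1e-10)


def test_unrotated_loading_columns_orthogonal(site):
    res = pca_varimax(site, rotate=False, n_components=3)
    L = res.loadings.to_numpy()
    g = L.T @ L
    assert np.allclose(g - np.diag(np.diag(g)), 0.0, atol=1e-10)


def test_known_eigenstructure_two_blocks():
    """A correlated pair plus an independent pair: two Kaiser components,
    the first loading the correlated pair strongly."""
    rng = np.random.default_rng(5)
    n = 200
    shared = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "sample_id": [str(i) for i in range(n)],
            "As": np.exp(shared + rng.normal(0, 0.1, n)),
            "Fe": np.exp(shared + rng.normal(0, 0.1, n)),
            "Cd": np.exp(rng.normal(size=n)),
            "Pb": np.exp(rng.normal(size=n)),
        }
    )
    table = SampleTable(df, metals=("As", "Fe", "Cd", "Pb"))
    res = pca_varimax(table)
    lead = res.loadings["PC1"]
    assert res.retained >= 2
    assert lead["As"] > 0.8 and lead["Fe"] > 0.8
    assert abs(lead["Cd"]) < 0.4 and abs(lead["Pb"]) < 0.4


def test_loading_interpretation_thresholds(site):
    res = pca_varimax(site)
    labels = interpret_loadings(res)
    L = res.loadings
    for metal in L.index:
        for pc in L.columns:
            a = abs(L.loc[metal, pc])
            expected = "strong" if a > 0.5 else ("moderate" if a >= 0.3 else "weak")
            assert labels.loc[metal, pc] == expected


def test_suggest_k_on_clean_two_cluster_geometry():
    X = np.vstack([np.zeros((3, 2)) + [[0, 0], [0.1, 0], [0, 0.1]],
                   np.ones((3, 2)) * 10 + [[0, 0], [0.1, 0], [0, 0.1]]])
    dend = ward_cluster(X)
    assert dend.suggest_k() == 2
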