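import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilrisk.indices import (
    classify,
    contamination_factor,
    enrichment_factor,
    geoaccumulation_index,
    index_report,
    load_class_schemes,
    pollution_load_index,
)
from soilrisk.samples import METALS, SampleTable, ValidationError, load_background
from soilrisk.synth import moment_match
import pandas as pd

conc = st.floats(0.01, 1e5, allow_nan=False)


def test_enrichment_factor_hand_arithmetic():
    assert enrichment_factor(10, 20_000, 0.3, 47_200) == pytest.approx(78.67, abs=0.01)
    assert enrichment_factor(40, 20_000, 20, 47_200) == pytest.approx(4.72, abs=0.01)
    assert enrichment_factor(5, 10, 50, 100) == pytest.approx(1.0)


def test_geoaccumulation_hand_values():
    assert geoaccumulation_index(1.5 * 7.0, 7.0) == pytest.approx(0.0)
    assert geoaccumulation_index(12.0, 0.3) == pytest.approx(4.74, abs=0.005)
    assert geoaccumulation_index(5.1, 13.0) == pytest.approx(-1.93, abs=0.005)


def test_contamination_factor_and_pli():
    assert contamination_factor(5.27, 0.3) == pytest.approx(17.57, abs=0.01)
    assert contamination_factor(49, 20) == pytest.approx(2.45)
    assert pollution_load_index([2, 8]) == pytest.approx(4.0)
    assert pollution_load_index([1, 1, 1, 16]) == pytest.approx(2.0)
    assert pollution_load_index([1] * 8) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        pollution_load_index([])
    with pytest.raises(ValidationError):
        pollution_load_index([1.0, -2.0])


def test_non_positive_inputs_rejected():
    for fn, args in [
        (enrichment_factor, (0, 1, 1, 1)),
        (geoaccumulation_index, (1, 0)),
        (contamination_factor, (-1, 1)),
    ]:
        with pytest.raises(ValidationError):
            fn(*args)


def test_classification_schemes_and_tie_rule():
    schemes = load_class_schemes()
    assert classify(-0.5, schemes["igeo"]) == "uncontaminated"
    # boundary values belong to the upper class
    assert classify(0.0, schemes["igeo"]) == "uncontaminated to moderately contaminated"
    assert classify(1.95, schemes["pli"]) == "moderately polluted"
    assert classify(1.0, schemes["hi"]) == "adverse non-carcinogenic risk"
    assert classify(2e-4, schemes["tcr"]) == "unacceptable carcinogenic risk"
    assert classify(5e-7, schemes["tcr"]) == "insignificant risk"


@settings(max_examples=50, derandomize=True)
@given(c=conc, b=conc)
def test_igeo_cf_cross_identity(c, b):
    """Igeo = log2(CF / 1.5) for any positive concentration/background pair."""
    assert geoaccumulation_index(c, b) == pytest.approx(
        np.log2(contamination_factor(c, b) / 1.5), rel=1e-10, abs=1e-10
    )


@settings(max_examples=50, derandomize=True)
@given(cfs=st.lists(st.floats(0.01, 100), min_size=1, max_size=8), k=st.floats(0.1, 10))
def test_pli_scale_covariance(cfs, k):
    """Multiplying every CF by k multiplies the PLI by k."""
    assert pollution_load_index([k * c for c in cfs]) == pytest.approx(
        k * pollution_load_index(cfs), rel=1e-9
    )


@settings(max_examples=30, derandomize=True)
@given(c=conc, b=conc, k=st.floats(0.1, 10))
def test_cf_linearity(c, b, k):
    assert contamination_factor(k * c, b) == pytest.approx(
        k * contamination_factor(c, b), rel=1e-12
    )


def test_index_report_single_sample_at_15x_background():
    bg = load_background("ASV")
    df = pd.DataFrame({"sample_id": ["only"], **{m: [1.5 * bg[m]] for m in METALS}})
    rep = index_report(SampleTable(df), bg)
    assert np.allclose(rep.per_sample["igeo"], 0.0, atol=1e-12)
    assert np.allclose(rep.per_sample["ef"], 1.5 / 1.5, atol=1e-12)
    assert rep.pli["pli"].iloc[0] == pytest.approx(1.5, rel=1e-12)


def test_report_mean_cf_equals_cf_of_mean(study):
    """Linearity: mean of per-sample CF equals mean concentration / background."""
    stats, asv, _ = study
    table = moment_match(stats, n=20, seed=4)
    rep = index_report(table, asv)
    for metal in METALS:
        expected = stats.stat(metal, "mean") / asv[metal]
        assert rep.summary.loc[metal, "cf_mean"] == pytest.approx(expected, rel=1e-9)


def test_reference_element_ef_is_unity(study):
    stats, asv, _ = study
    rep = index_report(moment_match(stats, n=20, seed=4), asv)
    fe = rep.per_sample[rep.per_sample["metal"] == "Fe"]
    assert np.allclose(fe["ef"], 1.0, atol=1e-12)


def test_pli_recomputable_from_cfs(study):
    stats, asv, _ = study
    table = moment_match(stats, n=20, seed=8)
    rep = index_report(table, asv)
    wide = rep.per_sample.pivot(index="sample_id", columns="metal", values="cf")
    recomputed = np.exp(np.log(wide).mean(axis=1))
    merged = rep.pli.set_index("sample_id")["pli"]
    assert np.allclose(recomputed.loc[merged.index], merged, rtol=1e-12)


def test_missing_background_metal_errors(small_table):
    from soilrisk.samples import BackgroundSet

    partial = BackgroundSet("partial", {"As": 13.0, "Fe": 47_200.0})
    with pytest.raises(ValidationError, match="lacks"):
        index_report(small_table, partial)
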