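import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as hs

from ecostoich import stoichiometry as st

ASIS = dict(
    beta_glucosidase=0.358, cellulase=0.146, xylanase=0.391, dehydrogenase=2.35e-3,
    urease=10.775, protease=0.217, acid_phosphatase=27.415,
    alkaline_phosphatase=40.645, arylsulphatase=1.764,
)
H400F = dict(
    beta_glucosidase=0.550, cellulase=0.086, xylanase=0.428, dehydrogenase=7.06e-3,
    urease=7.191, protease=0.237, acid_phosphatase=29.308,
    alkaline_phosphatase=44.405, arylsulphatase=2.354,
)
ZERO = {k: 0.0 for k in st.ENZYME_COLUMNS}

activity = hs.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def record(activities, sample_id="s1", group="g"):
    return st.EnzymeActivityRecord(sample_id=sample_id, group=group, **activities)


@pytest.mark.parametrize("activities, expected", [
    (ASIS, (0.893, 10.992, 27.415)),
    (H400F, (1.057, 7.428, 29.308)),
    (ZERO, (0.0, 0.0, 0.0)),
])
def test_pools_from_group_mean_activities(activities, expected):
    s = st.aggregate_eea(record(activities))
    assert (round(s.CE, 3), round(s.NE, 3), round(s.PE, 3)) == expected


def test_missing_activity_names_the_field():
    bad = dict(ASIS)
    bad["urease"] = math.nan
    with pytest.raises(st.ValidationError, match="urease"):
        record(bad)


def test_negative_activity_rejected():
    bad = dict(ASIS, cellulase=-0.1)
    with pytest.raises(st.ValidationError, match="cellulase"):
        record(bad)


@pytest.mark.parametrize("pools, expected", [
    ((0.893, 10.992, 27.415), (0.0326, 0.0812, 0.4009)),
    ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
    ((1.057, 7.428, 29.308), (0.0361, 0.1423, 0.2534)),
])
def test_stoichiometric_ratios(pools, expected):
    ce_pe, ce_ne, ne_pe = st.stoichiometric_ratios(*pools)
    assert (round(ce_pe, 4), round(ce_ne, 4), round(ne_pe, 4)) == expected


def test_zero_denominator_flags_ratio_not_raises():
    ce_pe, ce_ne, ne_pe = st.stoichiometric_ratios(1.0, 0.0, 0.0)
    assert math.isnan(ce_pe) and math.isnan(ce_ne) and math.isnan(ne_pe)


@pytest.mark.parametrize("pools, expected", [
    ((0.893, 10.992, 27.415), (0.031546, 0.075137)),
    ((1.0, 0.0, 0.0), (1.0, 1.0)),
    ((1.0, 1.0, 1.0), (0.5, 0.5)),
])
def test_vector_components(pools, expected):
    x, y = st.vector_components(*pools)
    assert x == pytest.approx(expected[0], abs=5e-6)
    assert y == pytest.approx(expected[1], abs=5e-6)


@pytest.mark.parametrize("xy, expected_vl, expected_va", [
    ((0.031546, 0.075137), 0.0815, 67.23),   # published angle 67.231
    ((0.1, 0.1), 0.14142, 45.0),
    ((0.03481, 0.12459), None, 74.39),       # pools of the H400f means
])
def test_vector_length_angle(xy, expected_vl, expected_va):
    vl, va = st.vector_length_angle(*xy)
    if expected_vl is not None:
        assert vl == pytest.approx(expected_vl, abs=5e-4)
    assert va == pytest.approx(expected_va, abs=0.05)


def test_zero_vector_undefined():
    vl, va = st.vector_length_angle(0.0, 0.0)
    assert math.isnan(vl) and math.isnan(va)


@pytest.mark.parametrize("vl, va, call, strength", [
    (0.118, 72.12, "P_limited", "weak"),
    (1.2, 40.0, "N_limited", "strong"),
    (0.5, 45.0, "balanced", "strong"),
])
def test_classify_limitation(vl, va, call, strength):
    assert st.classify_limitation(vl, va) == (call, strength)


def test_undefined_vector_gives_undefined_call():
    assert st.classify_limitation(math.nan, math.nan) == ("undefined", "undefined")


@pytest.mark.parametrize("alk, acid, ratio, flag", [
    (42.207, 32.196, 1.311, "no correction needed"),
    (3.0, 3.0, 1.0, "no correction needed"),
    (0.2, 1.0, 0.2, "liming indicated"),
])
def test_alk_acid_phosphatase_index(alk, acid, ratio, flag):
    r, f = st.alk_acid_phosphatase_index(alk, acid)
    assert round(r, 3) == ratio and f == flag


def test_negative_ce_kept_but_vector_undefined():
    s = st.summarize_record(record(dict(ZERO, dehydrogenase=5.0, urease=1.0,
                                        acid_phosphatase=1.0, alkaline_phosphatase=1.0)))
    assert s.CE == -5.0
    assert math.isnan(s.x_component) and math.isnan(s.vector_angle)
    assert s.limitation_call == "undefined"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(ce=activity, ne=activity, pe=activity)
def test_angle_in_quadrant_and_p_vs_n_rule(ce, ne, pe):
    """VA lies in (0, 90) and exceeds 45 deg exactly when PE > NE."""
    assume(abs(pe - ne) > 1e-6 * max(pe, ne))
    x, y = st.vector_components(ce, ne, pe)
    _, va = st.vector_length_angle(x, y)
    assert 0.0 < va < 90.0
    assert (va > 45.0) == (pe > ne)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(ce=activity, ne=activity, pe=activity)
def test_swapping_n_and_p_reflects_the_vector(ce, ne, pe):
    """Exchanging NE and PE preserves VL and maps VA to 90 - VA."""
    vl1, va1 = st.vector_length_angle(*st.vector_components(ce, ne, pe))
    vl2, va2 = st.vector_length_angle(*st.vector_components(ce, pe, ne))
    # components swap, so the point reflects about the diagonal
    assert vl1 == pytest.approx(vl2, rel=1e-9)
    assert va1 == pytest.approx(90.0 - va2, abs=1e-7)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(scale=hs.floats(min_value=1e-3, max_value=1e3),
       ne=activity, pe=activity)
def test_pool_linearity_and_vector_scale_invariance(scale, ne, pe):
    """Scaling all activities scales the pools and leaves the vector fixed."""
    base = dict(ZERO, beta_glucosidase=0.4, cellulase=0.2, xylanase=0.3,
                dehydrogenase=0.05, urease=ne, protease=0.0, acid_phosphatase=pe)
    scaled = {k: v * scale for k, v in base.items()}
    s1 = st.summarize_record(record(base))
    s2 = st.summarize_record(record(scaled))
    for pool in ("CE", "NE", "PE"):
        assert getattr(s2, pool) == pytest.approx(getattr(s1, pool) * scale, rel=1e-9)
    assert s2.x_component == pytest.approx(s1.x_component, rel=1e-9)
    assert s2.y_component == pytest.approx(s1.y_component, rel=1e-9)
    assert s2.vector_angle == pytest.approx(s1.vector_angle, abs=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(ce=activity, ne=activity, pe=activity)
def test_pool_round_trip(ce, ne, pe):
    """A record built to match given pools reproduces them exactly."""
    rec = record(dict(ZERO, beta_glucosidase=ce, urease=ne, acid_phosphatase=pe))
    s = st.aggregate_eea(rec)
    assert (s.CE, s.NE, s.PE) == (ce, ne, pe)


def test_group_modes_agree_on_identical_replicates():
    frame = pd.DataFrame([dict(ASIS, sample_id=f"r{i}", group="g") for i in range(5)])
    of_means = st.summarize_group(frame, mode="of_means")[0]
    per_rep = st.summarize_group(frame, mode="per_replicate")[0]
    for attr in ("CE", "NE", "PE", "ratio_CE_NE", "vector_length", "vector_angle"):
        assert getattr(of_means.mean, attr) == pytest.approx(getattr(per_rep.mean, attr), rel=1e-9)


def test_group_modes_differ_by_jensen_gap():
    # two replicates with CE/NE of 0.1 and 0.2
    rows = [dict(ZERO, beta_glucosidase=1.0, urease=10.0, acid_phosphatase=1.0,
                 sample_id="r1", group="g"),
            dict(ZERO, beta_glucosidase=2.0, urease=10.0, acid_phosphatase=1.0,
                 sample_id="r2", group="g")]
    frame = pd.DataFrame(rows)
    per_rep = st.summarize_group(frame, mode="per_replicate")[0]
    of_means = st.summarize_group(frame, mode="of_means")[0]
    assert per_rep.mean.ratio_CE_NE == pytest.approx(0.15, rel=1e-9)
    assert of_means.mean.ratio_CE_NE == pytest.approx(1.5 / 10.0, rel=1e-9)


def test_of_means_on_noise_free_design_reproduces_published_pools(cv0_bundle):
    groups = {g.group: g.mean for g in st.summarize_group(cv0_bundle.enzymes, mode="of_means")}
    assert round(groups["A. sisalana"].CE, 3) == 0.893
    assert round(groups["H11648"].CE, 3) == 1.334
    assert round(groups["H400f"].CE, 3) == 1.057


def test_empty_group_raises():
    with pytest.raises(st.ValidationError):
        st.summarize_group(pd.DataFrame(columns=["sample_id", "group", *st.ENZYME_COLUMNS]))
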