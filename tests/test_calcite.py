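import pytest
from hypothesis import given, settings, strategies as st

from coccotraits.calcite import (
    CALCITE_DENSITY,
    appendage_calcite,
    back_calculate_ks,
    cellular_pic,
    coccolith_pic,
    dimorphic_pic,
    exothecal_calcite,
    holococcolith_cn_estimate,
    total_cell_calcite,
    umbellosphaera_average_cl,
)
from coccotraits.errors import (
    ConfigurationError,
    DomainError,
    IncompleteRecordError,
    RuleNotApplicableError,
)
from coccotraits.pipeline import CoccosphereRecord
from coccotraits.registry import LifeCyclePhase, TaxonKey, TaxonParams

lengths = st.floats(min_value=0.3, max_value=20.0, allow_nan=False)
ks_values = st.floats(min_value=0.005, max_value=0.2, allow_nan=False)


# ----------------------------------------------------------------------
# cube law and inverse
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "c_l, ks, expected",
    [
        (1.8, 0.03, 0.472392),  # one Ophiaster osteolith, reported as 0.47
        (5.0, 0.007, 2.3625),
        (1.0, 0.5, 1.35),
    ],
)
def test_coccolith_pic_cube_law(c_l, ks, expected):
    assert coccolith_pic(c_l, ks) == pytest.approx(expected, rel=1e-9)


def test_coccolith_pic_domain():
    with pytest.raises(DomainError):
        coccolith_pic(0.0, 0.03)
    with pytest.raises(DomainError):
        coccolith_pic(2.0, -0.1)


def test_back_calculate_ks_calciosolenia():
    ks = back_calculate_ks(2.5, 5.0)
    assert ks == pytest.approx(2.5 / (125 * 2.7), rel=1e-12)
    assert float(f"{ks:.1g}") == 0.007  # one significant figure


def test_back_calculate_ks_unit_cube():
    assert back_calculate_ks(2.7, 1.0) == pytest.approx(1.0, rel=1e-12)


@settings(derandomize=True, max_examples=100)
@given(c_l=lengths, ks=ks_values)
def test_back_calculation_inverts_cube_law(c_l, ks):
    assert back_calculate_ks(coccolith_pic(c_l, ks), c_l) == pytest.approx(
        ks, rel=1e-12
    )


def test_cellular_pic():
    assert cellular_pic(0.472392, 14) == pytest.approx(6.613488)  # one arm, ~6.6
    assert cellular_pic(1.234, 1) == pytest.approx(1.234)
    assert cellular_pic(2.3625, 20) == pytest.approx(47.25)
    with pytest.raises(DomainError):
        cellular_pic(1.0, 0)


# ----------------------------------------------------------------------
# taxon-specific corrections
# ----------------------------------------------------------------------

def _michaelsarsia_params():
    return TaxonParams(
        ks_body=0.02, y_fraction=0.75,
        appendage_pg_per_appendage=12.5, appendage_default_count=8,
    )


def _ophiaster_params():
    return TaxonParams(ks_body=0.015, y_fraction=0.75, appendage_fixed_total_pg=33.0)


def test_appendage_calcite_michaelsarsia():
    params = _michaelsarsia_params()
    assert appendage_calcite(params, None) == pytest.approx(100.0)  # 8 assumed
    assert appendage_calcite(params, 10) == pytest.approx(125.0)


def test_appendage_calcite_ophiaster():
    params = _ophiaster_params()
    assert appendage_calcite(params, present=True) == pytest.approx(33.0)
    assert appendage_calcite(params, present=False) == pytest.approx(0.0)


def test_appendage_rule_not_applicable():
    plain = TaxonParams(ks_body=0.02, y_fraction=0.75)
    with pytest.raises(RuleNotApplicableError):
        appendage_calcite(plain, 4)


def _rhabdosphaera_params(**overrides):
    kwargs = dict(
        ks_body=0.025, ks_spinose=0.012, y_fraction=0.6,
        dimorphic_spinose_fraction=0.5, fixed_spine_length=5.0,
    )
    kwargs.update(overrides)
    return TaxonParams(**kwargs)


def test_dimorphic_split_with_spine_fallback():
    params = _rhabdosphaera_params()
    result = dimorphic_pic(2.0, None, 20, params)
    body_each = 0.025 * 8 * 2.7  # 0.54 pg per non-spinose coccolith
    spin_each = coccolith_pic(5.0, 0.012)  # fixed 5 µm fallback
    assert result.body_coccolith_pic == pytest.approx(body_each)
    assert result.body_total == pytest.approx(10 * body_each + 10 * spin_each)
    assert "fixed_spine_length_used" in result.flags


def test_dimorphic_fraction_zero_reduces_to_monomorphic():
    params = _rhabdosphaera_params(dimorphic_spinose_fraction=0.0)
    result = dimorphic_pic(2.0, None, 20, params)
    assert result.body_total == pytest.approx(cellular_pic(coccolith_pic(2.0, 0.025), 20))


def test_dimorphic_fractional_counts_not_rounded():
    params = _rhabdosphaera_params()
    result = dimorphic_pic(2.0, 4.0, 21, params)  # odd count → 10.5 each
    expected = 10.5 * coccolith_pic(2.0, 0.025) + 10.5 * coccolith_pic(4.0, 0.012)
    assert result.body_total == pytest.approx(expected, rel=1e-12)


def test_dimorphic_requires_count_and_spinose_ks():
    params = _rhabdosphaera_params()
    with pytest.raises(DomainError):
        dimorphic_pic(2.0, 4.0, 0, params)
    with pytest.raises(ConfigurationError):
        dimorphic_pic(2.0, 4.0, 20, _rhabdosphaera_params(ks_spinose=None))


@pytest.mark.parametrize(
    "n, c_l, expected",
    [(0, 2.0, 0.0), (10, 2.0, 4.32), (1, 1.0, 0.054)],
)
def test_exothecal_calcite(n, c_l, expected):
    assert exothecal_calcite(n, c_l, 0.02) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize(
    "esd, c_l, c_w, expected",
    [(8.0, 2.0, 1.5, 85), (3.0, 3.0, 3.0, 4), (4.0, 1.0, 1.0, 64)],
)
def test_holococcolith_count_back_calculation(esd, c_l, c_w, expected):
    assert holococcolith_cn_estimate(esd, c_l, c_w) == expected


def test_holococcolith_count_degenerate():
    with pytest.raises(DomainError):
        holococcolith_cn_estimate(0.3, 1.0, 1.0)  # coccolith larger than sphere


def test_umbellosphaera_average_cl_cubic_mean():
    avg, ratio = umbellosphaera_average_cl([2.0, 4.0], ks=0.03)
    assert avg == pytest.approx(36.0 ** (1 / 3), rel=1e-9)  # 3.3019
    assert ratio == pytest.approx(36.0 ** (1 / 3) / 4.0, rel=1e-9)  # 0.8255
    avg, ratio = umbellosphaera_average_cl([1.0, 1.0, 5.0], ks=0.03)
    assert avg == pytest.approx((127.0 / 3) ** (1 / 3), rel=1e-4)  # 3.486
    assert ratio == pytest.approx(0.697, abs=5e-4)


def test_umbellosphaera_average_cl_equal_lengths():
    avg, ratio = umbellosphaera_average_cl([3.3, 3.3, 3.3], ks=0.05)
    assert avg == pytest.approx(3.3, rel=1e-12)
    assert ratio == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(DomainError):
        umbellosphaera_average_cl([], ks=0.05)


@settings(derandomize=True, max_examples=100)
@given(st.lists(lengths, min_size=1, max_size=12))
def test_cubic_mean_dominates_arithmetic_mean(values):
    avg, ratio = umbellosphaera_average_cl(values, ks=0.03)
    assert ratio <= 1.0 + 1e-12
    assert avg >= sum(values) / len(values) - 1e-9  # power-mean inequality
    if max(values) - min(values) > 1e-9:
        assert ratio < 1.0


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def _record(genus="Gephyrocapsa", family="Noelaerhabdaceae", **overrides):
    kwargs = dict(
        record_id="r1",
        taxon=TaxonKey(family, genus),
        coccosphere_long_axis=8.0,
        coccosphere_short_axis=7.0,
        total_coccolith_count=20,
        coccolith_length=3.0,
    )
    kwargs.update(overrides)
    return CoccosphereRecord(**kwargs)


def test_plain_record_reduces_to_cube_law_times_count():
    params = TaxonParams(ks_body=0.02, y_fraction=0.65)
    result = total_cell_calcite(_record(), params)
    assert result.cellular_pic == pytest.approx(
        cellular_pic(coccolith_pic(3.0, 0.02), 20), rel=1e-12
    )
    assert result.exothecal_total == 0.0 and result.appendage_total == 0.0


def test_florisphaera_fixed_count_path():
    params = TaxonParams(ks_body=0.03, y_fraction=0.10, fixed_cn=145)
    record = _record(
        genus="Florisphaera", family="", coccolith_length=2.0,
        total_coccolith_count=None,
        taxon=TaxonKey("", "Florisphaera", "profunda",
                       life_cycle_phase=LifeCyclePhase.NANNOLITH),
    )
    result = total_cell_calcite(record, params)
    assert result.cellular_pic == pytest.approx(0.03 * 8 * 2.7 * 145)  # 93.96
    assert "fixed_cn_used" in result.flags


def test_michaelsarsia_adds_appendage_mass():
    params = _michaelsarsia_params()
    record = _record(genus="Michaelsarsia", n_appendages=8)
    body = cellular_pic(coccolith_pic(3.0, 0.02), 20)
    result = total_cell_calcite(record, params)
    assert result.cellular_pic == pytest.approx(body + 100.0, rel=1e-12)


def test_missing_measurement_raises_incomplete():
    params = TaxonParams(ks_body=0.02, y_fraction=0.65)
    with pytest.raises(IncompleteRecordError):
        total_cell_calcite(_record(coccolith_length=None), params)
    with pytest.raises(IncompleteRecordError):
        total_cell_calcite(_record(total_coccolith_count=None), params)


def test_breakdown_components_sum_exactly():
    params = TaxonParams(
        ks_body=0.03, y_fraction=0.65,
        appendage_pg_per_appendage=12.5, appendage_default_count=8,
    )
    record = _record(genus="Michaelsarsia", n_exothecal=5, n_appendages=9)
    result = total_cell_calcite(record, params)
    assert result.cellular_pic == (
        result.body_total + result.cfc_total + result.exothecal_total
        + result.appendage_total
    )


def _enumerate_oracle(record, params):
    """Independent per-coccolith enumeration of the cellular calcite."""
    total = 0.0
    c_l = record.coccolith_length
    c_n = record.total_coccolith_count + record.loose_adjacent_count
    f = params.dimorphic_spinose_fraction or 0.0
    spine = record.process_height or params.fixed_spine_length
    for _ in range(int(c_n)):
        total += (1 - f) * params.ks_body * c_l**3 * CALCITE_DENSITY
        if f:
            total += f * params.ks_spinose * spine**3 * CALCITE_DENSITY
    for _ in range(record.n_exothecal):
        total += params.ks_exothecal * c_l**3 * CALCITE_DENSITY
    if params.appendage_pg_per_appendage is not None:
        n = record.n_appendages
        if n is None:
            n = params.appendage_default_count
        total += params.appendage_pg_per_appendage * n
    elif params.appendage_fixed_total_pg is not None and record.appendages_present:
        total += params.appendage_fixed_total_pg
    return total


@settings(derandomize=True, max_examples=60)
@given(
    c_l=lengths,
    c_n=st.integers(min_value=4, max_value=60),
    n_xc=st.integers(min_value=0, max_value=12),
    ks=ks_values,
    dimorphic=st.booleans(),
    appendages=st.sampled_from(["none", "per_item", "fixed_total"]),
)
def test_total_against_per_coccolith_enumeration(
    c_l, c_n, n_xc, ks, dimorphic, appendages
):
    kwargs = dict(ks_body=ks, y_fraction=0.7)
    if dimorphic:
        kwargs.update(
            dimorphic_spinose_fraction=0.5, ks_spinose=0.012, fixed_spine_length=5.0
        )
    if appendages == "per_item":
        kwargs.update(appendage_pg_per_appendage=12.5, appendage_default_count=8)
    elif appendages == "fixed_total":
        kwargs.update(appendage_fixed_total_pg=33.0)
    params = TaxonParams(**kwargs)
    record = _record(
        coccolith_length=c_l,
        total_coccolith_count=c_n,
        n_exothecal=n_xc,
        process_height=4.0 if dimorphic else None,
        appendages_present=True if appendages == "fixed_total" else None,
        n_appendages=6 if appendages == "per_item" else None,
    )
    result = total_cell_calcite(record, params)
    assert result.cellular_pic == pytest.approx(
        _enumerate_oracle(record, params), rel=1e-9
    )


@settings(derandomize=True, max_examples=40)
@given(c_l=lengths, k=st.floats(min_value=0.5, max_value=2.0))
def test_calcite_scales_cubically_with_length(c_l, k):
    params = TaxonParams(ks_body=0.03, y_fraction=0.65)
    base = total_cell_calcite(_record(coccolith_length=c_l), params)
    scaled = total_cell_calcite(_record(coccolith_length=k * c_l), params)
    assert scaled.cellular_pic == pytest.approx(
        k**3 * base.cellular_pic, rel=1e-9
    )


def test_fixed_appendage_mass_invariant_under_length_scaling():
    params = _michaelsarsia_params()
    small = total_cell_calcite(
        _record(genus="Michaelsarsia", coccolith_length=2.0, n_appendages=8), params
    )
    large = total_cell_calcite(
        _record(genus="Michaelsarsia", coccolith_length=4.0, n_appendages=8), params
    )
    assert small.appendage_total == large.appendage_total == pytest.approx(100.0)
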