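"""Coarse-grained w weights, type II / type 0 partition and P_SCE."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidsce import (
    LipidClass,
    MissingParameterError,
    PsceParams,
    WModel,
    calibrate_w,
    classify,
    compute_w,
    generate_calibration_populations,
    parse_species,
    psce,
    w_model_grid,
)
from lipidsce.curvature import UndefinedCompositionError


def _params(heads, incr, pivot="PE 34:1", included=None, mode="inverse_weight"):
    return PsceParams(
        WModel({LipidClass(k): v for k, v in heads.items()}, incr),
        parse_species(pivot),
        frozenset(included or [LipidClass(k) for k in heads]),
        denominator_mode=mode,
    )


# -- w ----------------------------------------------------------------------

def test_w_pivot_self_consistency(psce_params):
    pe341 = parse_species("PE 34:1")
    heads = psce_params.w_model.head_terms
    expected = heads[LipidClass.PE] + psce_params.w_model.unsat_increment
    assert compute_w(pe341, psce_params) == pytest.approx(expected)
    assert psce_params.pivot_w == pytest.approx(expected)


def test_w_monotone_in_unsaturation(psce_params):
    w1 = compute_w(parse_species("PE 34:1"), psce_params)
    w2 = compute_w(parse_species("PE 34:2"), psce_params)
    assert w2 > w1


def test_w_saturated_equals_head_term(psce_params):
    w = compute_w(parse_species("PC 32:0"), psce_params)
    assert w == pytest.approx(psce_params.w_model.head_terms[LipidClass.PC])


def test_w_missing_class_errors():
    params = _params({"PE": 1.0}, 0.1)
    with pytest.raises(MissingParameterError):
        compute_w(parse_species("PC 34:1"), params)


# -- classification ---------------------------------------------------------

def test_pivot_is_type_0(psce_params):
    assert classify(psce_params.pivot_species, psce_params) == "type_0"


def test_boundary_epsilon_is_type_II():
    params = _params({"PE": 1.0, "PC": 1.0 + 0.1 + 1e-9}, 0.1)
    # PC 34:0: w = w_pivot + 1e-9, strictly above the boundary
    assert classify(parse_species("PC 34:0"), params) == "type_II"
    exact = _params({"PE": 1.0, "PC": 1.0 + 0.1}, 0.1)
    assert classify(parse_species("PC 34:0"), exact) == "type_0"  # equality


def test_saturated_pc_is_type_0_under_defaults(psce_params):
    assert classify(parse_species("PC 32:0"), psce_params) == "type_0"


def test_raising_pivot_never_promotes_to_type_II(psce_params):
    """A larger pivot weight can only demote species toward type 0."""
    import dataclasses
    species = [parse_species(s) for s in
               ("PC 34:2", "PE 34:2", "PE 32:1", "DAG 34:2", "PA 34:2", "PI 34:1")]
    low = psce_params
    high = dataclasses.replace(psce_params, pivot_species=parse_species("PE 34:3"))
    assert high.pivot_w > low.pivot_w
    for sp in species:
        if classify(sp, low) == "type_0":
            assert classify(sp, high) == "type_0"


# -- P_SCE ------------------------------------------------------------------

def test_psce_hand_value():
    """One type II lipid (w=2, 10 nmol) over one type 0 lipid (w=1, 10 nmol)
    with the inverse-weight denominator: P_SCE = (2*10)/(10/1) = 2."""
    params = _params({"PE": 2.0, "PC": 1.0}, 0.0, pivot="PC 32:0")
    comp = {parse_species("PE 32:0"): 10.0, parse_species("PC 32:0"): 10.0}
    res = psce(comp, params)
    assert res.classification[parse_species("PE 32:0")] == "type_II"
    assert res.p_sce == pytest.approx(2.0)
    direct = _params({"PE": 2.0, "PC": 1.0}, 0.0, pivot="PC 32:0",
                     mode="direct_weight")
    assert psce(comp, direct).p_sce == pytest.approx(2.0)  # w=1 => g equal either way


def test_psce_all_type_0_is_zero(psce_params):
    comp = {parse_species("PC 32:0"): 5.0, parse_species("PE 34:1"): 5.0}
    assert psce(comp, psce_params).p_sce == 0.0


def test_psce_zero_denominator_errors():
    params = _params({"PE": 2.0, "PC": 1.0}, 0.0, pivot="PC 32:0")
    with pytest.raises(UndefinedCompositionError):
        psce({parse_species("PE 32:0"): 10.0}, params)
    with pytest.raises(UndefinedCompositionError):
        psce({parse_species("PC 32:0"): 0.0}, params)


@settings(max_examples=100, derandomize=True)
@given(st.floats(min_value=1e-3, max_value=1e3))
def test_psce_scale_invariance(scale):
    params = PsceParams.from_yaml()
    comp = {parse_species("PE 34:2"): 4.0, parse_species("PC 34:1"): 10.0,
            parse_species("DAG 34:2"): 1.0, parse_species("PE 34:1"): 8.0}
    base = psce(comp, params).p_sce
    scaled = psce({k: v * scale for k, v in comp.items()}, params).p_sce
    assert scaled == pytest.approx(base, rel=1e-12)


def test_psce_monotonicity(psce_params):
    t2, t0 = parse_species("PE 34:2"), parse_species("PC 34:1")
    base = {t2: 4.0, t0: 10.0}
    p = psce(base, psce_params).p_sce
    assert psce({t2: 5.0, t0: 10.0}, psce_params).p_sce > p
    assert psce({t2: 4.0, t0: 12.0}, psce_params).p_sce < p


def test_psce_matches_rational_oracle():
    """Exact agreement with a Fraction-arithmetic evaluation on integer
    inputs, under both denominator readings."""
    for mode in ("inverse_weight", "direct_weight"):
        params = _params({"PE": 1.0, "PC": 0.5, "DAG": 1.5}, 0.25, mode=mode)
        comp = {parse_species("PE 34:2"): 3, parse_species("PE 34:1"): 7,
                parse_species("PC 34:1"): 11, parse_species("DAG 32:1"): 2}
        w_exact = {
            "PE 34:2": Fraction(1) + 2 * Fraction(1, 4),
            "PE 34:1": Fraction(1) + Fraction(1, 4),
            "PC 34:1": Fraction(1, 2) + Fraction(1, 4),
            "DAG 32:1": Fraction(3, 2) + Fraction(1, 4),
        }
        pivot = w_exact["PE 34:1"]
        num = den = Fraction(0)
        for name, n in ((str(k), v) for k, v in comp.items()):
            if w_exact[name] > pivot:
                num += w_exact[name] * n
            else:
                g = 1 / w_exact[name] if mode == "inverse_weight" else w_exact[name]
                den += g * n
        expected = float(num / den)
        assert psce(comp, params).p_sce == pytest.approx(expected, rel=1e-12)


# -- calibration ------------------------------------------------------------

def test_calibrate_identity_and_preconditions(psce_params):
    pops = generate_calibration_populations(psce_params, seed=0)
    same = calibrate_w(pops, psce_params, [psce_params.w_model])
    assert same.w_model == psce_params.w_model
    with pytest.raises(ValueError):
        calibrate_w(pops[:2], psce_params, [psce_params.w_model])
    with pytest.raises(ValueError):
        calibrate_w(pops, psce_params, [])


def test_calibrate_recovers_generating_increment(psce_params):
    increments = np.round(np.arange(0.05, 0.31, 0.025), 4)
    grid = w_model_grid(psce_params.w_model.head_terms, increments)
    pops = generate_calibration_populations(psce_params, noise_cv=0.01, seed=7)
    best = calibrate_w(pops, psce_params, grid)
    true_u = psce_params.w_model.unsat_increment
    assert abs(best.w_model.unsat_increment - true_u) <= 0.025 + 1e-12
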