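"""Spontaneous-curvature lookup, ideal mixing, tau and sensitivity."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidsce import (
    C0Entry,
    CurvatureParams,
    DEFAULT_VARIANT,
    LipidClass,
    LipidomeSample,
    MissingParameterError,
    SceVariant,
    WITH_DAG_VARIANT,
    WITH_PI_VARIANT,
    assign_chains,
    lookup_c0,
    mix_c0,
    parse_species,
    sensitivity_analysis,
)
from lipidsce.curvature import UndefinedCompositionError


def _entry(cls, chains, c0):
    return C0Entry(cls, chains, c0, provenance="test")


def _table(entries, defaults=None, k_m=5.0e-20):
    return CurvatureParams(entries=entries, class_defaults=defaults or {}, k_m=k_m)


# -- lookup -----------------------------------------------------------------

def test_lookup_exact_and_fallback():
    params = _table([
        _entry(LipidClass.PE, ((16, 0), (18, 1)), -3.2e8),
        _entry(LipidClass.PE, ((16, 1), (18, 1)), -3.7e8),
        _entry(LipidClass.PE, ((16, 1), (16, 1)), -3.5e8),
    ])
    exact = assign_chains(parse_species("PE 34:1"))
    assert lookup_c0(exact, params) == (-3.2e8, "exact")
    # PE 36:2 absent; same per-chain unsaturation (1,1) exists at 34 and 32
    missing = assign_chains(parse_species("PE 36:2"))
    assert missing.chain_double_bond_multiset() == (1, 1)
    assert lookup_c0(missing, params) == (-3.7e8, "fallback")


def test_lookup_tie_breaks_toward_shorter_chain():
    params = _table([
        _entry(LipidClass.PC, ((16, 0), (16, 1)), -1.0e8),  # 32 carbons
        _entry(LipidClass.PC, ((18, 0), (18, 1)), -2.0e8),  # 36 carbons
    ])
    sp = assign_chains(parse_species("PC 34:1"))  # equidistant from 32 and 36
    assert lookup_c0(sp, params) == (-1.0e8, "fallback")


def test_lookup_speculative_gating():
    params = _table(
        [],
        defaults={LipidClass.PI: _entry(LipidClass.PI, ((0, 0),), -1.0e8)},
    )
    pi = assign_chains(parse_species("PI 34:1"))
    with pytest.raises(MissingParameterError):
        lookup_c0(pi, params, allow_speculative=False)
    assert lookup_c0(pi, params, allow_speculative=True) == (-1.0e8, "speculative")


def test_lookup_requires_chains(curvature_params):
    with pytest.raises(ValueError, match="chain"):
        lookup_c0(parse_species("PE 34:1"), curvature_params)


def test_fallback_matches_exhaustive_enumeration():
    """The minimal-|delta carbons| same-unsaturation rule agrees with brute
    force over randomized tables."""
    rng = random.Random(42)
    for _ in range(200):
        entries = []
        for _ in range(rng.randint(3, 12)):
            c1, c2 = rng.choice([14, 16, 18, 20]), rng.choice([14, 16, 18, 20])
            d1, d2 = rng.randint(0, 2), rng.randint(0, 2)
            entries.append(
                _entry(LipidClass.PE, ((c1, d1), (c2, d2)), -rng.uniform(1e8, 5e8))
            )
        params = _table(entries)
        query = assign_chains(
            parse_species(f"PE {rng.choice([30, 32, 34, 36, 38])}:{rng.randint(0, 4)}")
        )
        db = query.chain_double_bond_multiset()
        candidates = [e for e in entries if e.db_multiset() == db]
        if not candidates:
            with pytest.raises(MissingParameterError):
                lookup_c0(query, params)
            continue
        c0, kind = lookup_c0(query, params)
        chain_ms = tuple(sorted((c.carbons, c.double_bonds) for c in query.chains))
        exact = [e for e in candidates if tuple(sorted(e.chains)) == chain_ms]
        if exact:
            assert kind == "exact" and c0 == exact[0].c0_per_m
        else:
            best_dist = min(abs(e.total_carbons - query.total_carbons) for e in candidates)
            best = min(
                (e for e in candidates
                 if abs(e.total_carbons - query.total_carbons) == best_dist),
                key=lambda e: e.total_carbons,
            )
            assert kind == "fallback" and c0 == best.c0_per_m


# -- mixing -----------------------------------------------------------------

def _two_lipid_params():
    return _table([
        _entry(LipidClass.PE, ((16, 0), (18, 1)), -3.0e8),
        _entry(LipidClass.PC, ((16, 0), (18, 1)), -1.0e8),
    ])


def test_mix_single_lipid():
    params = _two_lipid_params()
    res = mix_c0({parse_species("PE 34:1"): 5.0}, params,
                 SceVariant("pe", {LipidClass.PE}))
    assert res.c0_mix == -3.0e8
    assert res.tau == -2 * params.k_m * res.c0_mix


def test_mix_two_lipids_hand_value():
    """Equal-mole PC (C0 = -1e8/m) + PE (C0 = -3e8/m): C0_mix = -2e8/m and,
    with K_M = 5e-20 J, tau = 2e-11 N."""
    params = _two_lipid_params()
    res = mix_c0(
        {parse_species("PC 34:1"): 1.0, parse_species("PE 34:1"): 1.0},
        params, SceVariant("pcpe", {LipidClass.PC, LipidClass.PE}),
    )
    assert res.c0_mix == pytest.approx(-2.0e8, rel=1e-15)
    assert res.tau == pytest.approx(2.0e-11, rel=1e-15)


def test_mix_matches_per_molecule_average():
    """Ideal additive mixing equals a brute-force per-molecule average over
    an integer-count expansion of the composition."""
    params = _two_lipid_params()
    counts = {parse_species("PC 34:1"): 7, parse_species("PE 34:1"): 3}
    res = mix_c0(counts, params, SceVariant("v", {LipidClass.PC, LipidClass.PE}))
    molecules = [-1.0e8] * 7 + [-3.0e8] * 3
    assert res.c0_mix == pytest.approx(np.mean(molecules), rel=1e-12)


def test_mix_errors():
    params = _two_lipid_params()
    with pytest.raises(UndefinedCompositionError):
        mix_c0({parse_species("PE 34:1"): 0.0}, params,
               SceVariant("pe", {LipidClass.PE}))
    with pytest.raises(MissingParameterError):
        mix_c0({parse_species("PS 34:1"): 1.0}, params,
               SceVariant("ps", {LipidClass.PS}))
    with pytest.raises(ValueError):
        SceVariant("empty", frozenset())


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=2),
    st.floats(min_value=0.1, max_value=10.0),
)
def test_mix_scale_invariance_and_bounds(amounts, scale):
    params = _two_lipid_params()
    comp = {parse_species("PC 34:1"): amounts[0], parse_species("PE 34:1"): amounts[1]}
    variant = SceVariant("v", {LipidClass.PC, LipidClass.PE})
    res = mix_c0(comp, params, variant)
    scaled = mix_c0({k: v * scale for k, v in comp.items()}, params, variant)
    assert scaled.c0_mix == pytest.approx(res.c0_mix, rel=1e-12)
    used = [c0 for c0, _ in res.lookups.values()]
    assert min(used) - 1e-6 <= res.c0_mix <= max(used) + 1e-6
    assert res.tau == -2 * params.k_m * res.c0_mix  # exact identity, by construction
    assert sum(res.mole_fractions.values()) == pytest.approx(1.0, abs=1e-12)


def test_mix_monotone_in_most_negative_species():
    params = _two_lipid_params()
    variant = SceVariant("v", {LipidClass.PC, LipidClass.PE})
    pe, pc = parse_species("PE 34:1"), parse_species("PC 34:1")
    taus = [mix_c0({pc: 1.0, pe: x}, params, variant).tau for x in (0.1, 0.5, 1.0, 4.0)]
    assert all(b > a for a, b in zip(taus, taus[1:]))


def test_default_table_t0_exceeds_final_tau(curvature_params, default_timecourse):
    samples, _ = default_timecourse
    t0 = [s for s in samples if s.time_h == 0.0]
    tend = [s for s in samples if s.time_h == max(x.time_h for x in samples)]
    tau0 = np.mean([mix_c0(s, curvature_params).tau for s in t0])
    tau1 = np.mean([mix_c0(s, curvature_params).tau for s in tend])
    assert tau0 > tau1


# -- sensitivity ------------------------------------------------------------

def test_sensitivity_identity_alternate(curvature_params, default_timecourse):
    samples, _ = default_timecourse
    rep = sensitivity_analysis(samples, curvature_params,
                               alternates=[DEFAULT_VARIANT])
    assert rep.trend_preserved["default"]
    assert rep.deltas("default") == pytest.approx([0.0] * len(rep.times))


def test_sensitivity_pi_and_dag_preserve_trend(curvature_params, default_timecourse):
    samples, truth = default_timecourse
    pi_share = truth.expected_class_mol_pct(0.0)[LipidClass.PI]
    assert pi_share < 15.0  # low-abundance premise for the PI variant
    rep = sensitivity_analysis(samples, curvature_params,
                               alternates=[WITH_PI_VARIANT, WITH_DAG_VARIANT])
    assert rep.trend_preserved["with_pi_speculative"]
    assert rep.trend_preserved["with_dag"]


def test_sensitivity_needs_multiple_samples(curvature_params, default_timecourse):
    samples, _ = default_timecourse
    with pytest.raises(ValueError):
        sensitivity_analysis(samples[:1], curvature_params)
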