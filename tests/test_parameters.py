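"""Parameter containers, distribution sampling and atherosclerotic factors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from periwall import (
    AtheroFactors,
    ConfigurationError,
    DistributionSpec,
    Geometry,
    apply_athero_factors,
    load_distributions,
    parameter_sets_to_frame,
    sample_parameter_sets,
    vasa_area_density,
)
from periwall.parameters import VasaParams, build_parameter_set
from periwall.units import MMHG, UM


# --------------------------------------------------------------------------
# types and invariants
# --------------------------------------------------------------------------


def test_geometry_orders_radii():
    g = Geometry(r_lu=1.5e-3, t_i=4e-4, t_a=4e-4, t_p=4e-4)
    assert g.r_lu < g.r_ia < g.r_ap < g.r_ext
    assert g.r_ext == pytest.approx(2.7e-3)


@pytest.mark.parametrize("field", ["r_lu", "t_i", "t_a", "t_p"])
def test_geometry_rejects_nonpositive(field):
    kwargs = dict(r_lu=1.5e-3, t_i=4e-4, t_a=4e-4, t_p=4e-4)
    kwargs[field] = 0.0
    with pytest.raises(ValueError):
        Geometry(**kwargs)


def test_vasa_area_density_arithmetic():
    vasa = VasaParams(
        l_pv=1e-12, N_v=1e8, d_v=10e-6, p_v=0, pi_v=0, pi_t=0, sigma=0.9
    )
    # N_v·π·d_v with N_v = 1e8 m⁻², d_v = 10 µm
    assert vasa_area_density(vasa) == pytest.approx(math.pi * 1e3, rel=1e-12)
    doubled = VasaParams(
        l_pv=1e-12, N_v=2e8, d_v=10e-6, p_v=0, pi_v=0, pi_t=0, sigma=0.9
    )
    assert vasa_area_density(doubled) == pytest.approx(2 * vasa_area_density(vasa))
    off = VasaParams(l_pv=1e-12, N_v=0.0, d_v=10e-6, p_v=0, pi_v=0, pi_t=0, sigma=0.9)
    assert vasa_area_density(off) == 0.0


def test_sigma_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        VasaParams(l_pv=1e-12, N_v=1e8, d_v=1e-5, p_v=0, pi_v=0, pi_t=0, sigma=1.2)


# --------------------------------------------------------------------------
# config loading
# --------------------------------------------------------------------------


def test_defaults_load_complete(registry):
    assert "geometry.t_i" in registry.distributions
    assert registry.athero.factors  # factors shipped


def test_default_capillary_diameter_is_10_um(registry):
    spec = registry.spec("vasa.d_v")
    assert spec.kind == "fixed"
    assert spec.params["value"] == pytest.approx(10e-6)


def test_config_units_converted_on_load():
    reg = load_distributions(
        {"boundary": {"p_lu": 90.0}, "geometry": {"t_i": 350.0}}
    )
    assert reg.spec("boundary.p_lu").params["value"] == pytest.approx(90.0 * MMHG)
    assert reg.spec("geometry.t_i").params["value"] == pytest.approx(350.0 * UM)


def test_unknown_parameter_name_rejected():
    with pytest.raises(ConfigurationError):
        load_distributions({"tissue": {"k_z": 1e-16}})


def test_malformed_distribution_rejected():
    with pytest.raises(ConfigurationError):
        load_distributions({"tissue": {"k_i": {"kind": "gaussian", "mean": 1e-18}}})
    with pytest.raises(ConfigurationError):
        load_distributions({"tissue": {"k_i": {"kind": "triangular", "mean": 1e-18}}})


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------


def test_sampling_is_seeded_and_reproducible(registry):
    a = sample_parameter_sets(registry, 5, seed=7)
    b = sample_parameter_sets(registry, 5, seed=7)
    assert parameter_sets_to_frame(a).equals(parameter_sets_to_frame(b))
    c = sample_parameter_sets(registry, 5, seed=8)
    assert not parameter_sets_to_frame(a).equals(parameter_sets_to_frame(c))


def test_all_fixed_registry_yields_identical_sets(registry):
    from periwall.parameters import baseline_values

    fixed = registry.fixed(**baseline_values(registry))
    sets = sample_parameter_sets(fixed, 3, seed=0)
    flat = [ps.to_flat_dict() for ps in sets]
    assert flat[0] == flat[1] == flat[2]
    assert [ps.sample_id for ps in sets] == [0, 1, 2]


def test_loguniform_draws_uniform_in_log(registry):
    spec = DistributionSpec(
        "tissue.k_a", "loguniform", {"low": 1e-12, "high": 1e-10}
    )
    rng = np.random.default_rng(0)
    draws = np.array([spec.sample(rng) for _ in range(10_000)])
    assert draws.min() >= 1e-12 and draws.max() <= 1e-10
    stat = kstest(np.log10(draws), "uniform", args=(-12.0, 2.0))
    assert stat.pvalue > 1e-3


def test_gaussian_rejection_respects_positivity():
    # mean at zero: half the mass is inadmissible and must be redrawn
    spec = DistributionSpec("tissue.k_i", "gaussian", {"mean": 0.0, "sd": 1e-18})
    rng = np.random.default_rng(2)
    draws = [spec.sample(rng) for _ in range(500)]
    assert all(d > 0 for d in draws)
    assert spec.rejection_fraction() == pytest.approx(0.5, abs=1e-9)


def test_every_sampled_set_satisfies_invariants(registry):
    for ps in sample_parameter_sets(registry, 200, seed=3):
        g = ps.geometry
        assert g.r_lu < g.r_ia < g.r_ap < g.r_ext
        assert ps.tissue.k_i > 0 and ps.tissue.k_a > 0
        assert 0 <= ps.vasa.sigma <= 1
        assert ps.lymph.sink_rate >= 0


@settings(max_examples=50, derandomize=True)
@given(
    low=st.floats(min_value=1e-20, max_value=1e-10),
    ratio=st.floats(min_value=1.5, max_value=1e4),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_loguniform_draw_within_bounds(low, ratio, seed):
    spec = DistributionSpec(
        "lymph.q_tilde_l", "loguniform", {"low": low, "high": low * ratio}
    )
    x = spec.sample(np.random.default_rng(seed))
    assert low <= x <= low * ratio


# --------------------------------------------------------------------------
# atherosclerotic factors
# --------------------------------------------------------------------------


def test_identity_factors_change_only_condition(registry, baseline):
    unit = AtheroFactors(
        {
            p: DistributionSpec(p, "fixed", {"value": 1.0})
            for p in registry.athero.factors
        }
    )
    out = apply_athero_factors(baseline, unit, seed=0)
    assert out.condition == "atherosclerotic"
    a, b = baseline.to_flat_dict(), out.to_flat_dict()
    assert a == b


def test_factor_multiplies_lymph_rate(baseline):
    f = AtheroFactors(
        {"lymph.q_tilde_l": DistributionSpec("lymph.q_tilde_l", "fixed", {"value": 0.5})}
    )
    ps = baseline.replace(**{"lymph.q_tilde_l": 1.5e-11})
    out = apply_athero_factors(ps, f, seed=0)
    assert out.lymph.q_tilde_l == pytest.approx(0.75e-11)


def test_factor_against_reported_direction_warns(baseline):
    # q̃_ℓ is reported to decrease in disease; an increasing factor is suspect
    rising = AtheroFactors(
        {"lymph.q_tilde_l": DistributionSpec("lymph.q_tilde_l", "fixed", {"value": 2.0})}
    )
    with pytest.warns(UserWarning):
        apply_athero_factors(baseline, rising, seed=0)


def test_selected_case_permeability_factor_recovered():
    # healthy k_i = 1.5e-18 m² and its atherosclerotic counterpart 2.8e-18 m²
    # imply a multiplicative factor ≈ 1.87
    factor = 2.8e-18 / 1.5e-18
    assert factor == pytest.approx(1.8667, abs=1e-3)
    f = AtheroFactors(
        {"tissue.k_i": DistributionSpec("tissue.k_i", "fixed", {"value": factor})}
    )
    base = {
        "geometry.r_lu": 1.5e-3, "geometry.t_i": 4e-4, "geometry.t_a": 4e-4,
        "geometry.t_p": 4e-4, "tissue.k_i": 1.5e-18, "tissue.k_a": 1e-16,
        "tissue.mu": 1e-3, "vasa.l_pv": 1e-12, "vasa.N_v": 1e8,
        "vasa.d_v": 1e-5, "vasa.p_v": 25 * MMHG, "vasa.pi_v": 25 * MMHG,
        "vasa.pi_t": 10 * MMHG, "vasa.sigma": 0.9, "vasa.kappa_v": 0.0,
        "lymph.N_l": 3e6, "lymph.q_tilde_l": 1e-11, "lymph.l_bar_l": 1.0,
        "boundary.p_lu": 100 * MMHG,
    }
    ps = build_parameter_set(base)
    out = apply_athero_factors(ps, f, seed=0)
    assert out.tissue.k_i == pytest.approx(2.8e-18)


def test_athero_requires_healthy_input(baseline, registry):
    out = apply_athero_factors(baseline, registry.athero, seed=0)
    with pytest.raises(ValueError):
        apply_athero_factors(out, registry.athero, seed=0)
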