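"""Radial flow solver against closed-form oracles and physical invariants."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import i0, i1, k0, k1

from periwall import (
    FlowSolution,
    SolverOptions,
    conservation_residual,
    flow_rates,
    luminal_fraction,
    lymph_flux,
    solve_radial_flow,
    starling_flux,
)
from periwall.parameters import (
    Geometry,
    LymphParams,
    ParameterSet,
    TissueProperties,
    VasaParams,
    build_parameter_set,
)
from periwall.units import MMHG


def make_ps(**over):
    base = {
        "geometry.r_lu": 1.5e-3, "geometry.t_i": 4e-4, "geometry.t_a": 4e-4,
        "geometry.t_p": 4e-4, "tissue.k_i": 1e-18, "tissue.k_a": 1e-16,
        "tissue.mu": 1e-3, "vasa.l_pv": 2e-12, "vasa.N_v": 1e8,
        "vasa.d_v": 1e-5, "vasa.p_v": 25 * MMHG, "vasa.pi_v": 25 * MMHG,
        "vasa.pi_t": 10 * MMHG, "vasa.sigma": 0.9, "vasa.kappa_v": 0.0,
        "lymph.N_l": 3e6, "lymph.q_tilde_l": 1.2e-11, "lymph.l_bar_l": 1.0,
        "boundary.p_lu": 100 * MMHG,
    }
    base.update(over)
    return build_parameter_set(base)


# --------------------------------------------------------------------------
# local flux laws
# --------------------------------------------------------------------------


def test_starling_flux_clamps_negative_driving_pressure():
    vasa = VasaParams(
        l_pv=1e-10, N_v=1e8, d_v=1e-5, p_v=25 * MMHG, pi_v=25 * MMHG,
        pi_t=10 * MMHG, sigma=0.9,
    )
    # tissue pressure far above the vasa equilibrium: no filtration
    assert starling_flux(200 * MMHG, vasa) == 0.0


def test_starling_flux_linear_in_driving_pressure():
    vasa = VasaParams(
        l_pv=1e-10, N_v=1e8, d_v=1e-5, p_v=0.0, pi_v=0.0, pi_t=0.0, sigma=0.0
    )
    j1 = starling_flux(-10 * MMHG, vasa)  # δP = 10 mmHg
    j2 = starling_flux(-20 * MMHG, vasa)
    assert j2 == pytest.approx(2 * j1, rel=1e-12)
    # direct arithmetic: l_pv·Ā_v·δP
    assert j1 == pytest.approx(1e-10 * (1e8 * math.pi * 1e-5) * 10 * MMHG, rel=1e-12)


def test_starling_smoothing_vanishes_away_from_kink():
    vasa = VasaParams(
        l_pv=1e-10, N_v=1e8, d_v=1e-5, p_v=0.0, pi_v=0.0, pi_t=0.0, sigma=0.0
    )
    p = -10 * MMHG
    exact = starling_flux(p, vasa)
    smoothed = starling_flux(p, vasa, smoothing_eps=1e-3 * MMHG)
    # smooth max deviates from the clamp by ε²/(4δP) away from the kink
    assert smoothed == pytest.approx(exact, rel=1e-8)
    assert smoothed >= exact


def test_lymph_flux_is_constant_sink():
    assert lymph_flux(LymphParams(N_l=0.0, q_tilde_l=1e-11)) == 0.0
    # N_ℓ = 3e6 m⁻², q̃_ℓ = 1e-11 m²/s → 3e-5 s⁻¹ drainage rate
    assert lymph_flux(LymphParams(N_l=3e6, q_tilde_l=1e-11)) == pytest.approx(-3e-5)
    assert lymph_flux(
        LymphParams(N_l=3e6, q_tilde_l=1e-11, l_bar_l=1.0)
    ) == pytest.approx(-3e6 * 1e-11)


# --------------------------------------------------------------------------
# source-free and constant-sink closed forms
# --------------------------------------------------------------------------


def test_source_free_wall_has_no_flow():
    ps = make_ps(**{"vasa.l_pv": 0.0, "vasa.N_v": 0.0, "lymph.N_l": 0.0})
    sol = solve_radial_flow(ps)
    assert np.max(np.abs(sol.u)) < 1e-18
    assert np.max(np.abs(sol.p - ps.p_lu)) < 1e-6 * abs(ps.p_lu)
    assert flow_rates(sol) == pytest.approx((0.0, 0.0, 0.0), abs=1e-22)


def constant_sink_oracle(ps):
    """Closed form for vasa off, constant lymphatic sink in the outer layers.

    r·u = s_ℓ(r_ext² − r²)/2 in the sink region and constant inside; the
    pressure follows by piecewise Darcy quadrature.
    """
    g, t = ps.geometry, ps.tissue
    s_l = ps.lymph.sink_rate

    def q(r):
        r = np.asarray(r, dtype=float)
        return np.where(
            r < g.r_ia,
            s_l * (g.r_ext**2 - g.r_ia**2) / 2.0,
            s_l * (g.r_ext**2 - r**2) / 2.0,
        )

    def p(r_eval):
        out = []
        for r in np.atleast_1d(r_eval):
            val, _ = quad(
                lambda s: -t.mu * q(s) / (_k_of(ps, s) * s), g.r_lu, r, limit=200,
                points=[x for x in (g.r_ia, g.r_ap) if g.r_lu < x < r],
            )
            out.append(ps.p_lu + val)
        return np.array(out)

    return q, p


def _k_of(ps, r):
    g = ps.geometry
    if r < g.r_ia:
        return ps.tissue.k_i
    if r < g.r_ap:
        return ps.tissue.k_a
    return ps.tissue.k_p


def test_constant_sink_matches_piecewise_quadrature():
    ps = make_ps(**{"vasa.l_pv": 0.0, "vasa.N_v": 0.0})
    sol = solve_radial_flow(ps)
    q_o, p_o = constant_sink_oracle(ps)
    g = ps.geometry
    r = np.linspace(g.r_lu * 1.0001, g.r_ext * 0.9999, 40)
    assert np.max(np.abs(sol.q_at(r) - q_o(r))) < 1e-6 * np.max(np.abs(q_o(r)))
    p_ref = p_o(r)
    scale = np.max(np.abs(p_ref))
    assert np.max(np.abs(sol.p_at(r) - p_ref)) < 1e-6 * scale
    # analytic flow rates
    s_l = ps.lymph.sink_rate
    Q_l_exact = -s_l * math.pi * (g.r_ext**2 - g.r_ia**2)
    Q_lu, Q_v, Q_l = flow_rates(sol)
    assert Q_l == pytest.approx(Q_l_exact, rel=1e-12)
    assert Q_lu == pytest.approx(-Q_l_exact, rel=1e-6)
    assert Q_v == pytest.approx(0.0, abs=1e-6 * abs(Q_l_exact))


def bessel_two_region_oracle(ps):
    """Closed form with full Starling exchange, uniform outer permeability.

    Inner layer (source-free): p = p_lu + C·ln(r/r_lu), constant flux.
    Exchange region: a modified-Bessel equation around the equilibrium
    pressure p_part = p_eq − s_ℓ/a_v with λ = sqrt(a_v μ/k).  Valid while the
    Starling clamp stays inactive (p < p_eq everywhere).
    """
    g, t, v = ps.geometry, ps.tissue, ps.vasa
    assert t.k_a == t.k_p
    a_v = v.l_pv * v.a_bar_v
    s_l = ps.lymph.sink_rate
    p_eq = v.p_v - v.sigma * (v.pi_t - v.pi_v)
    p_part = p_eq - s_l / a_v
    lam = math.sqrt(a_v * t.mu / t.k_a)

    ri, re = g.r_ia, g.r_ext
    M = np.array(
        [
            [math.log(ri / g.r_lu), -i0(lam * ri), -k0(lam * ri)],
            [t.k_i, -t.k_a * ri * lam * i1(lam * ri), t.k_a * ri * lam * k1(lam * ri)],
            [0.0, i1(lam * re), -k1(lam * re)],
        ]
    )
    rhs = np.array([p_part - ps.p_lu, 0.0, 0.0])
    C, A, B = np.linalg.solve(M, rhs)

    def p(r):
        r = np.asarray(r, dtype=float)
        inner = ps.p_lu + C * np.log(r / g.r_lu)
        outer = p_part + A * i0(lam * r) + B * k0(lam * r)
        return np.where(r < ri, inner, outer)

    def q(r):
        r = np.asarray(r, dtype=float)
        inner = np.full_like(r, -t.k_i * C / t.mu)
        outer = -(t.k_a / t.mu) * r * lam * (A * i1(lam * r) - B * k1(lam * r))
        return np.where(r < ri, inner, outer)

    return p, q, p_eq


@pytest.mark.parametrize("l_pv,q_l,k", [
    (2e-12, 1.2e-11, 1e-16),
    (1e-12, 0.8e-11, 5e-17),
    (4e-12, 2.0e-11, 2e-16),
    (2e-12, 0.5e-11, 1e-16),
    (8e-13, 3.0e-11, 8e-17),
])
def test_full_model_matches_bessel_closed_form(l_pv, q_l, k):
    # low luminal pressure keeps the whole wall below the Starling
    # equilibrium, so the clamp never activates and the ODE stays linear
    ps = make_ps(**{
        "boundary.p_lu": 10 * MMHG,
        "vasa.l_pv": l_pv,
        "lymph.q_tilde_l": q_l,
        "tissue.k_a": k,
        "tissue.k_p": k,
    })
    sol = solve_radial_flow(ps)
    p_o, q_o, p_eq = bessel_two_region_oracle(ps)
    g = ps.geometry
    r = np.linspace(g.r_lu, g.r_ext, 60)
    assert np.max(sol.p_at(r)) < p_eq  # oracle validity
    scale_p = np.max(np.abs(p_o(r)))
    scale_q = np.max(np.abs(q_o(r)))
    assert np.max(np.abs(sol.p_at(r) - p_o(r))) < 1e-6 * scale_p
    assert np.max(np.abs(sol.q_at(r) - q_o(r))) < 1e-6 * scale_q


# --------------------------------------------------------------------------
# solver contracts
# --------------------------------------------------------------------------


def test_boundary_conditions_and_continuity(physiologic_ps, physiologic_flow):
    sol, g = physiologic_flow, physiologic_ps.geometry
    assert float(sol.p_at(g.r_lu)) == pytest.approx(physiologic_ps.p_lu, rel=1e-9)
    assert abs(float(sol.u_at(g.r_ext))) < 1e-9 * np.max(np.abs(sol.u))
    for edge in (g.r_ia, g.r_ap):
        below, above = edge * (1 - 1e-9), edge * (1 + 1e-9)
        assert float(sol.p_at(below)) == pytest.approx(float(sol.p_at(above)), rel=1e-6)
        assert float(sol.q_at(below)) == pytest.approx(float(sol.q_at(above)), rel=1e-6)


def test_mass_conservation_on_physiologic_case(physiologic_flow):
    assert conservation_residual(physiologic_flow) < 1e-6


def test_smoothing_epsilon_limit(physiologic_ps):
    a = solve_radial_flow(physiologic_ps, SolverOptions(starling_smoothing_eps=1e-3 * MMHG))
    b = solve_radial_flow(physiologic_ps, SolverOptions(starling_smoothing_eps=1e-6 * MMHG))
    r = np.linspace(physiologic_ps.geometry.r_lu, physiologic_ps.geometry.r_ext, 50)
    assert np.max(np.abs(a.p_at(r) - b.p_at(r))) < 1e-6 * np.max(np.abs(a.p_at(r)))


def test_grid_convergence_of_outer_pressure(physiologic_ps):
    g = physiologic_ps.geometry
    coarse = solve_radial_flow(physiologic_ps, SolverOptions(rel_tol=1e-8))
    fine = solve_radial_flow(physiologic_ps, SolverOptions(rel_tol=5e-9))
    pap_c = float(coarse.p_at(g.r_ap))
    pap_f = float(fine.p_at(g.r_ap))
    assert abs(pap_c - pap_f) < 1e-3 * max(abs(pap_f), MMHG)


def test_more_drainage_lowers_pressure_everywhere(physiologic_ps):
    lo = solve_radial_flow(physiologic_ps)
    hi = solve_radial_flow(
        physiologic_ps.replace(
            **{"lymph.q_tilde_l": physiologic_ps.lymph.q_tilde_l * 2}
        )
    )
    r = np.linspace(physiologic_ps.geometry.r_lu, physiologic_ps.geometry.r_ext, 80)
    assert np.all(hi.p_at(r) <= lo.p_at(r) + 1e-9)


def test_leakier_vasa_raise_outer_pressure(physiologic_ps):
    g = physiologic_ps.geometry
    lo = solve_radial_flow(physiologic_ps)
    hi = solve_radial_flow(
        physiologic_ps.replace(**{"vasa.l_pv": physiologic_ps.vasa.l_pv * 3})
    )
    assert float(hi.p_at(g.r_ap)) > float(lo.p_at(g.r_ap))


def test_pressure_drop_localises_in_tight_inner_layer():
    ps = make_ps(**{"tissue.k_i": 1e-19, "tissue.k_a": 1e-15, "tissue.k_p": 1e-15})
    sol = solve_radial_flow(ps)
    g = ps.geometry
    total = ps.p_lu - float(sol.p_at(g.r_ext))
    inner = ps.p_lu - float(sol.p_at(g.r_ia))
    assert inner / total > 0.97


# --------------------------------------------------------------------------
# luminal tracer
# --------------------------------------------------------------------------


def test_no_vasa_means_undiluted_lymph():
    ps = make_ps(**{"vasa.l_pv": 0.0, "vasa.N_v": 0.0})
    sol = solve_radial_flow(ps)
    f = luminal_fraction(sol)
    assert np.all(f >= 1.0 - 1e-12)


def make_constant_ratio_flow(gamma, u0=1e-7):
    """Synthetic flow with J_v/u ≡ γ over the exchange region.

    Constant velocity and constant Starling source (flat tissue pressure with
    σ = 0) make the tracer ODE exactly exponential.
    """
    jv = gamma * u0
    geometry = Geometry(r_lu=1.5e-3, t_i=4e-4, t_a=4e-4, t_p=4e-4)
    a_bar = 1e8 * math.pi * 1e-5
    p_v = 1000.0
    l_pv = jv / (a_bar * p_v)  # J_v = l_pv·Ā_v·(p_v − 0)
    ps = ParameterSet(
        geometry=geometry,
        tissue=TissueProperties(k_i=1e-18, k_a=1e-16, k_p=1e-16, mu=1e-3),
        vasa=VasaParams(
            l_pv=l_pv, N_v=1e8, d_v=1e-5, p_v=p_v, pi_v=0.0, pi_t=0.0, sigma=0.0
        ),
        lymph=LymphParams(N_l=0.0, q_tilde_l=0.0),
        p_lu=0.0,
    )
    r_grid = np.linspace(geometry.r_lu, geometry.r_ext, 200)
    return FlowSolution(
        ps=ps,
        r=r_grid,
        p=np.zeros_like(r_grid),
        u=np.full_like(r_grid, u0),
        J_v=np.full_like(r_grid, jv),
        J_l=np.zeros_like(r_grid),
        Q_lu=2 * math.pi * geometry.r_lu * u0,
        Q_v=0.0,
        Q_l=0.0,
        residual=0.0,
        p_at=lambda r: np.zeros_like(np.asarray(r, dtype=float)),
        q_at=lambda r: u0 * np.asarray(r, dtype=float),
        options=SolverOptions(starling_smoothing_eps=0.0),
    )


def test_tracer_exponential_closed_form():
    gamma = 2000.0  # 1/m
    sol = make_constant_ratio_flow(gamma)
    luminal_fraction(sol)
    g = sol.ps.geometry
    r = np.linspace(g.r_ia, g.r_ext * 0.999, 50)
    expected = np.exp(-gamma * (r - g.r_ia))
    assert np.max(np.abs(sol.f_at(r) - expected)) < 1e-6
    # fraction is 1 wherever the vasa source is absent
    assert float(sol.f_at(g.r_lu + 1e-4)) == pytest.approx(1.0)


def test_tracer_monotone_and_bounded(physiologic_flow):
    f = luminal_fraction(physiologic_flow)
    assert f[0] == pytest.approx(1.0)
    assert np.all(np.diff(f) <= 1e-12)
    assert np.all((f >= 0.0) & (f <= 1.0))


def test_tracer_consistent_with_flux_bookkeeping(physiologic_flow):
    """Flux-weighted lymph-average of f must match the vasa/lumen split."""
    sol = physiologic_flow
    luminal_fraction(sol)
    g = sol.ps.geometry
    s_l = sol.ps.lymph.sink_rate
    r = np.linspace(g.r_ia, g.r_ext, 20001)
    from scipy.integrate import simpson

    luminal_outflow = s_l * 2 * math.pi * simpson(sol.f_at(r) * r, x=r)
    expected_vasa_share = sol.Q_v / (sol.Q_v + sol.Q_lu)
    tracer_vasa_share = 1.0 - luminal_outflow / abs(sol.Q_l)
    assert tracer_vasa_share == pytest.approx(expected_vasa_share, abs=0.01)
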