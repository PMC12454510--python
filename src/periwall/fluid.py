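"""Radial Darcy flow across the artery wall with microvascular exchange.

The steady interstitial flow in a circumferentially invariant cylindrical wall
obeys Darcy's law ``u = -(k(r)/μ) dp/dr`` with a stepwise permeability per
layer, and mass conservation

    (1/r) d(r u)/dr = J_v + J_ℓ

where ``J_v`` is the vasa-vasorum filtration source (revised Starling
principle, clamped at zero driving pressure) and ``J_ℓ`` the lymphatic
drainage sink, both active only in the adventitia and PVAT.  Boundary
conditions: imposed pressure at the lumen-side endothelium and no flow at the
outer PVAT.

The problem is solved as a first-order system in ``(p, q)`` with ``q = r·u``
the conserved flux per radian.  Each of the three layers is mapped to the unit
interval and carries its own copy of the state, so every ODE component is
smooth; continuity of ``p`` and ``q`` at the two interfaces is imposed exactly
through the boundary conditions.  Collocation is scipy's ``solve_bvp``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_bvp

from .parameters import LymphParams, ParameterSet, VasaParams
from .units import MMHG

logger = logging.getLogger(__name__)


class FlowSolverError(RuntimeError):
    """Raised when the flow boundary-value problem fails to converge."""

    def __init__(self, message: str, residual: float = np.nan):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for the collocation solvers.

    ``n_grid`` is the initial number of mesh nodes per layer;
    ``starling_smoothing_eps`` is the pressure half-width (Pa) over which the
    Starling clamp ``max(δP, 0)`` is smoothed to keep the Newton Jacobian
    continuous (default 1e-3 mmHg, far below any physical pressure scale).
    """

    n_grid: int = 41
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    starling_smoothing_eps: float = 1e-3 * MMHG
    max_iter: int = 50_000  # node budget for adaptive refinement

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")


DEFAULT_OPTIONS = SolverOptions()


# --------------------------------------------------------------------------
# local exchange fluxes
# --------------------------------------------------------------------------


def starling_flux(
    p_local: float | np.ndarray,
    vasa: VasaParams,
    smoothing_eps: float = 0.0,
) -> float | np.ndarray:
    """Vasa-vasorum filtration source density J_v (s⁻¹) at tissue pressure ``p_local``.

    Revised Starling principle, piecewise linear: ``l_pv·Ā_v·δP`` when the
    driving pressure ``δP = p_v − p − σ(π_t − π_v)`` is positive, zero
    otherwise.  With ``smoothing_eps > 0`` the kink is replaced by the smooth
    max ``(δP + sqrt(δP² + ε²))/2``, which deviates from the exact clamp by at
    most ``ε/2`` and only within O(ε) of the kink.
    """
    dp = vasa.delta_p(p_local)
    if smoothing_eps > 0.0:
        pos = 0.5 * (dp + np.sqrt(dp * dp + smoothing_eps * smoothing_eps))
    else:
        pos = np.maximum(dp, 0.0)
    return vasa.l_pv * vasa.a_bar_v * pos


def _starling_slope(
    p_local: np.ndarray, vasa: VasaParams, smoothing_eps: float
) -> np.ndarray:
    """∂J_v/∂p for the smoothed clamp (used in the BVP Jacobian)."""
    dp = vasa.delta_p(p_local)
    if smoothing_eps > 0.0:
        dpos = 0.5 * (1.0 + dp / np.sqrt(dp * dp + smoothing_eps * smoothing_eps))
    else:
        dpos = (dp > 0.0).astype(float)
    return -vasa.l_pv * vasa.a_bar_v * dpos


def lymph_flux(lymph: LymphParams) -> float:
    """Lymphatic sink density J_ℓ = −N_ℓ·q̃_ℓ·l̄_ℓ (s⁻¹, ≤ 0).

    Drainage across the primary lymphatic valves is taken proportional to the
    vessel density and independent of local pressure.
    """
    return -lymph.sink_rate


# --------------------------------------------------------------------------
# solution container
# --------------------------------------------------------------------------


@dataclass
class FlowSolution:
    """Converged radial flow field.

    Arrays are sampled on ``r`` (the concatenated collocation mesh); smooth
    evaluation anywhere in the domain goes through the callables ``p_at``,
    ``u_at``, ``q_at`` and ``j_v_at`` which dispatch to the per-layer
    collocation interpolants.  ``f``/``f_r`` hold the luminal-origin fluid
    fraction once :func:`luminal_fraction` has run.  Flow rates are per unit
    axial length (m²·s⁻¹): ``Q_lu`` across the endothelium, ``Q_v`` from vasa
    vasorum, ``Q_l`` into lymphatics (≤ 0); their sum vanishes for a mass-
    conserving solution.
    """

    ps: ParameterSet
    r: np.ndarray
    p: np.ndarray
    u: np.ndarray
    J_v: np.ndarray
    J_l: np.ndarray
    Q_lu: float
    Q_v: float
    Q_l: float
    residual: float
    p_at: Callable[[np.ndarray], np.ndarray]
    q_at: Callable[[np.ndarray], np.ndarray]
    options: SolverOptions = field(default_factory=SolverOptions)
    f_r: np.ndarray | None = None
    f: np.ndarray | None = None
    u_reversal: bool = False
    tracer_truncated: bool = False

    def u_at(self, r: np.ndarray) -> np.ndarray:
        return self.q_at(r) / np.asarray(r, dtype=float)

    def j_v_at(self, r: np.ndarray) -> np.ndarray:
        """Vasa source density at radius r (zero in the inner layers)."""
        r = np.asarray(r, dtype=float)
        jv = starling_flux(
            self.p_at(r), self.ps.vasa, self.options.starling_smoothing_eps
        )
        return np.where(r >= self.ps.geometry.r_ia, jv, 0.0)

    def u_prime_at(self, r: np.ndarray) -> np.ndarray:
        """du/dr from the governing equation (exact on the converged solution)."""
        r = np.asarray(r, dtype=float)
        g = self.ps.geometry
        source = np.where(
            r >= g.r_ia, self.j_v_at(r) + lymph_flux(self.ps.lymph), 0.0
        )
        return source - self.u_at(r) / r

    def smooth_coefficients(self, n_knots: int = 400):
        """Per-layer C² spline representations of p(r) and u(r).

        The collocation interpolants are only C¹ across their own mesh nodes,
        which makes downstream BVPs (the solute problem) grind against
        spurious derivative kinks.  These splines re-sample each layer on a
        fine uniform grid; their interpolation error is far below the solver
        tolerance.  Built lazily and cached.
        """
        if getattr(self, "_splines", None) is not None:
            return self._splines
        from scipy.interpolate import CubicSpline

        g = self.ps.geometry
        layers = [(g.r_lu, g.r_ia), (g.r_ia, g.r_ap), (g.r_ap, g.r_ext)]
        splines = []
        for a, b in layers:
            r = np.linspace(a, b, n_knots)
            splines.append(
                {
                    "a": a,
                    "b": b,
                    "p": CubicSpline(r, self.p_at(r)),
                    "u": CubicSpline(r, self.q_at(r) / r),
                }
            )
        self._splines = splines
        return splines

    def _smooth_eval(self, r: np.ndarray, what: str) -> np.ndarray:
        splines = self.smooth_coefficients()
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r2 = np.atleast_1d(r).astype(float)
        edges = np.array([s["a"] for s in splines] + [splines[-1]["b"]])
        idx = np.clip(np.searchsorted(edges, r2, side="right") - 1, 0, 2)
        out = np.empty_like(r2)
        for j, s in enumerate(splines):
            m = idx == j
            if m.any():
                out[m] = s[what](np.clip(r2[m], s["a"], s["b"]))
        return out[0] if scalar else out

    def p_smooth(self, r: np.ndarray) -> np.ndarray:
        return self._smooth_eval(r, "p")

    def u_smooth(self, r: np.ndarray) -> np.ndarray:
        return self._smooth_eval(r, "u")

    def j_v_smooth(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        jv = starling_flux(
            self.p_smooth(r), self.ps.vasa, self.options.starling_smoothing_eps
        )
        return np.where(r >= self.ps.geometry.r_ia, jv, 0.0)

    def u_prime_smooth(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        source = np.where(
            r >= self.ps.geometry.r_ia,
            self.j_v_smooth(r) + lymph_flux(self.ps.lymph),
            0.0,
        )
        return source - self.u_smooth(r) / r

    def f_at(self, r: np.ndarray) -> np.ndarray:
        if self.f is None or self.f_r is None:
            raise ValueError("luminal fraction not computed; call luminal_fraction()")
        return np.interp(np.asarray(r, dtype=float), self.f_r, self.f)

    def scalar_outputs(self) -> dict[str, float]:
        return {
            "Q_lu": self.Q_lu,
            "Q_v": self.Q_v,
            "Q_l": self.Q_l,
            "residual": self.residual,
        }


# --------------------------------------------------------------------------
# solver
# --------------------------------------------------------------------------


def _layers(ps: ParameterSet) -> list[tuple[float, float, float, bool]]:
    """(r_start, r_end, permeability, has_exchange) per layer, inner to outer."""
    g, t = ps.geometry, ps.tissue
    return [
        (g.r_lu, g.r_ia, t.k_i, False),
        (g.r_ia, g.r_ap, t.k_a, True),
        (g.r_ap, g.r_ext, t.k_p, True),
    ]


def solve_radial_flow(
    ps: ParameterSet, opts: SolverOptions | None = None
) -> FlowSolution:
    """Solve the radial Darcy problem for one parameter set.

    Raises :class:`FlowSolverError` on non-convergence.  A solution with
    reverse flow (``u < 0`` anywhere) is returned but flagged via
    ``u_reversal``; the luminal tracer is undefined past a stagnation point.
    """
    opts = opts or DEFAULT_OPTIONS
    layers = _layers(ps)
    vasa, lymph = ps.vasa, ps.lymph
    mu = ps.tissue.mu
    eps = opts.starling_smoothing_eps
    j_l = lymph_flux(lymph)

    # internal scaling: pressures O(1) in p_scale, fluxes O(1) in q_scale
    p_scale = max(abs(ps.p_lu), abs(vasa.delta_p(0.0)), MMHG)
    q_scale = max(ps.tissue.k_i / mu * p_scale, 1e-30)
    # a sink-driven flux scale, in case exchange dominates the Darcy scale
    sink_q = abs(j_l) * ps.geometry.r_ext**2 / 2.0
    q_scale = max(q_scale, sink_q * 1e-3)

    starts = np.array([lay[0] for lay in layers])
    lengths = np.array([lay[1] - lay[0] for lay in layers])
    ks = np.array([lay[2] for lay in layers])
    has_src = np.array([lay[3] for lay in layers])

    def rhs(s: np.ndarray, y: np.ndarray) -> np.ndarray:
        out = np.empty_like(y)
        for j in range(3):
            r = starts[j] + s * lengths[j]
            p = y[2 * j] * p_scale
            q = y[2 * j + 1] * q_scale
            out[2 * j] = -lengths[j] * mu * q / (ks[j] * r) / p_scale
            if has_src[j]:
                src = starling_flux(p, vasa, eps) + j_l
                out[2 * j + 1] = lengths[j] * r * src / q_scale
            else:
                out[2 * j + 1] = np.zeros_like(r)
        return out

    def rhs_jac(s: np.ndarray, y: np.ndarray) -> np.ndarray:
        m = s.shape[0]
        J = np.zeros((6, 6, m))
        for j in range(3):
            r = starts[j] + s * lengths[j]
            J[2 * j, 2 * j + 1] = -lengths[j] * mu * q_scale / (ks[j] * r) / p_scale
            if has_src[j]:
                p = y[2 * j] * p_scale
                J[2 * j + 1, 2 * j] = (
                    lengths[j] * r * _starling_slope(p, vasa, eps) * p_scale / q_scale
                )
        return J

    def bc(ya: np.ndarray, yb: np.ndarray) -> np.ndarray:
        return np.array(
            [
                ya[0] - ps.p_lu / p_scale,  # imposed luminal pressure
                yb[5],  # no flow at the outer PVAT
                yb[0] - ya[2],  # p continuous at r_ia
                yb[1] - ya[3],  # q continuous at r_ia
                yb[2] - ya[4],  # p continuous at r_ap
                yb[3] - ya[5],  # q continuous at r_ap
            ]
        )

    def bc_jac(ya: np.ndarray, yb: np.ndarray):
        dbc_dya = np.zeros((6, 6))
        dbc_dyb = np.zeros((6, 6))
        dbc_dya[0, 0] = 1.0
        dbc_dyb[1, 5] = 1.0
        dbc_dyb[2, 0], dbc_dya[2, 2] = 1.0, -1.0
        dbc_dyb[3, 1], dbc_dya[3, 3] = 1.0, -1.0
        dbc_dyb[4, 2], dbc_dya[4, 4] = 1.0, -1.0
        dbc_dyb[5, 3], dbc_dya[5, 5] = 1.0, -1.0
        return dbc_dya, dbc_dyb

    s0 = np.linspace(0.0, 1.0, max(opts.n_grid, 5))
    y0 = np.zeros((6, s0.size))
    # initial guess: full pressure drop across the inner layers, flat outside,
    # flux from the lymphatic sink magnitude
    y0[0] = (ps.p_lu - (ps.p_lu - 0.0) * s0) / p_scale
    y0[2] = 0.0
    y0[4] = 0.0
    q_guess = abs(j_l) * (ps.geometry.r_ext**2 - ps.geometry.r_ia**2) / 2.0
    y0[1] = y0[3] = y0[5] = q_guess / q_scale

    sol = solve_bvp(
        rhs,
        bc,
        s0,
        y0,
        fun_jac=rhs_jac,
        bc_jac=bc_jac,
        tol=opts.rel_tol,
        bc_tol=opts.abs_tol,
        max_nodes=opts.max_iter,
    )
    if sol.status != 0:
        raise FlowSolverError(
            f"flow BVP failed: {sol.message}",
            residual=float(np.max(sol.rms_residuals)),
        )

    def make_eval(component: int) -> Callable[[np.ndarray], np.ndarray]:
        scale = p_scale if component % 2 == 0 else q_scale

        def _eval(r: np.ndarray) -> np.ndarray:
            r = np.asarray(r, dtype=float)
            scalar = r.ndim == 0
            r2 = np.atleast_1d(r).astype(float)
            out = np.empty_like(r2)
            edges = [layers[0][0], layers[0][1], layers[1][1], layers[2][1]]
            idx = np.clip(np.searchsorted(edges, r2, side="right") - 1, 0, 2)
            for j in range(3):
                m = idx == j
                if not m.any():
                    continue
                s = (r2[m] - starts[j]) / lengths[j]
                s = np.clip(s, 0.0, 1.0)
                out[m] = sol.sol(s)[2 * j + (component % 2)][...] * scale
            return out[0] if scalar else out

        return _eval

    p_at = make_eval(0)
    q_at = make_eval(1)

    # concatenated output grid from the final mesh (interfaces appear twice,
    # once from each side; values coincide by construction)
    r_parts, p_parts, q_parts = [], [], []
    for j in range(3):
        rj = starts[j] + sol.x * lengths[j]
        r_parts.append(rj)
        p_parts.append(sol.y[2 * j] * p_scale)
        q_parts.append(sol.y[2 * j + 1] * q_scale)
    r_all = np.concatenate(r_parts)
    p_all = np.concatenate(p_parts)
    q_all = np.concatenate(q_parts)
    u_all = q_all / r_all

    j_v_all = np.where(
        r_all >= ps.geometry.r_ia, starling_flux(p_all, vasa, eps), 0.0
    )
    j_l_all = np.where(r_all >= ps.geometry.r_ia, j_l, 0.0)

    # integrated flow rates per unit axial length
    g = ps.geometry
    Q_lu = 2.0 * np.pi * float(q_at(g.r_lu))
    Q_l = -lymph.sink_rate * np.pi * (g.r_ext**2 - g.r_ia**2)
    Q_v = _integrate_source(p_at, vasa, eps, g.r_ia, g.r_ap, g.r_ext)

    sol_out = FlowSolution(
        ps=ps,
        r=r_all,
        p=p_all,
        u=u_all,
        J_v=j_v_all,
        J_l=j_l_all,
        Q_lu=Q_lu,
        Q_v=Q_v,
        Q_l=Q_l,
        residual=float(np.max(sol.rms_residuals)),
        p_at=p_at,
        q_at=q_at,
        options=opts,
        u_reversal=bool(np.min(u_all) < -1e-12 * max(np.max(np.abs(u_all)), 1e-30)),
    )
    if sol_out.u_reversal:
        logger.debug("sample %d: reverse flow detected", ps.sample_id)
    return sol_out


def _integrate_source(
    p_at: Callable, vasa: VasaParams, eps: float, r_ia: float, r_ap: float, r_ext: float
) -> float:
    """∫ J_v 2πr dr over the exchange region, by composite Simpson per layer."""
    total = 0.0
    for a, b in ((r_ia, r_ap), (r_ap, r_ext)):
        r = np.linspace(a, b, 2001)
        jv = starling_flux(p_at(r), vasa, eps)
        from scipy.integrate import simpson

        total += 2.0 * np.pi * float(simpson(jv * r, x=r))
    return total


# --------------------------------------------------------------------------
# luminal-origin tracer
# --------------------------------------------------------------------------


def luminal_fraction(sol: FlowSolution) -> np.ndarray:
    """Fraction ``f(r)`` of the interstitial fluid that originated at the lumen.

    A steady well-mixed tracer: lymphatics remove mixed fluid (leaving ``f``
    unchanged), vasa vasorum add pure non-luminal fluid (diluting it), which
    reduces to ``df/dr = −(J_v/u)·f`` with ``f(r_lu) = 1``.  The fraction is 1
    throughout the inner layers (no vasa there) and decays outward.  Since
    ``u → 0`` at the no-flow outer boundary while ``J_v`` stays finite, the
    dilution integral diverges logarithmically and ``f(r_ext) → 0`` whenever
    the vasa are active there.

    If the velocity crosses zero in the interior, the tracer is undefined
    beyond the stagnation radius: the profile is frozen there and the solution
    flagged (``tracer_truncated``).  Results are stored on ``sol`` (``f_r``,
    ``f``) and returned.
    """
    g = sol.ps.geometry
    n = 4000
    # cluster nodes towards the outer no-flow boundary where J_v/u blows up
    t = np.linspace(0.0, 1.0, n)
    r_sink = g.r_ia + (g.r_ext - g.r_ia) * (1.0 - (1.0 - t) ** 2)
    r_sink[-1] = g.r_ext - 1e-9 * (g.r_ext - g.r_ia)

    u = sol.u_at(r_sink)
    jv = sol.j_v_at(r_sink)

    bad = u <= 0.0
    cut = n
    if bad.any():
        cut = int(np.argmax(bad))
        if cut == 0:
            sol.tracer_truncated = True
            sol.f_r = np.concatenate(([g.r_lu], r_sink, [g.r_ext]))
            sol.f = np.ones_like(sol.f_r)
            return sol.f
        sol.tracer_truncated = True

    gdil = np.zeros_like(r_sink)
    gdil[:cut] = jv[:cut] / u[:cut]
    integral = cumulative_trapezoid(gdil[:cut], r_sink[:cut], initial=0.0)
    f_sink = np.ones_like(r_sink)
    f_sink[:cut] = np.exp(-np.clip(integral, 0.0, 700.0))
    if cut < n:
        f_sink[cut:] = f_sink[cut - 1]  # frozen past stagnation

    # boundary value: fully diluted if vasa still active at the outer wall
    f_end = 0.0 if (cut == n and jv[-1] > 0.0) else f_sink[-1]
    sol.f_r = np.concatenate(([g.r_lu], r_sink, [g.r_ext]))
    sol.f = np.concatenate(([1.0], f_sink, [f_end]))
    return sol.f


def flow_rates(sol: FlowSolution) -> tuple[float, float, float]:
    """Integrated flow rates ``(Q_lu, Q_v, Q_l)`` per unit axial length (m²·s⁻¹).

    ``Q_lu = 2π·r_lu·u(r_lu)`` across the endothelium, ``Q_v = ∫ J_v·2πr dr``
    from the vasa, ``Q_l = ∫ J_ℓ·2πr dr`` into lymphatics; the three sum to
    zero within the solver tolerance.
    """
    return sol.Q_lu, sol.Q_v, sol.Q_l


def conservation_residual(sol: FlowSolution) -> float:
    """|Q_lu + Q_v + Q_l| relative to the largest flow magnitude."""
    denom = max(abs(sol.Q_lu), abs(sol.Q_l), abs(sol.Q_v), 1e-300)
    return abs(sol.Q_lu + sol.Q_v + sol.Q_l) / denom
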