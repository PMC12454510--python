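"""Key model outputs extracted from flow and solute solutions.

These are the quantities whose healthy/atherosclerotic distributions carry
the physiological story: mid-wall interstitial velocity (comparable with
animal measurements), the pressures at the media–adventitia (EEL) and
adventitia–PVAT boundaries, the vasa-vasorum share of the wall-draining
lymph, the dilution distance of luminal fluid, the EEL concentration for
lumen-sourced solutes, the maximum adventitial gradient and the dendritic-
cell (DC–CCL19) transport distance for EEL-sourced solutes, and the
convex/accumulative classification of adventitial concentration profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .fluid import FlowSolution, starling_flux
from .solute import EEL, LUMEN, SoluteSolution
from .units import pa_to_mmhg

#: luminal-fluid fraction below which the fluid counts as diluted
DILUTION_THRESHOLD = 0.1
#: chemotactic gradient (mm⁻¹, on concentration normalised by the source)
#: below which dendritic cells no longer migrate directionally in CCL19
DC_GRADIENT_THRESHOLD_PER_MM = 0.4

CONVEX = "convex"
ACCUMULATIVE = "accumulative"
NEITHER = "neither"


@dataclass
class MetricsRecord:
    """Per-sample metrics, in reporting units (µm/s, mmHg, mm⁻¹).

    Sentinels: ``dilution_distance`` is ``inf`` when the luminal fluid never
    falls below the dilution threshold.  Solute metrics are ``nan`` until the
    corresponding transport case has been evaluated.
    """

    u_mid: float = math.nan
    p_ia: float = math.nan
    p_ap: float = math.nan
    vasa_fraction: float = math.nan
    dilution_distance: float = math.nan
    dilution_from_endothelium: float = math.nan
    dilution_frac_adventitia: float = math.nan
    c_ia: float = math.nan
    max_grad: float = math.nan
    max_grad_location: float = math.nan
    dc_distance: float = math.nan
    t_star_dc_pvat: float = math.nan
    profile_class: str = ""


# --------------------------------------------------------------------------
# flow metrics
# --------------------------------------------------------------------------


def midwall_velocity(flow: FlowSolution) -> float:
    """Interstitial velocity halfway across the inner layers (m/s)."""
    g = flow.ps.geometry
    return float(flow.u_at(g.r_lu + g.t_i / 2.0))


def boundary_pressures(flow: FlowSolution) -> tuple[float, float]:
    """(p_ia, p_ap) in mmHg: pressures at the EEL and the adventitia–PVAT border."""
    g = flow.ps.geometry
    return (
        pa_to_mmhg(float(flow.p_at(g.r_ia))),
        pa_to_mmhg(float(flow.p_at(g.r_ap))),
    )


def vasa_fraction(flow: FlowSolution) -> float:
    """Share of the lymph-drained fluid that entered through vasa vasorum.

    ``Q_v/(Q_v + Q_lu)``; by whole-tissue mass balance the denominator equals
    the total lymphatic outflow magnitude.
    """
    total = flow.Q_v + flow.Q_lu
    if total <= 0.0:
        return math.nan
    return min(max(flow.Q_v / total, 0.0), 1.0)


def dilution_distance(
    flow: FlowSolution, threshold: float = DILUTION_THRESHOLD
) -> float:
    """Radius (m, from the lumen centre) where the luminal-fluid fraction first
    drops below ``threshold``; ``inf`` if it never does.

    Linear interpolation between tracer grid points.  Requires
    :func:`periwall.fluid.luminal_fraction` to have run on ``flow``.
    """
    if flow.f is None or flow.f_r is None:
        raise ValueError("luminal fraction not computed")
    f, r = flow.f, flow.f_r
    below = f < threshold
    if not below.any():
        return math.inf
    i = int(np.argmax(below))
    if i == 0:
        return float(r[0])
    # interpolate the crossing; log-space interpolation is exact for the
    # exponential-type decay the tracer produces
    f0, f1 = f[i - 1], f[i]
    if f1 > 0.0 and f0 > 0.0:
        w = (math.log(f0) - math.log(threshold)) / (math.log(f0) - math.log(f1))
    else:
        w = (f0 - threshold) / (f0 - f1)
    return float(r[i - 1] + w * (r[i] - r[i - 1]))


def eel_concentration(sol: SoluteSolution) -> float:
    """Concentration at the EEL (normalised by the source) for a lumen-source case."""
    if sol.source != LUMEN:
        raise ValueError("EEL concentration is defined for lumen-source solutions")
    if sol.ps is None:
        raise ValueError("requires a dimensional solution")
    return float(sol.c_at(sol.ps.geometry.r_ia))


def max_adventitial_gradient(sol: SoluteSolution) -> tuple[float, float]:
    """(max |dc/dr| in mm⁻¹, its radius in m) over the adventitia, EEL source.

    The gradient comes from the collocation derivative of the solution, not
    from finite-differencing sampled output.
    """
    if sol.source != EEL:
        raise ValueError("adventitial gradient is defined for EEL-source solutions")
    g = sol.ps.geometry
    r = np.linspace(g.r_ia, g.r_ap, 2001)
    grad = np.abs(sol.dcdr_at(r))
    i = int(np.argmax(grad))
    return float(grad[i] * 1e-3), float(r[i])  # 1/m → 1/mm


def dc_transport_distance(
    sol: SoluteSolution,
    threshold_per_mm: float = DC_GRADIENT_THRESHOLD_PER_MM,
) -> tuple[float, float]:
    """(distance, t*) of the DC–CCL19 chemotactic range, EEL source.

    The distance (m) is measured outward from the adventitia–PVAT border to
    the point where |dc/dr| drops below the threshold *and stays below* for
    the rest of the domain; 0 if it is already below at the border, capped at
    the domain end if it never drops.  ``t* = distance / t_p`` normalises by
    the PVAT thickness.
    """
    if sol.source != EEL:
        raise ValueError("DC transport distance is defined for EEL-source solutions")
    g = sol.ps.geometry
    thr = threshold_per_mm * 1e3  # 1/mm → 1/m
    r = np.linspace(g.r_ap, sol.r_end, 4001)
    grad = np.abs(sol.dcdr_at(r))
    above = grad >= thr
    if not above.any():
        return 0.0, 0.0
    i_last = int(np.where(above)[0][-1])
    if i_last == r.size - 1:
        d = float(r[-1] - g.r_ap)
        return d, d / g.t_p
    # interpolate the final downward crossing
    g0, g1 = grad[i_last], grad[i_last + 1]
    w = (g0 - thr) / (g0 - g1)
    rc = r[i_last] + w * (r[i_last + 1] - r[i_last])
    d = float(rc - g.r_ap)
    return d, d / g.t_p


def classify_profile(
    sol: SoluteSolution,
    accumulation_tol: float = 1e-3,
    interior_cells: int = 2,
) -> str:
    """Classify an EEL-source adventitial profile.

    ``accumulative``: the concentration exceeds the source value (1) by more
    than ``accumulation_tol`` somewhere strictly inside the domain — advection
    has piled the solute up.  ``convex``: the profile decreases monotonically
    but its steepest gradient sits strictly inside the adventitia (more than
    ``interior_cells`` grid cells from the EEL), i.e. flat near the source and
    steep further out.  A plain monotone decay steepest at the source is
    ``neither``.
    """
    if sol.source != EEL:
        raise ValueError("profile classification is defined for EEL-source solutions")
    g = sol.ps.geometry
    r = np.linspace(g.r_ia, sol.r_end, 2001)
    c = sol.c_at(r)
    if np.max(c[1:]) > 1.0 + accumulation_tol:
        return ACCUMULATIVE
    r_adv = np.linspace(g.r_ia, g.r_ap, 2001)
    grad = np.abs(sol.dcdr_at(r_adv))
    i = int(np.argmax(grad))
    cell = (g.r_ap - g.r_ia) / (r_adv.size - 1)
    interior = r_adv[i] > g.r_ia + interior_cells * cell
    non_increasing = np.all(np.diff(c) <= accumulation_tol)
    if interior and non_increasing:
        return CONVEX
    return NEITHER


def has_interior_accumulation(sol: SoluteSolution, tol: float = 1e-3) -> bool:
    """True when the concentration exceeds its source value strictly inside the
    domain — the advection-driven pile-up that appears at Pe ≈ 5 for
    lumen-sourced solutes."""
    r = np.linspace(sol.r_source, sol.r_end, 2001)
    c = sol.c_at(r)
    return bool(np.max(c[1:]) > float(c[0]) + tol)


def global_balance_audit(flow: FlowSolution) -> float:
    """Relative residual of the whole-tissue mass conservation statement

        N_ℓ q̃_ℓ V = Q_lu + l_pv Ā_v δP̄ V

    where V is the peripheral (adventitia + PVAT) cross-sectional area per
    unit axial length and δP̄ the cross-section-weighted mean Starling driving
    pressure (clamped, as in the flux law).  Expected below 1e-6 for any
    converged solution.
    """
    ps = flow.ps
    g = ps.geometry
    V = math.pi * (g.r_ext**2 - g.r_ia**2)
    lhs = ps.lymph.sink_rate * V

    dp_bar = 0.0
    for a, b in ((g.r_ia, g.r_ap), (g.r_ap, g.r_ext)):
        r = np.linspace(a, b, 2001)
        dp = starling_flux(flow.p_at(r), ps.vasa, flow.options.starling_smoothing_eps)
        # starling_flux already includes l_pv·Ā_v; integrate the flux density
        dp_bar += 2.0 * math.pi * float(simpson(dp * r, x=r))
    rhs = flow.Q_lu + dp_bar
    return abs(lhs - rhs) / max(abs(lhs), abs(rhs), 1e-300)


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------


def flow_metrics(flow: FlowSolution) -> MetricsRecord:
    """Fill the flow-side fields of a :class:`MetricsRecord`.

    Units follow the reporting conventions: µm/s for velocity, mmHg for
    pressures.  The dilution distance is reported from the lumen centre
    (``dilution_distance``), from the endothelium
    (``dilution_from_endothelium``), and as a fraction of the adventitial
    thickness measured from the EEL (``dilution_frac_adventitia``).
    """
    g = flow.ps.geometry
    p_ia, p_ap = boundary_pressures(flow)
    rec = MetricsRecord(
        u_mid=midwall_velocity(flow) * 1e6,
        p_ia=p_ia,
        p_ap=p_ap,
        vasa_fraction=vasa_fraction(flow),
    )
    if flow.f is not None:
        d = dilution_distance(flow)
        rec.dilution_distance = d
        rec.dilution_from_endothelium = d - g.r_lu if math.isfinite(d) else math.inf
        rec.dilution_frac_adventitia = (
            (d - g.r_ia) / g.t_a if math.isfinite(d) else math.inf
        )
    return rec


def solute_metrics(rec: MetricsRecord, sol: SoluteSolution) -> MetricsRecord:
    """Fill the solute-side fields of ``rec`` from one transport solution."""
    if sol.source == LUMEN:
        rec.c_ia = eel_concentration(sol)
    else:
        rec.max_grad, rec.max_grad_location = max_adventitial_gradient(sol)
        rec.dc_distance, rec.t_star_dc_pvat = dc_transport_distance(sol)
        rec.profile_class = classify_profile(sol)
    return rec
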