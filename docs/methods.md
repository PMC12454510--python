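# Methods

## The model

`periwall` computes steady interstitial fluid flow and solute transport in a
one-dimensional (radial) model of an artery wall. The wall is a cylinder of
three concentric porous layers: the inner layers (intima + media, `Ω_i`), the
adventitia (`Ω_a`) and the perivascular adipose tissue (PVAT, `Ω_p`). The
tissue is rigid and circumferentially invariant, so all fields depend only on
the radius r.

### Fluid flow

Darcy's law with a layerwise-constant permeability,

    u = −(k(r)/μ) dp/dr,        k|_{Ω_α} = k_α,

is combined with mass conservation carrying a distributed microvascular
source and sink, active only in the adventitia and PVAT:

    (1/r) d(r u)/dr = J_v + J_ℓ.

The vasa-vasorum filtration source follows the revised Starling principle,
piecewise-linear in the trans-endothelial driving pressure,

    J_v = l_pv · Ā_v · max(δP, 0),     δP(p) = p_v − p − σ(π_t − π_v),

with the exchange-surface density approximated by the total vessel
circumference per cross-sectional area, Ā_v = N_v·π·d_v. Lymphatic drainage
is a pressure-independent volumetric sink, J_ℓ = −N_ℓ·q̃_ℓ·l̄_ℓ (l̄_ℓ = 1 by
convention). Boundary conditions: imposed pressure p = p_lu at the lumen-side
endothelium (endothelial resistance is lumped into k_i, consistent with
whole-wall conductivity measurements) and no flow at the outer PVAT (all
fluid entering the periphery is assumed to leave through its lymphatics).

The problem is solved as a first-order system in (p, q) with q = r·u the
conserved flux per radian. Each layer is mapped to the unit interval and
carries its own copy of the state, giving a six-component boundary-value
problem whose components are all smooth; continuity of p and q at the two
interfaces is enforced exactly in the boundary conditions. Collocation uses
`scipy.integrate.solve_bvp` with analytic Jacobians, internal scaling of p
and q to O(1), and a default tolerance of 1e-8. The Starling clamp is
smoothed over ε = 1e-3 mmHg (a smooth max, deviating from the exact clamp by
at most ε²/4δP away from the kink) to keep the Newton Jacobian continuous;
tests verify the ε → 0 limit. Reverse flow (u < 0) is not forbidden; it is
flagged on the solution.

**Luminal-origin tracer.** The fraction f(r) of interstitial fluid that
entered from the lumen obeys df/dr = −(J_v/u)·f with f = 1 at the lumen:
lymphatics remove mixed fluid, vasa add pure plasma. Because u → 0 at the
no-flow boundary while J_v stays finite, f → 0 logarithmically at the outer
wall whenever vasa are active there. The tracer is integrated by cumulative
quadrature on a grid clustered toward the outer boundary; where u crosses
zero the profile is frozen and flagged rather than extrapolated. The
flux-weighted lymph average of f equals Q_lu/(Q_lu+Q_v) identically, which
the tests use as an independent bookkeeping oracle.

### The mass-balance deviation Λ and parameter refinement

Most microvascular parameters of the outer wall have never been measured in
situ. The workflow reduces this uncertainty with a physiologic-plausibility
filter on the outer adventitial pressure p_ap, which in other tissues lies
between −10 and 5 mmHg. A scalar mass balance — all exchange concentrated in
the PVAT at a single test pressure p_test = −2.5 mmHg — defines the
mass-balance deviation

    Λ = N_ℓ q̃_ℓ / (G(p_test) + l_pv Ā_v δP₊(p_test)),

where G is a serial two-layer Darcy conductance times the transmural driving
pressure, normalised per PVAT volume. Λ ≈ 1 when p_test approximates the true
exchange-weighted pressure. Across an ensemble, p_ap falls almost linearly
with Λ; the preimage of the physiologic band under an ordinary-least-squares
line (statsmodels) defines the physiologic Λ interval. Refined ensembles
re-sample parameter sets from the accepted stage-1 pool, draw Λ uniformly on
the interval, and impose it by inverting the formula for q̃_ℓ — the least
literature-constrained parameter — keeping the sample's lymphatic density.

Two caveats worth knowing. First, the scalar Darcy term G carries a factor
ln(r_ap/r_lu) that the exact series-annulus conductance does not, so G
underestimates the true transmural inflow by roughly that factor (≈ 0.4 for
the default geometry). This is harmless for the pipeline — the regression
self-calibrates the Λ scale — but it means Λ at the *solved* pressure is ≈ 1
only when microvascular exchange dominates the inflow; the corresponding test
uses such a configuration. Second, the refinement presumes the near-linearity
of p_ap in Λ; parameter spreads wide enough to break that linearity (an
initial q̃_ℓ range spanning much more than a decade, or order-of-magnitude
spreads on geometry) degrade the filter's selectivity.

### Solute transport

A non-binding solute entering from the lumen or secreted at the external
elastic lamina (EEL) obeys the steady advection–diffusion equation with
first-order microvascular uptake,

    (D/r) d/dr(r dc/dr) − d/dr(u c) − (J_v + κ_v Ā_v) c + J_ℓ c = 0,

with c = c₀ at the source radius and zero diffusive flux one PVAT thickness
beyond the outer PVAT: solutes keep diffusing past the end of the fluid
domain, so the solute domain is extended by t_p with u = 0 and sink
coefficients frozen at their outer-PVAT values (switchable to "off"; the
lymphatic uptake term in the extension is likewise flag-controlled, default
on). The advection term is the non-conservative d(uc)/dr form written above —
its deceleration term −u′c is exactly the mechanism that piles solute up near
the EEL at Pe ≳ 4. The κ_v Ā_v diffusive uptake stays active regardless of
the sign of δP, since it is independent of filtration. The equation is linear
in c and is solved by the same stacked-region collocation machinery; velocity
and pressure coefficients enter through per-layer C² resamplings (cubic
splines on 400 points per layer) of the converged flow, because the raw
collocation interpolants are only C¹ and their derivative kinks stall the
mesh refinement of the downstream problem.

Non-dimensionalising with r* = r/(t_a+t_p) and u* = u/[(k_i/μ)(p_lu/t_i)]
gives

    (1/r) d/dr(r dc/dr) − Pe d/dr(u c) − [Da_v δP(p)/δP(0) + R_d + Da_ℓ] c = 0

with Pe = (k_i/μ)(p_lu/t_i)(t_a+t_p)/D, Da_v = l_pv Ā_v δP(0)(t_a+t_p)²/D,
Da_ℓ = N_ℓ q̃_ℓ (t_a+t_p)²/D and R_d = κ_v Ā_v (t_a+t_p)²/D. The starred
solver is an independent assembly of this form (it reconstructs the velocity
divergence from the starred continuity equation rather than receiving it);
agreement with the rescaled dimensional solution to better than 1e-8 is an
acceptance property.

### Outputs

Per configuration the package reports: mid-wall velocity (µm/s; comparable
with animal measurements, 0.025–0.055 µm/s), the EEL and outer-adventitial
pressures (mmHg), the vasa share of lymph Q_v/(Q_v+Q_lu), the 10 %-dilution
distance of luminal fluid (from the lumen centre, from the endothelium, and
as a fraction of the adventitial thickness — both conventions exported
because both are in use), the EEL concentration for lumen sources, the
maximum adventitial gradient (mm⁻¹ on normalised concentration) for EEL
sources, the DC–CCL19 transport distance (outward from the adventitia–PVAT
border, to where the gradient drops below 0.4 mm⁻¹ and stays below), and a
convex/accumulative/neither classification of EEL-source profiles
(accumulative: interior maximum above the source value by > 1e-3;
convex: non-increasing with the steepest gradient more than two grid cells
inside the adventitia; both tolerances exposed). A whole-tissue audit checks
N_ℓ q̃_ℓ V = Q_lu + l_pv Ā_v δP̄ V with δP̄ the cross-section-weighted mean
clamped driving pressure; it holds to < 1e-6 on every converged solution.

## The default configuration (synthetic-data generator)

The Monte-Carlo machinery needs distributions for every parameter.
`data/defaults.yaml` ships a documented stand-in for a human coronary wall,
assembled from values reported in the modelling literature this package
follows (selected-case permeabilities k_i ∈ {0.6, 1.5}·10⁻¹⁸ m² healthy with
disease factors ≈ 1.9–2; drainage rates q̃_ℓ ≈ 0.8–1.5·10⁻¹¹ m²/s healthy;
capillary diameter 10 µm; luminal pressure 100 mmHg; healthy lymph sink
≈ 3·10⁻⁵ s⁻¹ rising to ≈ 7·10⁻⁵ s⁻¹ in disease) and standard microvascular
physiology for the Starling pressures. Where only orders of magnitude are
known the distribution is log-uniform; where a mean and reproducibility are
defensible it is Gaussian with ~10 % spread. The free choices were set so the
generator reproduces the reported ensemble behaviour of the healthy wall —
the near-linear p_ap–Λ relation (r² ≈ 0.95 reported, ≈ 0.98 here), its
interval geometry (≈ 20–40 mmHg per unit Λ), the 40–80 % vasa share of
lymph, the measured mid-wall velocity range, and the ~3·10⁻⁵ s⁻¹ healthy
sink — and were frozen thereafter. Atherosclerotic factors multiply a healthy
draw: thicker inner layers (×2–3) and adventitia (×1.2–1.8), more permeable
inner layers (×1.6–2.1), denser/leakier vasa (×1.8–3.2 each), denser but
individually slower lymphatics (N_ℓ ×3–4, q̃_ℓ ×0.4–0.9).

What the generator does *not* emulate: the unavailable site-specific
literature distributions behind the published ensembles (so exact interval
endpoints and tail fractions differ), any correlation between parameters in a
healthy draw, plaque-type dependence, axial/circumferential heterogeneity,
and measurement error structure. Passing ensemble tests therefore demonstrate
the workflow's internal consistency and the mechanisms' direction and rough
magnitude, not a site-calibrated prediction for real vessels.

## Numerical choices

- Flow BVP: tolerance 1e-8 (relative residual), bc tolerance 1e-10, initial
  mesh 41 nodes/layer, node budget 5e4. Typical solve ≈ 5–10 ms.
- Solute BVP: same machinery, one linear pass; ensemble runs use 1e-6.
- Integrals (flow rates, audits) by composite Simpson on ≥ 2001 points per
  layer evaluated through the collocation interpolants.
- The dilution-distance crossing interpolates log f linearly (exact for
  exponential decay); the DC-distance crossing interpolates the gradient
  linearly and takes the *last* downward crossing, so transient dips do not
  truncate the range.
- Degenerate inputs: zero vasa and lymph densities are legal (the flow field
  is identically zero and the tracer is 1 everywhere); a non-positive Λ
  denominator, an increasing p_ap–Λ relation, or an empty refined interval
  raise typed errors rather than returning nonsense.
- Seeding: every ensemble derives per-sample `numpy` SeedSequence children,
  so sample i is reproducible independently of the ensemble size, and
  healthy/atherosclerotic stage-2 runs use disjoint streams.

## Ensemble sizes

Stage 1 uses 1000 samples and stage 2 600 samples per condition in the
acceptance script, and 600/2000 in the ensemble self-consistency test; these
sizes put Monte-Carlo errors on reported fractions near one to two percentage
points, which is below the spread induced by the stand-in distributions.

## Known limitations

- One-dimensional, rigid, steady: no pulsatility, compliance,
  deformation-enhanced transport, or axial variation.
- No matrix binding or receptor kinetics: transport-limited penetration only.
- The extension region beyond the outer PVAT has no fluid model; its sink
  coefficients are frozen (an explicit least-assumption choice, switchable).
- The scalar Λ statistic inherits its published form's conservative Darcy
  term (see above); comparisons of Λ across packages should use the formula,
  not a series-conductance re-derivation.
- With the stand-in distributions, the refined healthy ensemble places ≈ 84 %
  of outer-adventitial pressures in the physiologic band (reported: ≈ 90 %),
  and disease-state tail fractions (e.g. pressures above 10 mmHg) run higher
  than reported; both are consequences of residual parameter scatter that
  site-specific literature distributions would pin down.
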