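# Default parameter distributions for a human coronary artery wall.
#
# Units in this file: lengths in µm, pressures in mmHg, everything else SI.
# Every leaf is either a scalar (fixed) or {kind: gaussian|uniform|loguniform, ...}.
#
# Provenance key:
#   [reported]   value printed in the modelling literature this package follows
#                (selected-case permeabilities and drainage rates, capillary
#                diameter, luminal pressure, measured mid-wall velocity range)
#   [physiology] standard microvascular physiology (Starling pressures)
#   [assumed]    plausible stand-in chosen where no site-specific distribution
#                is published; substitute via a user config when better
#                distributions are at hand.  Gaussian where a mean and spread
#                are defensible, log-uniform where only an order-of-magnitude
#                range is.

geometry:
  # Coronary lumen radius ~1.5 mm; layer thicknesses ~0.4 mm each.  Spreads of
  # ~10 % reflect measurement reproducibility within one vascular site; wider
  # spreads destroy the near-linear pressure response to the mass-balance
  # deviation that the refinement stage relies on. [reported]/[assumed]
  r_lu: {kind: gaussian, mean: 1500.0, sd: 150.0}
  t_i:  {kind: gaussian, mean: 400.0, sd: 40.0}
  t_a:  {kind: gaussian, mean: 400.0, sd: 40.0}
  # Epicardial/perivascular fat is thicker than the wall layers proper; its
  # thickness sets the volume over which transmural inflow is distributed and
  # is chosen, with l_pv below, so the healthy ensemble's lymphatic sink
  # settles near the reported 3e-5 s^-1 average. [assumed]/[reported]
  t_p:  {kind: gaussian, mean: 900.0, sd: 90.0}

tissue:
  # Inner-layer (intima+media) Darcy permeability, m². Selected healthy cases
  # use 0.6e-18 and 1.5e-18 m²; the mean sits between them. [reported]
  k_i: {kind: gaussian, mean: 1.05e-18, sd: 0.2e-18}
  # Adventitial permeability ~100x the inner layers (loose connective tissue).
  # The spread is kept to a factor of two either side of 1e-16 m²: wider
  # spreads make the adventitial pressure drop scatter so much that the
  # near-linear pressure response to the mass-balance deviation — the premise
  # of the refinement stage — degrades. [assumed]
  k_a: {kind: loguniform, low: 5.0e-17, high: 2.0e-16}
  # k_p deliberately absent: PVAT permeability defaults to k_a (its resistance
  # is secondary on the transwall path).
  # Interstitial fluid dynamic viscosity, Pa·s. [physiology]
  mu: 1.0e-3

vasa:
  # Capillary endothelial hydraulic conductivity, m/(Pa·s); order 1e-12 for
  # continuous capillaries.  The range is set so that, at physiologic tissue
  # pressure, vasa vasorum supply the reported 40-80% share of the
  # wall-draining lymph while the total healthy sink stays near the reported
  # 3e-5 s^-1. [assumed]/[reported]
  l_pv: {kind: loguniform, low: 1.0e-12, high: 2.0e-12}
  # Vasa vasorum count per cross-sectional area, m⁻² (100 vessels/mm²). [assumed]
  N_v: {kind: gaussian, mean: 1.0e8, sd: 1.5e7}
  # Capillary diameter, µm. [reported]
  d_v: 10.0
  # Starling pressures are tightly regulated; their spreads are kept small.
  # Vasa luminal hydrostatic pressure, mmHg.  Adventitial vasa vasorum are
  # venular-side microvessels; the value is chosen at the low end of the
  # capillary range so that, together with l_pv, the pressure response to the
  # mass-balance deviation reproduces the reported interval geometry
  # (a ~20 mmHg pressure change per unit deviation). [physiology]/[reported]
  p_v: {kind: gaussian, mean: 15.0, sd: 1.5}
  # Plasma colloid osmotic pressure, mmHg. [physiology]
  pi_v: {kind: gaussian, mean: 25.0, sd: 1.0}
  # Tissue colloid osmotic pressure, mmHg. [physiology]
  pi_t: {kind: gaussian, mean: 10.0, sd: 1.0}
  # Osmotic reflection coefficient of the vasa endothelium. [physiology]
  sigma: {kind: uniform, low: 0.8, high: 0.95}
  # Solute diffusive permeability, m/s; set per solute from the target R_d in
  # transport runs, so the fluid-model default is 0.
  kappa_v: 0.0

lymph:
  # Lymphatic vessel count per cross-sectional area, m⁻² (3 vessels/mm²),
  # chosen with q̃_ℓ so the mean volumetric sink N_ℓ·q̃_ℓ is near the healthy
  # average of 3e-5 s⁻¹. [assumed]/[reported]
  N_l: {kind: gaussian, mean: 3.0e6, sd: 3.6e5}
  # Drainage flux per unit vessel length, m²/s. Selected healthy cases use
  # 0.8e-11 and 1.5e-11 m²/s; the initial (stage-1) range spans roughly a
  # factor of three either side because this is the least-constrained
  # parameter — it must straddle the physiologic band while keeping the
  # pressure response in its near-linear regime, and the refinement stage
  # replaces it via the mass-balance deviation. [reported]/[assumed]
  q_tilde_l: {kind: loguniform, low: 5.0e-12, high: 4.0e-11}
  # Vessel length per unit radial thickness, conventionally 1.
  l_bar_l: 1.0

boundary:
  # Luminal (systemic) pressure, mmHg. [reported]
  p_lu: {kind: gaussian, mean: 100.0, sd: 5.0}

# Multiplicative factors turning a healthy draw into an atherosclerotic one.
# Directions follow the reported remodelling: thicker inner layers and
# adventitia, more permeable inner layers, denser and more conductive vasa
# vasorum, denser but individually slower-draining lymphatics.
athero_factors:
  # Intimal thickening by plaque more than doubles the inner layers; together
  # with the permeability rise this reproduces the reported one-third drop in
  # inner-layer velocity. [assumed]/[reported]
  geometry.t_i: {kind: uniform, low: 2.0, high: 3.0}
  geometry.t_a: {kind: uniform, low: 1.2, high: 1.8}
  # Selected cases imply k_i ratios of ~1.87 (1.5→2.8e-18) and 2 (0.6→1.2e-18).
  # [reported]
  tissue.k_i: {kind: uniform, low: 1.6, high: 2.1}
  # Denser and leakier vasa (neovascularisation): the per-pressure conductance
  # l_pv·N_v must rise considerably more than the net lymphatic outflow for
  # tissue pressure to climb, which is the reported mechanism of the
  # adventitial pressure elevation. [reported]
  vasa.N_v: {kind: uniform, low: 1.8, high: 3.2}
  vasa.l_pv: {kind: uniform, low: 1.8, high: 3.2}
  # Net lymph sink rises from ~3e-5 to ~7e-5 s⁻¹ (factor ~2.3) as the product
  # of denser vessels and a lower per-vessel rate; per-vessel ratios of the
  # selected cases are 0.67 (1.5→1e-11) and 0.25 (0.8→0.2e-11). [reported]
  lymph.N_l: {kind: uniform, low: 3.0, high: 4.0}
  lymph.q_tilde_l: {kind: uniform, low: 0.4, high: 0.9}
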