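"""Healthy versus atherosclerotic peri-arterial fluid balance.

Runs the full two-stage workflow at a small ensemble size: stage-1 Λ
refinement, then refined healthy and atherosclerotic ensembles (flow and
tracer only), and prints the headline comparison — outer adventitial
pressure, inner-layer velocity, the vasa-vasorum share of the lymph and the
dilution of lumen-derived fluid.
"""

from periwall import (
    EnsembleConfig,
    load_distributions,
    run_initial_ensemble,
    run_refined_ensemble,
)

registry = load_distributions()
cfg = EnsembleConfig(n_samples=400, seed=7)
res1, ctx = run_initial_ensemble(registry, cfg)
healthy = run_refined_ensemble(
    cfg, ctx, res1.pool, condition="healthy", n_samples=250, with_solute=False
)
athero = run_refined_ensemble(
    cfg, ctx, res1.pool, condition="atherosclerotic", registry=registry,
    n_samples=250, with_solute=False,
)

h, a = healthy.ok, athero.ok
print(f"{'quantity':42s} {'healthy':>12s} {'athero':>12s}")
print(f"{'outer adventitial pressure (mmHg)':42s} {h.p_ap_mmhg.mean():9.1f} +/- {h.p_ap_mmhg.std():4.1f} {a.p_ap_mmhg.mean():6.1f} +/- {a.p_ap_mmhg.std():4.1f}")
print(f"{'fraction with positive p_ap':42s} {(h.p_ap_mmhg > 0).mean():12.2f} {(a.p_ap_mmhg > 0).mean():12.2f}")
print(f"{'mid-wall velocity (um/s)':42s} {h.u_mid_um_s.mean():12.3f} {a.u_mid_um_s.mean():12.3f}")
print(f"{'vasa share of lymph (median)':42s} {h.vasa_fraction.median():12.2f} {a.vasa_fraction.median():12.2f}")
print(f"{'lymph sink rate (1e-5/s)':42s} {h.sink_rate.mean() * 1e5:12.2f} {a.sink_rate.mean() * 1e5:12.2f}")
print(f"{'dilution within adventitia (fraction)':42s} {(h.dilution_frac_adventitia < 1).mean():12.2f} {(a.dilution_frac_adventitia < 1).mean():12.2f}")

# Disease raises the lymphatic outflow and, even more, the vasa conductance;
# mass balance then forces tissue pressure up and floods the periphery with
# plasma of microvascular origin, so lumen-derived fluid is diluted to below
# 10 % before it leaves the adventitia.
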