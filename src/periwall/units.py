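"""Unit conventions.

Everything inside the package is SI (m, s, Pa, kg). Config files and a few
reporting surfaces use the field's customary units instead: mmHg for pressures,
micrometres for capillary-scale lengths, µm/s for interstitial velocities and
mm⁻¹ for normalised concentration gradients. Conversion happens at the edges.
"""

from __future__ import annotations

#: Pa per mmHg, fixed exactly.
MMHG = 133.322

#: metres per micrometre
UM = 1e-6


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG


def um_to_m(x_um: float) -> float:
    return x_um * UM


def m_to_um(x_m: float) -> float:
    return x_m / UM
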