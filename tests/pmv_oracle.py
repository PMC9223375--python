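"""Independent PMV reference for parity testing.

Solves the Fanger clothing-surface heat balance directly with bracketing
root-finding (scipy brentq) instead of the package's damped fixed-point
iteration, and assembles the heat-loss terms in their unscaled physical form.
Kept deliberately separate from the package implementation so the two routes
share only the published equation set.
"""

import math

from scipy.optimize import brentq


def pmv_reference(ta, tr, vr, rh, met, clo):
    pa = rh / 100.0 * 1000.0 * math.exp(16.6536 - 4030.183 / (ta + 235.0))
    icl = 0.155 * clo
    m = met * 58.15
    fcl = 1.0 + 1.29 * icl if icl <= 0.078 else 1.05 + 0.645 * icl
    hcf = 12.1 * math.sqrt(vr)

    def hc(tcl):
        return max(hcf, 2.38 * abs(tcl - ta) ** 0.25)

    def balance(tcl):
        # clothing surface equilibrium: skin-side supply equals losses
        rad = 3.96e-8 * fcl * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4)
        conv = fcl * hc(tcl) * (tcl - ta)
        return (35.7 - 0.028 * m) - tcl - icl * (rad + conv)

    tcl = brentq(balance, -60.0, 150.0, xtol=1e-10)

    rad = 3.96e-8 * fcl * ((tcl + 273.0) ** 4 - (tr + 273.0) ** 4)
    conv = fcl * hc(tcl) * (tcl - ta)
    diffusion = 3.05e-3 * (5733.0 - 6.99 * m - pa)
    sweat = 0.42 * (m - 58.15) if m > 58.15 else 0.0
    resp_latent = 1.7e-5 * m * (5867.0 - pa)
    resp_dry = 0.0014 * m * (34.0 - ta)
    load = m - diffusion - sweat - resp_latent - resp_dry - rad - conv
    return (0.303 * math.exp(-0.036 * m) + 0.028) * load
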