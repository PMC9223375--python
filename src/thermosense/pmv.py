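"""Fanger predicted mean vote (PMV), implemented from the heat-balance
equation set standardized in ISO 7730.

PMV maps six inputs -- air temperature, mean radiant temperature, relative
air speed, relative humidity, metabolic rate and clothing insulation -- to a
predicted mean thermal sensation on the -3..+3 scale.  The only implicit
quantity is the clothing surface temperature t_cl, solved here by the damped
fixed-point iteration of the standard (tolerance 1e-4 degC, max 150 steps).

Values are deliberately NOT clipped to +-3: comparison metrics elsewhere in
the package score the raw index, since clipping would silently shrink the
baseline's error on extreme conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class PMVInput:
    """The six Fanger parameters."""

    ta: float  # air temperature, degC
    tr: float  # mean radiant temperature, degC
    vr: float  # relative air speed, m/s
    rh: float  # relative humidity, %
    met: float  # metabolic rate, met (1 met = 58.15 W/m^2)
    clo: float  # clothing insulation, clo (1 clo = 0.155 m^2.K/W)

    def __post_init__(self):
        if self.met <= 0:
            raise ValueError("met must be positive")
        if self.clo < 0:
            raise ValueError("clo must be non-negative")
        if self.vr < 0:
            raise ValueError("vr must be non-negative")
        if not 0 <= self.rh <= 100:
            raise ValueError("rh must be in [0, 100] %")


@dataclass(frozen=True)
class PMVResult:
    pmv: float
    t_cl: float  # clothing surface temperature, degC
    iterations: int
    residual: float  # |t_cl update| at exit, degC

    def __float__(self):
        return self.pmv


_VALIDITY = {  # standard applicability ranges, checked with a warning only
    "ta": (10.0, 30.0),
    "tr": (10.0, 40.0),
    "vr": (0.0, 1.0),
    "met": (0.8, 4.0),
    "clo": (0.0, 2.0),
}


def saturation_vapour_pressure(ta: float) -> float:
    """Saturation water-vapour pressure in Pa at air temperature ta (degC),
    using the exponential fit of the ISO 7730 equation set."""
    return math.exp(16.6536 - 4030.183 / (ta + 235.0)) * 1000.0


def pmv(
    inp: PMVInput,
    tol: float = 1e-4,
    max_iter: int = 150,
) -> PMVResult:
    """Solve the heat balance and return the PMV index.

    Raises ``RuntimeError`` with the residual if the clothing-temperature
    iteration fails to converge.
    """
    for name, (lo, hi) in _VALIDITY.items():
        v = getattr(inp, name)
        if not lo <= v <= hi:
            warnings.warn(
                f"PMV input {name}={v:g} outside the standard validity range [{lo}, {hi}]"
            )

    pa = inp.rh / 100.0 * saturation_vapour_pressure(inp.ta)
    icl = 0.155 * inp.clo  # m^2.K/W
    m = inp.met * 58.15  # W/m^2
    w = 0.0  # external work, zero for the sedentary case
    mw = m - w

    fcl = 1.0 + 1.29 * icl if icl <= 0.078 else 1.05 + 0.645 * icl
    hcf = 12.1 * math.sqrt(inp.vr)
    taa = inp.ta + 273.0
    tra = inp.tr + 273.0

    # damped fixed point on the clothing surface temperature (in units of
    # 100 K to keep the quartic radiation term well scaled)
    tcla = taa + (35.5 - inp.ta) / (3.5 * icl + 0.1)
    p1 = icl * fcl
    p2 = p1 * 3.96
    p3 = p1 * 100.0
    p4 = p1 * taa
    p5 = 308.7 - 0.028 * mw + p2 * (tra / 100.0) ** 4

    xn = tcla / 100.0
    xf = tcla / 50.0
    eps = tol / 100.0  # tolerance expressed on the scaled variable
    hc = hcf
    n = 0
    while abs(xn - xf) > eps:
        n += 1
        if n > max_iter:
            raise RuntimeError(
                f"clothing-temperature iteration did not converge in {max_iter} "
                f"steps (residual {abs(xn - xf) * 100:.2e} degC)"
            )
        xf = (xf + xn) / 2.0
        hcn = 2.38 * abs(100.0 * xf - taa) ** 0.25
        hc = max(hcf, hcn)
        xn = (p5 + p4 * hc - p2 * xf**4) / (100.0 + p3 * hc)
    tcl = 100.0 * xn - 273.0

    hl1 = 3.05e-3 * (5733.0 - 6.99 * mw - pa)  # skin diffusion
    hl2 = 0.42 * (mw - 58.15) if mw > 58.15 else 0.0  # sweating
    hl3 = 1.7e-5 * m * (5867.0 - pa)  # latent respiration
    hl4 = 0.0014 * m * (34.0 - inp.ta)  # dry respiration
    hl5 = 3.96 * fcl * (xn**4 - (tra / 100.0) ** 4)  # radiation
    hl6 = fcl * hc * (tcl - inp.ta)  # convection

    ts = 0.303 * math.exp(-0.036 * m) + 0.028
    value = ts * (mw - hl1 - hl2 - hl3 - hl4 - hl5 - hl6)
    return PMVResult(pmv=value, t_cl=tcl, iterations=n, residual=abs(xn - xf) * 100.0)


def pmv_for_trial(
    env_temp: float,
    rh: float,
    wind_speed: float,
    met: float = 1.0,
    clo: float = 0.5,
    tr: float | None = None,
) -> float:
    """PMV under the study conventions: mean radiant temperature equal to air
    temperature (uniform chamber), 1.0 met seated, 0.5 clo summer clothing."""
    return pmv(
        PMVInput(
            ta=env_temp,
            tr=env_temp if tr is None else tr,
            vr=wind_speed,
            rh=rh,
            met=met,
            clo=clo,
        )
    ).pmv


def add_pmv_column(
    table: pd.DataFrame, met: float = 1.0, clo: float = 0.5
) -> pd.DataFrame:
    """Return a copy of a feature table with a ``pmv`` column computed from
    its EnvTemp / EnvRH / EnvWind columns."""
    out = table.copy()
    out["pmv"] = [
        pmv_for_trial(row["EnvTemp"], row["EnvRH"], row["EnvWind"], met=met, clo=clo)
        for _, row in table.iterrows()
    ]
    return out
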