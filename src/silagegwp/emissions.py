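"""Stoichiometric CO2e emission terms for one silage fermentation profile.

The model partitions silage dry matter loss into three CO2e fractions:

* ``C_M`` — direct CO2 from the decarboxylation of pyruvate during the
  fermentation of hexose sugars to acetic acid, ethanol and minor VOC;
* ``C_O`` — CO2e of tropospheric ozone formed from evaporated VOC, on a
  20-year (``C_O20``) or 100-year (``C_O100``) horizon;
* ``C_R`` — CO2 from respiration, inferred as a residual after subtracting
  glycolytic mass loss, metabolic CO2 and volatilized mass from measured dry
  matter loss. A negative ``C_R`` means less mass was lost than fermentation
  stoichiometry requires and is interpreted as CO2 recycling by the silage
  microbiome, not clamped.

Total CO2e on either horizon is the plain sum ``GWP = C_M + C_O + C_R``.
All computation is in mg per kg of silage dry matter; percentage-of-DM
values are converted only at I/O boundaries. Every term function accepts
scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, MG_PER_KG_PER_PERCENT, ModelConstants

__all__ = [
    "FermentationProfile",
    "EmissionBreakdown",
    "metabolic_co2",
    "ozone_co2e",
    "pyruvate_mass_loss",
    "volatile_mass",
    "respired_co2",
    "co2e_total",
    "linear_gwp",
    "percent_to_mgkg",
    "mgkg_to_percent",
    "compute_breakdowns",
]


def percent_to_mgkg(x):
    """Convert a %-of-DM value to mg per kg DM (multiply by 1e4)."""
    return np.asarray(x, dtype=float) * MG_PER_KG_PER_PERCENT if np.ndim(x) else float(x) * MG_PER_KG_PER_PERCENT


def mgkg_to_percent(x):
    """Convert mg per kg DM to % of DM (divide by 1e4)."""
    return np.asarray(x, dtype=float) / MG_PER_KG_PER_PERCENT if np.ndim(x) else float(x) / MG_PER_KG_PER_PERCENT


@dataclass
class FermentationProfile:
    """Metabolite and loss measures of one silage sample, mg per kg DM.

    ``dml`` is oven dry matter loss; ``vcdml`` is volatile-corrected dry
    matter loss (may legitimately be negative). At least one of the two is
    required before respiration CO2 can be computed.
    """

    acetic: float
    ethanol: float
    lactic: float
    ammonia: float | None = None
    dml: float | None = None
    vcdml: float | None = None
    sample_id: str = ""
    imputed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("acetic", "ethanol", "lactic", "ammonia"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id or 'profile'}: {name} must be nonnegative, got {v}")


@dataclass
class EmissionBreakdown:
    """All emission terms for one profile, mg (CO2e) per kg DM."""

    c_m: float
    c_o20: float
    c_o100: float
    p: float
    v: float
    c_r: float
    gwp20: float
    gwp100: float
    dml_pathway: str  # "vcdml" or "oven"

    def as_dict(self) -> dict:
        return {
            "c_m": self.c_m, "c_o20": self.c_o20, "c_o100": self.c_o100,
            "p": self.p, "v": self.v, "c_r": self.c_r,
            "gwp20": self.gwp20, "gwp100": self.gwp100,
            "dml_pathway": self.dml_pathway,
        }


def _check_nonneg(**kwargs) -> None:
    for name, v in kwargs.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be nonnegative")


def metabolic_co2(acetic, ethanol, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Direct fermentation CO2 (C_M), mg per kg DM.

    Stoichiometric CO2 from fermenting hexose to acetic acid, ethanol and
    minor VOC (the latter at their mean reported concentration constant),
    scaled by the hexose fraction of fermentable sugars. The default
    grouping applies the hexose fraction to the minor-VOC constant too; set
    ``constants.hexose_scales_minor_constant=False`` for the alternative.
    """
    _check_nonneg(acetic=acetic, ethanol=ethanol)
    c = constants
    metabolite = acetic * c.m_co2 / c.m_acetic + ethanol * c.m_co2 / c.m_ethanol
    if c.hexose_scales_minor_constant:
        return c.hexose_fraction * (metabolite + c.minor_voc_cdmp)
    return c.hexose_fraction * metabolite + c.minor_voc_cdmp


def ozone_co2e(acetic, ethanol, horizon: int, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Ozone-mediated CO2e of evaporated VOC (C_O), mg CO2e per kg DM.

    Evaporated fractions of acetic acid and ethanol form tropospheric ozone
    in proportion to their incremental reactivity; the ozone is weighted by
    its amortized CO2e multiplier for the horizon. Minor VOC contribute a
    constant (6.2e3 on 20 years, 1.3e3 on 100 years).
    """
    _check_nonneg(acetic=acetic, ethanol=ethanol)
    c = constants
    o3 = (acetic * c.volatility_acetic * c.ebir_acetic
          + ethanol * c.volatility_ethanol * c.ebir_ethanol)
    return c.minor_voc_gwp(horizon) + c.ozone_gwp(horizon) * o3


def pyruvate_mass_loss(lactic, acetic, ethanol, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Mass lost in glycolysis to pyruvate (P), mg per kg DM.

    Each mol of pyruvate formed sheds 3 g in glycolysis; the pyruvate demand
    is the molar sum of lactic acid, acetic acid, ethanol (mg/kg over g/mol
    gives mmol/kg) plus the minor-VOC constant of 99.2 mmol/kg, scaled by
    the hexose fraction.
    """
    _check_nonneg(lactic=lactic, acetic=acetic, ethanol=ethanol)
    c = constants
    mmol = (lactic / c.m_lactic + acetic / c.m_acetic + ethanol / c.m_ethanol
            + c.minor_voc_pyruvate_mmol)
    return c.hexose_fraction * c.glycolysis_loss * mmol


def volatile_mass(acetic, ethanol, lactic, ammonia, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Mass of volatiles lost during oven drying (V), mg per kg DM.

    Applies the 60 degC volatility coefficients to the four measured
    analytes and adds the minor-VOC mass constant (assumed fully volatile).
    """
    _check_nonneg(acetic=acetic, ethanol=ethanol, lactic=lactic, ammonia=ammonia)
    c = constants
    return (c.volatility_acetic * acetic + c.volatility_ethanol * ethanol
            + c.volatility_ammonia * ammonia + c.volatility_lactic * lactic
            + c.minor_voc_mass)


def respired_co2(dml, p, c_m, subtrahend, constants: ModelConstants = DEFAULT_CONSTANTS):
    """Respiration CO2 (C_R), mg per kg DM; negative values are meaningful.

    The residual dry matter loss not explained by glycolysis (``p``),
    metabolic CO2 (``c_m``) and volatilization (``subtrahend``) is treated
    as respired glucose and converted to CO2 by 6 * 44.01 / 180.156.

    ``subtrahend`` is the full volatile mass V when ``dml`` is oven dry
    matter loss, or the minor-VOC constant 6.2e3 when ``dml`` is already
    volatile-corrected.
    """
    return constants.respiration_factor * (np.asarray(dml, dtype=float) - p - c_m - subtrahend)


def co2e_total(profile: FermentationProfile,
               constants: ModelConstants = DEFAULT_CONSTANTS,
               prefer: str = "vcdml") -> EmissionBreakdown:
    """Evaluate every emission term for one profile.

    Uses the volatile-corrected pathway when ``vcdml`` is present (or
    ``prefer="oven"`` forces oven DML, which additionally requires ammonia
    for the volatile-mass term). GWP20 and GWP100 are exact sums of their
    three components.
    """
    c_m = metabolic_co2(profile.acetic, profile.ethanol, constants)
    c_o20 = ozone_co2e(profile.acetic, profile.ethanol, 20, constants)
    c_o100 = ozone_co2e(profile.acetic, profile.ethanol, 100, constants)
    p = pyruvate_mass_loss(profile.lactic, profile.acetic, profile.ethanol, constants)

    use_vcdml = profile.vcdml is not None and not (prefer == "oven" and profile.dml is not None)
    if use_vcdml:
        v = float("nan")
        c_r = respired_co2(profile.vcdml, p, c_m, constants.minor_voc_mass, constants)
        pathway = "vcdml"
    elif profile.dml is not None:
        if profile.ammonia is None:
            raise ValueError("ammonia is required for the oven-DML pathway")
        v = volatile_mass(profile.acetic, profile.ethanol, profile.lactic, profile.ammonia, constants)
        c_r = respired_co2(profile.dml, p, c_m, v, constants)
        pathway = "oven"
    else:
        raise ValueError("profile needs dml or vcdml to compute respiration CO2")

    return EmissionBreakdown(
        c_m=float(c_m), c_o20=float(c_o20), c_o100=float(c_o100),
        p=float(p), v=float(v), c_r=float(c_r),
        gwp20=float(c_m + c_o20 + c_r), gwp100=float(c_m + c_o100 + c_r),
        dml_pathway=pathway,
    )


def linear_gwp(acetic, ethanol, lactic, vcdml, coefficients):
    """Evaluate a linear surrogate GWP equation, mg CO2e per kg DM.

    ``coefficients`` is any object with ``intercept``, ``slope_a``,
    ``slope_e``, ``slope_l``, ``slope_dv`` attributes (and optionally
    ``slope_n``, applied to nothing here since ammonia does not enter the
    volatile-corrected surrogate). Inputs are mg per kg DM.
    """
    if vcdml is None:
        raise ValueError("linear surrogate requires volatile-corrected dry matter loss")
    return (coefficients.intercept
            + coefficients.slope_a * np.asarray(acetic, dtype=float)
            + coefficients.slope_e * np.asarray(ethanol, dtype=float)
            + coefficients.slope_l * np.asarray(lactic, dtype=float)
            + coefficients.slope_dv * np.asarray(vcdml, dtype=float))


def compute_breakdowns(frame: pd.DataFrame,
                       constants: ModelConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Vectorized breakdown over a profile table in mg per kg DM.

    ``frame`` needs columns acetic, ethanol, lactic and vcdml (volatile-
    corrected pathway) and may carry ammonia and dml. Returns a copy with
    c_m, c_o20, c_o100, p, c_r, gwp20 and gwp100 columns appended.
    """
    out = frame.copy()
    a = out["acetic"].to_numpy(float)
    e = out["ethanol"].to_numpy(float)
    l = out["lactic"].to_numpy(float)
    dv = out["vcdml"].to_numpy(float)
    c_m = metabolic_co2(a, e, constants)
    p = pyruvate_mass_loss(l, a, e, constants)
    c_r = respired_co2(dv, p, c_m, constants.minor_voc_mass, constants)
    out["c_m"] = c_m
    out["c_o20"] = ozone_co2e(a, e, 20, constants)
    out["c_o100"] = ozone_co2e(a, e, 100, constants)
    out["p"] = p
    out["c_r"] = c_r
    out["gwp20"] = out["c_m"] + out["c_o20"] + out["c_r"]
    out["gwp100"] = out["c_m"] + out["c_o100"] + out["c_r"]
    return out
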