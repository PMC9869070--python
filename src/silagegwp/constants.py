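"""Model constants for the silage fermentation CO2e equations.

All masses are in g/mol; all concentration-like constants are in mg per kg of
silage dry matter (ppm of DM) unless noted. The minor-VOC aggregate constants
are the published 2-significant-figure values that the emission equations
consume; recomputed variants (from the packaged compound table) are available
through :func:`silagegwp.voc_reference.minor_voc_aggregates` for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MOLAR_MASS_CO2 = 44.01
MOLAR_MASS_ACETIC = 60.05
MOLAR_MASS_ETHANOL = 46.07
#: Lactic acid molar mass; together with the respiration factor it fixes the
#: lactic-acid slope of the linear surrogate at -1.46573 * 1.95 / 90.08.
MOLAR_MASS_LACTIC = 90.08
MOLAR_MASS_GLUCOSE = 180.156

#: Mass lost per mole of pyruvate formed in glycolysis, g/mol.
GLYCOLYSIS_LOSS = 3.0
#: Fraction of fermentable sugars that are hexoses (remainder pentoses).
HEXOSE_FRACTION = 0.65
#: mg CO2 respired per mg dry matter: 6 mol CO2 per mol glucose.
RESPIRATION_FACTOR = 6 * MOLAR_MASS_CO2 / MOLAR_MASS_GLUCOSE  # 1.46573

# Minor-VOC aggregates (published values; consumed by the equations).
MINOR_VOC_MASS = 6.2e3  # total mean reported concentration, mg/kg DM
MINOR_VOC_CDMP = 1.6e3  # direct metabolic CO2 from minor VOC, mg/kg DM
MINOR_VOC_PYRUVATE_MMOL = 99.2  # pyruvate demand of minor VOC, mmol/kg DM
MINOR_VOC_WEIGHTED_EBIR = 0.49  # MRC-weighted mean EBIR of the 30 minors
MINOR_VOC_GWP20 = 6.2e3  # ozone-mediated CO2e of minor VOC, 20-y horizon
MINOR_VOC_GWP100 = 1.3e3  # ozone-mediated CO2e of minor VOC, 100-y horizon

#: CO2e multipliers for tropospheric ozone (amortized RNRF). The 20-year
#: value is the one the emission equations print (2.04); the underlying
#: derivation from RNRF 681.0 and a 22-day lifetime yields 2.05.
OZONE_GWP20 = 2.04
OZONE_GWP100 = 0.41
OZONE_RNRF = 681.0
OZONE_LIFETIME_DAYS = 22.0
DAYS_PER_YEAR = 365.25

# Ozone-forming reactivity (g O3 per g compound) of the two major VOC.
EBIR_ACETIC = 0.20
EBIR_ETHANOL = 0.57

# Volatility coefficients (fraction of analyte lost in oven drying).
VOLATILITY_60C = {"lactic": 0.090, "acetic": 0.554, "ethanol": 0.991, "ammonia": 1.003}
VOLATILITY_100C = {"lactic": 0.375, "acetic": 0.892, "ethanol": 0.975, "ammonia": 0.987}

# Imputation defaults for the vcDML workflow (meta-analysis means, % DM).
ETHANOL_DEFAULT_PCT = 1.0
AMMONIA_DEFAULT_PCT = 0.2

#: mg/kg per percentage point of dry matter.
MG_PER_KG_PER_PERCENT = 1.0e4


@dataclass(frozen=True)
class ModelConstants:
    """Bundle of constants consumed by the emission equations.

    Parameters
    ----------
    hexose_scales_minor_constant
        Grouping of the direct-metabolic-CO2 equation. When True (default)
        the hexose fraction multiplies the minor-VOC CO2 constant as well as
        the acetic/ethanol terms; when False it multiplies only the
        metabolite terms.
    ozone_gwp20
        CO2e multiplier of ozone on the 20-year horizon; 2.04 by default,
        2.05 matches the radiative-forcing derivation exactly.
    """

    m_acetic: float = MOLAR_MASS_ACETIC
    m_ethanol: float = MOLAR_MASS_ETHANOL
    m_lactic: float = MOLAR_MASS_LACTIC
    m_co2: float = MOLAR_MASS_CO2
    m_glucose: float = MOLAR_MASS_GLUCOSE
    glycolysis_loss: float = GLYCOLYSIS_LOSS
    hexose_fraction: float = HEXOSE_FRACTION
    hexose_scales_minor_constant: bool = True
    minor_voc_mass: float = MINOR_VOC_MASS
    minor_voc_cdmp: float = MINOR_VOC_CDMP
    minor_voc_pyruvate_mmol: float = MINOR_VOC_PYRUVATE_MMOL
    minor_voc_gwp20: float = MINOR_VOC_GWP20
    minor_voc_gwp100: float = MINOR_VOC_GWP100
    ozone_gwp20: float = OZONE_GWP20
    ozone_gwp100: float = OZONE_GWP100
    ebir_acetic: float = EBIR_ACETIC
    ebir_ethanol: float = EBIR_ETHANOL
    volatility_acetic: float = VOLATILITY_60C["acetic"]
    volatility_ethanol: float = VOLATILITY_60C["ethanol"]
    volatility_ammonia: float = VOLATILITY_60C["ammonia"]
    volatility_lactic: float = VOLATILITY_60C["lactic"]

    @property
    def respiration_factor(self) -> float:
        """mg CO2 per mg respired dry matter (6 * M_CO2 / M_glucose)."""
        return 6 * self.m_co2 / self.m_glucose

    def ozone_gwp(self, horizon: int) -> float:
        if horizon == 20:
            return self.ozone_gwp20
        if horizon == 100:
            return self.ozone_gwp100
        raise ValueError(f"unsupported GWP horizon: {horizon!r} (use 20 or 100)")

    def minor_voc_gwp(self, horizon: int) -> float:
        if horizon == 20:
            return self.minor_voc_gwp20
        if horizon == 100:
            return self.minor_voc_gwp100
        raise ValueError(f"unsupported GWP horizon: {horizon!r} (use 20 or 100)")


DEFAULT_CONSTANTS = ModelConstants()
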