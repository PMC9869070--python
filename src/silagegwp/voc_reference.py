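"""Reference chemistry of silage volatile organic compounds.

The packaged table lists 32 VOC observed in corn silage with their mean
reported concentration (MRC, mg per kg silage DM), molar CO2 equivalent
(MCE, mol CO2 stoichiometrically released per mol of compound fermented from
hexose), and equal benefit incremental reactivity (EBIR, g tropospheric O3
formed per g compound). Acetic acid and ethanol are the two "major" VOC that
enter the emission equations as variables; the remaining 30 "minor" VOC are
folded into aggregate constants.

A second packaged table holds atmospheric abundance and radiative-forcing
increases over pre-industrial levels for CO2, CH4 and O3, from which the
relative normalized radiative forcing (RNRF) of ozone and its amortized
CO2e multipliers are derived.

Published per-row CDMP and ozone-GWP cells are retained verbatim in
``*_printed`` audit columns; some are not reproducible from the row's own
MRC/MCE/EBIR arithmetic (heptanal's 20-year ozone cell is ~100x the product
of its MRC and EBIR), so derived quantities are always recomputed from the
base columns while the printed aggregates remain the constants the emission
equations consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from . import constants as C

__all__ = [
    "VOCRecord",
    "RadiativeForcingRecord",
    "MinorVOCConstants",
    "load_voc_table",
    "load_radiative_forcing",
    "cdmp",
    "minor_voc_aggregates",
    "rnrf",
    "ozone_gwp",
]


@dataclass(frozen=True)
class VOCRecord:
    """One compound row of the reference table."""

    name: str
    cas: str
    molar_mass: float  # g/mol
    mce: int  # mol CO2 per mol compound, in {0, 1, 2}
    mrc: float  # mean reported concentration, mg/kg DM
    ebir: float  # g O3 per g compound
    is_major: bool

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if self.mce not in (0, 1, 2):
            raise ValueError(f"{self.name}: MCE must be 0, 1 or 2")
        if self.mrc < 0 or self.ebir < 0:
            raise ValueError(f"{self.name}: MRC and EBIR must be nonnegative")


@dataclass(frozen=True)
class RadiativeForcingRecord:
    """Abundance and radiative-forcing increase of one atmospheric gas."""

    compound: str
    abundance_increase: float  # ppm over pre-industrial
    forcing_increase: float  # W/m^2 over pre-industrial

    @property
    def normalized_forcing(self) -> float:
        """Forcing increase per unit abundance increase, W m^-2 ppm^-1."""
        if self.abundance_increase <= 0:
            raise ValueError(f"{self.compound}: abundance increase must be positive")
        return self.forcing_increase / self.abundance_increase


@dataclass(frozen=True)
class MinorVOCConstants:
    """Aggregates over the 30 minor VOC: published values and recomputed audit values.

    The ``*_printed`` fields are the 2-significant-figure constants the
    emission equations consume; the ``*_recomputed`` fields come from the
    packaged per-compound table.
    """

    total_mass_printed: float = C.MINOR_VOC_MASS
    total_cdmp_printed: float = C.MINOR_VOC_CDMP
    pyruvate_mmol_printed: float = C.MINOR_VOC_PYRUVATE_MMOL
    weighted_ebir_printed: float = C.MINOR_VOC_WEIGHTED_EBIR
    gwp20_contrib_printed: float = C.MINOR_VOC_GWP20
    gwp100_contrib_printed: float = C.MINOR_VOC_GWP100
    total_mass_recomputed: float = float("nan")
    total_cdmp_recomputed: float = float("nan")
    pyruvate_mmol_recomputed: float = float("nan")
    weighted_ebir_recomputed: float = float("nan")
    gwp20_contrib_recomputed: float = float("nan")
    gwp100_contrib_recomputed: float = float("nan")


def _data_path(name: str):
    return resources.files("silagegwp.data").joinpath(name)


def load_voc_table(path=None) -> pd.DataFrame:
    """Load the packaged (or a user-supplied) VOC reference table.

    Returns a DataFrame with columns name, cas, molar_mass, mce, mrc, ebir,
    is_major plus the printed audit columns cdmp_printed, gwp20_o3_printed,
    gwp100_o3_printed.
    """
    src = path if path is not None else _data_path("voc_table.csv")
    df = pd.read_csv(src)
    df["is_major"] = df["is_major"].astype(bool)
    return df


def load_radiative_forcing(path=None) -> pd.DataFrame:
    src = path if path is not None else _data_path("radiative_forcing.csv")
    return pd.read_csv(src)


def records(df: pd.DataFrame | None = None) -> list[VOCRecord]:
    """Materialize the table as validated :class:`VOCRecord` objects."""
    if df is None:
        df = load_voc_table()
    return [
        VOCRecord(
            name=r.name, cas=r.cas, molar_mass=r.molar_mass, mce=int(r.mce),
            mrc=float(r.mrc), ebir=float(r.ebir), is_major=bool(r.is_major),
        )
        for r in df.itertuples(index=False)
    ]


def cdmp(record: VOCRecord) -> float:
    """Direct metabolic CO2 production for one compound, mg CO2 per kg DM.

    CDMP = MRC / molar_mass * MCE * 44.01: the mass of CO2 released when the
    compound is fermented from hexose at its mean reported concentration.
    Zero whenever the stoichiometry releases no CO2 (MCE = 0).
    """
    if record.molar_mass <= 0:
        raise ValueError(f"{record.name}: molar mass must be positive")
    return record.mrc / record.molar_mass * record.mce * C.MOLAR_MASS_CO2


def minor_voc_aggregates(table: pd.DataFrame | None = None,
                         constants: C.ModelConstants = C.DEFAULT_CONSTANTS) -> MinorVOCConstants:
    """Aggregate the 30 minor VOC: totals, weighted EBIR, ozone CO2e.

    The recomputed weighted EBIR is the MRC-weighted mean of per-compound
    EBIR. Ozone CO2e contributions assume full volatilization of each minor
    compound at its MRC.
    """
    if table is None:
        table = load_voc_table()
    minors = table.loc[~table["is_major"]]
    if minors.empty:
        raise ValueError("no minor VOC records to aggregate")
    total_mass = float(minors["mrc"].sum())
    per_cdmp = minors["mrc"] / minors["molar_mass"] * minors["mce"] * C.MOLAR_MASS_CO2
    weighted_ebir = float((minors["mrc"] * minors["ebir"]).sum() / total_mass)
    # Pyruvate demand per mol of product is a packaged column: it is not
    # derivable from MCE (acetoin takes 2 pyruvate yet releases 1 CO2).
    moles = minors["mrc"] / minors["molar_mass"]  # mmol/kg since mrc is mg/kg
    pyruvate = float((moles * minors["pyruvate_per_mol"]).sum())
    o3_mass = float((minors["mrc"] * minors["ebir"]).sum())
    return MinorVOCConstants(
        total_mass_recomputed=total_mass,
        total_cdmp_recomputed=float(per_cdmp.sum()),
        pyruvate_mmol_recomputed=pyruvate,
        weighted_ebir_recomputed=weighted_ebir,
        gwp20_contrib_recomputed=constants.ozone_gwp20 * o3_mass,
        gwp100_contrib_recomputed=constants.ozone_gwp100 * o3_mass,
    )


def rnrf(record: RadiativeForcingRecord, reference: RadiativeForcingRecord) -> float:
    """Relative normalized radiative forcing of ``record`` vs ``reference``.

    The forcing increase of each gas is normalized to its abundance increase;
    the ratio of normalized forcings expresses the gas's warming effect per
    unit abundance relative to the reference (conventionally CO2).
    """
    return record.normalized_forcing / reference.normalized_forcing


def ozone_gwp(rnrf_value: float, lifetime_days: float, horizon_years: float) -> float:
    """CO2e multiplier of a short-lived forcer amortized over a horizon.

    The instantaneous RNRF is scaled by the fraction of the horizon during
    which the compound persists (lifetime / horizon), so the product of the
    result with the horizon is constant.
    """
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    if lifetime_days <= 0:
        raise ValueError("lifetime must be positive")
    return rnrf_value * (lifetime_days / C.DAYS_PER_YEAR) / horizon_years
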