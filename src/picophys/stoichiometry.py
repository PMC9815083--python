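"""Yield stoichiometry and Cmol carbon-balance closure.

A sealed picoliter batch reactor holds a known initial glucose mass S0.
Once the colony has grown to substrate exhaustion, the substrate-to-biomass
yield follows from the biomass increment:

    Y_X,S = (m_total,end - m_total,0) / S0        [g/g]

with total biomass computed from the projected colony area, the chamber
height and the QPI dry-mass density.  Because the by-products of glucose
metabolism (CO2, organic acids from overflow metabolism) cannot be
speciated at this scale, they are lumped into a single product pool P on a
carbon-mole (Cmol) basis and recovered by difference from the carbon
balance around the cell:

    q_S   = mu / (Y_X,S * M_S)                    [Cmol gX^-1 h^-1]
    r_P   = q_S - mu / M_X                        [Cmol gX^-1 h^-1]
    Y_P,S = r_P / q_S = 1 - Y_X,S * M_S / M_X     [Cmol/Cmol]

where M_X and M_S are the Cmol masses of biomass (CH1.8O0.5N0.2,
24.63 g/Cmol) and glucose (CH2O, 30.03 g/Cmol).  The closure is exact by
construction: every Cmol of substrate carbon ends up in biomass or in P.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ReactorGeometry", "StoichiometrySet", "YieldRecord",
    "initial_substrate_mass", "total_biomass", "yield_xs",
    "specific_uptake_rate", "product_rate_from_yield", "carbon_balance_close",
    "yields_from_batch_series", "M_X_CMOL", "M_S_CMOL",
]

#: Cmol mass of biomass with elemental composition CH1.8O0.5N0.2, g/Cmol.
M_X_CMOL = 24.63
#: Cmol mass of glucose (CH2O per carbon), g/Cmol.
M_S_CMOL = 30.03


@dataclass(frozen=True)
class ReactorGeometry:
    """Picoliter batch chamber geometry.

    The default chamber is 60 x 100 x 1 um (width, length, height) with a
    total cultivation volume, including the attached medium reservoir, of
    606 pL.
    """

    chamber_width_um: float = 60.0
    chamber_length_um: float = 100.0
    chamber_height_um: float = 1.0
    total_volume_pL: float = 606.0

    def __post_init__(self) -> None:
        if min(self.chamber_width_um, self.chamber_length_um,
               self.chamber_height_um, self.total_volume_pL) <= 0:
            raise ValueError("all geometry values must be positive")


@dataclass(frozen=True)
class StoichiometrySet:
    """The closed set of kinetic and stoichiometric coefficients.

    Units: y_xs g/g; y_px Cmol/g; y_ps Cmol/Cmol; q_s g g^-1 h^-1
    (gram basis) carried alongside the Cmol-basis uptake inside
    :func:`carbon_balance_close`; r_p Cmol g^-1 h^-1.
    """

    y_xs: float
    y_px: float
    y_ps: float
    q_s: float
    r_p: float
    m_x_cmol: float = M_X_CMOL
    m_s_cmol: float = M_S_CMOL

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class YieldRecord:
    """Chamber-wise yield observation."""

    chamber_id: int
    s0_mass_pg: float
    m_total_0_pg: float
    m_total_end_pg: float
    y_xs: float
    excluded: bool = False


def initial_substrate_mass(concentration_g_L: float,
                           geometry: ReactorGeometry = ReactorGeometry()) -> float:
    """Initial substrate mass in pg from concentration and reactor volume.

    1 g/L equals 1 pg/pL, so a 1 g/L (0.1% w/v) fill of the 606 pL reactor
    holds 606 pg of glucose.
    """
    if concentration_g_L < 0:
        raise ValueError("concentration must be nonnegative")
    return concentration_g_L * geometry.total_volume_pL


def total_biomass(projected_area_um2: float, chamber_height_um: float,
                  density_pg_um3: float) -> float:
    """Total colony dry mass in pg from projected area, chamber height and
    dry-mass density.

    Monolayer growth in the 1 um-high chamber makes colony volume = area x
    height; multiplying by the QPI density gives dry mass.
    """
    if min(projected_area_um2, chamber_height_um, density_pg_um3) < 0:
        raise ValueError("arguments must be nonnegative")
    return projected_area_um2 * chamber_height_um * density_pg_um3


def yield_xs(m_total_end_pg: float, m_total_0_pg: float, s0_mass_pg: float) -> float:
    """Substrate-to-biomass yield Y_X,S = (m_end - m_0) / S0 in g/g."""
    if s0_mass_pg <= 0:
        raise ValueError("s0_mass must be positive")
    if m_total_end_pg < m_total_0_pg:
        warnings.warn("final biomass below initial biomass: negative yield",
                      stacklevel=2)
    return (m_total_end_pg - m_total_0_pg) / s0_mass_pg


def specific_uptake_rate(mu: float, y_xs: float) -> float:
    """Specific substrate uptake rate q_S = mu / Y_X,S in g g^-1 h^-1."""
    if y_xs <= 0:
        raise ValueError("y_xs must be positive")
    return mu / y_xs


def product_rate_from_yield(mu: float, y_px: float) -> float:
    """Specific product formation rate r_P = mu * Y_P,X in Cmol g^-1 h^-1."""
    if y_px < 0:
        raise ValueError("y_px must be nonnegative")
    return mu * y_px


def carbon_balance_close(mu: float, y_xs: float,
                         m_x_cmol: float = M_X_CMOL,
                         m_s_cmol: float = M_S_CMOL) -> tuple[float, float, float]:
    """Close the Cmol carbon balance around the cell.

    Returns ``(q_s_cmol, r_p, y_ps)``: the Cmol-basis specific substrate
    uptake rate, the lumped specific product formation rate, and the
    substrate-to-product yield.  The conservation identity
    ``y_ps = 1 - y_xs * m_s_cmol / m_x_cmol`` holds exactly — carbon not
    fixed in biomass appears in the product pool.

    Raises
    ------
    ValueError
        If the implied carbon yield exceeds 1 (more carbon in biomass than
        supplied by the substrate).
    """
    if y_xs <= 0 or m_x_cmol <= 0 or m_s_cmol <= 0:
        raise ValueError("y_xs and Cmol masses must be positive")
    if y_xs > m_x_cmol / m_s_cmol:
        raise ValueError(
            "balance violated: more carbon in biomass than in substrate "
            f"(y_xs = {y_xs:.3f} > {m_x_cmol / m_s_cmol:.3f} g/g)")
    q_s_cmol = mu / (y_xs * m_s_cmol)
    r_p = q_s_cmol - mu / m_x_cmol
    y_ps = r_p / q_s_cmol if q_s_cmol > 0 else 0.0
    return q_s_cmol, r_p, y_ps


def close_stoichiometry(mu: float, y_xs: float,
                        m_x_cmol: float = M_X_CMOL,
                        m_s_cmol: float = M_S_CMOL) -> StoichiometrySet:
    """Assemble the full StoichiometrySet from mu and Y_X,S."""
    q_s_cmol, r_p, y_ps = carbon_balance_close(mu, y_xs, m_x_cmol, m_s_cmol)
    return StoichiometrySet(
        y_xs=y_xs, y_px=r_p / mu if mu > 0 else 0.0, y_ps=y_ps,
        q_s=specific_uptake_rate(mu, y_xs), r_p=r_p,
        m_x_cmol=m_x_cmol, m_s_cmol=m_s_cmol)


def yields_from_batch_series(series: dict[int, pd.DataFrame],
                             s0_mass_pg: dict[int, float],
                             density_pg_um3: float,
                             geometry: ReactorGeometry = ReactorGeometry(),
                             min_initial_cells_pg: float = 0.0
                             ) -> list[YieldRecord]:
    """Chamber-wise yields from picoliter-batch area time series.

    Parameters
    ----------
    series
        Per-chamber DataFrames with columns ``time_min`` and ``area_um2``
        (the batch-series CSV schema); first and last frames give the
        initial and final biomass.
    s0_mass_pg
        Initial glucose mass per chamber.
    density_pg_um3
        Dry-mass density applied across the colony.
    min_initial_cells_pg
        Chambers starting below this biomass are flagged ``excluded``
        (sparse monolayers produce meaninglessly high apparent yields), as
        are chambers whose yield implies a carbon yield above 1.

    Yields above the carbon-balance ceiling are reported, not corrected.
    """
    records = []
    for chamber_id, df in series.items():
        if not {"time_min", "area_um2"} <= set(df.columns):
            raise ValueError("series needs columns time_min, area_um2")
        df = df.sort_values("time_min")
        m0 = total_biomass(float(df["area_um2"].iloc[0]),
                           geometry.chamber_height_um, density_pg_um3)
        m_end = total_biomass(float(df["area_um2"].iloc[-1]),
                              geometry.chamber_height_um, density_pg_um3)
        s0 = s0_mass_pg[chamber_id]
        y = yield_xs(m_end, m0, s0)
        excluded = m0 < min_initial_cells_pg or y > M_X_CMOL / M_S_CMOL
        records.append(YieldRecord(chamber_id, s0, m0, m_end, y, excluded))
    return records


def yield_records_to_frame(records: list[YieldRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
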