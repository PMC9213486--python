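"""Headspace gas accounting for SIP incubations.

Gas-chromatography readings of substrate concentration (% v/v) in a sealed
vial's headspace are converted to micromoles through the ideal gas law,
scaled to micromoles of carbon, and accumulated into consumption per gram
of fresh sample. This drives two study decisions: when to harvest a vial
(after ~100 or ~200 µmol C g⁻¹ consumed) and the substrate consumption
rate reported per site.

Dissolved-gas partitioning into the liquid phase is ignored (documented
approximation); defaults assume 25 °C and 1 atm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sipsim import Substrate

__all__ = [
    "HeadspaceSeries",
    "HarvestPoint",
    "headspace_micromoles",
    "carbon_micromoles",
    "cumulative_consumption",
    "harvest_time",
    "consumption_rate",
]

R_J_PER_MOL_K = 8.314462618


@dataclass
class HeadspaceSeries:
    """One vial's substrate concentration time series."""

    vial_id: str
    substrate: Substrate
    times: np.ndarray  # days
    pct_v_v: np.ndarray
    headspace_ml: float
    sample_g: float
    temperature_K: float = 298.15
    pressure_kPa: float = 101.325

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.pct_v_v = np.asarray(self.pct_v_v, dtype=float)
        if self.times.shape != self.pct_v_v.shape:
            raise ValueError("times and pct_v_v differ in shape")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.pct_v_v < 0):
            raise ValueError("pct_v_v must be >= 0")
        if self.sample_g <= 0:
            raise ValueError("sample_g must be > 0")


@dataclass(frozen=True)
class HarvestPoint:
    vial_id: str
    target_umolC_per_g: float
    time_reached: float | None


def headspace_micromoles(
    pct: float,
    headspace_ml: float,
    temperature_K: float = 298.15,
    pressure_kPa: float = 101.325,
):
    """µmol of gas occupying ``pct`` % (v/v) of the headspace (ideal gas law)."""
    if headspace_ml <= 0:
        raise ValueError("headspace volume must be > 0")
    pct = np.asarray(pct, dtype=float)
    if np.any(pct < 0) or np.any(pct > 100):
        raise ValueError("pct must lie in [0, 100]")
    volume_m3 = pct / 100.0 * headspace_ml * 1e-6
    mol = pressure_kPa * 1000.0 * volume_m3 / (R_J_PER_MOL_K * temperature_K)
    return mol * 1e6


def carbon_micromoles(umol_alkane, n_carbons: int):
    """µmol of carbon in ``umol_alkane`` µmol of a C_n alkane."""
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    return np.asarray(umol_alkane, dtype=float) * n_carbons


def cumulative_consumption(series: HeadspaceSeries) -> pd.DataFrame:
    """Cumulative µmol C consumed per g of sample at each time point.

    Noise-driven negative excursions are clipped to the running maximum so
    the result is non-decreasing.
    """
    if series.times.size < 2:
        raise ValueError("cumulative consumption needs >= 2 time points")
    umol = headspace_micromoles(
        series.pct_v_v, series.headspace_ml, series.temperature_K, series.pressure_kPa
    )
    umol_c = carbon_micromoles(umol, series.substrate.n_carbons)
    consumed = (umol_c[0] - umol_c) / series.sample_g
    consumed = np.maximum.accumulate(np.maximum(consumed, 0.0))
    return pd.DataFrame({"time_d": series.times, "umolC_per_g": consumed})


def harvest_time(series: HeadspaceSeries, target_umolC_per_g: float) -> HarvestPoint:
    """Earliest grid time at which cumulative consumption reaches the target."""
    if target_umolC_per_g < 0:
        raise ValueError("target must be >= 0")
    cum = cumulative_consumption(series)
    reached = cum[cum["umolC_per_g"] >= target_umolC_per_g]
    t = float(reached["time_d"].iloc[0]) if len(reached) else None
    return HarvestPoint(series.vial_id, target_umolC_per_g, t)


def _declining_phase_slope(series: HeadspaceSeries, depletion_floor: float = 0.05) -> float:
    """Least-squares slope of cumulative consumption over the declining phase.

    The fit window runs from t0 until the substrate first drops below
    ``depletion_floor`` of its initial concentration (that point included).
    """
    cum = cumulative_consumption(series)
    initial = series.pct_v_v[0]
    below = np.nonzero(series.pct_v_v < depletion_floor * initial)[0]
    end = below[0] + 1 if below.size else series.times.size
    end = max(end, 2)
    t, y = cum["time_d"].to_numpy()[:end], cum["umolC_per_g"].to_numpy()[:end]
    return float(stats.linregress(t, y).slope)


def consumption_rate(series_list, depletion_floor: float = 0.05) -> dict:
    """Consumption rate (µmol C g⁻¹ day⁻¹): replicate mean ± sd of slopes."""
    if isinstance(series_list, HeadspaceSeries):
        series_list = [series_list]
    slopes = np.array([_declining_phase_slope(s, depletion_floor) for s in series_list])
    return {
        "rate_umolC_per_g_per_day": float(slopes.mean()),
        "sd": float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0,
        "per_vial": {s.vial_id: float(r) for s, r in zip(series_list, slopes)},
    }
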