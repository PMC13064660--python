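"""Source-water d18O from precipitation via a simplified rootzone budget.

A single well-mixed bucket: rain (and degree-day snowmelt) adds water at
the precipitation isotope composition; transpiration and drainage
(overflow above capacity) remove water at the store's current
composition without fractionation.  The store damps and lags the
precipitation d18O signal by a few weeks, which is the behavior the
downstream analyses assume of boreal rootzone water.

Snow is handled as delayed input: sub-zero precipitation accumulates in
a separate store (with its own isotope mass balance) and melts at a
configurable degree-day rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RootzoneParams",
    "RootzoneState",
    "step_rootzone",
    "run_rootzone",
    "correct_precip_bias",
]


@dataclass(frozen=True)
class RootzoneParams:
    capacity_mm: float = 150.0
    melt_rate_mm_per_degday: float = 3.0
    snow_threshold_c: float = 0.0

    def __post_init__(self) -> None:
        if self.capacity_mm <= 0:
            raise ValueError("rootzone capacity must be positive")
        if self.melt_rate_mm_per_degday < 0:
            raise ValueError("melt rate must be non-negative")


@dataclass
class RootzoneState:
    """Liquid store and snowpack with their d18O (‰ VSMOW)."""

    store_mm: float
    delta_permil: float
    snow_mm: float = 0.0
    snow_delta_permil: float = 0.0

    def __post_init__(self) -> None:
        if self.store_mm < 0 or self.snow_mm < 0:
            raise ValueError("stores must be non-negative")


def _mix(w0: float, d0: float, w1: float, d1: float) -> float:
    if w0 + w1 <= 0:
        return d0
    return (w0 * d0 + w1 * d1) / (w0 + w1)


def step_rootzone(
    state: RootzoneState,
    precip_mm: float,
    delta_p_permil: float,
    et_mm: float,
    params: RootzoneParams,
    tair_c: float = 10.0,
) -> RootzoneState:
    """Advance the bucket one (daily) step; well-mixed mass balance.

    Inflow mixes into the store at the precipitation composition;
    drainage (overflow above capacity) and ET leave at the store's
    current composition unchanged; the store is clamped to
    ``[0, capacity]``.
    """
    if precip_mm < 0 or et_mm < 0:
        raise ValueError("precipitation and ET must be non-negative")
    store, delta = state.store_mm, state.delta_permil
    snow, snow_d = state.snow_mm, state.snow_delta_permil

    # partition precipitation into rain and snow accumulation
    if tair_c <= params.snow_threshold_c:
        snow_d = _mix(snow, snow_d, precip_mm, delta_p_permil)
        snow += precip_mm
        rain, rain_d = 0.0, delta_p_permil
    else:
        rain, rain_d = precip_mm, delta_p_permil

    # degree-day melt releases snow at the snowpack composition
    melt = min(snow, params.melt_rate_mm_per_degday
               * max(tair_c - params.snow_threshold_c, 0.0))
    snow -= melt

    inflow = rain + melt
    inflow_d = _mix(rain, rain_d, melt, snow_d)
    delta = _mix(store, delta, inflow, inflow_d)
    store += inflow
    # drainage and ET remove at current composition (no fractionation)
    store = min(store, params.capacity_mm)
    store = max(store - et_mm, 0.0)
    return RootzoneState(store_mm=store, delta_permil=delta,
                         snow_mm=snow, snow_delta_permil=snow_d)


def run_rootzone(
    daily: pd.DataFrame,
    params: RootzoneParams | None = None,
    initial: RootzoneState | None = None,
) -> pd.DataFrame:
    """Run the bucket over a daily table (columns ``precip_mm``,
    ``d18o_precip_permil``, ``et_mm``, ``tair_C``); returns a daily frame
    with ``d18o_sw_permil`` and the store diagnostics."""
    params = params or RootzoneParams()
    if initial is None:
        cold = daily["tair_C"] <= params.snow_threshold_c
        d0 = float(daily.loc[cold, "d18o_precip_permil"].mean()) if cold.any() \
            else float(daily["d18o_precip_permil"].mean())
        initial = RootzoneState(store_mm=0.6 * params.capacity_mm, delta_permil=d0)
    state = initial
    rows = np.empty((len(daily), 3))
    precip = daily["precip_mm"].to_numpy(float)
    dp = daily["d18o_precip_permil"].to_numpy(float)
    et = daily["et_mm"].to_numpy(float)
    tair = daily["tair_C"].to_numpy(float)
    for i in range(len(daily)):
        state = step_rootzone(state, precip[i], dp[i], et[i], params, tair_c=tair[i])
        rows[i] = (state.delta_permil, state.store_mm, state.snow_mm)
    return pd.DataFrame(
        {"d18o_sw_permil": rows[:, 0], "store_mm": rows[:, 1], "snow_mm": rows[:, 2]},
        index=daily.index,
    )


def correct_precip_bias(series, offset_permil: float):
    """Constant additive bias correction of a precipitation-d18O series."""
    arr = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("series must be finite")
    out = arr + offset_permil
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out if out.ndim else float(out)
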