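"""Signal analysis: window-weighted aggregation, multi-scale correlations,
apparent-p_ex inversion and regression, dating-sensitivity grids and the
source-water-variability scenario experiment.

Environmental drivers are aggregated over each subsection's
formation-to-maturation window with one of three weighting schemes:
net-assimilation weighting (``max(A_n, 0)``, so aggregated values
reflect when carbon was actually fixed), a fixed 9-15 h daytime window,
or clear-sky radiation (cosine of solar zenith), which needs no
gas-exchange modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chronology import TimeWindow
from .fractionation import VSMOW, delta_to_ratio
from .solar import cos_zenith
from .transport import ForwardResult, cellulose_from_wood, run_forward

__all__ = [
    "WEIGHTING_SCHEMES",
    "SCALES",
    "UndefinedMeanError",
    "window_mask",
    "window_weights",
    "window_weighted_mean",
    "clear_sky_weight",
    "season_of_center",
    "correlations_by_scale",
    "PexEstimate",
    "invert_apparent_pex",
    "pex_inversion_table",
    "PexFits",
    "fit_pex_functions",
    "SensitivityGrid",
    "sensitivity_grid",
    "sw_variability_scenarios",
    "sd_ratio",
]

WEIGHTING_SCHEMES = ("an_weighted", "daytime_9_to_15", "clear_sky_radiation")
SCALES = ("intra_annual", "interannual", "interannual_EGS", "interannual_MGS",
          "interannual_LGS")


class UndefinedMeanError(ValueError):
    """All weights vanish inside a window."""


def window_mask(index: pd.DatetimeIndex, window: TimeWindow) -> np.ndarray:
    """Boolean mask of timestamps inside a window (whole days, inclusive)."""
    doy = index.dayofyear.to_numpy()
    return ((index.year.to_numpy() == window.year)
            & (doy >= window.start_doy) & (doy <= window.end_doy))


def clear_sky_weight(index: pd.DatetimeIndex, latitude_deg: float) -> np.ndarray:
    """Clear-sky weighting: cosine of solar zenith, clamped at 0 at night."""
    return cos_zenith(index, latitude_deg)


def window_weights(index: pd.DatetimeIndex, scheme: str,
                   an: np.ndarray | None = None,
                   latitude_deg: float | None = None) -> np.ndarray:
    """Per-timestep non-negative weights for a scheme over the full series."""
    if scheme == "an_weighted":
        if an is None:
            raise ValueError("an_weighted scheme requires the A_n series")
        return np.maximum(np.asarray(an, dtype=float), 0.0)
    if scheme == "daytime_9_to_15":
        hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
        return ((hour >= 9.0) & (hour < 15.0)).astype(float)
    if scheme == "clear_sky_radiation":
        if latitude_deg is None:
            raise ValueError("clear_sky_radiation scheme requires the latitude")
        return clear_sky_weight(index, latitude_deg)
    raise ValueError(f"unknown weighting scheme {scheme!r}; "
                     f"expected one of {WEIGHTING_SCHEMES}")


def window_weighted_mean(series: pd.Series, window: TimeWindow, scheme: str,
                         an: pd.Series | None = None,
                         latitude_deg: float | None = None) -> float:
    """Weighted mean of a half-hourly series over one subsection window."""
    idx = series.index
    w = window_weights(idx, scheme,
                       an=None if an is None else an.to_numpy(float),
                       latitude_deg=latitude_deg)
    mask = window_mask(idx, window)
    if not mask.any():
        raise ValueError(f"window {window} not covered by the series")
    wsum = w[mask].sum()
    if wsum <= 0:
        raise UndefinedMeanError(f"all weights vanish in window {window}")
    return float((series.to_numpy(float)[mask] * w[mask]).sum() / wsum)


def season_of_center(center_doy: float, bounds: tuple[int, int, int, int]) -> str | None:
    """EGS/MGS/LGS membership of a window center date.

    Boundary days belong to the earlier season; centers outside the
    configured growing-season bounds return ``None``.
    """
    b0, b1, b2, b3 = bounds
    if center_doy < b0 or center_doy > b3:
        return None
    if center_doy <= b1:
        return "EGS"
    if center_doy <= b2:
        return "MGS"
    return "LGS"


def correlations_by_scale(
    df: pd.DataFrame,
    scale: str,
    season_bounds: tuple[int, int, int, int] | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation of columns ``x`` and ``y`` at a temporal scale.

    ``df`` carries one row per subsection with columns ``x``, ``y``,
    ``year`` and ``center_doy``.  Intra-annual pools all subsections;
    interannual averages within years first; the seasonal scales filter
    by the window center date before yearly averaging.  Two-sided
    significance; requires n >= 3 after aggregation.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    data = df
    if scale.startswith("interannual_"):
        if season_bounds is None:
            raise ValueError("seasonal scales require season_bounds")
        tag = scale.split("_")[1]
        keep = data["center_doy"].apply(
            lambda c: season_of_center(c, season_bounds) == tag)
        data = data[keep]
    if scale != "intra_annual":
        data = data.groupby("year", as_index=False)[["x", "y"]].mean()
    n = len(data)
    if n < 3:
        raise ValueError(f"insufficient data for {scale}: n={n} < 3")
    r, p = stats.pearsonr(data["x"], data["y"])
    return float(r), float(p), n


# ---------------------------------------------------------------------------
# Apparent p_ex
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PexEstimate:
    """Apparent exchange fraction for one subsection, with its
    observational-uncertainty band (from +/-0.5‰ on the ring value)."""

    p_ex: float
    lower: float
    upper: float
    out_of_range: bool


def _invert_one(r_cel: float, mean_sw: float, mean_ps: float) -> float:
    return (r_cel - mean_ps) / (mean_sw - mean_ps)


def invert_apparent_pex(
    d18o_wood_obs: float,
    mean_sw_term: float,
    mean_ps: float,
    obs_uncert_permil: float = 0.5,
    min_denom_permil: float = 0.1,
) -> PexEstimate:
    """Invert the cellulose mixing equation for the apparent p_ex.

    ``p_ex' = (R_cel,obs - <R_ps>) / (<alpha_wc R_sw> - <R_ps>)`` with
    the observed wood value corrected to the cellulose scale (+4.4‰).
    The band re-solves at the ring value +/- the observational
    uncertainty.  Values outside [0, 1] are reported and flagged, never
    clipped.
    """
    denom_permil = abs(mean_sw_term - mean_ps) / VSMOW.r_std * 1000.0
    if denom_permil < min_denom_permil:
        raise ZeroDivisionError(
            f"p_ex undefined: source-water and phloem terms differ by only "
            f"{denom_permil:.3g}‰ (< {min_denom_permil}‰)"
        )
    vals = []
    for d in (0.0, -obs_uncert_permil, obs_uncert_permil):
        r_cel = delta_to_ratio(cellulose_from_wood(d18o_wood_obs + d, "O"), VSMOW)
        vals.append(_invert_one(r_cel, mean_sw_term, mean_ps))
    p, a, b = vals
    return PexEstimate(p_ex=p, lower=min(a, b), upper=max(a, b),
                       out_of_range=not 0.0 <= p <= 1.0)


def pex_inversion_table(obs_values: np.ndarray, forward: ForwardResult,
                        obs_uncert_permil: float = 0.5) -> pd.DataFrame:
    """Apparent p_ex per subsection from observed ring d18O and the modeled
    integral terms; carries the window covariates (center DOY, A_n-weighted
    RH) for the regression step."""
    table = forward.table
    if len(obs_values) != len(table):
        raise ValueError("one observation per modeled subsection required")
    rows = []
    for obs, (_, m) in zip(obs_values, table.iterrows()):
        est = invert_apparent_pex(float(obs), float(m["mean_sw_term_ratio"]),
                                  float(m["mean_ps_o_ratio"]),
                                  obs_uncert_permil=obs_uncert_permil)
        rows.append(
            {
                "year": int(m["year"]),
                "center_doy": float(m["center_doy"]),
                "rh_pct": float(m["rh_an_weighted_pct"]),
                "p_ex": est.p_ex,
                "lower": est.lower,
                "upper": est.upper,
                "out_of_range": est.out_of_range,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PexFits:
    """Fitted p_ex' covariate models (pooled over sites)."""

    doy_slope: float
    doy_intercept: float
    doy_r: float
    rh_a: float
    rh_b: float
    rh_r: float

    def pex_of_doy(self, doy: float) -> float:
        return self.doy_intercept + self.doy_slope * doy

    def pex_of_rh(self, rh_pct: float) -> float:
        return self.rh_a * np.exp(-self.rh_b * rh_pct)


def fit_pex_functions(pex_table: pd.DataFrame) -> PexFits:
    """Fit p_ex' as a linear function of DOY and a monotone-decreasing
    exponential of RH (``a * exp(-b * RH)``), by least squares.

    Needs >= 10 points with non-degenerate covariates; returns the
    parameters together with the Pearson r between fitted and observed
    values for each model.
    """
    if len(pex_table) < 10:
        raise ValueError("need at least 10 p_ex points to fit covariate models")
    doy = pex_table["center_doy"].to_numpy(float)
    rh = pex_table["rh_pct"].to_numpy(float)
    pex = pex_table["p_ex"].to_numpy(float)
    for name, cov in (("center_doy", doy), ("rh_pct", rh)):
        if np.std(cov) == 0:
            raise ValueError(f"degenerate covariate {name}: zero variance")

    lin = stats.linregress(doy, pex)
    a0 = max(float(np.mean(pex)), 1e-3)
    try:
        (a, b), _ = optimize.curve_fit(
            lambda x, a, b: a * np.exp(-b * x), rh, pex,
            p0=(a0 * np.exp(0.01 * float(np.mean(rh))), 0.01),
            bounds=([1e-8, 0.0], [np.inf, 1.0]), maxfev=10000,
        )
        fitted = a * np.exp(-b * rh)
        rh_r = float(np.corrcoef(fitted, pex)[0, 1]) if np.std(fitted) > 0 else 0.0
    except RuntimeError:
        a, b, rh_r = a0, 0.0, 0.0
    return PexFits(
        doy_slope=float(lin.slope), doy_intercept=float(lin.intercept),
        doy_r=float(lin.rvalue), rh_a=float(a), rh_b=float(b), rh_r=rh_r,
    )


# ---------------------------------------------------------------------------
# Dating-sensitivity grid
# ---------------------------------------------------------------------------


@dataclass
class SensitivityGrid:
    """Correlation surface over (formation, maturation) date shifts."""

    d_formation: np.ndarray   # 1D shifts (days)
    d_maturation: np.ndarray  # 1D shifts (days)
    r: np.ndarray             # 2D [i_form, i_mat]; NaN where missing
    peak_d_formation: int
    peak_d_maturation: int
    r_peak: float
    contour_inner: float      # |r|max - 0.01
    contour_outer: float      # |r|max - 0.05

    @property
    def peak_mean_shift(self) -> float:
        return 0.5 * (self.peak_d_formation + self.peak_d_maturation)


def sensitivity_grid(
    ring_values: np.ndarray,
    windows: list[TimeWindow],
    target: pd.Series,
    weights: np.ndarray,
    shifts: np.ndarray | None = None,
) -> SensitivityGrid:
    """Correlation of ring values with re-aggregated target over shifted windows.

    Every grid cell moves all formation (start) dates by ``d_form`` and
    all maturation (end) dates by ``d_mat`` days, recomputes the weighted
    window means of ``target`` and the Pearson correlation with the fixed
    ring values.  Cells where any window inverts or runs off the series
    are marked missing.  The (0, 0) cell is the unshifted baseline.
    """
    if shifts is None:
        shifts = np.arange(-20, 21, 2)
    shifts = np.asarray(shifts, dtype=int)
    idx = target.index
    if len(idx) < 2:
        raise ValueError("target series too short")
    step_s = (idx[1] - idx[0]).total_seconds()
    per_day = int(round(86400.0 / step_s))
    x = target.to_numpy(float)
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must align with the target series")
    cs_wx = np.concatenate([[0.0], np.cumsum(w * x)])
    cs_w = np.concatenate([[0.0], np.cumsum(w)])

    # base index bounds per window: [i0, i1) covering whole days
    year = idx.year.to_numpy()
    doy = idx.dayofyear.to_numpy()
    key = year * 1000 + doy
    i0 = np.array([np.searchsorted(key, wd.year * 1000 + wd.start_doy)
                   for wd in windows])
    i1 = np.array([np.searchsorted(key, wd.year * 1000 + wd.end_doy, side="right")
                   for wd in windows])
    ring = np.asarray(ring_values, dtype=float)
    if len(ring) != len(windows):
        raise ValueError("one ring value per window required")

    nf, nm = len(shifts), len(shifts)
    r = np.full((nf, nm), np.nan)
    n_idx = len(x)
    for a, df in enumerate(shifts):
        j0 = i0 + df * per_day
        for b, dm in enumerate(shifts):
            j1 = i1 + dm * per_day
            if np.any(j0 >= j1) or j0.min() < 0 or j1.max() > n_idx:
                continue
            wsum = cs_w[j1] - cs_w[j0]
            if np.any(wsum <= 0):
                continue
            means = (cs_wx[j1] - cs_wx[j0]) / wsum
            if np.std(means) == 0 or np.std(ring) == 0:
                continue
            r[a, b] = np.corrcoef(ring, means)[0, 1]
    if np.all(np.isnan(r)):
        raise ValueError("sensitivity grid empty: all cells missing")
    flat = np.nanargmax(np.abs(r))
    ia, ib = np.unravel_index(flat, r.shape)
    r_peak = float(r[ia, ib])
    return SensitivityGrid(
        d_formation=shifts.copy(), d_maturation=shifts.copy(), r=r,
        peak_d_formation=int(shifts[ia]), peak_d_maturation=int(shifts[ib]),
        r_peak=r_peak,
        contour_inner=abs(r_peak) - 0.01, contour_outer=abs(r_peak) - 0.05,
    )


def grid_to_frame(grid: SensitivityGrid) -> pd.DataFrame:
    """Long-format table of a sensitivity grid (d_form, d_mat, r, missing)."""
    rows = []
    for a, df in enumerate(grid.d_formation):
        for b, dm in enumerate(grid.d_maturation):
            val = grid.r[a, b]
            rows.append({"d_form": int(df), "d_mat": int(dm),
                         "r": val, "missing": bool(np.isnan(val))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Source-water variability scenarios
# ---------------------------------------------------------------------------


def sd_ratio(enrichment_window_values, sw_window_values) -> float:
    """SD of window-aggregated evaporative enrichment over SD of
    window-aggregated source-water d18O."""
    enr = np.asarray(enrichment_window_values, dtype=float)
    sw = np.asarray(sw_window_values, dtype=float)
    if len(enr) < 2 or len(sw) < 2:
        raise ValueError("need at least two windows")
    sd_sw = float(np.std(sw, ddof=1))
    if sd_sw == 0:
        raise ZeroDivisionError("source-water SD is zero")
    return float(np.std(enr, ddof=1)) / sd_sw


def sw_variability_scenarios(
    dataset,
    windows: list[TimeWindow],
    params,
    scale_factors,
) -> pd.DataFrame:
    """Rerun the forward model with source-water d18O variability scaled
    around its mean and report how the RH and source-water signals in the
    modeled ring values trade off.

    ``s = 1`` reuses the original source-water series unchanged (baseline
    bit-identical); ``s = 0`` removes all source-water variability, so
    the ring-vs-source-water correlation is undefined (flagged) and the
    RH pathway carries the whole signal.
    """
    sw = dataset.drivers["d18o_sw_permil"].to_numpy(float)
    mean = float(np.mean(sw))
    rows = []
    for s in scale_factors:
        if s < 0:
            raise ValueError("scale factor must be non-negative")
        if s == 1.0:
            ds = dataset
        else:
            ds = dataset.replace_source_water(mean + s * (sw - mean))
        fwd = run_forward(ds.drivers, windows, params)
        t = fwd.table
        ring = t["d18o_wood_permil"].to_numpy(float)
        rh_w = t["rh_an_weighted_pct"].to_numpy(float)
        sw_w = t["sw_an_weighted_permil"].to_numpy(float)
        enr_w = t["enrichment_an_weighted_permil"].to_numpy(float)
        r_rh = float(stats.pearsonr(ring, rh_w)[0])
        sd_sw = float(np.std(sw_w, ddof=1))
        sd_enr = float(np.std(enr_w, ddof=1))
        # rounding residue of aggregating a constant series is not variability
        if sd_sw < 1e-9 * max(1.0, abs(float(np.mean(sw_w)))):
            sd_sw = 0.0
            r_sw, sw_undefined = float("nan"), True
        else:
            r_sw = float(stats.pearsonr(ring, sw_w)[0])
            sw_undefined = False
        rows.append(
            {
                "s": float(s),
                "sd_sw_over_sd_enrichment": sd_sw / sd_enr if sd_enr > 0 else float("nan"),
                "sd_enrichment_over_sd_sw": sd_enr / sd_sw if sd_sw > 0 else float("nan"),
                "r_ring_rh": r_rh,
                "r_ring_sw": r_sw,
                "r_sw_undefined": sw_undefined,
            }
        )
    return pd.DataFrame(rows)
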