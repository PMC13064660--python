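"""Seeded synthetic drivers, forcings and observations for the pipeline.

The generator emulates the structure of half-hourly boreal flux-site
drivers and reanalysis isotope forcings so the whole leaf-to-ring chain
runs without external data: sinusoidal seasonal and diurnal cycles with
AR(1) day-to-day residuals, precipitation as a seeded event process,
summer-enriched precipitation d18O, water vapor d18O at liquid-vapor
equilibrium with precipitation, a light/VPD/soil-moisture gas-exchange
stand-in, double-Gompertz xylogenesis curves, and 2-15 subsections per
ring per tree with analytical (0.2‰) and between-tree (~0.7-0.8‰)
observation noise.

All randomness flows from one master seed through named substreams, so
every component is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .chronology import GrowthCurves, Subsection, TimeWindow, window_for_subsection
from .fractionation import equilibrium_eps
from .params import IsotopeParams, NoiseSpec
from .solar import cos_zenith
from .source_water import RootzoneParams, run_rootzone
from .transport import ForwardResult, run_forward

__all__ = [
    "SitePreset",
    "SOUTHERN_BOREAL",
    "NORTHERN_BOREAL",
    "PRESETS",
    "GasExchangeParams",
    "gen_meteo",
    "gen_isotope_forcing",
    "gen_gas_exchange",
    "gen_growth_curves",
    "gen_subsection_layout",
    "make_truth",
    "TruthBundle",
    "SimulationDataset",
    "build_dataset",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SitePreset:
    """Seasonal climate statistics of a synthetic boreal site."""

    name: str
    latitude: float
    t_mean_c: float
    t_seasonal_amp_c: float
    t_diurnal_amp_c: float
    rh_mean_pct: float
    rh_seasonal_amp_pct: float
    dp_mean_permil: float        # precipitation d18O annual mean
    dp_seasonal_amp_permil: float
    gs_start_doy: int
    gs_end_doy: int
    #: (EGS start, EGS|MGS boundary, MGS|LGS boundary, LGS end) day-of-year
    season_bounds_doy: tuple[int, int, int, int]
    t_noise_sd_c: float = 3.0
    rh_noise_sd_pct: float = 7.0
    dp_noise_sd_permil: float = 1.2
    ar1_daily: float = 0.75
    wet_day_prob: float = 0.35

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must lie in [-90, 90]")
        if self.rh_mean_pct + self.rh_seasonal_amp_pct > 100.0:
            raise ValueError("RH mean + amplitude must not exceed 100%")
        for amp in (self.t_seasonal_amp_c, self.t_diurnal_amp_c,
                    self.rh_seasonal_amp_pct, self.dp_seasonal_amp_permil):
            if amp < 0:
                raise ValueError("amplitudes must be non-negative")
        if not 0 < self.gs_start_doy < self.gs_end_doy <= 366:
            raise ValueError("growing season bounds must be ordered within the year")


SOUTHERN_BOREAL = SitePreset(
    name="southern_boreal", latitude=61.85,
    t_mean_c=4.1, t_seasonal_amp_c=13.0, t_diurnal_amp_c=4.0,
    rh_mean_pct=78.0, rh_seasonal_amp_pct=10.0,
    dp_mean_permil=-11.5, dp_seasonal_amp_permil=4.0,
    gs_start_doy=121, gs_end_doy=273,
    season_bounds_doy=(135, 166, 227, 273),
)

NORTHERN_BOREAL = SitePreset(
    name="northern_boreal", latitude=67.77,
    t_mean_c=0.1, t_seasonal_amp_c=14.0, t_diurnal_amp_c=3.5,
    rh_mean_pct=79.0, rh_seasonal_amp_pct=10.0,
    dp_mean_permil=-13.8, dp_seasonal_amp_permil=4.0,
    gs_start_doy=140, gs_end_doy=260,
    season_bounds_doy=(152, 181, 212, 243),
)

PRESETS = {p.name: p for p in (SOUTHERN_BOREAL, NORTHERN_BOREAL)}

_T_PEAK_DOY = 197.0  # mid-July temperature (and precipitation-d18O) maximum


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Unit-variance AR(1) series."""
    eps = rng.standard_normal(n)
    return lfilter([np.sqrt(1.0 - rho**2)], [1.0, -rho], eps)


def _index(years: tuple[int, int]) -> pd.DatetimeIndex:
    y0, y1 = years
    if y1 < y0:
        raise ValueError("year range must be non-empty")
    return pd.date_range(f"{y0}-01-01", f"{y1 + 1}-01-01", freq="30min",
                         inclusive="left")


def gen_meteo(preset: SitePreset, years: tuple[int, int], seed: int) -> pd.DataFrame:
    """Half-hourly synthetic weather for ``years`` (inclusive range)."""
    idx = _index(years)
    n = len(idx)
    ndays = n // 48
    doy = idx.dayofyear.to_numpy().astype(float)
    hour = (idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0).astype(float)
    seasonal = np.cos(2.0 * np.pi * (doy - _T_PEAK_DOY) / 365.25)
    diurnal = np.cos(2.0 * np.pi * (hour - 14.0) / 24.0)

    rng_t = substream(seed, "meteo.tair")
    t_daily = np.repeat(_ar1(rng_t, ndays, preset.ar1_daily), 48)[:n]
    tair = (preset.t_mean_c + preset.t_seasonal_amp_c * seasonal
            + preset.t_diurnal_amp_c * diurnal
            + preset.t_noise_sd_c * t_daily)

    rng_rh = substream(seed, "meteo.rh")
    rh_daily = np.repeat(_ar1(rng_rh, ndays, preset.ar1_daily), 48)[:n]
    rh = (preset.rh_mean_pct
          - preset.rh_seasonal_amp_pct * seasonal  # drier air in summer
          - 1.6 * preset.t_diurnal_amp_c * diurnal  # anticorrelated within day
          + preset.rh_noise_sd_pct * rh_daily)
    rh = np.clip(rh, 2.0, 100.0)

    rng_p = substream(seed, "meteo.precip")
    wet = rng_p.random(ndays) < preset.wet_day_prob
    amounts = np.where(wet, rng_p.gamma(0.9, 6.0, ndays), 0.0)
    precip = np.zeros(n)
    starts = rng_p.integers(0, 42, ndays)
    for d in np.flatnonzero(wet):
        s = d * 48 + starts[d]
        precip[s:s + 6] += amounts[d] / 6.0

    rng_c = substream(seed, "meteo.cloud")
    cloud_ar = _ar1(rng_c, ndays, preset.ar1_daily)
    clear_frac = np.clip(0.72 + 0.18 * cloud_ar - 0.45 * wet, 0.12, 1.0)
    cosz = cos_zenith(idx, preset.latitude)
    par = 2100.0 * cosz * np.repeat(clear_frac, 48)[:n]
    rad_clear = 1361.0 * 0.75 * cosz

    # daily soil-moisture bucket (volumetric, 0.4 m rootzone)
    daily_p = amounts
    season_day = np.cos(2.0 * np.pi * (np.arange(ndays) % 365.25 + 1 - _T_PEAK_DOY)
                        / 365.25)
    et_demand = 2.5 * np.clip(season_day, 0.0, 1.0) + 0.3
    swc = np.empty(ndays)
    s = 0.30
    for d in range(ndays):
        # actual ET shuts down as the bucket dries (soil-limited supply)
        et = et_demand[d] * np.clip((s - 0.08) / (0.22 - 0.08), 0.1, 1.0)
        s = np.clip(s + (daily_p[d] - et) / 400.0, 0.08, 0.42)
        swc[d] = s

    return pd.DataFrame(
        {
            "tair_C": tair,
            "rh_pct": rh,
            "par_umol_m2_s": par,
            "precip_mm": precip,
            "swc_m3_m3": np.repeat(swc, 48)[:n],
            "rad_clear_W_m2": rad_clear,
        },
        index=idx,
    )


def gen_isotope_forcing(meteo: pd.DataFrame, preset: SitePreset,
                        seed: int) -> pd.DataFrame:
    """Precipitation/vapor d18O and atmospheric CO2 forcings on the meteo grid.

    Precipitation d18O follows a summer-maximum sinusoid with AR(1)
    day-to-day noise; vapor d18O is set to liquid-vapor equilibrium with
    precipitation at air temperature (so vapor is always lighter than
    precipitation above 0 °C).
    """
    idx = meteo.index
    n = len(idx)
    ndays = n // 48
    doy = idx.dayofyear.to_numpy().astype(float)
    seasonal = np.cos(2.0 * np.pi * (doy - _T_PEAK_DOY) / 365.25)

    rng = substream(seed, "forcing.dp")
    dp_noise = np.repeat(_ar1(rng, ndays, preset.ar1_daily), 48)[:n]
    dp = (preset.dp_mean_permil + preset.dp_seasonal_amp_permil * seasonal
          + preset.dp_noise_sd_permil * dp_noise)

    tair = np.clip(meteo["tair_C"].to_numpy(float), -5.0, 45.0)
    alpha_plus = 1.0 + equilibrium_eps(tair) / 1000.0
    dv = (dp + 1000.0) / alpha_plus - 1000.0

    co2 = 412.0 - 8.0 * seasonal
    rng_c = substream(seed, "forcing.d13c")
    d13c = (-8.5 + 0.25 * seasonal
            + 0.05 * np.repeat(_ar1(rng_c, ndays, preset.ar1_daily), 48)[:n])
    return pd.DataFrame(
        {
            "d18o_precip_permil": dp,
            "d18o_vapor_permil": dv,
            "d13c_co2_permil": d13c,
            "co2_ppm": co2,
        },
        index=idx,
    )


@dataclass(frozen=True)
class GasExchangeParams:
    """Stand-in leaf gas-exchange model (saturating light response with
    multiplicative VPD, soil-moisture and cold-temperature modifiers)."""

    a_max_umol_m2_s: float = 8.0
    k_par_umol_m2_s: float = 300.0
    rd25_umol_m2_s: float = 0.5
    q10: float = 2.0
    g0_mol_m2_s: float = 0.004
    g_slope_mol_per_umol: float = 0.015
    g_b_mol_m2_s: float = 0.8
    d0_kpa: float = 1.2
    swc_low: float = 0.08
    swc_high: float = 0.16
    t_cold_low_c: float = -2.0
    t_cold_high_c: float = 8.0
    daily_noise_sd: float = 0.08
    pressure_kpa: float = 101.3


def _esat_kpa(tair_c: np.ndarray) -> np.ndarray:
    return 0.6108 * np.exp(17.27 * tair_c / (tair_c + 237.3))


def gen_gas_exchange(meteo: pd.DataFrame, params: GasExchangeParams | None = None,
                     seed: int = 0, co2_ppm=410.0) -> pd.DataFrame:
    """Synthetic leaf gas exchange on the meteo grid (all-sided leaf area).

    In the dark the light response vanishes and ``A_n = -r_d`` exactly;
    transpiration is ``E = g_tot (w_i - w_a)`` through the
    stomatal/boundary-layer series conductance, zero when stomata close.
    """
    p = params or GasExchangeParams()
    idx = meteo.index
    n = len(idx)
    ndays = n // 48
    tair = meteo["tair_C"].to_numpy(float)
    rh = meteo["rh_pct"].to_numpy(float)
    par = meteo["par_umol_m2_s"].to_numpy(float)
    swc = meteo["swc_m3_m3"].to_numpy(float)

    esat = _esat_kpa(tair)
    wi = esat / p.pressure_kpa
    wa = rh / 100.0 * esat / p.pressure_kpa
    vpd = esat * (1.0 - rh / 100.0)

    f_vpd = 1.0 / (1.0 + vpd / p.d0_kpa)
    f_swc = np.clip((swc - p.swc_low) / (p.swc_high - p.swc_low), 0.0, 1.0)
    f_cold = np.clip((tair - p.t_cold_low_c) / (p.t_cold_high_c - p.t_cold_low_c),
                     0.0, 1.0)
    rng = substream(seed, "gasex.amax")
    noise = np.repeat(np.exp(p.daily_noise_sd * _ar1(rng, ndays, 0.7)), 48)[:n]

    a_gross = (p.a_max_umol_m2_s * noise * par / (par + p.k_par_umol_m2_s)
               * f_vpd * f_swc * f_cold)
    rd = p.rd25_umol_m2_s * p.q10 ** ((tair - 25.0) / 10.0)
    an = a_gross - rd

    gs = p.g0_mol_m2_s + p.g_slope_mol_per_umol * a_gross * f_vpd
    gb = np.full(n, p.g_b_mol_m2_s)
    gtot = gs * gb / (gs + gb)
    e_mol = gtot * np.maximum(wi - wa, 0.0)

    ca = np.asarray(co2_ppm, dtype=float)
    ci = ca - np.maximum(an, 0.0) * 1.6 / gs
    ci_ca = np.clip(ci / ca, 0.0, 1.0)

    return pd.DataFrame(
        {
            "an_umol_m2_s": an,
            "rd_umol_m2_s": rd,
            "gs_mol_m2_s": gs,
            "gb_mol_m2_s": gb,
            "e_mol_m2_s": e_mol,
            "wi_mol_mol": wi,
            "wa_mol_mol": wa,
            "ci_ca": ci_ca,
            "tleaf_C": tair,
        },
        index=idx,
    )


def gen_growth_curves(year: int, preset: SitePreset, seed: int) -> GrowthCurves:
    """Double-Gompertz xylogenesis curves for one year.

    Formation and maturation share the sigmoid rate; maturation lags
    formation by a jittered 15-25 days, so maturation <= formation holds
    pointwise and full maturation trails far beyond the formation season.
    """
    rng = substream(seed, f"growth.{year}")
    mid_f = preset.gs_start_doy + 55.0 + rng.normal(0.0, 4.0)
    b = 0.055 * np.exp(rng.normal(0.0, 0.12))
    lag = float(np.clip(18.0 + rng.normal(0.0, 3.0), 10.0, 30.0))
    doy = np.arange(1, 366)

    def curve(mid: float) -> np.ndarray:
        g = np.exp(-np.exp(-b * (doy - mid)))
        return np.clip((g - 0.02) / 0.98, 0.0, 1.0)

    return GrowthCurves(year=year, doy=doy, formation=curve(mid_f),
                        maturation=curve(mid_f + lag))


def gen_subsection_layout(n_trees: int, mean_count: float, seed: int,
                          count_sd: float = 2.5) -> list[list[tuple[float, float]]]:
    """Per-tree subsection intervals exactly tiling [0, 1].

    Counts are drawn around ``mean_count`` and clipped to the observed
    2-15 range; interval widths are Dirichlet-distributed so narrow and
    wide subsections coexist as in real thin-section series.
    """
    if n_trees < 1:
        raise ValueError("need at least one tree")
    if not 2.0 <= mean_count <= 15.0:
        raise ValueError("mean_count must lie in [2, 15]")
    rng = substream(seed, "layout")
    layouts = []
    for _ in range(n_trees):
        count = int(np.clip(round(rng.normal(mean_count, count_sd)), 2, 15))
        widths = rng.dirichlet(np.full(count, 3.0))
        edges = np.concatenate([[0.0], np.cumsum(widths)])
        edges[-1] = 1.0
        layouts.append([(float(edges[i]), float(edges[i + 1]))
                        for i in range(count)])
    return layouts


@dataclass
class SimulationDataset:
    """Assembled synthetic inputs for the forward model."""

    preset: SitePreset
    years: tuple[int, int]
    seed: int
    meteo: pd.DataFrame
    forcing: pd.DataFrame
    gasex: pd.DataFrame
    source_water_daily: pd.DataFrame
    drivers: pd.DataFrame
    growth_curves: dict[int, GrowthCurves]

    def replace_source_water(self, d18o_sw_halfhourly: np.ndarray) -> "SimulationDataset":
        drivers = self.drivers.copy()
        drivers["d18o_sw_permil"] = d18o_sw_halfhourly
        return replace(self, drivers=drivers)


def build_dataset(
    preset: SitePreset,
    years: tuple[int, int],
    seed: int,
    gas_params: GasExchangeParams | None = None,
    rootzone_params: RootzoneParams | None = None,
    lai_projected: float = 3.0,
) -> SimulationDataset:
    """Generate all drivers and assemble the forward-model input frame."""
    meteo = gen_meteo(preset, years, seed)
    forcing = gen_isotope_forcing(meteo, preset, seed)
    gasex = gen_gas_exchange(meteo, gas_params, seed,
                             co2_ppm=forcing["co2_ppm"].to_numpy(float))

    # daily rootzone forcing: canopy transpiration scaled by projected LAI
    dt = 1800.0
    et_half = gasex["e_mol_m2_s"].to_numpy(float) * dt * 0.018 * lai_projected
    daily = pd.DataFrame(
        {
            "precip_mm": meteo["precip_mm"].resample("1D").sum(),
            "d18o_precip_permil": forcing["d18o_precip_permil"].resample("1D").mean(),
            "et_mm": pd.Series(et_half, index=meteo.index).resample("1D").sum(),
            "tair_C": meteo["tair_C"].resample("1D").mean(),
        }
    )
    sw_daily = run_rootzone(daily, rootzone_params)
    sw_half = np.repeat(sw_daily["d18o_sw_permil"].to_numpy(float), 48)[: len(meteo)]

    drivers = pd.concat(
        [
            meteo[["tair_C", "rh_pct"]],
            gasex[["an_umol_m2_s", "rd_umol_m2_s", "gs_mol_m2_s", "gb_mol_m2_s",
                   "e_mol_m2_s", "wi_mol_mol", "wa_mol_mol", "ci_ca"]],
            forcing[["d18o_vapor_permil", "d13c_co2_permil"]],
        ],
        axis=1,
    )
    drivers["d18o_sw_permil"] = sw_half
    curves = {y: gen_growth_curves(y, preset, seed) for y in range(years[0], years[1] + 1)}
    return SimulationDataset(
        preset=preset, years=years, seed=seed, meteo=meteo, forcing=forcing,
        gasex=gasex, source_water_daily=sw_daily, drivers=drivers,
        growth_curves=curves,
    )


@dataclass
class TruthBundle:
    """Forward-model truth and noisy observations for recovery experiments."""

    params: IsotopeParams
    noise: NoiseSpec
    seed: int
    forward: ForwardResult
    noiseless: pd.DataFrame
    observed: pd.DataFrame


def make_truth(
    dataset: SimulationDataset,
    layouts: list[list[tuple[float, float]]],
    params: IsotopeParams,
    noise: NoiseSpec,
    seed: int,
) -> TruthBundle:
    """Forward-model 'truth' per tree and subsection, plus noisy observations.

    All trees share the environment and pools; their subsection layouts
    differ, so each tree samples the same ring signal at different
    resolutions.  Observations add a constant per-tree offset (configured
    between-tree SD) and per-subsection analytical noise.  With all noise
    SDs at zero, observations equal the noiseless truth exactly.
    """
    windows: list[TimeWindow] = []
    meta: list[tuple[int, int, float, float]] = []
    for t, layout in enumerate(layouts):
        for year in range(dataset.years[0], dataset.years[1] + 1):
            curves = dataset.growth_curves[year]
            for rel_start, rel_end in layout:
                windows.append(window_for_subsection(curves, rel_start, rel_end))
                meta.append((t, year, rel_start, rel_end))

    fwd = run_forward(dataset.drivers, windows, params)
    table = fwd.table
    # run_forward sorts its table; map windows back by original order
    order = pd.DataFrame(meta, columns=["tree", "year", "rel_start", "rel_end"])
    rows = []
    for i, w in enumerate(windows):
        match = table[(table["year"] == w.year) & (table["start_doy"] == w.start_doy)
                      & (table["end_doy"] == w.end_doy)].iloc[0]
        rows.append(
            {
                "tree_id": f"tree{order.tree[i] + 1}",
                "year": w.year,
                "rel_start": order.rel_start[i],
                "rel_end": order.rel_end[i],
                "start_doy": w.start_doy,
                "end_doy": w.end_doy,
                "d18o_wood_permil": match["d18o_wood_permil"],
                "d13c_wood_permil": match["d13c_wood_permil"],
            }
        )
    noiseless = pd.DataFrame(rows)

    rng = substream(seed, "truth.noise")
    # Between-tree deviations are drawn per tree and year (not as constant
    # whole-series offsets): individual trees track each other only weakly
    # from ring to ring, so their scatter is not a persistent offset.
    keys = sorted(set(zip(noiseless["tree_id"], noiseless["year"])))
    off_o = {k: rng.normal(0.0, noise.tree_sd_o) for k in keys}
    off_c = {k: rng.normal(0.0, noise.tree_sd_c) for k in keys}
    pair = list(zip(noiseless["tree_id"], noiseless["year"]))
    observed = noiseless.copy()
    observed["d18o_wood_permil"] = (
        noiseless["d18o_wood_permil"]
        + np.array([off_o[k] for k in pair])
        + rng.normal(0.0, noise.analytical_sd_o, len(noiseless))
    )
    observed["d13c_wood_permil"] = (
        noiseless["d13c_wood_permil"]
        + np.array([off_c[k] for k in pair])
        + rng.normal(0.0, noise.analytical_sd_c, len(noiseless))
    )
    return TruthBundle(params=params, noise=noise, seed=seed, forward=fwd,
                       noiseless=noiseless, observed=observed)


def observed_subsections(bundle: TruthBundle, isotope: str = "O") -> dict[str, dict[int, list[Subsection]]]:
    """Noisy observations regrouped as tree -> year -> subsections."""
    col = "d18o_wood_permil" if isotope == "O" else "d13c_wood_permil"
    out: dict[str, dict[int, list[Subsection]]] = {}
    for _, row in bundle.observed.iterrows():
        sub = Subsection(
            tree_id=row["tree_id"], year=int(row["year"]),
            rel_start=float(row["rel_start"]), rel_end=float(row["rel_end"]),
            value_permil=float(row[col]), isotope=isotope,
        )
        out.setdefault(row["tree_id"], {}).setdefault(int(row["year"]), []).append(sub)
    return out
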