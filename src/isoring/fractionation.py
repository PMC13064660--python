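"""Isotope ratio/delta conversions and fractionation factors.

All delta values are per-mil (‰) relative to VSMOW (oxygen) or VPDB
(carbon).  Fractionation epsilons are stored in ‰ as well; alphas
(``1 + eps/1000``) are computed on demand, which keeps the unit
convention uniform across the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeStandard",
    "VSMOW",
    "VPDB",
    "FractionationParams",
    "delta_to_ratio",
    "ratio_to_delta",
    "equilibrium_eps",
    "kinetic_alpha",
    "biochemical_eps",
    "load_eps_wc_table",
]


@dataclass(frozen=True)
class IsotopeStandard:
    """Reference standard for an isotope ratio scale."""

    name: str
    r_std: float  # dimensionless heavy/light ratio of the standard

    def __post_init__(self) -> None:
        if self.r_std <= 0:
            raise ValueError(f"reference ratio must be positive, got {self.r_std}")


#: 18O/16O of Vienna Standard Mean Ocean Water.
VSMOW = IsotopeStandard("VSMOW", 2.0052e-3)
#: 13C/12C of Vienna Pee Dee Belemnite.
VPDB = IsotopeStandard("VPDB", 1.11802e-2)


def delta_to_ratio(delta_permil, standard: IsotopeStandard = VSMOW):
    """Convert delta notation (‰) to an absolute isotope ratio.

    ``R = R_std * (1 + delta/1000)``.  Values at or below -1000‰ have no
    physical ratio and raise a ``ValueError``.
    """
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta must be > -1000 permil")
    out = standard.r_std * (1.0 + delta / 1000.0)
    return out if out.ndim else float(out)


def ratio_to_delta(ratio, standard: IsotopeStandard = VSMOW):
    """Convert an absolute isotope ratio to delta notation (‰)."""
    r = np.asarray(ratio, dtype=float)
    out = (r / standard.r_std - 1.0) * 1000.0
    return out if out.ndim else float(out)


_T_MIN_C = -5.0
_T_MAX_C = 45.0


def _check_temperature(temp_c) -> np.ndarray:
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < _T_MIN_C) or np.any(t > _T_MAX_C):
        raise ValueError(
            f"temperature outside supported range [{_T_MIN_C}, {_T_MAX_C}] degC"
        )
    return t


def equilibrium_eps(temp_c):
    """Liquid-vapor 18O equilibrium fractionation eps+ (‰) at ``temp_c`` (°C).

    Uses the Majoube (1971) closed form
    ``1000 ln(alpha) = 1.137e6/T^2 - 0.4156e3/T - 2.0667`` with T in kelvin;
    eps+(20 °C) ≈ 9.8‰, decreasing with temperature.
    """
    t = _check_temperature(temp_c)
    tk = t + 273.15
    ln_alpha = 1.137e6 / tk**2 - 0.4156e3 / tk - 2.0667
    out = (np.exp(ln_alpha / 1000.0) - 1.0) * 1000.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FractionationParams:
    """Kinetic and biochemical fractionation constants.

    eps_kb / eps_ks are the kinetic fractionations for water vapor
    diffusion through the leaf boundary layer (19‰) and stomata (28‰).
    ``eps_wc_table`` is the temperature lookup for the biochemical
    (carbonyl-water) fractionation: a warm plateau at 27‰ with a linear
    rise toward cold temperatures, clamped at the cold end.
    """

    eps_kb: float = 19.0
    eps_ks: float = 28.0
    eps_wc_warm: float = 27.0
    eps_wc_cold: float = 31.0
    t_warm_c: float = 20.0
    t_cold_c: float = 5.0
    eps_wc_table: tuple[tuple[float, float], ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.eps_kb < self.eps_ks:
            raise ValueError("eps_kb must be < eps_ks")
        if self.t_cold_c >= self.t_warm_c:
            raise ValueError("t_cold_c must be < t_warm_c")
        if self.eps_wc_cold < self.eps_wc_warm:
            raise ValueError("eps_wc must be non-increasing in temperature")
        if self.eps_wc_table is not None:
            t, e = zip(*self.eps_wc_table)
            if np.any(np.diff(t) <= 0):
                raise ValueError("eps_wc table temperatures must be increasing")
            if np.any(np.diff(e) > 0):
                raise ValueError("eps_wc table must be non-increasing with temperature")


DEFAULT_FRACTIONATION = FractionationParams()


def kinetic_alpha(g_s, g_b, params: FractionationParams = DEFAULT_FRACTIONATION):
    """Kinetic fractionation factor for vapor diffusion out of the leaf.

    ``alpha_k = 1 + (g_b*eps_ks + g_s*eps_kb) / (g_b + g_s)`` — the
    conductance form of the resistance-weighted mean of the stomatal and
    boundary-layer fractionations; bounded by the two single-pathway
    limits ``1 + eps_kb/1000`` and ``1 + eps_ks/1000``.
    """
    gs = np.asarray(g_s, dtype=float)
    gb = np.asarray(g_b, dtype=float)
    if np.any(gs < 0) or np.any(gb < 0):
        raise ValueError("conductances must be non-negative")
    total = gs + gb
    if np.any(total <= 0):
        raise ValueError("at least one conductance must be positive")
    out = 1.0 + (gb * params.eps_ks + gs * params.eps_kb) / total / 1000.0
    return out if out.ndim else float(out)


def biochemical_eps(temp_c, params: FractionationParams = DEFAULT_FRACTIONATION):
    """Biochemical (carbonyl-water) fractionation eps_wc (‰) at ``temp_c``.

    Piecewise-linear in temperature: constant ``eps_wc_warm`` (default
    27‰) above ``t_warm_c``, rising linearly to ``eps_wc_cold`` at
    ``t_cold_c`` and clamped below; continuous and non-increasing in T.
    A user table (``params.eps_wc_table``) overrides the default shape.
    """
    t = _check_temperature(temp_c)
    if params.eps_wc_table is not None:
        tt, ee = map(np.asarray, zip(*params.eps_wc_table))
        out = np.interp(t, tt, ee)
    else:
        slope = (params.eps_wc_warm - params.eps_wc_cold) / (
            params.t_warm_c - params.t_cold_c
        )
        out = params.eps_wc_cold + slope * (t - params.t_cold_c)
        out = np.clip(out, params.eps_wc_warm, params.eps_wc_cold)
    return out if np.ndim(out) else float(out)


def load_eps_wc_table(path) -> FractionationParams:
    """Load a CSV override (columns ``temperature_C, eps_wc_permil``) for eps_wc.

    The table is checked for monotonicity on load (non-increasing eps with
    increasing temperature).
    """
    df = pd.read_csv(path)
    missing = {"temperature_C", "eps_wc_permil"} - set(df.columns)
    if missing:
        raise ValueError(f"eps_wc table missing columns: {sorted(missing)}")
    df = df.sort_values("temperature_C")
    table = tuple(zip(df["temperature_C"].astype(float), df["eps_wc_permil"].astype(float)))
    return FractionationParams(eps_wc_table=table)
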