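"""Minimal solar geometry: cosine of the solar zenith angle.

Deterministic astronomy used for clear-sky radiation shapes and
clear-sky weighting.  Timestamps are interpreted as local solar time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cos_zenith"]


def cos_zenith(times: pd.DatetimeIndex, latitude_deg: float) -> np.ndarray:
    """Cosine of the solar zenith angle, clamped at 0 below the horizon."""
    if not -90.0 <= latitude_deg <= 90.0:
        raise ValueError("latitude must lie in [-90, 90]")
    doy = times.dayofyear.to_numpy()
    hour = times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    decl = np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (doy + 10) / 365.25)
    lat = np.deg2rad(latitude_deg)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    cosz = (np.sin(lat) * np.sin(decl)
            + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))
    return np.maximum(cosz, 0.0)
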