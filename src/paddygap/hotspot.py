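"""Getis-Ord Gi* hotspot statistic on per-field attribution values.

Local spatial clustering of a field-level scalar (here: a Shapley value for
one management practice) is scored with the self-inclusive Gi* z-statistic
under binary weights within a fixed great-circle distance band:

    z_i = [Σ_j w_ij x_j − X̄ Σ_j w_ij] /
          (S · sqrt[(n Σ_j w_ij² − (Σ_j w_ij)²) / (n − 1)])

with w_ij = 1 iff haversine distance(i, j) ≤ band (including j = i), X̄ and S
the global mean and population standard deviation over all n fields. Hot
spots (z above the two-sided normal critical value) are areas where the value
is consistently high among neighbours; cold spots consistently low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between WGS84 decimal-degree points."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class HotspotResult:
    """Per-field Gi* scores within a fixed distance band."""

    frame: pd.DataFrame  # z, neighbor_count, category (once classified)
    band_km: float

    @property
    def z(self) -> np.ndarray:
        return self.frame["z"].to_numpy(float)


def gi_star(
    lat: np.ndarray,
    lon: np.ndarray,
    values: np.ndarray,
    band_km: float = 10.0,
    chunk: int = 512,
) -> HotspotResult:
    """Gi* z-score for every field with binary weights inside ``band_km``.

    Self-inclusive: every field has at least itself as a neighbour, so the
    statistic is defined even for isolated fields (flagged via
    ``neighbor_count == 1``). If every pair falls inside the band the
    denominator is identically zero and z is reported as 0 for all fields
    (no local deviation is distinguishable from the global mean).
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    x = np.asarray(values, float)
    n = x.size
    if n < 2:
        raise ValueError("gi_star requires at least 2 fields")
    if lat.shape != x.shape or lon.shape != x.shape:
        raise ValueError("lat, lon and values must have equal length")
    xbar = x.mean()
    s = x.std()  # population SD
    if s == 0:
        raise ValueError("degenerate field: values have zero variance")

    w_sum = np.empty(n)
    wx_sum = np.empty(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = haversine_km(
            lat[start:stop, None], lon[start:stop, None], lat[None, :], lon[None, :]
        )
        w = d <= band_km
        w_sum[start:stop] = w.sum(axis=1)
        wx_sum[start:stop] = w @ x

    # binary weights: Σw² = Σw
    denom_sq = (n * w_sum - w_sum**2) / (n - 1)
    numer = wx_sum - xbar * w_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        z = numer / (s * np.sqrt(denom_sq))
    z[denom_sq <= 0] = 0.0

    frame = pd.DataFrame({"z": z, "neighbor_count": w_sum.astype(int)})
    return HotspotResult(frame, band_km=band_km)


def classify_hotspots(result: HotspotResult, alpha: float = 0.05) -> pd.Series:
    """Label each field hot / cold / not significant at the two-sided level alpha.

    No multiplicity correction across fields is applied by default, matching
    the raw Gi* class maps the method produces; pass a smaller alpha for a
    Bonferroni- or FDR-style cutoff computed externally.
    """
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    z = result.z
    cat = np.where(z >= crit, "hot", np.where(z <= -crit, "cold", "not significant"))
    result.frame["category"] = cat
    return pd.Series(cat, index=result.frame.index, name="category")
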