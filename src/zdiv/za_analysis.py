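"""Z/A ratio inference: divergence ratios, geography and Mantel layers.

Reduced effective migration on the Z chromosome leaves a geographic
footprint: where gene flow is strong (nearby population pairs), a
migration barrier specific to the Z keeps dXY(Z) elevated relative to
dXY(A), so the dXY(Z)/dXY(A) ratio declines with geographic distance
(or, using autosomal dXY itself as a gene-flow proxy, rises toward the
least-diverged pairs). This module assembles those ratio series from
pairwise matrices, attaches great-circle distances from population mean
coordinates, bins them for presentation, and tests the association with
one-sided permutation Mantel tests.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .resampling import MantelResult, mantel_test

EARTH_RADIUS_KM = 6371.0


def population_coordinates(meta) -> pd.DataFrame:
    """Arithmetic mean of sample coordinates per population.

    Populations with no located sample are excluded with a warning.
    Naive averaging is used; populations straddling the antimeridian
    trigger a warning because the arithmetic mean is then misleading.
    """
    rows = []
    pops: dict[str, list] = {}
    for m in meta:
        pops.setdefault(m.population, []).append(m)
    for pop, members in pops.items():
        lats = [m.latitude for m in members if math.isfinite(m.latitude)]
        lons = [m.longitude for m in members if math.isfinite(m.longitude)]
        if not lats or not lons:
            warnings.warn(f"population {pop!r} has no coordinates; excluded")
            continue
        if max(lons) - min(lons) > 180:
            warnings.warn(
                f"population {pop!r} straddles the ±180° meridian; "
                "naive coordinate mean used"
            )
        rows.append({"population": pop,
                     "latitude": float(np.mean(lats)),
                     "longitude": float(np.mean(lons))})
    return pd.DataFrame(rows).set_index("population")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on a spherical Earth (R = 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geographic_distance_matrix(coords: pd.DataFrame) -> pd.DataFrame:
    """Symmetric haversine distance matrix (km) from a coordinate table."""
    labels = list(coords.index)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(coords.iloc[i]["latitude"], coords.iloc[i]["longitude"],
                             coords.iloc[j]["latitude"], coords.iloc[j]["longitude"])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def za_ratio_matrix(dxy_auto: pd.DataFrame, dxy_z: pd.DataFrame) -> pd.DataFrame:
    """Elementwise dXY(Z)/dXY(A); NaN where the autosomal entry is zero."""
    if list(dxy_auto.index) != list(dxy_z.index):
        raise ValueError("dXY matrices have mismatched labels")
    a = dxy_auto.to_numpy(dtype=float)
    z = dxy_z.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(a != 0.0, z / a, np.nan)
    return pd.DataFrame(r, index=dxy_auto.index, columns=dxy_auto.columns)


def ratio_series(dxy_auto: pd.DataFrame, dxy_z: pd.DataFrame,
                 distance_km: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format pair table: dXY_A, dXY_Z, ratio and distance per pair."""
    ratio = za_ratio_matrix(dxy_auto, dxy_z)
    labels = list(dxy_auto.index)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({
                "pair": f"{labels[i]}|{labels[j]}",
                "a": labels[i], "b": labels[j],
                "dxy_A": float(dxy_auto.iloc[i, j]),
                "dxy_Z": float(dxy_z.iloc[i, j]),
                "ratio": float(ratio.iloc[i, j]),
                "geographic_km": (float(distance_km.loc[labels[i], labels[j]])
                                  if distance_km is not None else math.nan),
            })
    return pd.DataFrame(rows)


def bin_series(series: pd.DataFrame, axis: str = "geographic_km",
               width: float = 500.0, value: str = "ratio") -> pd.DataFrame:
    """Left-closed fixed-width bins from 0 with median/quartile summaries.

    ``axis`` is the binning variable (``geographic_km`` or ``dxy_A``);
    empty bins up to the last occupied one are reported with n = 0.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    x = series[axis].to_numpy(dtype=float)
    v = series[value].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(v)
    x, v = x[ok], v[ok]
    if x.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "n",
                                     "median", "q25", "q75"])
    n_bins = int(x.max() // width) + 1
    rows = []
    for b in range(n_bins):
        lo, hi = b * width, (b + 1) * width
        sel = v[(x >= lo) & (x < hi)]
        rows.append({
            "bin_left": lo, "bin_right": hi, "n": int(sel.size),
            "median": float(np.median(sel)) if sel.size else math.nan,
            "q25": float(np.quantile(sel, 0.25)) if sel.size else math.nan,
            "q75": float(np.quantile(sel, 0.75)) if sel.size else math.nan,
        })
    return pd.DataFrame(rows)


def ratio_vs_proxy_test(ratio_matrix: pd.DataFrame, proxy_matrix: pd.DataFrame,
                        proxy: str = "distance", n_permutations: int = 999,
                        seed: int | None = None,
                        alternative: str = "greater") -> MantelResult:
    """Mantel test of the Z/A divergence ratio against a gene-flow proxy.

    With ``proxy="distance"`` the hypothesized association is *negative*
    (higher ratio between nearby pairs), so the proxy is negated before
    the one-sided test; with ``proxy="dxy_A"`` the same direction is
    hypothesized (higher ratio at lower autosomal divergence) and the
    proxy is likewise negated. A positive Mantel r therefore always
    means "ratio elevated where gene flow is plausibly higher".
    """
    if proxy not in ("distance", "dxy_A"):
        raise ValueError("proxy must be 'distance' or 'dxy_A'")
    neg = proxy_matrix.copy()
    vals = -neg.to_numpy(dtype=float)
    np.fill_diagonal(vals, 0.0)
    neg = pd.DataFrame(vals, index=proxy_matrix.index,
                       columns=proxy_matrix.columns)
    return mantel_test(ratio_matrix, neg, n_permutations=n_permutations,
                       seed=seed, alternative=alternative)
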