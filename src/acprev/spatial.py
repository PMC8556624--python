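"""Inequality and spatial-clustering summaries of AC-level estimates.

Provides queen-contiguity spatial weights (two polygons are neighbours if
they share at least one boundary point), global Moran's I with its analytic
randomization-null two-tailed p-value (normal-approximation and permutation
nulls also available), per-state dispersion summaries (median, IQR, SD;
quantiles by linear interpolation), and equal-count decile classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import PolygonLayer

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    ids: list
    w: np.ndarray                 # binary symmetric adjacency, zero diagonal
    row_standardized: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        return float(self.w.sum())

    def islands(self) -> list:
        deg = self.w.sum(axis=1)
        return [self.ids[i] for i in np.flatnonzero(deg == 0)]

    def neighbors(self) -> dict:
        return {
            self.ids[i]: {self.ids[j] for j in np.flatnonzero(self.w[i] > 0)}
            for i in range(self.n)
        }

    def standardized(self) -> "SpatialWeights":
        deg = self.w.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            ws = np.where(deg > 0, self.w / deg, 0.0)
        return SpatialWeights(list(self.ids), ws, row_standardized=True)


def queen_weights(layer: PolygonLayer, id_col: str = "ac_id") -> SpatialWeights:
    """Queen contiguity: w_ij = 1 iff polygons i != j touch at any point."""
    if len(layer) < 2:
        raise ValueError("need at least 2 polygons for contiguity weights")
    from shapely.strtree import STRtree

    ids = list(layer.df[id_col])
    geoms = layer.geoms
    tree = STRtree(geoms)
    n = len(ids)
    w = np.zeros((n, n))
    for i in range(n):
        for j in (int(k) for k in tree.query(geoms[i], predicate="intersects")):
            if j != i and not geoms[i].intersection(geoms[j]).is_empty:
                w[i, j] = 1.0
                w[j, i] = 1.0
    isl = SpatialWeights(ids, w).islands()
    if isl:
        logger.info("%d island polygons (no neighbours): %s", len(isl), isl[:5])
    return SpatialWeights(ids, w)


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    null: str
    n: int
    n_islands_dropped: int = 0


def _moran_stat(x: np.ndarray, w: np.ndarray) -> float:
    n = len(x)
    z = x - x.mean()
    s0 = w.sum()
    return float(n / s0 * (z @ w @ z) / (z @ z))


def morans_i(
    values,
    weights: SpatialWeights,
    null: str = "randomization",
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with a two-tailed p-value.

    ``null``: 'randomization' (default; moment-based variance under random
    permutation of values), 'normal' (normality assumption), or
    'permutation' (Monte-Carlo, >= 999 draws recommended).  Island units are
    excluded with a warning.  All-equal values are a domain error.
    """
    x = np.asarray(values, dtype=float)
    if len(x) != weights.n:
        raise ValueError("values and weights have different lengths")
    keep = weights.w.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} island units from Moran's I")
    x = x[keep]
    w = weights.w[np.ix_(keep, keep)]
    n = len(x)
    if n < 2 or w.sum() == 0:
        raise ValueError("Moran's I needs >= 2 connected units (S0 > 0)")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for constant values")

    I = _moran_stat(x, w)
    e_i = -1.0 / (n - 1)
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()

    def _z_p(var):
        # degenerate graphs (e.g. fully connected) have zero null variance
        if not np.isfinite(var) or var <= 0:
            return float("nan"), float("nan"), 0.0
        z_sc = (I - e_i) / np.sqrt(var)
        return z_sc, 2.0 * norm.sf(abs(z_sc)), var

    if null == "normal":
        var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i * e_i
        z_sc, p, var = _z_p(var)
    elif null == "randomization":
        if n < 4:
            raise ValueError("randomization variance needs n >= 4 units")
        zc = x - x.mean()
        b2 = n * (zc**4).sum() / ((zc**2).sum() ** 2)
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
            (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i * e_i
        z_sc, p, var = _z_p(var)
    elif null == "permutation":
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for t in range(n_perm):
            sims[t] = _moran_stat(rng.permutation(x), w)
        var = float(sims.var(ddof=1))
        z_sc = (I - e_i) / np.sqrt(var) if var > 0 else float("nan")
        # two-tailed Monte-Carlo p around the permutation mean
        p_hi = (1 + (sims >= I).sum()) / (n_perm + 1)
        p_lo = (1 + (sims <= I).sum()) / (n_perm + 1)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
    else:
        raise ValueError(f"unknown null: {null!r}")
    return MoranResult(
        I=I, expected=e_i, variance=float(var), z=float(z_sc), p_value=float(p),
        null=null, n=n, n_islands_dropped=n_dropped,
    )


def state_summaries(ac_estimates: pd.DataFrame, value_col: str = "prevalence") -> pd.DataFrame:
    """Median, 25th/75th percentiles, IQR and SD of AC estimates per state.

    Adds an 'ALL' row per indicator for the pooled (all-states) summary.
    Quantiles use linear interpolation; the SD of a single-AC state is
    reported as missing.
    """
    def _summ(g: pd.DataFrame) -> pd.Series:
        v = g[value_col].to_numpy(dtype=float)
        q25, med, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
        return pd.Series(
            {
                "n_acs": len(v),
                "median": med,
                "q25": q25,
                "q75": q75,
                "iqr": q75 - q25,
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                "min": v.min(),
                "max": v.max(),
            }
        )

    parts = []
    grouped = ac_estimates.groupby(["indicator", "state_id"], dropna=False)
    per_state = grouped.apply(_summ, include_groups=False).reset_index()
    parts.append(per_state)
    overall = ac_estimates.groupby("indicator").apply(_summ, include_groups=False).reset_index()
    overall.insert(1, "state_id", "ALL")
    parts.append(overall)
    out = pd.concat(parts, ignore_index=True)
    out["n_acs"] = out["n_acs"].astype(int)
    return out


def decile_classes(values) -> np.ndarray:
    """Equal-count decile class (1..10) per value; ties keep first-seen rank order."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 10:
        warnings.warn(f"only {n} values: decile classes collapse")
    if n == 0:
        return np.array([], dtype=int)
    if np.ptp(x) == 0:
        warnings.warn("all values equal: every unit in class 1")
        return np.ones(n, dtype=int)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * 10) // n + 1
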