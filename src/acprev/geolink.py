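"""Cluster-to-polygon linkage: direct point-in-polygon and buffer reassignment.

Survey cluster GPS points are randomly displaced for privacy (up to 2 km
urban / 5 km rural), so the polygon containing the published point may not
be the polygon the cluster actually lies in.  Two linkages are produced:

* ``direct_assign`` — take the displaced point at face value ("nonadjustment
  sample");
* ``buffer_reassign`` — intersect a displacement-radius buffer with all
  polygons and assign the polygon holding the largest share of the buffer
  area ("reassignment sample").

Drop rules mirror the survey linkage: missing coordinates, points/buffers
outside the polygon layer, and polygons with a null (or duplicated) unit
name.  All geometry is planar; layers in geographic coordinates should be
projected first (see :func:`to_local_equal_area`).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .io import PolygonLayer

logger = logging.getLogger(__name__)

DROP_NONE = "none"
DROP_MISSING = "missing-coords"
DROP_OUTSIDE = "outside-boundary"
DROP_NULL_NAME = "null-ac-name"


class AmbiguousAssignmentError(ValueError):
    """A point lies in the interior of more than one polygon."""


def _bad_name_mask(layer: PolygonLayer, id_col: str) -> np.ndarray:
    ids = layer.df[id_col]
    null = ids.isna() | (ids.astype(str).str.strip() == "")
    dup = ids.duplicated(keep=False) & ~null
    return (null | dup).to_numpy()


def to_local_equal_area(lon, lat, lon0: float, lat0: float):
    """Spherical Lambert azimuthal equal-area projection (metres).

    Minimal stand-in for a full projection library: adequate for computing
    buffer area ratios from geographic coordinates over survey-scale extents.
    """
    R = 6_371_000.0
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    k = np.sqrt(2.0 / denom)
    x = R * k * np.cos(phi) * np.sin(lam - lam0)
    y = R * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return x, y


def direct_assign(
    points: pd.DataFrame,
    layer: PolygonLayer,
    id_col: str = "ac_id",
) -> pd.DataFrame:
    """Point-in-polygon spatial join with the survey linkage's drop rules.

    Boundary points contained by several polygons (shared edges) go to the
    lexicographically smallest id; a point in the *interior* of two polygons
    means the layer genuinely overlaps and raises
    :class:`AmbiguousAssignmentError`.
    """
    layer = layer.repaired()
    bad_name = _bad_name_mask(layer, id_col)
    tree = STRtree(layer.geoms)
    rows = []
    ids_arr = points["cluster_id"].tolist()
    xs = points["x"].tolist()
    ys = points["y"].tolist()
    for cid, x, y in zip(ids_arr, xs, ys):
        rec = {"cluster_id": cid, id_col: None,
               "method": "direct", "drop_reason": DROP_NONE, "area_ratios": None}
        if pd.isna(x) or pd.isna(y):
            rec["drop_reason"] = DROP_MISSING
            rows.append(rec)
            continue
        pt = Point(float(x), float(y))
        cand = [int(i) for i in tree.query(pt, predicate="covered_by")]
        interior = [i for i in cand if layer.geoms[i].contains(pt)]
        if len(interior) > 1:
            ids = sorted(str(layer.df.iloc[i][id_col]) for i in interior)
            raise AmbiguousAssignmentError(
                f"point for cluster {cid} lies inside overlapping polygons: {ids}"
            )
        chosen = interior if interior else cand
        if not chosen:
            rec["drop_reason"] = DROP_OUTSIDE
        else:
            idx = min(chosen, key=lambda i: str(layer.df.iloc[i][id_col]))
            if bad_name[idx]:
                rec["drop_reason"] = DROP_NULL_NAME
            else:
                rec[id_col] = layer.df.iloc[idx][id_col]
        rows.append(rec)
    return pd.DataFrame(rows)


def buffer_reassign(
    points: pd.DataFrame,
    layer: PolygonLayer,
    urban_radius: float = 2000.0,
    rural_radius: float = 5000.0,
    id_col: str = "ac_id",
    quad_segs: int = 128,
    constraint: Polygon | None = None,
) -> pd.DataFrame:
    """Displacement-aware linkage: assign the polygon with the highest
    buffer-area ratio.

    Per cluster, a circle of the urban (2 km) or rural (5 km) displacement
    radius is intersected with every polygon; ``area_ratios`` maps polygon id
    to intersection area / buffer area, and the argmax wins.  Ratio ties go
    to the smallest id with a logged warning.  An optional ``constraint``
    polygon (e.g. the admin unit displacement was confined to) clips the
    buffer first; off by default.
    """
    if urban_radius <= 0 or rural_radius <= 0:
        raise ValueError("displacement radii must be positive")
    layer = layer.repaired()
    bad_name = _bad_name_mask(layer, id_col)
    tree = STRtree(layer.geoms)
    urban = (
        points["urban"].tolist() if "urban" in points.columns else [0] * len(points)
    )
    rows = []
    for cid, x, y, urb in zip(
        points["cluster_id"].tolist(), points["x"].tolist(), points["y"].tolist(), urban
    ):
        rec = {"cluster_id": cid, id_col: None,
               "method": "reassigned", "drop_reason": DROP_NONE, "area_ratios": None}
        if pd.isna(x) or pd.isna(y):
            rec["drop_reason"] = DROP_MISSING
            rows.append(rec)
            continue
        r = urban_radius if urb == 1 else rural_radius
        buf = Point(float(x), float(y)).buffer(r, quad_segs=quad_segs)
        if constraint is not None:
            buf = buf.intersection(constraint)
        buf_area = buf.area
        ratios = {}
        for i in (int(j) for j in tree.query(buf, predicate="intersects")):
            inter = layer.geoms[i].intersection(buf)
            if inter.area <= 0:
                continue
            pid = layer.df.iloc[i][id_col]
            key = "<null>" if bad_name[i] else str(pid)
            ratios[key] = ratios.get(key, 0.0) + inter.area / buf_area
        if not ratios:
            rec["drop_reason"] = DROP_OUTSIDE
            rows.append(rec)
            continue
        best = max(ratios.values())
        winners = sorted(k for k, v in ratios.items() if abs(v - best) < 1e-12)
        if len(winners) > 1:
            logger.warning(
                "cluster %s: area-ratio tie between %s; taking smallest id", cid, winners
            )
        rec["area_ratios"] = ratios
        if winners[0] == "<null>":
            rec["drop_reason"] = DROP_NULL_NAME
        else:
            rec[id_col] = winners[0]
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_linkages(
    direct: pd.DataFrame,
    reassigned: pd.DataFrame,
    child_counts: pd.Series | None = None,
    id_col: str = "ac_id",
) -> dict:
    """Agreement diagnostics between the nonadjustment and reassignment linkages."""
    m = direct.merge(reassigned, on="cluster_id", suffixes=("_direct", "_reassigned"))
    both = m[(m[f"drop_reason_direct"] == DROP_NONE) & (m[f"drop_reason_reassigned"] == DROP_NONE)]
    differing = both[both[f"{id_col}_direct"].astype(str) != both[f"{id_col}_reassigned"].astype(str)]
    report = {
        "n_clusters": int(len(m)),
        "n_compared": int(len(both)),
        "n_differing": int(len(differing)),
        "fraction_differing": float(len(differing) / len(both)) if len(both) else float("nan"),
        "drop_crosstab": pd.crosstab(
            m["drop_reason_direct"], m["drop_reason_reassigned"]
        ),
        "differing_cluster_ids": differing["cluster_id"].tolist(),
    }
    if child_counts is not None:
        counts = child_counts.copy()
        counts.index = counts.index.astype(str)
        total = float(counts.reindex(both["cluster_id"].astype(str)).fillna(0).sum())
        moved = float(counts.reindex(differing["cluster_id"].astype(str)).fillna(0).sum())
        report["n_children_differing"] = int(moved)
        report["fraction_children_differing"] = moved / total if total else float("nan")
    return report
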