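"""Aggregation of cluster prevalences to electoral units (ACs).

The AC estimate is the unweighted arithmetic mean of the posterior
prevalences of its member clusters (a child-weighted option exists, default
off).  For the 5-level sensitivity model ACs must be forced into the
district tree: the district holding strictly more than 60% of an AC's linked
clusters wins; otherwise the district with the largest area of overlap with
the AC polygon.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import PolygonLayer

logger = logging.getLogger(__name__)


def ac_prevalence(
    cluster_estimates: pd.DataFrame,
    linkage: pd.DataFrame,
    indicator: str = "",
    state_of_ac: pd.Series | dict | None = None,
    child_weighted: bool = False,
) -> pd.DataFrame:
    """Per-AC prevalence: mean of member-cluster posterior prevalences.

    ``linkage`` is a linkage table (cluster_id, ac_id, drop_reason); dropped
    clusters and clusters without estimates are excluded.  ACs that end up
    with zero linked estimated clusters are absent from the output (logged).
    """
    link = linkage[linkage["drop_reason"] == "none"][["cluster_id", "ac_id"]]
    est = cluster_estimates.copy()
    est["cluster_id"] = est["cluster_id"].astype(str)
    link = link.copy()
    link["cluster_id"] = link["cluster_id"].astype(str)
    merged = link.merge(est, on="cluster_id", how="inner", validate="one_to_one")
    missing = set(est["cluster_id"]) - set(linkage["cluster_id"].astype(str))
    if missing:
        raise ValueError(
            f"{len(missing)} estimated clusters absent from linkage, e.g. {sorted(missing)[:5]}"
        )
    n_empty = linkage["ac_id"].nunique() - merged["ac_id"].nunique()
    if n_empty > 0:
        logger.info("%d ACs have no linked estimated clusters and are omitted", n_empty)

    def _agg(g: pd.DataFrame) -> pd.Series:
        if child_weighted and "n_children" in g:
            w = g["n_children"].to_numpy(dtype=float)
            prev = float(np.average(g["prevalence"], weights=w))
        else:
            prev = float(g["prevalence"].mean())
        return pd.Series(
            {
                "prevalence": prev,
                "n_clusters": int(len(g)),
                "n_children": int(g["n_children"].sum()) if "n_children" in g else 0,
                "prev_min": float(g["prevalence"].min()),
                "prev_max": float(g["prevalence"].max()),
            }
        )

    out = merged.groupby("ac_id").apply(_agg, include_groups=False).reset_index()
    out["n_clusters"] = out["n_clusters"].astype(int)
    out["n_children"] = out["n_children"].astype(int)
    out.insert(1, "indicator", indicator)
    if state_of_ac is not None:
        mapper = state_of_ac if isinstance(state_of_ac, dict) else state_of_ac.to_dict()
        out.insert(1, "state_id", out["ac_id"].map(mapper))
    return out


def assign_ac_to_district(
    linkage: pd.DataFrame,
    cluster_districts: pd.Series | pd.DataFrame,
    ac_layer: PolygonLayer,
    district_layer: PolygonLayer,
    majority: float = 0.6,
) -> pd.DataFrame:
    """Resolve each AC to one district for the 5-level model.

    Rule: the district covering strictly more than 60% of the AC's linked
    clusters; if no district clears that bar (clusters spread relatively
    equally), the district whose polygon overlaps the AC polygon with the
    largest area.  ACs with no linked clusters are excluded with a warning.
    Returns columns ac_id, district_id, rule ('majority' | 'area').
    """
    if isinstance(cluster_districts, pd.DataFrame):
        cluster_districts = cluster_districts.set_index("cluster_id")["district_id"]
    cd = cluster_districts.copy()
    cd.index = cd.index.astype(str)
    link = linkage[linkage["drop_reason"] == "none"][["cluster_id", "ac_id"]].copy()
    link["district_id"] = link["cluster_id"].astype(str).map(cd)

    ac_geom = dict(zip(ac_layer.df["ac_id"].astype(str), ac_layer.geoms))
    d_geom = dict(zip(district_layer.df["district_id"].astype(str), district_layer.geoms))

    rows = []
    for ac_id, g in link.groupby("ac_id"):
        counts = g["district_id"].value_counts()
        total = counts.sum()
        top_share = counts.iloc[0] / total
        if top_share > majority:
            rows.append({"ac_id": ac_id, "district_id": counts.index[0], "rule": "majority"})
            continue
        poly = ac_geom.get(str(ac_id))
        if poly is None:
            raise KeyError(f"AC {ac_id} missing from the polygon layer")
        best_d, best_area = None, -1.0
        for d_id in sorted(d_geom):
            area = poly.intersection(d_geom[d_id]).area
            if area > best_area:
                best_d, best_area = d_id, area
        rows.append({"ac_id": ac_id, "district_id": best_d, "rule": "area"})
    n_empty = ac_layer.df["ac_id"].astype(str).nunique() - len(rows)
    if n_empty > 0:
        logger.warning("%d ACs have no linked clusters and get no district assignment", n_empty)
    return pd.DataFrame(rows)


def compare_models(est4: pd.DataFrame, est5: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of |p4 - p5| in percentage points, per indicator."""
    m = est4.merge(est5, on=["ac_id", "indicator"], suffixes=("_4", "_5"))
    if m.empty:
        raise ValueError("no common (ac_id, indicator) pairs between the two estimate sets")
    m["abs_diff_pp"] = (m["prevalence_4"] - m["prevalence_5"]).abs() * 100.0
    out = (
        m.groupby("indicator")["abs_diff_pp"]
        .agg(mean_abs_diff_pp="mean", sd_abs_diff_pp="std", n_acs="count")
        .reset_index()
    )
    out["n_acs"] = out["n_acs"].astype(int)
    return out
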