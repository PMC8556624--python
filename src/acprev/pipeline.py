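"""End-to-end pipeline: simulate/load -> link -> samples -> fit -> aggregate -> summarize.

Stage order follows the source analysis workflow: clusters are linked to AC
polygons (both the nonadjustment and the displacement-aware reassignment
linkage), analytic samples are built, the multilevel model is fitted per
indicator and linkage, cluster prevalences are aggregated to ACs, and
dispersion/spatial-clustering summaries are produced.  A step-count table
records children/clusters/ACs/states surviving each stage with percentages
of the initial counts.  Every output embeds the seed and a config hash so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import geolink, indicators, mlm, spatial, synthetic
from .io import PolygonLayer, config_hash, write_csv, write_gal

logger = logging.getLogger(__name__)

INDICATOR_FLAG = {
    "stunting": "stunted",
    "underweight": "underweight",
    "wasting": "wasted",
    "anemia": "anemic",
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


@dataclass
class PipelineConfig:
    geography: synthetic.GeographySpec = field(default_factory=synthetic.GeographySpec)
    n_children_per_cluster: int = 10
    missingness: dict = field(default_factory=dict)
    indicators: tuple = ("stunting", "underweight", "wasting", "anemia")
    linkage_modes: tuple = ("direct", "reassigned")
    urban_radius: float = 2000.0
    rural_radius: float = 5000.0
    burn_in: int = 5000
    n_iter: int = 50_000
    thin: int = 1
    estimator_mode: str = "transform"
    moran_null: str = "randomization"
    run_sensitivity: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geography"] = dataclasses.asdict(self.geography)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "geography" in d and isinstance(d["geography"], dict):
            d["geography"] = synthetic.GeographySpec(**d["geography"])
        for key in ("indicators", "linkage_modes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _pct(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else float("nan")


def _linkage_for_mode(mode, clusters, ac_layer, cfg):
    pts = clusters[["cluster_id", "x", "y", "urban"]]
    if mode == "direct":
        return geolink.direct_assign(pts, ac_layer)
    if mode == "reassigned":
        return geolink.buffer_reassign(
            pts, ac_layer, urban_radius=cfg.urban_radius, rural_radius=cfg.rural_radius
        )
    raise ValueError(f"unknown linkage mode {mode!r}")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; write artifacts under ``outdir``; return them in memory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config_hash(config.to_dict())}
    (outdir / "config.json").write_text(
        json.dumps({"config": config.to_dict(), **meta}, indent=2, sort_keys=True, default=str)
    )
    out: dict = {"config": config, "meta": meta}

    def stage(name):
        logger.info("stage: %s", name)

    # -- simulate -----------------------------------------------------------
    try:
        stage("simulate")
        geo = synthetic.make_geography(config.geography, seed=config.seed)
        clusters = synthetic.displace_clusters(
            geo.clusters, config.urban_radius, config.rural_radius, seed=config.seed + 1
        )
        lms = synthetic.synthetic_lms_table()
        children, outcomes, truth = synthetic.simulate_children(
            clusters,
            n_children_per_cluster=config.n_children_per_cluster,
            missingness=config.missingness,
            seed=config.seed + 2,
            lms_table=lms,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"simulate: {exc}") from exc
    geo.acs.to_geojson(outdir / "geography_acs.geojson", metadata=meta)
    geo.districts.to_geojson(outdir / "geography_districts.geojson", metadata=meta)
    write_csv(clusters, outdir / "clusters.csv", metadata=meta)
    write_csv(children, outdir / "children.csv", metadata=meta)
    write_csv(outcomes, outdir / "outcomes.csv", metadata=meta)
    write_csv(truth, outdir / "truth.csv", metadata=meta)
    write_csv(lms, outdir / "lms_table.csv", metadata=meta)
    out.update(geography=geo, clusters=clusters, children=children, outcomes=outcomes, truth=truth)

    # -- link ---------------------------------------------------------------
    linkages = {}
    try:
        stage("link")
        for mode in config.linkage_modes:
            tab = _linkage_for_mode(mode, clusters, geo.acs, config)
            linkages[mode] = tab
            ser = tab.copy()
            ser["area_ratios"] = ser["area_ratios"].map(
                lambda d: json.dumps(d, sort_keys=True) if isinstance(d, dict) else ""
            )
            write_csv(ser, outdir / f"linkage_{mode}.csv", metadata=meta)
        if len(linkages) == 2:
            counts = children.groupby("cluster_id")["child_id"].count()
            counts.index = counts.index.astype(str)
            rep = geolink.compare_linkages(
                linkages["direct"], linkages["reassigned"], child_counts=counts
            )
            rep_out = {k: v for k, v in rep.items() if k != "drop_crosstab"}
            rep_out["drop_crosstab"] = rep["drop_crosstab"].to_dict()
            (outdir / "linkage_comparison.json").write_text(
                json.dumps(rep_out, indent=2, sort_keys=True, default=str)
            )
            out["linkage_comparison"] = rep
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"link: {exc}") from exc
    out["linkages"] = linkages

    # -- samples ------------------------------------------------------------
    try:
        stage("samples")
        samples = indicators.build_analytic_samples(children, lms_table=lms)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"samples: {exc}") from exc
    write_csv(samples.exclusion_log, outdir / "exclusion_log.csv", metadata=meta)
    out["samples"] = samples

    hier = clusters.set_index("cluster_id")[["district_id", "state_id"]]
    state_of_ac = dict(zip(geo.acs.df["ac_id"].astype(str), geo.acs.df["state_id"]))

    # -- fit + aggregate + summarize per linkage mode ----------------------
    step_rows = []
    n_children0 = len(children)
    n_clusters0 = len(clusters)
    n_acs0 = len(geo.acs)
    n_states0 = geo.acs.df["state_id"].nunique()
    all_ac_estimates: dict[str, pd.DataFrame] = {}
    cluster_prev_store: dict[tuple, pd.DataFrame] = {}
    for mode, link in linkages.items():
        ok = link[link["drop_reason"] == "none"]
        linked_cluster_ids = set(ok["cluster_id"])
        kids_linked = children[children["cluster_id"].isin(linked_cluster_ids)]
        step_rows.append(
            {
                "sample": mode, "step": "step1-spatial-join", "children": np.nan,
                "children_pct": np.nan,
                "clusters": len(ok), "clusters_pct": _pct(len(ok), n_clusters0),
                "acs": ok["ac_id"].nunique(), "acs_pct": _pct(ok["ac_id"].nunique(), n_acs0),
                "states": hier.loc[list(linked_cluster_ids), "state_id"].nunique(),
                "states_pct": _pct(
                    hier.loc[list(linked_cluster_ids), "state_id"].nunique(), n_states0
                ),
            }
        )
        cl_with_kids = set(kids_linked["cluster_id"])
        step_rows.append(
            {
                "sample": mode, "step": "step2-child-linkage",
                "children": len(kids_linked),
                "children_pct": _pct(len(kids_linked), n_children0),
                "clusters": len(cl_with_kids), "clusters_pct": _pct(len(cl_with_kids), n_clusters0),
                "acs": ok[ok["cluster_id"].isin(cl_with_kids)]["ac_id"].nunique(),
                "acs_pct": _pct(
                    ok[ok["cluster_id"].isin(cl_with_kids)]["ac_id"].nunique(), n_acs0
                ),
                "states": hier.loc[list(cl_with_kids), "state_id"].nunique(),
                "states_pct": _pct(hier.loc[list(cl_with_kids), "state_id"].nunique(), n_states0),
            }
        )

        ests = []
        for ind in config.indicators:
            flag = INDICATOR_FLAG[ind]
            base = samples.anemia if ind == "anemia" else samples.anthro
            sub = base[base["cluster_id"].isin(linked_cluster_ids)].copy()
            sub = sub[sub[flag].notna()]
            sub["y"] = sub[flag].astype(int)
            sub = sub.join(hier, on="cluster_id")
            step_name = (
                "step3-anemia-sample" if ind == "anemia" else "step3-anthro-sample"
            )
            if not any(
                r["sample"] == mode and r["step"] == step_name for r in step_rows
            ):
                sub_cl = sub["cluster_id"].nunique()
                step_rows.append(
                    {
                        "sample": mode, "step": step_name,
                        "children": len(sub), "children_pct": _pct(len(sub), n_children0),
                        "clusters": sub_cl, "clusters_pct": _pct(sub_cl, n_clusters0),
                        "acs": ok[ok["cluster_id"].isin(set(sub["cluster_id"]))]["ac_id"].nunique(),
                        "acs_pct": _pct(
                            ok[ok["cluster_id"].isin(set(sub["cluster_id"]))]["ac_id"].nunique(),
                            n_acs0,
                        ),
                        "states": sub["state_id"].nunique(),
                        "states_pct": _pct(sub["state_id"].nunique(), n_states0),
                    }
                )
            try:
                stage(f"fit:{mode}:{ind}")
                cfg = mlm.MCMCConfig(
                    burn_in=config.burn_in, n_iter=config.n_iter, thin=config.thin,
                    seed=(
                        config.seed * 1009
                        + 10 * list(config.indicators).index(ind)
                        + list(config.linkage_modes).index(mode)
                    ) % (2**31),
                )
                draws = mlm.fit_four_level(sub, cfg)
                nch = sub.groupby("cluster_id")["child_id"].count()
                cp = mlm.cluster_prevalence(draws, mode=config.estimator_mode, n_children=nch)
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"fit:{mode}:{ind}: {exc}") from exc
            cluster_prev_store[(mode, ind)] = cp
            write_csv(cp, outdir / f"cluster_prevalence_{mode}_{ind}.csv", metadata=meta)
            try:
                est = agg.ac_prevalence(cp, link, indicator=ind, state_of_ac=state_of_ac)
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"aggregate:{mode}:{ind}: {exc}") from exc
            est["decile"] = spatial.decile_classes(est["prevalence"]) if len(est) else []
            ests.append(est)
        ac_est = pd.concat(ests, ignore_index=True)
        all_ac_estimates[mode] = ac_est
        write_csv(ac_est, outdir / f"ac_estimates_{mode}.csv", metadata=meta)
        joined = geo.acs.df.copy()
        for ind in config.indicators:
            e = ac_est[ac_est["indicator"] == ind].set_index("ac_id")
            joined[f"prev_{ind}"] = joined["ac_id"].astype(str).map(e["prevalence"])
            joined[f"decile_{ind}"] = joined["ac_id"].astype(str).map(e["decile"])
        PolygonLayer(joined, geo.acs.geoms).to_geojson(
            outdir / f"ac_estimates_{mode}.geojson", metadata=meta
        )

        # join estimates onto polygons for mapping
        try:
            stage(f"summarize:{mode}")
            summ = spatial.state_summaries(ac_est)
            write_csv(summ, outdir / f"state_summaries_{mode}.csv", metadata=meta)
            weights = spatial.queen_weights(geo.acs)
            write_gal(weights.neighbors(), outdir / f"queen_weights_{mode}.gal")
            moran_rows = []
            for ind in config.indicators:
                e = ac_est[ac_est["indicator"] == ind].set_index("ac_id")["prevalence"]
                scopes = [("ALL", list(geo.acs.df["ac_id"].astype(str)))]
                for st, g in geo.acs.df.groupby("state_id"):
                    scopes.append((st, list(g["ac_id"].astype(str))))
                for scope, ac_ids in scopes:
                    present = [a for a in ac_ids if a in e.index]
                    row = {"indicator": ind, "scope": scope, "n_acs": len(present)}
                    try:
                        idx = [
                            i for i in range(len(geo.acs))
                            if str(geo.acs.df.iloc[i]["ac_id"]) in set(present)
                        ]
                        sub_layer = PolygonLayer(
                            geo.acs.df.iloc[idx].copy(), [geo.acs.geoms[i] for i in idx]
                        )
                        wts = spatial.queen_weights(sub_layer)
                        res = spatial.morans_i(
                            e.loc[[str(geo.acs.df.iloc[i]["ac_id"]) for i in idx]].to_numpy(),
                            wts, null=config.moran_null, seed=config.seed + 7,
                        )
                        row.update(
                            moran_i=res.I, expected=res.expected, variance=res.variance,
                            z=res.z, p_value=res.p_value, null=res.null,
                        )
                    except ValueError as exc:
                        row.update(moran_i=np.nan, p_value=np.nan, note=str(exc))
                    moran_rows.append(row)
            write_csv(pd.DataFrame(moran_rows), outdir / f"moran_{mode}.csv", metadata=meta)
            out[f"moran_{mode}"] = pd.DataFrame(moran_rows)
            out[f"state_summaries_{mode}"] = summ
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"summarize:{mode}: {exc}") from exc

    out["ac_estimates"] = all_ac_estimates
    out["cluster_prevalence"] = cluster_prev_store

    step_counts = pd.DataFrame(step_rows)
    write_csv(step_counts, outdir / "step_counts.csv", metadata=meta)
    out["step_counts"] = step_counts

    # -- optional 5-level sensitivity on the first linkage mode -------------
    if config.run_sensitivity:
        try:
            stage("sensitivity-5level")
            mode = config.linkage_modes[0]
            link = linkages[mode]
            ac_map = agg.assign_ac_to_district(
                link, clusters.set_index("cluster_id")["district_id"], geo.acs, geo.districts
            )
            comp_rows = []
            est5_all = []
            for ind in config.indicators:
                flag = INDICATOR_FLAG[ind]
                base = samples.anemia if ind == "anemia" else samples.anthro
                ok = link[link["drop_reason"] == "none"]
                sub = base[base["cluster_id"].isin(set(ok["cluster_id"]))].copy()
                sub = sub[sub[flag].notna()]
                sub["y"] = sub[flag].astype(int)
                sub = sub.join(hier, on="cluster_id")
                amap = dict(zip(ok["cluster_id"].astype(str), ok["ac_id"].astype(str)))
                sub["ac_id"] = sub["cluster_id"].astype(str).map(amap)
                cfg = mlm.MCMCConfig(
                    burn_in=config.burn_in, n_iter=config.n_iter, thin=config.thin,
                    seed=(
                        config.seed * 1009 + 10 * list(config.indicators).index(ind) + 5
                    ) % (2**31),
                )
                draws5 = mlm.fit_five_level(sub, ac_map, cfg)
                nch = sub.groupby("cluster_id")["child_id"].count()
                cp5 = mlm.cluster_prevalence(draws5, mode=config.estimator_mode, n_children=nch)
                est5 = agg.ac_prevalence(cp5, link, indicator=ind, state_of_ac=state_of_ac)
                est5_all.append(est5)
            est5_df = pd.concat(est5_all, ignore_index=True)
            write_csv(est5_df, outdir / f"ac_estimates_{mode}_5level.csv", metadata=meta)
            comp = agg.compare_models(all_ac_estimates[mode], est5_df)
            write_csv(comp, outdir / "model_comparison.csv", metadata=meta)
            out["model_comparison"] = comp
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"sensitivity: {exc}") from exc

    return out
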