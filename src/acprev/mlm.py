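"""Bayesian multilevel logistic models for cluster-level prevalence.

The estimation model is an intercept-only random-effects logistic
regression: for child *i* in cluster *j*, district *k*, state *l*,

    logit P(y_ijkl = 1) = beta0 + u_l + v_kl + w_jkl,
    u ~ N(0, sig2_state), v ~ N(0, sig2_district), w ~ N(0, sig2_cluster),

fitted by an exact Polya-Gamma-augmented Gibbs sampler with noninformative
priors (N(0, 1e6) on beta0; InverseGamma(0.001, 0.001) on each variance).
The 5-level sensitivity variant inserts an electoral-unit (AC) intercept
between cluster and district.  Cluster-specific prevalences are
precision-weighted (shrunken) posterior summaries: by default the posterior
mean of inverse-logit(beta0 + u + v + w) computed per iteration
(transform-then-average); a plug-in mode applying the inverse logit to the
posterior-mean linear predictor is also provided.

Defaults follow the source analysis: burn-in 5000, 50 000 monitored
iterations, a single chain.  Tests and the bundled drivers run much shorter
chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from ._pg import gibbs_logit_ranef
from .synthetic import FourLevelSpec  # noqa: F401  (re-export: generative twin)


class HierarchyError(ValueError):
    """Child table's cluster/district/state (or AC) ids are inconsistent."""


@dataclass(frozen=True)
class MCMCConfig:
    burn_in: int = 5000
    n_iter: int = 50_000
    thin: int = 1
    seed: int = 0
    beta0_prior_var: float = 1e6
    ig_shape: float = 0.001
    ig_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("require burn_in >= 0, n_iter >= 1, thin >= 1")


@dataclass
class PosteriorDraws:
    """MCMC draws for a fitted N-level model plus unit-id bookkeeping."""

    beta0: np.ndarray                      # (T,)
    sig2: pd.DataFrame                     # (T, K) columns e.g. sig2_state, ...
    effects: dict[str, np.ndarray]         # level -> (T, n_units)
    unit_ids: dict[str, np.ndarray]        # level -> ids in effect-column order
    lineage: pd.DataFrame                  # one row per cluster: its ancestor unit ids
    config: MCMCConfig
    levels: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return len(self.beta0)

    def unit_index(self, level: str) -> dict:
        return {uid: i for i, uid in enumerate(self.unit_ids[level])}

    def diagnostics(self) -> pd.DataFrame:
        """Effective sample size and split-Rhat for beta0 and the variances."""
        rows = []
        for name, draws in [("beta0", self.beta0)] + [
            (c, self.sig2[c].to_numpy()) for c in self.sig2.columns
        ]:
            half = len(draws) // 2
            split = np.vstack([draws[:half], draws[half : 2 * half]])
            constant = np.ptp(draws) == 0  # e.g. a variance pinned at zero
            rows.append(
                {
                    "param": name,
                    "mean": float(np.mean(draws)),
                    "sd": float(np.std(draws)),
                    "ess": float("nan") if constant else float(az.ess(np.asarray(draws)[None, :])),
                    "rhat_split": float("nan") if constant else float(az.rhat(split)),
                }
            )
        return pd.DataFrame(rows)


def _validate_hierarchy(df: pd.DataFrame, parent_of: list[tuple[str, str]]) -> None:
    for child_col, parent_col in parent_of:
        counts = df.groupby(child_col)[parent_col].nunique()
        bad = counts[counts > 1]
        if len(bad):
            raise HierarchyError(
                f"{child_col} -> {parent_col} is not a function; offending "
                f"{child_col}s: {list(bad.index[:5])}"
            )


def _fit(
    df: pd.DataFrame,
    level_cols: list[str],
    config: MCMCConfig,
    fix_zero: tuple[str, ...] = (),
) -> PosteriorDraws:
    y = df["y"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        warnings.warn("all outcomes identical: intercept is weakly identified")

    n = len(df)
    mem = np.zeros((len(level_cols), n), dtype=np.int64)
    n_units = np.zeros(len(level_cols), dtype=np.int64)
    unit_ids = {}
    for k, col in enumerate(level_cols):
        # first-appearance ordering keeps the sampler equivariant under
        # relabelling: renaming units does not reshuffle the RNG stream
        vals = df[col].astype(str)
        cats = pd.Categorical(vals, categories=pd.unique(vals))
        mem[k] = cats.codes
        n_units[k] = len(cats.categories)
        unit_ids[col] = np.asarray(cats.categories)
    free = np.array([col not in fix_zero for col in level_cols], dtype=np.bool_)

    n_keep = config.n_iter // config.thin
    b0, s2, eff = gibbs_logit_ranef(
        y, mem, n_units, free,
        config.beta0_prior_var, config.ig_shape, config.ig_rate,
        config.burn_in, n_keep, config.thin, config.seed % (2**31),
    )
    offsets = np.concatenate([[0], np.cumsum(n_units)])
    effects = {
        col: eff[:, offsets[k] : offsets[k + 1]] for k, col in enumerate(level_cols)
    }
    sig2 = pd.DataFrame(
        s2, columns=[f"sig2_{c.removesuffix('_id')}" for c in level_cols]
    )
    lineage = (
        df[["cluster_id"] + [c for c in level_cols if c != "cluster_id"]]
        .drop_duplicates("cluster_id")
        .reset_index(drop=True)
    )
    lineage["cluster_id"] = lineage["cluster_id"].astype(str)
    return PosteriorDraws(
        beta0=b0, sig2=sig2, effects=effects, unit_ids=unit_ids,
        lineage=lineage, config=config, levels=tuple(level_cols),
    )


def fit_four_level(
    sample: pd.DataFrame,
    config: MCMCConfig | None = None,
    fix_zero: tuple[str, ...] = (),
) -> PosteriorDraws:
    """Fit the 4-level model (child < cluster < district < state).

    ``sample`` needs columns y, cluster_id, district_id, state_id.
    ``fix_zero`` names levels whose variance is pinned at zero (their random
    intercepts stay 0) — used for desk-scale oracle checks.
    """
    config = config or MCMCConfig()
    _validate_hierarchy(sample, [("cluster_id", "district_id"), ("district_id", "state_id")])
    return _fit(sample, ["state_id", "district_id", "cluster_id"], config, fix_zero)


def fit_five_level(
    sample: pd.DataFrame,
    ac_map: pd.DataFrame | dict,
    config: MCMCConfig | None = None,
    fix_zero: tuple[str, ...] = (),
) -> PosteriorDraws:
    """Sensitivity model with an AC intercept between cluster and district.

    ``sample`` needs an ``ac_id`` column (the cluster's linked AC);
    ``ac_map`` gives the resolved AC-to-district assignment (dict or a
    DataFrame with ac_id / district_id), which replaces the sample's own
    district ids so the hierarchy is a tree.  An AC mapped to several
    districts is a validation error — resolve upstream.
    """
    config = config or MCMCConfig()
    if isinstance(ac_map, pd.DataFrame):
        if ac_map["ac_id"].duplicated().any():
            raise HierarchyError("ac_map assigns some AC to multiple districts")
        mapping = dict(zip(ac_map["ac_id"].astype(str), ac_map["district_id"].astype(str)))
    else:
        mapping = {str(k): str(v) for k, v in ac_map.items()}
    df = sample.copy()
    df["ac_id"] = df["ac_id"].astype(str)
    unmapped = set(df["ac_id"]) - set(mapping)
    if unmapped:
        raise HierarchyError(f"ACs without a district assignment: {sorted(unmapped)[:5]}")
    df["district_id"] = df["ac_id"].map(mapping)
    _validate_hierarchy(
        df,
        [("cluster_id", "ac_id"), ("ac_id", "district_id"), ("district_id", "state_id")],
    )
    return _fit(df, ["state_id", "district_id", "ac_id", "cluster_id"], config, fix_zero)


def cluster_prevalence(
    draws: PosteriorDraws,
    mode: str = "transform",
    n_children: pd.Series | None = None,
) -> pd.DataFrame:
    """Precision-weighted cluster prevalences from posterior draws.

    ``transform`` (default): p_t = expit(beta0_t + effects_t) per iteration,
    summarised by its mean and 2.5/97.5 percentiles.  ``plugin``: expit of
    the posterior-mean linear predictor (no credible bounds beyond the
    transformed percentiles of the linear predictor).
    """
    if mode not in ("transform", "plugin"):
        raise ValueError("mode must be 'transform' or 'plugin'")
    lin = draws.lineage
    t = draws.n_draws
    psi = np.tile(draws.beta0[:, None], (1, len(lin)))
    for level in draws.levels:
        idx_map = draws.unit_index(level)
        col = "cluster_id" if level == "cluster_id" else level
        idx = np.array([idx_map[str(u)] for u in lin[col].astype(str)])
        psi += draws.effects[level][:, idx]
    p_mat = expit(psi)
    point = p_mat.mean(axis=0) if mode == "transform" else expit(psi.mean(axis=0))
    out = pd.DataFrame(
        {
            "cluster_id": lin["cluster_id"].to_numpy(),
            "prevalence": point,
            "ci_lo": np.percentile(p_mat, 2.5, axis=0),
            "ci_hi": np.percentile(p_mat, 97.5, axis=0),
        }
    )
    if n_children is not None:
        nc = n_children.copy()
        nc.index = nc.index.astype(str)
        out["n_children"] = out["cluster_id"].astype(str).map(nc).fillna(0).astype(int)
    return out
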