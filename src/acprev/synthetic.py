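"""Synthetic survey world: geography, cluster displacement, and child outcomes.

Emulates the structure of a DHS-style survey linked to electoral-unit
polygons: children nest in clusters, clusters in districts, districts in
states, while the electoral units (assembly constituencies, ACs) tile each
state on a grid whose boundaries deliberately do NOT align with district
boundaries — so ACs cross districts, exactly the non-nesting that motivates
the whole pipeline.  Cluster GPS points are randomly displaced (up to 2 km
urban / 5 km rural, the DHS privacy rule), and child outcomes are drawn from
the same 4-level random-intercept logistic model the estimation stage
assumes, so every downstream stage can be tested against known truth.

All geometry is planar, in metres; there is no geodesy here by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm
from shapely.geometry import box

from .io import PolygonLayer

INDICATORS = ("stunting", "underweight", "wasting", "anemia")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GeographySpec:
    """Counts and sizes of the synthetic survey geography."""

    n_states: int = 4
    districts_per_state: int = 3
    acs_per_state: int = 9
    clusters_per_ac: int = 4
    urban_fraction: float = 0.3
    cell_size: float = 10_000.0  # AC cell edge, metres
    # interior district boundaries are shifted by this fraction of a cell so
    # that AC columns straddle districts (0 -> districts may nest ACs exactly)
    district_offset_frac: float = 0.4

    def __post_init__(self) -> None:
        for name in ("n_states", "districts_per_state", "acs_per_state", "clusters_per_ac"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigurationError(f"urban_fraction must be in [0,1], got {self.urban_fraction}")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")


@dataclass(frozen=True)
class FourLevelSpec:
    """Generative (and fitted) random-intercept logistic model parameters.

    ``beta0`` is the intercept on the logit scale; the variances are those of
    the state, district, cluster (and, for the 5-level variant, AC) random
    intercepts.
    """

    beta0: float
    var_state: float = 0.3
    var_district: float = 0.2
    var_cluster: float = 0.4
    var_ac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("var_state", "var_district", "var_cluster", "var_ac"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


#: Default generative spec per indicator.  Intercepts are the logits of the
#: national AC-level median prevalences reported for NFHS-4 (stunting 35.56%,
#: underweight 32.82%, wasting 19.91%, anemia 55.74%); variance components
#: use the reference simulation values (0.3 / 0.2 / 0.4).
DEFAULT_SPECS: dict[str, FourLevelSpec] = {
    "stunting": FourLevelSpec(beta0=float(logit(0.3556))),
    "underweight": FourLevelSpec(beta0=float(logit(0.3282))),
    "wasting": FourLevelSpec(beta0=float(logit(0.1991))),
    "anemia": FourLevelSpec(beta0=float(logit(0.5574))),
}

#: Default per-field missingness, chosen to reproduce the survey's attrition:
#: ~85.6% of children survive the height/weight screen and ~83% the
#: hemoglobin screen.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "age_months": 0.01,
    "height_cm": 0.07,
    "weight_kg": 0.07,
    "hb_gdl": 0.16,
}


@dataclass
class Geography:
    acs: PolygonLayer           # ac_id, state_id
    districts: PolygonLayer     # district_id, state_id
    clusters: pd.DataFrame      # cluster_id, x, y, urban, ac_id_true, district_id, state_id


def _state_grid(n_acs: int) -> tuple[int, int]:
    cols = int(np.ceil(np.sqrt(n_acs)))
    rows = int(np.ceil(n_acs / cols))
    return rows, cols


def make_geography(spec: GeographySpec, seed: int) -> Geography:
    """Build AC and district polygon layers plus clusters with true hierarchy ids.

    ACs tile each state's rectangular extent on a near-square grid; districts
    are vertical strips of the same extent whose interior boundaries are
    offset from the AC grid, so ACs generically span two districts.  Clusters
    are placed uniformly within their AC.
    """
    rng = np.random.default_rng(seed)
    rows, cols = _state_grid(spec.acs_per_state)
    cell = spec.cell_size
    width = cols * cell
    height = rows * cell

    ac_rows, ac_geoms = [], []
    d_rows, d_geoms = [], []
    cl_rows = []
    ac_counter = 0
    d_counter = 0
    cluster_counter = 0
    for s in range(spec.n_states):
        state_id = f"S{s:02d}"
        x0 = s * (width + cell)  # one-cell gap between states: no cross-state adjacency
        # district strips
        bounds = [x0 + k * width / spec.districts_per_state for k in range(spec.districts_per_state + 1)]
        for k in range(1, spec.districts_per_state):
            bounds[k] = min(max(bounds[k] + spec.district_offset_frac * cell, x0), x0 + width)
        district_ids = []
        for k in range(spec.districts_per_state):
            d_rows.append({"district_id": f"D{d_counter:03d}", "state_id": state_id})
            district_ids.append(f"D{d_counter:03d}")
            d_geoms.append(box(bounds[k], 0.0, bounds[k + 1], height))
            d_counter += 1
        d_bounds = np.asarray(bounds)

        # AC cells, last row widened to tile the full extent
        n_last = spec.acs_per_state - (rows - 1) * cols
        for r in range(rows):
            n_in_row = cols if r < rows - 1 else n_last
            w_cell = width / n_in_row
            for c in range(n_in_row):
                ac_id = f"AC{ac_counter:04d}"
                gx0 = x0 + c * w_cell
                poly = box(gx0, r * cell, gx0 + w_cell, (r + 1) * cell)
                ac_rows.append({"ac_id": ac_id, "state_id": state_id})
                ac_geoms.append(poly)
                ac_counter += 1
                for _ in range(spec.clusters_per_ac):
                    px = rng.uniform(gx0, gx0 + w_cell)
                    py = rng.uniform(r * cell, (r + 1) * cell)
                    # district = strip containing x (right-open intervals)
                    k = int(np.searchsorted(d_bounds, px, side="right") - 1)
                    k = min(max(k, 0), spec.districts_per_state - 1)
                    cl_rows.append(
                        {
                            "cluster_id": cluster_counter,
                            "x": px,
                            "y": py,
                            "urban": int(rng.random() < spec.urban_fraction),
                            "ac_id_true": ac_id,
                            "district_id": district_ids[k],
                            "state_id": state_id,
                        }
                    )
                    cluster_counter += 1

    return Geography(
        acs=PolygonLayer(pd.DataFrame(ac_rows), ac_geoms),
        districts=PolygonLayer(pd.DataFrame(d_rows), d_geoms),
        clusters=pd.DataFrame(cl_rows),
    )


def displace_clusters(
    clusters: pd.DataFrame,
    urban_radius: float = 2000.0,
    rural_radius: float = 5000.0,
    seed: int = 0,
    far_fraction: float = 0.0,
    far_radius: float = 10_000.0,
) -> pd.DataFrame:
    """Random displacement: distance ~ U(0, r), angle ~ U(0, 2*pi).

    ``r`` is 2 km for urban and 5 km for rural clusters.  The DHS practice of
    sending 1% of rural clusters up to 10 km is off by default
    (``far_fraction=0``).  True coordinates are kept as ``x_true``/``y_true``.
    """
    if urban_radius < 0 or rural_radius < 0 or far_radius < 0:
        raise ConfigurationError("displacement radii must be non-negative")
    if not 0.0 <= far_fraction <= 1.0:
        raise ConfigurationError("far_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    out = clusters.copy()
    n = len(out)
    radius = np.where(out["urban"].to_numpy() == 1, urban_radius, rural_radius).astype(float)
    if far_fraction > 0:
        far = (out["urban"].to_numpy() == 0) & (rng.random(n) < far_fraction)
        radius = np.where(far, far_radius, radius)
    dist = rng.uniform(0.0, radius, size=n) if n else np.empty(0)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    out["x_true"] = out["x"]
    out["y_true"] = out["y"]
    out["x"] = out["x_true"] + dist * np.cos(theta)
    out["y"] = out["y_true"] + dist * np.sin(theta)
    out["displacement_m"] = dist
    return out


# ---------------------------------------------------------------------------
# Synthetic growth reference (LMS) table
# ---------------------------------------------------------------------------

def synthetic_lms_table() -> pd.DataFrame:
    """Deterministic synthetic LMS reference with plausible smooth curves.

    SYNTHETIC stand-in for an official growth reference: columns
    (measure, sex, x, L, M, S) in the same layout, with x = age in months for
    height-for-age / weight-for-age and x = height in cm for
    weight-for-height.  Official tables can be supplied in the same format;
    they are never bundled.
    """
    rows = []
    ages = np.arange(0, 60)
    for sex, f in (("male", 0.0), ("female", 1.0)):
        m_h = 49.0 + 6.0 * np.sqrt(ages) + 0.25 * ages - 0.8 * f
        for a, m in zip(ages, m_h):
            rows.append(("height-for-age", sex, float(a), 1.0, round(float(m), 4), 0.035))
        m_w = 3.3 + 1.3 * np.sqrt(ages) + 0.08 * ages - 0.25 * f
        for a, m in zip(ages, m_w):
            rows.append(("weight-for-age", sex, float(a), 0.25, round(float(m), 4), 0.12))
    heights = np.arange(45.0, 120.5, 0.5)
    for sex, scale in (("male", 1.0), ("female", 0.97)):
        m_wh = (2.4 + 0.16 * (heights - 45.0) + 0.0012 * (heights - 45.0) ** 2) * scale
        for h, m in zip(heights, m_wh):
            rows.append(("weight-for-height", sex, float(h), -0.35, round(float(m), 4), 0.085))
    return pd.DataFrame(rows, columns=["measure", "sex", "x", "L", "M", "S"])


def lms_inverse(z, L, M, S):
    """Measurement value whose LMS z-score is ``z`` (inverse Box-Cox)."""
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    z = np.asarray(z, dtype=float)
    with np.errstate(invalid="ignore"):
        x = np.where(L != 0, M * np.power(1.0 + L * S * z, 1.0 / np.where(L != 0, L, 1.0)),
                     M * np.exp(S * z))
    return x


def _interp_lms(table: pd.DataFrame, measure: str, sex_arr: np.ndarray, x_arr: np.ndarray):
    L = np.empty(len(x_arr))
    M = np.empty(len(x_arr))
    S = np.empty(len(x_arr))
    for sex in ("male", "female"):
        sub = table[(table["measure"] == measure) & (table["sex"] == sex)].sort_values("x")
        mask = sex_arr == sex
        if mask.any():
            L[mask] = np.interp(x_arr[mask], sub["x"], sub["L"])
            M[mask] = np.interp(x_arr[mask], sub["x"], sub["M"])
            S[mask] = np.interp(x_arr[mask], sub["x"], sub["S"])
    return L, M, S


def _tail_z(rng: np.random.Generator, flags: np.ndarray, threshold: float = -2.0,
            lo: float = -5.5, hi: float = 5.5) -> np.ndarray:
    """Standard-normal z truncated to the side of ``threshold`` selected by flags."""
    z = np.empty(len(flags))
    below = flags.astype(bool)
    if below.any():
        z[below] = truncnorm.rvs(lo, threshold, size=int(below.sum()), random_state=rng)
    if (~below).any():
        z[~below] = truncnorm.rvs(threshold, hi, size=int((~below).sum()), random_state=rng)
    return z


def simulate_children(
    clusters: pd.DataFrame,
    specs: dict[str, FourLevelSpec] | None = None,
    n_children_per_cluster: int = 10,
    missingness: dict[str, float] | None = None,
    seed: int = 0,
    lms_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate child records from the 4-level model and back-generate measures.

    Returns ``(children, outcomes, truth)``:

    * ``children`` — the survey-like table: child_id, cluster_id, age_months,
      sex, height_cm, weight_kg, hb_gdl (with missingness applied);
    * ``outcomes`` — the simulated binary flags per child (ground truth the
      indicators module must reproduce when nothing is missing);
    * ``truth`` — per cluster and indicator, the true linear predictor and
      prevalence plus the cluster's true AC/district/state ids.

    Stunting, underweight and anemia are independent Bernoulli draws from
    their own 4-level specs, realised through height (via HAZ), weight (via
    WAZ) and hemoglobin.  A single weight value cannot also carry an
    independent weight-for-height flag, so the wasting flag is *derived* from
    the WHZ implied by the generated (height, weight) pair; its marginal
    prevalence is emergent.  Anemia outcomes apply only at ages 6-59 months.
    """
    specs = dict(DEFAULT_SPECS, **(specs or {}))
    rates = dict(DEFAULT_MISSINGNESS, **(missingness or {}))
    for key, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missingness rate for {key} must be in [0,1], got {rate}")
    if lms_table is None:
        lms_table = synthetic_lms_table()
    rng = np.random.default_rng(seed)

    cl = clusters.reset_index(drop=True)
    n_cl = len(cl)
    states = cl["state_id"].astype(str)
    districts = cl["district_id"].astype(str)
    state_ids = np.sort(states.unique())
    district_ids = np.sort(districts.unique())
    s_idx = pd.Categorical(states, categories=state_ids).codes
    d_idx = pd.Categorical(districts, categories=district_ids).codes

    n = n_cl * n_children_per_cluster
    child_cluster = np.repeat(cl["cluster_id"].to_numpy(), n_children_per_cluster)
    child_s = np.repeat(s_idx, n_children_per_cluster)
    child_d = np.repeat(d_idx, n_children_per_cluster)
    child_c = np.repeat(np.arange(n_cl), n_children_per_cluster)

    age = rng.integers(0, 60, size=n)
    sex = np.where(rng.random(n) < 0.517, "male", "female")

    truth_rows = []
    y = {}
    eta_by_ind = {}
    for ind in ("stunting", "underweight", "anemia"):
        sp = specs[ind]
        u = rng.normal(0.0, np.sqrt(sp.var_state), size=len(state_ids))
        v = rng.normal(0.0, np.sqrt(sp.var_district), size=len(district_ids))
        w = rng.normal(0.0, np.sqrt(sp.var_cluster), size=n_cl)
        eta_cl = sp.beta0 + u[s_idx] + v[d_idx] + w
        eta_by_ind[ind] = eta_cl
        p_child = expit(eta_cl[child_c])
        y[ind] = (rng.random(n) < p_child).astype(int)
        for j in range(n_cl):
            truth_rows.append(
                {
                    "cluster_id": int(cl.loc[j, "cluster_id"]),
                    "indicator": ind,
                    "ac_id_true": cl.loc[j, "ac_id_true"] if "ac_id_true" in cl else None,
                    "district_id": cl.loc[j, "district_id"],
                    "state_id": cl.loc[j, "state_id"],
                    "eta_true": float(eta_cl[j]),
                    "p_true": float(expit(eta_cl[j])),
                }
            )

    # back-generate continuous measures
    z_haz = _tail_z(rng, y["stunting"])
    L, M, S = _interp_lms(lms_table, "height-for-age", sex, age.astype(float))
    height = lms_inverse(z_haz, L, M, S)

    z_waz = _tail_z(rng, y["underweight"])
    L, M, S = _interp_lms(lms_table, "weight-for-age", sex, age.astype(float))
    weight = lms_inverse(z_waz, L, M, S)

    # wasting derived from the implied weight-for-height z-score
    from .indicators import lms_zscore  # local import to avoid cycle at module load

    Lw, Mw, Sw = _interp_lms(lms_table, "weight-for-height", sex, height)
    z_whz = lms_zscore(weight, Lw, Mw, Sw)
    y["wasting"] = (z_whz < -2.0).astype(int)
    # cluster-level truth for wasting: empirical prevalence of the derived flag
    wast = pd.DataFrame({"c": child_c, "y": y["wasting"]}).groupby("c")["y"].mean()
    for j in range(n_cl):
        p = float(wast.get(j, np.nan))
        truth_rows.append(
            {
                "cluster_id": int(cl.loc[j, "cluster_id"]),
                "indicator": "wasting",
                "ac_id_true": cl.loc[j, "ac_id_true"] if "ac_id_true" in cl else None,
                "district_id": cl.loc[j, "district_id"],
                "state_id": cl.loc[j, "state_id"],
                "eta_true": float(logit(min(max(p, 1e-6), 1 - 1e-6))) if np.isfinite(p) else np.nan,
                "p_true": p,
            }
        )

    # hemoglobin: anemia applies at 6-59 months only
    hb = np.empty(n)
    applicable = (age >= 6) & (age <= 59)
    anem = y["anemia"].astype(bool)
    lo_n = int((applicable & anem).sum())
    hi_n = int((applicable & ~anem).sum())
    a_lo, b_lo = (6.0 - 11.6) / 1.4, (11.0 - 11.6) / 1.4   # hb < 11
    a_hi, b_hi = (11.0 - 11.6) / 1.4, (16.5 - 11.6) / 1.4  # hb >= 11
    hb[applicable & anem] = 11.6 + 1.4 * truncnorm.rvs(a_lo, b_lo, size=lo_n, random_state=rng)
    hb[applicable & ~anem] = 11.6 + 1.4 * truncnorm.rvs(a_hi, b_hi, size=hi_n, random_state=rng)
    hb[~applicable] = rng.normal(11.6, 1.4, size=int((~applicable).sum()))
    y_anemia = y["anemia"].astype(float)
    y_anemia[~applicable] = np.nan

    children = pd.DataFrame(
        {
            "child_id": np.arange(n),
            "cluster_id": child_cluster,
            "age_months": age.astype(float),
            "sex": sex,
            "height_cm": height,
            "weight_kg": weight,
            "hb_gdl": hb,
        }
    )
    for col in ("age_months", "height_cm", "weight_kg", "hb_gdl"):
        rate = rates.get(col, 0.0)
        if rate > 0:
            children.loc[rng.random(n) < rate, col] = np.nan

    outcomes = pd.DataFrame(
        {
            "child_id": np.arange(n),
            "cluster_id": child_cluster,
            "y_stunting": y["stunting"],
            "y_underweight": y["underweight"],
            "y_wasting": y["wasting"],
            "y_anemia": y_anemia,
        }
    )
    truth = pd.DataFrame(truth_rows)
    return children, outcomes, truth
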