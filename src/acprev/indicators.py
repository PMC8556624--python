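"""Binary undernutrition indicators and the two analytic samples.

Four indicators for under-five children: stunting (height-for-age z < -2),
underweight (weight-for-age z < -2), wasting (weight-for-height z < -2) and
anemia (hemoglobin < 11.0 g/dL, assessed only at ages 6-59 months).
Thresholds are strict ("less than").  Missing inputs propagate: a child with
a missing measurement simply drops out of the corresponding analytic sample.

z-scores use the LMS (Box-Cox) transform against an age/sex-specific
reference table; precomputed z columns are also accepted so survey files
that ship z-scores can bypass the transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import _interp_lms


def lms_zscore(x, L, M, S):
    """LMS z-score: ((x/M)^L - 1) / (L*S) for L != 0, ln(x/M)/S for L = 0.

    Missing (NaN) measurements give NaN; nonpositive x or M is a domain
    error.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("LMS parameters require M > 0 and S > 0")
    if np.any(x[~np.isnan(x)] <= 0):
        raise ValueError("measurement values must be positive")
    with np.errstate(invalid="ignore"):
        z = np.where(L != 0, (np.power(x / M, L) - 1.0) / (L * S), np.log(x / M) / S)
    return z


def derive_zscores(children: pd.DataFrame, lms_table: pd.DataFrame) -> pd.DataFrame:
    """Attach z_haz, z_waz, z_whz computed from measures + LMS reference."""
    out = children.copy()
    sex = out["sex"].to_numpy(dtype=object)
    age = out["age_months"].to_numpy(dtype=float)
    height = out["height_cm"].to_numpy(dtype=float)
    weight = out["weight_kg"].to_numpy(dtype=float)

    def _z(measure, x_index, value):
        z = np.full(len(out), np.nan)
        ok = ~(np.isnan(x_index) | np.isnan(value))
        if ok.any():
            L, M, S = _interp_lms(lms_table, measure, sex[ok], x_index[ok])
            z[ok] = lms_zscore(value[ok], L, M, S)
        return z

    out["z_haz"] = _z("height-for-age", age, height)
    out["z_waz"] = _z("weight-for-age", age, weight)
    out["z_whz"] = _z("weight-for-height", height, weight)
    return out


def classify(
    z_haz,
    z_waz,
    z_whz,
    hb_gdl,
    age_months,
    implausible_filter: bool = False,
) -> pd.DataFrame:
    """Binary flags from z-scores and hemoglobin.

    Strict thresholds: z < -2.0 and hb < 11.0 g/dL; anemia is evaluated only
    for ages 6-59 months (not-applicable otherwise).  With
    ``implausible_filter`` set, biologically implausible z-scores
    (|HAZ| > 6, |WHZ| > 5, WAZ outside [-6, 5]) are blanked before
    classification; the survey analysis this emulates did not apply it, so it
    defaults off.
    """
    z_haz = np.asarray(z_haz, dtype=float).copy()
    z_waz = np.asarray(z_waz, dtype=float).copy()
    z_whz = np.asarray(z_whz, dtype=float).copy()
    hb = np.asarray(hb_gdl, dtype=float)
    age = np.asarray(age_months, dtype=float)
    if implausible_filter:
        z_haz[np.abs(z_haz) > 6] = np.nan
        z_whz[np.abs(z_whz) > 5] = np.nan
        z_waz[(z_waz < -6) | (z_waz > 5)] = np.nan

    def _flag(z):
        return pd.array(np.where(np.isnan(z), None, z < -2.0), dtype="boolean")

    anemia_applicable = (age >= 6) & (age <= 59)
    anemic = np.where(
        np.isnan(hb) | np.isnan(age) | ~anemia_applicable, None, hb < 11.0
    )
    return pd.DataFrame(
        {
            "stunted": _flag(z_haz),
            "underweight": _flag(z_waz),
            "wasted": _flag(z_whz),
            "anemic": pd.array(anemic, dtype="boolean"),
        }
    )


@dataclass
class AnalyticSamples:
    anthro: pd.DataFrame
    anemia: pd.DataFrame
    exclusion_log: pd.DataFrame

    def exclusion_text(self) -> str:
        lines = ["sample\treason\tn"]
        for _, r in self.exclusion_log.iterrows():
            lines.append(f"{r['sample']}\t{r['reason']}\t{r['n']}")
        return "\n".join(lines) + "\n"


def build_analytic_samples(
    children: pd.DataFrame,
    lms_table: pd.DataFrame | None = None,
    implausible_filter: bool = False,
) -> AnalyticSamples:
    """Construct the anthropometry and anemia analytic samples.

    The anthropometry sample requires non-missing age, height and weight; the
    anemia sample requires non-missing hemoglobin and age 6-59 months.  The
    two are built independently — a child missing only height stays in the
    anemia sample.  If the input lacks z-score columns they are derived from
    the LMS table first.  The exclusion log counts children per drop reason
    (a child is counted once per sample, under its first failing reason in
    the order age, height, weight / age, age-range, hemoglobin).
    """
    if children.empty:
        warnings.warn("empty child table: analytic samples are empty")
        log = pd.DataFrame(columns=["sample", "reason", "n"])
        return AnalyticSamples(children.copy(), children.copy(), log)
    df = children.copy()
    if not {"z_haz", "z_waz", "z_whz"}.issubset(df.columns):
        if lms_table is None:
            raise ValueError("need either z-score columns or an LMS reference table")
        df = derive_zscores(df, lms_table)

    flags = classify(
        df["z_haz"], df["z_waz"], df["z_whz"], df["hb_gdl"], df["age_months"],
        implausible_filter=implausible_filter,
    )
    df = pd.concat([df.reset_index(drop=True), flags], axis=1)

    age = df["age_months"].to_numpy(dtype=float)
    miss_age = np.isnan(age)
    miss_h = df["height_cm"].isna().to_numpy()
    miss_w = df["weight_kg"].isna().to_numpy()
    miss_hb = df["hb_gdl"].isna().to_numpy()

    in_anthro = ~(miss_age | miss_h | miss_w)
    age_in_range = (age >= 6) & (age <= 59)
    in_anemia = ~miss_age & age_in_range & ~miss_hb
    df["in_anthro_sample"] = in_anthro
    df["in_anemia_sample"] = in_anemia

    log_rows = [
        ("anthro", "missing-age", int(miss_age.sum())),
        ("anthro", "missing-height", int((~miss_age & miss_h).sum())),
        ("anthro", "missing-weight", int((~miss_age & ~miss_h & miss_w).sum())),
        ("anthro", "retained", int(in_anthro.sum())),
        ("anemia", "missing-age", int(miss_age.sum())),
        ("anemia", "age-outside-6-59m", int((~miss_age & ~age_in_range).sum())),
        ("anemia", "missing-hemoglobin", int((~miss_age & age_in_range & miss_hb).sum())),
        ("anemia", "retained", int(in_anemia.sum())),
    ]
    log = pd.DataFrame(log_rows, columns=["sample", "reason", "n"])
    return AnalyticSamples(
        anthro=df.loc[in_anthro].reset_index(drop=True),
        anemia=df.loc[in_anemia].reset_index(drop=True),
        exclusion_log=log,
    )
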