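"""Dispersion and spatial clustering of AC estimates.

Per-state median/IQR/SD of AC prevalence, plus global Moran's I with queen
contiguity (two-tailed p from the randomization null) per state and across
the whole synthetic country.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd  # noqa: E402
from _common import RESULTS, SEED, build_world  # noqa: E402

from acprev import spatial  # noqa: E402
from acprev.io import PolygonLayer, read_csv, write_csv, write_gal  # noqa: E402


def main() -> None:
    geo, _, _, _, _, _ = build_world()
    est_path = RESULTS / "ac_estimates_direct.csv"
    if not est_path.exists():
        print(f"run 05_aggregate.py first ({est_path} missing)")
        return
    est = read_csv(est_path)

    summ = spatial.state_summaries(est)
    write_csv(summ, RESULTS / "state_summaries.csv", metadata={"seed": SEED})
    print("per-state IQR of stunting prevalence:")
    print(summ[(summ["indicator"] == "stunting")][
        ["state_id", "n_acs", "median", "iqr", "sd"]
    ].to_string(index=False))

    weights = spatial.queen_weights(geo.acs)
    write_gal(weights.neighbors(), RESULTS / "queen_weights.gal")

    rows = []
    for ind, g in est.groupby("indicator"):
        scopes = [("ALL", None)] + [(s, s) for s in sorted(geo.acs.df["state_id"].unique())]
        for label, state in scopes:
            df_acs = geo.acs.df if state is None else geo.acs.df[geo.acs.df["state_id"] == state]
            idx = list(df_acs.index)
            sub_layer = PolygonLayer(df_acs.copy(), [geo.acs.geoms[i] for i in idx])
            gg = g.set_index("ac_id")["prevalence"]
            present = [i for i in idx if str(geo.acs.df.loc[i, "ac_id"]) in gg.index]
            vals = [gg[str(geo.acs.df.loc[i, "ac_id"])] for i in present]
            try:
                res = spatial.morans_i(vals, spatial.queen_weights(
                    PolygonLayer(geo.acs.df.loc[present].copy(),
                                 [geo.acs.geoms[i] for i in present])))
                rows.append({"indicator": ind, "scope": label, "n_acs": len(vals),
                             "moran_i": res.I, "z": res.z, "p_value": res.p_value})
            except ValueError as exc:
                rows.append({"indicator": ind, "scope": label, "n_acs": len(vals),
                             "note": str(exc)})
    moran = pd.DataFrame(rows)
    write_csv(moran, RESULTS / "moran.csv", metadata={"seed": SEED})
    print("\nglobal Moran's I (queen contiguity, randomization null):")
    print(moran[moran["scope"] == "ALL"].to_string(index=False))


if __name__ == "__main__":
    main()
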