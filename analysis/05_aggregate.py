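"""Aggregate cluster prevalences to AC estimates and classify deciles.

The AC estimate is the unweighted mean of member-cluster posterior
prevalences under each linkage; decile classes (1 = lowest burden,
10 = highest) support choropleth-style reporting.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd  # noqa: E402
from _common import RESULTS, SEED, build_linkages, build_world  # noqa: E402

from acprev import aggregate as agg  # noqa: E402
from acprev import spatial  # noqa: E402
from acprev.io import read_csv, write_csv  # noqa: E402
from acprev.pipeline import INDICATOR_FLAG  # noqa: E402


def main() -> None:
    geo, clusters, _, _, _, _ = build_world()
    linkages = build_linkages(geo, clusters)
    state_of_ac = dict(zip(geo.acs.df["ac_id"].astype(str), geo.acs.df["state_id"]))

    for mode, link in linkages.items():
        ests = []
        for ind in INDICATOR_FLAG:
            cp_path = RESULTS / f"cluster_prevalence_{ind}.csv"
            if not cp_path.exists():
                print(f"run 04_fit_models.py first ({cp_path} missing)")
                return
            cp = read_csv(cp_path)
            est = agg.ac_prevalence(cp, link, indicator=ind, state_of_ac=state_of_ac)
            est["decile"] = spatial.decile_classes(est["prevalence"])
            ests.append(est)
        ac_est = pd.concat(ests, ignore_index=True)
        write_csv(ac_est, RESULTS / f"ac_estimates_{mode}.csv", metadata={"seed": SEED})
        print(f"\n{mode}: {ac_est['ac_id'].nunique()} ACs estimated")
        for ind in INDICATOR_FLAG:
            e = ac_est[ac_est["indicator"] == ind]["prevalence"] * 100
            print(f"  {ind:12s} median {e.median():5.2f}%  "
                  f"IQR {e.quantile(0.25):.2f}%-{e.quantile(0.75):.2f}%  "
                  f"range {e.min():.2f}%-{e.max():.2f}%")


if __name__ == "__main__":
    main()
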