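"""Link displaced cluster points to AC polygons, both ways, and compare.

The nonadjustment linkage takes displaced points at face value; the
reassignment linkage intersects each cluster's displacement buffer with the
AC layer and assigns the AC holding the largest area share.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import RESULTS, SEED, build_linkages, build_world  # noqa: E402

from acprev.geolink import compare_linkages  # noqa: E402
from acprev.io import write_csv  # noqa: E402


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    geo, clusters, _, children, _, _ = build_world()
    linkages = build_linkages(geo, clusters)

    for mode, tab in linkages.items():
        ser = tab.copy()
        ser["area_ratios"] = ser["area_ratios"].map(
            lambda d: json.dumps(d, sort_keys=True) if isinstance(d, dict) else ""
        )
        write_csv(ser, RESULTS / f"linkage_{mode}.csv", metadata={"seed": SEED})
        kept = (tab["drop_reason"] == "none").sum()
        print(f"{mode}: {kept}/{len(tab)} clusters linked "
              f"({100 * kept / len(tab):.2f}%); drops: "
              f"{tab[tab['drop_reason'] != 'none']['drop_reason'].value_counts().to_dict()}")

    counts = children.groupby("cluster_id")["child_id"].count()
    rep = compare_linkages(linkages["direct"], linkages["reassigned"], child_counts=counts)
    print(f"assignments differing among clusters linked in both: "
          f"{rep['n_differing']}/{rep['n_compared']} "
          f"({100 * rep['fraction_differing']:.2f}% of clusters, "
          f"{100 * rep['fraction_children_differing']:.2f}% of children)")
    print("note: on this rectangular-grid world the AC containing a displaced "
          "point is almost always also the buffer-majority AC, so the "
          "reassignment gain comes from clusters the direct join drops as "
          "outside the layer")

    # recovery against simulation truth
    true = clusters.set_index("cluster_id")["ac_id_true"]
    for mode, tab in linkages.items():
        hit = (tab.set_index("cluster_id")["ac_id"] == true).mean()
        print(f"{mode}: recovers true AC for {100 * hit:.1f}% of clusters")


if __name__ == "__main__":
    main()
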