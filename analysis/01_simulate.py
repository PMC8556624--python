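"""Build the synthetic survey world and inspect its structure.

Generates a 4-state geography (9 ACs per state tiling each state, district
strips offset so ACs cross district borders), places 4 clusters per AC,
displaces their GPS points (2 km urban / 5 km rural), and simulates child
records whose binary outcomes follow the 4-level logistic model.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import RESULTS, SEED, build_world  # noqa: E402

from acprev.io import write_csv  # noqa: E402


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    geo, clusters, lms, children, outcomes, truth = build_world()

    geo.acs.to_geojson(RESULTS / "geography_acs.geojson", metadata={"seed": SEED})
    geo.districts.to_geojson(RESULTS / "geography_districts.geojson", metadata={"seed": SEED})
    for name, df in [
        ("clusters", clusters), ("children", children),
        ("outcomes", outcomes), ("truth", truth), ("lms_table", lms),
    ]:
        write_csv(df, RESULTS / f"{name}.csv", metadata={"seed": SEED})

    crossing = sum(
        1 for g in geo.acs.geoms
        if sum(g.intersection(d).area > 1.0 for d in geo.districts.geoms) >= 2
    )
    print(f"world: {geo.acs.df['state_id'].nunique()} states, "
          f"{len(geo.districts)} districts, {len(geo.acs)} ACs, "
          f"{len(clusters)} clusters, {len(children)} children")
    print(f"{crossing}/{len(geo.acs)} ACs cross a district boundary "
          "(the non-nesting the pipeline exists to handle)")
    print(f"urban clusters: {int(clusters['urban'].sum())} "
          f"({100 * clusters['urban'].mean():.1f}%); "
          f"median displacement {clusters['displacement_m'].median():.0f} m")
    miss = children[["age_months", "height_cm", "weight_kg", "hb_gdl"]].isna().mean()
    print("missingness:", ", ".join(f"{k} {100 * v:.1f}%" for k, v in miss.items()))
    print(f"outputs -> {RESULTS}")


if __name__ == "__main__":
    main()
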