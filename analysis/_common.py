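"""Shared world definition for the numbered analysis scripts.

Every script rebuilds the (deterministic, seeded) synthetic survey world via
the library so each step can be run standalone; results go to
``results/analysis/``.
"""

from pathlib import Path

from acprev import geolink, indicators, synthetic
from acprev.synthetic import GeographySpec

SEED = 7
GEOGRAPHY = GeographySpec(
    n_states=4, districts_per_state=3, acs_per_state=9, clusters_per_ac=4
)
N_CHILDREN = 10
BURN_IN = 500
N_ITER = 2000

RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"


def build_world():
    geo = synthetic.make_geography(GEOGRAPHY, seed=SEED)
    clusters = synthetic.displace_clusters(geo.clusters, seed=SEED + 1)
    lms = synthetic.synthetic_lms_table()
    children, outcomes, truth = synthetic.simulate_children(
        clusters, n_children_per_cluster=N_CHILDREN, seed=SEED + 2, lms_table=lms
    )
    return geo, clusters, lms, children, outcomes, truth


def build_linkages(geo, clusters):
    pts = clusters[["cluster_id", "x", "y", "urban"]]
    return {
        "direct": geolink.direct_assign(pts, geo.acs),
        "reassigned": geolink.buffer_reassign(pts, geo.acs),
    }


def build_samples(children, lms):
    return indicators.build_analytic_samples(children, lms_table=lms)
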