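"""Map the selected features to anatomy and time; clinical correlations.

Decodes every selected column to (window, region i, region j), joins the
atlas labels, summarizes distinct regions/networks/windows and node
degrees, and correlates the selected features with HAMD/HAMA in the
patient group after covariate adjustment.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dfcpipe.characterize import clinical_correlation, map_connections, node_degrees
from dfcpipe.connectivity import FeatureIndex, WindowScheme
from dfcpipe.simulate import read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    subjects, atlas = read_cohort(ROOT / "scratch" / "cohort")
    sel = json.loads((ROOT / "results" / "selection.json").read_text())
    selected = np.asarray(sel["selected_columns"], dtype=int)
    weights = np.asarray(sel["weights"])
    t, n = subjects[0].timeseries.shape
    index = FeatureIndex(WindowScheme(50, 2, t).n_windows, n)

    conn, summary = map_connections(selected, index, atlas, weights=weights,
                                    tr_seconds=2.0, step=2, width=50)
    resdir = ROOT / "results"
    conn.to_csv(resdir / "connections.tsv", sep="\t", index=False)
    deg = node_degrees(conn, atlas)
    deg.to_csv(resdir / "node_degrees.tsv", sep="\t", index=False)

    adjusted = np.load(ROOT / "scratch" / "features" / "dfc_adjusted.npy")
    patients = np.array([s.group for s in subjects]) == 1
    cov = np.column_stack([[s.gender for s in subjects],
                           [s.education for s in subjects]])
    corr = clinical_correlation(
        adjusted[patients][:, selected],
        {"hamd": np.array([s.hamd for s in subjects if s.group == 1]),
         "hama": np.array([s.hama for s in subjects if s.group == 1])},
        cov[patients], feature_columns=selected,
    )
    corr.to_csv(resdir / "clinical_correlations.tsv", sep="\t", index=False)

    print(json.dumps(summary, indent=1))
    sig = corr[corr["p"] < 0.05].sort_values("p")
    print(f"\n{len(sig)} selected-feature/scale pairs with p < 0.05 "
          f"(uncorrected); strongest:")
    print(sig.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
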