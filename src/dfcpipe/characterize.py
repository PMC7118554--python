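"""Spatiotemporal mapping of selected features and clinical correlation.

Selected feature columns are decoded back to (window, region i, region j),
joined with an atlas label table (region name, network name), and
summarized: distinct regions, networks and windows touched, plus node
degrees (number of selected connections incident to each region — degrees
sum to twice the connection count).

Windows are 0-based internally and 1-based in reports; window w spans
[w*step*TR, (w*step + width)*TR) seconds under the half-open convention.

Clinical correlation relates selected features to symptom-severity scores
(HAMD depression / HAMA anxiety) in the patient group only, after the
gender/education covariates are regressed out of the features; Pearson r
with two-sided p, uncorrected for multiple comparisons (flagged in the
output metadata).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import FeatureIndex
from .screening import regress_covariates

__all__ = ["map_connections", "node_degrees", "clinical_correlation"]


def map_connections(
    selected: np.ndarray,
    index: FeatureIndex,
    atlas: pd.DataFrame,
    weights: np.ndarray | None = None,
    tr_seconds: float = 2.0,
    step: int | None = None,
    width: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Decode selected columns into annotated connections.

    ``atlas`` must have columns region_id (1-based, row order = matrix
    order), region_name, network_name and cover every decoded region.
    Returns (connections table, summary dict with distinct counts).
    """
    if len(atlas) < index.n_regions:
        raise ValueError(
            f"atlas lists {len(atlas)} regions but features use {index.n_regions}"
        )
    rows = []
    for k, col in enumerate(np.asarray(selected, dtype=int)):
        w, i, j = index.to_triple(int(col))
        for r in (i, j):
            if r >= len(atlas):
                raise KeyError(f"region index {r} missing from atlas table")
        ai, aj = atlas.iloc[i], atlas.iloc[j]
        row = {
            "feature_column": int(col),
            "window": w + 1,  # 1-based in reports
            "region_i_id": int(ai["region_id"]),
            "region_j_id": int(aj["region_id"]),
            "region_i": str(ai["region_name"]),
            "region_j": str(aj["region_name"]),
            "network_i": str(ai["network_name"]),
            "network_j": str(aj["network_name"]),
        }
        if weights is not None:
            row["weight"] = float(weights[k])
        if step is not None and width is not None:
            row["window_start_s"] = w * step * tr_seconds
            row["window_end_s"] = (w * step + width) * tr_seconds
        rows.append(row)
    table = pd.DataFrame(rows)
    regions = set(table["region_i_id"]) | set(table["region_j_id"])
    networks = set(table["network_i"]) | set(table["network_j"])
    summary = {
        "n_connections": len(table),
        "n_distinct_regions": len(regions),
        "n_distinct_networks": len(networks),
        "n_distinct_windows": table["window"].nunique(),
    }
    return table, summary


def node_degrees(connections: pd.DataFrame, atlas: pd.DataFrame) -> pd.DataFrame:
    """Per-region degree over the selected connections (handshake: degrees
    sum to 2x the number of connections)."""
    counts: dict[int, int] = {}
    for _, row in connections.iterrows():
        for rid in (row["region_i_id"], row["region_j_id"]):
            counts[int(rid)] = counts.get(int(rid), 0) + 1
    out = atlas[atlas["region_id"].isin(counts)][
        ["region_id", "region_name", "network_name"]
    ].copy()
    out["degree"] = out["region_id"].map(counts)
    return out.sort_values("degree", ascending=False).reset_index(drop=True)


def clinical_correlation(
    features: np.ndarray,
    scores: dict[str, np.ndarray],
    covariates: np.ndarray,
    feature_columns: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted Pearson correlation of each selected feature with
    each clinical scale, patients only.

    ``features`` is patients x selected-features; ``scores`` maps scale name
    (e.g. 'hamd', 'hama') to per-patient values.  Correlations are
    uncorrected for multiple comparisons.
    """
    x = np.asarray(features, dtype=float)
    adjusted, _ = regress_covariates(x, covariates)
    cols = (np.arange(x.shape[1]) if feature_columns is None
            else np.asarray(feature_columns, dtype=int))
    records = []
    for scale, vals in scores.items():
        v = np.asarray(vals, dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"clinical scale {scale!r} has zero variance")
        for f in range(adjusted.shape[1]):
            r, p = stats.pearsonr(adjusted[:, f], v)
            records.append(
                {
                    "feature_column": int(cols[f]),
                    "scale": scale,
                    "r": float(r),
                    "p": float(p),
                    "sign": "+" if r >= 0 else "-",
                }
            )
    out = pd.DataFrame(records)
    out.attrs["multiple_testing_correction"] = "none (uncorrected)"
    return out
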