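"""Result surfaces: region PD/FP tables, filtered p-value tables,
significant-voxel counts, size-vs-power scatter data, and NIfTI overlays.

Tables are emitted as CSV with three-decimal formatting for frequencies
(full precision preserved in a parallel JSON written next to the CSV when
requested); overlay maps paint each region's statistic into its atlas label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .resampling import ResamplingSummary
from .synthetic import save_volume


@dataclass
class RunReport:
    """Bundle of summaries plus the config snapshot that reproduces them."""

    summaries: dict = field(default_factory=dict)  # label -> ResamplingSummary
    config_snapshot: dict = field(default_factory=dict)
    qc_summary: dict = field(default_factory=dict)
    artifact_paths: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config_snapshot,
            "qc": self.qc_summary,
            "artifacts": [str(p) for p in self.artifact_paths],
            "summaries": {
                k: {
                    "arm": s.arm,
                    "comparison": s.comparison,
                    "n_iterations": s.n_iterations,
                    "inner_permutations": s.inner_permutations,
                    "alpha": s.alpha,
                    "n_failures": s.n_failures,
                    "seed": s.seed,
                    "metadata": s.metadata,
                }
                for k, s in self.summaries.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def region_table(summaries: dict[str, ResamplingSummary], atlas, region_names: bool = True) -> pd.DataFrame:
    """One row per region; one detection-frequency column per summary label.

    Labels are caller-chosen (e.g. "SAM Pd", "SAM FP", "SPM Pd", ...).
    All summaries must cover exactly the atlas region set.
    """
    ids = atlas.region_ids
    out = pd.DataFrame({"region_id": ids})
    if region_names:
        out["name"] = atlas.regions["name"].to_numpy()
    for label, s in summaries.items():
        sr = s.per_region
        if not np.array_equal(np.sort(sr["region_id"].to_numpy()), np.sort(ids)):
            raise ValueError(f"summary {label!r} region set does not match the atlas")
        out[label] = out["region_id"].map(sr.set_index("region_id")["detect_freq"]).to_numpy()
    return out


def write_region_table(table: pd.DataFrame, csv_path, json_path=None) -> None:
    fmt = table.copy()
    for c in fmt.columns:
        if fmt[c].dtype.kind == "f":
            fmt[c] = fmt[c].map(lambda v: f"{v:.3f}")
    fmt.to_csv(csv_path, index=False)
    if json_path is not None:
        table.to_json(json_path, orient="records", indent=2)


def pvalue_table(
    summary: ResamplingSummary,
    atlas=None,
    min_flag_count: float | None = None,
) -> pd.DataFrame:
    """Regions whose flag count strictly exceeds the chance expectation.

    Default inclusion rule: flag_count > alpha * R (the expected number of
    flagged iterations for a calibrated test under the null); their Eq.-1
    p-values are listed. An empty inclusion set yields an empty table with
    the full header.
    """
    thresh = min_flag_count if min_flag_count is not None else summary.alpha * summary.n_iterations
    sr = summary.per_region
    keep = sr[sr["flag_count"] > thresh].copy()
    cols = ["region_id", "flag_count", "detect_freq", "p_value", "p_value_mean"]
    if atlas is not None:
        names = atlas.regions.set_index("region_id")["name"]
        keep["name"] = keep["region_id"].map(names)
        cols = ["region_id", "name"] + cols[1:]
    return keep[cols].reset_index(drop=True)


def voxel_count_table(cluster_results: dict) -> pd.DataFrame:
    """Significant-voxel totals per (scope, contrast).

    cluster_results maps (scope label, contrast) -> ClusterResult.
    """
    rows = [
        {"scope": scope, "contrast": contrast, "n_significant_voxels": res.n_significant_voxels}
        for (scope, contrast), res in cluster_results.items()
    ]
    return pd.DataFrame(rows, columns=["scope", "contrast", "n_significant_voxels"])


def paint_region_map(values_by_region: dict, atlas) -> np.ndarray:
    """Paint a per-region scalar (PD, FP, z, ...) into the atlas geometry."""
    lut = np.zeros(int(atlas.labels.max()) + 1)
    for rid, v in values_by_region.items():
        lut[int(rid)] = v
    return lut[atlas.labels]


def write_region_map(values_by_region: dict, atlas, path) -> None:
    save_volume(paint_region_map(values_by_region, atlas), path, atlas.voxel_mm)
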