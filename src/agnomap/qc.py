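"""Outlier identification for failed pre-processed GM maps.

Two-criterion rule: per voxel, z-scores are computed across subjects; a
subject whose fraction of in-mask voxels with |z| above a threshold exceeds a
percentage cut-off is marked suspicious, and suspicious subjects confirmed
(by default, all of them; a confirmation list stands in for visual
inspection) are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

Z_THRESH_DEFAULT = 5.0
FRAC_THRESH_DEFAULT = 0.03


def voxel_zscores(
    volumes: np.ndarray,
    mask: np.ndarray,
    z_thresh: float = Z_THRESH_DEFAULT,
) -> np.ndarray:
    """Per-subject fraction of in-mask voxels with |z| > z_thresh.

    z is computed per voxel across subjects with the n-1 denominator; voxels
    with zero variance contribute z = 0 for every subject.
    """
    if volumes.shape[0] < 3:
        raise ValueError("insufficient cohort for z-scores (need >= 3 subjects)")
    X = volumes.reshape(volumes.shape[0], -1)[:, mask.ravel()].astype(np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    flagged = np.zeros(X.shape[0], dtype=np.int64)
    if ok.any():
        z = (X[:, ok] - mu[ok]) / sd[ok]
        flagged = (np.abs(z) > z_thresh).sum(axis=1)
    return flagged / X.shape[1]


def flag_outliers(
    fractions: np.ndarray,
    subject_ids=None,
    frac_thresh: float = FRAC_THRESH_DEFAULT,
    confirm=None,
) -> pd.DataFrame:
    """Turn flagged-voxel fractions into a QC report.

    suspicious iff flagged_fraction strictly exceeds frac_thresh; excluded
    iff suspicious and confirmed. confirm=None confirms every suspicious
    subject; otherwise it is an iterable of subject ids to confirm.
    """
    fractions = np.asarray(fractions, dtype=float)
    if subject_ids is None:
        subject_ids = [f"sub_{i:04d}" for i in range(len(fractions))]
    suspicious = fractions > frac_thresh
    if confirm is None:
        excluded = suspicious.copy()
    else:
        confirm = set(confirm)
        excluded = suspicious & np.array([sid in confirm for sid in subject_ids])
    return pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "flagged_fraction": fractions,
            "suspicious": suspicious,
            "excluded": excluded,
        }
    )


def qc_cohort(
    volumes: np.ndarray,
    cohort: pd.DataFrame,
    mask: np.ndarray,
    z_thresh: float = Z_THRESH_DEFAULT,
    frac_thresh: float = FRAC_THRESH_DEFAULT,
    per_site: bool = False,
    confirm=None,
) -> pd.DataFrame:
    """QC report for a whole cohort; optionally z-scored within each site."""
    ids = cohort["subject_id"].tolist()
    fractions = np.zeros(len(cohort))
    if per_site:
        for _, idx in cohort.groupby("site").groups.items():
            pos = cohort.index.get_indexer(idx)
            fractions[pos] = voxel_zscores(volumes[pos], mask, z_thresh)
    else:
        fractions = voxel_zscores(volumes, mask, z_thresh)
    return flag_outliers(fractions, ids, frac_thresh, confirm)


def apply_qc(cohort: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Return the cohort with qc_excluded set from a QC report."""
    excl = report.set_index("subject_id")["excluded"]
    out = cohort.copy()
    out["qc_excluded"] = out["subject_id"].map(excl).fillna(False).astype(bool)
    return out
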