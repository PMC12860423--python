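"""Region-level agnostic mapping (SAM).

Per atlas region the pipeline is: rank voxels by two-sample |t| and keep the
top k (default 50); extract a single partial-least-squares component from
the selected voxels; train a linear soft-margin SVM and score it on its own
training sample (resubstitution / "replacement" accuracy); correct that
empirical accuracy down to a worst-case true accuracy via a concentration
bound at confidence 1 - alpha; and test the corrected accuracy against
chance (0.5) with a one-sided z-test.

The correction makes the procedure agnostic: significance is declared only
when even the worst plausible true accuracy beats chance, which controls
false positives without any parametric model of the voxel data. Two bound
families are provided: a Vapnik-style bound carrying an explicit complexity
term (the default — the resubstitution estimate is optimistically biased by
in-sample feature selection, and only a complexity-bearing bound absorbs
enough of that bias to stay worst-case at moderate n) and the tighter plain
Hoeffding deviation for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

K_VOXELS_DEFAULT = 50
PLS_COMPONENTS_DEFAULT = 1
ALPHA_DEFAULT = 0.05
BOUND_DEFAULT = "vapnik"


@dataclass(frozen=True)
class FESConfig:
    """Feature extraction/selection settings: top-k voxels by |t|, then PLS."""

    k_voxels: int = K_VOXELS_DEFAULT
    pls_components: int = PLS_COMPONENTS_DEFAULT

    def __post_init__(self):
        if self.k_voxels < 1 or self.pls_components < 1:
            raise ValueError("k_voxels and pls_components must be >= 1")


@dataclass(frozen=True)
class SAMRegionResult:
    region_id: int
    emp_accuracy: float
    worst_accuracy: float
    z_stat: float
    significant: bool
    n_subjects: int


def welch_t(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized Welch two-sample t per column of X (subjects x voxels).

    Zero-variance columns in both groups give t = 0.
    """
    y = np.asarray(labels)
    g1 = X[y > 0].astype(np.float64)
    g2 = X[y <= 0].astype(np.float64)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("degenerate t-test: each group needs >= 2 subjects")
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1) / len(g1)
    v2 = g2.var(axis=0, ddof=1) / len(g2)
    denom = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def select_voxels(region_values: np.ndarray, labels: np.ndarray, k: int = K_VOXELS_DEFAULT) -> np.ndarray:
    """Indices of the k voxels with largest |Welch t|, ties by ascending index.

    If the region holds fewer than k voxels, all are returned (|t|-ordered).
    """
    t = np.abs(welch_t(region_values, labels))
    k_eff = min(k, region_values.shape[1])
    # stable sort on -|t| keeps ascending-index order within ties
    order = np.argsort(-t, kind="stable")
    return order[:k_eff]


def pls_extract(X: np.ndarray, y: np.ndarray, n_components: int = PLS_COMPONENTS_DEFAULT) -> np.ndarray:
    """PLS1 (NIPALS) score extraction on column-centred X against ±1 labels.

    For one component the weight vector is the unit-normalized
    cross-covariance Xc^T y and the scores are Xc @ w.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds feature count")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if not np.any(Xc):
        raise ValueError("degenerate features: zero-variance X")
    scores = np.empty((X.shape[0], n_components))
    Xd, yd = Xc.copy(), yc.copy()
    for c in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("degenerate features: vanishing PLS weight")
        w /= nw
        t = Xd @ w
        scores[:, c] = t
        tt = t @ t
        # deflate
        p = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - t * (yd @ t) / tt
    return scores


def fit_svm_resub(scores: np.ndarray, y: np.ndarray, C: float = 1.0) -> float:
    """Resubstitution accuracy of a linear soft-margin SVM on PLS scores.

    Features are standardized before fitting; the classifier is evaluated on
    the very sample it was trained on (empirical risk minimization's
    "replacement" accuracy).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim == 1:
        scores = scores[:, None]
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input")
    sd = scores.std(axis=0)
    Z = (scores - scores.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    clf = SVC(kernel="linear", C=C)
    clf.fit(Z, y)
    return float(np.mean(clf.predict(Z) == y))


def hoeffding_delta(n: int, alpha: float) -> float:
    """Two-sided Hoeffding deviation sqrt(ln(2/alpha) / (2n))."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return float(np.sqrt(np.log(2.0 / alpha) / (2.0 * n)))


def vapnik_delta(n: int, alpha: float, vc_dim: int = 2) -> float:
    """Vapnik-style deviation with an explicit VC complexity term.

    sqrt((h (ln(2n/h) + 1) + ln(4/alpha)) / n) with h the VC dimension of
    the hypothesis class (2 for oriented thresholds on one PLS score).
    Looser than Hoeffding; the default, since the empirical accuracy it
    corrects is inflated by in-sample selection and fitting.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    h = vc_dim
    return float(np.sqrt((h * (np.log(2.0 * n / h) + 1.0) + np.log(4.0 / alpha)) / n))


def worst_case_accuracy(
    emp_accuracy: float, n: int, alpha: float = ALPHA_DEFAULT, bound: str = BOUND_DEFAULT
) -> float:
    """Worst-case true accuracy at confidence 1 - alpha (floored at 0)."""
    if bound == "hoeffding":
        delta = hoeffding_delta(n, alpha)
    elif bound == "vapnik":
        delta = vapnik_delta(n, alpha)
    else:
        raise ValueError(f"unknown bound family: {bound!r}")
    return max(0.0, float(emp_accuracy) - delta)


def region_significance(worst_accuracy: float, n: int, alpha: float = ALPHA_DEFAULT) -> tuple[float, bool]:
    """One-sided z-test of the worst-case accuracy against chance 0.5.

    z = (worst - 0.5) / sqrt(0.25 / n); significant iff z exceeds the upper
    alpha critical value. Below-chance accuracy is never significant.
    """
    z = (float(worst_accuracy) - 0.5) / np.sqrt(0.25 / n)
    crit = stats.norm.ppf(1.0 - alpha)
    return float(z), bool(z > crit)


def sam_region(
    region_values: np.ndarray,
    labels: np.ndarray,
    fes: FESConfig = FESConfig(),
    alpha: float = ALPHA_DEFAULT,
    bound: str = BOUND_DEFAULT,
) -> tuple[float, float, float, bool]:
    """Run the full SAM chain on one region's subjects x voxels matrix."""
    n = region_values.shape[0]
    sel = select_voxels(region_values, labels, fes.k_voxels)
    scores = pls_extract(region_values[:, sel], labels, fes.pls_components)
    emp = fit_svm_resub(scores, labels)
    worst = worst_case_accuracy(emp, n, alpha, bound)
    z, sig = region_significance(worst, n, alpha)
    return emp, worst, z, sig


def sam_map(
    volumes: np.ndarray,
    labels_pm1: np.ndarray,
    atlas,
    fes: FESConfig = FESConfig(),
    alpha: float = ALPHA_DEFAULT,
    bound: str = BOUND_DEFAULT,
) -> list[SAMRegionResult]:
    """SAM over every atlas region; one result per region.

    volumes: (n_subjects, *grid) GM maps (QC-excluded subjects already
    removed); labels_pm1: ±1 group labels aligned to volumes.
    """
    X = volumes.reshape(volumes.shape[0], -1)
    lab_flat = atlas.labels.ravel()
    out = []
    n = volumes.shape[0]
    for rid in atlas.region_ids:
        cols = np.flatnonzero(lab_flat == rid)
        emp, worst, z, sig = sam_region(X[:, cols], labels_pm1, fes, alpha, bound)
        out.append(
            SAMRegionResult(
                region_id=int(rid),
                emp_accuracy=emp,
                worst_accuracy=worst,
                z_stat=z,
                significant=sig,
                n_subjects=n,
            )
        )
    return out


def sam_results_frame(results: list[SAMRegionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
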