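"""Repeated-subsampling experiments and permutation p-values.

Two designs: HC-vs-ASC (the comparison of interest) and HC-vs-HC (two
disjoint control subsets, where every detection is false by construction).
An outer loop of R independent subsample draws yields per-region detection
frequencies — probability of detection (PD) under HC-vs-ASC, false-positive
(FP) rate under HC-vs-HC. A separate inner loop of M group-label shuffles on
a label-faithful draw yields the permutation p-value per region:

    p = (#{T_perm >= T_obs} + 1) / (M + 1)

with ties counting toward the numerator. The per-iteration region statistic
T and decision rule depend on the mapping arm: the SAM arm uses the
worst-case accuracy and its z-test flag; the parametric (SPM) arm uses the
largest suprathreshold cluster overlapping the region and flags regions
containing any FWE-significant cluster voxel; a plain calibrated arm
("ttest") applies a two-sample t-test to region-mean GM, exact at level
alpha under the null, and serves as the calibration reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import parametric, sam

ALPHA_DEFAULT = 0.05


class InsufficientSubjectsError(RuntimeError):
    """A subsample draw could not be satisfied from the available pool."""


@dataclass(frozen=True)
class ResamplingConfig:
    """Knobs of one resampling experiment (defaults mirror the full-scale
    design: R = M = 1000, alpha = 0.05)."""

    n_iterations: int = 1000
    inner_permutations: int = 1000
    alpha: float = ALPHA_DEFAULT
    comparison: str = "HC_vs_ASC"  # or "HC_vs_HC"
    scope: str = "all_centers"  # or "per_center"
    n_per_group: int | None = None  # None -> 100 all-centers, floor(pool/3) per-center
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1 or self.inner_permutations < 0:
            raise ValueError("n_iterations >= 1 and inner_permutations >= 0 required")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.comparison not in ("HC_vs_ASC", "HC_vs_HC"):
            raise ValueError("comparison must be HC_vs_ASC or HC_vs_HC")


@dataclass
class ResamplingSummary:
    per_region: pd.DataFrame  # region_id, n_voxels, detect_freq, T_obs, p_value, p_value_mean
    arm: str
    comparison: str
    n_iterations: int
    inner_permutations: int
    alpha: float
    n_failures: int = 0
    seed: int | None = None
    metadata: dict = field(default_factory=dict)


ALL_CENTERS_N_PER_GROUP = 100  # ~1/5 of each group's full-database total
PER_CENTER_FRACTION = 3  # 1/3 of each group within one center


def draw_subsample(
    cohort: pd.DataFrame,
    comparison: str,
    n_per_group: int | None,
    rng: np.random.Generator,
    site: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two disjoint subject index sets (positions into cohort rows).

    HC_vs_ASC: n per group from the HC and ASC pools; HC_vs_HC: two disjoint
    HC subsets of size n. Sampling is without replacement. QC-excluded
    subjects never enter the pools. With site given (per-center scope) the
    pool is restricted to that site and n defaults to floor(pool size / 3)
    per group.
    """
    ok = ~cohort["qc_excluded"].to_numpy(dtype=bool)
    if site is not None:
        ok &= (cohort["site"] == site).to_numpy()
    grp = cohort["group"].to_numpy()
    hc = np.flatnonzero(ok & (grp == "HC"))
    asc = np.flatnonzero(ok & (grp == "ASC"))
    where = site or "all centers"

    if comparison == "HC_vs_ASC":
        n_a = n_per_group if n_per_group is not None else (
            len(hc) // PER_CENTER_FRACTION if site else ALL_CENTERS_N_PER_GROUP)
        n_b = n_per_group if n_per_group is not None else (
            len(asc) // PER_CENTER_FRACTION if site else ALL_CENTERS_N_PER_GROUP)
        if n_a < 2 or n_b < 2 or n_a > len(hc) or n_b > len(asc):
            raise InsufficientSubjectsError(
                f"{where}: need {n_a} HC of {len(hc)} and {n_b} ASC of {len(asc)}")
        a = rng.choice(hc, size=n_a, replace=False)
        b = rng.choice(asc, size=n_b, replace=False)
    elif comparison == "HC_vs_HC":
        n = n_per_group if n_per_group is not None else (
            len(hc) // PER_CENTER_FRACTION if site else ALL_CENTERS_N_PER_GROUP)
        if n < 2 or 2 * n > len(hc):
            raise InsufficientSubjectsError(f"{where}: need 2x{n} HC of {len(hc)}")
        both = rng.choice(hc, size=2 * n, replace=False)
        a, b = both[:n], both[n:]
    else:
        raise ValueError("comparison must be HC_vs_ASC or HC_vs_HC")
    return np.sort(a), np.sort(b)


def permutation_pvalue(T_obs: float, T_null) -> float:
    """Permutation p-value (#{T_null >= T_obs} + 1) / (M + 1), ties inclusive."""
    T_null = np.asarray(T_null, dtype=float)
    if T_null.size == 0:
        raise ValueError("empty null list")
    return float((np.sum(T_null >= T_obs) + 1) / (T_null.size + 1))


def region_means(volumes: np.ndarray, atlas) -> np.ndarray:
    """(n_subjects x n_regions) mean GM per region; column order = atlas.region_ids."""
    lab = atlas.labels.ravel()
    inmask = lab > 0
    X = volumes.reshape(volumes.shape[0], -1)[:, inmask]
    lab_in = lab[inmask]
    order = np.argsort(lab_in, kind="stable")
    sorted_lab = lab_in[order]
    ids = atlas.region_ids
    # boundaries of each region's column block after sorting
    starts = np.searchsorted(sorted_lab, ids, side="left")
    sums = np.add.reduceat(X[:, order], starts, axis=1)
    counts = atlas.regions["n_voxels"].to_numpy()
    return sums / counts


# ---------------------------------------------------------------------------
# per-iteration arm evaluations: (flags bool[n_regions], T float[n_regions])

def _eval_ttest(rm_subset_a, rm_subset_b, alpha):
    t, p = stats.ttest_ind(rm_subset_a, rm_subset_b, axis=0, equal_var=True)
    return p <= alpha, np.abs(t)


def _eval_sam(volumes, idx_a, idx_b, atlas, alpha, fes, bound):
    sel = np.concatenate([idx_a, idx_b])
    labels = np.concatenate([-np.ones(len(idx_a)), np.ones(len(idx_b))])
    results = sam.sam_map(volumes[sel], labels, atlas, fes=fes, alpha=alpha, bound=bound)
    flags = np.array([r.significant for r in results])
    T = np.array([r.worst_accuracy for r in results])
    return flags, T


def _region_max_cluster_size(result: parametric.ClusterResult, atlas) -> np.ndarray:
    """Largest suprathreshold (pre-correction) cluster overlapping each region."""
    ids = atlas.region_ids
    out = np.zeros(len(ids))
    if result.label_grid is None or not result.clusters:
        return out
    sizes = {c["label"]: c["size"] for c in result.clusters}
    pos = {int(r): i for i, r in enumerate(ids)}
    lab = result.label_grid
    occupied = lab > 0
    pairs = np.unique(np.stack([atlas.labels[occupied], lab[occupied]]), axis=1)
    for rid, cl in pairs.T:
        if rid > 0:
            i = pos[int(rid)]
            out[i] = max(out[i], sizes[int(cl)])
    return out


def _eval_spm(volumes, idx_a, idx_b, atlas, alpha, spm_cfg, rng):
    sel = np.concatenate([idx_a, idx_b])
    groups = np.concatenate([-np.ones(len(idx_a)), np.ones(len(idx_b))])
    contrasts = spm_cfg.get("contrasts", ("HC<ASC", "ASC<HC"))
    mask = atlas.mask
    sm = volumes[sel] if spm_cfg.get("smoothed", False) else parametric.smooth_cohort(
        volumes[sel], spm_cfg.get("fwhm_mm", parametric.FWHM_DEFAULT_MM), atlas.voxel_mm, mask)
    n_regions = len(atlas.region_ids)
    flags = np.zeros(n_regions, dtype=bool)
    T = np.zeros(n_regions)
    for contrast in contrasts:
        res = parametric.cluster_fwe(
            sm, groups, mask,
            cluster_forming_p=spm_cfg.get("cluster_forming_p", parametric.CLUSTER_FORMING_P_DEFAULT),
            alpha=alpha,
            n_null=spm_cfg.get("n_null", parametric.N_NULL_DEFAULT),
            connectivity=spm_cfg.get("connectivity", 26),
            rng=np.random.default_rng(rng.integers(2**31 - 1)),
            contrast=contrast,
        )
        counts = parametric.region_voxel_counts(res, atlas)
        flags |= np.array([counts[int(r)] > 0 for r in atlas.region_ids])
        T = np.maximum(T, _region_max_cluster_size(res, atlas))
    return flags, T


def run_experiment(
    volumes: np.ndarray,
    cohort: pd.DataFrame,
    atlas,
    arm: str,
    config: ResamplingConfig,
    site: str | None = None,
    fes: sam.FESConfig = sam.FESConfig(),
    bound: str = sam.BOUND_DEFAULT,
    spm_config: dict | None = None,
    n_pvalue_draws: int = 1,
) -> ResamplingSummary:
    """Run one full resampling experiment for one arm and one design.

    Outer loop: config.n_iterations subsample draws, each scored by the
    arm's per-region decision rule; detection frequency = flags / R.
    Inner loop: on n_pvalue_draws fresh label-faithful draws, M =
    config.inner_permutations label shuffles give the per-region permutation
    p-value (first draw) and its mean across draws. Draw failures (pool too
    small) are counted, not raised.
    """
    if arm not in ("sam", "spm", "ttest"):
        raise ValueError("arm must be 'sam', 'spm' or 'ttest'")
    spm_cfg = dict(spm_config or {})
    if config.scope == "per_center" and site is None:
        raise ValueError("per_center scope requires a site")
    rng = np.random.default_rng(config.seed)
    ids = atlas.region_ids
    n_regions = len(ids)
    rm = region_means(volumes, atlas) if arm == "ttest" else None

    def evaluate(idx_a, idx_b, inner_rng):
        if arm == "ttest":
            return _eval_ttest(rm[idx_a], rm[idx_b], config.alpha)
        if arm == "sam":
            return _eval_sam(volumes, idx_a, idx_b, atlas, config.alpha, fes, bound)
        return _eval_spm(volumes, idx_a, idx_b, atlas, config.alpha, spm_cfg, inner_rng)

    flag_counts = np.zeros(n_regions)
    failures = 0
    for _ in range(config.n_iterations):
        try:
            idx_a, idx_b = draw_subsample(cohort, config.comparison, config.n_per_group, rng, site)
        except InsufficientSubjectsError:
            failures += 1
            continue
        flags, _ = evaluate(idx_a, idx_b, rng)
        flag_counts += flags

    T_obs = np.full(n_regions, np.nan)
    p_first = np.full(n_regions, np.nan)
    p_mean = np.full(n_regions, np.nan)
    M = config.inner_permutations
    if M > 0:
        p_draws = []
        for d in range(n_pvalue_draws):
            try:
                idx_a, idx_b = draw_subsample(cohort, config.comparison, config.n_per_group, rng, site)
            except InsufficientSubjectsError:
                failures += 1
                continue
            _, T_d = evaluate(idx_a, idx_b, rng)
            pool = np.concatenate([idx_a, idx_b])
            n_a = len(idx_a)
            T_null = np.empty((M, n_regions))
            for m in range(M):
                perm = rng.permutation(pool)
                _, T_null[m] = evaluate(np.sort(perm[:n_a]), np.sort(perm[n_a:]), rng)
            p_d = (np.sum(T_null >= T_d[None, :], axis=0) + 1) / (M + 1)
            p_draws.append(p_d)
            if d == 0:
                T_obs, p_first = T_d, p_d
        if p_draws:
            p_mean = np.mean(p_draws, axis=0)

    per_region = pd.DataFrame(
        {
            "region_id": ids,
            "n_voxels": atlas.regions["n_voxels"].to_numpy(),
            "detect_freq": flag_counts / config.n_iterations,
            "flag_count": flag_counts.astype(int),
            "T_obs": T_obs,
            "p_value": p_first,
            "p_value_mean": p_mean,
        }
    )
    return ResamplingSummary(
        per_region=per_region,
        arm=arm,
        comparison=config.comparison,
        n_iterations=config.n_iterations,
        inner_permutations=M,
        alpha=config.alpha,
        n_failures=failures,
        seed=config.seed,
        metadata={"site": site, "scope": config.scope, "bound": bound,
                  "n_per_group": config.n_per_group, "n_pvalue_draws": n_pvalue_draws},
    )


def size_power_profile(summary: ResamplingSummary, atlas, fp_summary: ResamplingSummary | None = None) -> pd.DataFrame:
    """(region_id, n_voxels, pd, fp) sorted by region size.

    ``summary`` supplies the HC-vs-ASC detection frequencies (pd);
    ``fp_summary``, if given, the HC-vs-HC frequencies (fp).
    """
    df = summary.per_region[["region_id", "n_voxels"]].copy()
    pd_col = summary.per_region["detect_freq"]
    df["pd"] = pd_col.to_numpy()
    if fp_summary is not None:
        fp = fp_summary.per_region.set_index("region_id")["detect_freq"]
        df["fp"] = df["region_id"].map(fp).to_numpy()
    else:
        df["fp"] = np.nan
    return df.sort_values("n_voxels", kind="stable").reset_index(drop=True)
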