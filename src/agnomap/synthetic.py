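"""Synthetic multi-site grey-matter cohorts.

Generates the raw material every other module consumes: an integer-labelled
brain parcellation (atlas), and per-subject grey-matter (GM) probability maps
for a multi-site two-group (HC / ASC) cohort with controllable group effect,
per-site intensity offsets, subject noise, and an injectable "failed
pre-processing" corruption mode.

The generator is deliberately simple and fully seeded: a smooth radially
decaying baseline GM field inside an ellipsoidal brain mask, additive scalar
site offsets, i.i.d. (optionally smoothed) Gaussian voxel noise, a planted
standardized mean shift (Cohen's d per voxel) in selected regions for the
ASC group, and clipping to the valid probability range [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

DEFAULT_GRID = (40, 48, 40)
FULL_GRID = (79, 95, 79)
DEFAULT_VOXEL_MM = 2.0
DEFAULT_N_REGIONS = 116


@dataclass(frozen=True)
class Atlas:
    """Labelled parcellation: integer grid (0 = background) + region table.

    ``regions`` has columns ``region_id``, ``name``, ``n_voxels``; every
    nonzero label in ``labels`` appears exactly once in the table.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_mm: float = DEFAULT_VOXEL_MM

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["region_id"].to_numpy()

    @property
    def n_mask_voxels(self) -> int:
        return int(np.count_nonzero(self.labels))

    def validate(self) -> None:
        grid_ids = np.unique(self.labels[self.labels > 0])
        table_ids = np.sort(self.region_ids)
        if not np.array_equal(grid_ids, table_ids):
            raise ValueError("region table and label grid disagree")
        counts = np.bincount(self.labels.ravel())
        for rid, n in zip(self.regions["region_id"], self.regions["n_voxels"]):
            if counts[rid] != n:
                raise ValueError(f"n_voxels mismatch for region {rid}")
        if self.regions["name"].duplicated().any():
            raise ValueError("region names not unique")


@dataclass(frozen=True)
class EffectSpec:
    """What to plant in a generated cohort.

    effect_size_d is a per-voxel standardized mean difference (Cohen's d):
    ASC voxels in ``effect_regions`` are shifted by ``effect_size_d *
    noise_sd``. Corruption emulates failed pre-processing: a fraction
    ``corruption_rate`` of subjects get ``corruption_frac`` of their in-mask
    voxels shifted by ±``corruption_magnitude`` noise SDs.
    """

    effect_regions: frozenset = frozenset()
    effect_size_d: float = 0.0
    site_offsets: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    corruption_rate: float = 0.0
    corruption_frac: float = 0.05
    corruption_magnitude: float = 10.0
    noise_smooth_fwhm_mm: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.corruption_rate <= 1.0):
            raise ValueError("corruption_rate must be in [0, 1]")
        if not (0.0 <= self.corruption_frac <= 1.0):
            raise ValueError("corruption_frac must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _ellipsoid_mask(grid_shape, brain_fraction):
    """Boolean ellipsoid centred on the grid; semi-axes are brain_fraction
    times the half-extent along each axis."""
    coords = np.indices(grid_shape, dtype=float)
    r2 = np.zeros(grid_shape)
    for ax, size in enumerate(grid_shape):
        c = (size - 1) / 2.0
        a = brain_fraction * size / 2.0
        r2 += ((coords[ax] - c) / a) ** 2
    return r2 <= 1.0, r2


def generate_atlas(
    grid_shape=DEFAULT_GRID,
    n_regions: int = DEFAULT_N_REGIONS,
    brain_fraction: float = 0.85,
    seed: int = 0,
    voxel_mm: float = DEFAULT_VOXEL_MM,
) -> Atlas:
    """Seeded-Voronoi parcellation of an ellipsoidal brain mask.

    ``n_regions`` random in-mask voxels act as Voronoi sites; every mask
    voxel takes the label of its nearest site, giving contiguous regions of
    heterogeneous size. Deterministic given ``seed``.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mask, _ = _ellipsoid_mask(grid_shape, brain_fraction)
    mask_idx = np.argwhere(mask)
    if n_regions > len(mask_idx):
        raise ValueError("atlas infeasible: n_regions exceeds mask voxel count")
    rng = np.random.default_rng(seed)
    sites = mask_idx[rng.choice(len(mask_idx), size=n_regions, replace=False)]
    labels = np.zeros(grid_shape, dtype=np.int32)
    _, nearest = cKDTree(sites).query(mask_idx)
    labels[tuple(mask_idx.T)] = nearest + 1
    counts = np.bincount(labels.ravel(), minlength=n_regions + 1)[1:]
    regions = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1, dtype=np.int32),
            "name": [f"Region_{i:03d}" for i in range(1, n_regions + 1)],
            "n_voxels": counts.astype(np.int64),
        }
    )
    return Atlas(labels=labels, regions=regions, voxel_mm=voxel_mm)


def baseline_field(atlas: Atlas, low: float = 0.2, high: float = 0.8) -> np.ndarray:
    """Smooth radially decaying baseline GM probability inside the mask.

    high at the mask centre, low at the mask boundary, 0 outside.
    """
    # recover the normalized ellipsoidal radius from the mask geometry
    shape = atlas.labels.shape
    coords = np.indices(shape, dtype=float)
    r2 = np.zeros(shape)
    for ax, size in enumerate(shape):
        c = (size - 1) / 2.0
        half = size / 2.0
        r2 += ((coords[ax] - c) / half) ** 2
    r2_in = r2[atlas.mask]
    r2n = r2 / max(r2_in.max(), 1e-12)
    base = np.where(atlas.mask, high - (high - low) * np.clip(r2n, 0, 1), 0.0)
    return base


def inject_corruption(
    volume: np.ndarray,
    frac: float,
    magnitude: float,
    noise_sd: float,
    mask: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Shift exactly round(frac * in-mask voxels) voxels by ±magnitude·noise_sd.

    frac == 0 returns the input unchanged. Voxel positions and signs are
    deterministic given seed.
    """
    if not (0.0 <= frac <= 1.0):
        raise ValueError("frac must be in [0, 1]")
    if frac == 0.0:
        return volume
    rng = np.random.default_rng(seed)
    flat_idx = np.flatnonzero(mask.ravel())
    n_hit = int(round(frac * len(flat_idx)))
    hit = rng.choice(flat_idx, size=n_hit, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_hit)
    out = volume.copy()
    out.ravel()[hit] += signs * magnitude * noise_sd
    return out


def generate_cohort(
    atlas: Atlas,
    site_sizes: dict,
    spec: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a multi-site two-group cohort of GM maps.

    site_sizes maps site name -> (n_HC, n_ASC). Each subject's map is
    baseline + site offset + planted ASC effect + Gaussian noise, clipped to
    [0, 1] in-mask (0 outside). Returns (cohort table, volumes) with volumes
    shaped (n_subjects, *grid); the table carries the ground-truth
    ``corrupted`` flag alongside subject_id, site, group, sex, age.
    """
    spec = spec or EffectSpec()
    unknown = set(spec.effect_regions) - set(atlas.region_ids.tolist())
    if unknown:
        raise ValueError(f"unknown region ids in effect_regions: {sorted(unknown)}")
    if not site_sizes:
        raise ValueError("site_sizes must be nonempty")

    rng = np.random.default_rng(seed)
    rows = []
    for site, (n_hc, n_asc) in site_sizes.items():
        for grp, n in (("HC", n_hc), ("ASC", n_asc)):
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"{site}_{grp}_{i:04d}",
                        "site": site,
                        "group": grp,
                        # sex ratio mirrors large ASC cohorts (~83% male)
                        "sex": "M" if rng.random() < 0.83 else "F",
                        "age": float(np.clip(rng.normal(16.0, 6.0), 6.0, 55.0)),
                        "corrupted": False,
                        "qc_excluded": False,
                    }
                )
    cohort = pd.DataFrame(rows)
    n_sub = len(cohort)

    mask = atlas.mask
    base = baseline_field(atlas)
    effect_mask = np.isin(atlas.labels, list(spec.effect_regions)) if spec.effect_regions else None
    shift = spec.effect_size_d * spec.noise_sd

    if spec.noise_smooth_fwhm_mm > 0:
        sigma_vox = spec.noise_smooth_fwhm_mm / (atlas.voxel_mm * 2.0 * np.sqrt(2.0 * np.log(2.0)))
    else:
        sigma_vox = 0.0

    volumes = np.zeros((n_sub, *atlas.labels.shape), dtype=np.float32)
    for s in range(n_sub):
        noise = rng.normal(0.0, spec.noise_sd, size=atlas.labels.shape)
        if sigma_vox > 0:
            noise = ndimage.gaussian_filter(noise, sigma_vox)
            # restore the requested marginal SD after smoothing
            noise *= spec.noise_sd / max(noise[mask].std(), 1e-12)
        vol = base + spec.site_offsets.get(cohort.at[s, "site"], 0.0) + noise
        if effect_mask is not None and cohort.at[s, "group"] == "ASC":
            vol = vol + shift * effect_mask
        vol = np.clip(vol, 0.0, 1.0)
        vol[~mask] = 0.0
        volumes[s] = vol

    if spec.corruption_rate > 0:
        n_corrupt = int(round(spec.corruption_rate * n_sub))
        victims = rng.choice(n_sub, size=n_corrupt, replace=False)
        for s in victims:
            volumes[s] = inject_corruption(
                volumes[s],
                spec.corruption_frac,
                spec.corruption_magnitude,
                spec.noise_sd,
                mask,
                seed=int(rng.integers(2**31 - 1)),
            )
            cohort.at[s, "corrupted"] = True
    return cohort, volumes


# ---------------------------------------------------------------------------
# NIfTI / CSV round-trips

def _affine(voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return aff


def save_volume(volume: np.ndarray, path, voxel_mm: float = DEFAULT_VOXEL_MM) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(voxel_mm)), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float32)


def save_atlas(atlas: Atlas, labels_path, regions_path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), _affine(atlas.voxel_mm)), str(labels_path))
    atlas.regions.to_csv(regions_path, index=False)


def load_atlas(labels_path, regions_path, voxel_mm: float = DEFAULT_VOXEL_MM) -> Atlas:
    labels = np.asarray(nib.load(str(labels_path)).get_fdata(), dtype=np.int32)
    regions = pd.read_csv(regions_path)
    atlas = Atlas(labels=labels, regions=regions, voxel_mm=voxel_mm)
    atlas.validate()
    return atlas


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids")
    return df
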