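"""Atlas-hierarchy seed connectivity analysis.

Seeds are drawn from the region hierarchy at any depth — whole regions down
to single cortical layers.  A seed time course is the unweighted voxel mean
over the region and all its descendants (the whole-structure average, not a
mean of child means), correlated voxel-wise or region-wise with Pearson r and
variance-stabilized as Fisher z = atanh(r).  Suprathreshold structure is
summarized as connectogram edge lists (default threshold z > 0.2) and a
seed-size scaling analysis: mean suprathreshold z falls and suprathreshold
extent grows as seeds get larger, both approximately log-log linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .images import AtlasHierarchy, Image3D, Image4D, ImageKind, resolve_region

__all__ = [
    "Z_CAP_R",
    "SeedMap",
    "ConnectivityMatrix",
    "seed_timecourse",
    "seed_map",
    "hierarchical_matrix",
    "connectogram_edges",
    "seed_size_scaling",
    "group_average",
]

# |r| is clipped here before atanh so z stays finite at self-correlation
Z_CAP_R = 1.0 - 1e-7
DIAG_SENTINEL = np.nan  # documented sentinel on matrix diagonals


def fisher_z(r):
    return np.arctanh(np.clip(r, -Z_CAP_R, Z_CAP_R))


@dataclass
class SeedMap:
    zmap: Image3D
    seed_region_id: int
    n_seed_voxels: int
    threshold: float
    seed_mask: Optional[np.ndarray] = None  # seed voxels flagged, not removed
    valid_mask: Optional[np.ndarray] = None  # voxels where z is defined


@dataclass
class ConnectivityMatrix:
    z: np.ndarray
    region_ids: List[int]
    level: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        R = len(self.region_ids)
        if self.z.shape != (R, R):
            raise ValueError("matrix/region_ids mismatch")
        if not np.allclose(
            np.nan_to_num(self.z), np.nan_to_num(self.z.T), atol=1e-12
        ):
            raise ValueError("matrix must be symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.region_ids, columns=self.region_ids)


def seed_timecourse(
    series: Image4D,
    atlas: AtlasHierarchy,
    region_id: int,
    include_descendants: bool = True,
    mask: Optional[Image3D] = None,
) -> np.ndarray:
    """Unweighted mean time course over the resolved region voxels."""
    vox = resolve_region(atlas, region_id, include_descendants)
    if mask is not None:
        vox = vox & mask.data.astype(bool)
    if not vox.any():
        raise ValueError(f"region {region_id} has no voxels in mask")
    return series.data[vox, :].mean(axis=0)


def _corr_with_seed(data2d: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """Pearson r of each row of (n_vox, T) against the seed course."""
    x = data2d - data2d.mean(axis=1, keepdims=True)
    s = seed - seed.mean()
    sx = np.sqrt((x**2).sum(axis=1))
    ss = np.sqrt((s**2).sum())
    num = x @ s
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (sx * ss)
    # relative tolerance: the float mean of a constant row is not exact
    tol = 1e-10 * (np.abs(data2d).max(axis=1) + 1.0) * np.sqrt(data2d.shape[1])
    r[(sx <= tol) | (ss <= 1e-300)] = np.nan
    return r


def seed_map(
    series: Image4D,
    atlas: AtlasHierarchy,
    region_id: int,
    threshold: float = 0.2,
    mask: Optional[Image3D] = None,
) -> SeedMap:
    """Voxel-wise Fisher-z correlation map against a seed region.

    Zero-variance voxels are undefined (NaN) and excluded from the valid
    mask; seed voxels are flagged but kept in the map.
    """
    if series.n_frames < 10:
        raise ValueError("need at least 10 frames")
    seed_vox = resolve_region(atlas, region_id, True)
    if mask is not None:
        seed_vox = seed_vox & mask.data.astype(bool)
    seed = seed_timecourse(series, atlas, region_id, True, mask)
    shape = series.data.shape[:3]
    flat = series.data.reshape(-1, series.n_frames)
    r = _corr_with_seed(flat, seed)
    z = fisher_z(r).reshape(shape)
    valid = np.isfinite(z)
    if mask is not None:
        valid &= mask.data.astype(bool)
        z = np.where(valid, z, np.nan)
    return SeedMap(
        zmap=Image3D(np.nan_to_num(z, nan=0.0), series.affine, ImageKind.anatomical),
        seed_region_id=region_id,
        n_seed_voxels=int(seed_vox.sum()),
        threshold=threshold,
        seed_mask=seed_vox,
        valid_mask=valid,
    )


def hierarchical_matrix(
    series: Image4D,
    atlas: AtlasHierarchy,
    level: int,
    mask: Optional[Image3D] = None,
) -> ConnectivityMatrix:
    """Pairwise Fisher-z matrix of region mean courses at one hierarchy depth.

    Each region's course is the voxel mean over the region and all of its
    descendants, identical to :func:`seed_timecourse`.
    """
    ids = atlas.regions_at_depth(level)
    if len(ids) < 2:
        raise ValueError(f"level {level} has fewer than 2 regions")
    courses = np.stack(
        [seed_timecourse(series, atlas, r, True, mask) for r in ids]
    )
    R = np.corrcoef(courses)
    z = fisher_z(R)
    np.fill_diagonal(z, DIAG_SENTINEL)
    return ConnectivityMatrix(z, ids, level)


def connectogram_edges(mat: ConnectivityMatrix, threshold: float = 0.2) -> pd.DataFrame:
    """Undirected suprathreshold edges (z > threshold), sorted by |z| desc."""
    rows = []
    R = len(mat.region_ids)
    for i in range(R):
        for j in range(i + 1, R):
            zij = mat.z[i, j]
            if np.isfinite(zij) and zij > threshold:
                rows.append(
                    {"region_a": mat.region_ids[i], "region_b": mat.region_ids[j], "z": zij}
                )
    df = pd.DataFrame(rows, columns=["region_a", "region_b", "z"])
    if len(df):
        df = df.reindex(df["z"].abs().sort_values(ascending=False).index).reset_index(
            drop=True
        )
    return df


def seed_size_scaling(
    series: Image4D,
    atlas: AtlasHierarchy,
    region_ids: Sequence[int],
    threshold: float = 0.2,
    mask: Optional[Image3D] = None,
    include_seed_voxels: bool = False,
) -> Tuple[pd.DataFrame, dict]:
    """Suprathreshold statistics vs seed size, with log-log OLS slopes.

    For each seed: number of seed voxels, mean suprathreshold z and
    suprathreshold voxel count at the given z threshold.  Seed voxels are
    excluded from the suprathreshold accounting unless
    ``include_seed_voxels`` (self-correlation inflates the counts).
    Returns the per-region table and OLS slopes of log(mean z) and
    log(count) against log(seed size); regions with no suprathreshold
    voxels are recorded but excluded from the fits.
    """
    if len(region_ids) < 3:
        raise ValueError("need at least 3 regions for the scaling fit")
    rows = []
    for rid in region_ids:
        sm = seed_map(series, atlas, rid, threshold, mask)
        z = sm.zmap.data
        sel = sm.valid_mask.copy()
        if not include_seed_voxels:
            sel &= ~sm.seed_mask
        supra = sel & (z > threshold)
        n_sup = int(supra.sum())
        rows.append(
            {
                "region_id": rid,
                "n_seed_voxels": sm.n_seed_voxels,
                "mean_suprathreshold_z": float(z[supra].mean()) if n_sup else np.nan,
                "n_suprathreshold": n_sup,
            }
        )
    table = pd.DataFrame(rows)
    ok = table["n_suprathreshold"] > 0
    fits = {}
    if ok.sum() >= 2:
        lx = np.log10(table.loc[ok, "n_seed_voxels"].astype(float))
        for col, key in (
            ("mean_suprathreshold_z", "slope_log_mean_z"),
            ("n_suprathreshold", "slope_log_count"),
        ):
            ly = np.log10(table.loc[ok, col].astype(float))
            A = np.vstack([lx, np.ones_like(lx)]).T
            coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
            fits[key] = float(coef[0])
            fits[key + "_intercept"] = float(coef[1])
    return table, fits


def group_average(maps: List[SeedMap], t_map: bool = False):
    """Voxel-wise Fisher-domain mean of seed maps on a common grid."""
    if not maps:
        raise ValueError("empty map list")
    shape = maps[0].zmap.shape
    for m in maps:
        if m.zmap.shape != shape:
            raise ValueError("grid mismatch across maps")
    stack = np.stack([m.zmap.data for m in maps])
    mean = stack.mean(axis=0)
    out = SeedMap(
        zmap=Image3D(mean, maps[0].zmap.affine, ImageKind.anatomical),
        seed_region_id=maps[0].seed_region_id,
        n_seed_voxels=maps[0].n_seed_voxels,
        threshold=maps[0].threshold,
    )
    if t_map:
        n = stack.shape[0]
        sd = stack.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n))
        return out, Image3D(np.nan_to_num(t), maps[0].zmap.affine, ImageKind.anatomical)
    return out
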