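"""Quality-control metrics mirroring the per-stage checks of the pipeline:
temporal SNR, image-to-reference correlation, smoothness aggregation and
residual-noise Gaussianity."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .images import Image3D, Image4D, ImageKind

__all__ = ["tsnr_map", "image_correlation", "dice"]


def tsnr_map(series: Image4D, mask: Optional[Image3D] = None) -> Image3D:
    """Per-voxel temporal mean / SD after linear detrending.

    Voxels with zero temporal SD are undefined and set to 0 (masked out).
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames for tSNR")
    data = series.data
    t = np.arange(data.shape[3], dtype=np.float64)
    tc = t - t.mean()
    beta = (data * tc).sum(axis=3) / (tc**2).sum()
    resid = data - data.mean(axis=3, keepdims=True) - beta[..., None] * tc
    sd = resid.std(axis=3, ddof=1)
    mean = data.mean(axis=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsnr = np.where(sd > 0, mean / sd, 0.0)
    if mask is not None:
        tsnr = tsnr * mask.data.astype(bool)
    return Image3D(tsnr, series.affine, ImageKind.anatomical)


def image_correlation(a: Image3D, b: Image3D, mask: Optional[Image3D] = None) -> float:
    """Masked Pearson correlation between two volumes on the same grid."""
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    m = np.ones(a.shape, bool) if mask is None else mask.data.astype(bool)
    x = a.data[m].astype(np.float64)
    y = b.data[m].astype(np.float64)
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt((x**2).sum() * (y**2).sum())
    if den == 0:
        raise ValueError("zero variance within mask")
    return float((x * y).sum() / den)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = a.astype(bool)
    b = b.astype(bool)
    s = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / s) if s else 1.0
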