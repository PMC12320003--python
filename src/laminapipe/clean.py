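"""Nuisance regression and temporal band-pass filtering.

The corrected series still carries slow scanner drift and motion-coupled
intensity fluctuations.  These are removed by voxel-wise least-squares
regression of a design built from the six rigid motion parameters and a slow
drift basis, followed by zero-phase band-pass filtering into the infra-slow
band (default 0.01-0.1 Hz) where spontaneous BOLD fluctuations live.

Regression runs before filtering, and the motion regressors are themselves
band-pass matched to the target band first, so that frequencies removed by
the filter cannot be reintroduced through the regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple
import warnings

import numpy as np
from scipy import signal

from .images import Image3D, Image4D
from .transforms import RigidMotion

__all__ = ["NuisanceDesign", "build_design", "regress_nuisance", "bandpass"]


@dataclass
class NuisanceDesign:
    """Frame x k regressor matrix with column labels.

    Non-constant columns are standardized; the constant column is always
    present and kept unscaled.
    """

    regressors: np.ndarray
    names: list

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=np.float64)
        if self.regressors.ndim != 2 or self.regressors.shape[1] != len(self.names):
            raise ValueError("regressors/names shape mismatch")
        if "constant" not in self.names:
            raise ValueError("design must include a constant column")
        rank = np.linalg.matrix_rank(self.regressors)
        if rank < self.regressors.shape[1]:
            raise ValueError("design is rank deficient")

    @property
    def k(self) -> int:
        return self.regressors.shape[1]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.regressors, columns=self.names)


def n_cosine_drift(n_frames: int, tr_s: float, cutoff_hz: float) -> int:
    """Number of DCT drift regressors with frequency below the cutoff."""
    duration = n_frames * tr_s
    return int(np.floor(2.0 * duration * cutoff_hz))


def build_design(
    motion: Optional[RigidMotion],
    n_frames: int,
    drift: str = "cosine",
    drift_order: int = 2,
    drift_cutoff_hz: float = 0.01,
    tr_s: float = 1.0,
) -> NuisanceDesign:
    """Assemble the nuisance design: motion + drift + constant.

    ``drift`` is 'cosine' (DCT-II basis up to ``drift_cutoff_hz``),
    'polynomial' (orders 1..drift_order) or 'none'.  All-zero motion columns
    are dropped with a warning; duplicate columns raise with their names.
    """
    cols = []
    names = []
    if motion is not None:
        if motion.n_frames != n_frames:
            raise ValueError("motion length != n_frames")
        labels = ["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]
        for c, lab in enumerate(labels):
            col = motion.per_frame[:, c]
            if np.allclose(col, col[0]):
                warnings.warn(f"motion column {lab} is constant; dropped", stacklevel=2)
                continue
            cols.append(col)
            names.append(lab)
    t = np.arange(n_frames)
    if drift == "polynomial":
        for p in range(1, drift_order + 1):
            cols.append(((t - t.mean()) / (n_frames / 2.0)) ** p)
            names.append(f"poly{p}")
    elif drift == "cosine":
        k = n_cosine_drift(n_frames, tr_s, drift_cutoff_hz)
        for j in range(1, k + 1):
            cols.append(np.cos(np.pi * j * (2 * t + 1) / (2 * n_frames)))
            names.append(f"cos{j}")
    elif drift != "none":
        raise ValueError(f"unknown drift spec {drift!r}")
    X = np.empty((n_frames, len(cols) + 1))
    for i, col in enumerate(cols):
        sd = col.std()
        X[:, i] = (col - col.mean()) / sd
    X[:, -1] = 1.0
    names = names + ["constant"]
    # prune duplicate columns before the rank check so the error can name them
    _, keep_idx = np.unique(np.round(X.T, 12), axis=0, return_index=True)
    if len(keep_idx) < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(keep_idx))
        raise ValueError(f"duplicate design columns: {[names[i] for i in dropped]}")
    return NuisanceDesign(X, names)


def regress_nuisance(
    series: Image4D, design: NuisanceDesign, mask: Optional[Image3D] = None
) -> Image4D:
    """Project out the nuisance subspace voxel-wise; voxel means restored."""
    if design.regressors.shape[0] != series.n_frames:
        raise ValueError("design frame count mismatch")
    X = design.regressors
    data = series.data
    nx, ny, nz, T = data.shape
    m = np.ones((nx, ny, nz), bool) if mask is None else mask.data.astype(bool)
    Y = data[m, :].T  # (T, n_vox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    resid += Y.mean(axis=0, keepdims=True)
    out = data.copy()
    out[m, :] = resid.T
    return Image4D(out, series.affine, series.tr_s, series.pe_axis)


def bandpass(
    series: Image4D,
    band_hz: Tuple[float, float] = (0.01, 0.1),
    order: int = 4,
) -> Image4D:
    """Zero-phase Butterworth band-pass along time.

    ``band_hz[0] == 0`` degenerates to a low-pass (the temporal mean is
    preserved); otherwise the voxel mean is removed by the filter and
    restored afterwards so intensities stay interpretable.  Zero-phase
    forward-backward filtering doubles the effective order (roll-off
    ~2*order*6 dB/octave) with no pass-band phase distortion.
    """
    lo, hi = band_hz
    nyq = 1.0 / (2.0 * series.tr_s)
    if not (0 <= lo < hi <= nyq):
        raise ValueError(f"band {band_hz} invalid for Nyquist {nyq}")
    if lo == 0:
        # unit DC gain: constant level passes through
        sos = signal.butter(order, hi / nyq, btype="lowpass", output="sos")
    else:
        # zero DC gain: the constant (mean) component is removed
        sos = signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    T = series.n_frames
    padlen = min(T - 1, 3 * (2 * sos.shape[0] + 1))  # short series stay filterable
    filt = signal.sosfiltfilt(sos, series.data, axis=3, padlen=padlen)
    return Image4D(filt, series.affine, series.tr_s, series.pe_axis)
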