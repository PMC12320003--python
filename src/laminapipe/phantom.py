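"""Layered digital brain phantom with known ground truth.

The phantom emulates the study conditions of high-resolution mouse rs-fMRI:
a 96 x 48 in-plane matrix over 9 slices, 310 frames at TR = 1 s, a cortical
ribbon subdivided into layers whose volumes mirror the barrel-field laminar
thicknesses (L1 0.12, L2-3 0.25, L4 0.20, L5 0.27, L6 0.32 mm of a 1.16 mm
total), a white-matter band and a subcortical core, each split into
hemispheres, under a 3-level region -> subregion -> layer hierarchy.

BOLD-like fluctuations are band-limited (default 0.01-0.1 Hz, the infra-slow
band) region time courses with a planted correlation structure; acquisition
applies, in fixed forward order, non-rigid deformation, rigid motion,
per-slice phase-encode drift, B0 field-map distortion, and i.i.d. Gaussian
thermal noise (the high-SNR magnitude approximation).  Every stage of the
pipeline can therefore be checked against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import AcquisitionParams, AtlasHierarchy, Image3D, Image4D, ImageKind
from .transforms import DisplacementField, RigidMotion, pe_shift_field, rigid_to_field
from .warp import compose_mappings, fieldmap_to_shift, invert_field, resample_volume

__all__ = [
    "LAYER_THICKNESS_MM",
    "PhantomTruth",
    "make_layered_phantom",
    "simulate_bold",
    "apply_acquisition",
    "default_phantom",
    "write_phantom_bundle",
]

# barrel-field laminar thicknesses (mm); total 1.16 mm
LAYER_THICKNESS_MM = np.array([0.12, 0.25, 0.20, 0.27, 0.32])

# region-id scheme: depth-1 parents, depth-2 subregions, depth-3 layers
CTX, WM, SUB = 1, 2, 3
CTX_L, CTX_R, WM_L, WM_R, SUB_L, SUB_R = 10, 20, 30, 40, 50, 60


@dataclass
class PhantomTruth:
    """Everything needed to score the pipeline against ground truth."""

    clean_series: Image4D
    rigid_motion: RigidMotion  # correction direction: maps frame onto reference
    nonrigid_field_per_frame: List[DisplacementField]  # correction direction
    fieldmap: Image3D
    atlas: AtlasHierarchy
    network_corr: pd.DataFrame  # region_a, region_b, r
    noise_sigma: float
    acq: Optional[AcquisitionParams] = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        _corr_matrix(self.network_corr)  # validates PSD


def _layer_weights(n_layers: int) -> np.ndarray:
    if n_layers == len(LAYER_THICKNESS_MM):
        w = LAYER_THICKNESS_MM
    else:
        w = np.ones(n_layers)
    return w / w.sum()


def make_layered_phantom(
    shape: Tuple[int, int, int] = (96, 48, 9),
    n_layers: int = 5,
    seed: int = 0,
) -> Tuple[Image3D, AtlasHierarchy]:
    """Build the anatomical volume and its labelled 3-level hierarchy.

    The brain is an in-plane ellipse; tissue bands are depth shells from the
    boundary (cortex outermost, then white matter, subcortical core).  Layer
    boundaries are depth quantiles of the cortical shell chosen so that layer
    volumes are proportional to the laminar thickness weights within rounding.
    """
    nx, ny, nz = shape
    if nx < 32 or ny < 32:
        raise ValueError("in-plane shape must be at least 32 x 32")
    if n_layers < 2:
        raise ValueError("need at least 2 layers")
    rng = np.random.default_rng(seed)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    a, b = 0.44 * nx, 0.42 * ny
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    brain2d = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    depth2d = ndimage.distance_transform_edt(brain2d)
    dmax = depth2d.max()
    cortex_depth = 0.45 * dmax
    wm_depth = 0.62 * dmax
    weights = _layer_weights(n_layers)
    cortex2d = brain2d & (depth2d <= cortex_depth)
    dvals = depth2d[cortex2d]
    if dvals.size < 2 * n_layers:
        raise ValueError("shape too small: a cortical band would be < 1 voxel thick")
    # rank-based partition (seeded tie-break) -> layer volumes proportional to
    # the thickness weights within rounding, outermost layer first
    order = np.argsort(dvals + 1e-9 * rng.random(dvals.size), kind="stable")
    ranks = np.empty(dvals.size, dtype=np.int64)
    ranks[order] = np.arange(dvals.size)
    bounds = np.round(np.cumsum(weights) * dvals.size).astype(np.int64)
    layer_of = np.searchsorted(bounds, ranks, side="right")
    layer_idx2d = np.zeros((nx, ny), dtype=np.int32)
    layer_idx2d[cortex2d] = layer_of  # 0 = outermost layer
    wm2d = brain2d & (depth2d > cortex_depth) & (depth2d <= wm_depth)
    sub2d = brain2d & (depth2d > wm_depth)
    left2d = X < cx

    labels2d = np.zeros((nx, ny), dtype=np.int32)
    for hemi, base in ((left2d, CTX_L), (~left2d, CTX_R)):
        for k in range(n_layers):
            labels2d[cortex2d & hemi & (layer_idx2d == k)] = base + 1 + k
    labels2d[wm2d & left2d] = WM_L
    labels2d[wm2d & ~left2d] = WM_R
    labels2d[sub2d & left2d] = SUB_L
    labels2d[sub2d & ~left2d] = SUB_R
    labels = np.repeat(labels2d[:, :, None], nz, axis=2)

    # anatomical contrast: distinct tissue intensities + smooth texture
    contrast = {WM_L: 1.35, WM_R: 1.35, SUB_L: 0.7, SUB_R: 0.7}
    layer_contrast = np.linspace(0.85, 1.1, n_layers)
    for base in (CTX_L, CTX_R):
        for k in range(n_layers):
            contrast[base + 1 + k] = layer_contrast[k]
    anat = np.zeros(shape)
    for lab, val in contrast.items():
        anat[labels == lab] = val
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    anat += 0.05 * texture * (labels > 0)
    anat[labels == 0] = 0.0

    rows = [
        (CTX, "CTX", None),
        (WM, "WM", None),
        (SUB, "SUB", None),
        (CTX_L, "CTX-l", CTX),
        (CTX_R, "CTX-r", CTX),
        (WM_L, "WM-l", WM),
        (WM_R, "WM-r", WM),
        (SUB_L, "SUB-l", SUB),
        (SUB_R, "SUB-r", SUB),
    ]
    for base, side in ((CTX_L, "l"), (CTX_R, "r")):
        for k in range(n_layers):
            rows.append((base + 1 + k, f"CTX-{side}-L{k + 1}", base))
    regions = pd.DataFrame(rows, columns=["region_id", "acronym", "parent_id"])
    affine = np.diag([0.25, 0.25, 0.5, 1.0])  # 0.25 mm in-plane, mm units
    atlas = AtlasHierarchy(Image3D(labels, affine, ImageKind.label), regions)
    return Image3D(anat, affine, ImageKind.anatomical), atlas


def _corr_matrix(network_corr: pd.DataFrame):
    """Embed the planted pair table in a full correlation matrix; check PSD."""
    ids = sorted(
        set(network_corr["region_a"].astype(int)) | set(network_corr["region_b"].astype(int))
    )
    k = len(ids)
    pos = {r: i for i, r in enumerate(ids)}
    C = np.eye(k)
    for _, row in network_corr.iterrows():
        i, j = pos[int(row["region_a"])], pos[int(row["region_b"])]
        C[i, j] = C[j, i] = float(row["r"])
    ev = np.linalg.eigvalsh(C)
    if ev.min() < -1e-10:
        raise ValueError("planted correlation table is not positive semidefinite")
    return ids, np.clip(C, -1, 1)


def _bandlimit(x: np.ndarray, tr_s: float, band_hz: Tuple[float, float]) -> np.ndarray:
    """Brick-wall band-pass along axis 0, then renormalize to unit SD."""
    n = x.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    X = np.fft.rfft(x, axis=0)
    X[~keep] = 0.0
    y = np.fft.irfft(X, n=n, axis=0)
    sd = y.std(axis=0, keepdims=True)
    return y / np.where(sd == 0, 1.0, sd)


def simulate_bold(
    atlas: AtlasHierarchy,
    network_corr: pd.DataFrame,
    n_frames: int = 310,
    tr_s: float = 1.0,
    band_hz: Tuple[float, float] = (0.01, 0.1),
    seed: int = 0,
    amplitude: float = 1.0,
    baseline: float = 100.0,
    voxel_jitter: float = 0.1,
    baseline_map: Optional[Image3D] = None,
) -> Image4D:
    """Region-course BOLD simulation with a planted correlation structure.

    Every leaf region carries a band-limited unit-SD time course; regions in
    ``network_corr`` (and all their descendants) share courses mixed to the
    planted correlations, all others are independent.  Voxels add small
    independent band-limited jitter (``voxel_jitter`` in units of signal SD).
    With ``baseline_map`` (e.g. the phantom anatomical) the static voxel
    intensity follows that map rescaled to mean ``baseline`` over the brain,
    giving the frames the tissue contrast a real EPI series has; otherwise
    the baseline is flat.
    """
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 <= band_hz[0] < band_hz[1] <= nyquist):
        raise ValueError("band must lie within (0, Nyquist)")
    rng = np.random.default_rng(seed)
    ids, C = _corr_matrix(network_corr)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(ids)))
    Z = _bandlimit(rng.standard_normal((n_frames, len(ids))), tr_s, band_hz)
    planted = Z @ L.T  # (n_frames, k); filtering first keeps correlations exact

    shape = atlas.labels.shape
    brain = atlas.labels.data > 0
    if baseline_map is not None:
        if baseline_map.shape != shape:
            raise ValueError("baseline_map geometry mismatch")
        base_vol = baseline_map.data * (baseline / baseline_map.data[brain].mean())
    else:
        base_vol = np.where(brain, float(baseline), 0.0)
    data = np.repeat(base_vol[..., None], n_frames, axis=3).astype(np.float64)
    course_of: dict = {}
    for rid, col in zip(ids, planted.T):
        for leaf in atlas.descendants(rid):
            course_of[leaf] = col
    present = [int(v) for v in np.unique(atlas.labels.data) if v != 0]
    for lab in present:
        if lab not in course_of:
            course_of[lab] = _bandlimit(
                rng.standard_normal((n_frames, 1)), tr_s, band_hz
            )[:, 0]
    for lab in present:
        vox = atlas.labels.data == lab
        nvox = int(vox.sum())
        jit = voxel_jitter * _bandlimit(
            rng.standard_normal((n_frames, nvox)), tr_s, band_hz
        )
        sig = course_of[lab][:, None] + jit
        data[vox, :] = base_vol[vox][:, None] + amplitude * sig.T
    return Image4D(data, atlas.labels.affine, tr_s=tr_s, pe_axis=1)


def apply_acquisition(
    clean: Image4D,
    truth: PhantomTruth,
    acq: AcquisitionParams,
    seed: int = 0,
) -> Image4D:
    """Forward acquisition model.

    Per frame the clean image is deformed by, in order: non-rigid deformation,
    rigid motion, per-slice phase-encode translation, B0 field-map shift —
    each the inverse of the stored correction-direction truth — composed into
    a single pullback field and applied with one interpolation; i.i.d.
    Gaussian thermal noise of ``noise_sigma`` is then added.
    """
    grid = clean.data.shape[:3]
    if truth.fieldmap.shape != grid:
        raise ValueError("fieldmap geometry mismatch")
    if truth.rigid_motion.n_frames != clean.n_frames:
        raise ValueError("rigid motion frame count mismatch")
    rng = np.random.default_rng(seed)
    vox_mm = np.sqrt((clean.affine[:3, :3] ** 2).sum(axis=0))
    b0_corr = fieldmap_to_shift(truth.fieldmap, acq, clean.pe_axis)
    b0_fwd = None
    if np.any(b0_corr.shifts != 0):
        b0_fwd = b0_corr  # distortion map is already the forward field
    out = np.empty_like(clean.data)
    for t in range(clean.n_frames):
        fields = []
        nr = truth.nonrigid_field_per_frame[t]
        if nr.max_abs() > 0:
            fields.append(invert_field(nr, tol=1e-3, max_iter=100))
        par = truth.rigid_motion.per_frame[t]
        if np.any(par != 0):
            fields.append(rigid_to_field(par, grid, vox_mm, inverse=True))
        sl = truth.rigid_motion.per_slice_pe_shift[t]
        if np.any(sl != 0):
            fields.append(pe_shift_field(grid, clean.pe_axis, -sl))
        if b0_fwd is not None:
            fields.append(b0_fwd)
        if fields:
            total = compose_mappings(fields, grid)
            out[..., t] = resample_volume(clean.data[..., t], total, "cubic_spline")
        else:
            out[..., t] = clean.data[..., t]
    if truth.noise_sigma > 0:
        out = out + rng.normal(0.0, truth.noise_sigma, out.shape)
    return Image4D(out, clean.affine, clean.tr_s, clean.pe_axis)


def _smooth_walk(rng, n, scale, smooth=10.0):
    """Zero-referenced smooth random walk for motion traces."""
    x = np.cumsum(rng.standard_normal(n))
    x = ndimage.gaussian_filter1d(x, smooth)
    x -= x[0]
    m = np.abs(x).max()
    return x * (scale / m) if m > 0 else x


def default_phantom(
    shape: Tuple[int, int, int] = (64, 40, 3),
    n_frames: int = 310,
    seed: int = 0,
    noise_sigma: float = 10.0,
    rigid_scale_mm: float = 0.12,
    rot_scale_deg: float = 0.4,
    pe_drift_vox: float = 0.6,
    nonrigid_amp_vox: float = 0.5,
    fieldmap_amp_hz: float = 30.0,
    planted_r: float = 0.6,
    with_motion: bool = True,
    with_fieldmap: bool = True,
) -> PhantomTruth:
    """Assemble the full truth bundle under the default study conditions.

    Defaults: baseline 100 with noise SD 10 (tSNR ~ 10 before denoising,
    thermal-noise-dominated as in high-resolution acquisitions), sub-voxel
    rigid motion, ~0.5-voxel non-rigid deformation and a +/-30 Hz field map.
    Planted network: left/right cortex correlated at ``planted_r``,
    uncorrelated with the subcortical regions.
    """
    rng = np.random.default_rng(seed)
    anat, atlas = make_layered_phantom(shape, 5, seed=rng.integers(2**31 - 1))
    network = pd.DataFrame(
        [
            {"region_a": CTX_L, "region_b": CTX_R, "r": planted_r},
            {"region_a": CTX_L, "region_b": SUB_L, "r": 0.0},
            {"region_a": CTX_R, "region_b": SUB_R, "r": 0.0},
        ]
    )
    clean = simulate_bold(
        atlas, network, n_frames=n_frames, tr_s=1.0,
        seed=int(rng.integers(2**31 - 1)), baseline_map=anat,
    )
    nz = shape[2]
    if with_motion:
        # predominantly in-plane motion (head-fixed animal, thin slab):
        # tx, ty translations plus in-plane rotation rz
        par = np.zeros((n_frames, 6))
        for c, sc in ((0, rigid_scale_mm), (1, rigid_scale_mm), (5, rot_scale_deg)):
            par[:, c] = _smooth_walk(rng, n_frames, sc)
        pe = np.stack(
            [_smooth_walk(rng, n_frames, pe_drift_vox * (0.6 + 0.4 * rng.random()))
             for _ in range(nz)],
            axis=1,
        )
        rigid = RigidMotion(par, pe, reference_frame=0)
        nonrigid = []
        kx = 2 * np.pi / shape[0]
        ky = 2 * np.pi / shape[1]
        X, Y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        phase = _smooth_walk(rng, n_frames, 1.0)
        for t in range(n_frames):
            amp = nonrigid_amp_vox * phase[t]
            f = np.zeros(shape + (3,))
            f[..., 0] = (amp * np.sin(kx * X) * np.cos(ky * Y))[:, :, None]
            f[..., 1] = (amp * np.cos(kx * X) * np.sin(ky * Y))[:, :, None]
            nonrigid.append(DisplacementField(f))
    else:
        rigid = RigidMotion.zero(n_frames, nz)
        nonrigid = [DisplacementField.zero(shape) for _ in range(n_frames)]
    if with_fieldmap:
        fmap = ndimage.gaussian_filter(rng.standard_normal(shape), 6.0)
        fmap = fieldmap_amp_hz * fmap / np.abs(fmap).max()
        fmap *= atlas.labels.data > 0
    else:
        fmap = np.zeros(shape)
    fieldmap = Image3D(fmap, anat.affine, ImageKind.fieldmap_hz)
    acq = AcquisitionParams(
        tr_s=1.0, te_s=0.016, matrix=(shape[0], shape[1]),
        fov_mm=(0.25 * shape[0], 0.25 * shape[1]),
        eff_echo_spacing_s=0.0004, flip_angle_deg=55.0,
    )
    return PhantomTruth(
        clean_series=clean,
        rigid_motion=rigid,
        nonrigid_field_per_frame=nonrigid,
        fieldmap=fieldmap,
        atlas=atlas,
        network_corr=network,
        noise_sigma=noise_sigma,
        acq=acq,
    )


def write_phantom_bundle(truth: PhantomTruth, out_dir, seed: int = 0) -> dict:
    """Materialize the phantom as NIfTI volumes + CSV tables for the runner.

    Applies the acquisition forward model with the given seed and writes
    acquired functional, clean functional, anatomical (the clean temporal
    mean), field map, atlas labels and region table.  Returns the path map.
    """
    from pathlib import Path

    from .images import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acquired = apply_acquisition(truth.clean_series, truth, truth.acq, seed=seed)
    anat = Image3D(
        truth.clean_series.data.mean(axis=3), truth.clean_series.affine,
        ImageKind.anatomical,
    )
    paths = {
        "func": out / "func.nii.gz",
        "clean_func": out / "func_clean.nii.gz",
        "anat": out / "anat.nii.gz",
        "fieldmap": out / "fieldmap_hz.nii.gz",
        "labels": out / "atlas_labels.nii.gz",
        "regions": out / "atlas_regions.csv",
        "network": out / "planted_network.csv",
    }
    write_image(acquired, paths["func"])
    write_image(truth.clean_series, paths["clean_func"])
    write_image(anat, paths["anat"])
    write_image(truth.fieldmap, paths["fieldmap"])
    truth.atlas.save(paths["labels"], paths["regions"])
    truth.network_corr.to_csv(paths["network"], index=False)
    return {k: str(v) for k, v in paths.items()}
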