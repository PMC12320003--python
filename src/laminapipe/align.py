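"""Subject-level alignment: bias correction, brain masking, linear
registration, small-deformation non-linear refinement, and transform chains.

Registration direction follows the texture-rich-to-poor rule: the richer
image (anatomical onto functional, atlas onto anatomical) is the moving
image.  Stored transforms are always the pullback used at resampling time: a
4x4 voxel-space matrix (or displacement field) mapping fixed-grid indices to
moving-grid sample locations, so applying a transform to the moving image
lands it on the fixed grid.

Chains concatenate steps (e.g. atlas -> anatomical -> EPI); applying a chain
composes every step into one displacement field and delegates the single
interpolation to the warp module.  Label volumes go through nearest-neighbour
gathers, never linear interpolation.

The non-linear step offers an external symmetric-normalization backend when
the optional `ants` dependency is installed, and an internal multi-resolution
diffusion-regularized demons refinement that keeps the package
self-contained; full diffeomorphic machinery is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage, optimize

from .images import Image3D, ImageKind
from .transforms import DisplacementField
from .warp import compose_mappings, invert_field, resample_volume

__all__ = [
    "bias_correct",
    "make_brain_mask",
    "register_linear",
    "register_nonlinear",
    "LinearTransform",
    "FieldTransform",
    "TransformChain",
    "build_chain",
    "apply_chain",
]


# ---------------------------------------------------------------------------
# bias field


def _poly_basis(coords: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones(coords.shape[0])]
    x, y, z = coords.T
    for d in range(1, degree + 1):
        for i in range(d + 1):
            for j in range(d + 1 - i):
                k = d - i - j
                cols.append((x**i) * (y**j) * (z**k))
    return np.stack(cols, axis=1)


def bias_correct(
    anat: Image3D,
    mask: Optional[Image3D] = None,
    degree: int = 3,
    return_field: bool = False,
):
    """Estimate and divide out a multiplicative low-frequency gain field.

    A polynomial of the given degree is fit to the log intensities inside the
    mask (smooth by construction: no spatial frequency above the polynomial
    order), exponentiated, and normalized to unit geometric mean, so the
    estimate is invariant to global scaling of the input.
    """
    m = (anat.data > 0) if mask is None else mask.data.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    if np.any(anat.data[m] <= 0):
        raise ValueError("nonpositive voxels inside mask")
    shape = anat.shape
    idx = np.argwhere(m).astype(np.float64)
    idx /= np.maximum(np.asarray(shape, float) - 1.0, 1.0)  # unit cube, conditioning
    B = _poly_basis(idx, degree)
    logv = np.log(anat.data[m])
    coef, *_ = np.linalg.lstsq(B, logv, rcond=None)
    logf = B @ coef
    logf -= logf.mean()  # unit geometric mean -> scale invariance
    fld = np.ones(shape)
    fld[m] = np.exp(logf)
    corrected = anat.data / fld
    out = Image3D(corrected, anat.affine, anat.kind)
    if return_field:
        return out, Image3D(fld, anat.affine, ImageKind.anatomical)
    return out


def make_brain_mask(
    anat: Image3D, threshold: Optional[float] = None, closing_radius: int = 2
) -> Image3D:
    """Binary brain mask: threshold, largest connected component, closing,
    hole filling.  Parameters are returned implicitly via the docstring
    contract; the threshold defaults to Otsu's."""
    data = anat.data
    if not np.any(data > 0):
        raise ValueError("image has no positive voxels: empty mask")
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(data))
    raw = data > threshold
    if not raw.any():
        raise ValueError("empty mask after threshold")
    lab, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        raw = lab == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        # in-plane closing: thin slabs would be eroded away by a 3D element
        st = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)[:, :, None]
        raw = ndimage.binary_closing(raw, st, iterations=closing_radius)
    raw = ndimage.binary_fill_holes(raw)
    return Image3D(raw.astype(np.uint8), anat.affine, ImageKind.mask)


# ---------------------------------------------------------------------------
# linear registration


def _params_to_matrix(params: np.ndarray, model: str, shape) -> np.ndarray:
    centre = (np.asarray(shape, float) - 1.0) / 2.0
    if model == "rigid":
        from .transforms import rigid_matrix

        return rigid_matrix(params, shape, (1.0, 1.0, 1.0))
    A = np.eye(3) + params[3:12].reshape(3, 3)
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = centre - A @ centre + params[:3]
    return M


def _metric_value(a: np.ndarray, b: np.ndarray, metric: str, bins: int = 32) -> float:
    """Similarity between two masked sample vectors (higher is better)."""
    if metric == "corr":
        a = a - a.mean()
        b = b - b.mean()
        den = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / den) ** 2 if den > 0 else 0.0
    if metric == "mutual_info":
        h, _, _ = np.histogram2d(a, b, bins=bins)
        p = h / h.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())
    raise ValueError(f"unknown metric {metric!r}")


def register_linear(
    moving: Image3D,
    fixed: Image3D,
    model: str = "rigid",
    metric: str = "corr",
    init: Optional[np.ndarray] = None,
    in_plane: Optional[bool] = None,
) -> "LinearTransform":
    """Rigid (6-DOF) or affine (12-DOF) registration of moving onto fixed.

    Multi-resolution Powell search maximizing the metric over the fixed
    image's interior.  Follows the texture-rich-to-poor direction: pass the
    richer image as ``moving``.  For thin slabs (< 8 slices) rigid
    registration restricts itself to the in-plane parameters (tx, ty, rz) by
    default — the out-of-plane ones are unidentifiable there.
    """
    if model not in ("rigid", "affine"):
        raise ValueError("model must be rigid or affine")
    shape = fixed.shape
    n_par = 6 if model == "rigid" else 12
    if in_plane is None:
        in_plane = model == "rigid" and shape[2] < 8
    free = np.ones(n_par, dtype=bool)
    if in_plane and model == "rigid":
        free[:] = False
        free[[0, 1, 5]] = True
    x0 = np.zeros(n_par) if init is None else np.asarray(init, float).copy()
    from .motion import _interior_mask

    m = _interior_mask(shape)
    idx = np.argwhere(m).astype(np.float64)

    def expand(p_free):
        p = np.zeros(n_par)
        p[free] = p_free
        return p

    def make_cost(mov, fvals):
        def cost(p_free):
            M = _params_to_matrix(expand(p_free), model, shape)
            coords = idx @ M[:3, :3].T + M[:3, 3]
            vals = ndimage.map_coordinates(mov, coords.T, order=1, mode="nearest")
            return -_metric_value(vals, fvals, metric)

        return cost

    full_cost = make_cost(moving.data, fixed.data[m])
    before = -full_cost(np.zeros(free.sum()))
    res = None
    x0 = x0[free]
    for smooth in (2.0, 0.0):
        mov = ndimage.gaussian_filter(moving.data, smooth) if smooth else moving.data
        fx = ndimage.gaussian_filter(fixed.data, smooth) if smooth else fixed.data
        res = optimize.minimize(
            make_cost(mov, fx[m]), x0, method="Powell",
            options={"xtol": 1e-5, "ftol": 1e-9, "maxiter": 4000},
        )
        x0 = res.x
    after = -full_cost(x0)
    x0 = expand(x0)
    if not np.isfinite(after):
        raise RuntimeError(f"linear registration diverged: {res.message}")
    M = _params_to_matrix(x0, model, shape)
    return LinearTransform(M, model, metric_before=before, metric_after=after)


# ---------------------------------------------------------------------------
# non-linear registration


def register_nonlinear(
    moving: Image3D,
    fixed: Image3D,
    backend: str = "internal_demons",
    iterations: Tuple[int, ...] = (60, 40, 20),
    smooth_update: float = 1.0,
    smooth_field: float = 1.5,
) -> DisplacementField:
    """Small-deformation refinement after linear pre-alignment.

    ``internal_demons`` runs multi-resolution intensity-driven demons with
    Gaussian (diffusion) regularization of both the update and the
    accumulated field.  ``external_syn`` delegates to the optional `ants`
    package if installed.
    """
    if backend == "external_syn":
        try:
            import ants  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "external_syn backend requires the optional 'ants' package; "
                "use backend='internal_demons' as the built-in fallback"
            ) from exc
        return _syn_external(moving, fixed)
    if backend != "internal_demons":
        raise ValueError(f"unknown backend {backend!r}")
    fix = fixed.data.astype(np.float64)
    mov = moving.data.astype(np.float64)
    scale = max(fix.std(), 1e-12)
    fix = fix / scale
    mov = mov / scale
    levels = len(iterations)
    fld = None
    for lev in range(levels):
        factor = 2 ** (levels - 1 - lev)
        if factor > 1:
            # never shrink an axis below 4 voxels (thin slabs stay intact)
            zoom = [max(1.0 / factor, min(4, s) / s) for s in fix.shape]
            f_l = ndimage.zoom(ndimage.gaussian_filter(fix, factor / 2), zoom, order=1)
            m_l = ndimage.zoom(ndimage.gaussian_filter(mov, factor / 2), zoom, order=1)
        else:
            f_l, m_l = fix, mov
        grid = f_l.shape
        if fld is None:
            u = np.zeros(grid + (3,))
        else:
            ratio = np.array(grid) / np.array(fld.shape[:3])
            u = np.stack(
                [
                    ndimage.zoom(fld[..., c], ratio, order=1) * ratio[c]
                    for c in range(3)
                ],
                axis=-1,
            )
        alpha2 = 0.05  # stabilizer in the demons force denominator
        for _ in range(iterations[lev]):
            warped = resample_volume(m_l, DisplacementField(u), "linear")
            grad = _gradient_safe(warped)
            diff = (f_l - warped)[..., None]
            g2 = (grad**2).sum(axis=-1, keepdims=True)
            force = diff * grad / (g2 + alpha2 + (diff**2) * 0.1)
            for c in range(3):
                force[..., c] = ndimage.gaussian_filter(force[..., c], smooth_update)
            u = u + force
            for c in range(3):
                u[..., c] = ndimage.gaussian_filter(u[..., c], smooth_field)
        fld = u
    return DisplacementField(fld)


def _gradient_safe(vol: np.ndarray) -> np.ndarray:
    """Per-axis central differences; singleton axes get zero gradient."""
    out = np.zeros(vol.shape + (3,))
    for ax in range(3):
        if vol.shape[ax] >= 2:
            out[..., ax] = np.gradient(vol, axis=ax)
    return out


def _syn_external(moving: Image3D, fixed: Image3D) -> DisplacementField:  # pragma: no cover
    import ants

    f = ants.from_numpy(fixed.data.astype(np.float32))
    m = ants.from_numpy(moving.data.astype(np.float32))
    reg = ants.registration(f, m, type_of_transform="SyNOnly")
    warp = ants.image_read(reg["fwdtransforms"][0])
    arr = warp.numpy()
    return DisplacementField(arr.reshape(fixed.shape + (3,)))


# ---------------------------------------------------------------------------
# transform chains


@dataclass
class LinearTransform:
    """Pullback matrix mapping fixed-grid indices to moving-grid locations."""

    matrix: np.ndarray
    model: str = "rigid"
    metric_before: Optional[float] = None
    metric_after: Optional[float] = None

    def inverse(self) -> "LinearTransform":
        return LinearTransform(np.linalg.inv(self.matrix), self.model)

    def mapping(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def to_dict(self) -> dict:
        return {"type": "linear", "model": self.model, "matrix": self.matrix.tolist()}


@dataclass
class FieldTransform:
    field: DisplacementField

    def inverse(self) -> "FieldTransform":
        return FieldTransform(invert_field(self.field, tol=0.005, max_iter=100))

    def mapping(self, points: np.ndarray) -> np.ndarray:
        return self.field.mapping(points)


Step = Union[LinearTransform, FieldTransform]


@dataclass
class TransformChain:
    """Ordered transform steps with source/target space labels.

    Steps are in application order: ``steps[0]`` is applied to the moving
    image first.  The inverse chain reverses the order and inverts each step.
    """

    steps: List[Step]
    source_space: str = "moving"
    target_space: str = "fixed"

    def inverse(self) -> "TransformChain":
        return TransformChain(
            [s.inverse() for s in reversed(self.steps)],
            source_space=self.target_space,
            target_space=self.source_space,
        )

    def to_field(self, grid, source_grid=None) -> DisplacementField:
        fields = []
        for s in self.steps:
            if isinstance(s, FieldTransform):
                fields.append(s.field)
            else:
                fields.append(_linear_to_field(s, grid))
        return compose_mappings(fields, grid, source_grid=source_grid)


def _linear_to_field(t: LinearTransform, grid) -> DisplacementField:
    from .transforms import matrix_to_field

    return matrix_to_field(t.matrix, grid)


def build_chain(steps: Sequence[Step], source_space="moving", target_space="fixed") -> TransformChain:
    return TransformChain(list(steps), source_space, target_space)


def apply_chain(
    chain: TransformChain,
    img: Image3D,
    grid=None,
    interp: str = "cubic_spline",
) -> Image3D:
    """Resample an image through the composed chain in one interpolation.

    Label volumes automatically use nearest-neighbour gathers.
    """
    grid = tuple(grid) if grid is not None else img.shape
    fld = chain.to_field(grid, source_grid=None)
    if img.kind == ImageKind.label:
        out = _nearest_resample(img.data, fld)
        return Image3D(out, img.affine, ImageKind.label)
    out = resample_volume(img.data, fld, interp)
    return Image3D(out, img.affine, img.kind)


def _nearest_resample(vol: np.ndarray, fld: DisplacementField) -> np.ndarray:
    grid = fld.grid
    nx, ny, nz = grid
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).astype(np.float64)
    coords = np.rint(idx + fld.shifts).astype(np.int64).reshape(-1, 3)
    inside = np.all((coords >= 0) & (coords < np.array(vol.shape)), axis=1)
    coords = np.clip(coords, 0, np.array(vol.shape) - 1)
    out = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
    out[~inside] = 0
    return out.reshape(grid)
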