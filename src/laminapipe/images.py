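"""Core image data model and NIfTI / atlas-table I/O.

The pipeline works on two in-memory containers: :class:`Image3D` for anatomical
volumes, field maps (Hz), masks and integer label volumes, and :class:`Image4D`
for the functional EPI series.  Voxel data are kept as 64-bit floats internally
(the denoising SVDs need the precision) regardless of the on-disk dtype; label
volumes are the exception and stay integer.

World coordinates are millimetres through the 4x4 affine; voxel indices are
0-based throughout.  The atlas region hierarchy is a flat delimited table
(id, acronym, parent_id) loaded into :class:`AtlasHierarchy`, which supports
descendant resolution down to cortical-layer leaves.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageKind",
    "Image3D",
    "Image4D",
    "AcquisitionParams",
    "AtlasHierarchy",
    "read_image",
    "write_image",
    "read_region_table",
    "read_region_tree_json",
    "resolve_region",
]


class ImageKind(str, enum.Enum):
    anatomical = "anatomical"
    fieldmap_hz = "fieldmap_hz"
    mask = "mask"
    label = "label"
    functional = "functional"


@dataclass
class Image3D:
    """A 3D volume: voxel array, voxel-to-world affine (mm), and a semantic kind."""

    data: np.ndarray
    affine: np.ndarray
    kind: ImageKind = ImageKind.anatomical

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Image3D requires 3 axes, got {self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        kind = ImageKind(self.kind)
        self.kind = kind
        if kind == ImageKind.fieldmap_hz:
            if not np.all(np.isfinite(self.data)):
                raise ValueError("field map contains non-finite voxels")
            self.data = self.data.astype(np.float64)
        elif kind == ImageKind.label:
            if not np.issubdtype(self.data.dtype, np.integer):
                rounded = np.rint(self.data)
                if not np.allclose(self.data, rounded):
                    raise ValueError("label volume has non-integer values")
                self.data = rounded.astype(np.int32)
            if self.data.min() < 0:
                raise ValueError("label volume has negative labels")
        elif kind == ImageKind.mask:
            uniq = np.unique(self.data)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("mask must be binary (0/1)")
            self.data = self.data.astype(bool)
        else:
            self.data = self.data.astype(np.float64)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def copy(self) -> "Image3D":
        return Image3D(self.data.copy(), self.affine.copy(), self.kind)


@dataclass
class Image4D:
    """A functional series: (x, y, slice, time) array plus affine, TR and PE axis.

    ``pe_axis`` indexes the in-plane phase-encode axis (0 or 1) along which B0
    off-resonance displaces voxels in EPI.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float = 1.0
    pe_axis: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Image4D requires 4 axes, got {self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")
        if self.pe_axis not in (0, 1):
            raise ValueError("pe_axis must be 0 or 1")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int) -> np.ndarray:
        return self.data[..., t]

    def copy(self) -> "Image4D":
        return Image4D(self.data.copy(), self.affine.copy(), self.tr_s, self.pe_axis)


@dataclass
class AcquisitionParams:
    """EPI acquisition parameters.

    ``eff_echo_spacing_s`` times the number of phase-encode lines gives the
    total EPI readout duration, which converts field-map Hz into voxel shift.
    ``flip_angle_deg`` is carried as metadata only.
    """

    tr_s: float
    te_s: float
    matrix: tuple  # (n_read, n_pe)
    fov_mm: tuple
    eff_echo_spacing_s: float
    flip_angle_deg: float = 55.0

    def __post_init__(self) -> None:
        for name in ("tr_s", "te_s", "eff_echo_spacing_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        self.matrix = tuple(int(m) for m in self.matrix)
        if any(m < 2 for m in self.matrix):
            raise ValueError("matrix entries must be >= 2")
        self.fov_mm = tuple(float(f) for f in self.fov_mm)
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError("fov_mm entries must be positive")

    @property
    def n_pe(self) -> int:
        return self.matrix[1]

    @property
    def readout_duration_s(self) -> float:
        return self.eff_echo_spacing_s * self.n_pe


class AtlasHierarchy:
    """Label volume plus a region tree (id, acronym, parent_id, depth).

    The region graph must be a forest; every nonzero label value in the volume
    must appear in the table.  ``depth`` is 1 for roots and parent depth + 1
    otherwise (computed, never trusted from the input table).
    """

    def __init__(self, labels: Image3D, regions: pd.DataFrame):
        if labels.kind != ImageKind.label:
            raise ValueError("labels must be an Image3D of kind 'label'")
        regions = regions.copy()
        required = {"region_id", "acronym", "parent_id"}
        if not required.issubset(regions.columns):
            raise ValueError(f"region table needs columns {sorted(required)}")
        regions["region_id"] = regions["region_id"].astype(int)
        if regions["region_id"].duplicated().any():
            raise ValueError("duplicate region_id in table")
        ids = set(regions["region_id"])
        parent = {}
        for rid, pid in zip(regions["region_id"], regions["parent_id"]):
            if pd.isna(pid):
                parent[rid] = None
            else:
                pid = int(pid)
                if pid not in ids:
                    raise ValueError(f"parent_id {pid} not in table")
                parent[rid] = pid
        # depth computation doubles as cycle detection
        depth = {}

        def _depth(r, trail):
            if r in depth:
                return depth[r]
            if r in trail:
                raise ValueError("region graph has a cycle")
            p = parent[r]
            d = 1 if p is None else _depth(p, trail | {r}) + 1
            depth[r] = d
            return d

        for r in ids:
            _depth(r, set())
        regions["depth"] = [depth[r] for r in regions["region_id"]]
        present = set(np.unique(labels.data)) - {0}
        missing = present - ids
        if missing:
            raise ValueError(f"label values absent from region table: {sorted(missing)}")
        self.labels = labels
        self.regions = regions.reset_index(drop=True)
        self._parent = parent
        self._children: dict = {r: [] for r in ids}
        for r, p in parent.items():
            if p is not None:
                self._children[p].append(r)

    @property
    def region_ids(self) -> list:
        return list(self.regions["region_id"])

    @property
    def max_depth(self) -> int:
        return int(self.regions["depth"].max())

    def acronym(self, region_id: int) -> str:
        row = self.regions[self.regions["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region_id {region_id}")
        return str(row["acronym"].iloc[0])

    def children(self, region_id: int) -> list:
        if region_id not in self._children:
            raise KeyError(f"unknown region_id {region_id}")
        return sorted(self._children[region_id])

    def descendants(self, region_id: int, include_self: bool = True) -> list:
        """All region ids below ``region_id`` (depth-first order)."""
        if region_id not in self._children:
            raise KeyError(f"unknown region_id {region_id}")
        out = [region_id] if include_self else []
        stack = list(self._children[region_id])
        while stack:
            r = stack.pop()
            out.append(r)
            stack.extend(self._children[r])
        return out

    def roots(self) -> list:
        return sorted(r for r, p in self._parent.items() if p is None)

    def regions_at_depth(self, depth: int) -> list:
        return sorted(self.regions.loc[self.regions["depth"] == depth, "region_id"])

    def save(self, labels_path, table_path) -> None:
        write_image(self.labels, labels_path)
        self.regions[["region_id", "acronym", "parent_id"]].to_csv(table_path, index=False)

    @classmethod
    def load(cls, labels_path, table_path) -> "AtlasHierarchy":
        labels = read_image(labels_path, ImageKind.label)
        return cls(labels, read_region_table(table_path))


# ---------------------------------------------------------------------------
# I/O


def read_image(path, expected_kind: Union[ImageKind, str] = ImageKind.anatomical):
    """Read a NIfTI volume as Image3D or Image4D.

    ``expected_kind`` selects the container: ``functional`` demands a 4D file
    (TR taken from the header time pixdim); any other kind demands 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    kind = ImageKind(expected_kind)
    if kind == ImageKind.functional:
        if data.ndim != 4:
            raise ValueError(f"{path}: expected 4D volume, file has {data.ndim} axes")
        tr = float(img.header["pixdim"][4])
        if tr <= 0:
            tr = 1.0
        pe_axis = int(img.header.get("intent_p1", 1) or 1)
        if pe_axis not in (0, 1):
            pe_axis = 1
        return Image4D(data, img.affine, tr_s=tr, pe_axis=pe_axis)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D volume, file has {data.ndim} axes")
    return Image3D(data, img.affine, kind)


def write_image(img: Union[Image3D, Image4D], path) -> None:
    """Write an image as NIfTI-1, preserving affine and (for 4D) TR."""
    path = Path(path)
    if isinstance(img, Image4D):
        out = nib.Nifti1Image(img.data, img.affine)
        out.header["pixdim"][4] = img.tr_s
        out.header["intent_p1"] = img.pe_axis
    elif isinstance(img, Image3D):
        data = img.data
        if img.kind == ImageKind.mask:
            data = data.astype(np.uint8)
        out = nib.Nifti1Image(data, img.affine)
    else:
        raise TypeError("img must be Image3D or Image4D")
    out.to_filename(str(path))


def read_region_table(path) -> pd.DataFrame:
    """Load the flat delimited region table (region_id, acronym, parent_id)."""
    df = pd.read_csv(path)
    return df


def read_region_tree_json(path) -> pd.DataFrame:
    """Convenience loader for a nested JSON tree dialect.

    Accepts ``{"id": ..., "acronym": ..., "children": [...]}`` (a single root
    or a list of roots) and flattens it into the canonical table.
    """
    with open(path) as fh:
        tree = json.load(fh)
    rows = []

    def _walk(node, parent):
        rows.append(
            {"region_id": int(node["id"]), "acronym": str(node.get("acronym", node["id"])),
             "parent_id": parent}
        )
        for child in node.get("children", []):
            _walk(child, int(node["id"]))

    for root in tree if isinstance(tree, list) else [tree]:
        _walk(root, None)
    return pd.DataFrame(rows)


def resolve_region(atlas: AtlasHierarchy, region_id: int, include_descendants: bool = True):
    """Voxel indices carrying a region's label (optionally any descendant label).

    Returns a boolean mask over the label volume.
    """
    if region_id not in set(atlas.region_ids):
        raise KeyError(f"unknown region_id {region_id}")
    ids = atlas.descendants(region_id) if include_descendants else [region_id]
    return np.isin(atlas.labels.data, ids)
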