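"""Atlas upsampling: recursive bisection of labeled regions.

Each atlas region is repeatedly cut by a plane perpendicular to its principal
(PCA) axis until the pieces fall below a voxel-count threshold, turning a
coarse parcellation into a finer one while preserving region boundaries.
With several subjects, the cutting axis is computed on a *group* region —
each subject's region voxels translated so their centroids coincide — so all
subjects are split consistently.

Voxel coordinates are scaled by the voxel size (mm) before PCA so that
anisotropic voxels do not bias the main axis.  The default cut passes through
the median projection (balanced halves, guaranteed termination); a
centroid-plane variant is available behind ``mode="centroid"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LabelVolume",
    "SubdivisionResult",
    "read_label_volume",
    "write_label_volume",
    "group_roi",
    "principal_axis",
    "bisect_roi",
    "subdivide",
]


@dataclass(frozen=True)
class LabelVolume:
    """3-D integer voxel labels (0 = background) with physical voxel size."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {arr.ndim}-D")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("labels must be integers")
        if (arr < 0).any():
            raise ValueError("labels must be nonnegative")
        if not (arr > 0).any():
            raise ValueError("label volume has no labeled voxels")
        object.__setattr__(self, "labels", arr)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    def region_voxels(self, label: int) -> np.ndarray:
        """Integer voxel indices (m, 3) of one label."""
        return np.argwhere(self.labels == label)

    def region_coords_mm(self, label: int) -> np.ndarray:
        """Region voxel coordinates scaled to millimetres."""
        return self.region_voxels(label) * np.asarray(self.voxel_size)


@dataclass(frozen=True)
class SubdivisionResult:
    volume: LabelVolume
    parent_of: dict[int, int]
    child_sizes: dict[int, int]
    threshold: int
    degenerate: tuple[int, ...] = field(default=())  # children left unsplit


def read_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    return LabelVolume(data, tuple(float(z) for z in zooms), np.asarray(img.affine))


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    affine = vol.affine if vol.affine is not None else np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.int32), affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def group_roi(volumes: Sequence[LabelVolume], label: int) -> np.ndarray:
    """Pool one region across subjects after centroid alignment.

    Each subject's voxel coordinate set (mm) is translated so its centroid
    sits at the origin, then all sets are pooled (multiset union).
    """
    pooled = []
    for s, vol in enumerate(volumes):
        coords = vol.region_coords_mm(label)
        if coords.size == 0:
            raise ValueError(f"label {label} absent in subject index {s}")
        pooled.append(coords - coords.mean(axis=0))
    return np.vstack(pooled)


def principal_axis(voxels: np.ndarray) -> np.ndarray:
    """Unit main axis of a point set: leading covariance eigenvector.

    Among eigenvalues tied at the maximum (within 1e-9 relative), the axis
    closest to +x, then +y, then +z is preferred; the sign is fixed so the
    largest-magnitude component is positive.
    """
    coords = np.asarray(voxels, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("expected an (m, 3) coordinate set")
    if np.unique(coords, axis=0).shape[0] < 2:
        raise ValueError("degenerate ROI: fewer than 2 distinct coordinates")
    cov = np.cov(coords, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam_max = eigvals[-1]
    tol = 1e-9 * max(lam_max, 1.0)
    tied = eigvals >= lam_max - tol
    if tied.sum() == 1:
        axis = eigvecs[:, -1]
    else:
        basis = eigvecs[:, tied]  # orthonormal columns spanning the tied subspace
        axis = None
        for unit in np.eye(3):  # lexicographic (x, y, z) preference
            proj = basis @ (basis.T @ unit)
            if np.linalg.norm(proj) > 1e-9:
                axis = proj / np.linalg.norm(proj)
                break
        if axis is None:  # unreachable: a 3-vector basis always catches one
            axis = eigvecs[:, -1]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def bisect_roi(voxels: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a point set by a plane perpendicular to ``axis`` at the median
    projection.  Voxels whose projection ties the median go to side A."""
    coords = np.asarray(voxels, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 voxels to bisect")
    proj = coords @ np.asarray(axis, dtype=float)
    mask = proj <= np.median(proj)
    return coords[mask], coords[~mask]


def _split_mask(proj: np.ndarray, cut: float) -> np.ndarray:
    return proj <= cut


def subdivide(
    volume: LabelVolume,
    threshold: int,
    group_volumes: Sequence[LabelVolume] | None = None,
    mode: str = "median",
) -> SubdivisionResult:
    """Recursively bisect every region of ``volume`` until pieces drop below
    ``threshold`` voxels.

    A region of exactly ``threshold`` voxels still splits — subdivision stops
    only once a piece has *dropped below* the threshold.  When
    ``group_volumes`` is given, the cutting axis and cut position come from
    the pooled group region (subject coordinates are centroid-aligned into
    group space), so all subjects split along the same planes; otherwise the
    single volume plays both roles.  Children get fresh consecutive labels
    (1, 2, …) and their genealogy and sizes are recorded.  Regions that turn
    degenerate during recursion (coincident coordinates, or a cut that fails
    to separate) are left unsplit and logged.
    """
    if threshold < 2:
        raise ValueError("threshold must be at least 2 voxels")
    if mode not in ("median", "centroid"):
        raise ValueError("mode must be 'median' or 'centroid'")

    out = np.zeros_like(volume.labels, dtype=np.int32)
    parent_of: dict[int, int] = {}
    child_sizes: dict[int, int] = {}
    degenerate: list[int] = []
    next_label = 1
    vsize = np.asarray(volume.voxel_size)

    for parent in np.unique(volume.labels[volume.labels > 0]):
        parent = int(parent)
        vox = volume.region_voxels(parent)  # (m, 3) int indices
        subj_coords = vox * vsize
        subj_centered = subj_coords - subj_coords.mean(axis=0)
        grp = (group_roi(group_volumes, parent) if group_volumes is not None
               else subj_centered)

        stack = [(vox, subj_centered, grp)]
        while stack:
            vox_r, subj_r, grp_r = stack.pop()
            size = vox_r.shape[0]

            def finalize(flag: bool = False):
                nonlocal next_label
                out[tuple(vox_r.T)] = next_label
                parent_of[next_label] = parent
                child_sizes[next_label] = size
                if flag:
                    degenerate.append(next_label)
                next_label += 1

            if size < threshold:
                finalize()
                continue
            try:
                axis = principal_axis(grp_r)
            except ValueError:
                logger.warning("region %d piece of %d voxels is degenerate; left unsplit",
                               parent, size)
                finalize(flag=True)
                continue
            gproj = grp_r @ axis
            cut = float(np.median(gproj)) if mode == "median" else float(gproj.mean())
            sproj = subj_r @ axis
            smask = _split_mask(sproj, cut)
            gmask = _split_mask(gproj, cut)
            if smask.all() or not smask.any() or gmask.all() or not gmask.any():
                logger.warning("region %d: cut fails to separate %d voxels; left unsplit",
                               parent, size)
                finalize(flag=True)
                continue
            # re-center each side so subsequent group alignment stays valid
            for sm, gm in ((smask, gmask), (~smask, ~gmask)):
                stack.append((vox_r[sm], subj_r[sm] - subj_r[sm].mean(axis=0),
                              grp_r[gm] - grp_r[gm].mean(axis=0)))

    vol_out = LabelVolume(out, volume.voxel_size, volume.affine)
    return SubdivisionResult(vol_out, parent_of, child_sizes, threshold, tuple(degenerate))
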