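"""ROI masks for the eight oculomotor regions on a common standard-space grid.

The eight regions (left/right FEF, inferior precentral, SEF, parietal) are
defined by published stereotaxic bounding boxes.  Because the original
functional maps are not available, each mask is synthesised as a connected
random voxel set of the requested size inside its bounding box, with all
masks kept pairwise disjoint.

The default analysis grid is a 2 mm isotropic standard-space grid: the
published voxel counts (564 SEF, 1043 parietal) refer to standard-space
voxels and geometrically cannot fit inside the boxes at the 3 x 3 x 3.3 mm
acquisition resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "RoiMask",
    "ROI_LABELS",
    "ROI_BOXES_MM",
    "DEFAULT_ROI_SIZES",
    "ACQUISITION_VOXEL_MM",
    "build_atlas",
    "mask_volume",
    "atlas_to_nifti",
    "atlas_from_nifti",
]

#: EPI acquisition voxel size (mm); analysis happens on the standard grid below.
ACQUISITION_VOXEL_MM = (3.0, 3.0, 3.3)

ROI_LABELS = ("L-FEF", "R-FEF", "L-Prec", "R-Prec", "L-SEF", "R-SEF", "L-Par", "R-Par")

#: stereotaxic bounding boxes, mm: (xmin, xmax, ymin, ymax, zmin, zmax)
ROI_BOXES_MM: dict[str, tuple[float, float, float, float, float, float]] = {
    "L-FEF": (-51, -15, -18, 9, 42, 69),
    "R-FEF": (24, 60, -15, 6, 42, 69),
    "L-Prec": (-56, -39, -10, 12, 30, 48),
    "R-Prec": (40, 62, -8, 12, 26, 40),
    "L-SEF": (-10, 2, -16, 4, 42, 68),
    "R-SEF": (2, 12, -14, 4, 42, 68),
    "L-Par": (-40, -10, -72, -38, 48, 70),
    "R-Par": (14, 42, -80, -46, 48, 74),
}

#: default mask sizes (voxels). SEF and parietal counts are published; FEF and
#: precentral counts are configuration chosen inside the published 564-1043 range.
DEFAULT_ROI_SIZES: dict[str, int] = {
    "L-FEF": 900,
    "R-FEF": 900,
    "L-Prec": 700,
    "R-Prec": 700,
    "L-SEF": 564,
    "R-SEF": 564,
    "L-Par": 1043,
    "R-Par": 1043,
}

# tight-capacity regions are grown first so contested box overlaps
# (e.g. L-Prec within the L-FEF box) cannot starve them
_BUILD_ORDER = ("L-Prec", "R-Prec", "L-SEF", "R-SEF", "L-Par", "R-Par", "L-FEF", "R-FEF")

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=int
)


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned standard-space voxel grid (mm coordinates at voxel centres)."""

    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: tuple[float, float, float] = (-64.0, -88.0, 20.0)
    shape: tuple[int, int, int] = (64, 52, 28)
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel dimensions must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def ijk_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk) * np.array(self.voxel_size_mm) + np.array(self.origin_mm)

    def box_index_ranges(
        self, box_mm: tuple[float, float, float, float, float, float]
    ) -> list[range]:
        """Index ranges of voxels whose centres fall in the half-open mm box."""
        ranges = []
        for ax in range(3):
            lo, hi = box_mm[2 * ax], box_mm[2 * ax + 1]
            vs, o = self.voxel_size_mm[ax], self.origin_mm[ax]
            i_lo = int(np.ceil((lo - o) / vs - 1e-9))
            i_hi = int(np.ceil((hi - o) / vs - 1e-9))  # exclusive
            i_lo = max(i_lo, 0)
            i_hi = min(i_hi, self.shape[ax])
            ranges.append(range(i_lo, i_hi))
        return ranges


@dataclass(frozen=True)
class RoiMask:
    label: str
    grid: GridSpec
    indices: np.ndarray  # sorted linear voxel indices (canonical voxel order)
    box_mm: tuple[float, float, float, float, float, float]
    target_size: int

    @property
    def size(self) -> int:
        return int(self.indices.size)

    def ijk(self) -> np.ndarray:
        return np.stack(np.unravel_index(self.indices, self.grid.shape), axis=1)

    def dense(self) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=bool)
        vol.ravel()[self.indices] = True
        return vol


def _grow_region(
    candidates: set[int],
    size: int,
    grid: GridSpec,
    rng: np.random.Generator,
    max_attempts: int = 25,
) -> np.ndarray | None:
    """Random-frontier growth of a 6-connected region of ``size`` voxels."""
    shape = grid.shape
    cand_list = sorted(candidates)
    for _ in range(max_attempts):
        start = cand_list[rng.integers(len(cand_list))]
        region = {start}
        frontier = [start]
        while frontier and len(region) < size:
            k = int(rng.integers(len(frontier)))
            frontier[k], frontier[-1] = frontier[-1], frontier[k]
            v = frontier.pop()
            ijk = np.array(np.unravel_index(v, shape))
            for off in _NEIGHBOR_OFFSETS:
                nijk = ijk + off
                if np.any(nijk < 0) or np.any(nijk >= shape):
                    continue
                nv = int(np.ravel_multi_index(nijk, shape))
                if nv in candidates and nv not in region:
                    region.add(nv)
                    frontier.append(nv)
                    if len(region) >= size:
                        break
        if len(region) >= size:
            return np.array(sorted(region), dtype=np.int64)
    return None


def build_atlas(
    grid: GridSpec | None = None,
    sizes: dict[str, int] | None = None,
    seed: int = 0,
) -> dict[str, RoiMask]:
    """Construct all eight ROI masks; deterministic given ``seed``.

    Raises ``ValueError`` when a requested size exceeds the number of voxels
    available inside the corresponding bounding box.
    """
    grid = grid or GridSpec()
    sizes = dict(DEFAULT_ROI_SIZES, **(sizes or {}))
    unknown = set(sizes) - set(ROI_LABELS)
    if unknown:
        raise ValueError(f"unknown ROI labels: {sorted(unknown)}")

    ss = np.random.SeedSequence(seed)
    label_rngs = {
        label: np.random.default_rng(child)
        for label, child in zip(_BUILD_ORDER, ss.spawn(len(_BUILD_ORDER)))
    }
    taken: set[int] = set()
    masks: dict[str, RoiMask] = {}
    for label in _BUILD_ORDER:
        box = ROI_BOXES_MM[label]
        size = sizes[label]
        rx, ry, rz = grid.box_index_ranges(box)
        ii, jj, kk = np.meshgrid(list(rx), list(ry), list(rz), indexing="ij")
        lin = np.ravel_multi_index((ii.ravel(), jj.ravel(), kk.ravel()), grid.shape)
        if size > lin.size:
            raise ValueError(
                f"{label}: requested {size} voxels but its box holds only {lin.size} "
                f"on this grid"
            )
        candidates = set(int(v) for v in lin) - taken
        if size > len(candidates):
            raise ValueError(
                f"{label}: requested {size} voxels but only {len(candidates)} remain "
                f"after earlier masks"
            )
        region = _grow_region(candidates, size, grid, label_rngs[label])
        if region is None:
            raise ValueError(f"{label}: could not grow a connected {size}-voxel region")
        taken.update(int(v) for v in region)
        masks[label] = RoiMask(
            label=label, grid=grid, indices=region, box_mm=box, target_size=size
        )
    return {label: masks[label] for label in ROI_LABELS}


def mask_volume(volume: np.ndarray, mask: RoiMask) -> np.ndarray:
    """Values of a 3-D volume at the mask's voxels, in canonical voxel order."""
    volume = np.asarray(volume)
    if volume.shape != mask.grid.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match grid {mask.grid.shape}"
        )
    return volume.reshape(-1)[mask.indices]


def atlas_to_nifti(masks: dict[str, RoiMask], path: str | Path) -> None:
    """Write the atlas as an integer-labelled NIfTI (1-based, canonical order)."""
    grid = next(iter(masks.values())).grid
    vol = np.zeros(grid.shape, dtype=np.int16)
    for i, label in enumerate(ROI_LABELS, start=1):
        if label in masks:
            vol.reshape(-1)[masks[label].indices] = i
    img = nib.Nifti1Image(vol, grid.affine())
    nib.save(img, str(path))


def atlas_from_nifti(path: str | Path, grid: GridSpec | None = None) -> dict[str, RoiMask]:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj).astype(int)
    if grid is None:
        aff = img.affine
        grid = GridSpec(
            voxel_size_mm=tuple(float(aff[i, i]) for i in range(3)),
            origin_mm=tuple(float(aff[i, 3]) for i in range(3)),
            shape=tuple(int(s) for s in vol.shape),
        )
    masks = {}
    for i, label in enumerate(ROI_LABELS, start=1):
        idx = np.flatnonzero(vol.reshape(-1) == i)
        if idx.size:
            masks[label] = RoiMask(
                label=label,
                grid=grid,
                indices=idx.astype(np.int64),
                box_mm=ROI_BOXES_MM[label],
                target_size=int(idx.size),
            )
    return masks


def atlas_to_tsv(masks: dict[str, RoiMask], path: str | Path) -> None:
    rows = []
    for label in ROI_LABELS:
        if label not in masks:
            continue
        m = masks[label]
        for (i, j, k), lin in zip(m.ijk(), m.indices):
            rows.append({"roi": label, "i": i, "j": j, "k": k, "linear_index": int(lin)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
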