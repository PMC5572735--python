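"""4D (re)modeling quantification between registered day-0 and day-15 masks.

Steps 4–5 of the dynamic algorithm: voxels present at both time points are
quiescent, gained voxels are newly formed, lost voxels are resorbed; volumes
and surfaces are normalized to the day-0 bone (MV/BV, EV/BV, MS/BS, ES/BS,
combining periosteal and endocortical envelopes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .core import BoneMask

logger = logging.getLogger(__name__)

BACKGROUND, QUIESCENT, FORMED, RESORBED = 0, 1, 2, 3
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class RemodelingLabelMap:
    """Voxel labels {0 background, 1 quiescent, 2 formed, 3 resorbed}."""

    grid: np.ndarray
    spacing: float
    min_cluster_applied: int = 1

    def mask_day0(self) -> np.ndarray:
        return (self.grid == QUIESCENT) | (self.grid == RESORBED)

    def mask_day15(self) -> np.ndarray:
        return (self.grid == QUIESCENT) | (self.grid == FORMED)

    def counts(self) -> dict:
        return {name: int(np.sum(self.grid == code)) for name, code in
                (("quiescent", QUIESCENT), ("formed", FORMED), ("resorbed", RESORBED))}


def _remove_small_clusters(region: np.ndarray, min_cluster: int) -> Tuple[np.ndarray, int]:
    """Drop 26-connected clusters smaller than min_cluster; return kept mask
    and the number of voxels removed."""
    if min_cluster <= 1 or not region.any():
        return region, 0
    labels, n = ndimage.label(region, structure=_STRUCT_26)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts[1:] < min_cluster) + 1
    if len(small) == 0:
        return region, 0
    kept = region & ~np.isin(labels, small)
    removed = int(region.sum() - kept.sum())
    return kept, removed


def label_remodeling(mask0: BoneMask, mask15: BoneMask, min_cluster: int = 2) -> RemodelingLabelMap:
    """Set-difference labeling of a registered mask pair.

    Formed/resorbed clusters smaller than ``min_cluster`` voxels
    (26-connectivity) are treated as interpolation speckle and reassigned:
    formed → background, resorbed → quiescent (the bone was and stays there).
    """
    if mask0.grid.shape != mask15.grid.shape:
        raise ValueError(f"grid mismatch: {mask0.grid.shape} vs {mask15.grid.shape}")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    m0, m15 = mask0.grid, mask15.grid
    formed = m15 & ~m0
    resorbed = m0 & ~m15

    formed, rm_f = _remove_small_clusters(formed, min_cluster)
    resorbed, rm_r = _remove_small_clusters(resorbed, min_cluster)
    if rm_f or rm_r:
        logger.info("label_remodeling: removed %d formed and %d resorbed speckle "
                    "voxel(s) below min_cluster=%d", rm_f, rm_r, min_cluster)

    grid = np.zeros(m0.shape, dtype=np.uint8)
    grid[m0 & m15] = QUIESCENT
    grid[formed] = FORMED
    grid[resorbed] = RESORBED
    # resorbed speckle reassigned to quiescent: bone present at day 0, loss discounted
    grid[(m0 & ~m15) & ~resorbed] = QUIESCENT
    return RemodelingLabelMap(grid=grid, spacing=mask0.spacing,
                              min_cluster_applied=min_cluster)


def quantify_volumes(labels: RemodelingLabelMap) -> Tuple[float, float, float]:
    """(MV/BV, EV/BV, BV_day0 [mm³]): formed and resorbed volume fractions
    normalized to the day-0 bone volume."""
    c = labels.counts()
    n0 = c["quiescent"] + c["resorbed"]
    if n0 == 0:
        raise ValueError("empty day-0 mask")
    voxel_mm3 = (labels.spacing / 1000.0) ** 3
    return c["formed"] / n0, c["resorbed"] / n0, n0 * voxel_mm3


def quantify_surfaces(labels: RemodelingLabelMap) -> Tuple[float, float, float]:
    """(MS/BS, ES/BS, BS_day0 [mm²]) by 6-connectivity face counting.

    BS_day0: day-0 bone faces exposed to non-bone (both envelopes).  A face is
    mineralizing if its adjacent exterior voxel became formed; eroded if its
    bone voxel was resorbed.  Axial faces on the first/last slice are VOI crop
    artifacts and are excluded.
    """
    grid = labels.grid
    m0 = labels.mask_day0()
    if not m0.any():
        raise ValueError("empty day-0 surface")
    formed = grid == FORMED
    resorbed = grid == RESORBED

    bs = ms = es = 0
    for axis in range(3):
        for direction in (1, -1):
            neigh_bone = _shift(m0, axis, direction)
            neigh_formed = _shift(formed, axis, direction)
            exposed = m0 & ~neigh_bone
            if axis == 2:  # axial end faces are VOI crop artifacts
                exposed &= ~_edge_face(m0, axis, direction)
            bs += int(exposed.sum())
            ms += int((exposed & neigh_formed).sum())
            es += int((exposed & resorbed).sum())
    if bs == 0:
        raise ValueError("empty day-0 surface")
    face_mm2 = (labels.spacing / 1000.0) ** 2
    return ms / bs, es / bs, bs * face_mm2


def _shift(m: np.ndarray, axis: int, direction: int) -> np.ndarray:
    """Neighbour occupancy of each voxel in +/- axis direction (False outside)."""
    out = np.zeros_like(m)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if direction > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(0, -1)
    else:
        src[axis] = slice(0, -1)
        dst[axis] = slice(1, None)
    out[tuple(dst)] = m[tuple(src)]
    return out


def _edge_face(m: np.ndarray, axis: int, direction: int) -> np.ndarray:
    """Voxels whose face in the given direction lies on the volume boundary."""
    out = np.zeros_like(m)
    idx = [slice(None)] * 3
    idx[axis] = -1 if direction > 0 else 0
    out[tuple(idx)] = m[tuple(idx)]
    return out
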