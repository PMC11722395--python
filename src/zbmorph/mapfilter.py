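"""From voxelwise p-maps to a validated affected-region mask.

Pipeline order is fixed: p-threshold → small-cluster removal → bilateral
symmetry filter (optionally a second cluster pass).  Each filter is
idempotent.  The mirror plane is the grid's mid-sagittal plane along the
stated midline axis, with index reflection x → (nx − 1 − x); the atlas is
assumed midline-aligned.  The workflow keeps uncorrected p ≤ 0.01 voxels
and relies on the cluster and symmetry filters — not on voxelwise
multiplicity correction — to suppress noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RegionMask",
    "threshold_pmap",
    "remove_small_clusters",
    "bilateral_filter",
    "make_mask",
    "mask_from_pmap",
]


@dataclass
class RegionMask:
    """Boolean mask on the atlas grid with filter provenance."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def threshold_pmap(pmap: np.ndarray, alpha: float) -> np.ndarray:
    """Keep voxels with p ≤ alpha; NaN (non-brain) voxels are excluded."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(pmap, dtype=float)
    with np.errstate(invalid="ignore"):
        return (p <= alpha) & np.isfinite(p)


_STRUCTS = {6: 1, 18: 2, 26: 3}


def remove_small_clusters(binary: np.ndarray, min_size: int,
                          connectivity: int = 26) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` voxels.

    ``connectivity`` is the 3-D neighbourhood: 6 (faces), 18 (+edges) or
    26 (+corners).
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    binary = np.asarray(binary, dtype=bool)
    struct = ndimage.generate_binary_structure(3, _STRUCTS[connectivity])
    lab, n = ndimage.label(binary, structure=struct)
    if n == 0:
        return binary.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[lab]


def bilateral_filter(binary: np.ndarray, midline_axis: int = 0,
                     tolerance_radius: int = 2) -> np.ndarray:
    """Keep a voxel iff some set voxel lies within ``tolerance_radius``
    (Chebyshev distance) of its mirror position about the mid-plane."""
    binary = np.asarray(binary, dtype=bool)
    if not (0 <= midline_axis < binary.ndim):
        raise ValueError(f"midline_axis {midline_axis} out of range for "
                         f"{binary.ndim}-D map")
    if tolerance_radius < 0:
        raise ValueError("tolerance_radius must be >= 0")
    mirrored = np.flip(binary, axis=midline_axis)
    if tolerance_radius > 0:
        size = [2 * tolerance_radius + 1] * binary.ndim
        mirrored = ndimage.binary_dilation(mirrored, structure=np.ones(size, bool))
    return binary & mirrored


def make_mask(binary: np.ndarray, spacing=(1.0, 1.0, 1.0),
              provenance: dict | None = None) -> RegionMask:
    """Wrap surviving voxels as a RegionMask; empty masks are an error
    (advising a review of the threshold and filter settings)."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError(
            "no voxels survive the filters; review alpha, min_cluster and "
            "symmetry tolerance"
        )
    return RegionMask(binary, tuple(spacing), provenance=dict(provenance or {}))


def mask_from_pmap(pmap: np.ndarray, spacing, alpha: float = 0.01,
                   min_cluster: int = 50, connectivity: int = 26,
                   midline_axis: int = 0, sym_tol: int = 2,
                   recluster: bool = False,
                   allow_empty: bool = False) -> RegionMask:
    """Full filter chain: threshold → cluster filter → symmetry filter
    (→ optional second cluster pass), with provenance recorded.

    With ``allow_empty`` an empty surviving set returns an empty
    RegionMask (a negative finding) instead of raising.
    """
    b = threshold_pmap(pmap, alpha)
    b = remove_small_clusters(b, min_cluster, connectivity)
    b = bilateral_filter(b, midline_axis, sym_tol)
    if recluster:
        b = remove_small_clusters(b, min_cluster, connectivity)
    if allow_empty and not b.any():
        return RegionMask(b, tuple(spacing),
                          provenance=dict(alpha=alpha, min_cluster=min_cluster,
                                          connectivity=connectivity,
                                          midline_axis=midline_axis,
                                          sym_tol=sym_tol, recluster=recluster,
                                          empty=True))
    return make_mask(
        b, spacing,
        provenance=dict(alpha=alpha, min_cluster=min_cluster,
                        connectivity=connectivity, midline_axis=midline_axis,
                        sym_tol=sym_tol, recluster=recluster),
    )
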