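"""Lesion-aware gray-matter group analysis mask.

The voxel-level analysis mask is built in three steps from per-participant
tissue probability maps (gray matter, white matter, cerebrospinal fluid),
per-patient lesion masks, and per-scan fMRI coverage masks, all on a common
grid:

1. every voxel is assigned to the tissue class with the maximal
   across-participant mean probability and the GM voxels are kept;
2. every voxel lesioned in at least one patient is removed, together with its
   six face-adjacent neighbors (Euclidean distance of exactly one voxel in
   index space) to guard against partial-volume contamination;
3. only voxels covered by every fMRI scan of every participant are retained.

Ties in step 1 are broken GM > WM > CSF (the analysis targets GM).  The
neighborhood in step 2 is 6-connected in voxel-index units; diagonal
neighbors (distance sqrt(2), sqrt(3)) are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Tissue label codes for the argmax map, in tie-break priority order.
TISSUE_ORDER: tuple[str, ...] = ("gm", "wm", "csf")
GM, WM, CSF = range(3)


class GridAlignmentError(ValueError):
    """Raised when voxel maps do not share a grid."""


@dataclass
class TissueProbabilityStack:
    """Per-participant tissue probability maps on a shared grid.

    ``gm``, ``wm`` and ``csf`` are arrays of shape ``(n_participants, *grid)``
    with probabilities in [0, 1].  ``voxel_size_mm`` is informational only;
    all neighborhood operations act in index space.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise GridAlignmentError("tissue maps do not share a grid")
        if self.gm.ndim < 2:
            raise GridAlignmentError("expected (n_participants, *grid) arrays")
        for arr, name in ((self.gm, "gm"), (self.wm, "wm"), (self.csf, "csf")):
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise ValueError(f"{name} probabilities outside [0, 1]")

    @property
    def n_participants(self) -> int:
        return self.gm.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.gm.shape[1:]


@dataclass
class GroupMask:
    """Boolean analysis mask plus a provenance log of voxel counts."""

    mask: np.ndarray
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def tissue_argmax(stack: TissueProbabilityStack) -> np.ndarray:
    """Label each voxel with the tissue whose across-participant mean
    probability is maximal (0=GM, 1=WM, 2=CSF; ties favor earlier classes)."""
    if stack.n_participants < 1:
        raise ValueError("need at least one participant")
    means = np.stack(
        [stack.gm.mean(axis=0), stack.wm.mean(axis=0), stack.csf.mean(axis=0)]
    )
    # np.argmax returns the first maximum, which encodes GM > WM > CSF.
    return np.argmax(means, axis=0)


def _check_grids(grid_shape, *masks: np.ndarray) -> None:
    for m in masks:
        if m.shape != tuple(grid_shape):
            raise GridAlignmentError(
                f"mask grid {m.shape} does not match {tuple(grid_shape)}"
            )


def lesion_exclusion(
    gm_voxels: np.ndarray, lesion_masks: np.ndarray | list[np.ndarray]
) -> np.ndarray:
    """Remove voxels lesioned in at least one patient plus their six
    face-adjacent neighbors.

    Out-of-bounds neighbors at grid edges are ignored.  The operation is
    idempotent for a fixed lesion set.
    """
    gm_voxels = np.asarray(gm_voxels, dtype=bool)
    lesions = np.asarray(lesion_masks, dtype=bool)
    if lesions.ndim == gm_voxels.ndim:
        lesions = lesions[None]
    _check_grids(gm_voxels.shape, *lesions)
    union = lesions.any(axis=0)
    structure = ndimage.generate_binary_structure(gm_voxels.ndim, 1)
    excluded = ndimage.binary_dilation(union, structure=structure)
    return gm_voxels & ~excluded


def coverage_intersection(
    voxels: np.ndarray, coverage_masks: np.ndarray | list[np.ndarray]
) -> np.ndarray:
    """Retain only voxels covered by every fMRI scan of every participant."""
    voxels = np.asarray(voxels, dtype=bool)
    coverage = np.asarray(coverage_masks, dtype=bool)
    if coverage.ndim == voxels.ndim:
        coverage = coverage[None]
    _check_grids(voxels.shape, *coverage)
    out = voxels & coverage.all(axis=0)
    if not out.any():
        logger.warning("coverage intersection produced an empty mask")
    return out


def build_group_mask(
    stack: TissueProbabilityStack,
    lesion_masks: np.ndarray | list[np.ndarray],
    coverage_masks: np.ndarray | list[np.ndarray],
) -> GroupMask:
    """Run the full three-step mask construction and log per-step counts."""
    labels = tissue_argmax(stack)
    gm = labels == GM
    prov = {"gm_argmax": int(gm.sum())}
    after_lesion = lesion_exclusion(gm, lesion_masks)
    prov["removed_by_lesions"] = int(gm.sum() - after_lesion.sum())
    final = coverage_intersection(after_lesion, coverage_masks)
    prov["removed_by_coverage"] = int(after_lesion.sum() - final.sum())
    prov["final"] = int(final.sum())
    logger.info("group mask: %s", prov)
    return GroupMask(mask=final, provenance=prov)


# ---------------------------------------------------------------------------
# NIfTI I/O (masks are exchanged 0-based with the affine preserved)
# ---------------------------------------------------------------------------

def load_mask_nifti(path):
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5, img.affine


def save_mask_nifti(mask: np.ndarray, affine: np.ndarray, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    nib.save(img, str(path))
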