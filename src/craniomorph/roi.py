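"""Brain-mask-guided anterior ROI standardization.

Open-source head MRI datasets are defaced with different tools, each
removing a different amount of face, scalp and forehead; extracranial
tissue measurements are therefore not comparable across datasets unless the
measurement region is standardized first.  This module implements the
brain-mask-based crop that does so: for every axial slice the most anterior
brain voxel defines a cut position, the cut is propagated superiorly so it
never moves posteriorly again, and everything anterior to the propagated
boundary is zeroed.  Any defacing that removed only voxels anterior to this
boundary yields an identical standardized ROI.

Conventions (see :mod:`craniomorph.io`): axis 0 (``x``) increases toward
anterior, axis 2 (``z``) toward superior; slices are indexed from 0
(inferior) and the voxel *at* the boundary is kept (only ``x > T*(z)`` is
removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import BinaryMask, GeometryError, HeadVolume, LabelMask


@dataclass
class CutBoundary:
    """Per-slice anterior cut positions.

    ``top[z]`` is the most anterior voxel index containing brain in slice
    ``z`` (0 for slices without brain); ``adjusted[z]`` is the running
    maximum of ``top`` from the most inferior slice upward, i.e. the cut
    actually applied.
    """

    top: np.ndarray
    adjusted: np.ndarray | None = None

    def __post_init__(self):
        self.top = np.asarray(self.top, dtype=np.int64)
        if self.adjusted is not None:
            self.adjusted = np.asarray(self.adjusted, dtype=np.int64)

    @property
    def n_slices(self) -> int:
        return len(self.top)

    def to_frame(self) -> pd.DataFrame:
        """Audit table (z, top, adjusted) for CSV export."""
        return pd.DataFrame(
            {
                "z": np.arange(self.n_slices),
                "top": self.top,
                "adjusted": self.adjusted
                if self.adjusted is not None
                else np.full(self.n_slices, -1),
            }
        )


def top_points(brain: BinaryMask) -> CutBoundary:
    """Most anterior brain voxel per axial slice.

    ``top[z] = max{x : any y with brain(x, y, z) = 1}``, and 0 where the
    slice contains no brain tissue.  An entirely empty mask is legal but
    almost certainly an upstream failure, so it warns.
    """
    data = brain.data
    any_xy = data.any(axis=1)  # (x, z): does slice z contain brain at x
    has_brain = any_xy.any(axis=0)  # per slice
    if not has_brain.any():
        warnings.warn("brain mask is empty; cut boundary is all zero",
                      stacklevel=2)
    H = data.shape[0]
    # most anterior x with brain, per slice; 0 where empty
    top = np.where(
        has_brain, (H - 1) - np.argmax(any_xy[::-1, :], axis=0), 0
    ).astype(np.int64)
    return CutBoundary(top=top)


def propagate_boundary(boundary: CutBoundary) -> CutBoundary:
    """Fill ``adjusted`` with the running maximum of ``top``.

    ``adjusted[z] = max(top[z], adjusted[z-1])`` with ``adjusted[-1] = 0``,
    so the cut plane never moves posteriorly while ascending the head.
    """
    adjusted = np.maximum.accumulate(boundary.top)
    return CutBoundary(top=boundary.top.copy(), adjusted=adjusted)


def _require_adjusted(boundary: CutBoundary) -> np.ndarray:
    if boundary.adjusted is None:
        raise ValueError("boundary has no adjusted positions; "
                         "run propagate_boundary first")
    return boundary.adjusted


def _crop_array(data: np.ndarray, adjusted: np.ndarray) -> np.ndarray:
    if data.shape[2] != len(adjusted):
        raise GeometryError(
            f"boundary has {len(adjusted)} slices but volume has "
            f"{data.shape[2]}"
        )
    x = np.arange(data.shape[0])
    remove = x[:, None, None] > adjusted[None, None, :]  # (x, 1, z)
    return np.where(remove, np.zeros((), dtype=data.dtype), data)


def crop_mask(mask: BinaryMask | LabelMask, boundary: CutBoundary):
    """Zero all voxels anterior to the adjusted boundary (``x > T*(z)``)."""
    adjusted = _require_adjusted(boundary)
    return replace(mask, data=_crop_array(mask.data, adjusted))


def crop_volume(vol: HeadVolume, boundary: CutBoundary) -> HeadVolume:
    """Apply the anterior crop to an intensity volume (defaced image)."""
    adjusted = _require_adjusted(boundary)
    return replace(vol, data=_crop_array(vol.data, adjusted))


def standardize_roi(
    labels: LabelMask,
    brain: BinaryMask,
    vol: HeadVolume | None = None,
    only_brain_slices: bool = False,
):
    """Full crop pipeline: top points -> propagation -> crop.

    Returns ``(cropped_labels, cropped_volume_or_None, boundary)``.  Brain
    voxels are never removed: each sits at ``x <= top[z] <= adjusted[z]``.

    With ``only_brain_slices`` the output is additionally restricted to the
    axial slab of slices that intersect the brain mask, which excludes the
    neck/inferior slab where an empty brain slice forces the cut to ``x=0``.
    """
    if labels.shape != brain.shape:
        raise GeometryError(
            f"labels {labels.shape} and brain mask {brain.shape} differ"
        )
    boundary = propagate_boundary(top_points(brain))
    out_labels = crop_mask(labels, boundary)
    out_vol = crop_volume(vol, boundary) if vol is not None else None
    if only_brain_slices:
        keep = brain.data.any(axis=(0, 1))
        out_labels.data[:, :, ~keep] = 0
        if out_vol is not None:
            out_vol.data[:, :, ~keep] = 0
    return out_labels, out_vol, boundary
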