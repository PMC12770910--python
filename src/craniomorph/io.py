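"""NIfTI I/O and the canonical voxel frame.

Every downstream operation in this package assumes one fixed axis
convention: axis 0 (``x``) increases posterior -> anterior, axis 1 (``y``)
left -> right, axis 2 (``z``) inferior -> superior — nibabel axis codes
``('A', 'R', 'S')``.  Volumes read from disk are reoriented into this frame
and the applied transform is recorded so a write can restore the on-disk
voxel layout exactly.

Label volumes use a small fixed vocabulary of head tissues: background,
brain, skull, subcutaneous fat and muscle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from nibabel.orientations import (
    apply_orientation,
    axcodes2ornt,
    inv_ornt_aff,
    io_orientation,
    ornt_transform,
)

CANONICAL_AXCODES = ("A", "R", "S")

#: default label vocabulary (value -> tissue name)
DEFAULT_LABEL_MAP: dict[int, str] = {
    0: "background",
    1: "brain",
    2: "skull",
    3: "subcutaneous_fat",
    4: "muscle",
}


class VolumeFormatError(ValueError):
    """File is not a readable 3-D NIfTI volume."""


class GeometryError(ValueError):
    """Spacing/shape/orientation contract violated."""


class LabelError(ValueError):
    """Label volume contains values outside the declared label map."""


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise GeometryError(f"spacing must be 3 positive floats, got {spacing}")
    return spacing


@dataclass
class HeadVolume:
    """A 3-D scalar head image (arbitrary intensity units, or HU for CT).

    ``data`` is stored in the canonical frame.  ``ornt`` is the nibabel
    orientation transform that was applied at read time (``None`` for
    volumes created in memory); :func:`write_volume` inverts it so a
    read/write round trip reproduces the original file's voxel layout.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    ornt: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D volume, got {self.data.ndim}-D"
            )
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class LabelMask:
    """Integer tissue-label volume over the head-tissue vocabulary."""

    data: np.ndarray
    label_map: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP)
    )
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    ornt: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D label volume, got {self.data.ndim}-D"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.floating) and np.all(
                self.data == np.round(self.data)
            ):
                self.data = self.data.astype(np.int16)
            else:
                raise LabelError("label volume has non-integer voxel values")
        self.label_map = {int(k): str(v) for k, v in self.label_map.items()}
        observed = np.unique(self.data)
        unknown = sorted(int(v) for v in observed if int(v) not in self.label_map)
        if unknown:
            raise LabelError(
                f"unexpected label value(s) {unknown}; known labels: "
                f"{sorted(self.label_map)}"
            )
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def value_of(self, cls: str) -> int:
        for value, name in self.label_map.items():
            if name == cls:
                return value
        raise LabelError(
            f"unknown class {cls!r}; known classes: "
            f"{sorted(self.label_map.values())}"
        )

    def class_names(self, include_background: bool = False) -> list[str]:
        names = [
            name
            for value, name in sorted(self.label_map.items())
            if include_background or value != 0
        ]
        return names


@dataclass
class BinaryMask:
    """A {0,1} voxel mask in the canonical frame."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D mask, got {self.data.ndim}-D"
            )
        values = np.unique(self.data)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binary mask must contain only 0 and 1")
        self.data = self.data.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _load_canonical(path) -> tuple[np.ndarray, tuple, np.ndarray, np.ndarray]:
    """Load a NIfTI file and reorient to the canonical ('A','R','S') frame.

    Returns (data, spacing, canonical_affine, ornt_transform_applied).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path} is {data.ndim}-D; this toolkit handles 3-D volumes only"
        )
    ornt = ornt_transform(
        io_orientation(img.affine), axcodes2ornt(CANONICAL_AXCODES)
    )
    data = apply_orientation(data, ornt)
    affine = img.affine @ inv_ornt_aff(ornt, data.shape)
    # spacing from the canonical affine (header zooms are in file axis order)
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    return data, spacing, affine, ornt


def read_volume(path) -> HeadVolume:
    """Read a NIfTI scalar volume and reorient it to the canonical frame."""
    data, spacing, affine, ornt = _load_canonical(path)
    return HeadVolume(
        data=data.astype(np.float32)
        if not np.issubdtype(data.dtype, np.floating)
        else data,
        spacing=spacing,
        affine=affine,
        ornt=ornt,
    )


def read_labels(path, label_map: Mapping[int, str] | None = None) -> LabelMask:
    """Read a NIfTI label volume; every observed value must be in ``label_map``."""
    data, spacing, affine, ornt = _load_canonical(path)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise LabelError(f"{path} contains non-integer voxel values")
        data = data.astype(np.int16)
    return LabelMask(
        data=data,
        label_map=label_map if label_map is not None else dict(DEFAULT_LABEL_MAP),
        spacing=spacing,
        affine=affine,
        ornt=ornt,
    )


def read_mask(path) -> BinaryMask:
    """Read a NIfTI binary (0/1) mask."""
    data, spacing, affine, _ = _load_canonical(path)
    return BinaryMask(data=data, spacing=spacing, affine=affine)


def write_volume(vol: HeadVolume | LabelMask | BinaryMask, path,
                 restore_orientation: bool = True) -> None:
    """Write a volume/mask to NIfTI.

    If the object was read from disk and ``restore_orientation`` is true, the
    recorded reorientation is inverted so the written file has the original
    voxel layout; otherwise it is written in the canonical frame.
    """
    data = vol.data
    affine = vol.affine
    ornt = getattr(vol, "ornt", None)
    if restore_orientation and ornt is not None:
        inv = _invert_ornt(ornt)
        data = apply_orientation(data, inv)
        affine = affine @ inv_ornt_aff(inv, data.shape)
    if isinstance(vol, (LabelMask, BinaryMask)):
        data = np.asarray(data, dtype=np.int16)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(
        tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    )
    nib.save(img, str(path))


def _invert_ornt(ornt: np.ndarray) -> np.ndarray:
    """Invert a nibabel orientation transform."""
    ornt = np.asarray(ornt)
    inv = np.empty_like(ornt)
    for out_axis, (in_axis, flip) in enumerate(ornt):
        inv[int(in_axis)] = (out_axis, flip)
    return inv


def canonicalize(vol: HeadVolume) -> HeadVolume:
    """Idempotent: volumes in this package are always canonical already."""
    return vol


# ---------------------------------------------------------------------------
# label utilities
# ---------------------------------------------------------------------------

def binarize(labels: LabelMask, cls: str) -> BinaryMask:
    """Binary mask of one tissue class (1 exactly where ``labels == cls``)."""
    value = labels.value_of(cls)
    return BinaryMask(
        data=(labels.data == value).astype(np.uint8),
        spacing=labels.spacing,
        affine=labels.affine,
    )


def foreground_mask(labels: LabelMask) -> BinaryMask:
    """Union of all non-background classes."""
    return BinaryMask(
        data=(labels.data != 0).astype(np.uint8),
        spacing=labels.spacing,
        affine=labels.affine,
    )


def load_label_map(path) -> dict[int, str]:
    """Read a ``{value: name}`` label map from a JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def check_isotropic_inplane(spacing, lo: float = 0.9, hi: float = 1.1) -> None:
    """Reject in-plane spacing outside [lo, hi] mm.

    The thickness pipeline's constants (measurement band extent, ray step)
    assume ~1 mm voxels after resampling; running it on coarser grids would
    silently mis-scale millimetre outputs.
    """
    sx, sy, _ = spacing
    if not (lo <= sx <= hi and lo <= sy <= hi):
        raise GeometryError(
            f"in-plane spacing ({sx:.3f}, {sy:.3f}) mm outside [{lo}, {hi}] mm; "
            "resample to ~1 mm isotropic before thickness estimation"
        )
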