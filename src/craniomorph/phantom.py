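"""Digital head phantoms and the perturbation harness.

The phantoms are *geometric*, not anatomical: nested ellipsoidal
compartments (brain, a CSF gap, a skull shell of known wall thickness, a
subcutaneous-fat layer), two lateral ellipsoidal muscle patches abutting
the skull (temporalis-like), and a nose-like "face" protrusion anterior to
the skull so that defacing and anterior ROI cropping have something to
remove.  Every compartment has a closed-form volume, so segmentation,
volumetric and thickness code can be validated against analytic truth
without any imaging data.

Alongside the generator, this module provides the perturbation harness
used for robustness checks: rigid head tilt (simulated registration
error), the standard intensity augmentations (gamma, brightness shift,
intensity rescaling), and simulated defacing in three styles whose removed
region is always strictly anterior to the brain's propagated cut boundary
— the regime in which ROI standardization must be exactly invariant.

All randomness (optional voxel noise) is driven by the spec's seed; the
same spec always produces bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import BinaryMask, DEFAULT_LABEL_MAP, HeadVolume, LabelMask
from .roi import propagate_boundary, top_points

DEFAULT_HU = {
    "background": -1000.0,
    "brain": 40.0,
    "skull": 1000.0,
    "subcutaneous_fat": -100.0,
    "muscle": 50.0,
}
# T1-weighted appearance: fat bright, cortical bone dark
DEFAULT_T1 = {
    "background": 0.0,
    "brain": 0.5,
    "skull": 0.08,
    "subcutaneous_fat": 0.9,
    "muscle": 0.4,
}


class PhantomSpecError(ValueError):
    """Phantom geometry is inconsistent (overlap, too-thin wall, overflow)."""


@dataclass
class PhantomSpec:
    """Geometry and appearance of one digital head phantom.

    All lengths in mm.  ``brain_semiaxes_mm`` are the (anterior-posterior,
    lateral, superior-inferior) semi-axes; the skull's inner surface sits
    ``csf_gap_mm`` outside the brain and its outer surface ``skull_wall_mm``
    further out, so the nominal wall thickness is ``skull_wall_mm``.
    ``cancellous_hu`` (optional) gives the inner half of the wall a second,
    lower CT density — a two-density skull for HU-threshold sweeps.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semiaxes_mm: tuple[float, float, float] = (55.0, 60.0, 50.0)
    csf_gap_mm: float = 2.0
    skull_wall_mm: float = 5.0
    fat_thickness_mm: float = 4.0
    muscle_semiaxes_mm: tuple[float, float, float] | None = (22.0, 14.0, 20.0)
    face_extent_mm: float = 12.0
    hu_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU))
    cancellous_hu: float | None = None
    t1_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_T1))
    t1_noise_sd: float = 0.0
    ct_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        sx, sy, sz = self.spacing
        min_sp = min(sx, sy, sz)
        if self.skull_wall_mm < 2.0 * min_sp:
            raise PhantomSpecError(
                f"skull wall {self.skull_wall_mm} mm is thinner than 2 voxels "
                f"({2 * min_sp} mm)"
            )
        if self.csf_gap_mm < 0 or self.fat_thickness_mm < 0:
            raise PhantomSpecError("negative layer thickness")
        a, b, c = self.brain_semiaxes_mm
        margin = self.csf_gap_mm + self.skull_wall_mm + self.fat_thickness_mm
        extents = (
            a + margin + self.face_extent_mm + 2.0,
            b + margin + 2.0,
            c + margin + 2.0,
        )
        half = (
            self.shape[0] * sx / 2.0,
            self.shape[1] * sy / 2.0,
            self.shape[2] * sz / 2.0,
        )
        for e, h, axis in zip(extents, half, "xyz"):
            if e > h:
                raise PhantomSpecError(
                    f"phantom extent {e:.1f} mm exceeds half-grid {h:.1f} mm "
                    f"along {axis}; compartments would overlap the border"
                )


def _ellipsoid_sq(coords, center_mm, semiaxes_mm):
    """Squared normalized ellipsoid coordinate (<=1 means inside)."""
    x, y, z = coords
    a, b, c = semiaxes_mm
    return (
        ((x - center_mm[0]) / a) ** 2
        + ((y - center_mm[1]) / b) ** 2
        + ((z - center_mm[2]) / c) ** 2
    )


def _ellipsoid_volume_mm3(semiaxes) -> float:
    a, b, c = semiaxes
    return 4.0 / 3.0 * np.pi * a * b * c


def make_phantom(spec: PhantomSpec):
    """Generate one phantom: labels, T1-like and CT-like volumes, truth.

    Returns ``(LabelMask, HeadVolume t1, HeadVolume ct, truth)`` where
    ``truth`` records the analytic compartment volumes (exact for brain and
    skull; fat/muscle/face interact so their truth is voxel-derived), the
    nominal wall thickness and the generating spec.
    """
    spec.validate()
    sx, sy, sz = spec.spacing
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(spec.seed)
    center = (nx * sx / 2.0, ny * sy / 2.0, nz * sz / 2.0)
    coords = np.meshgrid(
        np.arange(nx) * sx,
        np.arange(ny) * sy,
        np.arange(nz) * sz,
        indexing="ij",
        sparse=True,
    )

    a, b, c = spec.brain_semiaxes_mm
    g, w, f = spec.csf_gap_mm, spec.skull_wall_mm, spec.fat_thickness_mm
    inner = (a + g, b + g, c + g)
    outer = (a + g + w, b + g + w, c + g + w)
    fat_outer = (a + g + w + f, b + g + w + f, c + g + w + f)

    rho_brain = _ellipsoid_sq(coords, center, spec.brain_semiaxes_mm)
    rho_inner = _ellipsoid_sq(coords, center, inner)
    rho_outer = _ellipsoid_sq(coords, center, outer)

    brain = rho_brain <= 1.0
    skull = (rho_outer <= 1.0) & (rho_inner > 1.0)
    regions: dict[str, np.ndarray] = {"brain": brain, "skull": skull}

    if f > 0:
        rho_fat = _ellipsoid_sq(coords, center, fat_outer)
        regions["subcutaneous_fat"] = (rho_fat <= 1.0) & (rho_outer > 1.0)

    if spec.muscle_semiaxes_mm is not None:
        lateral = outer[1]  # muscle patch centres sit on the lateral skull
        muscle = np.zeros(spec.shape, dtype=bool)
        for side in (-1.0, 1.0):
            m_center = (center[0], center[1] + side * lateral, center[2])
            muscle |= (
                _ellipsoid_sq(coords, m_center, spec.muscle_semiaxes_mm) <= 1.0
            )
        regions["muscle"] = muscle & (rho_outer > 1.0)

    if spec.face_extent_mm > 0:
        # nose-like protrusion anterior to the skull, below the vertex
        face_center = (
            center[0] + outer[0] + spec.face_extent_mm / 2.0 - 4.0,
            center[1],
            center[2] - 10.0,
        )
        face_semi = (spec.face_extent_mm / 2.0 + 4.0, 14.0, 16.0)
        face = (_ellipsoid_sq(coords, face_center, face_semi) <= 1.0) & (
            rho_outer > 1.0
        )
        regions["face"] = face

    # assemble with precedence brain > skull > muscle > fat; face is fat
    value_of = {name: v for v, name in DEFAULT_LABEL_MAP.items()}
    labels = np.zeros(spec.shape, dtype=np.int16)
    order = ["subcutaneous_fat", "face", "muscle", "skull", "brain"]
    for name in order:
        if name in regions:
            cls = "subcutaneous_fat" if name == "face" else name
            labels[regions[name]] = value_of[cls]

    label_mask = LabelMask(
        data=labels, label_map=dict(DEFAULT_LABEL_MAP), spacing=spec.spacing
    )

    # intensity volumes: piecewise-constant per class (+ optional seeded noise)
    t1 = np.zeros(spec.shape, dtype=np.float32)
    ct = np.full(spec.shape, spec.hu_values["background"], dtype=np.float32)
    for value, name in DEFAULT_LABEL_MAP.items():
        if value == 0:
            t1[labels == 0] = spec.t1_values["background"]
            continue
        t1[labels == value] = spec.t1_values[name]
        ct[labels == value] = spec.hu_values[name]
    if spec.cancellous_hu is not None:
        mid = tuple(i + w / 2.0 for i in inner)
        rho_mid = _ellipsoid_sq(coords, center, mid)
        ct[skull & (rho_mid <= 1.0)] = spec.cancellous_hu
    if spec.t1_noise_sd > 0:
        t1 = t1 + rng.normal(0.0, spec.t1_noise_sd, spec.shape).astype(
            np.float32
        )
    if spec.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd, spec.shape).astype(
            np.float32
        )

    truth = {
        "analytic_volumes_cm3": {
            "brain": _ellipsoid_volume_mm3(spec.brain_semiaxes_mm) / 1000.0,
            "skull": (
                _ellipsoid_volume_mm3(outer) - _ellipsoid_volume_mm3(inner)
            )
            / 1000.0,
        },
        "voxel_volumes_cm3": {
            name: float(
                np.count_nonzero(labels == value) * sx * sy * sz / 1000.0
            )
            for value, name in DEFAULT_LABEL_MAP.items()
            if value != 0
        },
        "wall_thickness_mm": w,
        "center_voxel": tuple(
            int(round(cm / s)) for cm, s in zip(center, spec.spacing)
        ),
        "spec": asdict(spec),
    }
    t1_vol = HeadVolume(data=t1, spacing=spec.spacing)
    ct_vol = HeadVolume(data=ct, spacing=spec.spacing)
    return label_mask, t1_vol, ct_vol, truth


def preset_spec(name: str, **overrides) -> PhantomSpec:
    """Named presets: ``sphere``, ``ellipsoid``, ``two-density``."""
    if name == "sphere":
        base = dict(brain_semiaxes_mm=(55.0, 55.0, 55.0))
    elif name == "ellipsoid":
        base = dict(brain_semiaxes_mm=(55.0, 60.0, 50.0))
    elif name == "two-density":
        base = dict(
            brain_semiaxes_mm=(55.0, 55.0, 55.0),
            cancellous_hu=450.0,
            skull_wall_mm=6.0,
            face_extent_mm=0.0,  # HU-sweep phantom needs no face
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return PhantomSpec(**base)


def shell_spec(wall_mm: float, semiaxes_mm=(40.0, 40.0, 38.0),
               shape=(120, 120, 120), **overrides) -> PhantomSpec:
    """Minimal brain+skull shell phantom for thickness validation.

    No fat, muscle or face; the skull is a clean shell of nominal wall
    ``wall_mm`` around the given brain semi-axes.
    """
    return PhantomSpec(
        shape=shape,
        brain_semiaxes_mm=semiaxes_mm,
        skull_wall_mm=wall_mm,
        fat_thickness_mm=0.0,
        muscle_semiaxes_mm=None,
        face_extent_mm=0.0,
        **overrides,
    )


# ---------------------------------------------------------------------------
# perturbation harness
# ---------------------------------------------------------------------------

def apply_tilt(obj, degrees: float = 5.0):
    """Rigid anterior/posterior pitch about the left-right axis.

    Rotates in the (x, z) plane on the same grid (no reshape): nearest
    neighbour for label/binary masks, linear for intensity volumes.
    Emulates a small residual registration error.
    """
    if abs(degrees) > 15:
        raise ValueError(f"tilt {degrees}° out of supported range ±15°")
    order = 0 if isinstance(obj, (LabelMask, BinaryMask)) else 1
    rotated = ndimage.rotate(
        obj.data,
        degrees,
        axes=(0, 2),
        reshape=False,
        order=order,
        mode="constant",
        cval=0,
        prefilter=order > 0,
    )
    if isinstance(obj, (LabelMask, BinaryMask)):
        rotated = np.rint(rotated).astype(obj.data.dtype)
    return replace(obj, data=rotated)


def normalize01(vol: HeadVolume) -> HeadVolume:
    """Min-max rescale of the intensities to [0, 1]."""
    data = vol.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return replace(vol, data=np.zeros_like(data))
    return replace(vol, data=(data - lo) / (hi - lo))


AUGMENTATION_KINDS = (
    "gamma_0.7",
    "gamma_1.5",
    "brightness_+0.2",
    "brightness_-0.2",
    "scale_0_1.2",
)


def apply_intensity_augmentation(vol: HeadVolume, kind: str) -> HeadVolume:
    """One of the standard robustness augmentations, applied voxelwise.

    ``gamma_G`` raises (non-negative, [0,1]-normalized) intensities to the
    power G; ``brightness_B`` adds the constant B (no clipping, so the ±B
    pair is an exact inverse); ``scale_LO_HI`` min-max rescales to
    [LO, HI].  Labels are never touched by intensity augmentation.
    """
    data = vol.data.astype(np.float32)
    if kind.startswith("gamma_"):
        g = float(kind[len("gamma_"):])
        if g <= 0:
            raise ValueError(f"gamma must be positive, got {g}")
        if data.min() < 0:
            raise ValueError("gamma augmentation needs non-negative "
                             "intensities; normalize to [0, 1] first")
        out = data ** g
    elif kind.startswith("brightness_"):
        shift = float(kind[len("brightness_"):])
        out = data + shift
    elif kind.startswith("scale_"):
        try:
            lo, hi = (float(p) for p in kind[len("scale_"):].split("_"))
        except ValueError as exc:
            raise ValueError(f"malformed scale kind {kind!r}") from exc
        dmin, dmax = float(data.min()), float(data.max())
        if dmax == dmin:
            out = np.full_like(data, lo)
        else:
            out = lo + (data - dmin) / (dmax - dmin) * (hi - lo)
    else:
        raise ValueError(
            f"unknown augmentation kind {kind!r}; expected one of "
            f"{AUGMENTATION_KINDS} or gamma_G / brightness_B / scale_LO_HI"
        )
    return replace(vol, data=out.astype(np.float32))


DEFACING_STYLES = ("plane", "wedge", "aggressive")


def simulate_defacing(
    obj,
    brain: BinaryMask,
    style: str = "wedge",
    margin_mm: float = 2.0,
):
    """Zero an anterior face region, as a defacing tool would.

    All styles remove only voxels strictly anterior to the brain's
    propagated cut boundary (plus ``margin_mm``), so brain tissue is never
    touched and ROI standardization of the defaced output must equal that
    of the intact input:

    - ``plane``: a single coronal plane at the global anterior extreme;
    - ``wedge``: a per-slice cut following the propagated boundary;
    - ``aggressive``: the maximal legal removal — everything strictly
      anterior to the propagated boundary itself (margin ignored).

    Returns ``(defaced_object, removed_region_mask)``.
    """
    if style not in DEFACING_STYLES:
        raise ValueError(f"unknown defacing style {style!r}")
    if margin_mm < 0:
        raise ValueError(
            f"margin {margin_mm} mm would cut into brain tissue; must be >= 0"
        )
    if obj.data.shape != brain.data.shape:
        raise ValueError("object and brain mask shapes differ")
    sx = obj.spacing[0]
    adjusted = propagate_boundary(top_points(brain)).adjusted
    m = int(round(margin_mm / sx))
    if style == "plane":
        cut = np.full_like(adjusted, adjusted.max() + m)
    elif style == "wedge":
        cut = adjusted + m
    else:  # aggressive
        cut = adjusted.copy()
    x = np.arange(obj.data.shape[0])
    removed = x[:, None, None] > cut[None, None, :]
    removed = np.broadcast_to(removed, obj.data.shape) & (obj.data != 0)
    out = obj.data.copy()
    out[removed] = 0
    return (
        replace(obj, data=out),
        BinaryMask(data=removed.astype(np.uint8), spacing=obj.spacing),
    )
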