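"""Tangent-normal skull-thickness estimation from a binary skull mask.

The estimator works on axial cross-sections of the skull, which are
ring-like: an outer contour facing the scalp and an inner contour facing
the cranial cavity.  On each slice in a measurement band it

1. extracts outer and inner contours of the skull ring,
2. places ``n_points`` (default 100) samples uniformly by arc length on the
   outer contour,
3. at each sample estimates the local contour tangent and casts a ray along
   the *inward normal* (perpendicular to the tangent) in sub-voxel steps,
4. records the chord length (mm) from the outer boundary to the first exit
   into the cranial cavity; rays that leave the slice, exceed a maximum
   length, or exit into a non-cavity pocket (frontal sinus and orbital air
   spaces behave this way) yield *missing* samples rather than spurious
   lengths.

The per-subject summary pools all valid samples across the band, trims to
the central 95% (2.5–97.5 percentiles, linear interpolation) and reports
the median of the kept values.  The measurement band starts a fixed offset
(default 10 mm) superior to a reference slice — anatomically, the top of
the orbital roof — and spans 16 mm of physical extent, which keeps the
band clear of the orbits and most of the frontal sinus.

A CT-based reference segmentation is provided by simple Hounsfield
thresholding (default HU > 471) with largest-connected-component cleanup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .io import BinaryMask, GeometryError, HeadVolume, check_isotropic_inplane

MAX_RAY_MM = 50.0  # no skull is this thick; bound for runaway rays
RAY_STEP_VOXEL = 0.25  # sub-voxel marching step along the normal
TANGENT_HALF_WINDOW = 2  # contour samples on each side for tangent estimate


class InsufficientDataError(ValueError):
    """Too few valid thickness samples to summarize."""


class SliceBandError(ValueError):
    """Measurement band does not fit inside the volume."""


@dataclass
class ThicknessSample:
    """One normal-chord measurement at an outer-contour point."""

    slice_index: int
    point: tuple[float, float]  # (x, y) voxel coordinates on the outer contour
    normal: tuple[float, float]  # inward unit normal (mm frame)
    thickness_mm: float | None  # None = missing (open ray / sinus pocket)


@dataclass
class ThicknessResult:
    """Pooled, trimmed thickness summary over the measurement band."""

    median_thickness_mm: float
    n_samples_total: int
    n_samples_kept: int
    per_slice_counts: dict[int, int]
    reference_slice: int
    slice_band: tuple[int, int]  # half-open [z_start, z_end)
    trim_pct: float = 95.0
    samples: list[ThicknessSample] = field(default_factory=list, repr=False)

    def samples_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "slice": s.slice_index,
                    "x": s.point[0],
                    "y": s.point[1],
                    "thickness_mm": s.thickness_mm,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CT reference segmentation
# ---------------------------------------------------------------------------

def ct_skull_mask(ct: HeadVolume, hu_threshold: float = 471.0) -> BinaryMask:
    """Bone mask from a CT volume by strict HU thresholding.

    Voxels with ``HU > hu_threshold`` are kept and the largest connected
    component retained (drops mandible fragments, table artifacts).  An
    empty result — the threshold exceeds every bone voxel — is returned
    with a warning rather than raised, mirroring how such scans are flagged
    and excluded rather than crashing a batch.
    """
    if hu_threshold < -1000:
        raise ValueError(
            f"HU threshold {hu_threshold} is below air (-1000 HU)"
        )
    bone = ct.data > hu_threshold
    if not bone.any():
        warnings.warn(
            f"no voxels above {hu_threshold} HU; skull mask is empty "
            "(no valid segmentation contour at this threshold)",
            stacklevel=2,
        )
        return BinaryMask(
            data=np.zeros(ct.shape, dtype=np.uint8),
            spacing=ct.spacing,
            affine=ct.affine,
        )
    labeled, n = ndimage.label(bone)
    if n > 1:
        sizes = ndimage.sum_labels(bone, labeled, index=np.arange(1, n + 1))
        bone = labeled == (1 + int(np.argmax(sizes)))
    return BinaryMask(
        data=bone.astype(np.uint8), spacing=ct.spacing, affine=ct.affine
    )


# ---------------------------------------------------------------------------
# measurement band
# ---------------------------------------------------------------------------

def select_slices(
    z0: int,
    spacing_z: float,
    n_slices_superior: int,
    offset_mm: float = 10.0,
    n_slices: int = 16,
) -> tuple[int, int]:
    """Half-open slice band starting ``offset_mm`` superior to ``z0``.

    ``n_slices`` is defined at 1 mm slice thickness; on other z spacings the
    band covers the same *physical* extent (``n_slices`` mm), with
    ``round(n_slices / spacing_z)`` slices.  ``n_slices_superior`` is the
    number of slices in the volume (band must fit).
    """
    if spacing_z <= 0:
        raise GeometryError(f"non-positive z spacing {spacing_z}")
    z_start = int(z0 + round(offset_mm / spacing_z))
    count = int(round(n_slices * 1.0 / spacing_z))
    z_end = z_start + count
    if z_start < 0 or z_end > n_slices_superior:
        fit = max(0, n_slices_superior - z_start)
        raise SliceBandError(
            f"measurement band [{z_start}, {z_end}) exceeds volume extent "
            f"(0, {n_slices_superior}); only {fit} of {count} slices fit"
        )
    return z_start, z_end


def find_reference_slice(skull: BinaryMask) -> int:
    """Crude fallback reference-slice heuristic (NOT an anatomical detector).

    Returns the most inferior slice whose skull cross-section forms a closed
    ring (has an enclosed cavity) spanning both lateral halves of the head.
    Intended only for phantoms and quick looks; real analyses should supply
    the orbital-roof slice explicitly.
    """
    _, W, D = skull.shape
    for z in range(D):
        sl = skull.data[:, :, z]
        if not sl.any():
            continue
        ys = np.nonzero(sl)[1]
        if ys.min() >= W // 2 or ys.max() < W // 2:
            continue
        try:
            slice_boundaries(sl)
        except DegenerateSliceError:
            continue
        return z
    raise ValueError("no closed-ring skull slice found")


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

class DegenerateSliceError(ValueError):
    """Slice has no ring-like skull cross-section (no enclosed cavity)."""


def _largest_component(mask2d: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask2d)
    if n == 0:
        raise DegenerateSliceError("empty slice")
    if n == 1:
        return mask2d.astype(bool)
    sizes = ndimage.sum_labels(mask2d, labeled, index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def _longest_closed_contour(mask2d: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask2d.astype(float), 0.5)
    closed = [c for c in contours if np.allclose(c[0], c[-1])]
    if not closed:
        raise DegenerateSliceError("no closed contour found")
    lengths = [
        np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)) for c in closed
    ]
    return closed[int(np.argmax(lengths))]


def slice_boundaries(
    skull_slice: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Outer and inner contours of a ring-like 2-D skull cross-section.

    Returns ``(outer_contour, inner_contour, component, cavity)`` where the
    contours are ordered (N, 2) sub-voxel point arrays in (x, y) voxel
    coordinates, ``component`` is the largest connected component and
    ``cavity`` its largest enclosed hole (the cranial cavity).

    Raises :class:`DegenerateSliceError` for solid blobs (no cavity); such
    slices are skipped by the band aggregator.
    """
    comp = _largest_component(np.asarray(skull_slice) > 0)
    filled = ndimage.binary_fill_holes(comp)
    holes = filled & ~comp
    if not holes.any():
        raise DegenerateSliceError("no enclosed cavity (solid cross-section)")
    hole_labels, n = ndimage.label(holes)
    sizes = ndimage.sum_labels(holes, hole_labels, index=np.arange(1, n + 1))
    cavity = hole_labels == (1 + int(np.argmax(sizes)))
    outer = _longest_closed_contour(filled)
    inner = _longest_closed_contour(cavity)
    return outer, inner, comp, cavity


def sample_points(contour: np.ndarray, n: int = 100) -> np.ndarray:
    """``n`` points uniformly spaced by arc length along a closed contour.

    The first sample sits at the most anterior contour vertex (largest x;
    ties broken by smallest y), so sampling is reproducible across slices
    and subjects.
    """
    contour = np.asarray(contour, dtype=float)
    if not np.allclose(contour[0], contour[-1]):
        raise ValueError("contour must be closed (first point == last point)")
    pts = contour[:-1]  # drop duplicated closing vertex
    if len(pts) < 3:
        raise ValueError("contour too short to resample")
    # rotate so the most anterior vertex comes first
    order = np.lexsort((pts[:, 1], -pts[:, 0]))
    start = order[0]
    pts = np.roll(pts, -start, axis=0)
    ring = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate zero-length contour")
    targets = np.arange(n) * total / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return ring[idx] + frac[:, None] * (ring[idx + 1] - ring[idx])


# ---------------------------------------------------------------------------
# normal-chord measurement
# ---------------------------------------------------------------------------

def _inward_normals(samples: np.ndarray, comp: np.ndarray,
                    spacing_xy: tuple[float, float]) -> np.ndarray:
    """Unit inward normals (mm frame) at uniformly spaced contour samples."""
    sx, sy = spacing_xy
    mm = samples * np.array([sx, sy])
    k = TANGENT_HALF_WINDOW
    tangent = np.roll(mm, -k, axis=0) - np.roll(mm, k, axis=0)
    norms = np.linalg.norm(tangent, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangent /= norms
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    # orient inward: the direction with more mask occupancy just inside
    H, W = comp.shape
    probe_ts = np.array([0.75, 1.25, 1.75])  # voxels
    step_mm = min(sx, sy)
    score = np.zeros(len(samples))
    for t in probe_ts:
        for sign in (1.0, -1.0):
            probe = mm + sign * t * step_mm * normal
            vx = np.rint(probe[:, 0] / sx).astype(int)
            vy = np.rint(probe[:, 1] / sy).astype(int)
            inside = (vx >= 0) & (vx < H) & (vy >= 0) & (vy < W)
            hit = np.zeros(len(samples), dtype=bool)
            hit[inside] = comp[vx[inside], vy[inside]]
            score += sign * hit
    flip = score < 0
    normal[flip] *= -1
    return normal


def tangent_thickness(
    point: np.ndarray,
    normal: np.ndarray,
    comp: np.ndarray,
    cavity: np.ndarray,
    spacing_xy: tuple[float, float],
    max_ray_mm: float = MAX_RAY_MM,
) -> float | None:
    """Normal-chord thickness at one outer-contour point, in mm.

    Marches from the contour point along the inward normal in sub-voxel
    steps.  The ray must enter the skull component within ~2 voxels (else
    it started over an air pocket → missing) and the thickness is the
    distance from the contour point to the midpoint of the mask→cavity
    crossing.  Exits into non-cavity background (sinus pockets, rays that
    skim out of the ring) and rays that leave the slice or exceed
    ``max_ray_mm`` are missing.
    """
    sx, sy = spacing_xy
    step = RAY_STEP_VOXEL * min(sx, sy)
    n_steps = int(max_ray_mm / step)
    ts = (np.arange(n_steps) + 1) * step
    pos = point * np.array([sx, sy]) + ts[:, None] * normal
    vx = np.rint(pos[:, 0] / sx).astype(int)
    vy = np.rint(pos[:, 1] / sy).astype(int)
    H, W = comp.shape
    inside = (vx >= 0) & (vx < H) & (vy >= 0) & (vy < W)
    first_out = int(np.argmin(inside)) if not inside.all() else n_steps
    vx, vy = vx[:first_out], vy[:first_out]
    in_mask = comp[vx, vy]
    if not in_mask.any():
        return None
    entry = int(np.argmax(in_mask))
    if ts[entry] > 2.0 * max(sx, sy):  # started over an air pocket
        return None
    after = in_mask[entry:]
    if after.all():
        return None  # never exits within the slice / max length
    exit_rel = int(np.argmin(after))
    exit_idx = entry + exit_rel
    if not cavity[vx[exit_idx], vy[exit_idx]]:
        return None  # exited into a sinus-like pocket, not the cavity
    # midpoint between last in-mask and first cavity sample
    return float(0.5 * (ts[exit_idx - 1] + ts[exit_idx]))


def measure_slice(
    skull_slice: np.ndarray,
    z: int,
    spacing_xy: tuple[float, float],
    n_points: int = 100,
) -> list[ThicknessSample]:
    """All thickness samples for one axial slice (empty list if degenerate)."""
    try:
        outer, _inner, comp, cavity = slice_boundaries(skull_slice)
    except DegenerateSliceError:
        return []
    pts = sample_points(outer, n=n_points)
    normals = _inward_normals(pts, comp, spacing_xy)
    out = []
    for p, nrm in zip(pts, normals):
        t = tangent_thickness(p, nrm, comp, cavity, spacing_xy)
        out.append(
            ThicknessSample(
                slice_index=z,
                point=(float(p[0]), float(p[1])),
                normal=(float(nrm[0]), float(nrm[1])),
                thickness_mm=t,
            )
        )
    return out


def median_skull_thickness(
    skull: BinaryMask,
    z0: int,
    n_points: int = 100,
    n_slices: int = 16,
    offset_mm: float = 10.0,
    trim_pct: float = 95.0,
    min_valid_samples: int = 160,
    per_slice_trim: bool = False,
    keep_samples: bool = True,
) -> ThicknessResult:
    """Median skull thickness over the measurement band, central-95% trimmed.

    Pools all valid normal-chord samples from every slice of the band,
    discards values outside the central ``trim_pct`` percent of the pooled
    distribution (2.5–97.5 percentiles by default) and returns the median
    of the kept values.  ``per_slice_trim`` instead trims within each slice
    before pooling (an alternative reading of the aggregation; the pooled
    default is simpler and auditable).
    """
    check_isotropic_inplane(skull.spacing)
    sx, sy, sz = skull.spacing
    z_start, z_end = select_slices(
        z0, sz, skull.shape[2], offset_mm=offset_mm, n_slices=n_slices
    )
    all_samples: list[ThicknessSample] = []
    per_slice: dict[int, int] = {}
    for z in range(z_start, z_end):
        samples = measure_slice(
            skull.data[:, :, z], z, (sx, sy), n_points=n_points
        )
        per_slice[z] = sum(1 for s in samples if s.thickness_mm is not None)
        all_samples.extend(samples)

    def _trim(values: np.ndarray) -> np.ndarray:
        if len(values) == 0:
            return values
        half = (100.0 - trim_pct) / 2.0
        lo, hi = np.percentile(values, [half, 100.0 - half])
        return values[(values >= lo) & (values <= hi)]

    if per_slice_trim:
        kept_parts = []
        for z in range(z_start, z_end):
            vals = np.array(
                [
                    s.thickness_mm
                    for s in all_samples
                    if s.slice_index == z and s.thickness_mm is not None
                ]
            )
            kept_parts.append(_trim(vals))
        kept = np.concatenate(kept_parts) if kept_parts else np.array([])
        valid = np.array(
            [s.thickness_mm for s in all_samples if s.thickness_mm is not None]
        )
    else:
        valid = np.array(
            [s.thickness_mm for s in all_samples if s.thickness_mm is not None]
        )
        kept = _trim(valid)

    if len(valid) < min_valid_samples:
        raise InsufficientDataError(
            f"only {len(valid)} valid thickness samples in band "
            f"[{z_start}, {z_end}); need at least {min_valid_samples}"
        )
    return ThicknessResult(
        median_thickness_mm=float(np.median(kept)),
        n_samples_total=int(len(valid)),
        n_samples_kept=int(len(kept)),
        per_slice_counts=per_slice,
        reference_slice=int(z0),
        slice_band=(z_start, z_end),
        trim_pct=trim_pct,
        samples=all_samples if keep_samples else [],
    )


def compare_thickness(
    results: dict[str, "np.ndarray | list[float]"],
    reference_label: str,
) -> pd.DataFrame:
    """Cross-tool comparison table of per-subject median thicknesses.

    ``results`` maps a tool label to its per-subject thickness values
    (aligned across tools).  Reports each tool's mean (SD) and the mean
    absolute per-subject difference from the reference tool.
    """
    if reference_label not in results:
        raise KeyError(f"reference label {reference_label!r} not in results")
    if len(results) < 2:
        raise ValueError("need at least two labeled result sets")
    ref = np.asarray(results[reference_label], dtype=float)
    rows = []
    for label, values in results.items():
        values = np.asarray(values, dtype=float)
        if values.shape != ref.shape:
            raise ValueError(
                f"{label!r} has {values.shape} subjects, reference has "
                f"{ref.shape}"
            )
        rows.append(
            {
                "tool": label,
                "mean_thickness_mm": float(values.mean()),
                "sd_thickness_mm": float(values.std(ddof=1))
                if len(values) > 1
                else 0.0,
                "mean_abs_diff_mm": float(np.abs(values - ref).mean()),
                "is_reference": label == reference_label,
            }
        )
    return pd.DataFrame(rows)
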