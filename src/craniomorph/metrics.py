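"""Segmentation and rater agreement statistics.

Dice overlap and the 95th-percentile Hausdorff distance (HD95) evaluate
binary segmentations against a reference; Bland–Altman bias and limits of
agreement compare paired continuous measurements (e.g. MRI- vs CT-derived
skull thickness); Gwet's AC1 quantifies chance-corrected agreement between
two raters assigning categorical quality labels, and is preferred over
Cohen's kappa when one category dominates (kappa collapses under prevalence
imbalance, AC1 does not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm

from .io import BinaryMask, GeometryError


@dataclass
class AgreementResult:
    """A chance-corrected agreement coefficient with its 95% CI."""

    value: float
    ci_low: float
    ci_high: float
    n_subjects: int
    statistic: str = "gwet_ac1"


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)`` in [0, 1].

    Two empty masks agree perfectly on absence and score 1 (documented
    convention; avoids NaN in per-class batch reports).
    """
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-adjacent background neighbour.

    The volume border counts as background, so voxels on the array edge are
    surface voxels.
    """
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def hd95(a: BinaryMask, b: BinaryMask) -> float:
    """95th percentile of the symmetric surface distance distribution, in mm.

    Surface voxels of each mask are mapped to physical coordinates (voxel
    index × spacing), directed nearest-surface distances are computed in
    both directions, pooled, and the 95th percentile (linear interpolation)
    of the pooled distribution returned.  This is the robust variant of the
    Hausdorff distance (the exact Hausdorff is the pool's maximum).
    """
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.spacing != b.spacing:
        raise GeometryError(f"spacing mismatch {a.spacing} vs {b.spacing}")
    if a.count() == 0 or b.count() == 0:
        raise ValueError("HD95 is undefined for an empty mask")
    spacing = np.asarray(a.spacing)
    pa = np.argwhere(surface_voxels(a.data.astype(bool))) * spacing
    pb = np.argwhere(surface_voxels(b.data.astype(bool))) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


# ---------------------------------------------------------------------------
# paired-measurement agreement
# ---------------------------------------------------------------------------

def bland_altman(x, y) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement for paired measurements.

    ``bias = mean(y - x)``; limits are ``bias ± 1.96 · SD(y - x)`` (sample
    SD).  Returns ``(bias, loa_low, loa_high)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


# ---------------------------------------------------------------------------
# Gwet AC1
# ---------------------------------------------------------------------------

def gwet_ac1(
    ratings: pd.DataFrame,
    rater_pair: tuple[str, str] | None = None,
    ci_level: float = 0.95,
    categories=None,
) -> AgreementResult:
    """Gwet's AC1 inter-rater agreement for two raters, with CI.

    ``ratings`` is a subjects × raters table of categorical labels;
    ``rater_pair`` names the two columns to compare (default: the first
    two).  Subjects with a missing rating from either rater are dropped
    (pairwise-complete analysis).

    With observed agreement ``pa`` and, per category ``q``, the mean
    marginal proportion ``π_q`` across the two raters,

        pe  = (1 / (Q - 1)) · Σ_q π_q (1 - π_q)
        AC1 = (pa - pe) / (1 - pe)

    The CI uses Gwet's subject-level linearized variance with a normal
    approximation, truncated above at 1.
    """
    if rater_pair is None:
        rater_pair = tuple(ratings.columns[:2])
    r1, r2 = rater_pair
    for r in (r1, r2):
        if r not in ratings.columns:
            raise KeyError(f"rater {r!r} not in table columns")
        if ratings[r].isna().all():
            raise ValueError(f"rater {r!r} has no ratings")
    pair = ratings[[r1, r2]].dropna()
    n = len(pair)
    if n < 2:
        raise ValueError(f"only {n} subjects rated by both raters; need >= 2")
    if categories is None:
        categories = sorted(set(pair[r1]) | set(pair[r2]), key=str)
    q = len(categories)
    if q < 2:
        # single observed category: agreement is perfect but chance
        # correction is undefined; report 1 by the pa=1 limit
        return AgreementResult(1.0, 1.0, 1.0, n)

    a = pair[r1].to_numpy()
    b = pair[r2].to_numpy()
    agree_i = (a == b).astype(float)
    pa = agree_i.mean()
    # r_iq/r: per subject, fraction of the 2 raters choosing category q
    frac = np.stack(
        [((a == c).astype(float) + (b == c).astype(float)) / 2.0
         for c in categories],
        axis=1,
    )  # (n, q)
    pi = frac.mean(axis=0)
    pe = float(np.sum(pi * (1 - pi)) / (q - 1))
    if pe >= 1.0:
        raise ValueError("degenerate ratings: chance agreement is 1")
    ac1 = (pa - pe) / (1 - pe)

    # Gwet's linearized subject-level variance
    ac1_i = (agree_i - pe) / (1 - pe)
    pe_i = (frac @ (1 - pi)) / (q - 1)
    ac1_star = ac1_i - 2.0 * (1 - ac1) * (pe_i - pe) / (1 - pe)
    var = float(np.sum((ac1_star - ac1) ** 2) / (n * (n - 1)))
    z = norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return AgreementResult(
        value=float(ac1),
        ci_low=float(min(ac1 - half, 1.0)),
        ci_high=float(min(ac1 + half, 1.0)),
        n_subjects=n,
    )


def ratings_from_long(frame: pd.DataFrame,
                      subject_col: str = "subject_id",
                      rater_col: str = "rater",
                      category_col: str = "category") -> pd.DataFrame:
    """Pivot a long (subject, rater, category) table to subjects × raters."""
    return frame.pivot(index=subject_col, columns=rater_col,
                       values=category_col)
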