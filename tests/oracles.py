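"""Independent brute-force oracles for the test suite.

Everything here is deliberately slow and literal — triple loops over
voxels, exhaustive pairwise distances — so it shares no code path with the
vectorized implementations it validates.
"""

import numpy as np


def top_points_loop(brain: np.ndarray) -> np.ndarray:
    """Most anterior brain voxel per slice, by exhaustive scan."""
    H, W, D = brain.shape
    top = np.zeros(D, dtype=np.int64)
    for z in range(D):
        best = 0
        found = False
        for x in range(H):
            for y in range(W):
                if brain[x, y, z]:
                    found = True
                    if x > best:
                        best = x
        top[z] = best if found else 0
    return top


def running_max_loop(top) -> np.ndarray:
    out = np.zeros(len(top), dtype=np.int64)
    prev = 0
    for z, t in enumerate(top):
        prev = max(int(t), prev)
        out[z] = prev
    return out


def crop_loop(data: np.ndarray, adjusted) -> np.ndarray:
    H, W, D = data.shape
    out = data.copy()
    for z in range(D):
        for x in range(H):
            if x > adjusted[z]:
                out[x, :, z] = 0
    return out


def dice_counts(a: np.ndarray, b: np.ndarray) -> float:
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def surface_loop(mask: np.ndarray) -> list:
    """Surface voxels: mask voxels with a face-adjacent background
    neighbour (volume edge counts as background)."""
    H, W, D = mask.shape
    pts = []
    for x in range(H):
        for y in range(W):
            for z in range(D):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in (
                    (1, 0, 0), (-1, 0, 0),
                    (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1),
                ):
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if (
                        nx < 0 or nx >= H
                        or ny < 0 or ny >= W
                        or nz < 0 or nz >= D
                        or not mask[nx, ny, nz]
                    ):
                        pts.append((x, y, z))
                        break
    return pts


def hd95_pairwise(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """HD95 by exhaustive pairwise surface distances."""
    sa = np.array(surface_loop(a), dtype=float) * np.asarray(spacing)
    sb = np.array(surface_loop(b), dtype=float) * np.asarray(spacing)
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2))
    directed = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(directed, 95))


def gwet_ac1_by_hand(pairs, categories) -> float:
    """AC1 from first principles on a list of (rating1, rating2) pairs."""
    n = len(pairs)
    pa = sum(1.0 for a, b in pairs if a == b) / n
    q = len(categories)
    pe = 0.0
    for c in categories:
        p1 = sum(1.0 for a, _ in pairs if a == c) / n
        p2 = sum(1.0 for _, b in pairs if b == c) / n
        pi = (p1 + p2) / 2.0
        pe += pi * (1 - pi)
    pe /= q - 1
    return (pa - pe) / (1 - pe)


def ellipse_normal_chord(a_out, b_out, a_in, b_in, theta) -> float:
    """Length of the inward-normal chord of an elliptical annulus.

    Starting from the point of the outer ellipse at parametric angle
    ``theta``, march along the inward normal until the inner ellipse
    ``(x/a_in)^2 + (y/b_in)^2 = 1`` is crossed; solved numerically by
    bisection on a fine bracketing scan.
    """
    x0 = a_out * np.cos(theta)
    y0 = b_out * np.sin(theta)
    # outward normal direction of the ellipse at (x0, y0) is (x/a^2, y/b^2)
    nx, ny = x0 / a_out**2, y0 / b_out**2
    nrm = np.hypot(nx, ny)
    nx, ny = -nx / nrm, -ny / nrm  # inward

    def inside_inner(t):
        x, y = x0 + t * nx, y0 + t * ny
        return (x / a_in) ** 2 + (y / b_in) ** 2 <= 1.0

    ts = np.linspace(0, 2 * (a_out - a_in) + 10.0, 4000)
    hit = next((t for t in ts if inside_inner(t)), None)
    if hit is None:
        return np.nan
    lo, hi = max(hit - (ts[1] - ts[0]), 0.0), hit
    for _ in range(60):
        mid = (lo + hi) / 2
        if inside_inner(mid):
            hi = mid
        else:
            lo = mid
    return float((lo + hi) / 2)
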