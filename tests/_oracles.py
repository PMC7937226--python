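"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (queue-based flood fill, explicit
loops) that share no code with the package, so agreement is meaningful.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGH4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
NEIGH8 = NEIGH4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def floodfill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling by BFS flood fill, raster-order labels."""
    neigh = NEIGH8 if connectivity == 8 else NEIGH4
    rows, cols = mask.shape
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = current
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols:
                            if mask[rr, cc] and labels[rr, cc] == 0:
                                labels[rr, cc] = current
                                queue.append((rr, cc))
    return labels


def floodfill_clear_border(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Remove components touching the border, via flood-fill labeling."""
    labels = floodfill_label(mask, connectivity)
    doomed = set()
    rows, cols = mask.shape
    for r in range(rows):
        for c in (0, cols - 1):
            if labels[r, c]:
                doomed.add(labels[r, c])
    for c in range(cols):
        for r in (0, rows - 1):
            if labels[r, c]:
                doomed.add(labels[r, c])
    out = mask.copy()
    for lab in doomed:
        out[labels == lab] = False
    return out


def floodfill_fill_holes(mask: np.ndarray, foreground_connectivity: int = 8) -> np.ndarray:
    """Fill enclosed holes: background not reachable from the border.

    Background connectivity is complementary to the foreground's
    (8-connected particles enclose 4-connected holes).
    """
    bg_conn = 4 if foreground_connectivity == 8 else 8
    neigh = NEIGH8 if bg_conn == 8 else NEIGH4
    rows, cols = mask.shape
    reach = np.zeros(mask.shape, dtype=bool)
    queue = deque()
    for r in range(rows):
        for c in (0, cols - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    for c in range(cols):
        for r in (0, rows - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                if not mask[rr, cc] and not reach[rr, cc]:
                    reach[rr, cc] = True
                    queue.append((rr, cc))
    return mask | ~reach


def mad_outliers(values) -> np.ndarray:
    """Three-scaled-MAD outlier rule, evaluated element by element."""
    x = [float(v) for v in values]
    med = float(np.median(x))
    mad = float(np.median([abs(v - med) for v in x]))
    scaled = 1.4826 * mad
    return np.array([abs(v - med) > 3.0 * scaled for v in x])


def cv_of_rows(values: np.ndarray) -> list[float]:
    """Per-row sample-SD/mean, NaN rows with < 2 finite values."""
    out = []
    for row in values:
        finite = [v for v in row if not np.isnan(v)]
        if len(finite) < 2:
            out.append(float("nan"))
            continue
        n = len(finite)
        mean = sum(finite) / n
        var = sum((v - mean) ** 2 for v in finite) / (n - 1)
        out.append((var ** 0.5) / mean)
    return out


def rmcv_of_rows(values: np.ndarray, start: int, end: int) -> float:
    cvs = [v for v in cv_of_rows(values)[start : end + 1] if not np.isnan(v)]
    return sum(cvs) / len(cvs)


def global_mean_threshold(pixels: np.ndarray, sensitivity: float = 0.5) -> np.ndarray:
    """Single global-mean threshold (the rule adaptive thresholding beats
    on gradient-illuminated images): dark foreground below the global
    mean minus the same sensitivity-scaled offset."""
    px = pixels.astype(float)
    offset = (1.0 - sensitivity) * px.std()
    return px < px.mean() - offset


def random_mask(rng: np.random.Generator, max_side: int = 64) -> np.ndarray:
    """Random binary mask with a mix of speckle and blobby structure."""
    rows = int(rng.integers(4, max_side + 1))
    cols = int(rng.integers(4, max_side + 1))
    p = rng.uniform(0.2, 0.7)
    mask = rng.random((rows, cols)) < p
    if rng.random() < 0.5:  # add a few rectangles for larger structures
        for _ in range(int(rng.integers(1, 4))):
            r0 = int(rng.integers(0, rows))
            c0 = int(rng.integers(0, cols))
            h = int(rng.integers(1, max(2, rows // 3)))
            w = int(rng.integers(1, max(2, cols // 3)))
            mask[r0 : r0 + h, c0 : c0 + w] = rng.random() < 0.5
    return mask
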