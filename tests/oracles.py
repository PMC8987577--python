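"""Brute-force reference implementations used to verify the fast paths.

Everything here is deliberately naive (per-pixel loops, flood fills,
exhaustive maximization) and shares no code with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_N4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def label_components(mask: np.ndarray, connectivity: int = 2) -> list[list[tuple[int, int]]]:
    """Flood-fill labeling; returns pixel lists per component."""
    offsets = _N8 if connectivity == 2 else _N4
    rows, cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or seen[r, c]:
                continue
            queue = deque([(r, c)])
            seen[r, c] = True
            pixels = []
            while queue:
                pr, pc = queue.popleft()
                pixels.append((pr, pc))
                for dr, dc in offsets:
                    nr, nc = pr + dr, pc + dc
                    if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        queue.append((nr, nc))
            components.append(pixels)
    return components


def despeckle(mask: np.ndarray, min_size: int, connectivity: int = 2) -> np.ndarray:
    out = np.zeros_like(mask, dtype=bool)
    for pixels in label_components(np.asarray(mask, bool), connectivity):
        if len(pixels) >= min_size:
            for r, c in pixels:
                out[r, c] = True
    return out


def fill_holes(mask: np.ndarray, hole_size: int, connectivity: int = 2) -> np.ndarray:
    m = np.asarray(mask, bool)
    out = m.copy()
    rows, cols = m.shape
    for pixels in label_components(~m, connectivity):
        touches_border = any(r in (0, rows - 1) or c in (0, cols - 1) for r, c in pixels)
        if not touches_border and len(pixels) < hole_size:
            for r, c in pixels:
                out[r, c] = True
    return out


def erode(mask: np.ndarray, iterations: int) -> np.ndarray:
    m = np.asarray(mask, bool).copy()
    rows, cols = m.shape
    for _ in range(iterations):
        nxt = m.copy()
        for r in range(rows):
            for c in range(cols):
                if not m[r, c]:
                    continue
                for dr, dc in _N8:
                    nr, nc = r + dr, c + dc
                    if not (0 <= nr < rows and 0 <= nc < cols) or not m[nr, nc]:
                        nxt[r, c] = False
                        break
        m = nxt
    return m


def dilation_fill(mask: np.ndarray, n: int, thresh: float) -> np.ndarray:
    m = np.asarray(mask, bool)
    rows, cols = m.shape
    offsets = [
        (dr, dc)
        for dr in range(-n, n + 1)
        for dc in range(-n, n + 1)
        if (dr, dc) != (0, 0) and dr * dr + dc * dc <= n * n
    ]
    out = m.copy()
    for r in range(rows):
        for c in range(cols):
            if m[r, c]:
                continue
            white = total = 0
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if 0 <= nr < rows and 0 <= nc < cols:
                    total += 1
                    white += bool(m[nr, nc])
            if total and white / total > thresh:
                out[r, c] = True
    return out


def perimeter(mask: np.ndarray) -> float:
    m = np.asarray(mask, bool)
    rows, cols = m.shape
    edges = 0
    for r in range(rows):
        for c in range(cols):
            if not m[r, c]:
                continue
            for dr, dc in _N4:
                nr, nc = r + dr, c + dc
                if not (0 <= nr < rows and 0 <= nc < cols) or not m[nr, nc]:
                    edges += 1
    return float(edges)


def otsu_mask(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive between-class-variance maximization over all cut points.

    Returns the best foreground mask (strictly above the best cut) and the
    maximal between-class variance achieved.
    """
    img = np.asarray(image, dtype=float)
    values = np.unique(img)
    best_var = -1.0
    best_mask = None
    total = img.size
    grand = img.mean()
    for cut in values[:-1]:  # cutting above the max leaves no foreground
        fg = img > cut
        n_fg = int(fg.sum())
        n_bg = total - n_fg
        if n_fg == 0 or n_bg == 0:
            continue
        mu_fg = img[fg].mean()
        mu_bg = img[~fg].mean()
        var = (n_fg / total) * (mu_fg - grand) ** 2 + (n_bg / total) * (mu_bg - grand) ** 2
        if var > best_var:
            best_var = var
            best_mask = fg
    return best_mask, best_var


def between_class_variance(image: np.ndarray, mask: np.ndarray) -> float:
    img = np.asarray(image, dtype=float)
    fg = np.asarray(mask, bool)
    n_fg = int(fg.sum())
    n_bg = img.size - n_fg
    if n_fg == 0 or n_bg == 0:
        return 0.0
    grand = img.mean()
    return (n_fg / img.size) * (img[fg].mean() - grand) ** 2 + (
        n_bg / img.size
    ) * (img[~fg].mean() - grand) ** 2
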