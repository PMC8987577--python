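"""Cortex-region segmentation from cortex-glia and nuclei binary masks.

The cortex (the cell-body rind of the larval CNS) is recovered in four
steps: merge the two channel masks, close the gaps between nuclei and glial
membranes with a neighborhood-fraction dilation fill, fill the remaining
enclosed holes, and erode to fine-tune the slightly over-grown boundary.
Defaults (n=15 px, thresh=0.10, hole_size=5000 px, erosions=10) are the
parameter set selected by grid search against manually traced cortex masks.

Validation against a manual mask uses two percentages: OL/M (overlap over
manual area, a true-positive-rate proxy) and OL/A (overlap over automated
area, a false-positive proxy).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.morphology import disk


@dataclass(frozen=True)
class SegmentationParams:
    """The four tunable cortex-segmentation parameters."""

    n: int = 15
    thresh: float = 0.10
    hole_size: int = 5000
    erosions: int = 10

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 < self.thresh < 1.0):
            raise ValueError("thresh must lie in (0, 1)")
        if self.hole_size < 0:
            raise ValueError("hole_size must be >= 0")
        if self.erosions < 0:
            raise ValueError("erosions must be >= 0")


DEFAULT_PARAMS = SegmentationParams()

#: 3-4 values per parameter, 192 combinations in total, spanning the ranges
#: explored when the defaults were selected.
DEFAULT_GRID: dict[str, list] = {
    "n": [5, 10, 15, 20],
    "thresh": [0.05, 0.10, 0.15, 0.20],
    "hole_size": [1000, 2500, 5000, 7500],
    "erosions": [5, 10, 15],
}


@dataclass
class CortexSegmentation:
    """Binary cortex region for one plane plus the parameters behind it."""

    mask: np.ndarray
    params: SegmentationParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class ValidationMetrics:
    overlap_px: int
    manual_px: int
    auto_px: int
    ol_m: float
    ol_a: float


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def merge_masks(cg: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Pixelwise union of the cortex-glia and nuclei masks."""
    cg, nuclei = _as_bool(cg), _as_bool(nuclei)
    if cg.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: {cg.shape} vs {nuclei.shape}")
    return cg | nuclei


def dilation_fill(mask: np.ndarray, n: int = 15, thresh: float = 0.10) -> np.ndarray:
    """Flip background pixels surrounded by enough foreground.

    One simultaneous pass: a background pixel becomes foreground iff the
    fraction of foreground among its in-image neighbors within a Euclidean
    disk of radius ``n`` (the pixel itself excluded) is strictly greater
    than ``thresh``.  Foreground pixels never change, so the output is a
    superset of the input.  Neighbor fractions use only in-image pixels; no
    padding is assumed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < thresh < 1.0):
        raise ValueError("thresh must lie in (0, 1)")
    m = _as_bool(mask)
    kernel = disk(n).astype(np.float64)
    kernel[n, n] = 0.0
    # Counts are small integers; FFT round-off is far below 0.5, so rint
    # restores exact neighbor counts.
    white = np.rint(fftconvolve(m.astype(np.float64), kernel, mode="same"))
    total = np.rint(fftconvolve(np.ones(m.shape), kernel, mode="same"))
    frac = white / total
    return m | (~m & (frac > thresh))


def fill_holes(
    mask: np.ndarray, hole_size: int = 5000, connectivity: int = 2
) -> np.ndarray:
    """Fill enclosed background holes smaller than ``hole_size`` pixels.

    A hole is a background connected component that does not touch the
    image border; components of ``hole_size`` or more pixels, and any
    border-touching background, are preserved.
    """
    if hole_size < 0:
        raise ValueError("hole_size must be >= 0")
    m = _as_bool(mask)
    if hole_size == 0:
        return m.copy()
    structure = (
        np.ones((3, 3), dtype=bool)
        if connectivity == 2
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n_lab = ndimage.label(~m, structure=structure)
    if n_lab == 0:
        return m.copy()
    sizes = np.bincount(labels.ravel(), minlength=n_lab + 1)
    fill = sizes < hole_size
    fill[0] = False
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    fill[border] = False
    return m | fill[labels]


def erode(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Peel the mask: each pass removes foreground pixels touching background.

    A foreground pixel with any background pixel among its 8 immediate
    neighbors (the image border counts as background) turns background.
    ``iterations=0`` is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    m = _as_bool(mask)
    if iterations == 0:
        return m.copy()
    return ndimage.binary_erosion(
        m, structure=np.ones((3, 3), dtype=bool), iterations=iterations, border_value=0
    )


def segment_cortex(
    cg: np.ndarray,
    nuclei: np.ndarray,
    params: SegmentationParams = DEFAULT_PARAMS,
) -> CortexSegmentation:
    """Merge -> dilation fill -> hole fill -> erode, with ``params``."""
    merged = merge_masks(cg, nuclei)
    filled = dilation_fill(merged, params.n, params.thresh)
    solid = fill_holes(filled, params.hole_size)
    final = erode(solid, params.erosions)
    return CortexSegmentation(mask=final, params=params)


def overlap_metrics(auto: np.ndarray, manual: np.ndarray) -> ValidationMetrics:
    """OL/M and OL/A percentages between automated and manual cortex masks."""
    a, m = _as_bool(auto), _as_bool(manual)
    if a.shape != m.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {m.shape}")
    auto_px = int(np.count_nonzero(a))
    manual_px = int(np.count_nonzero(m))
    if manual_px == 0:
        raise ValueError("empty manual mask: OL/M undefined")
    if auto_px == 0:
        raise ValueError("empty automated mask: OL/A undefined")
    overlap_px = int(np.count_nonzero(a & m))
    return ValidationMetrics(
        overlap_px=overlap_px,
        manual_px=manual_px,
        auto_px=auto_px,
        ol_m=100.0 * overlap_px / manual_px,
        ol_a=100.0 * overlap_px / auto_px,
    )


def parameter_grid_search(
    images: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    grid: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Evaluate every parameter combination against manual cortex masks.

    ``images`` holds ``(cg_mask, nuclei_mask, manual_cortex_mask)`` triples;
    ``grid`` maps each of ``n``, ``thresh``, ``hole_size``, ``erosions`` to
    its candidate values (default: :data:`DEFAULT_GRID`).  Returns one row
    per combination with mean OL/M and OL/A over the images, sorted by
    descending mean OL/M then descending mean OL/A, with a ``pareto``
    column flagging the non-dominated front on the two means.
    """
    if not images:
        raise ValueError("need at least one (cg, nuclei, manual) image triple")
    grid = dict(DEFAULT_GRID if grid is None else grid)
    missing = {"n", "thresh", "hole_size", "erosions"} - set(grid)
    if missing:
        raise ValueError(f"grid is missing parameters: {sorted(missing)}")
    if any(len(v) == 0 for v in grid.values()):
        raise ValueError("every grid parameter needs at least one value")

    rows = []
    for n, thresh, hole_size, erosions in itertools.product(
        grid["n"], grid["thresh"], grid["hole_size"], grid["erosions"]
    ):
        params = SegmentationParams(n=n, thresh=thresh, hole_size=hole_size, erosions=erosions)
        ol_m, ol_a = [], []
        for cg, nuclei, manual in images:
            seg = segment_cortex(cg, nuclei, params)
            if seg.area == 0:
                ol_m.append(0.0)
                ol_a.append(0.0)
                continue
            metrics = overlap_metrics(seg.mask, manual)
            ol_m.append(metrics.ol_m)
            ol_a.append(metrics.ol_a)
        rows.append(
            {
                "n": n,
                "thresh": thresh,
                "hole_size": hole_size,
                "erosions": erosions,
                "mean_ol_m": float(np.mean(ol_m)),
                "mean_ol_a": float(np.mean(ol_a)),
            }
        )

    df = pd.DataFrame(rows).sort_values(
        ["mean_ol_m", "mean_ol_a"], ascending=False, kind="mergesort"
    )
    df = df.reset_index(drop=True)
    scores = df[["mean_ol_m", "mean_ol_a"]].to_numpy()
    pareto = np.ones(len(df), dtype=bool)
    for i in range(len(df)):
        dominated = (
            (scores[:, 0] >= scores[i, 0])
            & (scores[:, 1] >= scores[i, 1])
            & ((scores[:, 0] > scores[i, 0]) | (scores[:, 1] > scores[i, 1]))
        )
        pareto[i] = not dominated.any()
    df["pareto"] = pareto
    return df
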