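"""Denoising, global thresholding and quality-aware algorithm selection.

Each channel is denoised by unsharp masking and then binarized with one of
four global thresholding algorithms (Otsu, Triangle, Li, Yen).  No single
algorithm is reliable on every image, so a per-channel decision tree starts
from Otsu's output and inspects it for the two stereotyped failure modes:

* **blown out** -- background speckle passed as signal.  Detected by
  despeckling (removing foreground components below 75 px) and measuring the
  white-pixel loss inside the band corresponding to the neuropil (the middle
  third of rows by default); a loss of 7% or more flags the image.
* **blacked out** -- true signal removed.  Detected when fewer than 2% of
  pixels are foreground.

A blown-out Otsu result is re-thresholded with Triangle.  A blacked-out one
falls back to Li for the nuclei channel and Yen for the astrocyte channel;
the cortex-glia tree only chooses between Otsu and Triangle.  All constants
are configurable; defaults match the values above.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import (
    threshold_li,
    threshold_otsu,
    threshold_triangle,
    threshold_yen,
)
THRESHOLD_METHODS = ("otsu", "triangle", "li", "yen")

_METHOD_FUNCS = {
    "otsu": threshold_otsu,
    "triangle": threshold_triangle,
    "li": threshold_li,
    "yen": threshold_yen,
}

#: Thresholding algorithms each channel's decision tree may choose from.
CHANNEL_ALGORITHMS = {
    "nuclei": ("otsu", "triangle", "li"),
    "cortex_glia": ("otsu", "triangle"),
    "astrocyte": ("otsu", "triangle", "yen"),
}


class DegenerateImageWarning(UserWarning):
    """Raised as a warning when a constant image cannot be thresholded."""


@dataclass(frozen=True)
class DenoiseParams:
    """Unsharp-mask parameters.

    ``amount`` scales the high-frequency residual; ``radius`` is the
    standard deviation (pixels) of the Gaussian blur used to form it.
    Defaults are the astrocyte/cortex-glia setting (2, 20); the nuclei
    channel uses (3, 20).
    """

    amount: float = 2.0
    radius: float = 20.0

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be non-negative")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


#: Per-channel denoising defaults.
DEFAULT_DENOISE: dict[str, DenoiseParams] = {
    "astrocyte": DenoiseParams(2.0, 20.0),
    "cortex_glia": DenoiseParams(2.0, 20.0),
    "nuclei": DenoiseParams(3.0, 20.0),
}


@dataclass(frozen=True)
class ThresholdDecision:
    """Audit record of one decision-tree pass over one channel image."""

    channel: str
    chosen_algorithm: str
    blown_out: bool
    blacked_out: bool
    despeckle_reduction: float
    white_fraction: float
    threshold_value: float | None


def unsharp_mask(image: np.ndarray, params: DenoiseParams) -> np.ndarray:
    """Sharpen ``image`` by adding the scaled difference from its blur.

    ``out = image + amount * (image - gaussian(image, sigma=radius))``,
    clipped back to the input intensity range so denoising never widens it.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    blurred = ndimage.gaussian_filter(img, sigma=params.radius, mode="nearest")
    sharp = img + params.amount * (img - blurred)
    return np.clip(sharp, img.min(), img.max())


def threshold_global(
    image: np.ndarray, method: str
) -> tuple[np.ndarray, float | None]:
    """Binarize with a named global algorithm; foreground is strictly above.

    Returns ``(mask, threshold)``.  A constant image has no definable
    threshold: an all-background mask is returned with ``threshold=None``
    and a :class:`DegenerateImageWarning`.
    """
    if method not in _METHOD_FUNCS:
        raise ValueError(f"unknown thresholding method {method!r}")
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() == img.max():
        warnings.warn(
            "constant image: no global threshold definable; returning all-background",
            DegenerateImageWarning,
            stacklevel=2,
        )
        return np.zeros(img.shape, dtype=bool), None
    t = float(_METHOD_FUNCS[method](img))
    return img > t, t


def despeckle(mask: np.ndarray, min_size: int = 75, connectivity: int = 2) -> np.ndarray:
    """Remove foreground connected components with area below ``min_size``.

    Components of exactly ``min_size`` pixels survive.  Connectivity 2 means
    8-neighborhood (the package-wide default), 1 means 4-neighborhood.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    m = np.asarray(mask, dtype=bool)
    if min_size == 1:
        return m.copy()
    structure = (
        np.ones((3, 3), dtype=bool)
        if connectivity == 2
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n_lab = ndimage.label(m, structure=structure)
    if n_lab == 0:
        return m.copy()
    sizes = np.bincount(labels.ravel(), minlength=n_lab + 1)
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def middle_band(shape: Sequence[int], axis: int = 0) -> tuple[slice, ...]:
    """Index expression selecting the middle third of ``shape`` along ``axis``."""
    n = shape[axis]
    sel: list[slice] = [slice(None)] * len(shape)
    sel[axis] = slice(n // 3, (2 * n) // 3)
    return tuple(sel)


def is_blown_out(
    mask: np.ndarray,
    band: tuple[slice, ...] | np.ndarray | None = None,
    min_size: int = 75,
    reduction_threshold: float = 0.07,
    connectivity: int = 2,
    band_axis: int = 0,
) -> tuple[bool, float]:
    """Detect excess speckle noise passed as signal by an Otsu mask.

    The mask is despeckled and the white-pixel count inside ``band``
    (default: the middle third of rows, where the neuropil lies) is compared
    before and after.  A fractional reduction of ``reduction_threshold`` or
    more (non-strict, "7% or greater") flags the image as blown out.
    """
    m = np.asarray(mask, dtype=bool)
    if band is None:
        band = middle_band(m.shape, axis=band_axis)
    before = int(np.count_nonzero(m[band]))
    if before == 0:
        return False, 0.0
    after = int(np.count_nonzero(despeckle(m, min_size, connectivity)[band]))
    reduction = 1.0 - after / before
    return reduction >= reduction_threshold, float(reduction)


def is_blacked_out(
    mask: np.ndarray, white_fraction_threshold: float = 0.02
) -> tuple[bool, float]:
    """Detect removal of true signal: strictly less than 2% foreground."""
    m = np.asarray(mask, dtype=bool)
    white_fraction = float(np.count_nonzero(m)) / m.size
    return white_fraction < white_fraction_threshold, white_fraction


def select_threshold(
    image: np.ndarray,
    channel: str,
    *,
    min_size: int = 75,
    blowout_threshold: float = 0.07,
    blackout_threshold: float = 0.02,
    band_axis: int = 0,
    connectivity: int = 2,
) -> tuple[np.ndarray, ThresholdDecision]:
    """Run the per-channel decision tree and return the chosen binarization.

    Otsu is tried first and its output inspected once (single-pass tree; the
    re-thresholded result is not re-inspected):

    * nuclei: blown out -> Triangle, else blacked out -> Li, else Otsu;
    * cortex glia: blown out -> Triangle, else Otsu;
    * astrocyte: blown out -> Triangle, else blacked out -> Yen, else Otsu.

    A constant image short-circuits to an all-background mask attributed to
    Otsu (present in every channel's permitted set), with both failure flags
    recorded from the empty mask.
    """
    if channel not in CHANNEL_ALGORITHMS:
        raise ValueError(f"unknown channel {channel!r}")

    otsu_mask, otsu_t = threshold_global(image, "otsu")
    if otsu_t is None:
        decision = ThresholdDecision(
            channel=channel,
            chosen_algorithm="otsu",
            blown_out=False,
            blacked_out=True,
            despeckle_reduction=0.0,
            white_fraction=0.0,
            threshold_value=None,
        )
        return otsu_mask, decision

    blown, reduction = is_blown_out(
        otsu_mask,
        min_size=min_size,
        reduction_threshold=blowout_threshold,
        connectivity=connectivity,
        band_axis=band_axis,
    )
    blacked, white_fraction = is_blacked_out(otsu_mask, blackout_threshold)

    if blown:
        chosen = "triangle"
    elif blacked and channel == "nuclei":
        chosen = "li"
    elif blacked and channel == "astrocyte":
        chosen = "yen"
    else:
        chosen = "otsu"

    if chosen == "otsu":
        mask, t = otsu_mask, otsu_t
    else:
        mask, t = threshold_global(image, chosen)

    decision = ThresholdDecision(
        channel=channel,
        chosen_algorithm=chosen,
        blown_out=blown,
        blacked_out=blacked,
        despeckle_reduction=reduction,
        white_fraction=white_fraction,
        threshold_value=t,
    )
    return mask, decision


def score_algorithm_rankings(
    rankings: Iterable[Sequence[object]],
) -> dict[str, int]:
    """Tally the 3/2/1 ranking scheme used to shortlist global algorithms.

    Each element of ``rankings`` is one image's best-first ranking of up to
    three algorithm names; first place earns 3 points, second 2, third 1.
    A rank entry may itself be a tuple/set of names to record a tie, in
    which case every tied algorithm receives that rank's points.  Returns
    total points per algorithm, for users auditioning additional algorithms
    against the built-in four.
    """
    points = (3, 2, 1)
    tally: Counter[str] = Counter()
    for ranking in rankings:
        if len(ranking) > 3:
            raise ValueError("a ranking lists at most three algorithms")
        for score, entry in zip(points, ranking):
            names = (entry,) if isinstance(entry, str) else tuple(entry)
            for name in names:
                tally[str(name)] += score
    return dict(tally)
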