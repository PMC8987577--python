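"""Per-plane morphology and infiltration scores.

Two scores summarize one z-plane:

* **AMI** (automated morphology index): total cortex-glia perimeter as a
  percentage of cortex area.  Healthy cortex glia form a thin mesh with a
  large perimeter; globular (dysfunctional) glia collapse into compact
  blobs, so a lower AMI means stronger morphological disruption.
* **AIS** (automated infiltration score): astrocyte pixels overlapping the
  cortex, after excluding astrocyte cell bodies, as a percentage of cortex
  area.  Cell bodies normally sit at the cortex/neuropil interface and are
  not aberrant infiltration; they are recognized and removed by their shape
  (area window, high bounding-box extent, high roundness).

The perimeter estimator counts exposed unit pixel edges (edges adjacent to
background or to the image border).  It is exactly verifiable by edge
enumeration and is used consistently for AMI and for object roundness; a
Crofton-style estimator can be substituted via ``perimeter_func`` where a
Euclidean-calibrated length is preferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .cortex import CortexSegmentation


def total_perimeter(mask: np.ndarray) -> float:
    """Total exposed-edge perimeter of all foreground pixels.

    Every foreground pixel contributes one unit per side that faces
    background or the image border: an isolated pixel counts 4, a filled
    k-by-k square counts 4k.
    """
    m = np.asarray(mask, dtype=bool)
    n = int(np.count_nonzero(m))
    if n == 0:
        return 0.0
    horiz = int(np.count_nonzero(m[:, :-1] & m[:, 1:]))
    vert = int(np.count_nonzero(m[:-1, :] & m[1:, :]))
    return float(4 * n - 2 * (horiz + vert))


@dataclass(frozen=True)
class ObjectFeatures:
    """Shape features of one 8-connected foreground object."""

    label: int
    area: int
    perimeter: float
    extent: float
    roundness: float
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


@dataclass(frozen=True)
class CellBodyFilter:
    """Shape gate deciding which astrocyte objects are cell bodies.

    An object is excluded (treated as a cell body) when its area lies in
    ``[min_area, max_area]`` AND its extent is at least ``min_extent`` AND
    its roundness is at least ``min_roundness``.  Defaults are calibrated
    to the synthetic-fixture scale, where cell bodies render as disks of
    radius 5-7 px; real data will need recalibrated cutoffs.
    """

    min_area: int = 50
    max_area: int = 800
    min_extent: float = 0.6
    min_roundness: float = 0.5

    def __post_init__(self) -> None:
        if self.min_area > self.max_area:
            raise ValueError("min_area must not exceed max_area")
        if not (0.0 <= self.min_extent <= 1.0):
            raise ValueError("min_extent must lie in [0, 1]")
        if self.min_roundness < 0.0:
            raise ValueError("min_roundness must be >= 0")

    def is_cell_body(self, obj: ObjectFeatures) -> bool:
        return (
            self.min_area <= obj.area <= self.max_area
            and obj.extent >= self.min_extent
            and obj.roundness >= self.min_roundness
        )


DEFAULT_BODY_FILTER = CellBodyFilter()


@dataclass(frozen=True)
class PlaneScores:
    """AMI, AIS and diagnostics for one plane of one animal.

    Scores are ``nan`` (missing, never 0) when the cortex area is zero.
    """

    animal_id: str
    group: str
    z_index: int
    z_norm: float
    ami: float
    ais: float
    cortex_area: int
    cg_perimeter: float
    infiltration_px: int
    n_excluded_bodies: int


def label_objects(
    mask: np.ndarray,
    connectivity: int = 2,
    perimeter_func: Callable[[np.ndarray], float] = total_perimeter,
) -> list[ObjectFeatures]:
    """Connected components with area, bbox, extent and roundness.

    Labels follow row-major order of each object's first pixel, so the
    output order is deterministic.  Roundness is ``4*pi*area / perimeter**2``
    with the same perimeter estimator used for AMI.
    """
    m = np.asarray(mask, dtype=bool)
    labels = sk_label(m, connectivity=connectivity)
    out: list[ObjectFeatures] = []
    for prop in regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        crop = labels[r0:r1, c0:c1] == prop.label
        perimeter = perimeter_func(crop)
        area = int(prop.area)
        bbox_area = (r1 - r0) * (c1 - c0)
        roundness = 4.0 * math.pi * area / perimeter**2 if perimeter > 0 else 0.0
        out.append(
            ObjectFeatures(
                label=int(prop.label),
                area=area,
                perimeter=perimeter,
                extent=area / bbox_area,
                roundness=roundness,
                bbox=(r0, c0, r1, c1),
            )
        )
    return out


def exclude_cell_bodies(
    astro_mask: np.ndarray,
    body_filter: CellBodyFilter = DEFAULT_BODY_FILTER,
    connectivity: int = 2,
) -> tuple[np.ndarray, int]:
    """Delete objects matching the cell-body shape gate; keep the rest."""
    m = np.asarray(astro_mask, dtype=bool)
    labels = sk_label(m, connectivity=connectivity)
    objects = label_objects(m, connectivity=connectivity)
    body_labels = [obj.label for obj in objects if body_filter.is_cell_body(obj)]
    if not body_labels:
        return m.copy(), 0
    out = m & ~np.isin(labels, body_labels)
    return out, len(body_labels)


def _cortex_of(cortex: CortexSegmentation | np.ndarray) -> CortexSegmentation:
    if isinstance(cortex, CortexSegmentation):
        return cortex
    return CortexSegmentation(mask=np.asarray(cortex, dtype=bool))


def compute_ami(
    cg_mask: np.ndarray,
    cortex: CortexSegmentation | np.ndarray,
    *,
    clip_to_cortex: bool = False,
    perimeter_func: Callable[[np.ndarray], float] = total_perimeter,
) -> tuple[float, dict]:
    """Cortex-glia perimeter per unit cortex area, as a percentage.

    The perimeter is measured on the full plane's cortex-glia mask by
    default (``clip_to_cortex=True`` restricts it to the cortex region
    first) and normalized by the cortex area.  Returns ``(ami, diag)``;
    ``ami`` is ``nan`` when the cortex area is zero.
    """
    cortex = _cortex_of(cortex)
    cg = np.asarray(cg_mask, dtype=bool)
    if clip_to_cortex:
        if cg.shape != cortex.mask.shape:
            raise ValueError("cortex-glia mask and cortex must share a shape")
        cg = cg & cortex.mask
    perimeter = perimeter_func(cg)
    area = cortex.area
    ami = 100.0 * perimeter / area if area > 0 else float("nan")
    return ami, {"cg_perimeter": perimeter, "cortex_area": area}


def compute_ais(
    astro_mask: np.ndarray,
    cortex: CortexSegmentation | np.ndarray,
    body_filter: CellBodyFilter = DEFAULT_BODY_FILTER,
) -> tuple[float, dict]:
    """Astrocyte-cortex overlap after cell-body exclusion, as a percentage.

    The astrocyte mask is first clipped to the cortex region; objects are
    then assessed on that cortex-clipped mask, cell bodies removed, and the
    surviving pixel count expressed as a percent of cortex area.  Returns
    ``(ais, diag)``; ``ais`` is ``nan`` when the cortex area is zero.
    """
    cortex = _cortex_of(cortex)
    astro = np.asarray(astro_mask, dtype=bool)
    if astro.shape != cortex.mask.shape:
        raise ValueError("astrocyte mask and cortex must share a shape")
    area = cortex.area
    if area == 0:
        return float("nan"), {"infiltration_px": 0, "n_excluded_bodies": 0, "cortex_area": 0}
    clipped = astro & cortex.mask
    kept, n_excluded = exclude_cell_bodies(clipped, body_filter)
    infiltration_px = int(np.count_nonzero(kept))
    ais = 100.0 * infiltration_px / area
    return ais, {
        "infiltration_px": infiltration_px,
        "n_excluded_bodies": n_excluded,
        "cortex_area": area,
    }


def score_plane(
    astro_mask: np.ndarray,
    cg_mask: np.ndarray,
    cortex: CortexSegmentation | np.ndarray,
    *,
    animal_id: str,
    group: str,
    z_index: int,
    z_norm: float,
    body_filter: CellBodyFilter = DEFAULT_BODY_FILTER,
    clip_ami_to_cortex: bool = False,
) -> PlaneScores:
    """Assemble AMI, AIS and diagnostics for one plane."""
    cortex = _cortex_of(cortex)
    ami, ami_diag = compute_ami(cg_mask, cortex, clip_to_cortex=clip_ami_to_cortex)
    ais, ais_diag = compute_ais(astro_mask, cortex, body_filter)
    return PlaneScores(
        animal_id=animal_id,
        group=group,
        z_index=z_index,
        z_norm=z_norm,
        ami=ami,
        ais=ais,
        cortex_area=cortex.area,
        cg_perimeter=ami_diag["cg_perimeter"],
        infiltration_px=ais_diag["infiltration_px"],
        n_excluded_bodies=ais_diag["n_excluded_bodies"],
    )
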