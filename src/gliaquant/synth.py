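"""Seeded synthetic confocal fixtures with known ground truth.

The generator emulates a longitudinal optical section of the larval ventral
nerve cord: a central horizontal neuropil band (the middle third of rows,
matching the blown-out detector's band convention) flanked above and below
by cortex, with an empty outside-the-CNS margin around everything.

* **nuclei channel** -- bright disks (radius 5-8 px, clipped at the cortex
  surface) packed densely into the cortex, emulating the near-solid packing
  of neuronal cell bodies;
* **cortex-glia channel** -- a morphology continuum controlled by
  ``globularity`` in [0, 1]: at 0, a thin (2 px) mesh formed by the Voronoi
  boundaries between nuclei plus a 3 px sheath along the cortex surface
  (cortex glia ensheath both the somas and the cortex); at 1, a handful of
  compact disks
  (radius 8-14 px) at fixed, stereotyped positions.  Intermediate values
  remove a matching fraction of mesh segments and add a matching number of
  disks, so the ground-truth perimeter falls monotonically with
  globularity;
* **astrocyte channel** -- cell bodies (disks, radius 5-7 px) seated on the
  cortex/neuropil interface, dense fine processes inside the neuropil, and
  cortex-penetrating processes grown pixel-by-pixel until the planted
  infiltration target (``infiltration_fraction`` of the cortex area) is met
  exactly; the achieved count is recorded as ``true_infiltration_px``.

Rendering paints foreground objects at 160-200 intensity on a 10-30
background, applies a Gaussian blur and additive Gaussian noise, and clips
to [0, 255].  All randomness derives from the spec seed with independent
streams per plane and channel, so identical specs produce bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from .scoring import total_perimeter
from .stacks import StackRecord, write_stack

#: Outside-the-CNS margin (pixels) around the tissue on all sides.
MARGIN = 20

#: Group presets used by :func:`write_fixture_set`: the control condition,
#: a weaker knockdown (partial globularity, mild infiltration) and a
#: stronger knockdown (near-total globularity, strongest infiltration).
GROUP_PRESETS: dict[str, dict[str, float]] = {
    "control": {"globularity": 0.05, "infiltration": 0.01},
    "driver1": {"globularity": 0.50, "infiltration": 0.04},
    "driver2": {"globularity": 0.85, "infiltration": 0.08},
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic stack."""

    shape: tuple[int, int] = (256, 256)
    n_planes: int = 5
    globularity: float = 0.0
    infiltration_fraction: float = 0.0
    n_nuclei: int = 170
    n_cell_bodies: int = 8
    n_globules: int = 8
    noise_sd: float = 4.0
    blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 96:
            raise ValueError("shape must have at least 96 rows to host the neuropil band")
        for name in ("globularity", "infiltration_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_planes < 1:
            raise ValueError("need at least one plane")
        if self.n_nuclei < 3:
            raise ValueError("need at least 3 nuclei to define a mesh")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be non-negative")


@dataclass
class FixtureTruth:
    """Ground truth accompanying one generated plane."""

    cortex_mask: np.ndarray
    neuropil_mask: np.ndarray
    nuclei_mask: np.ndarray
    cg_mask: np.ndarray
    astro_mask: np.ndarray
    true_infiltration_px: int
    true_cg_perimeter: float
    nuclei_centers: list[tuple[int, int]] = field(default_factory=list)
    cell_body_centers: list[tuple[int, int]] = field(default_factory=list)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _regions(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Tissue layout: cortex bands flanking the central neuropil band.

    The neuropil occupies the middle third of rows; cortex band corners are
    rounded by a Euclidean opening (tissue has no 90-degree corners).
    """
    rows, cols = shape
    r0, r1 = rows // 3, (2 * rows) // 3
    cortex = np.zeros(shape, dtype=bool)
    cortex[MARGIN:r0, MARGIN : cols - MARGIN] = True
    cortex[r1 : rows - MARGIN, MARGIN : cols - MARGIN] = True
    radius = min(14.0, (r0 - MARGIN) / 2.0 - 1.0)
    eroded = ndimage.distance_transform_edt(cortex) >= radius
    cortex = ndimage.distance_transform_edt(~eroded) <= radius
    cortex[r0:r1] = False  # opening must not leak into the neuropil band
    cortex[: MARGIN] = False
    cortex[rows - MARGIN :] = False
    cortex[:, : MARGIN] = False
    cortex[:, cols - MARGIN :] = False
    neuropil = np.zeros(shape, dtype=bool)
    neuropil[r0:r1, MARGIN : cols - MARGIN] = True
    return cortex, neuropil, r0, r1


def _stamp_disk(mask: np.ndarray, center: tuple[int, int], radius: float) -> None:
    r, c = center
    rad = int(np.ceil(radius))
    r0, r1 = max(0, r - rad), min(mask.shape[0], r + rad + 1)
    c0, c1 = max(0, c - rad), min(mask.shape[1], c + rad + 1)
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2


def _place_nuclei(
    rng: np.random.Generator,
    cortex: np.ndarray,
    n: int,
    r_range: tuple[float, float] = (5.0, 8.0),
    min_sep: float = 8.0,
) -> tuple[list[tuple[int, int]], list[float]]:
    """Greedy dart-throwing placement of nucleus disks.

    Somas pack the cortex to its surface, so centers only need to sit
    inside the cortex (disks are clipped at the region boundary when
    stamped); a minimum center separation keeps the packing plausible.
    """
    dist = ndimage.distance_transform_edt(cortex)
    rows, cols = cortex.shape
    centers: list[tuple[int, int]] = []
    placed = np.empty((0, 2), dtype=float)
    radii: list[float] = []
    attempts = 0
    max_attempts = 200 * n
    sep2 = min_sep**2
    while len(centers) < n and attempts < max_attempts:
        attempts += 1
        radius = rng.uniform(*r_range)
        r = int(rng.integers(0, rows))
        c = int(rng.integers(0, cols))
        if dist[r, c] <= 2:
            continue
        if placed.size and (((placed[:, 0] - r) ** 2 + (placed[:, 1] - c) ** 2) < sep2).any():
            continue
        centers.append((r, c))
        placed = np.vstack([placed, (r, c)])
        radii.append(radius)
    if len(centers) < 3:
        raise ValueError("could not place enough nuclei; cortex too small")
    return centers, radii


def _mesh_segments(
    cortex: np.ndarray, centers: Sequence[tuple[int, int]]
) -> list[np.ndarray]:
    """Voronoi-boundary mesh over the nuclei, grouped per cell-cell edge.

    Returns a list of (k, 2) pixel-coordinate arrays, one per pair of
    adjacent Voronoi cells, each drawn ~2 px wide.
    """
    rr, cc = np.nonzero(cortex)
    _, lab = cKDTree(np.asarray(centers)).query(np.c_[rr, cc])
    label_img = np.full(cortex.shape, -1, dtype=np.int64)
    label_img[rr, cc] = lab

    pair_pixels: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def _collect(a_idx, b_idx, off):
        a = label_img[a_idx]
        b = label_img[b_idx]
        where = (a >= 0) & (b >= 0) & (a != b)
        pr, pc = np.nonzero(where)
        if off == "h":
            coords = [((r, c), (r, c + 1)) for r, c in zip(pr, pc)]
            labs = [(a[r, c], b[r, c]) for r, c in zip(pr, pc)]
        else:
            coords = [((r, c), (r + 1, c)) for r, c in zip(pr, pc)]
            labs = [(a[r, c], b[r, c]) for r, c in zip(pr, pc)]
        for (p1, p2), (l1, l2) in zip(coords, labs):
            key = (min(l1, l2), max(l1, l2))
            pair_pixels.setdefault(key, []).extend([p1, p2])

    _collect((slice(None), slice(None, -1)), (slice(None), slice(1, None)), "h")
    _collect((slice(None, -1), slice(None)), (slice(1, None), slice(None)), "v")

    return [np.unique(np.asarray(px), axis=0) for px in pair_pixels.values()]


def _outline_segments(cortex: np.ndarray, chunk: int = 24) -> list[np.ndarray]:
    """Cortex surface sheath (3 px wide) split into removable chunks."""
    inner = ndimage.binary_erosion(
        cortex, structure=np.ones((3, 3), dtype=bool), iterations=3, border_value=1
    )
    outline = cortex & ~inner
    pr, pc = np.nonzero(outline)
    # group outline pixels into local tiles so chunks are contiguous-ish
    keys = (pr // 16) * 10000 + pc // chunk
    segments = []
    for key in np.unique(keys):
        sel = keys == key
        segments.append(np.c_[pr[sel], pc[sel]])
    return segments


def _globule_layout(
    shape: tuple[int, int], n: int, r0: int, r1: int
) -> list[tuple[int, int]]:
    """Fixed, stereotyped globule positions alternating between cortex bands."""
    rows, cols = shape
    top_row = (MARGIN + r0) // 2
    bottom_row = (r1 + rows - MARGIN) // 2
    per_band = (n + 1) // 2
    usable = cols - 2 * MARGIN
    positions = []
    for i in range(n):
        band_row = top_row if i % 2 == 0 else bottom_row
        slot = i // 2
        col = MARGIN + int((slot + 0.5) * usable / per_band)
        positions.append((band_row, col))
    return positions


def _cg_mask(
    rng: np.random.Generator,
    spec: FixtureSpec,
    cortex: np.ndarray,
    centers: Sequence[tuple[int, int]],
    globularity: float,
    r0: int,
    r1: int,
) -> np.ndarray:
    segments = _mesh_segments(cortex, centers) + _outline_segments(cortex)
    order = rng.permutation(len(segments))
    n_keep = int(round((1.0 - globularity) * len(segments)))
    mask = np.zeros(spec.shape, dtype=bool)
    for idx in order[:n_keep]:
        px = segments[idx]
        mask[px[:, 0], px[:, 1]] = True
    mask &= cortex

    positions = _globule_layout(spec.shape, spec.n_globules, r0, r1)
    radii = rng.uniform(8.0, 14.0, size=spec.n_globules)
    n_globules = int(round(globularity * spec.n_globules))
    globs = np.zeros(spec.shape, dtype=bool)
    for (r, c), rad in list(zip(positions, radii))[:n_globules]:
        _stamp_disk(globs, (r, c), rad)
    return mask | (globs & cortex)


def _astro_mask(
    rng: np.random.Generator,
    spec: FixtureSpec,
    cortex: np.ndarray,
    neuropil: np.ndarray,
    infiltration: float,
    r0: int,
    r1: int,
) -> tuple[np.ndarray, int, list[tuple[int, int]]]:
    rows, cols = spec.shape
    bodies = np.zeros(spec.shape, dtype=bool)
    body_centers: list[tuple[int, int]] = []
    usable = cols - 2 * MARGIN
    per_side = (spec.n_cell_bodies + 1) // 2
    for i in range(spec.n_cell_bodies):
        slot = i // 2
        col = MARGIN + int((slot + 0.5) * usable / max(per_side, 1))
        col += int(rng.integers(-4, 5))
        col = int(np.clip(col, MARGIN + 8, cols - MARGIN - 8))
        # seated at the interface, nudged into the cortex
        row = (r0 - 4) if i % 2 == 0 else (r1 + 3)
        radius = rng.uniform(5.0, 7.0)
        _stamp_disk(bodies, (row, col), radius)
        body_centers.append((row, col))

    # fine processes radiating into the neuropil; anchored at the cell
    # bodies (or fixed interface anchors when bodies are absent) so each
    # arborization stays one large connected structure
    processes = np.zeros(spec.shape, dtype=bool)
    if body_centers:
        walk_roots = list(body_centers)
    else:
        walk_roots = [
            (r0 + 2 if i % 2 == 0 else r1 - 3, MARGIN + int((i // 2 + 0.5) * usable / 4))
            for i in range(8)
        ]
    for root_r, root_c in walk_roots * 2:
        r, c = root_r, root_c
        for _ in range(int(rng.integers(100, 160))):
            if neuropil[r, c]:
                processes[r, c] = True
                if rng.random() < 0.5 and neuropil[r, c + 1]:
                    processes[r, c + 1] = True
            step = rng.integers(0, 4)
            r += (-1, 1, 0, 0)[step]
            c += (0, 0, -1, 1)[step]
            r = int(np.clip(r, r0, r1 - 1))
            c = int(np.clip(c, MARGIN, cols - MARGIN - 1))

    # cortex-penetrating processes, grown until the planted target is hit
    cortex_area = int(np.count_nonzero(cortex))
    target = int(round(infiltration * cortex_area))
    # clearance wide enough that blur halos cannot bridge a process onto a
    # body after binarization (merged objects would evade the body filter)
    forbidden = ndimage.binary_dilation(
        bodies, structure=np.ones((3, 3), dtype=bool), iterations=3
    )
    available = int(np.count_nonzero(cortex & ~forbidden))
    if target > available:
        raise ValueError(
            f"infeasible infiltration target {target} px (only {available} free cortex px)"
        )
    infil = np.zeros(spec.shape, dtype=bool)
    count = 0
    guard = 0
    while count < target:
        guard += 1
        if guard > 100000:
            raise RuntimeError("infiltration steering failed to converge")
        top = bool(rng.integers(0, 2))
        r = (r0 - 1) if top else r1
        dr = -1 if top else 1
        c = int(rng.integers(MARGIN + 1, cols - MARGIN - 2))
        for _ in range(int(rng.integers(15, 45))):
            if not cortex[r, c] or forbidden[r, c]:
                break
            for cc_ in (c, c + 1):  # 2 px wide
                if cortex[r, cc_] and not forbidden[r, cc_] and not infil[r, cc_]:
                    infil[r, cc_] = True
                    count += 1
                    if count == target:
                        break
            if count == target:
                break
            if rng.random() < 0.6:
                r += dr
            else:
                c += int(rng.choice((-1, 1)))

    astro = bodies | processes | infil
    return astro, count, body_centers


def _render(
    mask: np.ndarray,
    rng: np.random.Generator,
    blur_sigma: float,
    noise_sd: float,
) -> np.ndarray:
    # intensity levels: background 20 +/- 10 per image, foreground
    # 180 +/- 20 per object; pixel noise comes only from noise_sd
    img = np.full(mask.shape, rng.uniform(10.0, 30.0))
    labels, n_obj = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n_obj:
        values = rng.uniform(160.0, 200.0, size=n_obj + 1)
        img[mask] = values[labels[mask]]
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_plane(
    spec: FixtureSpec,
    z_index: int = 0,
    *,
    globularity: float | None = None,
    infiltration: float | None = None,
) -> tuple[np.ndarray, FixtureTruth]:
    """Generate one plane: ``(channels, truth)``.

    ``channels`` has shape ``(3, rows, cols)`` ordered (astrocyte,
    cortex glia, nuclei) to match :data:`gliaquant.stacks.CHANNELS`.
    Per-plane ``globularity`` / ``infiltration`` override the spec values,
    enabling depth-varying stacks.
    """
    g = spec.globularity if globularity is None else float(globularity)
    f = spec.infiltration_fraction if infiltration is None else float(infiltration)
    if not (0.0 <= g <= 1.0) or not (0.0 <= f <= 1.0):
        raise ValueError("globularity and infiltration must lie in [0, 1]")

    cortex, neuropil, r0, r1 = _regions(spec.shape)
    geom = _rng(spec.seed, z_index, 0)

    nuclei_centers, nuclei_radii = _place_nuclei(geom, cortex, spec.n_nuclei)
    nuclei_mask = np.zeros(spec.shape, dtype=bool)
    for center, radius in zip(nuclei_centers, nuclei_radii):
        _stamp_disk(nuclei_mask, center, radius)
    nuclei_mask &= cortex

    cg_mask = _cg_mask(geom, spec, cortex, nuclei_centers, g, r0, r1)
    astro_mask, infiltration_px, body_centers = _astro_mask(
        geom, spec, cortex, neuropil, f, r0, r1
    )

    channels = np.stack(
        [
            _render(astro_mask, _rng(spec.seed, z_index, 1), spec.blur_sigma, spec.noise_sd),
            _render(cg_mask, _rng(spec.seed, z_index, 2), spec.blur_sigma, spec.noise_sd),
            _render(nuclei_mask, _rng(spec.seed, z_index, 3), spec.blur_sigma, spec.noise_sd),
        ]
    )
    truth = FixtureTruth(
        cortex_mask=cortex,
        neuropil_mask=neuropil,
        nuclei_mask=nuclei_mask,
        cg_mask=cg_mask,
        astro_mask=astro_mask,
        true_infiltration_px=infiltration_px,
        true_cg_perimeter=total_perimeter(cg_mask),
        nuclei_centers=nuclei_centers,
        cell_body_centers=body_centers,
    )
    return channels, truth


def generate_stack(
    spec: FixtureSpec,
    globularity_profile: Sequence[float] | None = None,
    infiltration_profile: Sequence[float] | None = None,
    *,
    animal_id: str = "synthetic",
    group: str = "control",
    z_orientation: str = "ventral_first",
    path: str | Path | None = None,
) -> tuple[StackRecord, list[FixtureTruth]]:
    """Generate a full stack, optionally with depth-varying parameters.

    Profiles, when given, must have one value per plane.  If ``path`` is
    set the stack is also written as a ZCYX TIFF.
    """
    for name, profile in (
        ("globularity_profile", globularity_profile),
        ("infiltration_profile", infiltration_profile),
    ):
        if profile is not None and len(profile) != spec.n_planes:
            raise ValueError(f"{name} length must equal n_planes={spec.n_planes}")

    planes = []
    truths = []
    for z in range(spec.n_planes):
        g = None if globularity_profile is None else globularity_profile[z]
        f = None if infiltration_profile is None else infiltration_profile[z]
        channels, truth = generate_plane(spec, z, globularity=g, infiltration=f)
        planes.append(channels)
        truths.append(truth)
    data = np.stack(planes)
    if path is not None:
        write_stack(path, data)
    record = StackRecord(
        animal_id=animal_id, group=group, data=data, z_orientation=z_orientation
    )
    return record, truths


def generate_score_table(
    n_per_group: int = 10,
    *,
    groups: Sequence[str] = ("control", "driver1", "driver2"),
    group_ami_offsets: Sequence[float] = (0.0, -3.0, -6.0),
    ami_base: float = 12.0,
    ami_animal_sd: float = 1.0,
    ami_plane_sd: float = 0.5,
    intercept: float = 8.0,
    slope: float = -0.5,
    noise_sd: float = 0.5,
    n_planes: int = 11,
    seed: int = 0,
):
    """Synthetic score table with a planted linear AMI -> AIS link.

    Each animal draws a baseline AMI (group offset plus animal-level
    noise); plane AMIs scatter around it, and each plane's AIS is
    ``intercept + slope * ami + N(0, noise_sd)``.  With ``slope < 0`` and
    ``noise_sd = 0`` the table has an exact antitone AMI-AIS relationship;
    with ``slope = 0`` the two scores are independent (null table).
    """
    import pandas as pd

    if len(groups) != len(group_ami_offsets):
        raise ValueError("groups and group_ami_offsets must align")
    if noise_sd < 0 or ami_animal_sd < 0 or ami_plane_sd < 0:
        raise ValueError("noise standard deviations must be >= 0")
    rng = _rng(seed, 9000)
    z_norm = (
        100.0 * np.arange(n_planes) / (n_planes - 1) if n_planes > 1 else np.array([0.0])
    )
    rows = []
    for gi, (group, offset) in enumerate(zip(groups, group_ami_offsets)):
        for a in range(n_per_group):
            animal = f"{group}_{a:02d}"
            ami_animal = ami_base + offset + rng.normal(0.0, ami_animal_sd)
            for z in range(n_planes):
                ami = ami_animal + rng.normal(0.0, ami_plane_sd)
                ais = intercept + slope * ami + rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "z_index": z,
                        "z_norm": float(z_norm[z]),
                        "ami": float(ami),
                        "ais": float(ais),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deterministic presets exercising the threshold decision tree


def preset_clean(shape: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Bimodal image with large clean blobs: the Otsu branch."""
    img = np.full(shape, 20, dtype=np.uint8)
    mask = np.zeros(shape, dtype=bool)
    rows, cols = shape
    for r, c in ((rows // 5, cols // 4), (rows // 2, 3 * cols // 4), (4 * rows // 5, cols // 3)):
        _stamp_disk(mask, (r, c), 9.0)
    img[mask] = 200
    return img


def preset_blown_out(shape: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Dense sub-75 px speckle in the neuropil band: the Triangle branch.

    Otsu passes the speckle as foreground; despeckling the middle third
    removes well over 7% of its white pixels.
    """
    img = np.full(shape, 20, dtype=np.uint8)
    mask = np.zeros(shape, dtype=bool)
    rows, cols = shape
    _stamp_disk(mask, (rows // 6, cols // 2), 10.0)
    _stamp_disk(mask, (5 * rows // 6, cols // 2), 10.0)
    band_lo, band_hi = rows // 3, (2 * rows) // 3
    _stamp_disk(mask, ((band_lo + band_hi) // 2, cols // 4), 12.0)
    for r in range(band_lo + 2, band_hi - 2, 6):
        for c in range(6, cols - 6, 6):
            if abs(c - cols // 4) < 18:
                continue  # keep the large in-band blob isolated
            mask[r : r + 2, c : c + 2] = True
    img[mask] = 200
    return img


def preset_blacked_out(shape: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Under 2% foreground in a single large object: the Li/Yen branch."""
    img = np.full(shape, 20, dtype=np.uint8)
    rows, cols = shape
    img[rows // 8 : rows // 8 + 16, cols // 8 : cols // 8 + 15] = 200
    return img


# ---------------------------------------------------------------------------
# Fixture sets on disk (demo data + end-to-end tests)


def write_fixture_set(
    outdir: str | Path,
    *,
    n_animals: int = 3,
    n_planes: int = 5,
    shape: tuple[int, int] = (256, 256),
    groups: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 4.0,
    blur_sigma: float = 0.8,
    seed: int = 0,
    write_truth: bool = True,
) -> Path:
    """Write a directory of fixture stacks plus a ready-to-run config.

    One TIFF per animal per group (conditions from :data:`GROUP_PRESETS` by
    default), the ground-truth cortex mask of every plane (single-page
    TIFFs, for validating the segmentation), and ``config.yaml`` listing
    the stacks for :func:`gliaquant.pipeline.run_pipeline`.  Infiltration
    follows a mild mid-depth-peaked profile so depth-resolved statistics
    have structure to find.  Returns the config path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = dict(GROUP_PRESETS if groups is None else groups)

    entries = []
    stack_idx = 0
    for group, preset in groups.items():
        for a in range(n_animals):
            stack_idx += 1
            animal_id = f"{group}_{a:02d}"
            spec = FixtureSpec(
                shape=shape,
                n_planes=n_planes,
                globularity=preset["globularity"],
                infiltration_fraction=preset["infiltration"],
                noise_sd=noise_sd,
                blur_sigma=blur_sigma,
                seed=(seed * 1000 + stack_idx) % (2**31 - 1),
            )
            if n_planes > 1:
                depth = np.arange(n_planes) / (n_planes - 1)
                infil = preset["infiltration"] * (0.7 + 0.6 * np.sin(np.pi * depth))
            else:
                infil = [preset["infiltration"]]
            path = outdir / f"{animal_id}.tif"
            _, truths = generate_stack(
                spec,
                infiltration_profile=list(infil),
                animal_id=animal_id,
                group=group,
                path=path,
            )
            if write_truth:
                for z, truth in enumerate(truths):
                    tifffile.imwrite(
                        outdir / f"{animal_id}_z{z}_cortex.tif",
                        truth.cortex_mask.astype(np.uint8) * 255,
                    )
            entries.append(
                {
                    "path": path.name,
                    "animal_id": animal_id,
                    "group": group,
                    "z_orientation": "ventral_first",
                }
            )

    config = {
        "stacks": entries,
        "output_dir": "results",
        "seed": seed,
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
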