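"""Reading and bookkeeping for multi-channel confocal Z-stacks.

A stack is one animal's ventral nerve cord imaged as a series of z-planes,
each with three fluorescence channels: astrocytes (red), cortex glia (green)
and neuronal nuclei (blue).  Everything downstream works plane-by-plane, so
this module's job is to get pixel data out of multi-page TIFF files, attach
per-animal metadata (genotype group, z orientation) and map each plane onto
a normalized depth axis where 0 is the ventral surface and 100 the dorsal
surface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

#: Biological channel names in the canonical in-memory order.
CHANNELS: tuple[str, str, str] = ("astrocyte", "cortex_glia", "nuclei")

#: Default acquisition order (red, green, blue) -> position in the file.
DEFAULT_CHANNEL_MAP: dict[str, int] = {"astrocyte": 0, "cortex_glia": 1, "nuclei": 2}

VENTRAL_FIRST = "ventral_first"
DORSAL_FIRST = "dorsal_first"
_ORIENTATIONS = (VENTRAL_FIRST, DORSAL_FIRST)


@dataclass(frozen=True)
class Plane:
    """One channel of one z-plane, with identity and normalized depth."""

    animal_id: str
    group: str
    z_index: int
    z_norm: float | None
    channel: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.z_norm is not None and not (0.0 <= self.z_norm <= 100.0):
            raise ValueError("z_norm must lie in [0, 100]")


@dataclass
class StackRecord:
    """A three-channel z-stack for one animal.

    ``data`` has shape ``(n_planes, 3, rows, cols)`` with the channel axis
    ordered as :data:`CHANNELS`.  ``z_norm`` is filled by
    :func:`normalize_z`; it is ``None`` on a freshly read stack.
    """

    animal_id: str
    group: str
    data: np.ndarray
    z_orientation: str = VENTRAL_FIRST
    z_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[1] != len(CHANNELS):
            raise ValueError(
                "stack data must have shape (n_planes, 3, rows, cols); "
                f"got {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one plane")
        if np.issubdtype(self.data.dtype, np.signedinteger) or np.issubdtype(
            self.data.dtype, np.floating
        ):
            if (self.data < 0).any():
                raise ValueError("channel rasters must be non-negative intensities")
        if self.z_orientation not in _ORIENTATIONS:
            raise ValueError(f"z_orientation must be one of {_ORIENTATIONS}")
        if self.z_norm is not None:
            self.z_norm = np.asarray(self.z_norm, dtype=float)
            if self.z_norm.shape != (self.data.shape[0],):
                raise ValueError("z_norm length must equal the plane count")

    @property
    def n_planes(self) -> int:
        return int(self.data.shape[0])

    @property
    def plane_shape(self) -> tuple[int, int]:
        return tuple(self.data.shape[2:])  # type: ignore[return-value]

    def channel(self, z: int, name: str) -> np.ndarray:
        """Pixel raster for one channel of plane ``z``."""
        return self.data[z, CHANNELS.index(name)]

    def plane_channels(self, z: int) -> dict[str, np.ndarray]:
        """All three channel rasters of plane ``z`` keyed by channel name."""
        return {name: self.data[z, i] for i, name in enumerate(CHANNELS)}

    def iter_planes(self) -> Iterator[Plane]:
        for z in range(self.n_planes):
            zn = None if self.z_norm is None else float(self.z_norm[z])
            for i, name in enumerate(CHANNELS):
                yield Plane(self.animal_id, self.group, z, zn, name, self.data[z, i])


def _axes_to_zc(arr: np.ndarray, path: Path) -> np.ndarray:
    """Coerce the raw TIFF array into (Z, 3, rows, cols).

    Accepted dialects: 4-D ZCYX or ZYXC with a length-3 channel axis, a 3-D
    page series with channels interleaved (pages = 3 * n_planes), and a
    single RGB-style (rows, cols, 3) plane.
    """
    if arr.ndim == 4:
        if arr.shape[1] == 3:
            return arr
        if arr.shape[-1] == 3:
            return np.moveaxis(arr, -1, 1)
        raise ValueError(
            f"{path}: expected a length-3 channel axis in 4-D stack, got shape {arr.shape}"
        )
    if arr.ndim == 3:
        if arr.shape[0] % 3 == 0 and arr.shape[0] > 0:
            z = arr.shape[0] // 3
            return arr.reshape(z, 3, *arr.shape[1:])
        if arr.shape[-1] == 3:
            return np.moveaxis(arr, -1, 0)[None, ...]
        raise ValueError(
            f"{path}: page count {arr.shape[0]} is not a multiple of 3 channels"
        )
    raise ValueError(
        f"{path}: expected a multi-page 3-channel TIFF, got array of shape {arr.shape}"
    )


def read_stack(
    path: str | Path,
    *,
    group: str,
    animal_id: str | None = None,
    z_orientation: str = VENTRAL_FIRST,
    channel_map: Mapping[str, int] | None = None,
    keep_range: tuple[int, int] | None = None,
) -> StackRecord:
    """Read a 3-channel z-stack from a multi-page TIFF.

    Parameters
    ----------
    path:
        TIFF file with three channels per z-plane (ZCYX, ZYXC or interleaved
        page dialects all accepted).
    group:
        Genotype / condition label carried through to the score table.
    animal_id:
        Defaults to the file stem.
    z_orientation:
        ``"ventral_first"`` if plane 0 is the ventral surface, else
        ``"dorsal_first"``.  Orientation is required metadata; it is never
        inferred from the image content.
    channel_map:
        Mapping from biological channel name to its index along the file's
        channel axis.  Defaults to red=astrocyte, green=cortex glia,
        blue=nuclei.
    keep_range:
        Optional inclusive ``(first, last)`` plane indices to retain, for
        trimming out-of-focus planes at the ends of a stack.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            shapes = [tuple(p.shape) for p in tf.pages]
            if len(set(shapes)) > 1:
                ref = shapes[0]
                bad = next(i for i, s in enumerate(shapes) if s != ref)
                raise ValueError(
                    f"{path}: page {bad} has shape {shapes[bad]}, "
                    f"inconsistent with page 0 shape {ref}"
                )
            arr = tf.asarray()
    except ValueError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise ValueError(f"{path}: unreadable TIFF ({exc})") from exc

    arr = _axes_to_zc(np.asarray(arr), path)

    cmap = dict(DEFAULT_CHANNEL_MAP if channel_map is None else channel_map)
    if sorted(cmap.values()) != [0, 1, 2] or set(cmap) != set(CHANNELS):
        raise ValueError("channel_map must assign indices 0..2 to the three channels")
    order = [cmap[name] for name in CHANNELS]
    data = arr[:, order]

    if keep_range is not None:
        first, last = keep_range
        if not (0 <= first <= last < data.shape[0]):
            raise ValueError(
                f"keep_range {keep_range} outside plane range 0..{data.shape[0] - 1}"
            )
        data = data[first : last + 1]

    return StackRecord(
        animal_id=animal_id if animal_id is not None else path.stem,
        group=group,
        data=data,
        z_orientation=z_orientation,
    )


def write_stack(path: str | Path, data: np.ndarray, layout: str = "zcyx") -> None:
    """Write a ``(Z, 3, rows, cols)`` array to a multi-page TIFF.

    ``layout="zcyx"`` stores the 4-D array directly; ``layout="pages"``
    writes interleaved single-channel pages.  Both round-trip through
    :func:`read_stack`.
    """
    data = np.asarray(data)
    if data.ndim != 4 or data.shape[1] != 3:
        raise ValueError("data must have shape (n_planes, 3, rows, cols)")
    if layout == "zcyx":
        tifffile.imwrite(
            path, data, photometric="minisblack", metadata={"axes": "ZCYX"}
        )
    elif layout == "pages":
        tifffile.imwrite(
            path, data.reshape(-1, *data.shape[2:]), photometric="minisblack"
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")


def normalize_z(stack: StackRecord) -> StackRecord:
    """Attach normalized depth coordinates (ventral = 0, dorsal = 100).

    Plane index ``k`` of ``K`` planes maps to ``100 * k / (K - 1)`` for a
    ventral-first stack and the reverse for dorsal-first.  A single-plane
    stack gets ``z_norm = 0``.
    """
    k = stack.n_planes
    if k == 1:
        z = np.array([0.0])
    else:
        z = 100.0 * np.arange(k) / (k - 1)
    if stack.z_orientation == DORSAL_FIRST:
        z = z[::-1].copy()
    return dataclasses.replace(stack, z_norm=z)
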