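"""Shared data model and image primitives.

All assay modules operate on :class:`ImageStack` (a 5-D intensity grid with
physical metadata) and :class:`LabelMask` (integer-labeled 2-D regions).
Conventions used everywhere in the package:

* axis order ``(channel, time, z, y, x)``; 2-D images are stacks with
  singleton channel/time/z axes;
* y increases downward, pixel indices are 0-based, a pixel's site is its
  center;
* areas are reported as ``pixel_count * pixel_size_nm**2``;
* intensity thresholds are strict (``value > threshold``), so a uniform
  image never contains above-threshold structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "ImageStack",
    "LabelMask",
    "MetadataError",
    "FormatError",
    "read_stack",
    "write_stack",
    "background_subtract",
    "project",
    "label_regions",
    "make_summary_table",
    "write_table",
    "read_table",
]

AXES = ("channel", "time", "z", "y", "x")

SUMMARY_COLUMNS = ["scenario", "cell_id", "phagosome_id", "metric", "value", "units"]


class MetadataError(ValueError):
    """Physical metadata (pixel size, frame interval) missing or invalid."""


class FormatError(ValueError):
    """File could not be parsed as an image stack."""


@dataclass
class ImageStack:
    """n-D fluorescence intensity grid with acquisition geometry.

    ``data`` is always stored 5-D as (channel, time, z, y, x); use
    :meth:`from_array` to promote lower-dimensional arrays.
    """

    data: np.ndarray
    pixel_size_nm: float
    z_step_nm: float = 0.0
    frame_interval_s: float = 0.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"ImageStack data must be 5-D (c,t,z,y,x); got {self.data.ndim}-D"
            )
        if not (self.pixel_size_nm > 0):
            raise MetadataError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        pixel_size_nm: float,
        axes: str = "auto",
        **meta,
    ) -> "ImageStack":
        """Promote a 2-/3-/4-/5-D array to the canonical 5-D layout.

        With ``axes="auto"`` a 2-D array is (y, x), 3-D is (t, y, x), 4-D is
        (t, z, y, x), 5-D is (c, t, z, y, x).  Pass an explicit axes string
        (e.g. ``"zyx"``, ``"ctzyx"``) to override.
        """
        data = np.asarray(data)
        if axes == "auto":
            axes = {2: "yx", 3: "tyx", 4: "tzyx", 5: "ctzyx"}.get(data.ndim, "")
        if len(axes) != data.ndim or not set(axes) <= {"c", "t", "z", "y", "x"}:
            raise ValueError(f"cannot map {data.ndim}-D array with axes={axes!r}")
        full = data
        for ax, key in enumerate("ctzyx"):
            if key not in axes:
                full = np.expand_dims(full, ax)
        # reorder present axes into c,t,z,y,x
        order = [axes.index(k) for k in "ctzyx" if k in axes]
        if order != sorted(order):
            data = np.transpose(data, order)
            full = data
            for ax, key in enumerate("ctzyx"):
                if key not in axes:
                    full = np.expand_dims(full, ax)
        return cls(full, pixel_size_nm, **meta)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_planes(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def plane(self, channel: int = 0, time: int = 0, z: int = 0) -> np.ndarray:
        return self.data[channel, time, z]

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return replace(self, data=np.asarray(data))


@dataclass
class LabelMask:
    """Integer-labeled regions on a single (y, x) plane.

    Label 0 is background.  ``role`` names what the labels delineate
    (cell, phagosome, cytosol, bead_ingested, bead_free, ring).
    """

    labels: np.ndarray
    role: str = "phagosome"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMask must be 2-D (y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMask labels must be integer")

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def region(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


# ---------------------------------------------------------------------------
# I/O


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF; metadata goes in the description tag."""
    meta = {
        "axes": "CTZYX",
        "shape": list(stack.data.shape),
        "pixel_size_nm": stack.pixel_size_nm,
        "z_step_nm": stack.z_step_nm,
        "frame_interval_s": stack.frame_interval_s,
        "channel_names": list(stack.channel_names),
    }
    pages = stack.data.reshape(-1, *stack.data.shape[3:])
    tifffile.imwrite(str(path), pages, photometric="minisblack",
                     description=json.dumps(meta))


def read_stack(path, **overrides) -> ImageStack:
    """Read a TIFF (single or multi-page) into an :class:`ImageStack`.

    Metadata written by :func:`write_stack` is honored; for foreign TIFFs
    ``pixel_size_nm`` must be supplied as an override or a
    :class:`MetadataError` is raised.  Overrides always win.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    meta = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except json.JSONDecodeError:
            pass
    shape = meta.get("shape")
    if shape is not None and int(np.prod(shape)) == data.size:
        data = data.reshape(shape)
    kwargs = {
        "pixel_size_nm": meta.get("pixel_size_nm"),
        "z_step_nm": meta.get("z_step_nm", 0.0),
        "frame_interval_s": meta.get("frame_interval_s", 0.0),
        "channel_names": list(meta.get("channel_names", [])),
    }
    kwargs.update(overrides)
    if kwargs["pixel_size_nm"] is None:
        raise MetadataError(
            f"{path}: pixel size not recorded in file; pass pixel_size_nm="
        )
    if data.ndim == 5:
        return ImageStack(data, **kwargs)
    return ImageStack.from_array(data, axes="auto", **kwargs)


def write_mask(path, mask: LabelMask) -> None:
    tifffile.imwrite(
        str(path), mask.labels.astype(np.uint16), description=json.dumps({"role": mask.role})
    )


def read_mask(path, role: str | None = None) -> LabelMask:
    with tifffile.TiffFile(str(path)) as tif:
        labels = tif.asarray().astype(np.int32)
        desc = tif.pages[0].description or "{}"
    try:
        stored = json.loads(desc).get("role", "phagosome")
    except (json.JSONDecodeError, AttributeError):
        stored = "phagosome"
    return LabelMask(labels, role=role or stored)


# ---------------------------------------------------------------------------
# Image primitives


def background_subtract(
    img: ImageStack,
    method: str = "percentile",
    param=1.0,
) -> ImageStack:
    """Subtract a per-frame scalar background estimate; clamp negatives to 0.

    method="percentile": the given percentile of each (c, t, z) plane.
    method="region": the mean over a background :class:`LabelMask` region.
    """
    data = img.data.astype(np.float64, copy=True)
    if method == "percentile":
        p = float(param)
        if not 0 < p < 100:
            raise ValueError(f"percentile must be in (0, 100), got {p}")
        bg = np.percentile(data, p, axis=(3, 4), keepdims=True)
    elif method == "region":
        if not isinstance(param, LabelMask):
            raise TypeError("region method requires a LabelMask param")
        region = param.foreground
        if not region.any():
            raise ValueError("background region mask is empty")
        bg = data[..., region].mean(axis=-1)[..., None, None]
    else:
        raise ValueError(f"unknown background method {method!r}")
    out = np.clip(data - bg, 0.0, None)
    return img.with_data(out)


def project(img: ImageStack, mode: str = "max", axis: str = "z") -> ImageStack:
    """Collapse the z axis by max or sum; metadata preserved (z becomes singleton)."""
    if axis != "z":
        raise ValueError("only z projection is supported")
    reducer = {"max": np.max, "sum": np.sum}.get(mode)
    if reducer is None:
        raise ValueError(f"unknown projection mode {mode!r}")
    out = reducer(img.data, axis=2, keepdims=True)
    return img.with_data(out)


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


def label_regions(binary: np.ndarray, connectivity: int = 8) -> LabelMask:
    """Label maximal connected components of a boolean grid.

    Components are numbered 1..n in raster order of their anchor pixel
    (first pixel reached scanning rows top to bottom, left to right).
    """
    binary = np.asarray(binary, bool)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    raw, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    if n == 0:
        return LabelMask(raw.astype(np.int32), role="component")
    # relabel by raster order of each component's first (anchor) pixel
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1)
    return LabelMask(remap[raw], role="component")


# ---------------------------------------------------------------------------
# Summary tables


def make_summary_table(rows) -> pd.DataFrame:
    """Build the shared long-format results table.

    ``rows`` is an iterable of dicts with keys scenario, cell_id,
    phagosome_id, metric, value, units (missing keys filled with NA/"").
    """
    df = pd.DataFrame(list(rows))
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[SUMMARY_COLUMNS]


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
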