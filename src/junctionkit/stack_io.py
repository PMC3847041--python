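"""Image-stack and tabular I/O.

Conventions fixed here and relied on by every downstream module:

* pixel coordinates are 0-based ``(row, column)``;
* time is measured in minutes from the start of the acquisition;
* on-disk stacks are OME-TIFF with axis order ``TZCYX``; plain multipage
  TIFFs are accepted on read when the missing metadata is supplied through
  a config mapping.

Spectral ("lambda") stacks are stored as single-timepoint OME-TIFFs whose
channels are named ``band-<center>nm``; the band centers are recovered from
those channel names on read.
"""
from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, InvalidParameterError

logger = logging.getLogger(__name__)

_BAND_NAME = re.compile(r"^band-([0-9.]+)nm$")
_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32)


@dataclass
class FrameStack:
    """A T x Z x C x Y x X intensity stack with acquisition metadata.

    Arrays of lower dimensionality are promoted on construction by
    prepending singleton axes (a 2D image becomes T=Z=C=1).
    """

    data: np.ndarray
    frame_interval: float = 1.0  # minutes between frames
    pixel_size: float = 1.0  # micrometres per pixel
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim > 5:
            raise InvalidParameterError(f"stack has {arr.ndim} axes, at most 5 supported")
        while arr.ndim < 5:
            arr = arr[np.newaxis]
        self.data = arr
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise InvalidParameterError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in minutes."""
        return np.arange(self.n_frames) * self.frame_interval

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """The (T, Z, Y, X) sub-stack of one channel."""
        idx = name_or_index if isinstance(name_or_index, int) else self.channel_index(name_or_index)
        return self.data[:, :, idx]


@dataclass
class SpectralStack:
    """A Y x X x B per-pixel emission spectrum image ("lambda stack")."""

    data: np.ndarray
    band_centers: np.ndarray  # nm, strictly increasing, length B

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.data.ndim != 3:
            raise InvalidParameterError("spectral stack must be Y x X x B")
        if self.data.shape[2] != self.band_centers.size:
            raise InvalidParameterError("band_centers length must match last axis")
        if self.band_centers.size < 3:
            raise InvalidParameterError("need at least 3 spectral bands")
        if not np.all(np.diff(self.band_centers) > 0):
            raise InvalidParameterError("band_centers must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.band_centers.size

    def pixels(self) -> np.ndarray:
        """Flattened (N, B) view of the per-pixel spectra."""
        return self.data.reshape(-1, self.n_bands)


# ---------------------------------------------------------------------------
# TIFF round trips
# ---------------------------------------------------------------------------

def _check_dtype(arr: np.ndarray) -> np.ndarray:
    if arr.dtype in (np.float64,):
        return arr.astype(np.float32)
    if not any(arr.dtype == d for d in _SUPPORTED_DTYPES):
        raise InvalidParameterError(
            f"unsupported dtype {arr.dtype}; use uint8, uint16 or float32"
        )
    return arr


def write_stack(stack: FrameStack | SpectralStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF (axes TZCYX; lambda stacks as CYX)."""
    path = Path(path)
    if isinstance(stack, SpectralStack):
        data = _check_dtype(np.moveaxis(stack.data, -1, 0))  # B,Y,X -> C axis
        names = [f"band-{c:.2f}nm" for c in stack.band_centers]
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={"axes": "CYX", "Channel": {"Name": names}},
        )
        return
    data = _check_dtype(stack.data)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "TZCYX",
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": stack.frame_interval,
            "TimeIncrementUnit": "min",
        },
    )


def _parse_ome(xml_text: str) -> dict:
    """Pull axis metadata out of an OME-XML blob (namespace-agnostic)."""
    meta: dict = {"channel_names": []}
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return meta
    for elem in root.iter():
        tag = elem.tag.rsplit("}", 1)[-1]
        if tag == "Pixels":
            for key in ("PhysicalSizeX", "TimeIncrement"):
                if key in elem.attrib:
                    meta[key] = float(elem.attrib[key])
        elif tag == "Channel" and "Name" in elem.attrib:
            meta["channel_names"].append(elem.attrib["Name"])
    return meta


def read_stack(
    path: str | Path, config: Mapping | None = None
) -> FrameStack | SpectralStack:
    """Read an OME-TIFF (or plain TIFF plus ``config`` metadata).

    Returns a :class:`SpectralStack` when every channel is named
    ``band-<nm>nm``, otherwise a :class:`FrameStack` with axes normalised
    to TZCYX.  Metadata missing from the file is taken from ``config``
    (keys ``frame_interval``, ``pixel_size``, ``axes``, ``channel_names``)
    with a logged warning.
    """
    path = Path(path)
    config = dict(config or {})
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            ome_meta = _parse_ome(tif.ome_metadata) if tif.ome_metadata else {}
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt files
        raise FormatError(f"cannot read {path}: {exc}") from exc

    names = ome_meta.get("channel_names") or list(config.get("channel_names", []))
    band_centers = _band_centers_from_names(names)
    if band_centers is not None and axes in ("CYX", "ZYX", "QYX"):
        return SpectralStack(np.moveaxis(data, 0, -1), band_centers)

    # normalise whatever axes we have onto TZCYX
    axes = config.get("axes", axes)
    known = "TZCYX"
    if any(a not in known for a in axes):
        # single unknown leading axis on a 3D stack defaults to T only if
        # the caller sanctioned it via config; otherwise refuse.
        raise FormatError(
            f"cannot map axes {axes!r} of {path} onto TZCYX; "
            "supply config={'axes': ...}"
        )
    if len(axes) != data.ndim:
        raise FormatError(f"axes {axes!r} do not match data of ndim {data.ndim}")
    order = [axes.index(a) for a in known if a in axes]
    data = np.transpose(data, order)
    for i, a in enumerate(known):
        if a not in axes:
            data = np.expand_dims(data, i)

    def _meta(file_key: str, config_key: str, default: float) -> float:
        if file_key in ome_meta:
            return ome_meta[file_key]
        if config_key in config:
            return float(config[config_key])
        logger.warning(
            "%s: no %s in file or config, defaulting to %s", path.name, config_key, default
        )
        return default

    return FrameStack(
        data,
        frame_interval=_meta("TimeIncrement", "frame_interval", 1.0),
        pixel_size=_meta("PhysicalSizeX", "pixel_size", 1.0),
        channel_names=list(names) if names else [],
    )


def _band_centers_from_names(names: Sequence[str]) -> np.ndarray | None:
    if len(names) < 3:
        return None
    centers = []
    for n in names:
        m = _BAND_NAME.match(n)
        if not m:
            return None
        centers.append(float(m.group(1)))
    return np.asarray(centers)


# ---------------------------------------------------------------------------
# Tables and configuration
# ---------------------------------------------------------------------------

def write_table(records: Sequence[Mapping], path: str | Path) -> None:
    """Write homogeneous records to UTF-8 CSV with a header row."""
    records = list(records)
    if not records:
        raise InvalidParameterError("cannot write an empty record list")
    keys = tuple(records[0].keys())
    for r in records:
        if tuple(r.keys()) != keys:
            raise InvalidParameterError("records have heterogeneous fields")
    pd.DataFrame.from_records(records, columns=list(keys)).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
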