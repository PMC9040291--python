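"""Multi-channel 2-D image container and TIFF round-trip.

The universal input of every quantification stage is a small set of named
fluorescence channels (``aqp4``, ``lectin``, ``gfp``, ``tracer``, ``ptau``,
``nuclei`` -- any subset) sharing one raster geometry and one physical pixel
size in micrometres.  Images are stored as plain multi-page TIFF written in
ImageJ layout (so FIJI opens them with the correct calibration) plus a JSON
sidecar carrying the channel names and pixel size explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Image2D", "read_image", "write_image"]

KNOWN_CHANNELS = ("aqp4", "lectin", "gfp", "tracer", "ptau", "nuclei")


@dataclass
class Image2D:
    """Named intensity channels over one raster with physical calibration.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2-D float array (arbitrary
        fluorescence units, AU).  All channels must share one shape.
    pixel_size_um
        Physical edge length of a pixel in micrometres; must be positive.
    metadata
        Free-form provenance (source path, acquisition note, generator spec).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("Image2D requires at least one channel")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shape mismatch: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D (ndim={arr.ndim})")
            a = np.asarray(arr, dtype=np.float64)
            if np.any(a < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = a

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height_px(self) -> int:
        return self.shape[0]

    @property
    def width_px(self) -> int:
        return self.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None

    def area_mm2(self) -> float:
        """Raster area in mm^2 (pixel count x pixel_size_um^2 x 1e-6)."""
        h, w = self.shape
        return h * w * self.pixel_size_um**2 * 1e-6


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: Image2D, path: str | Path) -> Path:
    """Write an :class:`Image2D` as ImageJ-layout TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        path,
        stack,
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um", "axes": "CYX", "Labels": names},
    )
    sidecar = {
        "pixel_size_um": image.pixel_size_um,
        "channels": names,
        "metadata": {k: v for k, v in image.metadata.items() if _json_ok(v)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _json_ok(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel_names: list[str] | None = None,
) -> Image2D:
    """Read a TIFF into an :class:`Image2D`.

    Pixel size is resolved in order of trust: JSON sidecar, TIFF resolution
    tags, then the ``pixel_size_um`` override.  A plain TIFF with no
    calibration and no override is rejected rather than silently assuming a
    default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or CYX TIFF, got shape {arr.shape}")

    sidecar = _sidecar_path(path)
    side = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    px = side.get("pixel_size_um") or tag_px or pixel_size_um
    if px is None:
        raise ValueError(
            f"{path}: no pixel size in sidecar or TIFF tags; pass pixel_size_um"
        )

    names = channel_names or side.get("channels")
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[0])] if arr.shape[0] > 1 else ["ch0"]
    if len(names) != arr.shape[0]:
        raise ValueError(
            f"{len(names)} channel names for {arr.shape[0]} planes in {path}"
        )
    channels = {n: arr[i].astype(np.float64) for i, n in enumerate(names)}
    meta = dict(side.get("metadata", {}))
    meta.setdefault("source_path", str(path))
    return Image2D(channels=channels, pixel_size_um=float(px), metadata=meta)


def _pixel_size_from_tags(tif: "tifffile.TiffFile") -> float | None:
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    unit = page.tags.get("ResolutionUnit")
    # ImageJ writes unit "um" in its own metadata block; plain TIFF tags use
    # inch/cm and are not trusted for micrometre calibration here.
    ij = tif.imagej_metadata or {}
    if ij.get("unit") in ("um", "micron", "µm"):
        return den / num
    if unit is not None and getattr(unit, "name", "") == "NONE":
        return den / num
    return None
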