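"""Image container and multi-page TIFF I/O.

All arrays in this package are ordered ``(z, y, x)``: ``x`` is the
illumination axis of the light sheet (stripes run along it), ``z`` the
detection axis of the stack. Physical voxel sizes are carried as an
``(x, y, z)`` triple in micrometers, matching the usual metadata
convention; helpers translate to array order where needed.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_VOXEL_SIZE_UM = (0.645, 0.645, 1.0)


@dataclass
class ImageVolume:
    """A single-channel 3D intensity grid with physical voxel size.

    Parameters
    ----------
    data:
        3D array in ``(z, y, x)`` order. Stored as float; integer input
        is rescaled to ``[0, 1]`` by the dtype maximum.
    voxel_size_um:
        Physical voxel edge lengths ``(x, y, z)`` in micrometers.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3D (z, y, x) array, got ndim={arr.ndim}")
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
        else:
            arr = arr.astype(np.float64, copy=False)
        self.data = arr
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive lengths (x, y, z), got {vs}")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel size reordered to match the array axes (z, y, x)."""
        vx, vy, vz = self.voxel_size_um
        return (vz, vy, vx)

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data, self.voxel_size_um, dict(self.meta))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page float32 TIFF plus a JSON sidecar.

    Pages are z-slices. XY voxel size goes into the TIFF resolution
    tags (pixels per micrometer); the sidecar records the full voxel
    size, the axis order and the producing command line.
    """
    if not isinstance(vol, ImageVolume):
        vol = ImageVolume(np.asarray(vol))
    path = Path(path)
    vx, vy, vz = vol.voxel_size_um
    tifffile.imwrite(
        path,
        vol.data.astype(np.float32),
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
        imagej=True,
    )
    sidecar = {
        "voxel_size_um": list(vol.voxel_size_um),
        "axis_order": "zyx",
        "command": " ".join(sys.argv),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(
    path: str | Path,
    voxel_size_override: tuple[float, float, float] | None = None,
) -> ImageVolume:
    """Load a multi-page TIFF as a ``(z, y, x)`` volume.

    Voxel size resolution order (highest priority last): TIFF
    resolution tags, JSON sidecar, explicit override. Missing
    everywhere is an error. 16-bit integer data is converted to float
    in ``[0, 1]`` by dividing by the dtype maximum.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        voxel = _voxel_from_tags(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {arr.shape}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "voxel_size_um" in meta:
            voxel = tuple(float(v) for v in meta["voxel_size_um"])
    if voxel_size_override is not None:
        voxel = tuple(float(v) for v in voxel_size_override)
    if voxel is None:
        raise ValueError(
            f"{path}: voxel size not found in TIFF tags or sidecar and no override given"
        )
    return ImageVolume(arr, voxel)


def _voxel_from_tags(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    vx = xres[1] / xres[0] if xres[0] else None
    vy = yres[1] / yres[0] if yres[0] else None
    vz = None
    if tif.imagej_metadata:
        vz = tif.imagej_metadata.get("spacing")
    if vx is None or vy is None or vz is None:
        return None
    return (float(vx), float(vy), float(vz))
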