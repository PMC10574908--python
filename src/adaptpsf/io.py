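"""Image, curve and report I/O.

Images travel as 8/16-bit TIFF or PNG, 32-bit float TIFF for metric maps, or
raw binary with a JSON sidecar (shape, dtype, endianness). Internally all
pixels are float64 ADU; quantization happens only at write time.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InputError

__all__ = ["read_image", "write_image", "read_curve_csv", "write_curve_csv"]


def read_image(path: str | Path, with_meta: bool = False):
    """Read a 2D image to float64.

    8-bit inputs are promoted to the working range unchanged (values stay
    0–255; the recorded scale notes the source bit depth). Raw ``.raw``
    payloads need a sibling ``.json`` sidecar with keys shape, dtype and
    (optionally) endianness; a payload whose size disagrees with the sidecar
    raises an integrity error.
    """
    path = Path(path)
    meta: dict = {"path": str(path)}
    if path.suffix.lower() == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise InputError(f"raw image {path} has no JSON sidecar {sidecar}")
        spec = json.loads(sidecar.read_text())
        dtype = np.dtype(spec["dtype"])
        if spec.get("endianness") == "big":
            dtype = dtype.newbyteorder(">")
        shape = tuple(spec["shape"])
        payload = np.fromfile(path, dtype=dtype)
        if payload.size != int(np.prod(shape)):
            raise InputError(
                f"sidecar shape {shape} disagrees with payload of {payload.size} items"
            )
        arr = payload.reshape(shape)
        meta["dtype"] = str(dtype)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        meta["dtype"] = str(arr.dtype)
    elif path.suffix.lower() == ".png":
        arr = iio.imread(path)
        meta["dtype"] = str(arr.dtype)
    else:
        raise InputError(f"unsupported image container {path.suffix!r}")
    if arr.ndim == 3 and arr.shape[2] in (3, 4):  # color PNG: luminance only
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2:
        raise InputError(f"expected a 2D image, got shape {arr.shape}")
    if arr.dtype.itemsize == 1:
        meta["promoted_from"] = "8-bit"
        meta["scale"] = 255.0
    elif np.issubdtype(arr.dtype, np.integer):
        meta["scale"] = float(np.iinfo(arr.dtype).max)
    out = arr.astype(np.float64)
    return (out, meta) if with_meta else out


def write_image(img: np.ndarray, path: str | Path, dtype: str = "uint16") -> None:
    """Write a 2D image; uint16 (clipped/rounded) or float32 TIFF.

    The 16-bit path is lossless for integer-valued data in [0, 65535];
    float maps should use dtype='float32'.
    """
    path = Path(path)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InputError("can only write 2D images")
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "uint16":
        data = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = arr.astype(np.float32)
    else:
        raise InputError(f"unsupported output dtype {dtype!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        if dtype == "float32":
            raise InputError("PNG cannot hold float32 maps; use TIFF")
        iio.imwrite(path, data)
    else:
        raise InputError(f"unsupported image container {path.suffix!r}")


def write_curve_csv(path: str | Path, x: np.ndarray, y: np.ndarray, header: str) -> None:
    """Two-column CSV for MTF/LSF/score curves."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.column_stack([x, y]), delimiter=",", header=header, comments="")


def read_curve_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2:
        raise InputError(f"{path} is not a two-column curve CSV")
    return data[:, 0], data[:, 1]
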