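"""File I/O: masks, k-space data, images, iteration logs.

Lossless paths use NPY (complex arrays) and HDF5; human-viewable paths use
8/16-bit PNG of magnitudes and NIfTI (complex images stored as a trailing
real/imaginary channel pair).  All writes are atomic: data goes to a
temporary file in the target directory which is then renamed into place.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .sampling import KSpaceData, SamplingMask

__all__ = [
    "atomic_write",
    "save_mask", "load_mask",
    "save_kspace", "load_kspace",
    "save_image_npy", "load_image_npy",
    "save_image_png", "save_image_nifti", "load_image_nifti",
    "save_json", "load_json",
]


def atomic_write(path, writer):
    """Call ``writer(tmp_path)`` then atomically rename onto ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # keep the real suffix so format-sniffing writers (np.save, nibabel)
    # treat the temporary file exactly like the final one
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-",
                               suffix=path.suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def save_mask(mask: SamplingMask, path) -> None:
    """Write a mask as NPY (bool) or PNG (0/255), by extension."""
    path = Path(path)
    if path.suffix == ".npy":
        atomic_write(path, lambda tmp: np.save(tmp, mask.keep,
                                               allow_pickle=False))
    elif path.suffix == ".png":
        img = Image.fromarray((mask.keep * np.uint8(255)))
        atomic_write(path, lambda tmp: img.save(tmp, format="PNG"))
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")


def load_mask(path, scheme: str = "file", seed: int | None = None) -> SamplingMask:
    path = Path(path)
    if path.suffix == ".npy":
        keep = np.load(path).astype(bool)
    elif path.suffix == ".png":
        keep = np.asarray(Image.open(path)) > 127
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")
    return SamplingMask(keep=keep, scheme=scheme, seed=seed)


def save_kspace(b: KSpaceData, path) -> None:
    """Write k-space values + mask + sigma to HDF5."""
    def writer(tmp):
        with h5py.File(tmp, "w") as f:
            f.create_dataset("values", data=b.values)
            f.create_dataset("mask", data=b.mask.keep)
            f.attrs["sigma"] = b.sigma
            f.attrs["scheme"] = b.mask.scheme
            f.attrs["seed"] = -1 if b.mask.seed is None else b.mask.seed

    atomic_write(path, writer)


def load_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        keep = f["mask"][...].astype(bool)
        sigma = float(f.attrs["sigma"])
        scheme = str(f.attrs["scheme"])
        seed = int(f.attrs["seed"])
    mask = SamplingMask(keep=keep, scheme=scheme,
                        seed=None if seed < 0 else seed)
    return KSpaceData(values=values, mask=mask, sigma=sigma)


def save_image_npy(u: np.ndarray, path) -> None:
    atomic_write(path, lambda tmp: np.save(tmp, np.asarray(u),
                                           allow_pickle=False))


def load_image_npy(path) -> np.ndarray:
    return np.load(path)


def save_image_png(u: np.ndarray, path, bits: int = 8,
                   vmax: float | None = None) -> None:
    """Write the magnitude of an image as 8- or 16-bit grayscale PNG."""
    mag = np.abs(np.asarray(u)).astype(float)
    if vmax is None:
        vmax = mag.max() or 1.0
    scale = (2 ** bits - 1) / vmax
    arr = np.clip(mag * scale, 0, 2 ** bits - 1)
    if bits == 8:
        img = Image.fromarray(arr.astype(np.uint8), mode="L")
    elif bits == 16:
        img = Image.fromarray(arr.astype(np.uint16))
    else:
        raise ValueError("bits must be 8 or 16")
    atomic_write(path, lambda tmp: img.save(tmp, format="PNG"))


def save_image_nifti(u: np.ndarray, path) -> None:
    """Write a (possibly complex) image as NIfTI with real/imag channels."""
    import nibabel as nib

    u = np.asarray(u)
    data = np.stack([u.real, u.imag], axis=-1).astype(np.float64)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    atomic_write(path, lambda tmp: nib.save(img, tmp))


def load_image_nifti(path) -> np.ndarray:
    import nibabel as nib

    data = np.asarray(nib.load(path).dataobj)
    if data.ndim == 3 and data.shape[-1] == 2:
        return data[..., 0] + 1j * data[..., 1]
    return data


def save_json(obj, path) -> None:
    atomic_write(path, lambda tmp: Path(tmp).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n"))


def load_json(path):
    return json.loads(Path(path).read_text())
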