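"""Interfile-like sinogram storage: a text header plus raw binary data.

``write_sinogram(sino, prefix)`` produces ``prefix.shdr`` (YAML text header
with dims, kind, scanner, bin size, dtype, byte order) and ``prefix.sraw``
(little-endian C-order array).  Count sinograms are stored as int64,
expected/ACF as float64.  An optional NIfTI export maps (plane, angle,
radial) onto voxel axes for quick viewing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidSpecError
from .projector import Sinogram

_HEADER_SUFFIX = ".shdr"
_DATA_SUFFIX = ".sraw"


def write_sinogram(sino: Sinogram, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    dtype = "<i8" if sino.kind in ("prompts", "trues", "scatter") else "<f8"
    arr = np.asarray(sino.data).astype(dtype)
    header = {
        "format": "neuropetsim-sinogram-1",
        "kind": sino.kind,
        "scanner": sino.scanner_name,
        "shape": list(arr.shape),           # [n_planes, n_angles, n_radial]
        "radial_bin_size_mm": float(sino.radial_bin_size_mm),
        "dtype": dtype,
        "byte_order": "little",
        "data_file": prefix.name + _DATA_SUFFIX,
        "total_counts": float(arr.sum()),
    }
    hpath = prefix.with_suffix(prefix.suffix + _HEADER_SUFFIX)
    dpath = prefix.with_suffix(prefix.suffix + _DATA_SUFFIX)
    hpath.write_text(yaml.safe_dump(header, sort_keys=False))
    arr.tofile(dpath)
    return hpath, dpath


def read_sinogram(prefix_or_header) -> Sinogram:
    p = Path(prefix_or_header)
    hpath = p if p.suffix == _HEADER_SUFFIX else p.with_suffix(p.suffix + _HEADER_SUFFIX)
    header = yaml.safe_load(hpath.read_text())
    if header.get("format") != "neuropetsim-sinogram-1":
        raise InvalidSpecError(f"{hpath}: not a recognised sinogram header")
    dpath = hpath.parent / header["data_file"]
    arr = np.fromfile(dpath, dtype=np.dtype(header["dtype"])).reshape(header["shape"])
    return Sinogram(arr, kind=header["kind"], scanner_name=header.get("scanner", ""),
                    radial_bin_size_mm=header.get("radial_bin_size_mm", 1.0))


def sinogram_to_nifti(sino: Sinogram, path) -> None:
    """Viewing convenience: store the (radial, angle, plane) stack as NIfTI."""
    import nibabel as nib

    data = np.ascontiguousarray(np.moveaxis(np.asarray(sino.data, dtype=np.float64), 0, 2))
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
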