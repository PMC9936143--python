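"""Reading and writing HRTF sets as SOFA (SimpleFreeFieldHRIR) files.

SOFA files are netCDF-4 containers, which are HDF5 files with dimension
scales; this module reads and writes them through h5py.  The writer emits
the SimpleFreeFieldHRIR convention's mandatory variables and attributes
with netCDF-style dimension scales attached, so files round-trip losslessly
through this module and remain readable by netCDF-based SOFA tools.

Coordinate convention: SOFA source azimuths are measured counterclockwise
from the front (positive toward the listener's left), matching this
package's internal sign convention; only the wrapping differs (SOFA uses
[0, 360), internally [-180, 180)).
"""

from __future__ import annotations

import datetime

import h5py
import numpy as np

from .coords import wrap_degrees
from .hrtf import HRTFSet

__all__ = ["SOFAFormatError", "read_sofa", "write_sofa"]


class SOFAFormatError(Exception):
    """Raised when a file does not follow SimpleFreeFieldHRIR."""


_REQUIRED_VARS = ["Data.IR", "Data.SamplingRate", "SourcePosition"]


def _attach_dims(f: h5py.File, var: h5py.Dataset, dim_names: tuple[str, ...]):
    for axis, name in enumerate(dim_names):
        size = var.shape[axis]
        if name not in f:
            scale = f.create_dataset(name, shape=(size,), dtype="f4")
            scale.attrs["NAME"] = np.bytes_(
                "This is a netCDF dimension but not a netCDF variable."
            )
            scale.make_scale(name)
        var.dims[axis].attach_scale(f[name])


def write_sofa(hrtf: HRTFSet, path, title: str = "synthetic HRTF set") -> None:
    """Write an :class:`HRTFSet` as a SimpleFreeFieldHRIR SOFA file."""
    m, r, n = hrtf.ir.shape
    now = datetime.datetime.now().isoformat(sep=" ", timespec="seconds")
    with h5py.File(path, "w") as f:
        f.attrs.update(
            {
                "Conventions": "SOFA",
                "Version": "2.1",
                "SOFAConventions": "SimpleFreeFieldHRIR",
                "SOFAConventionsVersion": "1.0",
                "DataType": "FIR",
                "RoomType": "free field",
                "Title": title,
                "DateCreated": now,
                "DateModified": now,
                "APIName": "dynloc",
                "APIVersion": "0.1.0",
                "AuthorContact": "",
                "Organization": "",
                "License": "No license provided",
            }
        )

        def var(name, data, dims, units=None, vartype=None):
            d = f.create_dataset(name, data=np.asarray(data, dtype="f8"))
            if units is not None:
                d.attrs["Units"] = units
            if vartype is not None:
                d.attrs["Type"] = vartype
            _attach_dims(f, d, dims)
            return d

        az = wrap_degrees(hrtf.az_deg, lo=0.0)
        src = np.column_stack([az, hrtf.el_deg, np.full(m, 1.2)])
        var("Data.IR", hrtf.ir, ("M", "R", "N"))
        var("Data.SamplingRate", [hrtf.fs], ("I",), units="hertz")
        delay = np.zeros((m, r)) if hrtf.toa is None else hrtf.toa * hrtf.fs
        var("Data.Delay", delay, ("M", "R"))
        var("SourcePosition", src, ("M", "C"),
            units="degree, degree, metre", vartype="spherical")
        var("ListenerPosition", [[0.0, 0.0, 0.0]], ("I", "C"),
            units="metre", vartype="cartesian")
        var("ListenerView", [[1.0, 0.0, 0.0]], ("I", "C"),
            units="metre", vartype="cartesian")
        var("ListenerUp", [[0.0, 0.0, 1.0]], ("I", "C"),
            units="metre", vartype="cartesian")
        var("ReceiverPosition",
            [[[0.0], [0.09], [0.0]], [[0.0], [-0.09], [0.0]]], ("R", "C", "I"),
            units="metre", vartype="cartesian")
        var("EmitterPosition", [[[0.0], [0.0], [0.0]]], ("E", "C", "I"),
            units="metre", vartype="cartesian")


def read_sofa(path) -> HRTFSet:
    """Read a SimpleFreeFieldHRIR SOFA file into an :class:`HRTFSet`."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SOFAFormatError(f"not an HDF5/netCDF-4 file: {path}") from exc
    with f:
        conv = f.attrs.get("SOFAConventions")
        if conv is None:
            raise SOFAFormatError("missing global attribute 'SOFAConventions'")
        conv = conv.decode() if isinstance(conv, bytes) else str(conv)
        if conv != "SimpleFreeFieldHRIR":
            raise SOFAFormatError(
                f"unsupported SOFAConventions {conv!r}; need SimpleFreeFieldHRIR"
            )
        for name in _REQUIRED_VARS:
            if name not in f:
                raise SOFAFormatError(f"missing variable {name!r}")
        ir = np.asarray(f["Data.IR"], dtype=float)
        if ir.ndim != 3:
            raise SOFAFormatError("Data.IR must have dimensions (M, R, N)")
        if ir.shape[1] != 2:
            raise SOFAFormatError(
                f"expected 2 receivers (ears), found {ir.shape[1]}"
            )
        fs = float(np.ravel(f["Data.SamplingRate"])[0])
        src = np.asarray(f["SourcePosition"], dtype=float)
        if src.ndim != 2 or src.shape[0] != ir.shape[0] or src.shape[1] < 2:
            raise SOFAFormatError("SourcePosition must have dimensions (M, C)")
        az = wrap_degrees(src[:, 0])
        el = src[:, 1]
        toa = None
        if "Data.Delay" in f:
            delay = np.asarray(f["Data.Delay"], dtype=float)
            if delay.ndim == 2 and delay.shape == ir.shape[:2] and np.any(delay):
                toa = delay / fs
        return HRTFSet(az, el, fs, ir, toa)
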