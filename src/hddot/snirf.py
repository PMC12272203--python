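"""SNIRF (Shared Near Infrared Format) continuous-wave I/O on HDF5.

Writes and reads the standard CW layout: ``/nirs1/data1/dataTimeSeries``
(time x measurement), ``time``, per-measurement ``measurementList{i}``
groups (1-based source/detector/wavelength indices, dataType 1 = CW
amplitude), and ``/nirs1/probe`` with ``sourcePos3D`` / ``detectorPos3D``
in mm and the nominal wavelength table.  Covers the subset of the format
the pipeline produces and consumes; unknown wavelengths are accepted with
a warning (spectral unmixing later requires a matching extinction entry).
"""

from __future__ import annotations

import warnings

import h5py
import numpy as np
import pandas as pd

from .arrays import OptodeArray
from .preprocess import RawRecording

__all__ = ["write_snirf", "read_snirf"]


def _str_ds(group, name, value: str):
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(path, rec: RawRecording, optodes: OptodeArray) -> None:
    """Write a recording + probe geometry as a SNIRF CW amplitude file."""
    ch = rec.channels
    wl_table = sorted(set(float(w) for w in ch["wavelength"]))
    with h5py.File(path, "w") as f:
        _str_ds(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        _str_ds(meta, "SubjectID", rec.participant or "unknown")
        _str_ds(meta, "MeasurementDate", "unknown")
        _str_ds(meta, "MeasurementTime", "unknown")
        _str_ds(meta, "LengthUnit", "mm")
        _str_ds(meta, "TimeUnit", "s")
        _str_ds(meta, "FrequencyUnit", "Hz")
        data = nirs.create_group("data1")
        data.create_dataset(
            "dataTimeSeries", data=rec.intensity.T.astype(np.float64)
        )
        data.create_dataset("time", data=rec.times)
        for i, row in enumerate(ch.itertuples(index=False), start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=np.int32(row.source + 1))
            ml.create_dataset("detectorIndex", data=np.int32(row.detector + 1))
            ml.create_dataset(
                "wavelengthIndex", data=np.int32(wl_table.index(float(row.wavelength)) + 1)
            )
            ml.create_dataset("dataType", data=np.int32(1))
            ml.create_dataset("dataTypeIndex", data=np.int32(1))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wl_table, float))
        probe.create_dataset("sourcePos3D", data=np.asarray(optodes.source_positions))
        probe.create_dataset("detectorPos3D", data=np.asarray(optodes.detector_positions))


def read_snirf(path, known_wavelengths=(735.0, 850.0)) -> tuple[RawRecording, OptodeArray]:
    """Read a SNIRF CW file back into a recording and probe geometry.

    Separations are recomputed from the probe positions; the sampling rate
    from the time vector (uniform sampling required).
    """
    with h5py.File(path, "r") as f:
        nirs = f["nirs1"]
        if "probe" not in nirs:
            raise ValueError("SNIRF file missing required field: /nirs1/probe")
        probe = nirs["probe"]
        for req in ("sourcePos3D", "detectorPos3D", "wavelengths"):
            if req not in probe:
                raise ValueError(f"SNIRF probe missing required field: {req}")
        src = np.asarray(probe["sourcePos3D"])
        det = np.asarray(probe["detectorPos3D"])
        wl_table = np.asarray(probe["wavelengths"], float).ravel()
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"]).ravel()
        if ts.size == 0 or ts.shape[1] == 0:
            raise ValueError("SNIRF file contains zero channels")
        dt = np.diff(time)
        if len(dt) and (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise ValueError("non-uniform sampling in SNIRF time vector")
        fs = 1.0 / dt.mean() if len(dt) else 1.0
        rows = []
        n_meas = ts.shape[1]
        for i in range(1, n_meas + 1):
            ml = data[f"measurementList{i}"]
            s = int(np.asarray(ml["sourceIndex"])) - 1
            d = int(np.asarray(ml["detectorIndex"])) - 1
            wl = float(wl_table[int(np.asarray(ml["wavelengthIndex"])) - 1])
            rows.append((s, d, wl, float(np.linalg.norm(src[s] - det[d]))))
        meta = nirs.get("metaDataTags", {})
        subject = ""
        if "SubjectID" in meta:
            subject = np.asarray(meta["SubjectID"]).item().decode()
    ch = pd.DataFrame(rows, columns=["source", "detector", "wavelength", "separation"])
    unknown = sorted(set(ch["wavelength"]) - set(float(w) for w in known_wavelengths))
    if unknown:
        warnings.warn(
            f"unfamiliar wavelengths {unknown} nm; chromophore unmixing will "
            "need matching extinction entries"
        )
    rec = RawRecording(intensity=ts.T, fs=fs, channels=ch, participant=subject)
    arr = OptodeArray(
        source_positions=src,
        detector_positions=det,
        source_tile=np.zeros(len(src), dtype=int),
        detector_tile=np.zeros(len(det), dtype=int),
        wavelengths=tuple(wl_table),
    )
    return rec, arr
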