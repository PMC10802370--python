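"""Minimal SNIRF (HDF5) writer/reader for continuous-wave two-wavelength data.

Implements the subset of the SNIRF layout the pipeline needs:
``/formatVersion``, ``/nirs/metaDataTags``, ``/nirs/data1`` with one
``measurementList`` group per channel×wavelength (dataType 1, raw CW
amplitude), and ``/nirs/probe`` with wavelengths and 2-D optode positions.
Measurements are stored wavelength-minor in fixture channel order, so a
write→read round trip reproduces the intensity array exactly.
"""

from __future__ import annotations

import h5py
import numpy as np

from .probe import Probe
from .simulate import RawRecording

_STR = h5py.string_dtype(encoding="utf-8")


def write_snirf(recording: RawRecording, probe: Probe, path: str) -> None:
    I = recording.intensity
    n_ch, n_wl, n_t = I.shape
    src_labels = list(probe.sources)
    det_labels = list(probe.detectors)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=_STR)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for k, v in [("SubjectID", recording.subject),
                     ("MeasurementDate", "unknown"), ("MeasurementTime", "unknown"),
                     ("LengthUnit", "cm"), ("TimeUnit", "s"), ("FrequencyUnit", "Hz"),
                     ("ProbeFixture", recording.probe_name)]:
            meta.create_dataset(k, data=v, dtype=_STR)
        meta.create_dataset("VisitAgeMonths", data=float(recording.visit_age_months))

        data = nirs.create_group("data1")
        flat = I.reshape(n_ch * n_wl, n_t).T            # (T, M), wavelength-minor
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(n_t) / recording.fs)
        for c, ch in enumerate(probe.channels):
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{c * n_wl + w + 1}")
                ml.create_dataset("sourceIndex", data=src_labels.index(ch.source) + 1)
                ml.create_dataset("detectorIndex", data=det_labels.index(ch.detector) + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)

        pg = nirs.create_group("probe")
        pg.create_dataset("wavelengths", data=np.asarray(recording.wavelengths_nm, float))
        pg.create_dataset("sourcePos2D", data=np.array([probe.sources[s] for s in src_labels]))
        pg.create_dataset("detectorPos2D", data=np.array([probe.detectors[d] for d in det_labels]))
        pg.create_dataset("sourceLabels", data=np.array(src_labels, dtype=_STR))
        pg.create_dataset("detectorLabels", data=np.array(det_labels, dtype=_STR))


def read_snirf(path: str) -> RawRecording:
    with h5py.File(path, "r") as f:
        if "nirs" not in f or "probe" not in f["nirs"]:
            raise ValueError("not a SNIRF file: missing /nirs/probe group")
        nirs = f["nirs"]
        data = nirs["data1"]
        flat = np.asarray(data["dataTimeSeries"])       # (T, M)
        time = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(time))) if len(time) > 1 else 0.0
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"], float))
        n_wl = len(wavelengths)

        ml_names = sorted((k for k in data if k.startswith("measurementList")),
                          key=lambda s: int(s[len("measurementList"):]))
        order: list[tuple[int, int]] = []               # (channel key order, wavelengthIndex)
        chan_keys: list[tuple[int, int]] = []
        for name in ml_names:
            g = data[name]
            key = (int(g["sourceIndex"][()]), int(g["detectorIndex"][()]))
            if key not in chan_keys:
                chan_keys.append(key)
            order.append((chan_keys.index(key), int(g["wavelengthIndex"][()]) - 1))
        n_ch = len(chan_keys)
        I = np.empty((n_ch, n_wl, flat.shape[0]))
        for m, (c, w) in enumerate(order):
            I[c, w, :] = flat[:, m]

        meta = nirs.get("metaDataTags", {})
        def _tag(name, default):
            if name in meta:
                v = meta[name][()]
                return v.decode() if isinstance(v, bytes) else v
            return default
        return RawRecording(
            intensity=I, fs=fs, wavelengths_nm=wavelengths,
            probe_name=str(_tag("ProbeFixture", "bright_infant")),
            subject=str(_tag("SubjectID", "unknown")),
            visit_age_months=float(_tag("VisitAgeMonths", 24.0)))
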