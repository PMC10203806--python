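"""File formats: SNIRF recordings, montage/events tables, result CSVs.

The SNIRF writer/reader covers the subset of the standard this package
needs: raw continuous-wave intensities, the two wavelengths, sampling
rate, probe geometry and stimulus tables. The channel table (ROI labels
and short-channel flags, which SNIRF has no standard slot for) is carried
in a ``metaDataTags`` entry as TSV text, so a written file reads back to
an identical :class:`~emonirs.synth.NirsRecording`.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import NirsRecording

SNIRF_VERSION = "1.0"


def write_snirf(recording: NirsRecording, path: str | Path) -> None:
    """Write a recording to a SNIRF (HDF5) file."""
    n_ch, n_wl, n_t = recording.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=SNIRF_VERSION)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="sim")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        buf = _io.StringIO()
        recording.montage.to_csv(buf, sep="\t", index=False)
        meta.create_dataset("MontageTable", data=buf.getvalue())

        data = nirs.create_group("data1")
        # columns ordered channel-major, wavelength-minor
        series = recording.intensity.reshape(n_ch * n_wl, n_t).T
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset(
            "time", data=np.array([0.0, 1.0 / recording.rate_hz]))
        m = 1
        for i in range(n_ch):
            for w in range(n_wl):
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset(
                    "sourceIndex",
                    data=int(recording.montage.iloc[i]["source"]))
                ml.create_dataset(
                    "detectorIndex",
                    data=int(recording.montage.iloc[i]["detector"]))
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths",
                             data=np.asarray(recording.wavelengths_nm))
        n_src = int(recording.montage["source"].max())
        n_det = int(recording.montage["detector"].max())
        src = np.zeros((n_src, 2))
        det = np.zeros((n_det, 2))
        for _, row in recording.montage.iterrows():
            s, d = int(row["source"]) - 1, int(row["detector"]) - 1
            src[s] = (s * 50.0, 0.0)
            det[d] = (s * 50.0 + row["distance_mm"], 0.0)
        probe.create_dataset("sourcePos2D", data=src)
        probe.create_dataset("detectorPos2D", data=det)

        for k, (label, g) in enumerate(
                recording.events.groupby(["kind", "trial_type"], sort=False)
                if "kind" in recording.events.columns
                else recording.events.groupby(
                    [pd.Series("experimental", index=recording.events.index),
                     recording.events["trial_type"]], sort=False), start=1):
            kind, trial_type = label
            stim = nirs.create_group(f"stim{k}")
            stim.create_dataset("name", data=f"{kind}/{trial_type}")
            arr = np.column_stack([
                g["onset"].to_numpy(float),
                g["duration"].to_numpy(float),
                np.ones(len(g)),
            ])
            stim.create_dataset("data", data=arr)


def _read_str(ds) -> str:
    val = ds[()]
    return val.decode() if isinstance(val, bytes) else str(val)


def read_snirf(path: str | Path) -> NirsRecording:
    """Read a SNIRF file written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise ValueError("malformed SNIRF: missing /nirs group")
        nirs = f["nirs"]
        if "probe" not in nirs or "wavelengths" not in nirs["probe"]:
            raise ValueError("malformed SNIRF: missing probe/wavelengths")
        wavelengths = tuple(float(w) for w in nirs["probe/wavelengths"][()])
        if "data1" not in nirs:
            raise ValueError("malformed SNIRF: missing data1 group")
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"][()])
        time = np.asarray(data["time"][()])
        if len(time) == 2:
            rate_hz = 1.0 / float(time[1] - time[0])
        else:
            rate_hz = 1.0 / float(np.median(np.diff(time)))

        if "metaDataTags" not in nirs or "MontageTable" not in \
                nirs["metaDataTags"]:
            raise ValueError("malformed SNIRF: missing MontageTable tag")
        montage = pd.read_csv(
            _io.StringIO(_read_str(nirs["metaDataTags/MontageTable"])),
            sep="\t")

        n_wl = len(wavelengths)
        n_ch = series.shape[1] // n_wl
        intensity = series.T.reshape(n_ch, n_wl, -1)

        ev_rows = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            stim = nirs[key]
            name = _read_str(stim["name"])
            kind, _, trial_type = name.partition("/")
            for onset, duration, _ in np.atleast_2d(stim["data"][()]):
                ev_rows.append({"onset": float(onset),
                                "duration": float(duration),
                                "trial_type": trial_type, "kind": kind})
        events = pd.DataFrame(ev_rows).sort_values("onset") \
            .reset_index(drop=True) if ev_rows else \
            pd.DataFrame(columns=["onset", "duration", "trial_type", "kind"])

    return NirsRecording(
        intensity=intensity,
        rate_hz=rate_hz,
        wavelengths_nm=wavelengths,   # type: ignore[arg-type]
        montage=montage,
        events=events,
    )


def write_montage(montage: pd.DataFrame, path: str | Path) -> None:
    montage.to_csv(path, sep="\t", index=False)


def read_montage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"channel", "distance_mm", "roi", "is_short"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"montage table missing columns: {sorted(missing)}")
    return df
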