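"""Readers and writers for the standard on-disk formats.

EEG travels as BrainVision triplets (.vhdr/.vmrk/.eeg, IEEE float32) or
EDF; fNIRS as SNIRF v1 (HDF5); events as TSV with columns
onset_s / duration_s / label. Readers never mutate on-disk data, and every
writer/reader pair round-trips at float32 precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (EVENT_LABELS, EegRecording, EventTable,
                         FnirsRecording, MsfusionError)

# 32-channel cap layout (extended 10-20 names, actiCAP-style ordering)
NAMES_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2",
    "FC6", "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6",
    "TP9", "TP10", "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz",
    "O2", "PO10",
]

_MONTAGE_CACHE: dict = {}


def template_names(n_channels: int) -> list[str]:
    if n_channels == 32:
        return list(NAMES_32)
    return [f"E{i + 1:02d}" for i in range(n_channels)]


def template_positions(n_channels: int) -> np.ndarray:
    """Unit-sphere electrode positions from the 10-5 template (or a
    quasi-uniform hemisphere when no named layout fits)."""
    names = template_names(n_channels)
    if n_channels == 32:
        return positions_for_names(names)
    return _fibonacci_hemisphere(n_channels)


def positions_for_names(names: list[str]) -> np.ndarray:
    """Look up electrode positions in the built-in 10-5 montage."""
    if "1005" not in _MONTAGE_CACHE:
        import mne

        try:
            montage = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:
            montage = mne.channels.make_standard_montage("standard_1005")
        _MONTAGE_CACHE["1005"] = montage.get_positions()["ch_pos"]
    ch_pos = _MONTAGE_CACHE["1005"]
    missing = [n for n in names if n not in ch_pos]
    if missing:
        raise MsfusionError(f"channels not in the 10-5 template: {missing}")
    pos = np.asarray([ch_pos[n] for n in names], float)
    pos = pos - pos.mean(axis=0)
    return pos / np.linalg.norm(pos, axis=1, keepdims=True)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 0.1 + 0.9 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1 - z ** 2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# ---------------------------------------------------------------------------
# BrainVision

def write_brainvision(rec: EegRecording, path) -> None:
    """Write a BrainVision triplet (header, markers, float32 binary data)."""
    path = Path(path)
    if path.suffix != ".vhdr":
        raise MsfusionError("BrainVision header path must end in .vhdr")
    stem = path.stem
    eeg_name, vmrk_name = f"{stem}.eeg", f"{stem}.vmrk"
    interval_us = 1e6 / rec.fs
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names):
        lines.append(f"Ch{i + 1}={name},,1,µV")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    if rec.events is not None:
        for k, row in enumerate(rec.events.table.itertuples(), start=2):
            sample = int(round(row.onset_s * rec.fs)) + 1  # 1-based
            size = max(int(round(row.duration_s * rec.fs)), 1)
            mlines.append(f"Mk{k}=Stimulus,{row.label},{sample},{size},0")
    (path.parent / vmrk_name).write_text("\n".join(mlines) + "\n",
                                         encoding="utf-8")
    rec.data.astype("<f4").T.tofile(path.parent / eeg_name)


def read_eeg(path) -> EegRecording:
    """Read BrainVision (.vhdr) or EDF into an :class:`EegRecording`.

    Data are returned in microvolts; event annotations whose description
    matches the pipeline vocabulary are parsed into the event table, and
    channel positions are attached from the built-in 10-5 template when
    the file carries none.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise MsfusionError(f"no such file: {path}")
    if path.suffix == ".vhdr":
        for companion in (path.with_suffix(".vmrk"), path.with_suffix(".eeg")):
            if not companion.exists():
                raise MsfusionError(f"missing companion file: {companion}")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix in (".edf", ".EDF"):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise MsfusionError(f"unsupported EEG format: {path.suffix}")

    data = raw.get_data(units="uV")
    names = list(raw.ch_names)
    onsets, durations, labels = [], [], []
    for ann in raw.annotations:
        desc = ann["description"].split("/")[-1].strip()
        if desc in EVENT_LABELS:
            onsets.append(float(ann["onset"]))
            durations.append(float(ann["duration"]))
            labels.append(desc)
    if onsets and np.any(np.diff(onsets) < 0):
        warnings.warn("event onsets were unsorted; sorting")
    events = (EventTable.from_arrays(onsets, durations, labels)
              if onsets else None)
    try:
        pos = positions_for_names(names)
    except MsfusionError:
        pos = _fibonacci_hemisphere(len(names))
    return EegRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_names=names, channel_positions=pos,
                        events=events)


# ---------------------------------------------------------------------------
# SNIRF

def write_snirf(rec: FnirsRecording, path) -> None:
    """Write a minimal SNIRF v1 file (continuous-wave amplitude)."""
    if rec.intensity is None:
        raise MsfusionError("SNIRF writer needs raw intensities")
    n_wl, n_ch, n_t = rec.intensity.shape
    cols = rec.intensity.reshape(n_wl * n_ch, n_t).T  # time x measurement
    str_dt = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=str_dt,
                         track_times=False)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for key, val in [("SubjectID", rec.meta.get("subject", "synthetic")),
                         ("MeasurementDate", "2000-01-01"),
                         ("MeasurementTime", "00:00:00"),
                         ("LengthUnit", "mm"), ("TimeUnit", "s"),
                         ("FrequencyUnit", "Hz")]:
            meta.create_dataset(key, data=val, dtype=str_dt,
                                track_times=False)
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=cols,
                             track_times=False)
        data1.create_dataset("time", data=np.array([0.0, 1.0 / rec.fs]),
                             track_times=False)
        k = 0
        for wl in range(n_wl):
            for ch in range(n_ch):
                row = rec.channel_table.iloc[ch]
                ml = data1.create_group(f"measurementList{k + 1}")
                ml.create_dataset("sourceIndex", data=int(row["source"]),
                                  track_times=False)
                ml.create_dataset("detectorIndex", data=int(row["detector"]),
                                  track_times=False)
                ml.create_dataset("wavelengthIndex", data=wl + 1,
                                  track_times=False)
                ml.create_dataset("dataType", data=1, track_times=False)
                ml.create_dataset("dataTypeIndex", data=1, track_times=False)
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths),
                             track_times=False)
        probe.create_dataset("sourcePos3D", data=np.asarray(rec.source_pos),
                             track_times=False)
        probe.create_dataset("detectorPos3D", data=np.asarray(rec.detector_pos),
                             track_times=False)
        n_src = rec.source_pos.shape[0]
        n_det = rec.detector_pos.shape[0]
        probe.create_dataset(
            "sourceLabels", track_times=False,
            data=np.array([f"S{i + 1}" for i in range(n_src)], dtype=str_dt))
        probe.create_dataset(
            "detectorLabels", track_times=False,
            data=np.array([f"D{i + 1}" for i in range(n_det)], dtype=str_dt))


def read_fnirs(path, ss_threshold_mm: float = 15.0) -> FnirsRecording:
    """Read a SNIRF v1 file.

    Channels are classified short- vs long-separation by source-detector
    distance (threshold ``ss_threshold_mm``); an error is raised when the
    file carries no probe geometry.
    """
    path = Path(path)
    if not path.exists():
        raise MsfusionError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        nirs = f["nirs1"] if "nirs1" in f else f["nirs"]
        data1 = nirs["data1"]
        cols = np.asarray(data1["dataTimeSeries"])  # time x measurement
        time = np.asarray(data1["time"]).ravel()
        if time.size == 2:
            fs = 1.0 / (time[1] - time[0])
        else:
            fs = 1.0 / np.median(np.diff(time))
        ml_names = sorted((k for k in data1 if k.startswith("measurementList")),
                          key=lambda s: int(s[len("measurementList"):]))
        src_i, det_i, wl_i = [], [], []
        for name in ml_names:
            g = data1[name]
            src_i.append(int(np.asarray(g["sourceIndex"])))
            det_i.append(int(np.asarray(g["detectorIndex"])))
            wl_i.append(int(np.asarray(g["wavelengthIndex"])))
        probe = nirs["probe"]
        wavelengths = np.asarray(probe["wavelengths"]).ravel()
        pos_key_s = "sourcePos3D" if "sourcePos3D" in probe else "sourcePos2D"
        pos_key_d = ("detectorPos3D" if "detectorPos3D" in probe
                     else "detectorPos2D")
        if pos_key_s not in probe or pos_key_d not in probe:
            raise MsfusionError("SNIRF file lacks probe geometry; cannot "
                                "classify short/long separation channels")
        src_pos = np.asarray(probe[pos_key_s], float)
        det_pos = np.asarray(probe[pos_key_d], float)
        if src_pos.shape[1] == 2:
            src_pos = np.column_stack([src_pos, np.zeros(len(src_pos))])
            det_pos = np.column_stack([det_pos, np.zeros(len(det_pos))])

    src_i = np.asarray(src_i)
    det_i = np.asarray(det_i)
    wl_i = np.asarray(wl_i)
    pairs = sorted(set(zip(src_i, det_i)),
                   key=lambda p: list(zip(src_i, det_i)).index(p))
    n_ch = len(pairs)
    n_wl = wavelengths.size
    n_t = cols.shape[0]
    intensity = np.zeros((n_wl, n_ch, n_t))
    for m, (s, d) in enumerate(zip(src_i, det_i)):
        ch = pairs.index((s, d))
        intensity[wl_i[m] - 1, ch] = cols[:, m]
    rows = []
    for s, d in pairs:
        sep = float(np.linalg.norm(src_pos[s - 1] - det_pos[d - 1]))
        rows.append({"source": s, "detector": d, "separation_mm": sep,
                     "kind": "SS" if sep < ss_threshold_mm else "LS"})
    table = pd.DataFrame(rows)
    return FnirsRecording(fs=float(fs), wavelengths=wavelengths,
                          channel_table=table, intensity=intensity,
                          source_pos=src_pos, detector_pos=det_pos)


# ---------------------------------------------------------------------------
# events and alignment

def write_events_tsv(events: EventTable, path) -> None:
    events.table.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> EventTable:
    return EventTable(pd.read_csv(path, sep="\t"))


def align_modalities(eeg: EegRecording, fnirs: FnirsRecording,
                     events: EventTable | None = None,
                     grid_fs: float = 10.0, max_offset_s: float = 30.0
                     ) -> tuple[EegRecording, FnirsRecording, float]:
    """Align EEG and fNIRS streams on their shared trigger annotations.

    The relative offset is recovered by cross-correlating impulse trains
    built from each stream's trigger onsets on a common ``grid_fs`` grid,
    then both streams are cropped to the overlapping span. Returns the
    cropped recordings and the estimated offset (positive when the fNIRS
    clock starts after the EEG clock).
    """
    ev_eeg = eeg.events if eeg.events is not None else events
    ev_fnirs = fnirs.events if fnirs.events is not None else events
    if ev_eeg is None or ev_fnirs is None or not len(ev_eeg) or not len(ev_fnirs):
        raise MsfusionError("no shared triggers; cannot align")

    offset = _train_offset(ev_eeg.onsets, ev_fnirs.onsets, grid_fs,
                           max_offset_s)
    # fNIRS event at t appears at t + offset on the EEG clock
    start_eeg = max(0.0, offset)
    start_fnirs = max(0.0, -offset)
    span = min(eeg.duration_s - start_eeg,
               fnirs.n_samples / fnirs.fs - start_fnirs)
    if span <= 0:
        raise MsfusionError("no overlapping span after alignment")
    span = np.floor(span)  # 1-s epoch grid

    e0 = int(round(start_eeg * eeg.fs))
    e1 = e0 + int(round(span * eeg.fs))
    f0 = int(round(start_fnirs * fnirs.fs))
    f1 = f0 + int(round(span * fnirs.fs))
    eeg_c = eeg.copy_with(data=eeg.data[:, e0:e1])
    kwargs = {}
    for name in ("intensity", "od"):
        arr = getattr(fnirs, name)
        if arr is not None:
            kwargs[name] = arr[..., f0:f1]
    for name in ("hbo", "hbr"):
        arr = getattr(fnirs, name)
        if arr is not None:
            kwargs[name] = arr[..., f0:f1]
    fnirs_c = fnirs.copy_with(**kwargs)
    return eeg_c, fnirs_c, float(offset)


def _train_offset(onsets_a: np.ndarray, onsets_b: np.ndarray,
                  grid_fs: float, max_offset_s: float) -> float:
    import scipy.signal

    t_max = max(onsets_a.max(), onsets_b.max()) + 1.0
    n = int(np.ceil(t_max * grid_fs)) + 1
    a = np.zeros(n)
    b = np.zeros(n)
    a[np.round(onsets_a * grid_fs).astype(int)] = 1.0
    b[np.round(onsets_b * grid_fs).astype(int)] = 1.0
    corr = scipy.signal.correlate(a, b, mode="full")
    lags = scipy.signal.correlation_lags(n, n, mode="full")
    keep = np.abs(lags) <= max_offset_s * grid_fs
    best = lags[keep][np.argmax(corr[keep])]
    return float(best / grid_fs)
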