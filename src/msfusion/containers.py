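"""In-memory containers for multimodal (EEG + fNIRS) recording sessions.

All internal sample indexing is 0-based with half-open intervals; event
onsets are in seconds (float). EEG data are microvolts, fNIRS chromophore
series are micromolar-millimetre (unit partial pathlength).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Vocabulary of event labels used throughout the pipeline.
EVENT_LABELS = ("task_start", "task_stop", "needle_drop", "incorrect_insertion")

#: Labels that mark an error commission.
ERROR_LABELS = ("needle_drop", "incorrect_insertion")


class MsfusionError(Exception):
    """Base class for errors raised by this package."""


@dataclass
class EventTable:
    """Task / error event annotations.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``onset_s``, ``duration_s``, ``label``. Onsets are sorted
        on construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"onset_s", "duration_s", "label"}
        missing = required - set(self.table.columns)
        if missing:
            raise MsfusionError(f"event table missing columns: {sorted(missing)}")
        bad = set(self.table["label"]) - set(EVENT_LABELS)
        if bad:
            raise MsfusionError(f"unknown event labels: {sorted(bad)}")
        if not self.table["onset_s"].is_monotonic_increasing:
            self.table = self.table.sort_values("onset_s", ignore_index=True)

    @classmethod
    def from_arrays(cls, onset_s, duration_s, label) -> "EventTable":
        return cls(
            pd.DataFrame(
                {"onset_s": np.asarray(onset_s, float),
                 "duration_s": np.asarray(duration_s, float),
                 "label": list(label)}
            )
        )

    def select(self, labels) -> "EventTable":
        """Return the sub-table whose labels are in ``labels``."""
        if isinstance(labels, str):
            labels = (labels,)
        sub = self.table[self.table["label"].isin(labels)].reset_index(drop=True)
        return EventTable(sub)

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset_s"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EegRecording:
    """Multichannel EEG time series.

    ``data`` is channels x samples in microvolts. ``channel_positions`` are
    unit-sphere 3D coordinates (one row per channel) used for spherical
    spline interpolation and the surface Laplacian.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_positions: np.ndarray | None = None
    events: EventTable | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise MsfusionError("EEG data must be channels x samples")
        if self.fs <= 0:
            raise MsfusionError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise MsfusionError("channel_names length mismatch")
        if self.channel_positions is not None:
            pos = np.asarray(self.channel_positions, float)
            if pos.shape != (self.data.shape[0], 3):
                raise MsfusionError("channel_positions must be (n_channels, 3)")
            norms = np.linalg.norm(pos, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                pos = pos / norms[:, None]
            self.channel_positions = pos

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "EegRecording":
        return replace(self, **kwargs)


@dataclass
class FnirsRecording:
    """Continuous-wave fNIRS recording.

    ``intensity`` / ``od`` are (n_wavelengths, n_channels, n_samples).
    ``hbo`` / ``hbr`` are (n_channels, n_samples) in uM*mm (unit partial
    pathlength). ``channel_table`` has one row per optode pair with columns
    ``source``, ``detector``, ``separation_mm`` and ``kind`` in {"SS", "LS"}.
    """

    fs: float
    wavelengths: np.ndarray
    channel_table: pd.DataFrame
    intensity: np.ndarray | None = None
    od: np.ndarray | None = None
    hbo: np.ndarray | None = None
    hbr: np.ndarray | None = None
    source_pos: np.ndarray | None = None
    detector_pos: np.ndarray | None = None
    events: EventTable | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise MsfusionError("sampling rate must be positive")
        self.wavelengths = np.asarray(self.wavelengths, float)
        required = {"source", "detector", "separation_mm", "kind"}
        missing = required - set(self.channel_table.columns)
        if missing:
            raise MsfusionError(f"channel_table missing columns: {sorted(missing)}")
        kinds = set(self.channel_table["kind"])
        if not kinds <= {"SS", "LS"}:
            raise MsfusionError(f"unknown channel kinds: {sorted(kinds - {'SS', 'LS'})}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_table)

    @property
    def ls_index(self) -> np.ndarray:
        return np.flatnonzero((self.channel_table["kind"] == "LS").to_numpy())

    @property
    def ss_index(self) -> np.ndarray:
        return np.flatnonzero((self.channel_table["kind"] == "SS").to_numpy())

    @property
    def n_samples(self) -> int:
        for arr in (self.hbo, self.od, self.intensity):
            if arr is not None:
                return arr.shape[-1]
        raise MsfusionError("recording holds no data")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "FnirsRecording":
        return replace(self, **kwargs)
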