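"""EEG preprocessing chain.

The cleaning chain mirrors common mobile-EEG practice: downsample to
250 Hz, zero-phase 1 Hz high-pass, sliding-window sinusoid regression for
line noise, bad-channel detection and spherical-spline interpolation,
average re-referencing, artifact subspace reconstruction (ASR), and an
optional spherical-spline surface Laplacian. A band-power branch (1-40 Hz
envelope resampled to the fNIRS rate) feeds the fusion stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .containers import EegRecording, EventTable, MsfusionError
from .splines import interpolation_operator, surface_laplacian_operator

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """What the cleaning chain did to a recording."""

    bad_channels: list[str] = field(default_factory=list)
    fraction_samples_modified_by_asr: float = 0.0
    filters_applied: list[dict] = field(default_factory=list)
    excluded: bool = False

    def to_dict(self) -> dict:
        return {
            "bad_channels": list(self.bad_channels),
            "fraction_samples_modified_by_asr": float(
                self.fraction_samples_modified_by_asr),
            "filters_applied": list(self.filters_applied),
            "excluded": bool(self.excluded),
        }


# ---------------------------------------------------------------------------
# filtering

def filter_chain(rec: EegRecording, target_fs: float = 250.0,
                 highpass_hz: float = 1.0, line_freq: float = 60.0,
                 report: PreprocessReport | None = None) -> EegRecording:
    """Downsample, high-pass and remove line noise (zero-phase throughout)."""
    if rec.fs < 2 * target_fs:
        raise MsfusionError(
            f"sampling rate {rec.fs} too low to downsample to {target_fs}")
    data = rec.data
    if rec.fs != target_fs:
        ratio = rec.fs / target_fs
        if abs(ratio - round(ratio)) > 1e-9:
            raise MsfusionError("target rate must divide the sampling rate")
        data = scipy.signal.resample_poly(data, up=1, down=int(round(ratio)),
                                          axis=1)
    sos = scipy.signal.butter(4, highpass_hz, btype="highpass",
                              fs=target_fs, output="sos")
    data = scipy.signal.sosfiltfilt(sos, data, axis=1)
    data = remove_line_noise(data, target_fs, line_freq)
    if report is not None:
        report.filters_applied += [
            {"name": "resample", "target_fs": target_fs},
            {"name": "highpass", "cutoff_hz": highpass_hz, "order": 4,
             "zero_phase": True},
            {"name": "line_regression", "freq_hz": line_freq},
        ]
    return rec.copy_with(data=data, fs=target_fs)


def remove_line_noise(data: np.ndarray, fs: float, line_freq: float,
                      window_s: float = 4.0) -> np.ndarray:
    """Regress out line-frequency sinusoids (and harmonics) in sliding windows.

    Sinusoid regression adapts to slow amplitude/phase drift of the mains
    component without the ringing of a notch filter.
    """
    freqs = [f for f in np.arange(line_freq, fs / 2, line_freq)]
    if not freqs:
        return data
    n = data.shape[1]
    win = min(int(round(window_s * fs)), n)
    hop = max(win // 2, 1)
    t = np.arange(n) / fs
    out = np.zeros_like(data)
    norm = np.zeros(n)
    taper = scipy.signal.windows.hann(win, sym=False) + 1e-12
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if starts[-1] != n - win:
        starts.append(n - win)
    for s in starts:
        sl = slice(s, s + win)
        tt = t[sl]
        basis = np.column_stack(
            [f(2 * np.pi * fr * tt) for fr in freqs for f in (np.sin, np.cos)])
        beta, *_ = np.linalg.lstsq(basis, data[:, sl].T, rcond=None)
        cleaned = data[:, sl] - (basis @ beta).T
        out[:, sl] += cleaned * taper
        norm[sl] += taper
    return out / norm


# ---------------------------------------------------------------------------
# channel quality

def detect_bad_channels(rec: EegRecording, flat_sd: float = 1e-8,
                        corr_r: float = 0.8, window_s: float = 5.0,
                        bad_fraction: float = 0.5,
                        max_bad: int = 5,
                        report: PreprocessReport | None = None) -> list[str]:
    """Flag flat channels and channels unpredictable from their neighbours.

    A channel is *flat* if its standard deviation stays below ``flat_sd``
    over a stretch of at least ``window_s`` seconds. A channel is
    *poorly correlated* if, in more than ``bad_fraction`` of windows, it
    correlates below ``corr_r`` with its spherical-spline prediction from
    the remaining channels.
    """
    if rec.n_channels < 8:
        raise MsfusionError("bad-channel detection needs >= 8 channels")
    if rec.channel_positions is None:
        raise MsfusionError("channel positions required")
    win = int(round(window_s * rec.fs))
    n_win = max(rec.n_samples // win, 1)
    X = rec.data[:, : n_win * win].reshape(rec.n_channels, n_win, win)
    sds = X.std(axis=2)

    bads: list[str] = []
    for i, name in enumerate(rec.channel_names):
        if np.any(sds[i] < flat_sd):
            bads.append(name)
    flat_idx = {rec.channel_names.index(b) for b in bads}

    for i, name in enumerate(rec.channel_names):
        if name in bads:
            continue
        others = [j for j in range(rec.n_channels)
                  if j != i and j not in flat_idx]
        P = interpolation_operator(rec.channel_positions[others],
                                   rec.channel_positions[[i]])
        pred = (P @ rec.data[others])[0]
        predw = pred[: n_win * win].reshape(n_win, win)
        rs = _rowwise_corr(X[i], predw)
        if np.mean(rs < corr_r) > bad_fraction:
            bads.append(name)

    if report is not None:
        report.bad_channels = list(bads)
        if len(bads) > max_bad:
            report.excluded = True
            logger.warning("subject flagged for exclusion: %d bad channels",
                           len(bads))
    return bads


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    denom[denom == 0] = np.inf
    return np.sum(a * b, axis=1) / denom


def spherical_spline_interpolate(rec: EegRecording, bads: list[str],
                                 m: int = 4, lam: float = 1e-5) -> EegRecording:
    """Replace bad channels by spherical-spline estimates from good ones."""
    if not bads:
        return rec.copy_with(data=rec.data.copy())
    bad_idx = [rec.channel_names.index(b) for b in bads]
    good_idx = [i for i in range(rec.n_channels) if i not in bad_idx]
    if len(good_idx) < 4:
        raise MsfusionError("fewer than 4 good channels; cannot interpolate")
    P = interpolation_operator(rec.channel_positions[good_idx],
                               rec.channel_positions[bad_idx], m=m, lam=lam)
    data = rec.data.copy()
    data[bad_idx] = P @ data[good_idx]
    return rec.copy_with(data=data)


def rereference_average(rec: EegRecording) -> EegRecording:
    """Re-reference to the global average (zero channel mean per sample)."""
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# artifact subspace reconstruction

def asr_clean(rec: EegRecording, k: float = 20.0, window_s: float = 0.5,
              calib_s: float = 60.0,
              report: PreprocessReport | None = None
              ) -> tuple[EegRecording, PreprocessReport]:
    """Artifact subspace reconstruction, simplified Euclidean form.

    Calibration data are the quietest ``calib_s`` seconds by windowed RMS.
    In sliding half-overlapping windows, principal components whose
    amplitude exceeds ``k`` times the calibration standard deviation along
    the same direction are reconstructed from the calibration covariance;
    windows are blended with a Hann taper.
    """
    if report is None:
        report = PreprocessReport()
    data = rec.data
    n = rec.n_samples
    win = int(round(window_s * rec.fs))
    if n < win * 2:
        raise MsfusionError("recording too short for ASR")
    calib = _calibration_data(data, rec.fs, calib_s)
    C_cal = np.cov(calib)
    # ridge against the zero-variance direction left by average referencing
    C_cal += 1e-6 * np.trace(C_cal) / C_cal.shape[0] * np.eye(C_cal.shape[0])
    M = scipy.linalg.sqrtm(C_cal).real

    if not np.isfinite(k):
        report.fraction_samples_modified_by_asr = 0.0
        return rec.copy_with(data=data.copy()), report

    hop = win // 2
    taper = scipy.signal.windows.hann(win, sym=False) + 1e-12
    out = np.zeros_like(data)
    norm = np.zeros(n)
    modified = np.zeros(n, bool)
    starts = list(range(0, n - win + 1, hop))
    if starts[-1] != n - win:
        starts.append(n - win)
    for s in starts:
        seg = data[:, s:s + win]
        cov = (seg @ seg.T) / win
        evals, V = np.linalg.eigh(cov)
        amps = np.sqrt(np.maximum(evals, 0))
        calib_sd = np.sqrt(np.maximum(np.einsum("ij,jk,ki->i", V.T, C_cal, V), 0))
        # directions with (near-)zero calibration variance, e.g. the constant
        # vector removed by average referencing, carry no artifact evidence
        degenerate = calib_sd < 1e-9 * calib_sd.max()
        keep = (amps <= k * calib_sd) | degenerate
        if np.all(keep):
            rec_seg = seg
        else:
            VtM = V.T @ M
            VtM_kept = VtM * keep[:, None]
            R = M @ np.linalg.pinv(VtM_kept, rcond=1e-6) @ V.T
            rec_seg = R @ seg
            modified[s:s + win] = True
        out[:, s:s + win] += rec_seg * taper
        norm[s:s + win] += taper
    out /= norm
    report.fraction_samples_modified_by_asr = float(modified.mean())
    return rec.copy_with(data=out), report


def _calibration_data(data: np.ndarray, fs: float, calib_s: float,
                      win_s: float = 1.0) -> np.ndarray:
    win = int(round(win_s * fs))
    n_win = data.shape[1] // win
    if n_win * win_s < 10.0:
        raise MsfusionError("recording shorter than the 10 s ASR calibration minimum")
    segs = data[:, : n_win * win].reshape(data.shape[0], n_win, win)
    rms = np.sqrt((segs ** 2).mean(axis=(0, 2)))
    n_take = min(max(int(np.ceil(calib_s / win_s)), 10), n_win)
    order = np.argsort(rms)[:n_take]
    return segs[:, np.sort(order), :].reshape(data.shape[0], -1)


# ---------------------------------------------------------------------------
# spatial filtering and features

def surface_laplacian(rec: EegRecording, m: int = 4, lam: float = 1e-5,
                      head_radius_m: float = 0.085) -> EegRecording:
    """Spherical-spline surface Laplacian (output in uV/m^2)."""
    if rec.channel_positions is None:
        raise MsfusionError("channel positions required for the Laplacian")
    if rec.n_channels < 16:
        warnings.warn("surface Laplacian is poorly conditioned below 16 channels")
    L = surface_laplacian_operator(rec.channel_positions, m=m, lam=lam,
                                   head_radius_m=head_radius_m)
    return rec.copy_with(data=L @ rec.data)


def bandpower_envelope(rec: EegRecording, low: float = 1.0, high: float = 40.0,
                       out_fs: float = 5.0, window_s: float = 1.0) -> np.ndarray:
    """Per-channel band power in sliding windows, resampled to ``out_fs``.

    Returns an array (n_channels, n_out) of mean squared band-limited
    amplitude in 1-s windows centred on the output sample times.
    """
    if rec.fs <= 2 * high:
        raise MsfusionError("sampling rate too low for the requested band")
    win = int(round(window_s * rec.fs))
    if win > rec.n_samples:
        raise MsfusionError("window longer than recording")
    sos = scipy.signal.butter(4, [low, high], btype="bandpass",
                              fs=rec.fs, output="sos")
    band = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    power = band ** 2
    kernel = np.ones(win) / win
    smooth = scipy.signal.fftconvolve(
        power, kernel[None, :], mode="same", axes=1)
    n_out = int(np.floor(rec.n_samples / rec.fs * out_fs))
    idx = np.clip(np.round(np.arange(n_out) / out_fs * rec.fs).astype(int),
                  0, rec.n_samples - 1)
    return np.maximum(smooth[:, idx], 0.0)


def epoch_extract(rec: EegRecording, events: EventTable, which: str,
                  length_s: float = 10.0) -> list[np.ndarray]:
    """Cut half-open [onset, onset + length_s) windows around events.

    ``which`` is ``"task_start"`` or ``"error"`` (needle drop or incorrect
    insertion). Partial windows at the end of the recording are dropped
    with a warning; overlapping epochs are all emitted.
    """
    from .containers import ERROR_LABELS

    labels = ERROR_LABELS if which == "error" else (which,)
    sel = events.select(labels)
    if len(sel) == 0:
        warnings.warn(f"no events of kind '{which}'")
        return []
    n_len = int(round(length_s * rec.fs))
    epochs = []
    for onset in sel.onsets:
        start = int(round(onset * rec.fs))
        if start + n_len > rec.n_samples:
            warnings.warn(f"dropping partial epoch at {onset:.1f} s")
            continue
        epochs.append(rec.data[:, start:start + n_len])
    return epochs


# ---------------------------------------------------------------------------
# full chain

def preprocess_eeg(rec: EegRecording, target_fs: float = 250.0,
                   highpass_hz: float = 1.0, line_freq: float = 60.0,
                   asr_k: float = 20.0, flat_sd: float = 1e-8,
                   corr_r: float = 0.8, max_bad: int = 5
                   ) -> tuple[EegRecording, PreprocessReport]:
    """Run the full cleaning chain and return the cleaned recording.

    Order: resample/high-pass/line removal, bad-channel rejection and
    spherical-spline interpolation, average re-reference, ASR, average
    re-reference again.
    """
    report = PreprocessReport()
    rec = filter_chain(rec, target_fs, highpass_hz, line_freq, report)
    bads = detect_bad_channels(rec, flat_sd=flat_sd, corr_r=corr_r,
                               max_bad=max_bad, report=report)
    rec = spherical_spline_interpolate(rec, bads)
    rec = rereference_average(rec)
    rec, report = asr_clean(rec, k=asr_k, report=report)
    rec = rereference_average(rec)
    return rec, report
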