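"""fNIRS preprocessing: intensity -> OD -> motion correction -> band-pass ->
chromophore concentrations via the modified Beer-Lambert law.

Concentrations are expressed in uM*mm with a unit partial pathlength
factor, i.e. the product of concentration change and effective pathlength
divided by the source-detector distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .containers import FnirsRecording, MsfusionError

# Molar extinction coefficients, 1/(uM * mm) * 1e-3, for oxy- and
# deoxy-hemoglobin at the two operating wavelengths (values interpolated
# from the standard compiled absorption tables used in CW-NIRS software).
# Rows: wavelength; columns: (HbO, HbR).
EXTINCTION = {
    760.0: (1.4866e-3, 3.8437e-3),
    850.0: (2.5264e-3, 1.7986e-3),
}


def extinction_matrix(wavelengths) -> np.ndarray:
    """2x2 matrix E with rows per wavelength, columns (HbO, HbR)."""
    rows = []
    for wl in wavelengths:
        key = min(EXTINCTION, key=lambda k: abs(k - wl))
        if abs(key - wl) > 25:
            raise MsfusionError(f"no extinction data near {wl} nm")
        rows.append(EXTINCTION[key])
    E = np.asarray(rows, float)
    if abs(np.linalg.det(E)) < 1e-12:
        raise MsfusionError("singular extinction matrix (identical wavelengths?)")
    return E


@dataclass
class MotionMask:
    """Per-channel boolean series marking motion-artifact samples."""

    mask: np.ndarray  # (n_wavelengths, n_channels, n_samples) bool
    amp_threshold_od: float
    sd_factor: float

    @property
    def any_channel(self) -> np.ndarray:
        return self.mask.any(axis=(0, 1))


def intensity_to_od(rec: FnirsRecording) -> FnirsRecording:
    """Optical density OD(t) = -log10(I(t) / mean(I)) per channel/wavelength."""
    if rec.intensity is None:
        raise MsfusionError("no intensity data")
    I = np.asarray(rec.intensity, float)
    if np.any(I <= 0):
        wl, ch, _ = np.unravel_index(np.argmin(I), I.shape)
        raise MsfusionError(
            f"non-positive intensity in channel {ch} at wavelength index {wl}")
    od = -np.log10(I / I.mean(axis=2, keepdims=True))
    return rec.copy_with(od=od)


def motion_correct_sg(rec: FnirsRecording, amp_threshold_od: float = 0.5,
                      sd_factor: float = 50.0, detect_window_s: float = 0.5,
                      sg_window_s: float = 10.0, sg_order: int = 3
                      ) -> tuple[FnirsRecording, MotionMask]:
    """Detect motion artifacts on OD and patch them with a Savitzky-Golay
    smoothed trace.

    Detection flags samples where the OD excursion within a short window
    exceeds ``amp_threshold_od`` or where the local first-difference
    exceeds ``sd_factor`` times the channel's median absolute deviation.
    """
    if rec.od is None:
        raise MsfusionError("compute optical density first")
    od = rec.od
    n = od.shape[-1]
    wdet = max(int(round(detect_window_s * rec.fs)), 2)
    wsg = int(round(sg_window_s * rec.fs))
    if wsg % 2 == 0:
        wsg += 1
    if wsg > n:
        raise MsfusionError("Savitzky-Golay window exceeds the recording")
    if wsg <= sg_order + 1:
        raise MsfusionError("Savitzky-Golay window too short for its order")

    mask = np.zeros(od.shape, bool)
    diff = np.abs(np.diff(od, axis=-1, prepend=od[..., :1]))
    mad = np.median(np.abs(diff - np.median(diff, axis=-1, keepdims=True)),
                    axis=-1, keepdims=True) + 1e-12
    jump = diff > sd_factor * mad
    # amplitude rule: peak-to-peak within the short window
    for w in range(od.shape[0]):
        for c in range(od.shape[1]):
            x = od[w, c]
            roll_max = _rolling_extreme(x, wdet, np.maximum)
            roll_min = _rolling_extreme(x, wdet, np.minimum)
            amp_flag = (roll_max - roll_min) > amp_threshold_od
            mask[w, c] = amp_flag | jump[w, c]
    # dilate flags by the detection window so whole spikes are patched
    mask = _dilate(mask, wdet)

    # bridge flagged spans before smoothing so the artifact does not leak
    # into the Savitzky-Golay reference trace
    bridged = od.copy()
    idx = np.arange(n)
    for w in range(od.shape[0]):
        for c in range(od.shape[1]):
            m = mask[w, c]
            if m.any() and not m.all():
                bridged[w, c, m] = np.interp(idx[m], idx[~m], od[w, c, ~m])
    smooth = scipy.signal.savgol_filter(bridged, wsg, sg_order, axis=-1)
    fixed = np.where(mask, smooth, od)
    return rec.copy_with(od=fixed), MotionMask(mask, amp_threshold_od, sd_factor)


def _rolling_extreme(x: np.ndarray, w: int, op) -> np.ndarray:
    out = x.copy()
    for k in range(1, w):
        shifted = np.empty_like(x)
        shifted[:k] = x[0]
        shifted[k:] = x[:-k]
        out = op(out, shifted)
    return out


def _dilate(mask: np.ndarray, w: int) -> np.ndarray:
    out = mask.copy()
    for k in range(1, w):
        out[..., :-k] |= mask[..., k:]
        out[..., k:] |= mask[..., :-k]
    return out


def bandpass_nvc(rec: FnirsRecording, low: float = 0.01, high: float = 0.1
                 ) -> FnirsRecording:
    """Zero-phase band-pass to the neurovascular coupling band (0.01-0.1 Hz)."""
    if rec.fs < 0.25:
        raise MsfusionError("sampling rate too low for the NVC band")
    if rec.od is None:
        raise MsfusionError("compute optical density first")
    sos = scipy.signal.butter(3, [low, high], btype="bandpass",
                              fs=rec.fs, output="sos")
    od = scipy.signal.sosfiltfilt(sos, rec.od, axis=-1)
    return rec.copy_with(od=od)


def od_to_conc(rec: FnirsRecording, ppf: float = 1.0) -> FnirsRecording:
    """Modified Beer-Lambert inversion: [HbO; HbR] = E^-1 OD / (d * ppf)."""
    if rec.od is None:
        raise MsfusionError("compute optical density first")
    if rec.od.shape[0] != 2:
        raise MsfusionError("chromophore inversion needs two wavelengths")
    E = extinction_matrix(rec.wavelengths)
    Einv = np.linalg.inv(E)
    d = rec.channel_table["separation_mm"].to_numpy(float)
    if np.any(d <= 0):
        raise MsfusionError("non-positive source-detector separation")
    od = rec.od / (d[None, :, None] * ppf)
    conc = np.einsum("cw,wnt->cnt", Einv, od)
    return rec.copy_with(hbo=conc[0], hbr=conc[1])


def preprocess_fnirs(rec: FnirsRecording, amp_threshold_od: float = 0.5,
                     sd_factor: float = 50.0, sg_window_s: float = 10.0,
                     sg_order: int = 3, low: float = 0.01, high: float = 0.1
                     ) -> tuple[FnirsRecording, MotionMask]:
    """Full chain: intensity -> OD -> motion patch -> NVC band-pass -> HbO."""
    rec = intensity_to_od(rec)
    rec, mask = motion_correct_sg(rec, amp_threshold_od, sd_factor,
                                  sg_window_s=sg_window_s, sg_order=sg_order)
    rec = bandpass_nvc(rec, low, high)
    rec = od_to_conc(rec)
    return rec, mask
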