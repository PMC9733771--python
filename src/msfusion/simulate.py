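"""Ground-truthed synthetic EEG + fNIRS cohorts.

The generator emulates the statistical structure the analysis assumes:

* EEG is a sequence of quasi-stable zero-mean scalp topographies (the
  microstates) with gamma-distributed segment durations, a semi-Markov
  label chain, per-segment polarity flips, a smooth positive amplitude
  envelope and additive 1/f sensor noise.
* Long-separation fNIRS oxyhemoglobin equals a hemodynamic response
  function convolved with the EEG 1-40 Hz band power, mixed into channels,
  plus systemic physiology (Mayer wave, respiration, cardiac) shared with
  the short-separation channels, plus sensor noise. The forward modified
  Beer-Lambert model emits raw two-wavelength intensities so the
  preprocessing inverse recovers the target concentrations.
* Error events ("needle drop", "incorrect insertion") transiently boost
  the EEG amplitude envelope, giving a genuine error-evoked neurovascular
  response; the boost magnitude differs between groups.

Two groups (expert / novice analogues) differ in mean state duration,
transition structure and error-burst amplitude.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats
import yaml

from .config import SimConfig, validate_transition_matrix
from .containers import EegRecording, EventTable, FnirsRecording, MsfusionError
from .eeg import bandpower_envelope
from .fnirs import extinction_matrix

#: EEG amplitude scale so that global field power lands in the few-uV range.
SIGNAL_SCALE_UV = 15.0

#: Relative amplitude of the error-evoked envelope burst per group.
ERROR_BURST_GAIN = {"novice": 0.8, "expert": 0.3}

#: Group-specific mean state duration (ms); the common default sits between.
GROUP_MEAN_DURATION = {"novice": 70.0, "expert": 95.0}


@dataclass
class GroundTruth:
    """Everything needed to score parameter recovery downstream."""

    state_sequence: np.ndarray          # per-EEG-sample label, 0..K-1
    segment_starts: np.ndarray          # first sample of each segment
    segment_labels: np.ndarray
    polarity_per_segment: np.ndarray    # +-1
    prototypes_true: np.ndarray         # (K, C) zero-mean unit-norm rows
    event_times: EventTable
    hrf_kernel: np.ndarray | None = None
    mixing_weights: np.ndarray | None = None
    systemic_series: np.ndarray | None = None
    neural_hbo: np.ndarray | None = None   # (n_ls, n_fnirs_samples)
    amplitude_envelope: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# state sequence

def gen_state_sequence(cfg: SimConfig, seed: int | np.random.Generator,
                       prototypes: np.ndarray | None = None) -> GroundTruth:
    """Semi-Markov state sequence with gamma durations plus event markers.

    ``prototypes`` lets a cohort share one topography set across subjects
    (microstate maps are population-level objects); when omitted a fresh
    set is drawn.
    """
    rng = np.random.default_rng(seed)
    P = validate_transition_matrix(np.asarray(cfg.transition_matrix, float),
                                   cfg.k_true)
    n_samples = int(round(cfg.session_duration_s * cfg.fs_eeg))
    mean_samp = cfg.mean_state_duration / 1000.0 * cfg.fs_eeg
    scale = mean_samp / cfg.duration_shape

    labels, starts, pols = [], [], []
    seq = np.empty(n_samples, dtype=np.int32)
    pos = 0
    state = int(rng.integers(cfg.k_true))
    while pos < n_samples:
        dur = max(int(round(rng.gamma(cfg.duration_shape, scale))), 1)
        end = min(pos + dur, n_samples)
        seq[pos:end] = state
        labels.append(state)
        starts.append(pos)
        pols.append(1 if rng.random() < 0.5 else -1)
        pos = end
        state = int(rng.choice(cfg.k_true, p=P[state]))

    if prototypes is None:
        from .io import template_positions

        prototypes = gen_prototypes(
            cfg.k_true, cfg.n_channels_eeg, rng,
            positions=template_positions(cfg.n_channels_eeg))
    else:
        prototypes = np.asarray(prototypes, float)
        if prototypes.shape != (cfg.k_true, cfg.n_channels_eeg):
            raise MsfusionError("prototype array shape mismatch")
    events = _gen_events(cfg, rng)
    return GroundTruth(
        state_sequence=seq,
        segment_starts=np.asarray(starts),
        segment_labels=np.asarray(labels),
        polarity_per_segment=np.asarray(pols),
        prototypes_true=prototypes,
        event_times=events,
    )


def gen_prototypes(k: int, n_channels: int, rng: np.random.Generator,
                   positions: np.ndarray | None = None,
                   max_corr: float = 0.7, max_tries: int = 2000) -> np.ndarray:
    """Zero-mean unit-norm topographies with pairwise |corr| < ``max_corr``.

    When electrode ``positions`` are given, maps are random combinations
    of low-order spherical harmonics of the montage, giving the spatial
    smoothness that volume-conducted scalp fields have; otherwise maps
    are spatially white (useful for abstract clustering tests).
    """
    basis = None
    if positions is not None:
        basis = _harmonic_basis(np.asarray(positions, float))
    protos: list[np.ndarray] = []
    for _ in range(max_tries):
        if basis is None:
            v = rng.standard_normal(n_channels)
        else:
            v = basis @ rng.standard_normal(basis.shape[1])
        v -= v.mean()
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            continue
        v /= norm
        if all(abs(v @ p) < max_corr for p in protos):
            protos.append(v)
        if len(protos) == k:
            return np.asarray(protos)
    raise MsfusionError("prototype rejection sampling failed")


def _harmonic_basis(pos: np.ndarray) -> np.ndarray:
    """Real solid harmonics up to degree 3, evaluated at the electrodes."""
    x, y, z = pos.T
    r2 = x ** 2 + y ** 2 + z ** 2
    cols = [
        x, y, z,
        x * y, x * z, y * z, x ** 2 - y ** 2, 3 * z ** 2 - r2,
        x * (5 * z ** 2 - r2), y * (5 * z ** 2 - r2),
        z * (5 * z ** 2 - 3 * r2), x * y * z,
        z * (x ** 2 - y ** 2), x * (x ** 2 - 3 * y ** 2),
        y * (3 * x ** 2 - y ** 2),
    ]
    B = np.column_stack(cols)
    B -= B.mean(axis=0)
    return B / (np.linalg.norm(B, axis=0) + 1e-30)


def _gen_events(cfg: SimConfig, rng: np.random.Generator) -> EventTable:
    onsets, durations, labels = [], [], []
    t = 0.0
    for trial in range(cfg.n_trials):
        onsets.append(t)
        durations.append(cfg.trial_duration_s)
        labels.append("task_start")
        # error events strictly inside the trial, clear of its edges
        lo, hi = t + 5.0, t + cfg.trial_duration_s - 12.0
        if hi > lo and cfg.events_per_trial > 0:
            times = np.sort(rng.uniform(lo, hi, cfg.events_per_trial))
            for et in times:
                onsets.append(float(et))
                durations.append(0.0)
                labels.append("needle_drop" if rng.random() < 0.5
                              else "incorrect_insertion")
        t += cfg.trial_duration_s
        onsets.append(t)
        durations.append(0.0)
        labels.append("task_stop")
        t += cfg.rest_duration_s
    return EventTable.from_arrays(onsets, durations, labels)


# ---------------------------------------------------------------------------
# EEG synthesis

def gen_eeg(truth: GroundTruth, cfg: SimConfig,
            seed: int | np.random.Generator, error_burst_gain: float = 0.0
            ) -> EegRecording:
    """Render the state sequence into multichannel EEG with 1/f noise."""
    rng = np.random.default_rng(seed)
    if truth.prototypes_true.shape[0] != cfg.k_true:
        raise MsfusionError("prototype count does not match k_true")
    n = truth.state_sequence.size
    env = _amplitude_envelope(n, cfg.fs_eeg, rng)
    if error_burst_gain > 0:
        env = env * (1.0 + error_burst_gain *
                     _error_burst(truth.event_times, n, cfg.fs_eeg))
    pol = np.repeat(
        truth.polarity_per_segment,
        np.diff(np.append(truth.segment_starts, n)))

    signal = (truth.prototypes_true[truth.state_sequence]
              * (env * pol)[:, None]).T * SIGNAL_SCALE_UV
    if np.isfinite(cfg.snr_db):
        noise = _background_noise(cfg, n, rng)
        sig_var = signal.var()
        noise *= np.sqrt(sig_var / 10 ** (cfg.snr_db / 10.0)) / noise.std()
        data = signal + noise
    else:
        data = signal
    truth.amplitude_envelope = env
    from .io import template_names, template_positions

    names = template_names(cfg.n_channels_eeg)
    pos = template_positions(cfg.n_channels_eeg)
    return EegRecording(data=data, fs=cfg.fs_eeg, channel_names=names,
                        channel_positions=pos, events=truth.event_times)


def _amplitude_envelope(n: int, fs: float, rng: np.random.Generator,
                        band=(5.0, 15.0), floor: float = 0.3) -> np.ndarray:
    """Smooth positive envelope: rectified band-limited noise plus a floor.

    The 5-15 Hz band gives waxing-waning topographic strength with GFP
    maxima every few tens of milliseconds, the regime peak picking expects.
    """
    x = rng.standard_normal(n)
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = scipy.signal.sosfiltfilt(sos, x)
    x = np.abs(x)
    x /= x.std() + 1e-30
    return floor + x


def _error_burst(events: EventTable, n: int, fs: float,
                 rise_s: float = 0.5, decay_s: float = 2.0) -> np.ndarray:
    """Unit-peak transient after each error event (gamma-shaped)."""
    from .containers import ERROR_LABELS

    burst = np.zeros(n)
    t = np.arange(int(6 * fs)) / fs
    kern = (t / rise_s) * np.exp(1 - t / decay_s)
    kern /= kern.max() + 1e-30
    for onset in events.select(ERROR_LABELS).onsets:
        s = int(round(onset * fs))
        e = min(s + kern.size, n)
        if s < n:
            burst[s:e] = np.maximum(burst[s:e], kern[: e - s])
    return burst


def _background_noise(cfg: SimConfig, n: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Background activity: spatially smooth 1/f 'brain noise' (random
    harmonic fields, like any volume-conducted source) plus a smaller
    spatially independent sensor-noise floor."""
    from .io import template_positions

    basis = _harmonic_basis(template_positions(cfg.n_channels_eeg))
    smooth = basis @ pink_noise((basis.shape[1], n), rng,
                                exponent=cfg.noise_exponent)
    smooth /= smooth.std() + 1e-30
    white = pink_noise((cfg.n_channels_eeg, n), rng,
                       exponent=cfg.noise_exponent)
    frac = cfg.spatial_noise_frac
    return np.sqrt(frac) * smooth + np.sqrt(1.0 - frac) * white


def pink_noise(shape: tuple, rng: np.random.Generator,
               exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise along the last axis via spectral shaping."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal(shape[:-1] + (freqs.size,))
            + 1j * rng.standard_normal(shape[:-1] + (freqs.size,)))
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    return x / x.std()


# ---------------------------------------------------------------------------
# hemodynamics

def canonical_hrf(cfg: SimConfig, oversample: float = 1.0) -> np.ndarray:
    """Double-gamma hemodynamic response kernel sampled at the fNIRS rate.

    Positive lobe peaking at ``hrf_peak_s``, undershoot at
    ``hrf_undershoot_s``, peak value normalized to 1.
    """
    if cfg.hrf_peak_s <= 0 or cfg.hrf_undershoot_s <= 0:
        raise MsfusionError("HRF latencies must be positive")
    fs = cfg.fs_fnirs * oversample
    support = cfg.hrf_undershoot_s + 16.0
    t = np.arange(0.0, support, 1.0 / fs)
    # gamma pdf with unit scale has its mode at shape-1
    peak = scipy.stats.gamma.pdf(t, cfg.hrf_peak_s + 1.0)
    under = scipy.stats.gamma.pdf(t, cfg.hrf_undershoot_s + 1.0)
    h = peak - under / 6.0
    return h / h.max()


def gen_fnirs(eeg: EegRecording, truth: GroundTruth, cfg: SimConfig,
              seed: int | np.random.Generator,
              coupling: float | None = None) -> FnirsRecording:
    """Forward-model fNIRS intensities from the EEG band power.

    Long-separation HbO = mixing_weights @ (HRF * band power) + systemic
    + noise; short-separation channels carry the systemic component and
    noise only. Ground-truth series are stored on ``truth``.
    """
    rng = np.random.default_rng(seed)
    if eeg.fs != cfg.fs_eeg:
        raise MsfusionError("EEG sampling rate does not match the configuration")
    hrf = canonical_hrf(cfg)
    if eeg.n_samples / eeg.fs <= hrf.size / cfg.fs_fnirs:
        raise MsfusionError("EEG shorter than one HRF support")

    bp = bandpower_envelope(eeg, low=1.0, high=min(40.0, eeg.fs / 2 - 10),
                            out_fs=cfg.fs_fnirs)
    bp = bp - bp.mean(axis=1, keepdims=True)
    n5 = bp.shape[1]
    drive = scipy.signal.fftconvolve(bp, hrf[None, :], axes=1)[:, :n5]
    drive_rms = drive.std() + 1e-30

    if truth.mixing_weights is None:
        W = rng.uniform(0.0, 1.0, (cfg.n_ls, cfg.n_channels_eeg)) ** 3
        W /= W.sum(axis=1, keepdims=True)
        truth.mixing_weights = W
    W = truth.mixing_weights

    strength = cfg.coupling_strength if coupling is None else coupling
    neural = (W @ drive) / drive_rms * strength  # uM, unit-RMS-ish scale
    truth.neural_hbo = neural
    truth.hrf_kernel = hrf

    if truth.systemic_series is None:
        t5 = np.arange(n5) / cfg.fs_fnirs
        sys_series = np.zeros(n5)
        for f in cfg.systemic_freqs:
            sys_series += np.sin(2 * np.pi * f * t5 + rng.uniform(0, 2 * np.pi))
        drift = pink_noise((n5,), rng, exponent=2.0)
        sos = scipy.signal.butter(2, 0.05, btype="lowpass", fs=cfg.fs_fnirs,
                                  output="sos")
        drift = scipy.signal.sosfiltfilt(sos, drift)
        sys_series = sys_series + drift / (drift.std() + 1e-30)
        truth.systemic_series = sys_series * cfg.systemic_amp
    systemic = truth.systemic_series

    gains_ls = rng.uniform(0.8, 1.2, cfg.n_ls)
    gains_ss = rng.uniform(0.8, 1.2, cfg.n_ss)
    noise_ls = rng.standard_normal((cfg.n_ls, n5)) * cfg.fnirs_noise_sd
    noise_ss = rng.standard_normal((cfg.n_ss, n5)) * cfg.fnirs_noise_sd
    hbo_ls = neural + gains_ls[:, None] * systemic + noise_ls
    hbo_ss = gains_ss[:, None] * systemic + noise_ss
    hbo = np.vstack([hbo_ls, hbo_ss])
    hbr = -0.3 * hbo

    table, src_pos, det_pos = _default_geometry(cfg, rng)
    wavelengths = np.array([760.0, 850.0])
    E = extinction_matrix(wavelengths)
    d = table["separation_mm"].to_numpy(float)
    od = np.einsum("wc,cnt->wnt", E, np.stack([hbo, hbr])) * d[None, :, None]
    baseline = rng.uniform(0.5, 2.0, (2, hbo.shape[0])) * 1e5
    intensity = baseline[:, :, None] * 10.0 ** (-od)

    truth.extras["hbo_true_ls"] = hbo_ls
    truth.extras["hbo_true_ss"] = hbo_ss
    return FnirsRecording(
        fs=cfg.fs_fnirs, wavelengths=wavelengths, channel_table=table,
        intensity=intensity, source_pos=src_pos, detector_pos=det_pos,
        events=truth.event_times,
    )


def _default_geometry(cfg: SimConfig, rng: np.random.Generator):
    """Probe layout: LS pairs ~30 mm apart, SS pairs ~8 mm, on a flat grid."""
    n_src = max(cfg.n_ls // 2, 1) + cfg.n_ss
    rows = []
    src_pos = np.zeros((n_src, 3))
    det_pos = np.zeros((cfg.n_ls + cfg.n_ss, 3))
    det = 0
    for ch in range(cfg.n_ls):
        src = ch % max(cfg.n_ls // 2, 1)
        src_pos[src] = [src * 40.0, 0.0, 0.0]
        det_pos[det] = [src * 40.0 + 30.0, 0.0, 0.0]
        rows.append({"source": src + 1, "detector": det + 1,
                     "separation_mm": 30.0, "kind": "LS"})
        det += 1
    for ch in range(cfg.n_ss):
        src = max(cfg.n_ls // 2, 1) + ch
        src_pos[src] = [ch * 40.0, 60.0, 0.0]
        det_pos[det] = [ch * 40.0 + 8.0, 60.0, 0.0]
        rows.append({"source": src + 1, "detector": det + 1,
                     "separation_mm": 8.0, "kind": "SS"})
        det += 1
    return pd.DataFrame(rows), src_pos, det_pos


# ---------------------------------------------------------------------------
# cohort on disk

def gen_subject(cfg: SimConfig, seed: int, group: str,
                prototypes: np.ndarray | None = None
                ) -> tuple[EegRecording, FnirsRecording, GroundTruth]:
    """One subject: state sequence, EEG and fNIRS with group-specific bursts."""
    ss = np.random.SeedSequence(seed)
    s_state, s_eeg, s_fnirs = ss.spawn(3)
    truth = gen_state_sequence(cfg, np.random.default_rng(s_state),
                               prototypes=prototypes)
    burst = ERROR_BURST_GAIN.get(group, 0.0)
    eeg = gen_eeg(truth, cfg, np.random.default_rng(s_eeg),
                  error_burst_gain=burst)
    fnirs = gen_fnirs(eeg, truth, cfg, np.random.default_rng(s_fnirs))
    return eeg, fnirs, truth


def group_config(cfg: SimConfig, group: str) -> SimConfig:
    """Group-specific generator parameters (duration and transition bias)."""
    tm = group_transition_matrix(cfg.k_true, group)
    return dataclasses.replace(
        cfg,
        mean_state_duration=GROUP_MEAN_DURATION.get(
            group, cfg.mean_state_duration),
        transition_matrix=tm,
    )


def group_transition_matrix(k: int, group: str) -> np.ndarray:
    """Deterministic structured transition matrices that differ by group.

    Novices: uniform off-diagonal. Experts: probability decaying with
    state-index distance, biasing transitions toward neighbouring states.
    """
    if group == "novice":
        m = np.full((k, k), 1.0)
    else:
        idx = np.arange(k)
        m = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]) ** 1.5)
    np.fill_diagonal(m, 0.0)
    return m / m.sum(axis=1, keepdims=True)


def gen_cohort(cfg: SimConfig, out_dir, overwrite: bool = False) -> dict:
    """Write the full two-group cohort to disk and return the manifest.

    Each subject directory holds a BrainVision EEG triplet, a SNIRF fNIRS
    file, an events TSV and a ground-truth archive. The manifest records
    per-subject seeds so re-running with the same master seed reproduces
    byte-identical arrays.
    """
    from . import io as msio

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise MsfusionError(f"output directory {out_dir} is not empty "
                            "(pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(cfg.seed)
    groups = ["novice"] * cfg.n_novices + ["expert"] * cfg.n_experts
    proto_ss, *subject_ss = master.spawn(len(groups) + 1)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in subject_ss]
    from .io import template_positions

    prototypes = gen_prototypes(
        cfg.k_true, cfg.n_channels_eeg, np.random.default_rng(proto_ss),
        positions=template_positions(cfg.n_channels_eeg))
    manifest = {"master_seed": int(cfg.seed), "subjects": []}
    for i, (group, seed) in enumerate(zip(groups, child_seeds)):
        sub_id = f"sub-{i + 1:02d}"
        sub_dir = out_dir / sub_id
        sub_dir.mkdir(exist_ok=True)
        gcfg = group_config(cfg, group)
        eeg, fnirs, truth = gen_subject(gcfg, seed, group,
                                        prototypes=prototypes)
        msio.write_brainvision(eeg, sub_dir / f"{sub_id}_eeg.vhdr")
        msio.write_snirf(fnirs, sub_dir / f"{sub_id}_fnirs.snirf")
        msio.write_events_tsv(truth.event_times, sub_dir / f"{sub_id}_events.tsv")
        np.savez_compressed(
            sub_dir / f"{sub_id}_truth.npz",
            state_sequence=truth.state_sequence,
            segment_starts=truth.segment_starts,
            segment_labels=truth.segment_labels,
            polarity_per_segment=truth.polarity_per_segment,
            prototypes_true=truth.prototypes_true,
            hrf_kernel=truth.hrf_kernel,
            mixing_weights=truth.mixing_weights,
            systemic_series=truth.systemic_series,
            neural_hbo=truth.neural_hbo,
            transition_matrix=gcfg.transition_matrix,
            mean_state_duration=gcfg.mean_state_duration,
        )
        manifest["subjects"].append(
            {"id": sub_id, "group": group, "seed": int(seed),
             "dir": sub_id})
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
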