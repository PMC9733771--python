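"""Configuration objects and YAML loading with strict validation."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .containers import MsfusionError

logger = logging.getLogger(__name__)


class ConfigError(MsfusionError):
    """Raised when a configuration file or object fails validation."""


def default_transition_matrix(k: int) -> np.ndarray:
    """Uniform off-diagonal transition matrix with zero diagonal."""
    if k < 2:
        raise ConfigError("need at least 2 states")
    m = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class SimConfig:
    """Parameters of the synthetic two-group EEG + fNIRS cohort.

    The acquisition constants mirror a mobile surgical-training study
    setup: 32-channel EEG at 500 Hz, 32 long-separation plus 8
    short-separation fNIRS channels at 5 Hz, with brain states modelled
    as quasi-stable scalp topographies of ~80 ms mean duration.

    Attributes
    ----------
    mean_state_duration : float
        Mean microstate segment duration in milliseconds.
    duration_shape : float
        Gamma shape of the segment-duration distribution.
    transition_matrix : ndarray or None
        Row-stochastic K x K matrix with zero diagonal; ``None`` means
        uniform off-diagonal.
    snr_db : float
        Sensor signal-to-noise ratio of the EEG in dB (signal variance over
        pink-noise variance). The default puts the group-level explained
        variance of the state model in the 0.7-0.8 range typical of scalp
        microstate analyses.
    hrf_peak_s, hrf_undershoot_s : float
        Peak and undershoot latencies of the double-gamma hemodynamic
        response kernel, seconds.
    systemic_freqs : tuple
        Frequencies (Hz) of the shared systemic physiology: Mayer wave,
        respiration, cardiac.
    trial_duration_s, n_trials, rest_duration_s : float, int, float
        Per-subject session layout: ``n_trials`` task blocks of
        ``trial_duration_s`` seconds separated by rests.
    """

    n_channels_eeg: int = 32
    n_ls: int = 32
    n_ss: int = 8
    fs_eeg: float = 500.0
    fs_fnirs: float = 5.0
    k_true: int = 6
    mean_state_duration: float = 80.0
    duration_shape: float = 2.0
    transition_matrix: np.ndarray | None = None
    snr_db: float = 10.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    systemic_freqs: tuple = (0.1, 0.25, 1.0)
    systemic_amp: float = 1.0
    coupling_strength: float = 1.0
    fnirs_noise_sd: float = 0.1
    n_novices: int = 13
    n_experts: int = 9
    events_per_trial: int = 5
    trial_duration_s: float = 90.0
    n_trials: int = 3
    rest_duration_s: float = 30.0
    noise_exponent: float = 1.0
    spatial_noise_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ConfigError("k_true must be >= 2")
        if not (self.fs_fnirs < self.fs_eeg):
            raise ConfigError("fs_fnirs must be below fs_eeg")
        for name in ("fs_eeg", "fs_fnirs", "mean_state_duration",
                     "duration_shape", "trial_duration_s", "rest_duration_s",
                     "hrf_peak_s", "hrf_undershoot_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.hrf_peak_s >= self.hrf_undershoot_s:
            raise ConfigError("hrf_peak_s must precede hrf_undershoot_s")
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.k_true)
        else:
            self.transition_matrix = validate_transition_matrix(
                np.asarray(self.transition_matrix, float), self.k_true
            )

    @property
    def session_duration_s(self) -> float:
        return self.n_trials * self.trial_duration_s + \
            (self.n_trials - 1) * self.rest_duration_s

    @property
    def n_subjects(self) -> int:
        return self.n_novices + self.n_experts


def validate_transition_matrix(m: np.ndarray, k: int) -> np.ndarray:
    if m.shape != (k, k):
        raise ConfigError(f"transition matrix must be {k}x{k}, got {m.shape}")
    if np.any(np.abs(np.diag(m)) > 0):
        raise ConfigError("transition matrix diagonal must be zero")
    if np.any(m < 0):
        raise ConfigError("transition matrix entries must be non-negative")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ConfigError("transition matrix rows must sum to 1")
    return m


@dataclass
class AnalysisConfig:
    """Parameters of the analysis chain (preprocessing through statistics)."""

    # EEG preprocessing
    eeg_target_fs: float = 250.0
    highpass_hz: float = 1.0
    line_freq: float = 60.0
    asr_k: float = 20.0
    bad_flat_sd: float = 1e-8
    bad_corr_r: float = 0.8
    max_bad_channels: int = 5
    microstates_on_laplacian: bool = False

    # fNIRS preprocessing
    nvc_low_hz: float = 0.01
    nvc_high_hz: float = 0.1
    sg_window_s: float = 10.0
    sg_order: int = 3
    motion_amp_od: float = 0.5
    motion_sd_factor: float = 50.0
    ss_threshold_mm: float = 15.0

    # microstates
    k_min: int = 2
    k_max: int = 8
    n_peaks_per_subject: int = 1000
    min_peak_distance_ms: float = 10.0
    gfp_sd_reject: float = 1.0
    kmeans_restarts: int = 100
    kmeans_max_iter: int = 1000
    kmeans_tol: float = 1e-6

    # backfitting
    min_segment_ms: float = 30.0
    epoch_length_s: float = 10.0

    # fusion
    band_low_hz: float = 1.0
    band_high_hz: float = 40.0
    tcca_max_lag_s: float = 8.0
    tcca_step_s: float = 0.4
    tcca_reg: float = 1e-4
    cca_ct: float = 0.99
    cca_max_n: int | None = 15
    drift_order: int = 3

    # statistics
    alpha: float = 0.05
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if self.asr_k <= 0:
            raise ConfigError("asr_k must be positive")
        if not (2 <= self.k_min <= self.k_max):
            raise ConfigError("need 2 <= k_min <= k_max")
        if self.nvc_low_hz >= self.nvc_high_hz:
            raise ConfigError("nvc band limits out of order")
        if self.band_low_hz >= self.band_high_hz:
            raise ConfigError("EEG band limits out of order")
        if self.drift_order < 0:
            raise ConfigError("drift_order must be >= 0")


@dataclass
class PipelineConfig:
    """Top-level configuration: simulation plus analysis plus run options."""

    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def _build_section(cls, raw: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown keys under '{path}': {sorted(unknown)}")
    try:
        return cls(**raw)
    except TypeError as exc:  # wrong value type
        raise ConfigError(f"invalid configuration under '{path}': {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load a YAML configuration, fill defaults and reject unknown keys.

    An empty file yields the full default configuration. The effective
    configuration is echoed to the log.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - {"sim", "analysis", "seed"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    sim = _build_section(SimConfig, raw.get("sim", {}) or {}, "sim")
    analysis = _build_section(AnalysisConfig, raw.get("analysis", {}) or {}, "analysis")
    cfg = PipelineConfig(sim=sim, analysis=analysis, seed=int(raw.get("seed", 0)))
    logger.info("effective configuration: %s", dump_config(cfg))
    return cfg


def dump_config(cfg: PipelineConfig) -> str:
    """Serialize a configuration back to YAML (round-trips with load)."""
    def as_dict(obj):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    return yaml.safe_dump(
        {"sim": as_dict(cfg.sim), "analysis": as_dict(cfg.analysis), "seed": cfg.seed},
        sort_keys=False,
    )
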