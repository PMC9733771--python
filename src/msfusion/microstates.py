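"""EEG microstate prototype extraction.

Global field power (GFP) is the spatial standard deviation of the scalp
map at one time point,

    GFP(t) = sqrt( (1/N) sum_i (EEG_i(t) - mean_i EEG(t))^2 ).

Candidate topographies are sampled at GFP peaks (high signal-to-noise
maps), clustered with the polarity-invariant modified K-means algorithm,
and scored by global explained variance

    GEV = sum_t (Corr(EEG(t), A_{l(t)}) * GFP(t))^2 / sum_t GFP(t)^2

and the cross-validation criterion

    CV = sigma^2 * ((C - 1) / (C - K - 1))^2,

where sigma^2 is the mean squared residual orthogonal to the assigned
prototypes, C the channel count and K the number of states. GEV grows
monotonically with K while CV penalizes cluster count; the model with
minimal CV is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .containers import EegRecording, MsfusionError

logger = logging.getLogger(__name__)


@dataclass
class GfpSeries:
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise MsfusionError("GFP must be non-negative")


@dataclass
class PeakSample:
    """A GFP-peak topography from one subject."""

    subject: str
    sample_index: int
    topography: np.ndarray
    gfp: float


@dataclass
class MicrostateModel:
    """K polarity-invariant prototype topographies with fit metrics."""

    prototypes: np.ndarray          # (K, C), zero-mean unit-norm rows
    k: int
    gev_total: float
    gev_per_state: np.ndarray
    cv: float
    sigma2: float = np.nan
    restarts: int = 0
    n_iter: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, float)
        norms = np.linalg.norm(self.prototypes, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MsfusionError("prototypes must be unit-norm")

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "prototypes": self.prototypes.tolist(),
            "gev_total": float(self.gev_total),
            "gev_per_state": np.asarray(self.gev_per_state).tolist(),
            "cv": float(self.cv),
            "sigma2": float(self.sigma2),
            "restarts": int(self.restarts),
            "n_iter": int(self.n_iter),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MicrostateModel":
        return cls(prototypes=np.asarray(d["prototypes"]), k=d["k"],
                   gev_total=d["gev_total"],
                   gev_per_state=np.asarray(d["gev_per_state"]),
                   cv=d["cv"], sigma2=d.get("sigma2", np.nan),
                   restarts=d.get("restarts", 0), n_iter=d.get("n_iter", 0),
                   seed=d.get("seed"))


# ---------------------------------------------------------------------------
# GFP and peaks

def compute_gfp(rec_or_maps, fs: float | None = None) -> GfpSeries:
    """Global field power: spatial SD of the scalp map at each sample."""
    if isinstance(rec_or_maps, EegRecording):
        data, fs = rec_or_maps.data, rec_or_maps.fs
    else:
        data = np.asarray(rec_or_maps, float)
        fs = fs or 1.0
    if data.shape[0] < 2:
        raise MsfusionError("GFP needs at least 2 channels")
    if np.any(~np.isfinite(data)):
        raise MsfusionError("NaN or inf in input")
    return GfpSeries(values=data.std(axis=0, ddof=0), fs=fs)


def find_gfp_peaks(gfp: GfpSeries, maps: np.ndarray,
                   min_dist_ms: float = 10.0, n_per_subject: int = 1000,
                   sd_reject: float = 1.0, seed=0,
                   subject: str = "") -> list[PeakSample]:
    """Sample high-SNR topographies at GFP local maxima.

    Peaks closer than ``min_dist_ms`` are thinned keeping the larger;
    outlying peaks with GFP above mean + ``sd_reject`` * SD of the whole
    GFP series are rejected; ``n_per_subject`` peaks are then drawn
    uniformly without replacement (all kept when fewer remain).
    """
    dist = max(int(round(min_dist_ms / 1000.0 * gfp.fs)), 1)
    idx, _ = scipy.signal.find_peaks(gfp.values, distance=dist)
    if idx.size == 0:
        raise MsfusionError("no GFP peaks found")
    if sd_reject is not None and np.isfinite(sd_reject):
        cut = gfp.values.mean() + sd_reject * gfp.values.std()
        idx = idx[gfp.values[idx] <= cut]
    if idx.size == 0:
        raise MsfusionError("all GFP peaks rejected as outliers")
    rng = np.random.default_rng(seed)
    if idx.size > n_per_subject:
        idx = np.sort(rng.choice(idx, size=n_per_subject, replace=False))
    maps = np.asarray(maps, float)
    maps = maps - maps.mean(axis=0, keepdims=True)  # average reference
    return [PeakSample(subject=subject, sample_index=int(i),
                       topography=maps[:, i].copy(), gfp=float(gfp.values[i]))
            for i in idx]


def samples_to_matrix(samples) -> np.ndarray:
    """Stack peak samples into an (n_samples, C) matrix."""
    if isinstance(samples, np.ndarray):
        return samples
    return np.asarray([s.topography for s in samples], float)


# ---------------------------------------------------------------------------
# modified K-means

def modified_kmeans(samples, k: int, restarts: int = 100,
                    max_iter: int = 1000, tol: float = 1e-6,
                    seed=0) -> MicrostateModel:
    """Polarity-invariant modified K-means clustering of topographies.

    Each map ``s`` is assigned to the prototype maximizing the squared
    projection (a_k^T s)^2 — sign-blind by construction — and each
    prototype is updated to the dominant eigenvector of its cluster's
    scatter matrix sum_s s s^T. Iterations stop when the relative change
    of the residual variance falls below ``tol``; the best of ``restarts``
    random initializations (by residual variance) wins. Prototypes are
    sorted in decreasing GEV on the sample set.
    """
    X = samples_to_matrix(samples)
    n, c = X.shape
    if n < k:
        raise MsfusionError(f"need at least {k} samples, got {n}")
    X = X - X.mean(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    total_ss = float(np.sum(X ** 2))

    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(max(restarts, 1)):
        A = _init_plusplus(X, k, rng)
        prev = np.inf
        for it in range(max_iter):
            proj = X @ A.T                      # (n, k)
            labels = np.argmax(proj ** 2, axis=1)
            resid = total_ss
            for j in range(k):
                members = labels == j
                if not members.any():
                    # re-seed from the worst-fit sample
                    fit = np.max(proj ** 2, axis=1) / (np.sum(X ** 2, axis=1)
                                                       + 1e-30)
                    worst = int(np.argmin(fit))
                    A[j] = X[worst] / (np.linalg.norm(X[worst]) + 1e-30)
                    labels[worst] = j
                    members = labels == j
                S = X[members].T @ X[members]
                w, V = np.linalg.eigh(S)
                A[j] = V[:, -1]
                resid -= w[-1]
            sigma2 = resid / (n * (c - 1))
            if np.isfinite(prev) and prev - sigma2 <= tol * max(prev, 1e-30):
                break
            prev = sigma2
        if best is None or sigma2 < best[0]:
            best = (sigma2, A.copy(), labels.copy(), it + 1)

    sigma2, A, labels, n_iter = best
    gev_total, gev_per_state = compute_gev(X.T, labels, A)
    order = np.argsort(gev_per_state)[::-1]
    A = A[order]
    remap = np.empty(k, int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    gev_per_state = gev_per_state[order]
    cv = compute_cv(sigma2, c, k) if k < c - 1 else np.nan
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return MicrostateModel(prototypes=A, k=k, gev_total=gev_total,
                           gev_per_state=gev_per_state, cv=cv, sigma2=sigma2,
                           restarts=restarts, n_iter=n_iter, seed=seed_val)


def _init_plusplus(X: np.ndarray, k: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """k-means++-style seeding with the polarity-invariant distance
    d(s, a) = 1 - (a^T s)^2 / ||s||^2 for unit-norm prototypes."""
    n = X.shape[0]
    norms2 = np.sum(X ** 2, axis=1) + 1e-30
    first = int(rng.integers(n))
    A = [X[first] / np.sqrt(norms2[first])]
    d = 1.0 - (X @ A[0]) ** 2 / norms2
    for _ in range(1, k):
        w = np.maximum(d, 0)
        total = w.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=w / total))
        a = X[idx] / np.sqrt(norms2[idx])
        A.append(a)
        d = np.minimum(d, 1.0 - (X @ a) ** 2 / norms2)
    return np.asarray(A)


def spatial_corr(maps: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Pearson spatial correlation between average-referenced maps and
    prototypes; maps (C, L), prototypes (K, C) -> (L, K)."""
    M = maps - maps.mean(axis=0, keepdims=True)
    P = prototypes - prototypes.mean(axis=1, keepdims=True)
    Mn = M / (np.linalg.norm(M, axis=0, keepdims=True) + 1e-30)
    Pn = P / (np.linalg.norm(P, axis=1, keepdims=True) + 1e-30)
    return Mn.T @ Pn.T


def compute_gev(maps: np.ndarray, labels: np.ndarray,
                prototypes: np.ndarray) -> tuple[float, np.ndarray]:
    """GFP-weighted explained variance of labeled maps.

    ``maps`` is (C, L); per-state terms partition the numerator by label.
    Polarity is handled by squaring the correlation.
    """
    maps = np.asarray(maps, float)
    labels = np.asarray(labels, int)
    gfp = maps.std(axis=0, ddof=0)
    denom = float(np.sum(gfp ** 2))
    if denom == 0:
        raise MsfusionError("zero total GFP")
    corr = spatial_corr(maps, prototypes)          # (L, K)
    corr_assigned = corr[np.arange(labels.size), labels]
    terms = (corr_assigned * gfp) ** 2
    k = prototypes.shape[0]
    per_state = np.array([terms[labels == j].sum() for j in range(k)]) / denom
    return float(per_state.sum()), per_state


def compute_cv(sigma2: float, c: int, k: int) -> float:
    """Cross-validation criterion sigma^2 * ((C-1)/(C-K-1))^2."""
    if k >= c - 1:
        raise MsfusionError("CV undefined for K >= C - 1")
    return float(sigma2 * ((c - 1) / (c - k - 1)) ** 2)


def select_k(samples, k_range=(2, 8), restarts: int = 100,
             max_iter: int = 1000, tol: float = 1e-6, seed=0
             ) -> tuple[MicrostateModel, pd.DataFrame]:
    """Fit each K in ``k_range`` and return the model with minimal CV.

    Also returns the (K, GEV, CV) table. Ties in CV go to the smaller K.
    """
    X = samples_to_matrix(samples)
    c = X.shape[1]
    k_min, k_max = k_range
    if not (2 <= k_min <= k_max <= c - 2):
        raise MsfusionError(f"k_range {k_range} outside validity [2, {c - 2}]")
    ss = np.random.SeedSequence(seed)
    rows = []
    models = {}
    for k, child in zip(range(k_min, k_max + 1),
                        ss.spawn(k_max - k_min + 1)):
        model = modified_kmeans(X, k, restarts=restarts, max_iter=max_iter,
                                tol=tol, seed=np.random.default_rng(child))
        models[k] = model
        rows.append({"k": k, "gev": model.gev_total, "cv": model.cv,
                     "sigma2": model.sigma2})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["cv"].idxmin(), "k"])  # idxmin: first min
    logger.info("selected K=%d by the CV criterion", best_k)
    return models[best_k], table
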