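"""Reconstruction of long-separation HbO from EEG band power.

The auxiliary (EEG band power) signals are temporally embedded — lagged
copies spanning the hemodynamic delay — and coupled to the long-separation
HbO channels by ridge-regularized canonical correlation analysis. The
canonical variates passing the correlation threshold become regressors in
a per-channel GLM together with the short-separation HbO channels
(systemic nuisance) and a Legendre polynomial drift basis; the EEG-only
part of the fit is the reconstructed neural HbO.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import MsfusionError

logger = logging.getLogger(__name__)


@dataclass
class EmbeddedDesign:
    """Lagged copies of the auxiliary signals, aligned with fNIRS samples."""

    matrix: np.ndarray                  # (n_rows, n_channels * n_lags)
    lags_s: np.ndarray
    provenance: list[tuple[int, float]]  # (channel, lag_s) per column
    row_offset: int                     # rows dropped from the start


@dataclass
class CcaResult:
    """Canonical correlations (descending) and auxiliary-side weights."""

    correlations: np.ndarray
    x_weights: np.ndarray               # (n_features, n_components)
    x_variates: np.ndarray              # (n_rows, n_components)
    row_offset: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.correlations, float)
        if np.any(np.diff(c) > 1e-9):
            raise MsfusionError("canonical correlations must be non-increasing")
        if np.any((c < -1e-9) | (c > 1 + 1e-9)):
            raise MsfusionError("canonical correlations must lie in [0, 1]")


@dataclass
class GlmFit:
    """Per-channel least-squares fit of the fused design."""

    beta: np.ndarray                    # (n_cols, n_ls)
    fitted: np.ndarray                  # (n_ls, n_rows)
    eeg_recon: np.ndarray               # (n_ls, n_rows)
    r_fit: np.ndarray                   # per-channel corr(fitted, observed)
    column_groups: dict = field(default_factory=dict)
    row_offset: int = 0


# ---------------------------------------------------------------------------

def nvc_bandlimit(aux: np.ndarray, fs: float, low: float = 0.01,
                  high: float = 0.1) -> np.ndarray:
    """Band-limit auxiliary signals to the neurovascular coupling band.

    The HbO side of the CCA is already confined to this band by the fNIRS
    preprocessing; leaving the band-power regressors broadband would put
    most of their variance where no coupling can exist and depress the
    canonical correlations.
    """
    import scipy.signal

    sos = scipy.signal.butter(3, [low, high], btype="bandpass", fs=fs,
                              output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(aux, float), axis=-1)


def temporal_embed(aux: np.ndarray, fs: float, max_lag_s: float = 8.0,
                   step_s: float = 0.4) -> EmbeddedDesign:
    """Build the lagged design: columns are aux channels delayed by
    0, step, ..., max_lag seconds (past values predict present HbO).

    Leading rows with incomplete history are dropped; ``row_offset``
    records how many, so the HbO side can be cropped consistently.
    """
    aux = np.atleast_2d(np.asarray(aux, float))
    n_ch, n = aux.shape
    step_samp = step_s * fs
    if abs(step_samp - round(step_samp)) > 1e-9:
        raise MsfusionError("lag step must be a multiple of 1/fs")
    step_samp = int(round(step_samp))
    n_lags = int(np.floor(max_lag_s / step_s)) + 1
    max_shift = (n_lags - 1) * step_samp
    if max_shift >= n:
        raise MsfusionError("max lag exceeds the recording length")
    rows = n - max_shift
    cols = np.empty((rows, n_ch * n_lags))
    prov = []
    lags = np.arange(n_lags) * step_s
    k = 0
    for ch in range(n_ch):
        for li in range(n_lags):
            shift = li * step_samp
            cols[:, k] = aux[ch, max_shift - shift: n - shift]
            prov.append((ch, float(lags[li])))
            k += 1
    return EmbeddedDesign(matrix=cols, lags_s=lags, provenance=prov,
                          row_offset=max_shift)


def regularized_cca(X, Y, reg: float = 0.01) -> CcaResult:
    """Ridge-regularized CCA between the embedded design and LS HbO.

    Both covariance blocks get an additive ridge scaled by their mean
    diagonal, C <- C + reg * mean(diag(C)) * I, so canonical correlations
    shrink monotonically toward 0 as ``reg`` grows. Returns descending
    correlations (clipped to [0, 1]) and the auxiliary-side variates.
    """
    if isinstance(X, EmbeddedDesign):
        offset = X.row_offset
        X = X.matrix
    else:
        offset = 0
        X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        if Y.shape[0] == X.shape[0] + offset:
            Y = Y[offset:]
        else:
            raise MsfusionError("row mismatch between X and Y")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Cxx = _shrink(Xc.T @ Xc / n, reg)
    Cyy = _shrink(Yc.T @ Yc / n, reg)
    Cxy = Xc.T @ Yc / n
    try:
        Lx = np.linalg.cholesky(Cxx)
        Ly = np.linalg.cholesky(Cyy)
    except np.linalg.LinAlgError as exc:
        raise MsfusionError("rank-deficient covariance; increase reg") from exc
    K = scipy.linalg.solve_triangular(Lx, Cxy, lower=True)
    K = scipy.linalg.solve_triangular(Ly, K.T, lower=True).T
    U, s, _ = np.linalg.svd(K, full_matrices=False)
    corrs = np.clip(s, 0.0, 1.0)
    Wx = scipy.linalg.solve_triangular(Lx.T, U, lower=False)
    variates = Xc @ Wx
    sd = variates.std(axis=0)
    sd[sd == 0] = 1.0
    variates /= sd
    Wx /= sd
    return CcaResult(correlations=corrs, x_weights=Wx, x_variates=variates,
                     row_offset=offset)


def _shrink(C: np.ndarray, reg: float) -> np.ndarray:
    scale = float(np.mean(np.diag(C)))
    if scale <= 0:
        scale = 1.0
    return C + (reg + 1e-12) * scale * np.eye(C.shape[0])


def select_regressors(cca: CcaResult, ct: float = 0.99,
                      max_n: int | None = None) -> np.ndarray:
    """Keep canonical variates whose correlation exceeds ``ct``.

    Returns an (n_rows, n_selected) matrix; the count is reported, not
    enforced. An empty selection triggers a warning (the GLM then falls
    back to nuisance-only regression).
    """
    keep = cca.correlations > ct
    if max_n is not None:
        keep &= np.arange(keep.size) < max_n
    n_sel = int(keep.sum())
    logger.info("selected %d EEG-derived regressors (ct=%.3g)", n_sel, ct)
    if n_sel == 0:
        warnings.warn("no canonical variate passed the threshold; "
                      "GLM will use nuisance regressors only")
    return cca.x_variates[:, keep]


def build_design(regressors: np.ndarray, ss_hbo: np.ndarray | None,
                 drift_order: int = 3) -> tuple[np.ndarray, dict]:
    """Stack EEG regressors, SS HbO nuisance channels and a Legendre drift
    basis; standardize all non-constant columns and drop collinear ones.

    Returns the design matrix and a dict of column index groups
    ("eeg", "ss", "drift").
    """
    blocks = []
    groups = {}
    col = 0
    reg = np.atleast_2d(np.asarray(regressors, float))
    if reg.shape[0] < reg.shape[1] and reg.shape[0] > 0 and reg.size:
        reg = reg.T
    if reg.shape[0] > 0:
        n_rows = reg.shape[0]
    elif ss_hbo is not None and np.asarray(ss_hbo).size:
        n_rows = np.asarray(ss_hbo).shape[1]
    else:
        raise MsfusionError("empty design: no regressors at all")
    if reg.size:
        blocks.append(_standardize(reg))
        groups["eeg"] = list(range(col, col + reg.shape[1]))
        col += reg.shape[1]
    else:
        groups["eeg"] = []
    if ss_hbo is not None and ss_hbo.size:
        ss = np.asarray(ss_hbo, float).T  # channels x time -> rows x ch
        if ss.shape[0] != n_rows:
            raise MsfusionError("SS regressor rows misaligned with design")
        blocks.append(_standardize(ss))
        groups["ss"] = list(range(col, col + ss.shape[1]))
        col += ss.shape[1]
    else:
        groups["ss"] = []
    t = np.linspace(-1.0, 1.0, n_rows)
    drift = np.polynomial.legendre.legvander(t, drift_order)
    blocks.append(drift)
    groups["drift"] = list(range(col, col + drift.shape[1]))
    X = np.hstack(blocks)

    # drop duplicate/degenerate columns (keep the constant drift term)
    keep = _independent_columns(X, protected=groups["drift"][0])
    if len(keep) < X.shape[1]:
        warnings.warn(f"dropped {X.shape[1] - len(keep)} collinear or "
                      "constant design columns")
        remap = {old: new for new, old in enumerate(keep)}
        groups = {g: [remap[i] for i in idx if i in remap]
                  for g, idx in groups.items()}
        X = X[:, keep]
    cond = np.linalg.cond(X)
    logger.info("design: %d columns, condition number %.3g", X.shape[1], cond)
    return X, groups


def _standardize(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return M / sd


def _independent_columns(X: np.ndarray, protected: int,
                         tol: float = 1e-8) -> list[int]:
    keep: list[int] = []
    basis = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        v = X[:, j]
        if j != protected and v.std() == 0:
            continue
        if basis.shape[1]:
            proj = basis @ (basis.T @ v)
            resid = v - proj
        else:
            resid = v
        norm = np.linalg.norm(resid)
        if norm > tol * max(np.linalg.norm(v), 1.0):
            keep.append(j)
            basis = np.hstack([basis, (resid / norm)[:, None]])
    return keep


def glm_solve(ls_hbo: np.ndarray, design: np.ndarray,
              column_groups: dict | None = None,
              row_offset: int = 0) -> GlmFit:
    """Ordinary least squares per LS channel.

    ``ls_hbo`` is (n_ls, n_samples); rows beyond the design length are
    assumed to be the dropped embedding history and trimmed from the
    front. The EEG-only reconstruction uses the "eeg" column group.
    """
    Y = np.asarray(ls_hbo, float)
    if Y.ndim == 1:
        Y = Y[None, :]
    n_rows = design.shape[0]
    if Y.shape[1] != n_rows:
        if Y.shape[1] == n_rows + row_offset:
            Y = Y[:, row_offset:]
        else:
            raise MsfusionError("row mismatch between design and HbO")
    if n_rows < design.shape[1]:
        raise MsfusionError("fewer rows than design columns; reduce lags "
                            "or strengthen regularization")
    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    fitted = (design @ beta).T
    groups = column_groups or {"eeg": list(range(design.shape[1]))}
    eeg_cols = groups.get("eeg", [])
    if eeg_cols:
        eeg_recon = (design[:, eeg_cols] @ beta[eeg_cols]).T
    else:
        eeg_recon = np.zeros_like(fitted)
    r_fit = _rowwise_corr(fitted, Y)
    return GlmFit(beta=beta, fitted=fitted, eeg_recon=eeg_recon,
                  r_fit=r_fit, column_groups=groups, row_offset=row_offset)


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    out = np.zeros(a.shape[0])
    nz = denom > 0
    out[nz] = np.sum(a * b, axis=1)[nz] / denom[nz]
    return out


def epoch_response(fit: GlmFit, events, fs: float, length_s: float = 10.0,
                   recording_offset_s: float = 0.0) -> np.ndarray | None:
    """Average per-channel EEG-reconstructed HbO over event windows.

    Returns (n_ls, n_window_samples) or ``None`` when no usable events
    remain. ``recording_offset_s`` accounts for rows dropped by the
    temporal embedding.
    """
    n_len = int(round(length_s * fs))
    n = fit.eeg_recon.shape[1]
    windows = []
    onsets = events.onsets if hasattr(events, "onsets") else np.asarray(events)
    for onset in onsets:
        start = int(round((onset - recording_offset_s) * fs))
        if start < 0 or start + n_len > n:
            continue
        windows.append(fit.eeg_recon[:, start:start + n_len])
    if not windows:
        warnings.warn("no events with a complete response window")
        return None
    return np.mean(windows, axis=0)
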