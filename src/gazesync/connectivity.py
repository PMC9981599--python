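"""Synchrony statistics: PLV, PDC and ITC.

PLV (phase locking value) is the magnitude of the mean unit phasor of the
phase *difference* between two channels within a temporal window; ITC
(inter-trial coherence) is the same circular mean taken over trials at a
fixed peri-event time; both lie in [0, 1].  PDC (partial directed
coherence) is a frequency-domain directed-influence measure computed from
the coefficients of a bivariate autoregressive (VAR) model, here the
standard column-normalised form

    PDC_{j -> i}(f) = |Abar_ij(f)| / sqrt(sum_m |Abar_mj(f)|^2),

with Abar(f) = I - sum_k A_k exp(-2 pi i f k / fs).  VAR models are fitted
by least squares on lagged regressors, pooling disjoint segments or trials
without crossing segment boundaries; model order is selected by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VARModel",
    "SynchronyMap",
    "fit_var",
    "select_var_order_bic",
    "var_spectral_matrix",
    "pdc_from_var",
    "pdc_windowed",
    "plv",
    "plv_windowed",
    "itc",
    "event_locked_plv",
    "event_locked_pdc",
]


@dataclass
class VARModel:
    """Bivariate VAR(p): x_t = sum_k A_k x_{t-k} + e_t, cov(e) = sigma."""

    coefs: np.ndarray  # (p, 2, 2)
    sigma: np.ndarray  # (2, 2)
    fs: float
    n_obs: int = 0

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    def companion_spectral_radius(self) -> float:
        p = self.order
        d = self.coefs.shape[1]
        comp = np.zeros((d * p, d * p))
        comp[:d, :] = np.concatenate(list(self.coefs), axis=1)
        if p > 1:
            comp[d:, : d * (p - 1)] = np.eye(d * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.companion_spectral_radius() < tol


@dataclass
class SynchronyMap:
    """One synchrony metric on the wavelet grid.

    ``values`` is (n_freqs, n_times) for event-locked maps or (n_freqs,)
    for non-event-locked (time-collapsed) values; all entries in [0, 1].
    """

    metric: str
    values: np.ndarray
    freqs: np.ndarray
    times: Optional[np.ndarray] = None
    electrodes: Sequence[str] = ()
    n_trials: Optional[int] = None

    @property
    def low_confidence(self) -> bool:
        """Fewer than 5 trials entered this map (inclusion rule)."""
        return self.n_trials is not None and self.n_trials < 5


# --------------------------------------------------------------------------
# VAR fitting


def _as_segments(x, y=None):
    """Normalise input to a list of (T_i, 2) float arrays."""
    if y is not None:
        x = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    if isinstance(x, np.ndarray):
        if x.ndim != 2 or x.shape[1] != 2:
            raise ValueError("expected a (T, 2) array of paired series")
        return [x.astype(float)]
    return [np.asarray(s, float) for s in x]


def _lagged_design(segments, p):
    """Stacked (targets, lagged regressors) excluding cross-segment lags."""
    ys, xs = [], []
    for seg in segments:
        T = seg.shape[0]
        if T <= p:
            continue
        ys.append(seg[p:])
        xs.append(np.concatenate([seg[p - k : T - k] for k in range(1, p + 1)], axis=1))
    if not ys:
        raise ValueError(f"no segment longer than the model order {p}")
    return np.concatenate(ys), np.concatenate(xs)


def fit_var(x, y=None, order: int = 5, fs: float = 1.0) -> VARModel:
    """Least-squares bivariate VAR fit, pooling segments.

    ``x`` may be a (T, 2) array, a list of (T_i, 2) segments, or a 1-D
    series with ``y`` the second series.
    """
    segments = _as_segments(x, y)
    p = int(order)
    if p < 1:
        raise ValueError("order must be >= 1")
    Y, X = _lagged_design(segments, p)
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("ill-conditioned VAR regression")
    resid = Y - X @ B
    n = Y.shape[0]
    sigma = resid.T @ resid / max(n - 2 * p, 1)
    coefs = np.stack([B[2 * k : 2 * (k + 1)].T for k in range(p)])
    return VARModel(coefs=coefs, sigma=sigma, fs=fs, n_obs=n)


def _bic(model: VARModel) -> float:
    # ln det(innovation covariance) + p d^2 ln(T)/T, d = 2
    sign, logdet = np.linalg.slogdet(model.sigma)
    if sign <= 0:
        return np.inf
    T = model.n_obs
    return float(logdet + model.order * 4.0 * np.log(T) / T)


def select_var_order_bic(x, y=None, max_order: int = 10, per_segment: bool = False):
    """BIC-minimising VAR order on the grid 1..max_order.

    With ``per_segment=True`` (segment collections) each segment is
    scored independently and the per-segment orders are averaged and
    rounded — the convention for per-look segment data.
    """
    segments = _as_segments(x, y)
    if per_segment:
        orders = [
            select_var_order_bic([seg], max_order=max_order) for seg in segments
            if seg.shape[0] > max_order + 2
        ]
        if not orders:
            raise ValueError("no segment long enough for order selection")
        return int(round(float(np.mean(orders))))
    bics = []
    for p in range(1, max_order + 1):
        try:
            bics.append(_bic(fit_var(segments, order=p)))
        except (ValueError, np.linalg.LinAlgError):
            bics.append(np.inf)
    if not np.isfinite(bics).any():
        raise ValueError("order selection failed on all candidate orders")
    return int(np.argmin(bics) + 1)


# --------------------------------------------------------------------------
# PDC


def var_spectral_matrix(coefs: np.ndarray, freqs, fs: float) -> np.ndarray:
    """Abar(f) = I - sum_k A_k e^{-2 pi i f k / fs}, shape (F, d, d)."""
    coefs = np.asarray(coefs)
    freqs = np.atleast_1d(np.asarray(freqs, float))
    p, d, _ = coefs.shape
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)  # (F, p)
    out = np.eye(d)[None] - np.einsum("fk,kij->fij", phase, coefs.astype(complex))
    return out


def pdc_from_var(model, freqs, fs: Optional[float] = None) -> np.ndarray:
    """Column-normalised PDC, shape (d, d, F); [i, j] is source j -> target i.

    ``model`` may be a VARModel or a raw (p, d, d) coefficient array (then
    ``fs`` is required).
    """
    if isinstance(model, VARModel):
        coefs, fs = model.coefs, model.fs
    else:
        coefs = np.asarray(model)
        if fs is None:
            raise ValueError("fs required when passing raw coefficients")
    A = var_spectral_matrix(coefs, freqs, fs)  # (F, d, d)
    denom = np.sqrt((np.abs(A) ** 2).sum(axis=1, keepdims=True))  # per column j
    pdc = np.abs(A) / np.where(denom == 0, 1.0, denom)
    return np.moveaxis(pdc, 0, -1)  # (d, d, F)


def pdc_windowed(
    x,
    y=None,
    fs: float = 512.0,
    order: int = 5,
    freqs=None,
    window_s: float = 1.0,
):
    """PDC in non-overlapping windows, averaged over windows.

    Windows are carved within each segment (never across boundaries); a
    window with an unstable or singular fit is skipped and counted.
    Returns (SynchronyMap x->y, SynchronyMap y->x, info dict).
    """
    from .timefreq import default_freqs

    freqs = default_freqs() if freqs is None else np.atleast_1d(np.asarray(freqs, float))
    segments = _as_segments(x, y)
    w = int(round(window_s * fs))
    vals_xy, vals_yx, skipped = [], [], 0
    for seg in segments:
        for i in range(seg.shape[0] // w):
            win = seg[i * w : (i + 1) * w]
            try:
                m = fit_var(win, order=order, fs=fs)
            except (ValueError, np.linalg.LinAlgError):
                skipped += 1
                continue
            if not m.is_stable(tol=1.0 + 1e-8):
                skipped += 1
                continue
            p = pdc_from_var(m, freqs)
            vals_xy.append(p[1, 0])
            vals_yx.append(p[0, 1])
    if not vals_xy:
        raise ValueError("no analysable window")
    mean_xy = np.mean(vals_xy, axis=0)
    mean_yx = np.mean(vals_yx, axis=0)
    info = {"n_windows": len(vals_xy), "n_skipped": skipped}
    return (
        SynchronyMap("PDC_x->y", mean_xy, freqs, n_trials=len(vals_xy)),
        SynchronyMap("PDC_y->x", mean_yx, freqs, n_trials=len(vals_yx)),
        info,
    )


# --------------------------------------------------------------------------
# phase statistics


def plv(phase_x, phase_y, axis=-1):
    """|mean exp(i(phi - psi))| along ``axis``."""
    d = np.asarray(phase_x) - np.asarray(phase_y)
    return np.abs(np.exp(1j * d).mean(axis=axis))


def plv_windowed(phase_x, phase_y, fs: float, window_s: float = 1.0):
    """PLV in non-overlapping windows along the last axis.

    Input phases have shape (..., T); output (..., n_windows).
    """
    phase_x = np.asarray(phase_x)
    phase_y = np.asarray(phase_y)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase arrays must be the same shape")
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError("window must contain at least 2 samples")
    T = phase_x.shape[-1]
    n_win = T // w
    if n_win == 0:
        raise ValueError("series shorter than one window")
    d = phase_x[..., : n_win * w] - phase_y[..., : n_win * w]
    ph = np.exp(1j * d).reshape(d.shape[:-1] + (n_win, w))
    return np.abs(ph.mean(axis=-1))


def itc(phases, axis=0):
    """Inter-trial coherence: |mean_k exp(i phi_k)| over the trial axis."""
    phases = np.asarray(phases)
    if phases.shape[axis] < 2:
        raise ValueError("ITC needs at least 2 trials")
    return np.abs(np.exp(1j * phases).mean(axis=axis))


def event_locked_plv(phases_x, phases_y, freqs=None, times=None) -> SynchronyMap:
    """Across-trial phase-difference consistency at each (f, t).

    Inputs are (n_trials, n_freqs, n_times) phase arrays from both
    partners' epochs on the identical clock.
    """
    phases_x = np.asarray(phases_x)
    phases_y = np.asarray(phases_y)
    if phases_x.shape != phases_y.shape:
        raise ValueError("epoch phase arrays must align")
    k = phases_x.shape[0]
    if k < 2:
        raise ValueError("need at least 2 trials")
    vals = np.abs(np.exp(1j * (phases_x - phases_y)).mean(axis=0))
    f = np.arange(vals.shape[0]) if freqs is None else np.asarray(freqs)
    return SynchronyMap("PLV", vals, f, times=times, n_trials=k)


def event_locked_pdc(
    epochs_x,
    epochs_y,
    fs: float,
    order: int = 5,
    freqs=None,
    window_s: float = 1.0,
    step_s: float = 0.1,
    t_start: float = -2.5,
):
    """Time-varying PDC across the peri-event axis.

    A 1-s window slides in ``step_s`` steps; per window a single VAR is
    fitted pooling the per-trial slices as disjoint segments (no lags
    across trials), and PDC is evaluated on the wavelet grid at the
    window centre.  Returns (SynchronyMap x->y, SynchronyMap y->x).
    """
    from .timefreq import default_freqs

    freqs = default_freqs() if freqs is None else np.atleast_1d(np.asarray(freqs, float))
    X = np.asarray(epochs_x, float)
    Y = np.asarray(epochs_y, float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("epochs must be matching (n_trials, n_samples) arrays")
    k, T = X.shape
    w = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    starts = np.arange(0, T - w + 1, step)
    centres = t_start + (starts + w / 2) / fs
    maps_xy = np.full((len(freqs), len(starts)), np.nan)
    maps_yx = np.full((len(freqs), len(starts)), np.nan)
    for i, s in enumerate(starts):
        segs = [np.column_stack([X[t, s : s + w], Y[t, s : s + w]]) for t in range(k)]
        try:
            m = fit_var(segs, order=order, fs=fs)
        except (ValueError, np.linalg.LinAlgError):
            continue
        p = pdc_from_var(m, freqs)
        maps_xy[:, i] = p[1, 0]
        maps_yx[:, i] = p[0, 1]
    return (
        SynchronyMap("PDC_x->y", maps_xy, freqs, times=centres, n_trials=k),
        SynchronyMap("PDC_y->x", maps_yx, freqs, times=centres, n_trials=k),
    )
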