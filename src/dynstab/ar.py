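"""Sliding-window least-squares identification of linear dynamics.

Each window of a recording is modelled as a first-order linear system
``x(k) = A x(k-1) + eps(k)`` and the transition matrix ``A`` is estimated by
ordinary least squares (minimum-norm pseudoinverse solution, so rank-deficient
windows still return the minimum-norm fit). Model-order diagnostics (AIC/BIC
over VAR(p) fits) are provided separately; all eigenmode analysis downstream
operates on the first-order fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording, WindowIndex, slice_windows

__all__ = [
    "WindowModel",
    "ModelTrack",
    "fit_ar1_window",
    "fit_sliding",
    "select_order",
    "OrderSelection",
]


@dataclass
class WindowModel:
    """A fitted transition matrix for one window.

    ``degenerate`` marks windows whose lagged regressors are rank-deficient
    (rank < n channels): the minimum-norm fit is still returned but the
    dynamics are not uniquely identified there.
    """

    A: np.ndarray
    window: WindowIndex
    residual_cov: np.ndarray
    r2: np.ndarray
    fs: float
    rank: int
    degenerate: bool
    flags: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.A)).max())


@dataclass
class ModelTrack:
    """Ordered per-window models over a recording."""

    models: list[WindowModel]
    window_s: float
    shift_s: float
    channel_labels: list[str]
    fs: float
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        centers = [m.window.center_time for m in self.models]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("window centers must be strictly increasing")
        dims = {m.n_channels for m in self.models}
        if len(dims) > 1:
            raise ValueError("all window models must share the channel count")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    @property
    def centers(self) -> np.ndarray:
        return np.array([m.window.center_time for m in self.models])

    @property
    def n_channels(self) -> int:
        return self.models[0].n_channels

    def event_time(self, label: str) -> float:
        for ev in self.events:
            if ev.label == label:
                return ev.t_start
        raise KeyError(f"no event labelled {label!r}")

    def onset_windows(self, count: int, label: str = "UEO",
                      fully_after: bool = False) -> list[int]:
        """Indices of the first ``count`` windows at/after the labelled onset.

        With ``fully_after=True`` only windows whose whole span lies after the
        onset are used (no pre-onset samples mixed into the fit).
        """
        t0 = self.event_time(label)
        if fully_after:
            idx = [i for i, m in enumerate(self.models)
                   if m.window.start / self.fs >= t0]
        else:
            idx = [i for i, m in enumerate(self.models)
                   if m.window.center_time >= t0]
        if len(idx) < count:
            raise ValueError(
                f"only {len(idx)} windows at/after {label}; {count} requested")
        return idx[:count]


def fit_ar1_window(
    segment: np.ndarray,
    fs: float,
    window: WindowIndex | None = None,
    ridge: float = 0.0,
) -> WindowModel:
    """Least-squares fit of ``x(k) = A x(k-1)`` on one channels x w segment.

    The estimate minimizes ``sum_k ||x(k) - A x(k-1)||^2``; it is computed
    through the pseudoinverse of the lagged regressors, which returns the
    minimum-norm solution when the window is rank-deficient. No intercept is
    fitted (recordings are assumed high-passed, so channel means are ~0).
    An optional ridge penalty (default 0: plain least squares) regularizes
    the Gram matrix.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2:
        raise ValueError("segment must be channels x samples")
    n, w = segment.shape
    if w < 2:
        raise ValueError("window must contain at least 2 samples")
    X = segment[:, :-1]
    Y = segment[:, 1:]
    if ridge > 0:
        G = X @ X.T + ridge * np.eye(n)
        A = Y @ X.T @ np.linalg.inv(G)
    else:
        A = Y @ np.linalg.pinv(X)
    rank = int(np.linalg.matrix_rank(X))
    resid = Y - A @ X
    t_eff = w - 1
    residual_cov = resid @ resid.T / t_eff
    var_y = Y.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var_y > 0, 1.0 - resid.var(axis=1) / var_y, 0.0)
    if window is None:
        window = WindowIndex(0, w, w / (2 * fs))
    return WindowModel(
        A=A, window=window, residual_cov=residual_cov, r2=r2, fs=fs,
        rank=rank, degenerate=rank < n,
        flags=["degenerate"] if rank < n else [],
    )


def fit_sliding(
    rec: Recording,
    window_s: float = 1.0,
    shift_s: float = 0.1,
    ridge: float = 0.0,
) -> ModelTrack:
    """Fit one :func:`fit_ar1_window` per sliding window of the recording."""
    windows = slice_windows(rec, window_s, shift_s)
    models = []
    for win in windows:
        try:
            models.append(
                fit_ar1_window(rec.data[:, win.start:win.stop], rec.fs,
                               window=win, ridge=ridge)
            )
        except Exception as exc:
            raise RuntimeError(
                f"fit failed in window [{win.start}, {win.stop})") from exc
    return ModelTrack(
        models=models, window_s=window_s, shift_s=shift_s,
        channel_labels=list(rec.channel_labels), fs=rec.fs,
        events=list(rec.events),
    )


@dataclass(frozen=True)
class OrderSelection:
    orders: tuple[int, ...]
    aic: tuple[float, ...]
    bic: tuple[float, ...]
    aic_order: int
    bic_order: int
    singular_cov: bool


def _log_det_psd(S: np.ndarray) -> tuple[float, bool]:
    """log(det S) for a PSD matrix; falls back to the log pseudo-determinant
    (sum of logs of positive eigenvalues) when S is singular."""
    eig = np.linalg.eigvalsh(S)
    tol = max(S.shape[0], 1) * np.finfo(float).eps * max(eig.max(), 0.0)
    pos = eig[eig > tol]
    singular = len(pos) < len(eig)
    if len(pos) == 0:
        return -np.inf, True
    return float(np.sum(np.log(pos))), singular


def select_order(segment: np.ndarray, p_max: int) -> OrderSelection:
    """AIC/BIC model-order diagnostics for VAR(p), p = 1..p_max.

    Each order is fitted by least squares without intercept on its own
    ``w - p`` regression targets;
    ``AIC(p) = ln det(Sigma_p) + 2 p n^2 / T_eff`` and
    ``BIC(p) = ln det(Sigma_p) + p n^2 ln(T_eff) / T_eff``.
    """
    segment = np.asarray(segment, dtype=float)
    n, w = segment.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if w <= n * p_max + 1:
        raise ValueError("segment too short to fit VAR(p_max)")
    aics, bics = [], []
    singular = False
    for p in range(1, p_max + 1):
        Y = segment[:, p:]
        X = np.vstack([segment[:, p - l:w - l] for l in range(1, p + 1)])
        coeffs = Y @ np.linalg.pinv(X)
        resid = Y - coeffs @ X
        t_eff = w - p
        sigma = resid @ resid.T / t_eff
        ld, sing = _log_det_psd(sigma)
        singular = singular or sing
        aics.append(ld + 2.0 * p * n**2 / t_eff)
        bics.append(ld + p * n**2 * np.log(t_eff) / t_eff)
    orders = tuple(range(1, p_max + 1))
    return OrderSelection(
        orders=orders,
        aic=tuple(aics),
        bic=tuple(bics),
        aic_order=orders[int(np.argmin(aics))],
        bic_order=orders[int(np.argmin(bics))],
        singular_cov=singular,
    )
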