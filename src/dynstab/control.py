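"""Static output feedback design by generalized pole placement.

Given per-window transition matrices ``A_j`` from a switching linear system,
the goal is one constant gain ``K`` such that the closed loops
``A_j + B K C`` have their fast, persistent oscillatory eigenvalues pulled
toward a damped target radius. ``B`` and ``C`` are selection matrices picking
the stimulating and sensing electrode subsets.

The design splits into two sub-problems:

1. exact, per window — eigenvector-preserving spectrum reassignment: replace
   every eigenvalue with frequency above ``f_thresh`` and modulus above
   ``r_target`` by ``r_target * exp(i * angle)`` (angle preserved, conjugate
   symmetry maintained) and rebuild ``A~_j = Re(V Lambda~ V^-1)``, giving the
   exactly-stabilizing perturbation ``Delta_j = A~_j - A_j``;
2. least squares, across windows — project onto the actuation-realizable set:
   ``K = argmin_K sum_j ||B K C - Delta_j||_F^2``, a convex quadratic whose
   unique minimizer for selection matrices is the entrywise mean of the
   ``Delta_j`` restricted to the stimulated rows and sensed columns.

With all electrodes actuated and a single window the placement is exact; a
classical state-feedback pole placement (Kautsky-Nichols) is provided as the
all-electrode baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import place_poles

from .modes import BandDefinition, ModeTable

__all__ = [
    "ActuationSpec",
    "TargetSpec",
    "FeedbackDesign",
    "DefectiveMatrixError",
    "desired_spectrum",
    "reassign_spectrum",
    "design_static_output_feedback",
    "design_gain",
    "place_state_feedback",
    "select_electrodes",
    "spectrum_distance",
]


class DefectiveMatrixError(np.linalg.LinAlgError):
    """Raised when a window matrix is not diagonalizable to tolerance."""


@dataclass(frozen=True)
class ActuationSpec:
    """Electrode subsets used for stimulation (rows of B) and sensing
    (rows of C); both are identity selections into an n-channel system."""

    stim_idx: tuple[int, ...]
    sense_idx: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        for name, idx in (("stim", self.stim_idx), ("sense", self.sense_idx)):
            if len(idx) < 1:
                raise ValueError(f"at least one {name} electrode required")
            if len(set(idx)) != len(idx):
                raise ValueError(f"{name} indices must be unique")
            if any(not 0 <= i < self.n for i in idx):
                raise ValueError(f"{name} indices out of range")

    @property
    def B(self) -> np.ndarray:
        B = np.zeros((self.n, len(self.stim_idx)))
        B[list(self.stim_idx), range(len(self.stim_idx))] = 1.0
        return B

    @property
    def C(self) -> np.ndarray:
        C = np.zeros((len(self.sense_idx), self.n))
        C[range(len(self.sense_idx)), list(self.sense_idx)] = 1.0
        return C


@dataclass(frozen=True)
class TargetSpec:
    """Retargeting rule: eigenvalues with frequency above ``f_thresh`` (Hz)
    and modulus above ``r_target`` are pulled onto the circle of radius
    ``r_target`` (angle preserved)."""

    f_thresh: float = 15.0
    r_target: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.r_target < 1:
            raise ValueError("r_target must lie in (0, 1)")
        if self.f_thresh < 0:
            raise ValueError("f_thresh must be >= 0")


@dataclass
class FeedbackDesign:
    """A designed static output feedback gain and its provenance."""

    K: np.ndarray  # |stim| x |sense|
    actuation: ActuationSpec
    target: TargetSpec
    objective_value: float  # sum_j ||B K C - Delta_j||_F^2
    per_window_residuals: list[float]
    source_windows: list[int]
    fs: float

    @property
    def BKC(self) -> np.ndarray:
        return self.actuation.B @ self.K @ self.actuation.C

    def closed_loop_matrix(self, A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        if A.shape != (self.actuation.n, self.actuation.n):
            raise ValueError("dimension mismatch between design and matrix")
        return A + self.BKC

    def to_json_dict(self) -> dict:
        return {
            "stim_idx": list(self.actuation.stim_idx),
            "sense_idx": list(self.actuation.sense_idx),
            "f_thresh_hz": self.target.f_thresh,
            "r_target": self.target.r_target,
            "K": self.K.ravel().tolist(),  # row-major
            "K_shape": list(self.K.shape),
            "objective_value": self.objective_value,
            "source_windows": list(self.source_windows),
            "fs": self.fs,
        }

    @classmethod
    def from_json_dict(cls, d: dict, n: int) -> "FeedbackDesign":
        act = ActuationSpec(tuple(d["stim_idx"]), tuple(d["sense_idx"]), n)
        K = np.asarray(d["K"], dtype=float).reshape(d["K_shape"])
        return cls(K=K, actuation=act,
                   target=TargetSpec(d["f_thresh_hz"], d["r_target"]),
                   objective_value=float(d["objective_value"]),
                   per_window_residuals=[],
                   source_windows=list(d["source_windows"]),
                   fs=float(d["fs"]))


def _check_conjugate_symmetric(eigvals: np.ndarray, rtol: float = 1e-8) -> None:
    scale = max(1.0, float(np.abs(eigvals).max(initial=0.0)))
    if spectrum_distance(eigvals, np.conj(eigvals)) > rtol * scale:
        raise ValueError("spectrum is not conjugate-symmetric")


def spectrum_distance(w1, w2) -> float:
    """Greatest pairing distance between two eigenvalue multisets under the
    optimal one-to-one assignment."""
    w1 = np.atleast_1d(np.asarray(w1, dtype=complex))
    w2 = np.atleast_1d(np.asarray(w2, dtype=complex))
    if w1.shape != w2.shape:
        raise ValueError("spectra must have equal length")
    cost = np.abs(w1[:, None] - w2[None, :])
    r, c = linear_sum_assignment(cost)
    return float(cost[r, c].max())


def desired_spectrum(
    eigvals: np.ndarray, target: TargetSpec, fs: float
) -> np.ndarray:
    """Target eigenvalue multiset under the retargeting rule.

    Eigenvalues with frequency ``|angle| * fs / (2 pi)`` strictly above
    ``f_thresh`` and modulus strictly above ``r_target`` move to
    ``r_target * exp(i * angle)``; everything else (slow modes, and fast
    modes already inside the target radius) is left unchanged. Real
    eigenvalues above threshold map to ``+/- r_target`` preserving sign.
    Conjugate partners receive conjugate targets by construction.
    """
    eigvals = np.asarray(eigvals, dtype=complex)
    _check_conjugate_symmetric(eigvals)
    out = eigvals.copy()
    freqs = np.abs(np.angle(eigvals)) * fs / (2 * math.pi)
    move = (freqs > target.f_thresh) & (np.abs(eigvals) > target.r_target)
    out[move] = target.r_target * np.exp(1j * np.angle(eigvals[move]))
    # keep exactly-real eigenvalues real despite exp() rounding
    real = move & (eigvals.imag == 0)
    out[real] = target.r_target * np.sign(eigvals[real].real)
    return out


def reassign_spectrum(
    A: np.ndarray, target: TargetSpec, fs: float,
    reconstruction_rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvector-preserving spectrum reassignment.

    Returns ``(A_tilde, Delta)`` with ``A_tilde = Re(V Lambda~ V^-1)`` and
    ``Delta = A_tilde - A``. Raises :class:`DefectiveMatrixError` when A is
    not diagonalizable to tolerance (such windows are skipped in the design).
    """
    A = np.asarray(A, dtype=float)
    norm_A = np.linalg.norm(A)
    eigvals, V = np.linalg.eig(A)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise DefectiveMatrixError("eigenvector matrix is singular") from exc
    if norm_A > 0 and (
        np.linalg.norm(A - (V * eigvals) @ Vinv) > reconstruction_rtol * norm_A
    ):
        raise DefectiveMatrixError("matrix is defective to tolerance")
    targets = desired_spectrum(eigvals, target, fs)
    A_tilde_c = (V * targets) @ Vinv
    # conjugate symmetry guarantees a real result up to rounding
    imag_norm = np.linalg.norm(A_tilde_c.imag)
    if norm_A > 0 and imag_norm > 1e-8 * norm_A:
        warnings.warn(
            f"imaginary residue {imag_norm:.2e} before real cast", RuntimeWarning)
    A_tilde = A_tilde_c.real
    return A_tilde, A_tilde - A


def design_gain(deltas: list[np.ndarray], B: np.ndarray, C: np.ndarray
                ) -> np.ndarray:
    """Minimize sum_j ||B K C - Delta_j||_F^2 over K for general B, C via
    pseudoinverses: K = B^+ (mean_j Delta_j) C^+."""
    Dbar = np.mean(deltas, axis=0)
    return np.linalg.pinv(B) @ Dbar @ np.linalg.pinv(C)


def design_static_output_feedback(
    A_list,
    actuation: ActuationSpec,
    target: TargetSpec,
    fs: float,
    window_ids=None,
) -> FeedbackDesign:
    """Generalized pole placement across switching windows.

    Every usable window contributes its exactly-stabilizing perturbation
    ``Delta_j`` (see :func:`reassign_spectrum`); the returned gain is the
    global minimizer of ``sum_j ||B K C - Delta_j||_F^2``. Defective windows
    are skipped with a warning.
    """
    A_list = [np.asarray(A, dtype=float) for A in A_list]
    if not A_list:
        raise ValueError("A_list must be non-empty")
    n = A_list[0].shape[0]
    if any(A.shape != (n, n) for A in A_list):
        raise ValueError("all windows must share a common dimension")
    if actuation.n != n:
        raise ValueError("actuation dimension mismatch")
    if window_ids is None:
        window_ids = list(range(len(A_list)))

    deltas, used = [], []
    for wid, A in zip(window_ids, A_list):
        try:
            _, delta = reassign_spectrum(A, target, fs)
        except DefectiveMatrixError:
            warnings.warn(f"skipping defective window {wid}", RuntimeWarning)
            continue
        deltas.append(delta)
        used.append(wid)
    if not deltas:
        raise ValueError("no usable (diagonalizable) windows in the design set")

    stim = list(actuation.stim_idx)
    sense = list(actuation.sense_idx)
    # selection-matrix actuation: the objective separates entrywise and the
    # minimizer is the mean of the Deltas on the actuated block
    K = np.mean(deltas, axis=0)[np.ix_(stim, sense)]
    BKC = actuation.B @ K @ actuation.C
    residuals = [float(np.linalg.norm(BKC - d) ** 2) for d in deltas]
    return FeedbackDesign(
        K=K, actuation=actuation, target=target,
        objective_value=float(sum(residuals)),
        per_window_residuals=residuals,
        source_windows=used,
        fs=fs,
    )


def place_state_feedback(
    A: np.ndarray, B: np.ndarray, desired, rtol: float = 1e-6
) -> np.ndarray:
    """State-feedback pole placement: K with eig(A + B K) = desired.

    Wraps the Kautsky-Nichols placement; the desired multiset must be
    conjugate-symmetric and of length n. If the desired spectrum already
    equals eig(A), the zero gain is returned. Raises if the achieved
    spectrum misses the request by more than ``rtol`` (e.g. when an
    uncontrollable mode would have to move).
    """
    A = np.asarray(A, dtype=float)
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n = A.shape[0]
    desired = np.asarray(desired, dtype=complex)
    if desired.shape != (n,):
        raise ValueError("desired spectrum must have length n")
    _check_conjugate_symmetric(desired)

    current = np.linalg.eigvals(A)
    scale = max(1.0, float(np.abs(current).max()))
    if spectrum_distance(current, desired) <= rtol * scale:
        return np.zeros((B.shape[1], n))

    try:
        res = place_poles(A, B, desired)
    except ValueError as exc:
        raise ValueError(f"pole placement failed: {exc}") from exc
    K = -res.gain_matrix  # scipy places eig(A - B K_scipy)
    achieved = np.linalg.eigvals(A + B @ K)
    if spectrum_distance(achieved, desired) > rtol * scale:
        raise ValueError("requested spectrum could not be assigned "
                         "(uncontrollable mode?)")
    return K


def select_electrodes(
    table: ModeTable,
    band: BandDefinition,
    m: int,
    window_range: tuple[float, float],
) -> list[int]:
    """Top-m channels by mean in-band eigenvector loading over a window range.

    ``window_range`` is a (t_lo, t_hi) interval of window-center times,
    half-open on the right. Ties rank the lower channel index first.
    """
    n = len(table.channel_labels)
    if m > n:
        raise ValueError("cannot select more electrodes than channels")
    t_lo, t_hi = window_range
    rec = table.records
    sel = (
        (rec["frequency_hz"] >= band.f_lo)
        & (rec["frequency_hz"] < band.f_hi)
        & (rec["window_center_s"] >= t_lo)
        & (rec["window_center_s"] < t_hi)
    )
    if not sel.any():
        raise ValueError("no modes in the requested band and window range")
    mean_loading = table.loadings[sel.to_numpy()].mean(axis=0)
    # sort by loading descending, ties by channel index ascending
    order = np.lexsort((np.arange(n), -mean_loading))
    return [int(i) for i in order[:m]]
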