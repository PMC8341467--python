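"""Spectral and time-domain evaluation of feedback designs.

A design is judged two ways: spectrally, by comparing the open-loop and
closed-loop eigenmodes window by window (modes matched by frequency-descending
rank), and in simulation, by running the same switching system with identical
noise draws with and without the feedback term so that any difference is
attributable to the gain alone. The offline train/test scenario designs one
gain on the onset windows of several stereotyped seizures and evaluates it on
a held-out seizure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ar import ModelTrack
from .control import ActuationSpec, FeedbackDesign, TargetSpec, \
    design_static_output_feedback
from .io import Recording
from .modes import EigenMode, decompose_matrix
from .synth import SwitchingSystemSpec, simulate_switching_lti

__all__ = [
    "ClosedLoopReport",
    "closed_loop_spectrum",
    "evaluate_design",
    "simulate_closed_loop",
    "offline_generalization",
]


@dataclass
class ClosedLoopReport:
    """Per-window, per-mode open vs closed spectra plus aggregates.

    ``records`` columns: window_center_s, mode_id, open_stability,
    closed_stability, open_frequency, closed_frequency, targeted.
    ``open_loadings`` carries the open-loop loading vector per record so that
    spatial concentration of each mode can be inspected. Untargeted modes are
    reported as-is — the design makes no no-harm guarantee and their movement
    must stay visible.
    """

    records: pd.DataFrame
    open_loadings: np.ndarray
    fraction_targeted_reduced: float
    max_closed_spectral_radius: float
    objective_value: float

    def targeted(self) -> pd.DataFrame:
        return self.records[self.records["targeted"]]


def closed_loop_spectrum(
    A: np.ndarray, design: FeedbackDesign, window_center: float = 0.0
) -> list[EigenMode]:
    """Retained eigenmodes of the closed loop A + B K C."""
    modes, _ = decompose_matrix(design.closed_loop_matrix(A), design.fs,
                                window_center=window_center)
    return modes


def _by_frequency_rank(modes: list[EigenMode]) -> list[EigenMode]:
    return sorted(modes, key=lambda m: -m.frequency)


def evaluate_design(
    track: ModelTrack,
    design: FeedbackDesign,
    target: TargetSpec | None = None,
    window_indices=None,
) -> ClosedLoopReport:
    """Compare open vs closed spectra over (a subset of) a track's windows.

    Open and closed modes are matched by frequency-descending rank, the same
    ordering used when plotting eigenvalue distributions. A mode is
    ``targeted`` when its open-loop frequency exceeds ``f_thresh`` and its
    open-loop stability exceeds ``r_target``. The evaluation windows may
    differ from the windows the design was fitted on (generalization).
    """
    if target is None:
        target = design.target
    idx = range(len(track)) if window_indices is None else window_indices
    rows, loadings = [], []
    n_targeted = n_reduced = 0
    max_radius = 0.0
    for i in idx:
        model = track[i]
        open_modes, _ = decompose_matrix(model.A, track.fs,
                                         model.window.center_time)
        closed_modes = closed_loop_spectrum(model.A, design,
                                            model.window.center_time)
        open_modes = _by_frequency_rank(open_modes)
        closed_modes = _by_frequency_rank(closed_modes)
        for rank, om in enumerate(open_modes, start=1):
            cm = closed_modes[rank - 1] if rank - 1 < len(closed_modes) else None
            targeted = (om.frequency > target.f_thresh
                        and om.stability > target.r_target)
            closed_stab = cm.stability if cm is not None else float("nan")
            closed_freq = cm.frequency if cm is not None else float("nan")
            if cm is not None:
                max_radius = max(max_radius, cm.stability)
            if targeted and cm is not None:
                n_targeted += 1
                n_reduced += closed_stab < om.stability
            rows.append({
                "window_center_s": om.window_center,
                "mode_id": rank,
                "open_stability": om.stability,
                "closed_stability": closed_stab,
                "open_frequency": om.frequency,
                "closed_frequency": closed_freq,
                "targeted": targeted,
            })
            loadings.append(om.loadings)
    return ClosedLoopReport(
        records=pd.DataFrame(rows),
        open_loadings=np.asarray(loadings),
        fraction_targeted_reduced=(n_reduced / n_targeted
                                   if n_targeted else float("nan")),
        max_closed_spectral_radius=max_radius,
        objective_value=design.objective_value,
    )


def simulate_closed_loop(
    spec: SwitchingSystemSpec,
    design: FeedbackDesign,
    seed: int | None = None,
) -> tuple[Recording, Recording]:
    """Paired open/closed simulations of a switching system.

    Both runs consume the identical innovation sequence (drawn once from
    ``seed``, defaulting to the spec's seed), so any difference between the
    trajectories is caused by the feedback term alone.
    """
    n = spec.n
    if design.actuation.n != n:
        raise ValueError("design dimension does not match the system")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    noise = (rng.normal(0.0, spec.noise_sd, size=(n, spec.n_samples))
             if spec.noise_sd > 0 else np.zeros((n, spec.n_samples)))
    open_rec = simulate_switching_lti(spec, noise=noise)
    BKC = design.BKC
    closed_spec = SwitchingSystemSpec(
        matrices=tuple(np.asarray(A) + BKC for A in spec.matrices),
        segment_lengths=spec.segment_lengths,
        noise_sd=spec.noise_sd,
        x0=spec.x0,
        fs=spec.fs,
        seed=spec.seed,
    )
    closed_rec = simulate_switching_lti(closed_spec, noise=noise)
    return open_rec, closed_rec


def offline_generalization(
    train_tracks: list[ModelTrack],
    test_track: ModelTrack,
    actuation: ActuationSpec,
    target: TargetSpec,
    windows_per_seizure: int = 10,
    onset_label: str = "UEO",
) -> tuple[FeedbackDesign, ClosedLoopReport]:
    """Design on the onset windows of training seizures, evaluate held out.

    The design set is the first ``windows_per_seizure`` onset windows of every
    training track (e.g. 4 seizures x 10 windows = 40 design windows); the
    single resulting gain is then evaluated on the held-out test track's
    onset windows.
    """
    if not train_tracks:
        raise ValueError("at least one training track required")
    fs = test_track.fs
    A_list, ids = [], []
    for t_i, track in enumerate(train_tracks):
        if track.fs != fs or track.n_channels != test_track.n_channels:
            raise ValueError("all tracks must share dimension and rate")
        for w_i in track.onset_windows(windows_per_seizure, label=onset_label):
            model = track[w_i]
            if model.degenerate:
                continue
            A_list.append(model.A)
            ids.append(f"train{t_i}:w{w_i}")
    design = design_static_output_feedback(A_list, actuation, target, fs,
                                           window_ids=ids)
    test_idx = test_track.onset_windows(windows_per_seizure, label=onset_label)
    report = evaluate_design(test_track, design, target,
                             window_indices=test_idx)
    return design, report
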