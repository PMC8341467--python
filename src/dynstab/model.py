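"""Model/Results interface tying the pipeline together.

``DynamicalStability`` is constructed from a multichannel recording (or a
plain array plus sampling rate); ``fit()`` runs the sliding-window linear
system identification and returns a :class:`DynamicalStabilityResults`
carrying the per-window transition matrices, the eigenmode table, summary
statistics, onset contrasts, and the control-design entry points.

Example
-------
>>> from dynstab import DynamicalStability, synth
>>> rec = synth.figure1_dataset()
>>> res = DynamicalStability(rec).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from . import closedloop as _cl
from .ar import ModelTrack, fit_sliding
from .control import (ActuationSpec, FeedbackDesign, TargetSpec,
                      design_static_output_feedback, select_electrodes)
from .io import Recording, highpass
from .modes import (DEFAULT_BANDS, BandDefinition, ContrastResult, ModeTable,
                    band_summary_per_window, build_mode_table, onset_contrast)

__all__ = ["DynamicalStability", "DynamicalStabilityResults"]


class DynamicalStability:
    """Sliding-window linear dynamical-stability model of a recording.

    Parameters
    ----------
    recording : Recording
        Channels x samples data with sampling rate and (optionally) events.
    window_s, shift_s : float
        Sliding-window length and shift in seconds (defaults 1.0 and 0.1).
    highpass_hz : float or None
        Zero-phase high-pass cutoff applied before fitting; None skips
        filtering (synthetic data are already zero-mean).
    bands : tuple of BandDefinition
        Frequency bands used when tabulating modes.
    """

    def __init__(
        self,
        recording: Recording,
        window_s: float = 1.0,
        shift_s: float = 0.1,
        highpass_hz: float | None = None,
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    ):
        self.recording = recording
        self.window_s = window_s
        self.shift_s = shift_s
        self.highpass_hz = highpass_hz
        self.bands = tuple(bands)

    @classmethod
    def from_arrays(
        cls, data: np.ndarray, fs: float, channel_labels=None, **kwargs
    ) -> "DynamicalStability":
        return cls(Recording(data=np.asarray(data, dtype=float), fs=fs,
                             channel_labels=channel_labels), **kwargs)

    def fit(self, ridge: float = 0.0) -> "DynamicalStabilityResults":
        """Estimate one transition matrix per sliding window (least squares)."""
        rec = self.recording
        if self.highpass_hz is not None:
            rec = highpass(rec, self.highpass_hz)
        track = fit_sliding(rec, self.window_s, self.shift_s, ridge=ridge)
        return DynamicalStabilityResults(self, rec, track)


@dataclass
class DynamicalStabilityResults:
    """Fitted sliding-window models and the analytics derived from them."""

    model: DynamicalStability
    recording: Recording
    track: ModelTrack

    @cached_property
    def mode_table(self) -> ModeTable:
        """Long-form eigenmode table (one row per retained mode per window)."""
        return build_mode_table(self.track, self.model.bands)

    @property
    def n_windows(self) -> int:
        return len(self.track)

    def band_summary(self, band: BandDefinition,
                     loading_mode: str = "mean") -> pd.DataFrame:
        """Per-window in-band statistics (n modes, max loading, kurtosis...)."""
        return band_summary_per_window(self.track, band,
                                       loading_mode=loading_mode)

    def top_frequency_per_window(self) -> pd.DataFrame:
        """The fastest retained mode of each window."""
        rec = self.mode_table.records
        return rec[rec["mode_id"] == 1][
            ["window_center_s", "frequency_hz", "stability"]
        ].reset_index(drop=True)

    def onset_contrast(
        self,
        band: BandDefinition,
        statistic: str = "max_loading",
        onset_label: str = "UEO",
        pre_s: float = 5.0,
        post_s: float = 5.0,
    ) -> ContrastResult:
        """Wilcoxon rank-sum contrast of a band statistic pre vs post onset.

        Windows with undefined statistics (empty band / zero variance) are
        dropped from both samples.
        """
        t0 = self.track.event_time(onset_label)
        summary = self.band_summary(band)
        c = summary["window_center_s"]
        ok = summary["defined"] & summary[statistic].notna()
        pre = summary[ok & (c >= t0 - pre_s) & (c < t0)][statistic]
        post = summary[ok & (c >= t0) & (c < t0 + post_s)][statistic]
        return onset_contrast(pre, post)

    def select_electrodes(
        self, band: BandDefinition, m: int, window_range: tuple[float, float]
    ) -> list[int]:
        """Top-m channels by mean in-band loading over a time range."""
        return select_electrodes(self.mode_table, band, m, window_range)

    def design_feedback(
        self,
        actuation: ActuationSpec,
        target: TargetSpec,
        window_indices=None,
    ) -> FeedbackDesign:
        """Static output feedback gain from (a subset of) the fitted windows."""
        idx = (list(range(len(self.track))) if window_indices is None
               else list(window_indices))
        A_list = [self.track[i].A for i in idx
                  if not self.track[i].degenerate]
        ids = [i for i in idx if not self.track[i].degenerate]
        return design_static_output_feedback(
            A_list, actuation, target, self.track.fs, window_ids=ids)

    def evaluate_design(self, design: FeedbackDesign,
                        window_indices=None) -> _cl.ClosedLoopReport:
        """Open vs closed spectra of the fitted windows under a design."""
        return _cl.evaluate_design(self.track, design,
                                   window_indices=window_indices)

    def summary(self) -> str:
        """Plain-text overview of the fitted model."""
        track = self.track
        rec = self.mode_table.records
        top = rec[rec["mode_id"] == 1]
        degenerate = sum(m.degenerate for m in track)
        radii = [m.spectral_radius for m in track]
        lines = [
            "Dynamical stability analysis",
            "=" * 60,
            f"channels:              {track.n_channels}",
            f"sampling rate:         {track.fs:g} Hz",
            f"window / shift:        {self.model.window_s:g} s / "
            f"{self.model.shift_s:g} s",
            f"windows fitted:        {len(track)}"
            + (f"  ({degenerate} rank-deficient)" if degenerate else ""),
            f"mode records:          {len(rec)}",
            f"spectral radius:       median {np.median(radii):.4f}, "
            f"max {np.max(radii):.4f}",
            f"top-mode frequency:    median {top['frequency_hz'].median():.2f} Hz, "
            f"max {top['frequency_hz'].max():.2f} Hz",
        ]
        for band in self.model.bands:
            nb = (rec["band"] == band.name).sum()
            lines.append(
                f"modes in {band.name:<6} [{band.f_lo:g}, {band.f_hi:g}) Hz: {nb}")
        return "\n".join(lines)

    # --- plotting -----------------------------------------------------------

    def plot_argand(self, window_indices=None, ax=None):
        """Eigenvalues on the complex plane (radius = stability,
        angle = frequency), colored by window time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        idx = (range(len(self.track)) if window_indices is None
               else window_indices)
        cmap = plt.get_cmap("viridis")
        t_all = self.track.centers
        for i in idx:
            ev = np.linalg.eigvals(self.track[i].A)
            color = cmap((t_all[i] - t_all.min()) /
                         max(t_all.max() - t_all.min(), 1e-12))
            ax.scatter(ev.real, ev.imag, s=12, color=color)
        th = np.linspace(0, 2 * np.pi, 200)
        ax.plot(np.cos(th), np.sin(th), "k--", lw=0.8)
        ax.set_xlabel("Re λ")
        ax.set_ylabel("Im λ")
        ax.set_aspect("equal")
        return ax

    def plot_band_loadings(self, band: BandDefinition, ax=None):
        """Heat map of per-channel mean in-band loadings over time."""
        import matplotlib.pyplot as plt

        summary_rows = []
        for model in self.track:
            from .modes import decompose, mode_statistics

            s = mode_statistics(decompose(model), band)
            summary_rows.append(
                s.channel_loadings if s.defined
                else np.full(self.track.n_channels, np.nan))
        M = np.asarray(summary_rows).T
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = self.track.centers
        im = ax.imshow(M, aspect="auto", origin="lower",
                       extent=(t[0], t[-1], -0.5, M.shape[0] - 0.5),
                       cmap="magma", vmin=0, vmax=1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("channel")
        ax.set_title(f"{band.name} loadings")
        plt.colorbar(im, ax=ax, label="mean |v| (normalized)")
        return ax
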