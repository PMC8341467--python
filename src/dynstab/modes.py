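"""Eigenmode analytics for fitted window models.

Each window's transition matrix A is eigendecomposed (general similarity
A = V Lambda V^{-1}); every eigenvalue lambda yields

* stability ``|lambda|`` — modulus; <1 decaying, ~1 sustained, >1 growing;
* frequency ``f = |theta| * fs / (2 pi)`` Hz, theta the eigenvalue angle;
* growth rate ``rho = fs * ln|lambda|`` in 1/s;
* spatial loadings — the right eigenvector's moduli max-normalized to [0, 1].

Complex-conjugate pairs describe one oscillation and are retained once
(theta >= 0). Band-restricted summaries (max loading, loading kurtosis),
nonparametric pre/post onset contrasts (Wilcoxon rank-sum) and
spatiotemporal subsampling sweeps mirror the seizure-onset focality
statistics computed from such models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import norm, rankdata

from .ar import ModelTrack, WindowModel, fit_sliding
from .io import Recording

__all__ = [
    "EigenMode",
    "BandDefinition",
    "ModeTable",
    "BandSummary",
    "ContrastResult",
    "DEFAULT_BANDS",
    "decompose",
    "decompose_matrix",
    "normalize_loadings",
    "mode_statistics",
    "mode_trajectory",
    "build_mode_table",
    "band_summary_per_window",
    "onset_contrast",
    "subsample_robustness",
    "loading_kurtosis",
]

#: Relative magnitude below which an eigenvalue is treated as numerically
#: zero; the angle of such an eigenvalue is meaningless, so its frequency is
#: reported as 0 Hz.
NULL_EIGENVALUE_RTOL = 1e-9


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError("require 0 <= f_lo < f_hi")

    def contains(self, f: float) -> bool:
        return self.f_lo <= f < self.f_hi


#: gamma and beta limits as commonly printed for iEEG onset analyses; alpha
#: is a conventional default.
DEFAULT_BANDS = (
    BandDefinition("gamma", 25.0, 55.0),
    BandDefinition("beta", 12.0, 25.0),
    BandDefinition("alpha", 8.0, 12.0),
)


@dataclass
class EigenMode:
    """One retained eigenvalue-eigenvector pair of a window model."""

    eigenvalue: complex
    stability: float
    angle: float  # rad/sample, >= 0 for retained modes
    frequency: float  # Hz
    growth_rate: float  # 1/s
    loadings: np.ndarray  # |v| / max|v|, in [0, 1]
    right_eigenvector: np.ndarray
    left_eigenvector: np.ndarray
    is_real_mode: bool
    window_center: float

    @property
    def n_channels(self) -> int:
        return len(self.loadings)


def normalize_loadings(v: np.ndarray) -> np.ndarray:
    """Max-normalized moduli of an eigenvector: |v| / max|v|, max exactly 1."""
    v = np.asarray(v)
    m = np.abs(v)
    peak = m.max()
    if peak == 0:
        raise ValueError("cannot normalize a zero eigenvector")
    out = m / peak
    out[np.argmax(m)] = 1.0  # exact despite rounding
    return out


def loading_kurtosis(values: np.ndarray) -> float:
    """Population (non-excess) Pearson kurtosis m4 / m2^2; NaN if variance 0."""
    values = np.asarray(values, dtype=float)
    d = values - values.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        return float("nan")
    return float(np.mean(d**4) / m2**2)


def decompose_matrix(
    A: np.ndarray,
    fs: float,
    window_center: float = 0.0,
    reconstruction_rtol: float = 1e-8,
) -> tuple[list[EigenMode], bool]:
    """Eigendecompose a real matrix into retained modes.

    Conjugate pairs are collapsed to the theta >= 0 member; unpaired real
    eigenvalues are flagged ``is_real_mode``. Left eigenvectors are the rows
    of V^{-1}, so the modal coordinate z_i(k) = (left eigenvector) x(k)
    satisfies z_i(k) = lambda_i z_i(k-1) exactly for noiseless data.

    Returns (modes, defective): if A is not diagonalizable to within
    ``reconstruction_rtol`` the decomposition is retried on an infinitesimally
    perturbed copy and ``defective=True`` is reported.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    norm_A = np.linalg.norm(A)
    defective = False
    eigvals, V = np.linalg.eig(A)
    try:
        Vinv = np.linalg.inv(V)
        err = np.linalg.norm(A - (V * eigvals) @ Vinv)
    except np.linalg.LinAlgError:
        err = np.inf
    if norm_A > 0 and err > reconstruction_rtol * norm_A:
        # defective (or nearly so): perturb and flag
        defective = True
        rng = np.random.default_rng(0)
        for magnitude in (1e-10, 1e-8, 1e-6):
            Ap = A + magnitude * norm_A * rng.standard_normal(A.shape)
            eigvals, V = np.linalg.eig(Ap)
            try:
                Vinv = np.linalg.inv(V)
            except np.linalg.LinAlgError:
                continue
            err = np.linalg.norm(Ap - (V * eigvals) @ Vinv)
            if err <= reconstruction_rtol * np.linalg.norm(Ap):
                break

    scale = max(1.0, float(np.abs(eigvals).max(initial=0.0)))
    modes: list[EigenMode] = []
    for i, lam in enumerate(eigvals):
        if lam.imag < 0:  # conjugate partner of a retained mode
            continue
        mag = abs(lam)
        theta = abs(np.angle(lam))
        null = mag <= NULL_EIGENVALUE_RTOL * scale
        freq = 0.0 if null else theta * fs / (2 * math.pi)
        with np.errstate(divide="ignore"):
            growth = fs * float(np.log(mag)) if mag > 0 else -math.inf
        v = V[:, i]
        loadings = (np.zeros(n) if np.abs(v).max() == 0
                    else normalize_loadings(v))
        modes.append(
            EigenMode(
                eigenvalue=complex(lam),
                stability=float(mag),
                angle=float(theta),
                frequency=float(freq),
                growth_rate=growth,
                loadings=loadings,
                right_eigenvector=v,
                left_eigenvector=Vinv[i, :],
                is_real_mode=bool(lam.imag == 0),
                window_center=window_center,
            )
        )
    return modes, defective


def decompose(model: WindowModel) -> list[EigenMode]:
    """Retained eigenmodes of a fitted window model.

    A defective (non-diagonalizable) matrix is decomposed after a tiny
    perturbation and the window is flagged with ``'defective'``.
    """
    modes, defective = decompose_matrix(
        model.A, model.fs, window_center=model.window.center_time)
    if defective and "defective" not in model.flags:
        model.flags.append("defective")
    return modes


def mode_trajectory(segment: np.ndarray, mode: EigenMode) -> np.ndarray:
    """Modal coordinate z_i(k) = (left eigenvector) . x(k) over a segment."""
    segment = np.asarray(segment)
    if segment.shape[0] != mode.n_channels:
        raise ValueError("segment channel count does not match the mode")
    return mode.left_eigenvector @ segment


@dataclass(frozen=True)
class BandSummary:
    """Band-restricted summary of one window's modes.

    ``max_loading`` and ``kurtosis`` are computed on the per-channel mean of
    loadings across the in-band modes. ``defined`` is False when the band is
    empty; ``kurtosis`` is NaN when the loading profile has zero variance.
    """

    n_modes_in_band: int
    mean_stability: float
    mean_frequency: float
    max_loading: float
    kurtosis: float
    channel_loadings: np.ndarray | None
    defined: bool


def mode_statistics(
    modes: list[EigenMode],
    band: BandDefinition,
    loading_mode: str = "mean",
) -> BandSummary:
    """Summarize the modes whose frequency falls in ``band``.

    ``loading_mode='mean'`` averages loadings across in-band modes (the
    default); ``'dominant'`` instead uses the loading profile of the most
    stable in-band mode.
    """
    in_band = [m for m in modes if band.contains(m.frequency)]
    if not in_band:
        return BandSummary(0, float("nan"), float("nan"), float("nan"),
                           float("nan"), None, False)
    if loading_mode == "mean":
        L = np.mean([m.loadings for m in in_band], axis=0)
    elif loading_mode == "dominant":
        L = max(in_band, key=lambda m: m.stability).loadings
    else:
        raise ValueError("loading_mode must be 'mean' or 'dominant'")
    return BandSummary(
        n_modes_in_band=len(in_band),
        mean_stability=float(np.mean([m.stability for m in in_band])),
        mean_frequency=float(np.mean([m.frequency for m in in_band])),
        max_loading=float(L.max()),
        kurtosis=loading_kurtosis(L),
        channel_loadings=L,
        defined=True,
    )


class ModeTable:
    """Long-form mode records over a :class:`ModelTrack`.

    One record per retained mode per window; ``mode_id`` ranks modes by
    frequency, descending, within each window (mode 1 is the fastest). The
    per-record ``kurtosis`` is the focality of that mode's own loading
    profile. Per-mode loading vectors are kept alongside for electrode
    selection and heat-map rendering.
    """

    COLUMNS = ["window_center_s", "mode_id", "frequency_hz", "stability",
               "growth_rate_per_s", "max_loading", "kurtosis", "band"]

    def __init__(self, records: pd.DataFrame, loadings: np.ndarray,
                 channel_labels: list[str], bands: tuple[BandDefinition, ...]):
        self.records = records
        self.loadings = loadings
        self.channel_labels = channel_labels
        self.bands = bands

    def __len__(self) -> int:
        return len(self.records)

    @property
    def window_centers(self) -> np.ndarray:
        return self.records["window_center_s"].unique()

    def in_band(self, band: BandDefinition | str) -> pd.DataFrame:
        name = band.name if isinstance(band, BandDefinition) else band
        return self.records[self.records["band"] == name]

    def to_csv(self, path, loadings_path=None) -> None:
        self.records.to_csv(path, index=False, float_format="%.12g")
        if loadings_path is not None:
            pd.DataFrame(self.loadings, columns=self.channel_labels).to_csv(
                loadings_path, index=False, float_format="%.12g")


def _band_of(f: float, bands: tuple[BandDefinition, ...]) -> str:
    for b in bands:
        if b.contains(f):
            return b.name
    return "none"


def build_mode_table(
    track: ModelTrack,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> ModeTable:
    """Decompose every window of a track into a long-form mode table."""
    rows = []
    loadings = []
    for model in track:
        modes = decompose(model)
        modes.sort(key=lambda m: -m.frequency)
        for rank, m in enumerate(modes, start=1):
            rows.append({
                "window_center_s": m.window_center,
                "mode_id": rank,
                "frequency_hz": m.frequency,
                "stability": m.stability,
                "growth_rate_per_s": m.growth_rate,
                "max_loading": float(m.loadings.max()),
                "kurtosis": loading_kurtosis(m.loadings),
                "band": _band_of(m.frequency, bands),
            })
            loadings.append(m.loadings)
    records = pd.DataFrame(rows, columns=ModeTable.COLUMNS)
    return ModeTable(records, np.asarray(loadings), list(track.channel_labels),
                     tuple(bands))


def band_summary_per_window(
    track: ModelTrack,
    band: BandDefinition,
    loading_mode: str = "mean",
) -> pd.DataFrame:
    """Per-window :func:`mode_statistics` over a track, as a DataFrame."""
    rows = []
    for model in track:
        s = mode_statistics(decompose(model), band, loading_mode=loading_mode)
        rows.append({
            "window_center_s": model.window.center_time,
            "n_modes_in_band": s.n_modes_in_band,
            "mean_stability": s.mean_stability,
            "mean_frequency": s.mean_frequency,
            "max_loading": s.max_loading,
            "kurtosis": s.kurtosis,
            "defined": s.defined,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContrastResult:
    """Wilcoxon rank-sum contrast; the statistic is the rank-sum of the
    second (post) sample."""

    statistic: float
    pvalue: float
    method: str  # 'exact' or 'normal'
    n_pre: int
    n_post: int


# combined sample size up to which the exact permutation distribution of the
# rank-sum statistic is enumerated
EXACT_ENUMERATION_MAX_N = 12


def onset_contrast(pre_values, post_values) -> ContrastResult:
    """Two-sided Wilcoxon rank-sum test between two value samples.

    Midranks are assigned to ties. For combined sample sizes up to
    ``EXACT_ENUMERATION_MAX_N`` the p-value is computed by exhaustive
    enumeration of all allocations of the combined sample; larger samples use
    the tie-corrected normal approximation (no continuity correction).
    """
    pre = np.asarray(list(pre_values), dtype=float)
    post = np.asarray(list(post_values), dtype=float)
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(pre).all() and np.isfinite(post).all()):
        raise ValueError("samples must be finite (drop undefined windows first)")
    n1, n2 = len(pre), len(post)
    n = n1 + n2
    combined = np.concatenate([pre, post])
    ranks = rankdata(combined)
    W = float(ranks[n1:].sum())
    mu = n2 * (n + 1) / 2.0

    if n <= EXACT_ENUMERATION_MAX_N:
        dev = abs(W - mu) - 1e-12
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n2):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mu) >= dev:
                count += 1
        return ContrastResult(W, count / total, "exact", n1, n2)

    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return ContrastResult(W, 1.0, "normal", n1, n2)
    z = (W - mu) / math.sqrt(var)
    return ContrastResult(W, float(2 * norm.sf(abs(z))), "normal", n1, n2)


def _decimate_recording(rec: Recording, fs_new: float) -> tuple[Recording, bool]:
    """Anti-alias resample to fs_new; exact decimation for integer factors,
    rational polyphase resampling otherwise (flagged)."""
    if fs_new > rec.fs:
        raise ValueError("can only downsample")
    if fs_new == rec.fs:
        return rec, False
    factor = rec.fs / fs_new
    if abs(factor - round(factor)) < 1e-9:
        data = sps.decimate(rec.data, int(round(factor)), axis=1,
                            zero_phase=True)
        return Recording(data=data, fs=fs_new, events=list(rec.events),
                         channel_labels=rec.channel_labels,
                         units=rec.units), False
    from fractions import Fraction

    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(data=data, fs=rec.fs * frac.numerator / frac.denominator,
                     events=list(rec.events), channel_labels=rec.channel_labels,
                     units=rec.units), True


def subsample_robustness(
    rec: Recording,
    fs_list,
    channel_counts,
    n_rep: int = 1,
    seed: int = 0,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_s: float = 1.0,
    shift_s: float = 0.1,
    onset_label: str = "UEO",
    pre_s: float = 5.0,
    post_s: float = 5.0,
) -> pd.DataFrame:
    """Re-run the eigenmode analysis over a grid of sampling rates and random
    channel subsets.

    For every (fs', m, repetition) the recording is anti-alias resampled to
    fs', m channels are drawn without replacement (seeded), the sliding-window
    models are refitted and per-band onset statistics recomputed. When the
    recording carries an onset event, pre/post rank-sum p-values on max
    loading and kurtosis are included. Returns a long-form grid with
    |fs_list| x |channel_counts| x n_rep x |bands| rows.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fs_new in fs_list:
        sub_rec, inexact = _decimate_recording(rec, fs_new)
        for m in channel_counts:
            if m > rec.n_channels:
                raise ValueError("channel count exceeds recording channels")
            for rep in range(n_rep):
                chans = np.sort(rng.choice(rec.n_channels, size=m,
                                           replace=False))
                r = Recording(
                    data=sub_rec.data[chans],
                    fs=sub_rec.fs,
                    channel_labels=[rec.channel_labels[c] for c in chans],
                    events=list(rec.events),
                    units=rec.units,
                )
                track = fit_sliding(r, window_s, shift_s)
                for band in bands:
                    summary = band_summary_per_window(track, band)
                    row = {
                        "fs": sub_rec.fs, "n_channels": m, "rep": rep,
                        "band": band.name,
                        "inexact_resample": inexact,
                        "mean_n_modes": summary["n_modes_in_band"].mean(),
                        "mean_max_loading": summary["max_loading"].mean(),
                        "mean_kurtosis": summary["kurtosis"].mean(),
                    }
                    try:
                        t0 = r.event_time(onset_label)
                    except KeyError:
                        t0 = None
                    if t0 is not None:
                        ok = summary["defined"]
                        c = summary["window_center_s"]
                        pre = summary[ok & (c >= t0 - pre_s) & (c < t0)]
                        post = summary[ok & (c >= t0) & (c < t0 + post_s)]
                        for stat in ("max_loading", "kurtosis"):
                            key = f"p_{stat}"
                            a = pre[stat].dropna()
                            b = post[stat].dropna()
                            row[key] = (
                                onset_contrast(a, b).pvalue
                                if len(a) and len(b) else float("nan"))
                    rows.append(row)
    return pd.DataFrame(rows)
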