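"""Synthetic multichannel signals with planted oscillatory structure.

Two families of generators are provided:

* enveloped-sinusoid source mixtures — each source is ``sin(a*t + b)`` under
  an exponential (``exp(c*t)``) or Gaussian envelope, linearly mixed onto
  channels with a fixed pi/2 phase lead between consecutive sources; these
  build pedagogical datasets with a known planted locus, frequency, and
  damping of oscillatory activity;
* switching linear time-invariant (LTI) systems ``x(k) = A_j x(k-1) + noise``
  — piecewise-constant transition matrices driven by Gaussian noise, used as
  seizure surrogates for the control experiments, including a focal
  high-frequency onset confined to a known channel subset.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import ortho_group

from .io import Event, Recording

__all__ = [
    "SourceSpec",
    "MixtureSpec",
    "SwitchingSystemSpec",
    "render_source",
    "render_mixture",
    "figure1_dataset",
    "FIGURE1_HF_INTERVAL",
    "FIGURE1_HF_HZ",
    "simulate_switching_lti",
    "make_focal_seizure_surrogate",
    "FocalSurrogate",
]


@dataclass(frozen=True)
class SourceSpec:
    """A single enveloped-sinusoid source.

    ``kind='baseline'`` sources are ``amplitude * sin(a*t + b) * exp(c*t)``;
    ``kind='transient'`` sources are
    ``amplitude * sin(a*t + b) * (1 / (2*sigma*sqrt(2*pi))) * exp(-(t-mu)^2 / sigma^2)``
    with ``t`` in seconds measured from ``t_on``. The transient envelope is
    used in exactly this (non-standard Gaussian) form; ``peak_normalized=True``
    rescales it so the envelope maximum equals ``amplitude``. The source is
    identically zero outside ``[t_on, t_off)``.
    """

    kind: str  # {'baseline', 'transient'}
    a: float  # angular frequency, rad/s
    b: float = 0.0  # phase, rad
    c: float = 0.0  # exponential envelope rate, 1/s (baseline)
    mu: float | None = None  # Gaussian envelope center, s from t_on (transient)
    sigma: float | None = None  # Gaussian envelope width, s (transient)
    t_on: float = 0.0
    t_off: float = math.inf
    amplitude: float = 1.0
    peak_normalized: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("baseline", "transient"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.a < 0:
            raise ValueError("angular frequency a must be >= 0")
        if not self.t_on < self.t_off:
            raise ValueError("require t_on < t_off")
        if self.kind == "transient":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("transient source requires sigma > 0")
            if self.mu is None:
                raise ValueError("transient source requires mu")

    @property
    def frequency_hz(self) -> float:
        return self.a / (2 * math.pi)


@dataclass(frozen=True)
class MixtureSpec:
    """A linear mixture of sources onto channels.

    ``mixing`` has shape (n_sources, n_channels). Source ``i`` is rendered
    with an extra phase of ``-i * source_lag`` so that each source leads the
    next one by ``source_lag`` radians (default pi/2).
    """

    fs: float
    duration: float
    sources: tuple[SourceSpec, ...]
    mixing: tuple[tuple[float, ...], ...]
    source_lag: float = math.pi / 2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        M = np.asarray(self.mixing, dtype=float)
        if M.ndim != 2 or M.shape[0] != len(self.sources):
            raise ValueError("mixing must be a (n_sources, n_channels) matrix")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")

    @property
    def mixing_matrix(self) -> np.ndarray:
        return np.asarray(self.mixing, dtype=float)


def render_source(src: SourceSpec, fs: float, duration: float) -> np.ndarray:
    """Render one source as a 1-D signal of round(duration * fs) samples."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    out = np.zeros(n)
    mask = (t >= src.t_on) & (t < src.t_off)
    tau = t[mask] - src.t_on
    carrier = np.sin(src.a * tau + src.b)
    if src.kind == "baseline":
        env = np.exp(src.c * tau)
    else:
        pref = 1.0 if src.peak_normalized else 1.0 / (2 * src.sigma * math.sqrt(2 * math.pi))
        env = pref * np.exp(-((tau - src.mu) ** 2) / src.sigma**2)
    out[mask] = src.amplitude * carrier * env
    return out


def render_mixture(spec: MixtureSpec) -> Recording:
    """Superimpose the mixture's sources onto channels, plus Gaussian noise."""
    n_sources = len(spec.sources)
    sources = np.empty((n_sources, int(round(spec.duration * spec.fs))))
    for i, src in enumerate(spec.sources):
        shifted = SourceSpec(
            kind=src.kind, a=src.a, b=src.b - i * spec.source_lag, c=src.c,
            mu=src.mu, sigma=src.sigma, t_on=src.t_on, t_off=src.t_off,
            amplitude=src.amplitude, peak_normalized=src.peak_normalized,
        )
        sources[i] = render_source(shifted, spec.fs, spec.duration)
    data = spec.mixing_matrix.T @ sources
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    return Recording(data=data, fs=spec.fs)


# --- canonical 4-channel pedagogical dataset -------------------------------

#: Interval (s) over which the late high-frequency source is active.
FIGURE1_HF_INTERVAL = (6.0, 8.0)
#: Planted frequency (Hz) of the late high-frequency source.
FIGURE1_HF_HZ = 64.0


def figure1_spec() -> MixtureSpec:
    """Specification of the canonical 4-channel, 512 Hz dataset.

    Four enveloped-sinusoid sources with a pi/2 phase lead between
    consecutive sources:

    1. a 5 Hz baseline damping away early (c = -0.4/s), present throughout;
    2. a 20 Hz Gaussian transient centred at 4.5 s;
    3. and 4. a growing (c = +0.5/s) 64 Hz pair active over 6-8 s, mixed
       onto channels 1 and 3 only. Being consecutive sources, the pair is in
       phase quadrature, so the planted high-frequency component is exactly
       a 2-D rotation-scaling process on those channels.

    Only the 64 Hz plant is treated as ground truth; the remaining source
    frequencies, envelope rates and mixing weights are fixed pedagogical
    constants. The dataset is noise-free and fully deterministic.
    """
    sources = (
        SourceSpec("baseline", a=2 * math.pi * 5.0, b=math.pi / 2, c=-0.4,
                   t_on=0.0, t_off=10.0, amplitude=1.0),
        SourceSpec("transient", a=2 * math.pi * 20.0, b=math.pi / 2,
                   mu=1.5, sigma=0.4, t_on=3.0, t_off=6.0, amplitude=1.0),
        SourceSpec("baseline", a=2 * math.pi * FIGURE1_HF_HZ, b=math.pi / 2,
                   c=0.5, t_on=FIGURE1_HF_INTERVAL[0],
                   t_off=FIGURE1_HF_INTERVAL[1], amplitude=0.05),
        SourceSpec("baseline", a=2 * math.pi * FIGURE1_HF_HZ, b=math.pi / 2,
                   c=0.5, t_on=FIGURE1_HF_INTERVAL[0],
                   t_off=FIGURE1_HF_INTERVAL[1], amplitude=0.05),
    )
    mixing = (
        (0.6, 1.0, 0.2, 0.8),
        (0.3, 0.5, 0.2, 1.0),
        (1.0, 0.0, 0.4, 0.0),
        (0.4, 0.0, 1.0, 0.0),
    )
    return MixtureSpec(fs=512.0, duration=10.0, sources=sources, mixing=mixing,
                       source_lag=math.pi / 2, noise_sd=0.0, seed=0)


def figure1_dataset() -> Recording:
    """The canonical 4-channel, 512 Hz, 10 s dataset with a late-emerging
    64 Hz component on channels 1 and 3 (see :func:`figure1_spec`).

    The active interval of the high-frequency source is recorded as an
    ``hf_active`` event.
    """
    rec = render_mixture(figure1_spec())
    rec.events.append(Event("hf_active", *FIGURE1_HF_INTERVAL))
    return rec


# --- switching linear systems ----------------------------------------------


@dataclass(frozen=True)
class SwitchingSystemSpec:
    """A piecewise-LTI system: segment j evolves x(k) = A_j x(k-1) + eta(k)
    with eta ~ N(0, noise_sd^2 I)."""

    matrices: tuple[np.ndarray, ...]
    segment_lengths: tuple[int, ...]
    noise_sd: float
    x0: np.ndarray
    fs: float
    seed: int = 0

    def __post_init__(self) -> None:
        n = None
        for A in self.matrices:
            A = np.asarray(A)
            if A.ndim != 2 or A.shape[0] != A.shape[1]:
                raise ValueError("transition matrices must be square")
            if n is None:
                n = A.shape[0]
            elif A.shape[0] != n:
                raise ValueError("all matrices must share the same dimension")
        if len(self.segment_lengths) != len(self.matrices):
            raise ValueError("one segment length per matrix required")
        if any(l <= 0 for l in self.segment_lengths):
            raise ValueError("segment lengths must be positive")
        if sum(self.segment_lengths) + 1 < 2:
            raise ValueError("total length must be at least 2 samples")
        if np.asarray(self.x0).shape != (n,):
            raise ValueError("x0 dimension mismatch")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n(self) -> int:
        return np.asarray(self.matrices[0]).shape[0]

    @property
    def n_samples(self) -> int:
        return sum(self.segment_lengths) + 1

    def segment_matrix_at(self, k: int) -> np.ndarray:
        """Transition matrix governing the step into sample k (k >= 1)."""
        edges = np.cumsum(self.segment_lengths)
        j = int(np.searchsorted(edges, k, side="left"))
        return np.asarray(self.matrices[min(j, len(self.matrices) - 1)])


def _switching_events(spec: SwitchingSystemSpec) -> list[Event]:
    edges = np.concatenate([[0], np.cumsum(spec.segment_lengths)])
    return [
        Event(f"segment_{j}", edges[j] / spec.fs, edges[j + 1] / spec.fs)
        for j in range(len(spec.matrices))
    ]


def simulate_switching_lti(
    spec: SwitchingSystemSpec, noise: np.ndarray | None = None
) -> Recording:
    """Simulate the switching system; segment boundaries become events.

    ``noise`` may supply a pre-drawn (n, n_samples) innovation array (used by
    the paired open/closed-loop simulations); by default innovations are
    drawn from the spec's seed.
    """
    n, total = spec.n, spec.n_samples
    if noise is None:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=(n, total)) if spec.noise_sd > 0 \
            else np.zeros((n, total))
    if noise.shape != (n, total):
        raise ValueError("noise array has wrong shape")
    x = np.empty((n, total))
    x[:, 0] = np.asarray(spec.x0, dtype=float)
    edges = np.cumsum(spec.segment_lengths)
    j = 0
    for k in range(1, total):
        while k > edges[j] and j < len(edges) - 1:
            j += 1
        A = np.asarray(spec.matrices[j])
        x[:, k] = A @ x[:, k - 1] + noise[:, k]
    return Recording(data=x, fs=spec.fs, events=_switching_events(spec))


def _rotation_block(f_hz: float, fs: float) -> np.ndarray:
    th = 2 * math.pi * f_hz / fs
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s], [s, c]])


def random_background_matrix(
    rng: np.random.Generator,
    n: int,
    radius: float,
    fs: float,
    f_range: tuple[float, float],
) -> np.ndarray:
    """A random orthogonal matrix scaled to the given spectral radius, with
    rotation frequencies drawn uniformly from ``f_range`` (Hz).

    The matrix is ``radius * U D U^T`` with U Haar-orthogonal and D
    block-diagonal 2x2 rotations, so all eigenvalues sit exactly on the
    circle of the requested radius while the eigenvectors are delocalized
    and the oscillation frequencies are controlled. An odd dimension gets
    one real eigenvalue at +radius.
    """
    U = ortho_group.rvs(n, random_state=rng) if n > 1 else np.ones((1, 1))
    D = np.zeros((n, n))
    for i, f in enumerate(rng.uniform(f_range[0], f_range[1], size=n // 2)):
        D[2 * i: 2 * i + 2, 2 * i: 2 * i + 2] = _rotation_block(f, fs)
    if n % 2:
        D[-1, -1] = 1.0
    return radius * U @ D @ U.T


@dataclass
class FocalSurrogate:
    """A focal-onset switching surrogate plus its ground truth.

    ``ictal_basis`` (n, 2) spans the planted oscillation's invariant
    subspace; its rows are zero off the SOZ channels. ``ictal_loadings`` is
    the planted mode's max-normalized loading profile (root-sum-square of the
    basis rows, scaled to peak 1).
    """

    recording: Recording
    spec: SwitchingSystemSpec
    soz_channels: tuple[int, ...]
    f_ictal: float
    ictal_eigenvalues: tuple[complex, complex]
    ictal_basis: np.ndarray
    ictal_loadings: np.ndarray
    onset_s: float


def make_focal_seizure_surrogate(
    n_channels: int = 20,
    soz_channels: tuple[int, ...] = (2, 5, 11, 14),
    onset_s: float = 10.0,
    f_ictal: float = 30.0,
    radius_pre: float = 0.95,
    radius_ictal: float = 1.0,
    fs: float = 512.0,
    duration: float = 20.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    ictal_seed: int | None = None,
    segment_s: float = 1.0,
    f_background_pre: tuple[float, float] = (0.5, 100.0),
    f_background_post: tuple[float, float] = (0.5, 15.0),
) -> FocalSurrogate:
    """Switching-LTI surrogate of a focal high-frequency seizure onset.

    Pre-onset segments are broadband random stable backgrounds (spectral
    radius ``radius_pre``, rotation frequencies over ``f_background_pre``).
    From ``onset_s`` onward each segment embeds a fixed 2x2 rotation-scaling
    block at ``f_ictal`` Hz and radius ``radius_ictal`` whose eigenvectors
    are supported exactly on ``soz_channels`` — with a tapered involvement
    profile (linearly decaying from 1 to 0.55 across the SOZ channels, random
    phase pattern) so every SOZ channel participates strongly in the planted
    oscillation — while the remaining background slows down to
    ``f_background_post``: low-voltage fast activity confined to the seizure
    onset zone against a slowing background. The background is re-drawn every
    ``segment_s`` seconds (the system switches) but the planted ictal block
    is held fixed.

    ``ictal_seed`` fixes the ictal subspace independently of the background
    and noise seed, so several stereotyped "seizures" can share one ictal
    generator. The onset is recorded as a ``UEO`` event.
    """
    soz = tuple(int(c) for c in soz_channels)
    if len(set(soz)) != len(soz) or len(soz) < 2:
        raise ValueError("need at least two distinct SOZ channels")
    if any(not 0 <= c < n_channels for c in soz):
        raise ValueError("soz_channels out of range")
    if not 0 < f_ictal < fs / 2:
        raise ValueError("f_ictal must lie in (0, fs/2)")
    if not radius_ictal > radius_pre:
        raise ValueError("radius_ictal must exceed radius_pre")
    if not 0 < onset_s < duration:
        raise ValueError("onset_s must lie inside the recording")

    rng = np.random.default_rng(seed)
    ictal_rng = np.random.default_rng(seed if ictal_seed is None else ictal_seed)

    # 2-D ictal subspace supported on the SOZ channels: channel k of the SOZ
    # participates with magnitude profile[k] and phase phi[k], so the planted
    # mode's loadings are exactly the taper profile
    m = len(soz)
    profile = np.linspace(1.0, 0.55, m)
    phi = ictal_rng.uniform(0, 2 * math.pi) + np.arange(m) * math.pi / m
    basis = np.zeros((n_channels, 2))
    basis[list(soz), 0] = profile * np.cos(phi)
    basis[list(soz), 1] = profile * np.sin(phi)
    ictal_loadings = np.zeros(n_channels)
    ictal_loadings[list(soz)] = profile
    ictal_block = radius_ictal * _rotation_block(f_ictal, fs)

    seg_len = int(round(segment_s * fs))
    n_total = int(round(duration * fs))
    n_seg = max(1, n_total // seg_len)
    matrices, seg_lengths = [], []
    for j in range(n_seg):
        t0 = j * seg_len / fs
        length = seg_len if j < n_seg - 1 else n_total - 1 - seg_len * (n_seg - 1)
        if length <= 0:
            continue
        if t0 < onset_s:
            A = random_background_matrix(rng, n_channels, radius_pre, fs,
                                         f_background_pre)
        else:
            # complete the ictal basis with an orthonormal basis of its
            # orthogonal complement; similarity keeps the planted spectrum
            # and eigenvector support exact
            Q = np.linalg.qr(
                np.hstack([basis, rng.standard_normal((n_channels, n_channels - 2))])
            )[0]
            V = np.hstack([basis, Q[:, 2:]])
            blk = np.zeros((n_channels, n_channels))
            blk[:2, :2] = ictal_block
            blk[2:, 2:] = random_background_matrix(
                rng, n_channels - 2, radius_pre, fs, f_background_post)
            A = V @ blk @ np.linalg.inv(V)
        matrices.append(A)
        seg_lengths.append(length)

    spec = SwitchingSystemSpec(
        matrices=tuple(matrices),
        segment_lengths=tuple(seg_lengths),
        noise_sd=noise_sd,
        x0=rng.normal(0.0, max(noise_sd, 1e-12), size=n_channels),
        fs=fs,
        seed=int(rng.integers(2**31 - 1)),
    )
    rec = simulate_switching_lti(spec)
    rec.events.append(Event("UEO", onset_s))

    theta = 2 * math.pi * f_ictal / fs
    lam = radius_ictal * complex(math.cos(theta), math.sin(theta))
    return FocalSurrogate(
        recording=rec,
        spec=spec,
        soz_channels=soz,
        f_ictal=f_ictal,
        ictal_eigenvalues=(lam, lam.conjugate()),
        ictal_basis=basis,
        ictal_loadings=ictal_loadings,
        onset_s=onset_s,
    )
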