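"""V1 simple-cell input stage: oriented difference-of-Gaussians filters.

Each retinal image is filtered by a bank of 32 kernels — 4 spatial
frequencies (0.5, 0.25, 0.125, 0.0625 cycles/pixel) × 4 orientations
(0°–135° in 45° steps) × 2 signs (±1).  A kernel is a difference of two
Gaussians along the axis ``u = x·cosθ + y·sinθ`` weighted by a third,
orthogonal Gaussian along ``v = x·sinθ − y·cosθ``:

    Γ(x, y; ρ, θ, f) = ρ [ exp(−(u f/√2)²) − (1/1.6) exp(−(u f/(1.6√2))²) ]
                         · exp(−(v f/(3√2))²)

so the value at the origin is ρ(1 − 1/1.6) = 0.375ρ.  Responses are
half-wave rectified, giving segregated positive/negative channel pairs of
non-negative firing rates.

The :class:`DoGFilterBank` transformer also carries an optional per-
frequency-band normalization (each band divided by its maximum response
over a reference image set) so that no band dominates downstream dot
products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft2, rfft2
from sklearn.base import BaseEstimator, TransformerMixin

FREQUENCIES = (0.5, 0.25, 0.125, 0.0625)
ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)
SIGNS = (1, -1)
N_CHANNELS = len(FREQUENCIES) * len(ORIENTATIONS) * len(SIGNS)

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class FilterSpec:
    frequency: float
    orientation: float
    sign: int

    @property
    def channel(self) -> int:
        return (FREQUENCIES.index(self.frequency) * len(ORIENTATIONS)
                + ORIENTATIONS.index(self.orientation)) * 2 \
            + (0 if self.sign > 0 else 1)


@dataclass(frozen=True)
class FilterKernel:
    spec: FilterSpec
    taps: np.ndarray  # (2r+1, 2r+1)


def filter_specs() -> list[FilterSpec]:
    return [FilterSpec(f, o, s) for f in FREQUENCIES for o in ORIENTATIONS
            for s in SIGNS]


def dog_kernel(spec: FilterSpec, radius: int) -> np.ndarray:
    """Sample the oriented DoG on integer offsets |x|,|y| <= radius.

    ``x`` is the horizontal (column) offset and ``y`` the vertical (row,
    upward-positive) offset, so θ = 0 varies along x and prefers vertical
    edges.
    """
    f = spec.frequency
    t = np.deg2rad(spec.orientation)
    off = np.arange(-radius, radius + 1, dtype=np.float64)
    y, x = np.meshgrid(-off, off, indexing="ij")  # row index grows downward
    u = x * np.cos(t) + y * np.sin(t)
    v = x * np.sin(t) - y * np.cos(t)
    s1 = _SQRT2 / f
    s2 = 1.6 * _SQRT2 / f
    s3 = 3.0 * _SQRT2 / f
    core = np.exp(-((u / s1) ** 2)) - np.exp(-((u / s2) ** 2)) / 1.6
    return spec.sign * core * np.exp(-((v / s3) ** 2))


def kernel_radius(frequency: float, canvas_size: int) -> int:
    """Truncation radius: three times the widest Gaussian envelope
    (values beyond are < ~1.2e-4 of peak), capped at half the canvas."""
    return int(min(np.ceil(3.0 * 3.0 * _SQRT2 / frequency), canvas_size // 2))


def build_bank(canvas_size: int) -> list[FilterKernel]:
    """All 32 kernels for a square canvas."""
    bank = []
    for spec in filter_specs():
        r = kernel_radius(spec.frequency, canvas_size)
        bank.append(FilterKernel(spec, dog_kernel(spec, r)))
    return bank


class DoGFilterBank(TransformerMixin, BaseEstimator):
    """Transform grayscale frames into the 32-channel retinal code.

    Parameters
    ----------
    canvas_size : side of the square input frames, in pixels.
    band_normalize : if True, each frequency band of the rectified
        responses is divided by its maximum over the frames passed to
        :meth:`fit` (mild rebalancing; the per-band connection counts of
        the first network layer already equalise coverage).
    fit_stride : use every ``fit_stride``-th frame when estimating the
        band maxima, to keep fitting cheap on long sequences.

    Attributes
    ----------
    band_max_ : (4,) per-frequency-band maxima used for normalization.
    """

    def __init__(self, canvas_size: int = 128, band_normalize: bool = True,
                 frame_normalize: bool = False, fit_stride: int = 1):
        self.canvas_size = canvas_size
        self.band_normalize = band_normalize
        self.frame_normalize = frame_normalize
        self.fit_stride = fit_stride

    # -- plumbing -----------------------------------------------------
    def _ensure_kernels(self) -> None:
        if getattr(self, "_kfft", None) is not None:
            return
        n = self.canvas_size
        rmax = kernel_radius(min(FREQUENCIES), n)
        self._pad = rmax
        self._shape = (n + 2 * rmax, n + 2 * rmax)
        kfft = []
        for kern in build_bank(n):
            r = kern.taps.shape[0] // 2
            big = np.zeros(self._shape)
            # place kernel so that correlation output aligns at [pad:pad+n]
            big[:2 * r + 1, :2 * r + 1] = kern.taps[::-1, ::-1]
            kfft.append(rfft2(big))
        self._kfft = kfft

    def _filter_one(self, frame: np.ndarray) -> np.ndarray:
        n = self.canvas_size
        if frame.shape != (n, n):
            raise ValueError(f"frame shape {frame.shape} does not match "
                             f"canvas {(n, n)}")
        self._ensure_kernels()
        work = np.zeros(self._shape)
        work[self._pad:self._pad + n, self._pad:self._pad + n] = \
            frame - frame.mean()
        ffreq = rfft2(work)
        code = np.empty((n, n, N_CHANNELS), dtype=np.float32)
        for ch, (spec, kf) in enumerate(zip(filter_specs(), self._kfft)):
            r = kernel_radius(spec.frequency, n)
            full = irfft2(ffreq * kf, s=self._shape)
            block = full[self._pad + r:self._pad + r + n,
                         self._pad + r:self._pad + r + n]
            code[:, :, spec.channel] = block
        np.maximum(code, 0.0, out=code)
        return code

    # -- sklearn surface ----------------------------------------------
    def fit(self, X, y=None):
        """Estimate per-band normalization maxima from frames ``X``
        (array-like of shape (n_frames, H, W))."""
        self._kfft = None
        self.band_max_ = np.ones(len(FREQUENCIES))
        if self.band_normalize:
            maxima = np.zeros(len(FREQUENCIES))
            frames = np.asarray(X, dtype=np.float64)[::max(1, self.fit_stride)]
            for frame in frames:
                code = self._filter_one(frame)
                for b in range(len(FREQUENCIES)):
                    sl = code[:, :, 8 * b:8 * (b + 1)]
                    maxima[b] = max(maxima[b], float(sl.max()))
            maxima[maxima == 0] = 1.0
            self.band_max_ = maxima
        return self

    def transform(self, X) -> np.ndarray:
        """Filter frames into retinal codes of shape (n_frames, H, W, 32)."""
        if not hasattr(self, "band_max_"):
            raise RuntimeError("DoGFilterBank must be fitted before transform")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.empty((len(X), self.canvas_size, self.canvas_size,
                        N_CHANNELS), dtype=np.float32)
        for i, frame in enumerate(X):
            out[i] = self._filter_one(frame)
        if self.band_normalize:
            for b, m in enumerate(self.band_max_):
                out[:, :, :, 8 * b:8 * (b + 1)] /= m
        if self.frame_normalize:
            flat = out.reshape(len(out), -1)
            norms = np.linalg.norm(flat, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            flat /= norms
        return out[0] if single else out


def apply_bank(frame: np.ndarray, bank: DoGFilterBank) -> np.ndarray:
    """Functional wrapper: one frame -> (H, W, 32) rectified retinal code."""
    return bank.transform(frame)


def allocate_layer1_afferents(retina_shape: tuple[int, int, int],
                              grid_shape: tuple[int, int],
                              counts_per_frequency: tuple[int, ...],
                              radius: float,
                              seed: int | np.random.Generator) -> np.ndarray:
    """Wire each first-layer neuron to the retinal code.

    Per neuron, ``counts_per_frequency[b]`` connections are drawn from
    frequency band ``b``, spread as evenly as possible over that band's 8
    (orientation × sign) channels.  Retinal locations are sampled from an
    isotropic 2D Gaussian centred on the neuron's topologically
    corresponding retinal position, with σ = radius/1.49 so that ~67% of
    draws fall within ``radius``; duplicates of a (channel, pixel) pair
    are redrawn.  Returns flat indices into the (H, W, C) code, of shape
    (n_neurons, total_connections).
    """
    h, w, n_ch = retina_shape
    if n_ch != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS}-channel retina, got {n_ch}")
    if len(counts_per_frequency) != len(FREQUENCIES):
        raise ValueError("one connection count per frequency band required")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    gr, gc = grid_shape
    total = int(sum(counts_per_frequency))
    sigma = radius / 1.49
    out = np.empty((gr * gc, total), dtype=np.int64)
    # even split of a band's count over its 8 channels
    per_channel: list[tuple[int, int]] = []  # (channel, n_draws)
    for b, count in enumerate(counts_per_frequency):
        base, rem = divmod(int(count), 8)
        for k in range(8):
            n = base + (1 if k < rem else 0)
            if n:
                per_channel.append((8 * b + k, n))
    for gi in range(gr):
        for gj in range(gc):
            cy = (gi + 0.5) * h / gr - 0.5
            cx = (gj + 0.5) * w / gc - 0.5
            chosen: set[int] = set()
            flat = []
            for ch, n in per_channel:
                got = 0
                while got < n:
                    dy, dx = rng.normal(0.0, sigma, size=2)
                    py = int(np.rint(cy + dy)) % h
                    px = int(np.rint(cx + dx)) % w
                    idx = (py * w + px) * n_ch + ch
                    if idx in chosen:
                        continue
                    chosen.add(idx)
                    flat.append(idx)
                    got += 1
            out[gi * gc + gj] = flat
    return out
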