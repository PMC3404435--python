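"""Four-layer hierarchical competitive network with Hebbian learning.

Each layer is a grid of rate neurons wired to a topologically
corresponding neighbourhood of the previous stage (the 32-channel retinal
code for layer 1, the previous layer's firing for layers 2–4).  A
presentation proceeds, per layer, as

1. linear activation   h_i = Σ_j w_ij · y_j           (dot product)
2. lateral inhibition  r = h ⊛ I (toroidal), where the kernel I has an
   excitatory centre and a Gaussian inhibitory surround and sums to 1
3. contrast enhancement y = 1 / (1 + exp(−2β (r − α))), with the
   threshold α set each presentation to a fixed percentile of r so the
   layer's firing sparseness is controlled
4. (during that layer's training only) Hebbian update δw_ij = α_rate y_i x_j
   followed by renormalizing each neuron's weight vector to unit length.

Weight normalization is what makes the learning competitive: without it a
few neurons would come to win for every input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft2, rfft2
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .filters import allocate_layer1_afferents

# σ of the connection Gaussian from the 67%-mass-within-radius rule:
# 1 - exp(-r²/2σ²) = 0.67  =>  r/σ = 1.49
RADIUS_TO_SIGMA = 1.0 / 1.49


@dataclass(frozen=True)
class LayerConfig:
    """One row of the architecture tables: grid, fan-in, connection
    radius (67% rule), inhibition width σ and contrast δ, sigmoid
    percentile and slope β."""

    shape: tuple[int, int]
    n_connections: int
    radius: float
    inhib_sigma: float
    inhib_delta: float
    percentile: float
    beta: float


# Full-preset architecture (32×32 layers over a 128×128×32 retina).
FULL_LAYERS = (
    LayerConfig((32, 32), 272, 6.0, 1.38, 1.5, 95.0, 190.0),
    LayerConfig((32, 32), 100, 6.0, 2.7, 1.5, 95.0, 40.0),
    LayerConfig((32, 32), 100, 9.0, 4.0, 1.6, 88.0, 75.0),
    LayerConfig((32, 32), 100, 12.0, 6.0, 1.4, 91.0, 26.0),
)
FULL_BAND_COUNTS = (201, 50, 13, 8)  # layer-1 fan-in per frequency band

# Desk-scale preset: 16×16 layers over a 64×64×32 retina, radii and
# inhibition widths halved with the retina, layer-1 band counts scaled to
# keep the 201:50:13:8 proportions.
SCALED_LAYERS = (
    LayerConfig((16, 16), 136, 3.0, 0.69, 1.5, 95.0, 190.0),
    LayerConfig((16, 16), 100, 3.0, 1.35, 1.5, 95.0, 40.0),
    LayerConfig((16, 16), 100, 4.5, 2.0, 1.6, 88.0, 75.0),
    LayerConfig((16, 16), 100, 6.0, 3.0, 1.4, 91.0, 26.0),
)
SCALED_BAND_COUNTS = (100, 25, 7, 4)


def inhibition_kernel(shape: tuple[int, int], sigma: float,
                      delta: float) -> np.ndarray:
    """Lateral-inhibition kernel laid out on the layer's torus.

    Off-centre taps are −δ·exp(−d²/σ²) with d the toroidal offset
    distance, truncated at |offset| ≤ ceil(3σ); the centre tap is one
    minus the sum of the others, so the whole kernel sums to exactly 1
    and a uniform activation pattern is a fixed point.
    """
    rows, cols = shape
    a = np.minimum(np.arange(rows), rows - np.arange(rows))
    b = np.minimum(np.arange(cols), cols - np.arange(cols))
    d2 = a[:, None] ** 2 + b[None, :] ** 2
    trunc = int(np.ceil(3.0 * sigma))
    kern = np.where((a[:, None] <= trunc) & (b[None, :] <= trunc),
                    -delta * np.exp(-d2 / sigma ** 2), 0.0)
    kern[0, 0] = 1.0 - kern.ravel()[1:].sum()
    return kern


def inhibit(h: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Toroidal (circular) convolution of the activation grid with the
    inhibition kernel."""
    if h.shape != kernel.shape:
        raise ValueError("activation grid and kernel shapes differ")
    return irfft2(rfft2(h) * rfft2(kernel), s=h.shape)


def activate(y_prev: np.ndarray, afferents: np.ndarray,
             weights: np.ndarray) -> np.ndarray:
    """h_i = Σ_j w_ij y_j over each neuron's wired afferents."""
    return np.einsum("ij,ij->i", weights, y_prev[afferents])


def contrast_enhance(r: np.ndarray, percentile: float,
                     beta: float) -> tuple[np.ndarray, float]:
    """Sigmoid squashing with the threshold at the given percentile of
    the current activation distribution.  For an all-equal r the
    threshold equals that value and every neuron fires at 0.5 (the
    documented degenerate behaviour)."""
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    if beta <= 0:
        raise ValueError("beta must be positive")
    alpha = float(np.percentile(r, percentile))
    # keep firing strictly inside (0,1): the sigmoid never reaches its
    # asymptotes, but float arithmetic saturates for |2β(r−α)| ≳ 40
    y = np.clip(expit(2.0 * beta * (r - alpha)), 1e-12, 1.0 - 1e-12)
    return y, alpha


def sparseness(y: np.ndarray) -> float:
    """Rolls–Treves population sparseness a = (Σy/N)² / (Σy²/N); the
    fraction of active neurons in the binary case."""
    y = np.asarray(y, dtype=np.float64)
    if np.any(y < 0):
        raise ValueError("firing rates must be non-negative")
    ssq = float(np.sum(y ** 2))
    if ssq == 0.0:
        raise ValueError("sparseness undefined for all-zero firing")
    n = y.size
    return (y.sum() / n) ** 2 / (ssq / n)


def hebbian_update(weights: np.ndarray, afferents: np.ndarray,
                   y_post: np.ndarray, y_pre: np.ndarray,
                   rate: float) -> None:
    """In-place associative update δw_ij = rate·y_i·x_j followed by
    renormalizing each neuron's weight vector to unit Euclidean length."""
    if rate <= 0:
        raise ValueError("learning rate must be positive")
    weights += rate * y_post[:, None] * y_pre[afferents]
    norms = np.linalg.norm(weights, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    weights /= norms


@dataclass
class LayerActivity:
    h: np.ndarray
    r: np.ndarray
    y: np.ndarray
    alpha_threshold: float


def init_layer_connectivity(config: LayerConfig,
                            source_shape: tuple[int, int],
                            rng: np.random.Generator) -> np.ndarray:
    """Afferent indices into the flattened source grid, one row per
    neuron: draws from an isotropic Gaussian (σ = radius/1.49) around the
    topologically corresponding source cell, toroidal wrap, no duplicate
    sources per neuron."""
    sr, sc = source_shape
    if config.radius >= min(sr, sc):
        raise ValueError("connection radius exceeds source grid")
    gr, gc = config.shape
    sigma = config.radius * RADIUS_TO_SIGMA
    n = config.n_connections
    out = np.empty((gr * gc, n), dtype=np.int64)
    for gi in range(gr):
        for gj in range(gc):
            cy = (gi + 0.5) * sr / gr - 0.5
            cx = (gj + 0.5) * sc / gc - 0.5
            chosen: set[int] = set()
            flat = []
            while len(flat) < n:
                dy, dx = rng.normal(0.0, sigma, size=2)
                py = int(np.rint(cy + dy)) % sr
                px = int(np.rint(cx + dx)) % sc
                idx = py * sc + px
                if idx in chosen:
                    continue
                chosen.add(idx)
                flat.append(idx)
            out[gi * gc + gj] = flat
    return out


def init_weights(n_neurons: int, n_connections: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Uniform-positive weights, each neuron's vector normalized to 1."""
    w = rng.uniform(0.0, 1.0, size=(n_neurons, n_connections))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return w


class HierarchicalCompetitiveNetwork(BaseEstimator, TransformerMixin):
    """The 4-layer competitive hierarchy as an unsupervised transformer.

    ``fit`` trains the layers on ordered view sequences of retinal codes
    (continuous-transformation learning: frames must arrive in smooth
    angular order); ``transform`` maps codes to output-layer firing with
    the weights frozen.

    Parameters
    ----------
    layer_configs : per-layer architecture rows (defaults to the full
        32×32 preset).
    band_counts : layer-1 fan-in per retinal frequency band.
    epochs : training epochs per layer (int or one per layer).
    learning_rates : Hebbian rates per layer.
    training_mode : 'layerwise' trains one layer at a time from the
        bottom with lower layers frozen (the default and reference
        schedule); 'sweep' updates all layers within each presentation.
    random_state : seed for wiring and weight initialization.

    Attributes
    ----------
    afferents_ : list of per-layer afferent index arrays.
    weights_ : list of per-layer weight matrices (unit row norms).
    inhibition_kernels_ : per-layer lateral-inhibition kernels.
    input_shape_ : (H, W, C) retinal-code geometry the network expects.
    """

    def __init__(self, layer_configs=FULL_LAYERS, band_counts=FULL_BAND_COUNTS,
                 epochs=50, learning_rates=(0.109, 0.1, 0.1, 0.1),
                 training_mode="layerwise", random_state=0):
        self.layer_configs = layer_configs
        self.band_counts = band_counts
        self.epochs = epochs
        self.learning_rates = learning_rates
        self.training_mode = training_mode
        self.random_state = random_state

    # ------------------------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.layer_configs)

    def _epochs_per_layer(self) -> list[int]:
        if np.isscalar(self.epochs):
            return [int(self.epochs)] * self.n_layers
        return [int(e) for e in self.epochs]

    def initialize(self, input_shape: tuple[int, int, int]):
        """Build wiring and random unit-norm weights; the network is then
        usable untrained (the epoch-0 baseline) or trainable."""
        rng = np.random.default_rng(self.random_state)
        cfg0 = self.layer_configs[0]
        if sum(self.band_counts) != cfg0.n_connections:
            raise ValueError("band counts must sum to the layer-1 fan-in")
        self.input_shape_ = tuple(input_shape)
        self.afferents_ = [allocate_layer1_afferents(
            self.input_shape_, cfg0.shape, self.band_counts, cfg0.radius, rng)]
        for prev, cfg in zip(self.layer_configs[:-1], self.layer_configs[1:]):
            self.afferents_.append(
                init_layer_connectivity(cfg, prev.shape, rng))
        self.weights_ = [init_weights(len(aff), aff.shape[1], rng)
                         for aff in self.afferents_]
        self.inhibition_kernels_ = [
            inhibition_kernel(c.shape, c.inhib_sigma, c.inhib_delta)
            for c in self.layer_configs]
        self.trained_epochs_ = [0] * self.n_layers
        return self

    def _check_initialized(self):
        if not hasattr(self, "weights_"):
            raise RuntimeError("network not initialized; call initialize() "
                               "or fit() first")

    # ------------------------------------------------------------------
    def _layer_step(self, layer: int, x_prev: np.ndarray) -> LayerActivity:
        cfg = self.layer_configs[layer]
        h = activate(x_prev, self.afferents_[layer], self.weights_[layer])
        r = inhibit(h.reshape(cfg.shape),
                    self.inhibition_kernels_[layer]).ravel()
        y, alpha = contrast_enhance(r, cfg.percentile, cfg.beta)
        return LayerActivity(h, r, y, alpha)

    def forward_pass(self, code: np.ndarray,
                     up_to_layer: int | None = None) -> list[LayerActivity]:
        """Run activate → inhibit → contrast-enhance through layers
        1..up_to_layer for one retinal code; returns all activities."""
        self._check_initialized()
        stop = self.n_layers if up_to_layer is None else up_to_layer
        x = np.asarray(code, dtype=np.float64).ravel()
        acts = []
        for layer in range(stop):
            act = self._layer_step(layer, x)
            acts.append(act)
            x = act.y
        return acts

    # ------------------------------------------------------------------
    def _flatten_sequences(self, sequences) -> tuple[np.ndarray, list[int]]:
        """Stack sequences of codes into one (n_frames, D) float32 array,
        preserving presentation order."""
        frames = []
        for seq in sequences:
            arr = np.asarray(seq)
            if arr.shape[1:] != tuple(self.input_shape_):
                raise ValueError("sequence code geometry does not match "
                                 f"{self.input_shape_}")
            frames.append(arr.reshape(len(arr), -1))
        lengths = [len(f) for f in frames]
        return np.concatenate(frames, axis=0), lengths

    def train_layer(self, layer: int, x_frames: np.ndarray,
                    epochs: int, rate: float) -> None:
        """Online Hebbian training of one layer from cached afferent
        activity, frames in presentation order within each epoch."""
        self._check_initialized()
        if layer > 0 and self.training_mode == "layerwise" and \
                self.trained_epochs_[layer - 1] == 0:
            raise RuntimeError(f"layer {layer} requires layer {layer - 1} "
                               "to be trained first")
        aff, w = self.afferents_[layer], self.weights_[layer]
        for _ in range(epochs):
            for x in x_frames:
                x64 = x.astype(np.float64)
                act = self._layer_step(layer, x64)
                hebbian_update(w, aff, act.y, x64, rate)
        self.trained_epochs_[layer] += epochs

    def _propagate(self, x_frames: np.ndarray, layer: int) -> np.ndarray:
        """Push cached frames one layer up (frozen weights)."""
        out = np.empty((len(x_frames), int(np.prod(self.layer_configs[layer].shape))),
                       dtype=np.float64)
        for i, x in enumerate(x_frames):
            out[i] = self._layer_step(layer, x.astype(np.float64)).y
        return out

    def fit(self, X, y=None):
        """Train on ``X``: a list of view sequences, each an array of
        retinal codes (n_frames, H, W, C) in angular order.

        Layerwise mode trains layer 1 for its epoch budget over every
        sequence, freezes it, re-propagates the stimuli, then trains the
        next layer, and so on.  Sweep mode updates all layers within each
        frame presentation.
        """
        first = np.asarray(X[0])
        self.initialize(first.shape[1:])
        x_frames, _ = self._flatten_sequences(X)
        epochs = self._epochs_per_layer()
        rates = list(self.learning_rates)
        if self.training_mode == "layerwise":
            for layer in range(self.n_layers):
                self.train_layer(layer, x_frames, epochs[layer], rates[layer])
                if layer < self.n_layers - 1:
                    x_frames = self._propagate(x_frames, layer)
        elif self.training_mode == "sweep":
            for _ in range(max(epochs)):
                for x in x_frames:
                    xcur = x.astype(np.float64)
                    for layer in range(self.n_layers):
                        act = self._layer_step(layer, xcur)
                        hebbian_update(self.weights_[layer],
                                       self.afferents_[layer], act.y, xcur,
                                       rates[layer])
                        xcur = act.y
            self.trained_epochs_ = [max(epochs)] * self.n_layers
        else:
            raise ValueError(f"unknown training_mode {self.training_mode!r}")
        return self

    def transform(self, X) -> np.ndarray:
        """Output-layer firing for codes ``X`` of shape (n, H, W, C) or a
        single (H, W, C) code; weights are left untouched."""
        self._check_initialized()
        X = np.asarray(X)
        single = X.ndim == 3
        if single:
            X = X[None]
        out = np.empty((len(X), int(np.prod(self.layer_configs[-1].shape))))
        for i, code in enumerate(X):
            out[i] = self.forward_pass(code)[-1].y
        return out[0] if single else out

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint wiring, weights and configuration to one ``.npz``
        container (schema versioned)."""
        self._check_initialized()
        payload = {"schema_version": np.int64(1),
                   "input_shape": np.asarray(self.input_shape_),
                   "trained_epochs": np.asarray(self.trained_epochs_),
                   "band_counts": np.asarray(self.band_counts),
                   "random_state": np.int64(self.random_state)}
        for i, (aff, w, cfg) in enumerate(zip(self.afferents_, self.weights_,
                                              self.layer_configs)):
            payload[f"afferents_{i}"] = aff
            payload[f"weights_{i}"] = w
            payload[f"config_{i}"] = np.asarray(
                [*cfg.shape, cfg.n_connections, cfg.radius, cfg.inhib_sigma,
                 cfg.inhib_delta, cfg.percentile, cfg.beta])
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "HierarchicalCompetitiveNetwork":
        data = np.load(path)
        if int(data["schema_version"]) != 1:
            raise ValueError("unsupported checkpoint schema")
        configs = []
        i = 0
        while f"config_{i}" in data:
            c = data[f"config_{i}"]
            configs.append(LayerConfig((int(c[0]), int(c[1])), int(c[2]),
                                       float(c[3]), float(c[4]), float(c[5]),
                                       float(c[6]), float(c[7])))
            i += 1
        net = cls(layer_configs=tuple(configs),
                  band_counts=tuple(int(b) for b in data["band_counts"]),
                  random_state=int(data["random_state"]))
        net.input_shape_ = tuple(int(v) for v in data["input_shape"])
        net.afferents_ = [data[f"afferents_{k}"] for k in range(len(configs))]
        net.weights_ = [data[f"weights_{k}"] for k in range(len(configs))]
        net.inhibition_kernels_ = [
            inhibition_kernel(c.shape, c.inhib_sigma, c.inhib_delta)
            for c in configs]
        net.trained_epochs_ = [int(e) for e in data["trained_epochs"]]
        return net
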