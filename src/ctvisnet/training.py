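"""Training orchestration: presets, schedules, manifests and the
one-layer continuous-transformation toy demonstration.

The reference schedule trains the hierarchy one layer at a time from the
bottom: each layer sees every frame of all 15 training sequences (the
occluded object paired with each occluder, then every occluder pair) in
increasing-angle order, for its full epoch budget, with all lower layers
frozen.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .filters import DoGFilterBank
from .network import (FULL_BAND_COUNTS, FULL_LAYERS, SCALED_BAND_COUNTS,
                      SCALED_LAYERS, HierarchicalCompetitiveNetwork)
from .stimuli import ViewSequence, build_training_set, pentagon_layout
from .geometry import make_object_library


@dataclass(frozen=True)
class Preset:
    name: str
    canvas_size: int
    step_deg: float
    layer_configs: tuple
    band_counts: tuple
    epochs: int
    learning_rates: tuple = (0.109, 0.1, 0.1, 0.1)


FULL_PRESET = Preset("full", 128, 1.0, FULL_LAYERS, FULL_BAND_COUNTS, 50)
SCALED_PRESET = Preset("scaled", 64, 5.0, SCALED_LAYERS, SCALED_BAND_COUNTS, 10)
PRESETS = {p.name: p for p in (FULL_PRESET, SCALED_PRESET)}


@dataclass
class TrainingSchedule:
    epochs: int
    learning_rates: tuple
    step_deg: float
    seed: int
    sequence_order: str = "occluded-pairs-then-occluder-pairs"


@dataclass
class RunManifest:
    preset: str
    seed: int
    stimulus_hash: str
    checkpoints: list = field(default_factory=list)
    wall_log: list = field(default_factory=list)

    def log(self, message: str) -> None:
        self.wall_log.append(f"{time.strftime('%H:%M:%S')} {message}")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def stimulus_hash(sequences: list[ViewSequence]) -> str:
    md = hashlib.sha256()
    for seq in sequences:
        md.update(seq.name.encode())
        md.update(np.ascontiguousarray(seq.as_array()))
    return md.hexdigest()[:16]


def train_network(training_codes: list[np.ndarray], preset: Preset,
                  seed: int, out_dir=None,
                  training_mode: str = "layerwise",
                  manifest: RunManifest | None = None,
                  ) -> HierarchicalCompetitiveNetwork:
    """Train a network of the given preset on pre-filtered retinal-code
    sequences (one array of shape (n_frames, H, W, 32) per sequence, in
    schedule order); optionally checkpoint to ``out_dir``."""
    net = HierarchicalCompetitiveNetwork(
        layer_configs=preset.layer_configs, band_counts=preset.band_counts,
        epochs=preset.epochs, learning_rates=preset.learning_rates,
        training_mode=training_mode, random_state=seed)
    net.fit(training_codes)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ckpt = out / f"network_{preset.name}_seed{seed}.npz"
        net.save(ckpt)
        if manifest is not None:
            manifest.checkpoints.append(str(ckpt))
    return net


def build_and_filter_training_set(preset: Preset, library_seed: int = 0,
                                  ) -> tuple[DoGFilterBank, list[np.ndarray],
                                             dict]:
    """Render the 15 training sequences for a preset, fit the filter
    bank's band normalization on them, and return the filtered codes."""
    models = make_object_library(library_seed)
    layout = pentagon_layout(preset.canvas_size)
    seqs = build_training_set(models, layout, preset.step_deg)
    bank = DoGFilterBank(canvas_size=preset.canvas_size, fit_stride=7)
    all_frames = np.concatenate([s.as_array() for s in seqs])
    bank.fit(all_frames)
    codes = [bank.transform(s.as_array()) for s in seqs]
    ctx = {"models": models, "layout": layout, "sequences": seqs}
    return bank, codes, ctx


# ----------------------------------------------------------------------
# Idealized one-layer demonstration of continuous-transformation learning
# ----------------------------------------------------------------------

@dataclass
class ToyDemoReport:
    """Winner map of the 1D competitive network after training."""
    coverage: list[dict[int, set]]   # per bar: {output neuron: set of positions won}
    invariant_cells: list[list[int]]  # per bar: neurons winning at every position

    def has_invariant_cell(self, bar: int = 0) -> bool:
        return len(self.invariant_cells[bar]) > 0


def run_ct_toy_demo(n_input: int = 32, bar_width: int = 3, n_output: int = 8,
                    epochs: int = 20, seed: int = 0, learning_rate: float = 1.0,
                    bars: list[tuple[int, int]] | None = None) -> ToyDemoReport:
    """Idealized continuous-transformation learning on a 1D input ring.

    A bar of ``bar_width`` active inputs steps one unit per presentation
    around the ring; the output layer is winner-take-all competitive with
    Hebbian learning and weight normalization.  With overlapping
    successive positions (width ≥ 2) the winning output neuron follows
    the bar and becomes position invariant; with width 1 there is no
    overlap to chain positions together and coverage fragments.

    ``bars`` optionally lists (offset, n_positions) windows, each with
    its own stepping bar; they are trained in interleaved blocks within
    each epoch (one block per bar).  Distinct bars confined to disjoint
    windows come to be covered by distinct output neurons.
    """
    if bar_width < 1:
        raise ValueError("bar width must be >= 1")
    rng = np.random.default_rng(seed)
    if bars is None:
        bars = [(0, n_input)]
    patterns = []
    for offset, n_pos in bars:
        pats = np.zeros((n_pos, n_input))
        for p in range(n_pos):
            pats[p, [(offset + p + k) % n_input for k in range(bar_width)]] = 1.0
        patterns.append(pats)
    w = rng.uniform(0.0, 1.0, size=(n_output, n_input))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    final_winners: list[dict[int, int]] = [dict() for _ in bars]
    for epoch in range(epochs):
        for bar_idx, pats in enumerate(patterns):
            for p, x in enumerate(pats):
                winner = int(np.argmax(w @ x))
                if epoch == epochs - 1:
                    final_winners[bar_idx][p] = winner
                w[winner] += learning_rate * x
                w[winner] /= np.linalg.norm(w[winner])
    # the winner map is read out from the last epoch's presentations: the
    # competition operates online, and invariance here means the same
    # output neuron keeps winning as the bar steps through every position
    coverage, invariant = [], []
    for bar_idx, pats in enumerate(patterns):
        cov: dict[int, set] = {}
        for p, winner in final_winners[bar_idx].items():
            cov.setdefault(winner, set()).add(p)
        coverage.append(cov)
        invariant.append(sorted(i for i, pos in cov.items()
                                if len(pos) == len(pats)))
    return ToyDemoReport(coverage, invariant)
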