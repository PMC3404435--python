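"""End-to-end occlusion experiments: render → filter → train → test →
information analysis.

`run_occlusion_experiment` reproduces the full protocol at a chosen
preset: train on the 15 paired sequences (the central object always
partially hidden), then test with each trained object alone, the five
partial-view fragment sequences, six novel objects at the trained
positions, and the untrained (epoch-0) network as baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import DoGFilterBank
from .geometry import OCCLUDED_ID, TRAINED_IDS, make_object_library
from .info import (ResponseMatrix, ensemble_information, record_responses,
                   view_coverage)
from .network import HierarchicalCompetitiveNetwork
from .stimuli import (build_fragment_set, build_test_sets, build_training_set,
                      pentagon_layout)
from .training import Preset, SCALED_PRESET, train_network


@dataclass
class ExperimentResult:
    """Everything the analyses need from one seed's run."""
    seed: int
    network: HierarchicalCompetitiveNetwork
    matrices: dict[str, ResponseMatrix]       # condition -> responses
    info: dict[str, dict]                     # condition -> info pipeline out

    @property
    def multi_cell_bits(self) -> dict[str, float]:
        return {c: r["multi_cell_bits"] for c, r in self.info.items()}


def build_stimuli(preset: Preset, library_seed: int = 0) -> dict:
    """Render every sequence set the protocol needs."""
    models = make_object_library(library_seed)
    layout = pentagon_layout(preset.canvas_size)
    return {
        "models": models,
        "layout": layout,
        "training": build_training_set(models, layout, preset.step_deg),
        "trained_alone": build_test_sets(models, layout, preset.step_deg)[0],
        "novel_alone": build_test_sets(models, layout, preset.step_deg)[1],
        "fragments": build_fragment_set(models, layout, preset.step_deg),
    }


def run_occlusion_experiment(preset: Preset = SCALED_PRESET,
                             network_seed: int = 0,
                             library_seed: int = 0,
                             stimuli: dict | None = None,
                             bank: DoGFilterBank | None = None,
                             training_codes: list[np.ndarray] | None = None,
                             n_bins: int = 10,
                             decoder: str = "cosine") -> ExperimentResult:
    """One full run at one network seed.

    Stimuli, filter bank and training codes may be passed in to share
    them across seeds (they do not depend on the network seed).
    """
    if stimuli is None:
        stimuli = build_stimuli(preset, library_seed)
    if bank is None:
        bank = DoGFilterBank(canvas_size=preset.canvas_size, fit_stride=7)
        bank.fit(np.concatenate([s.as_array() for s in stimuli["training"]]))
    if training_codes is None:
        training_codes = [bank.transform(s.as_array())
                          for s in stimuli["training"]]

    # untrained baseline: same wiring/weights, epoch 0
    baseline = HierarchicalCompetitiveNetwork(
        layer_configs=preset.layer_configs, band_counts=preset.band_counts,
        epochs=0, learning_rates=preset.learning_rates,
        random_state=network_seed)
    baseline.initialize(training_codes[0].shape[1:])
    matrices = {"untrained": record_responses(
        baseline, bank, stimuli["trained_alone"], "untrained-network")}

    net = train_network(training_codes, preset, network_seed)
    matrices["trained"] = record_responses(
        net, bank, stimuli["trained_alone"], "trained-objects")
    matrices["novel"] = record_responses(
        net, bank, stimuli["novel_alone"], "novel-objects")
    matrices["fragments"] = record_responses(
        net, bank, stimuli["fragments"], "fragments")

    info = {cond: ensemble_information(matrices[cond], n_bins=n_bins,
                                       decoder=decoder)
            for cond in ("untrained", "trained", "novel")}
    return ExperimentResult(network_seed, net, matrices, info)


def occluded_object_readout(result: ExperimentResult,
                            threshold: float = 0.5) -> dict:
    """Selectivity of the single most occluded-object-informative output
    cell: view coverage of the occluded object, exclusivity over other
    objects, and its responsiveness in the five fragment conditions."""
    obj = TRAINED_IDS.index(OCCLUDED_ID)
    sci = result.info["trained"]["single_cell"]
    cell = int(sci.top_cells_for_object(obj, 1)[0])
    coverage, exclusive = view_coverage(result.matrices["trained"], cell, obj,
                                        threshold)
    frag = result.matrices["fragments"].firing[cell]   # (5, n_views)
    responds_each_fragment = (frag > threshold).any(axis=1)
    return {"cell": cell,
            "coverage": coverage,
            "exclusive": exclusive,
            "fragment_response": responds_each_fragment,
            "fragment_view_fraction": (frag > threshold).mean(axis=1)}


def per_object_invariant_cells(result: ExperimentResult,
                               min_coverage: float = 0.8,
                               threshold: float = 0.5) -> dict[str, bool]:
    """For each trained object: does some output cell respond to at
    least ``min_coverage`` of its views and to no view of any other?"""
    mat = result.matrices["trained"]
    firing = mat.firing                       # (cells, objects, views)
    above = firing > threshold
    frac = above.mean(axis=2)                 # (cells, objects)
    out = {}
    for o, oid in enumerate(mat.object_ids):
        others = np.delete(above, o, axis=1).any(axis=(1, 2))
        out[oid] = bool(((frac[:, o] >= min_coverage) & ~others).any())
    return out


def untrained_reference(preset: Preset, seeds=(0, 1, 2), library_seed: int = 0,
                        n_bins: int = 10, decoder: str = "cosine",
                        fit_stride: int = 10) -> dict:
    """Multiple-cell information of the untrained (random, normalized-
    weight) network on the six trained-condition objects, streamed frame
    by frame so the full-resolution retina fits in memory; averaged over
    seeds."""
    models = make_object_library(library_seed)
    layout = pentagon_layout(preset.canvas_size)
    trained_alone, _ = build_test_sets(models, layout, preset.step_deg)
    bank = DoGFilterBank(canvas_size=preset.canvas_size,
                         fit_stride=fit_stride)
    bank.fit(np.concatenate([s.as_array()[::fit_stride]
                             for s in trained_alone]))
    nets = []
    for seed in seeds:
        net = HierarchicalCompetitiveNetwork(
            layer_configs=preset.layer_configs,
            band_counts=preset.band_counts, epochs=0,
            random_state=seed)
        net.initialize((preset.canvas_size, preset.canvas_size, 32))
        nets.append(net)
    n_views = len(trained_alone[0])
    n_cells = int(np.prod(preset.layer_configs[-1].shape))
    firing = np.zeros((len(seeds), n_cells, len(trained_alone), n_views))
    for o, seq in enumerate(trained_alone):
        for v, frame in enumerate(seq.frames):
            code = bank.transform(frame.pixels)
            for k, net in enumerate(nets):
                firing[k, :, o, v] = net.forward_pass(code)[-1].y
    bits = []
    for k, seed in enumerate(seeds):
        mat = ResponseMatrix(firing[k], tuple(s.name for s in trained_alone),
                             "untrained-network")
        bits.append(ensemble_information(mat, n_bins=n_bins,
                                         decoder=decoder)["multi_cell_bits"])
    return {"bits_per_seed": dict(zip(seeds, bits)),
            "mean_bits": float(np.mean(bits)),
            "n_trials": len(trained_alone) * n_views}
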