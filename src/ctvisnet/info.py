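"""Information-theoretic readout of the output layer.

Two complementary measures quantify how well the output layer separates
the objects after training:

* **Single-cell stimulus-specific information.**  With views serving as
  trials and objects equiprobable, a cell's discretized responses r give,
  for each object s,

      I(s, R) = Σ_r P(r|s) log2 [ P(r|s) / P(r) ]

  whose ceiling is log2(n_objects) — reached by a cell that fires for
  every view of exactly one object and never otherwise.

* **Multiple-cell information.**  An ensemble (the five most informative
  cells per object) is decoded trial-by-trial with a leave-one-view-out
  nearest-class-mean rule (cosine similarity); the mutual information of
  the resulting (true object, decoded object) confusion table,

      I(S, S') = Σ_{s,s'} P(s, s') log2 [ P(s, s') / (P(s) P(s')) ],

  measures how much the population as a whole tells about which object
  was shown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ResponseMatrix:
    """Output-layer firing indexed by (cell, object, view) in [0, 1]."""

    firing: np.ndarray                   # (n_cells, n_objects, n_views)
    object_ids: tuple[str, ...]
    condition: str = ""                  # trained-objects | novel-objects | ...

    @property
    def n_cells(self) -> int:
        return self.firing.shape[0]

    @property
    def n_objects(self) -> int:
        return self.firing.shape[1]

    @property
    def n_views(self) -> int:
        return self.firing.shape[2]


@dataclass
class SingleCellInfo:
    info: np.ndarray        # (n_cells, n_objects) bits
    max_per_cell: np.ndarray
    ranking: np.ndarray     # cells in descending order of max info

    def top_cells_for_object(self, obj: int, k: int) -> np.ndarray:
        order = np.lexsort((np.arange(len(self.info)), -self.info[:, obj]))
        return order[:k]


def record_responses(network, bank, sequences, condition: str = "",
                     ) -> ResponseMatrix:
    """Filter and present test sequences with frozen weights; returns
    output-layer firing per (cell, object, view).  Any weight drift
    during testing is a hard error."""
    before = [w.copy() for w in network.weights_]
    mats = []
    for seq in sequences:
        codes = bank.transform(seq.as_array())
        mats.append(network.transform(codes).T)  # (n_cells, n_views)
    for w0, w1 in zip(before, network.weights_):
        if not np.array_equal(w0, w1):
            raise RuntimeError("synaptic weights changed during testing")
    return ResponseMatrix(np.stack(mats, axis=1),
                          tuple(s.name for s in sequences), condition)


def discretize_responses(firing: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantize each cell's rates into equal-width bins over that cell's
    observed range; constant cells occupy a single bin."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    f = np.asarray(firing, dtype=np.float64)
    lo = f.reshape(f.shape[0], -1).min(axis=1)
    hi = f.reshape(f.shape[0], -1).max(axis=1)
    span = hi - lo
    flat = span == 0
    span[flat] = 1.0
    scaled = (f - lo[:, None, None]) / span[:, None, None]
    binned = np.minimum((scaled * n_bins).astype(np.int64), n_bins - 1)
    binned[flat] = 0
    return binned


def single_cell_information(matrix: ResponseMatrix,
                            n_bins: int = 10) -> SingleCellInfo:
    """Per-cell, per-object stimulus-specific information (bits), with
    views as trials and equiprobable objects."""
    if matrix.firing.size == 0:
        raise ValueError("empty response matrix")
    if matrix.n_objects < 2:
        raise ValueError("need at least two objects")
    binned = discretize_responses(matrix.firing, n_bins)
    n_cells, n_obj, n_views = binned.shape
    info = np.zeros((n_cells, n_obj))
    for c in range(n_cells):
        # P(r|s) table: n_obj × n_bins
        p_rs = np.zeros((n_obj, n_bins))
        for s in range(n_obj):
            counts = np.bincount(binned[c, s], minlength=n_bins)
            p_rs[s] = counts / n_views
        p_r = p_rs.mean(axis=0)  # equiprobable objects
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_rs > 0, p_rs / p_r, 1.0)
            info[c] = np.sum(np.where(p_rs > 0, p_rs * np.log2(ratio), 0.0),
                             axis=1)
    max_per_cell = info.max(axis=1)
    ranking = np.lexsort((np.arange(n_cells), -max_per_cell))
    return SingleCellInfo(info, max_per_cell, ranking)


def select_ensemble(info: SingleCellInfo, per_object: int = 5) -> np.ndarray:
    """Union of each object's ``per_object`` most informative cells
    (duplicates across objects counted once); ties broken by cell index."""
    chosen: list[int] = []
    for obj in range(info.info.shape[1]):
        for c in info.top_cells_for_object(obj, per_object):
            if c not in chosen:
                chosen.append(int(c))
    return np.array(sorted(chosen), dtype=np.int64)


def decode_and_tabulate(matrix: ResponseMatrix, ensemble: np.ndarray,
                        decoder: str = "cosine") -> np.ndarray:
    """Leave-one-view-out decoding of object identity from the ensemble
    response vector; returns the (true, decoded) confusion-count table.

    ``cosine`` decodes to the object whose training-fold mean vector has
    the highest cosine similarity to the held-out vector (invariant to
    positive rescaling of the trial vector); ``gaussian`` is a naive-
    Bayes alternative with per-object diagonal Gaussians.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    resp = matrix.firing[ensemble]                   # (m, n_obj, n_views)
    m, n_obj, n_views = resp.shape
    table = np.zeros((n_obj, n_obj), dtype=np.int64)
    sums = resp.sum(axis=2)                          # (m, n_obj)
    if decoder == "gaussian":
        sq_sums = (resp ** 2).sum(axis=2)
    for s in range(n_obj):
        for v in range(n_views):
            x = resp[:, s, v]
            held = np.zeros((m, n_obj))
            held[:, s] = x
            counts = np.full(n_obj, n_views, dtype=np.float64)
            counts[s] -= 1
            means = (sums - held) / counts
            if decoder == "cosine":
                num = means.T @ x
                den = np.linalg.norm(means, axis=0) * np.linalg.norm(x)
                score = np.divide(num, den, out=np.zeros(n_obj),
                                  where=den > 0)
            elif decoder == "gaussian":
                held_sq = np.zeros((m, n_obj))
                held_sq[:, s] = x ** 2
                var = (sq_sums - held_sq) / counts - means ** 2
                var = np.maximum(var, 1e-6)
                score = -np.sum((x[:, None] - means) ** 2 / var
                                + np.log(var), axis=0)
            else:
                raise ValueError(f"unknown decoder {decoder!r}")
            table[s, int(np.argmax(score))] += 1
    return table


def multiple_cell_information(table: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a confusion-count table."""
    table = np.asarray(table, dtype=np.float64)
    total = table.sum()
    if total == 0:
        raise ValueError("all-zero confusion table")
    p = table / total
    ps = p.sum(axis=1, keepdims=True)
    pd_ = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (ps * pd_)), 0.0)
    return float(terms.sum())


def information_ceiling(n_objects: int) -> float:
    return float(np.log2(n_objects))


def ensemble_information(matrix: ResponseMatrix, per_object: int = 5,
                         n_bins: int = 10, decoder: str = "cosine",
                         ensemble: np.ndarray | None = None) -> dict:
    """Full pipeline: single-cell info → ensemble → decoding → multi-cell
    information.  An externally selected ensemble (e.g. from the trained
    condition, reused for novel objects) may be supplied."""
    sci = single_cell_information(matrix, n_bins)
    if ensemble is None:
        ensemble = select_ensemble(sci, per_object)
    table = decode_and_tabulate(matrix, ensemble, decoder)
    return {"single_cell": sci, "ensemble": ensemble,
            "confusion": table,
            "multi_cell_bits": multiple_cell_information(table)}


def view_coverage(matrix: ResponseMatrix, cell: int, obj: int,
                  threshold: float = 0.5) -> tuple[float, bool]:
    """Fraction of the object's views driving ``cell`` above threshold,
    and whether the cell stays below threshold for every view of every
    other object (exclusive selectivity)."""
    resp = matrix.firing[cell]
    frac = float((resp[obj] > threshold).mean())
    others = np.delete(resp, obj, axis=0)
    return frac, bool((others <= threshold).all())


def report(results: dict[str, dict], matrices: dict[str, ResponseMatrix],
           out_dir) -> None:
    """Write CSV tables and summary figures for a set of conditions.

    ``results`` maps condition name → :func:`ensemble_information`
    output; ``matrices`` the corresponding response matrices.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # ranked single-cell info curves
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, res in results.items():
        sci = res["single_cell"]
        ax.plot(sci.max_per_cell[sci.ranking], label=cond)
        rows = [{"cell": c, "object": matrices[cond].object_ids[o],
                 "bits": sci.info[c, o]}
                for c in range(sci.info.shape[0])
                for o in range(sci.info.shape[1])]
        pd.DataFrame(rows).to_csv(out / f"single_cell_info_{cond}.csv",
                                  index=False)
        pd.DataFrame(res["confusion"],
                     index=matrices[cond].object_ids,
                     columns=matrices[cond].object_ids
                     ).to_csv(out / f"confusion_{cond}.csv")
    ax.set_xlabel("cell rank")
    ax.set_ylabel("max single-cell information (bits)")
    ax.legend()
    fig.savefig(out / "single_cell_info_ranked.png", dpi=120)
    plt.close(fig)
    # multi-cell summary
    pd.DataFrame([{"condition": cond,
                   "multi_cell_bits": res["multi_cell_bits"],
                   "ensemble_size": len(res["ensemble"])}
                  for cond, res in results.items()]
                 ).to_csv(out / "multi_cell_info.csv", index=False)
    # per-cell response-vs-view plots for the best cell of each condition
    for cond, res in results.items():
        mat = matrices[cond]
        best = int(res["single_cell"].ranking[0])
        fig, axes = plt.subplots(1, mat.n_objects, figsize=(3 * mat.n_objects, 2.4),
                                 sharey=True)
        for o, ax in enumerate(np.atleast_1d(axes)):
            ax.plot(mat.firing[best, o])
            ax.set_title(mat.object_ids[o], fontsize=8)
            ax.set_ylim(-0.05, 1.05)
        fig.suptitle(f"{cond}: cell {best}")
        fig.savefig(out / f"best_cell_responses_{cond}.png", dpi=120)
        plt.close(fig)
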