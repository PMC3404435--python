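import numpy as np
import pytest

from ctvisnet.info import (ResponseMatrix, decode_and_tabulate,
                           discretize_responses, ensemble_information,
                           multiple_cell_information, select_ensemble,
                           single_cell_information, view_coverage)

OBJECTS = tuple("abcdef")


def brute_force_single_cell(binned_cell, n_bins):
    """Independent direct summation of the stimulus-specific information
    I(s,R) = Σ_r P(r|s) log2 [P(r|s)/P(r)] with equiprobable objects."""
    n_obj, n_views = binned_cell.shape
    out = np.zeros(n_obj)
    for s in range(n_obj):
        for r in range(n_bins):
            p_rs = np.mean(binned_cell[s] == r)
            p_r = np.mean([np.mean(binned_cell[t] == r)
                           for t in range(n_obj)])
            if p_rs > 0:
                out[s] += p_rs * np.log2(p_rs / p_r)
    return out


def brute_force_mutual_information(table):
    total = table.sum()
    out = 0.0
    for s in range(table.shape[0]):
        for t in range(table.shape[1]):
            p = table[s, t] / total
            if p > 0:
                out += p * np.log2(p / (table[s].sum() / total
                                        * table[:, t].sum() / total))
    return out


def make_matrix(firing, condition="test"):
    return ResponseMatrix(np.asarray(firing, dtype=float),
                          OBJECTS[:np.asarray(firing).shape[1]], condition)


# ------------------------------------------------------------ discretize
def test_binary_firing_two_bins():
    f = np.array([[[0.0, 1.0, 1.0], [0.0, 0.0, 1.0]]])
    b = discretize_responses(f, n_bins=2)
    np.testing.assert_array_equal(b[0], [[0, 1, 1], [0, 0, 1]])


def test_constant_cell_single_bin_and_zero_info():
    f = np.full((1, 4, 6), 0.7)
    assert (discretize_responses(f, 10) == 0).all()
    info = single_cell_information(make_matrix(f), n_bins=10)
    np.testing.assert_allclose(info.info, 0.0, atol=1e-12)


def test_uniform_rates_spread_over_bins(rng):
    f = rng.random((1, 2, 5000))
    b = discretize_responses(f, 10)
    occupancy = np.bincount(b.ravel(), minlength=10) / b.size
    np.testing.assert_allclose(occupancy, 0.1, atol=0.02)


# ------------------------------------------------------------ single cell
def test_perfectly_selective_cell_reaches_ceiling():
    f = np.zeros((1, 6, 360))
    f[0, 2, :] = 1.0
    info = single_cell_information(make_matrix(f), n_bins=10)
    assert info.max_per_cell[0] == pytest.approx(np.log2(6), abs=1e-12)
    assert round(info.max_per_cell[0], 2) == 2.58


def test_object_blind_cell_carries_no_information(rng):
    pattern = rng.random(8)
    f = np.tile(pattern, (1, 4, 1))
    info = single_cell_information(make_matrix(f), n_bins=5)
    np.testing.assert_allclose(info.info, 0.0, atol=1e-12)


def test_single_cell_matches_brute_force(rng):
    f = rng.random((20, 4, 8))
    n_bins = 3
    info = single_cell_information(make_matrix(f), n_bins=n_bins)
    binned = discretize_responses(f, n_bins)
    for c in range(20):
        np.testing.assert_allclose(info.info[c],
                                   brute_force_single_cell(binned[c], n_bins),
                                   atol=1e-10)


def test_coarser_bins_never_increase_information(rng):
    """Merging response bins is data processing: information can only
    shrink when the 8 equal-width bins collapse pairwise into 4."""
    f = rng.random((30, 5, 12))
    fine = single_cell_information(make_matrix(f), n_bins=8)
    coarse = single_cell_information(make_matrix(f), n_bins=4)
    assert (coarse.info <= fine.info + 1e-10).all()


def test_info_bounds_and_ranking(rng):
    f = rng.random((50, 6, 10))
    info = single_cell_information(make_matrix(f), n_bins=4)
    assert (info.info >= -1e-12).all()
    assert (info.info <= np.log2(6) + 1e-12).all()
    assert sorted(info.ranking) == list(range(50))
    ranked = info.max_per_cell[info.ranking]
    assert (np.diff(ranked) <= 1e-12).all()


# ------------------------------------------------------------ ensemble
def test_ensemble_takes_top_five_per_object():
    info = np.zeros((40, 6))
    for o in range(6):
        info[5 * o:5 * o + 5, o] = np.arange(5, 0, -1)
    from ctvisnet.info import SingleCellInfo
    sci = SingleCellInfo(info, info.max(1), np.argsort(-info.max(1)))
    ens = select_ensemble(sci, per_object=5)
    assert len(ens) == 30
    np.testing.assert_array_equal(ens, np.arange(30))


def test_overlapping_top_lists_deduplicate():
    info = np.zeros((10, 6))
    info[:5, :] = 1.0  # same five cells best for every object
    from ctvisnet.info import SingleCellInfo
    sci = SingleCellInfo(info, info.max(1), np.argsort(-info.max(1)))
    assert len(select_ensemble(sci, per_object=5)) == 5


# ------------------------------------------------------------ decoding
def test_selective_ensemble_decodes_diagonally():
    f = np.zeros((6, 6, 10))
    for o in range(6):
        f[o, o, :] = 1.0
    table = decode_and_tabulate(make_matrix(f), np.arange(6))
    np.testing.assert_array_equal(table, np.eye(6, dtype=int) * 10)
    assert multiple_cell_information(table) == pytest.approx(np.log2(6))


def test_decoder_scale_invariance(rng):
    """The cosine rule assigns the same object to a trial vector and any
    positively rescaled copy of it, training-fold means held fixed."""
    f = rng.random((8, 4, 12))
    s, v = 1, 3
    means = f.mean(axis=2)
    means[:, s] = (f[:, s].sum(axis=1) - f[:, s, v]) / 11
    for gain in (1.0, 0.2, 7.5):
        x = gain * f[:, s, v]
        score = means.T @ x / (np.linalg.norm(means, axis=0)
                               * np.linalg.norm(x))
        if gain == 1.0:
            ref = int(np.argmax(score))
        else:
            assert int(np.argmax(score)) == ref


def test_unstructured_responses_decode_near_chance(rng):
    f = rng.random((30, 6, 40))
    table = decode_and_tabulate(make_matrix(f), np.arange(30))
    assert table.sum() == 240
    assert multiple_cell_information(table) < 0.4


def test_multiple_cell_matches_brute_force(rng):
    for _ in range(20):
        table = rng.integers(0, 30, size=(5, 5))
        table[0, 0] += 1  # non-degenerate
        np.testing.assert_allclose(multiple_cell_information(table),
                                   brute_force_mutual_information(table),
                                   atol=1e-10)


def test_independent_table_zero_information():
    table = np.outer([10, 20, 30], [5, 5, 5])
    assert multiple_cell_information(table) == pytest.approx(0.0, abs=1e-12)


def test_gaussian_decoder_also_separates():
    f = np.zeros((6, 6, 10))
    for o in range(6):
        f[o, o, :] = 1.0
    table = decode_and_tabulate(make_matrix(f), np.arange(6),
                                decoder="gaussian")
    assert np.trace(table) == 60


# ------------------------------------------------------------ coverage
def test_view_coverage_and_exclusivity():
    f = np.zeros((2, 3, 10))
    f[0, 1, :9] = 1.0
    f[1, 1, :] = 1.0
    f[1, 2, 0] = 1.0
    mat = make_matrix(f)
    frac, exclusive = view_coverage(mat, 0, 1)
    assert frac == pytest.approx(0.9) and exclusive
    frac, exclusive = view_coverage(mat, 1, 1)
    assert frac == 1.0 and not exclusive


def test_report_writes_tables_and_figures(tmp_path, rng):
    f = rng.random((12, 6, 9))
    mat = make_matrix(f, "trained")
    res = {"trained": ensemble_information(mat, per_object=2)}
    from ctvisnet.info import report
    report(res, {"trained": mat}, tmp_path)
    assert (tmp_path / "multi_cell_info.csv").exists()
    assert (tmp_path / "single_cell_info_trained.csv").exists()
    assert (tmp_path / "single_cell_info_ranked.png").exists()
    import pandas as pd
    df = pd.read_csv(tmp_path / "single_cell_info_trained.csv")
    assert len(df) == 12 * 6
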