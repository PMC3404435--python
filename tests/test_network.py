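import numpy as np
import pytest

from ctvisnet.network import (FULL_LAYERS, SCALED_BAND_COUNTS, SCALED_LAYERS,
                              HierarchicalCompetitiveNetwork, activate,
                              contrast_enhance, hebbian_update,
                              inhibition_kernel, inhibit,
                              init_layer_connectivity, init_weights,
                              sparseness)


# ---------------------------------------------------------------- kernels
def test_inhibition_kernel_sums_to_one():
    for shape, sigma, delta in [((16, 16), 1.35, 1.5), ((32, 32), 6.0, 1.4),
                                ((8, 8), 1.38, 1.5)]:
        assert inhibition_kernel(shape, sigma, delta).sum() == \
            pytest.approx(1.0, abs=1e-12)


def test_uniform_activation_is_fixed_point():
    k = inhibition_kernel((16, 16), 2.7, 1.5)
    h = np.full((16, 16), 0.37)
    np.testing.assert_allclose(inhibit(h, k), h, atol=1e-12)


def test_single_active_neuron_suppresses_neighbours():
    sigma, delta = 1.38, 1.5
    k = inhibition_kernel((16, 16), sigma, delta)
    h = np.zeros((16, 16))
    h[4, 4] = 1.0
    r = inhibit(h, k)
    assert r[4, 5] == pytest.approx(-delta * np.exp(-1.0 / sigma ** 2))
    assert r[4, 4] > 0


def test_inhibit_matches_double_loop_oracle(rng):
    h = rng.random((8, 8))
    k = inhibition_kernel((8, 8), 1.38, 1.5)
    oracle = np.zeros((8, 8))
    for i in range(8):
        for j in range(8):
            oracle[i, j] = sum(k[a, b] * h[(i - a) % 8, (j - b) % 8]
                               for a in range(8) for b in range(8))
    np.testing.assert_allclose(inhibit(h, k), oracle, atol=1e-12)


# ---------------------------------------------------------------- activation
def test_activate_matches_dense_oracle(rng):
    w = rng.random((16, 5))
    aff = rng.integers(0, 20, size=(16, 5))
    x = rng.random(20)
    dense = np.zeros((16, 20))
    for i in range(16):
        for jj, j in enumerate(aff[i]):
            dense[i, j] += w[i, jj]
    np.testing.assert_allclose(activate(x, aff, w), dense @ x, atol=1e-12)


def test_activate_zero_and_one_hot(rng):
    w = rng.random((4, 3))
    aff = np.array([[0, 1, 2], [2, 3, 4], [0, 4, 5], [1, 2, 3]])
    assert (activate(np.zeros(6), aff, w) == 0).all()
    x = np.zeros(6)
    x[2] = 1.0
    h = activate(x, aff, w)
    assert h[0] == pytest.approx(w[0, 2])
    assert h[2] == 0.0


# ---------------------------------------------------------------- sigmoid
def test_sigmoid_midpoint_and_percentile(rng):
    r = rng.random(100)
    y, alpha = contrast_enhance(r, 95.0, 190.0)
    assert alpha == pytest.approx(np.percentile(r, 95))
    assert (y > 0.5).sum() == (r > alpha).sum()
    # a response exactly at threshold fires at one half
    y2, a2 = contrast_enhance(np.full(10, 0.3), 95.0, 26.0)
    assert (y2 == 0.5).all() and a2 == pytest.approx(0.3)


def test_sigmoid_sparseness_tracks_percentile(rng):
    r = rng.random(100)
    y, _ = contrast_enhance(r, 95.0, 1e4)
    a = sparseness((y > 0.5).astype(float))
    assert a == pytest.approx(0.05, abs=0.01)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(arrays(np.float64, st.integers(2, 40),
                  elements=st.floats(0.0, 1.0)))
    def test_sparseness_bounded_on_nonnegative_rates(y):
        if y.sum() == 0:
            with pytest.raises(ValueError):
                sparseness(y)
        else:
            assert 0.0 < sparseness(y) <= 1.0 + 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sigmoid_threshold_splits_at_percentile(seed):
        r = np.random.default_rng(seed).normal(size=64)
        y, alpha = contrast_enhance(r, 91.0, 26.0)
        assert ((y > 0.5) == (r > alpha)).all()
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_sparseness_reference_values():
    assert sparseness(np.array([1.0, 1.0, 0.0, 0.0])) == pytest.approx(0.5)
    assert sparseness(np.full(17, 0.3)) == pytest.approx(1.0)
    one_hot = np.zeros(100)
    one_hot[42] = 1.0
    assert sparseness(one_hot) == pytest.approx(0.01)
    with pytest.raises(ValueError):
        sparseness(np.zeros(5))


# ---------------------------------------------------------------- learning
def test_hebbian_update_properties(rng):
    w = init_weights(4, 6, rng)
    aff = np.tile(np.arange(6), (4, 1))
    x = rng.random(6)
    before = w.copy()
    hebbian_update(w, aff, np.array([0.0, 1.0, 0.0, 0.5]), x, 0.3)
    np.testing.assert_allclose(np.linalg.norm(w, axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(w[0], before[0], atol=1e-12)  # silent neuron
    assert (w >= 0).all()


def test_repeated_pairing_converges_to_input_direction(rng):
    w = init_weights(1, 8, rng)
    aff = np.arange(8)[None, :]
    x = rng.random(8)
    target = x / np.linalg.norm(x)
    prev = float(w[0] @ target)
    for _ in range(60):
        hebbian_update(w, aff, np.ones(1), x, 0.5)
        cos = float(w[0] @ target)
        assert cos >= prev - 1e-12
        prev = cos
    assert prev == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------- wiring
def test_connectivity_counts_and_init_norms(rng):
    cfg = FULL_LAYERS[3]
    aff = init_layer_connectivity(cfg, (32, 32), rng)
    assert aff.shape == (1024, 100)
    assert all(len(set(row)) == 100 for row in aff[::57])
    w = init_weights(len(aff), 100, rng)
    np.testing.assert_allclose(np.linalg.norm(w, axis=1), 1.0, atol=1e-12)


def test_connectivity_radius_against_monte_carlo_oracle(rng):
    """The implemented wiring (Gaussian σ = radius/1.49, rounded to the
    torus, duplicates redrawn) is compared with an independent
    Monte-Carlo simulation of that same stated procedure."""
    cfg = FULL_LAYERS[1]  # radius 6, 100 connections
    aff = init_layer_connectivity(cfg, (32, 32), rng)
    n_in = tot = 0
    for nn in range(0, 1024, 8):
        gi, gj = divmod(nn, 32)
        py, px = np.divmod(aff[nn], 32)
        dy = (py - gi + 16) % 32 - 16
        dx = (px - gj + 16) % 32 - 16
        n_in += int((dy ** 2 + dx ** 2 <= 36).sum())
        tot += 100
    impl_frac = n_in / tot
    oracle_rng = np.random.default_rng(7)
    hits = 0
    reps = 100
    for _ in range(reps):
        chosen = set()
        while len(chosen) < 100:
            dy, dx = oracle_rng.normal(0, 6.0 / 1.49, 2)
            p = (int(np.rint(dy)) % 32, int(np.rint(dx)) % 32)
            if p in chosen:
                continue
            chosen.add(p)
            wy = (p[0] + 16) % 32 - 16
            wx = (p[1] + 16) % 32 - 16
            hits += wy * wy + wx * wx <= 36
    assert impl_frac == pytest.approx(hits / (100 * reps), abs=0.03)


def test_radius_larger_than_source_grid_raises(rng):
    from ctvisnet.network import LayerConfig
    bad = LayerConfig((4, 4), 5, 10.0, 1.0, 1.5, 95.0, 40.0)
    with pytest.raises(ValueError):
        init_layer_connectivity(bad, (8, 8), rng)


# ---------------------------------------------------------------- forward
@pytest.fixture(scope="module")
def small_net():
    net = HierarchicalCompetitiveNetwork(SCALED_LAYERS, SCALED_BAND_COUNTS,
                                         epochs=0, random_state=0)
    return net.initialize((64, 64, 32))


def test_uniform_input_degenerate_path(small_net):
    acts = small_net.forward_pass(np.zeros((64, 64, 32)))
    assert (acts[0].h == 0).all()
    assert (acts[0].y == 0.5).all()  # documented degenerate behaviour


def test_forward_pass_composition(small_net, rng):
    code = rng.random((64, 64, 32)).astype(np.float32)
    one = small_net.forward_pass(code, up_to_layer=1)
    full = small_net.forward_pass(code)
    assert len(one) == 1 and len(full) == 4
    np.testing.assert_array_equal(one[0].y, full[0].y)


def test_firing_bounded_and_sparseness_near_target(small_net, rng):
    code = rng.random((64, 64, 32)).astype(np.float32)
    for act, cfg in zip(small_net.forward_pass(code), SCALED_LAYERS):
        assert (act.y > 0).all() and (act.y < 1).all()
        n_active = int((act.y > 0.5).sum())
        target = 256 * (100.0 - cfg.percentile) / 100.0
        assert abs(n_active - target) <= 2


def test_checkpoint_roundtrip(tmp_path, small_net, rng):
    path = tmp_path / "net.npz"
    small_net.save(path)
    loaded = HierarchicalCompetitiveNetwork.load(path)
    code = rng.random((64, 64, 32)).astype(np.float32)
    np.testing.assert_array_equal(small_net.transform(code),
                                  loaded.transform(code))
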