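import numpy as np
import pytest

import snpauth as sa
from snpauth.intensity import reference_channel_quantiles


def _frame_from_baf(baf, r=2.0):
    """Back-compute X/Y from BAF with total intensity r (the simulator's map)."""
    baf = np.asarray(baf, dtype=float)
    X = r * (1 - baf)
    Y = r * baf
    samples = [f"s{i}" for i in range(baf.shape[0])]
    markers = [f"m{j}" for j in range(baf.shape[1])]
    return sa.IntensityFrame(samples, markers, X, Y)


def test_cluster_centroids_at_observed_thetas():
    # 3 reference samples per genotype, exactly at theta 0.05 / 0.5 / 0.95
    theta = np.array([[0.05], [0.05], [0.05], [0.5], [0.5], [0.5], [0.95], [0.95], [0.95]])
    X = 2.0 * np.cos(theta * np.pi / 2) ** 2  # build X/Y with the wanted arctan ratio
    Y = X * np.tan(theta * np.pi / 2)
    frame = sa.IntensityFrame([f"s{i}" for i in range(9)], ["m0"], X, Y)
    calls = np.array([[0], [0], [0], [1], [1], [1], [2], [2], [2]], dtype=float)
    model = sa.estimate_marker_clusters(frame, calls)
    np.testing.assert_allclose(model.theta[0], [0.05, 0.5, 0.95], atol=1e-12)
    assert not model.imputed[0].any()


def test_missing_ab_cluster_imputed_at_midpoint():
    baf = np.array([[0.0], [0.0], [1.0], [1.0]])
    frame = _frame_from_baf(baf)
    calls = np.array([[0], [0], [2], [2]], dtype=float)
    model = sa.estimate_marker_clusters(frame, calls)
    assert model.theta[0, 1] == pytest.approx(0.5 * (model.theta[0, 0] + model.theta[0, 2]))
    assert model.imputed[0, 1] and not model.imputed[0, 0]


def test_centroid_median_robust_to_single_outlier():
    baf = np.full((21, 1), 0.0)
    baf[20, 0] = 0.9  # one wild reference among 20 clean AA samples
    frame = _frame_from_baf(baf)
    calls = np.zeros((21, 1))
    model = sa.estimate_marker_clusters(frame, calls)
    assert model.theta[0, 0] == pytest.approx(0.0, abs=1e-9)


def _ideal_model(n_markers=1, r=2.0):
    """Cluster model with centroids exactly at genotype BAF 0 / 0.5 / 1."""
    baf = np.array([[0.0], [0.5], [1.0]]).repeat(n_markers, axis=1)
    frame = _frame_from_baf(baf, r)
    calls = np.array([[0], [1], [2]], dtype=float).repeat(n_markers, axis=1)
    return sa.estimate_marker_clusters(frame, calls)


def test_baf_lrr_at_and_between_centroids():
    model = _ideal_model()
    # exactly at the AB centroid -> BAF 0.5, LRR 0
    out = sa.compute_baf_lrr(_frame_from_baf(np.array([[0.5]])), model)
    assert out.baf[0, 0] == pytest.approx(0.5)
    assert out.lrr[0, 0] == pytest.approx(0.0, abs=1e-12)
    # theta midway between AA and AB centroids, R as expected -> BAF 0.25, LRR 0
    t_mid = 0.5 * (model.theta[0, 0] + model.theta[0, 1])
    r_mid = 0.5 * (model.R[0, 0] + model.R[0, 1])
    tan = np.tan(t_mid * np.pi / 2)
    X = r_mid / (1 + tan)
    Y = r_mid * tan / (1 + tan)
    frame = sa.IntensityFrame(["s"], ["m0"], [[X]], [[Y]])
    out = sa.compute_baf_lrr(frame, model)
    assert out.baf[0, 0] == pytest.approx(0.25, abs=1e-9)
    assert out.lrr[0, 0] == pytest.approx(0.0, abs=1e-9)
    # doubling the observed R adds exactly one to the LRR
    frame2 = sa.IntensityFrame(["s"], ["m0"], [[2 * X]], [[2 * Y]])
    assert sa.compute_baf_lrr(frame2, model).lrr[0, 0] == pytest.approx(1.0, abs=1e-9)


def test_zero_intensity_marker_is_missing():
    model = _ideal_model()
    out = sa.compute_baf_lrr(sa.IntensityFrame(["s"], ["m0"], [[0.0]], [[0.0]]), model)
    assert np.isnan(out.baf[0, 0]) and np.isnan(out.lrr[0, 0])


def test_round_trip_exact_at_clusters_bounded_elsewhere():
    """X/Y -> theta -> BAF recovery is exact at the genotype clusters and
    within the arctan map's distortion bound (<0.05) in between."""
    model = _ideal_model()
    bafs = np.array([[0.0, 0.25, 0.4, 0.5, 0.75, 1.0]])
    frame = sa.IntensityFrame(
        [f"s{i}" for i in range(6)], ["m0"],
        2.0 * (1 - bafs.T), 2.0 * bafs.T,
    )
    out = sa.compute_baf_lrr(frame, model)
    got = out.baf[:, 0]
    np.testing.assert_allclose(got[[0, 3, 5]], [0.0, 0.5, 1.0], atol=1e-12)
    assert np.all(np.abs(got - bafs.ravel()) < 0.05)
    assert np.all(np.diff(got) > 0)  # the map stays monotone
    np.testing.assert_allclose(out.lrr[:, 0], 0.0, atol=1e-9)


def test_simulated_centroid_intensities_give_exact_baf_lrr(small_panel):
    frame = sa.simulate_intensities(small_panel, sa.NoiseSpec(seed=0).zero_noise())
    refs = list(range(len(frame.samples)))
    model = sa.estimate_marker_clusters(frame, small_panel.genotypes.calls, refs)
    out = sa.compute_baf_lrr(frame, model)
    called = np.isfinite(small_panel.genotypes.calls)
    assert np.isin(np.round(out.baf[called], 9), [0.0, 0.5, 1.0]).all()
    np.testing.assert_allclose(out.lrr[called], 0.0, atol=1e-9)


def test_tqn_identity_cap_and_idempotence(rng):
    n = 500
    ref_values = np.sort(rng.gamma(4.0, 0.5, size=2 * n))
    # a frame whose channels sit exactly on the reference quantile function
    x = np.interp(
        (np.arange(n) + 0.5) / n, (np.arange(ref_values.size) + 0.5) / ref_values.size,
        ref_values,
    )
    frame = sa.IntensityFrame(["s"], [f"m{j}" for j in range(n)],
                              x[np.newaxis, :], x[np.newaxis, :])
    out = sa.tqn_normalize(frame, ref_values)
    np.testing.assert_allclose(out.X[0], x, rtol=1e-6)

    # Y globally doubled: mapped back toward the reference, but the
    # correction is capped at a factor 1/1.5
    frame2 = sa.IntensityFrame(["s"], frame.markers, x[np.newaxis, :], (2 * x)[np.newaxis, :])
    out2 = sa.tqn_normalize(frame2, ref_values)
    ratio = out2.Y[0][x > 0] / (2 * x[x > 0])
    assert np.all(ratio >= 1 / 1.5 - 1e-9)
    assert np.any(np.isclose(ratio, 1 / 1.5))

    # rank preservation under a monotone transform
    frame3 = sa.IntensityFrame(["s"], frame.markers, (x**1.7)[np.newaxis, :], x[np.newaxis, :])
    out3 = sa.tqn_normalize(frame3, ref_values, threshold=100.0)
    assert np.array_equal(np.argsort(out3.X[0]), np.argsort(frame3.X[0]))

    # idempotence when the cap is not binding
    once = sa.tqn_normalize(frame3, ref_values, threshold=100.0)
    twice = sa.tqn_normalize(once, ref_values, threshold=100.0)
    np.testing.assert_allclose(twice.X[0], once.X[0], rtol=1e-9)


def test_reference_channel_quantiles_pools_both_channels(rng):
    frame = sa.IntensityFrame(
        ["a", "b"], ["m0", "m1"], rng.random((2, 2)), rng.random((2, 2))
    )
    q = reference_channel_quantiles(frame, [0, 1])
    assert q.size == 8 and np.all(np.diff(q) >= 0)


def test_gc_wave_adjust_removes_constructed_signal(rng):
    n = 10_000
    gc = rng.uniform(0.3, 0.6, n)
    lrr = 0.5 * (gc - gc.mean())
    adj = sa.gc_wave_adjust(lrr, gc)
    np.testing.assert_allclose(adj, 0.0, atol=1e-9)


def test_gc_wave_adjust_preserves_mean_and_ignores_independent_noise(rng):
    n = 10_000
    gc = rng.uniform(0.3, 0.6, n)
    lrr = rng.normal(0, 0.15, n)
    adj = sa.gc_wave_adjust(lrr, gc)
    assert adj.mean() == pytest.approx(lrr.mean(), abs=1e-9)
    # independent regressor: the adjustment is tiny
    assert np.abs(adj - lrr).max() < 0.01


def test_gc_wave_adjust_degenerate_inputs(rng):
    lrr = rng.normal(0, 0.1, 100)
    np.testing.assert_array_equal(sa.gc_wave_adjust(lrr, np.full(100, np.nan)), lrr)
    with pytest.warns(UserWarning):
        out = sa.gc_wave_adjust(lrr, np.full(100, 0.5))
    np.testing.assert_array_equal(out, lrr)
    with pytest.raises(ValueError):
        gc = np.full(100, np.nan)
        gc[:10] = 0.4  # only 10% annotated
        sa.gc_wave_adjust(lrr, gc)
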