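"""GFP, spatial correlation, AAHC clustering, GEV, labeling."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mstates import (
    PeakMaps,
    Recording,
    SimulationConfig,
    aahc_cluster,
    canonical_templates,
    compute_gev,
    compute_gfp,
    extract_peak_maps,
    label_maps,
    make_templates,
    simulate_recording,
    spatial_correlation,
    two_level_clustering,
)
from mstates.io import templates_to_model
from mstates.metrics import Segmentation, backfit
from mstates.model import MicrostateModel, _principal_map
from mstates.preprocess import average_reference


def test_gfp_hand_values():
    rec = Recording(np.array([[3.0, 1.0], [3.0, -1.0]]), 250.0)
    gfp = compute_gfp(rec)
    assert gfp.values[0] == pytest.approx(0.0)  # constant map -> zero spread
    assert gfp.values[1] == pytest.approx(1.0)  # (1,-1) -> sqrt(mean(1,1))


@given(a=st.floats(-50, 50, allow_nan=False))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_gfp_homogeneity(a):
    rng = np.random.default_rng(0)
    data = rng.standard_normal((8, 20))
    g1 = compute_gfp(Recording(data, 250.0)).values
    g2 = compute_gfp(Recording(a * data, 250.0)).values
    assert np.allclose(g2, abs(a) * g1, atol=1e-9)


def test_gfp_peak_separation():
    # two maxima 1 sample apart collapse to one under a 10 ms rule at 250 Hz
    v = np.zeros(50)
    v[[20, 22]] = [1.0, 0.9]
    data = np.vstack([v, -v])
    gfp = compute_gfp(Recording(data, 250.0), min_peak_separation_ms=10)
    assert list(gfp.peak_indices) == [20]


def test_spatial_correlation_hand_values():
    m = np.array([1.0, -1.0, 0.0])
    assert spatial_correlation(m, m) == pytest.approx(1.0)
    assert spatial_correlation(m, -m) == pytest.approx(-1.0)
    assert spatial_correlation(m, -m, polarity_invariant=True) == pytest.approx(1.0)
    other = np.array([0.0, 1.0, -1.0])
    assert spatial_correlation(m, other) == pytest.approx(-0.5)
    assert spatial_correlation(m, other, polarity_invariant=True) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        spatial_correlation(m, np.array([2.0, 2.0, 2.0]))
    with pytest.raises(ValueError):
        spatial_correlation(m, np.array([1.0, 2.0]))


def test_extract_peak_maps_counts_and_polarity(small_sim):
    rec = average_reference(small_sim.recording)
    gfp = compute_gfp(rec)
    pm = extract_peak_maps(rec, gfp)
    assert pm.n_maps == gfp.peak_indices.size
    assert np.allclose(np.linalg.norm(pm.maps, axis=1), 1.0)
    assert np.abs(pm.maps.mean(axis=1)).max() < 1e-10
    neg = rec.copy_with(data=-rec.data)
    pm2 = extract_peak_maps(neg, compute_gfp(neg))
    assert np.allclose(np.abs(pm.maps), np.abs(pm2.maps))


def test_noiseless_peak_maps_match_templates(noiseless_sim):
    rec = noiseless_sim.recording
    gfp = compute_gfp(rec)
    pm = extract_peak_maps(rec, gfp)
    truth = noiseless_sim.truth_model.maps
    best = np.abs(pm.maps @ truth.T).max(axis=1)
    assert best.min() > 1 - 1e-9


def _random_peak_maps(n, c, seed, weights=None):
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((n, c))
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    w = np.ones(n) if weights is None else weights
    return PeakMaps(maps=maps, weights=w, peak_indices=np.arange(n))


def test_aahc_k_equals_n_is_perfect_fit():
    pm = _random_peak_maps(6, 10, seed=3)
    model, assign = aahc_cluster(pm, 6)
    assert model.gev == pytest.approx(1.0)
    assert sorted(assign) == list(range(6))


def test_aahc_two_orthogonal_templates_with_sign_flips():
    """40 noiseless copies (half sign-flipped) of 2 orthogonal maps -> the
    two centroids match the templates with |corr| = 1."""
    ts = make_templates(12, 2, seed=5)
    maps = np.repeat(ts.maps, 20, axis=0)
    signs = np.resize([1.0, -1.0], 40)
    pm = PeakMaps(maps=maps * signs[:, None], weights=np.ones(40),
                  peak_indices=np.arange(40))
    model, assign = aahc_cluster(pm, 2)
    corr = np.abs(model.maps @ ts.maps.T)
    assert np.allclose(corr.max(axis=1), 1.0, atol=1e-9)
    # the two template populations land in different clusters
    assert len({tuple(assign[:20]), tuple(assign[20:])}) == 2


def test_aahc_sign_flip_invariance():
    pm = _random_peak_maps(30, 8, seed=9)
    model1, assign1 = aahc_cluster(pm, 3)
    flipped = pm.maps.copy()
    flipped[::2] *= -1.0
    pm2 = PeakMaps(maps=flipped, weights=pm.weights,
                   peak_indices=pm.peak_indices)
    model2, assign2 = aahc_cluster(pm2, 3)
    assert np.array_equal(assign1, assign2)
    assert np.allclose(np.abs(model1.maps), np.abs(model2.maps))


def _exhaustive_best_gev(maps, w, k=2):
    """Oracle: best k=2 partition by brute force over all bipartitions."""
    n = maps.shape[0]
    best = -1.0
    for bits in range(1, 2 ** (n - 1)):
        part = [[], []]
        for i in range(n):
            part[(bits >> i) & 1].append(i)
        if not part[0] or not part[1]:
            continue
        tot = 0.0
        for members in part:
            m = maps[members]
            v = _principal_map(m)
            tot += float(w[members] @ (m @ v) ** 2)
        best = max(best, tot / w.sum())
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_aahc_near_optimal_on_tiny_instances(seed):
    """Greedy AAHC reaches within 5% of the exhaustive-search optimum at
    n <= 8 maps, K = 2 (it is a greedy method, not guaranteed exact)."""
    pm = _random_peak_maps(8, 6, seed=seed)
    model, _ = aahc_cluster(pm, 2)
    best = _exhaustive_best_gev(pm.maps, pm.weights)
    assert model.gev <= best + 1e-9
    assert model.gev >= 0.95 * best


def test_gev_noiseless_truth_is_one(noiseless_sim):
    rec = noiseless_sim.recording
    seg = Segmentation(noiseless_sim.truth_labels, rec.sampling_rate_hz,
                       list(noiseless_sim.truth_model.class_labels))
    gev = compute_gev(rec, templates_to_model(noiseless_sim.truth_model), seg)
    assert gev == pytest.approx(1.0, abs=1e-9)


def test_gev_null_on_white_noise():
    rng = np.random.default_rng(11)
    rec = Recording(rng.standard_normal((64, 2000)), 250.0)
    model = templates_to_model(make_templates(64, 4, seed=1))
    labels = rng.integers(0, 4, size=2000)
    seg = Segmentation(labels, 250.0, ["A", "B", "C", "D"])
    gev = compute_gev(rec, model, seg)
    assert gev < 0.2  # ~ E[r^2] of random 64-channel maps


def test_gev_monotone_in_k(small_prepped):
    gfp = compute_gfp(small_prepped)
    pm = extract_peak_maps(small_prepped, gfp)
    gevs = []
    for k in range(2, 9):
        model, _ = aahc_cluster(pm, k)
        seg = backfit(small_prepped, gfp, model)
        gevs.append(compute_gev(small_prepped, model, seg))
    assert np.all(np.diff(gevs) >= -1e-6)


def test_two_level_single_subject_equals_subject_model(small_prepped):
    gfp = compute_gfp(small_prepped)
    pm = extract_peak_maps(small_prepped, gfp)
    subject, _ = aahc_cluster(pm, 4)
    group = two_level_clustering([pm], 4)
    corr = np.abs(group.maps @ subject.maps.T)
    assert np.allclose(corr.max(axis=1), 1.0, atol=1e-6)


def test_two_level_subject_order_invariance():
    cfgs = [SimulationConfig(n_channels=16, sampling_rate_hz=250,
                             duration_s=15, snr=4.0, seed=s)
            for s in (31, 32, 33)]
    ts = make_templates(16, 4, seed=40)
    pms = []
    for cfg in cfgs:
        sim = simulate_recording(cfg, templates=ts)
        rec = average_reference(sim.recording)
        pms.append(extract_peak_maps(rec, compute_gfp(rec)))
    g1 = two_level_clustering(pms, 4)
    g2 = two_level_clustering(pms[::-1], 4)
    corr = np.abs(g1.maps @ g2.maps.T)
    assert np.allclose(corr.max(axis=1), 1.0, atol=1e-6)


def test_two_level_skips_short_subjects():
    pm_ok = _random_peak_maps(30, 8, seed=1)
    pm_short = _random_peak_maps(2, 8, seed=2)
    with pytest.warns(UserWarning, match="skipped"):
        model = two_level_clustering([pm_ok, pm_short], 4)
    assert model.n_classes == 4
    with pytest.raises(ValueError):
        two_level_clustering([pm_short], 4)


def test_label_maps_recovers_shuffle_and_sign():
    canon = canonical_templates(n_channels=32)
    perm = [2, 0, 3, 1]
    signs = np.array([1.0, -1.0, -1.0, 1.0])
    model = MicrostateModel(
        maps=canon.maps[perm] * signs[:, None],
        class_labels=["1", "2", "3", "4"],
        gev=0.8,
    )
    labeled = label_maps(model, canon)
    assert labeled.class_labels == ["A", "B", "C", "D"]
    for i in range(4):
        assert spatial_correlation(labeled.maps[i], canon.maps[i]) == \
            pytest.approx(1.0, abs=1e-9)


def test_label_maps_beats_all_permutations(small_prepped):
    canon = canonical_templates(n_channels=32)
    gfp = compute_gfp(small_prepped)
    model, _ = aahc_cluster(extract_peak_maps(small_prepped, gfp), 4)
    labeled = label_maps(model, canon)
    achieved = sum(
        abs(spatial_correlation(labeled.maps[i], canon.maps[i]))
        for i in range(4)
    )
    for perm in itertools.permutations(range(4)):
        alt = sum(
            abs(spatial_correlation(model.maps[perm[i]], canon.maps[i]))
            for i in range(4)
        )
        assert achieved >= alt - 1e-9


def test_label_maps_k_mismatch_errors():
    canon = canonical_templates(n_channels=16)
    model = templates_to_model(make_templates(16, 5, seed=0))
    with pytest.raises(ValueError):
        label_maps(model, canon)


def test_canonical_templates_are_distinguishable():
    ts = canonical_templates(n_channels=64)
    ts.validate()  # centered, unit norm, pairwise |corr| < 0.95
    assert ts.class_labels == ["A", "B", "C", "D"]
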