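"""Trajectory metrics against constructed and brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.special import gammaln

from cephalosleep.datatypes import PatternTrajectory
from cephalosleep.patterns import (
    align_start, default_featurizer, distance_summary, dtw_distance, dtw_ratio,
    inter_distance, intra_distance, nearest_distances, parallel_analysis,
    pca_project, silhouette_by_animal, wake_in_as_test,
)


# --------------------------------------------------------------------------- #
# featurizer

def test_featurizer_uniform_image_is_zero():
    img = np.full((96, 96), 127, dtype=np.uint8)
    f = default_featurizer(img)
    assert f.shape == (512,)
    assert np.allclose(f, 0.0, atol=1e-9)


def test_featurizer_deterministic():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, (96, 96)).astype(np.uint8)
    assert np.array_equal(default_featurizer(img), default_featurizer(img.copy()))


def test_featurizer_separates_patterns_from_renoised_copies():
    """Across layouts the feature distance is >5x the re-noised within-layout one."""
    from cephalosleep.simulate import PatternImageConfig, gen_mantle_texture

    cfg = PatternImageConfig(size=(128, 128))
    inter, intra = [], []
    for seed in range(10):
        a1 = default_featurizer(gen_mantle_texture(cfg, seed=seed, noise_seed=0))
        a2 = default_featurizer(gen_mantle_texture(cfg, seed=seed, noise_seed=1))
        b = default_featurizer(gen_mantle_texture(cfg, seed=seed + 100, noise_seed=0))
        intra.append(np.linalg.norm(a1 - a2))
        inter.append(np.linalg.norm(a1 - b))
    assert np.mean(inter) > 5 * np.mean(intra)


def test_featurizer_nonfinite_raises():
    img = np.full((64, 64), np.nan)
    with pytest.raises(ValueError):
        default_featurizer(img)


# --------------------------------------------------------------------------- #
# start alignment

def test_align_start_finds_motion_onset():
    rng = np.random.default_rng(1)
    D = 16
    still = np.tile(rng.normal(0, 1, D), (60, 1))
    direction = rng.normal(0, 1, D)
    moving = still[0] + np.outer(np.linspace(0, 5, 20), direction)
    X = np.vstack([still, moving]) + rng.normal(0, 1e-4, (80, D))
    start = align_start(PatternTrajectory(X, fps=30.0))
    assert abs(start - 60) <= 1


def test_align_start_constant_trajectory_signals_no_start():
    X = np.ones((50, 8))
    assert align_start(PatternTrajectory(X, fps=30.0)) is None


def test_align_start_default_threshold():
    import inspect

    assert inspect.signature(align_start).parameters["threshold"].default == 0.1


# --------------------------------------------------------------------------- #
# distances

def test_intra_distance_constant_and_staircase():
    assert intra_distance(np.ones((10, 4))) == 0.0
    stair = np.zeros((7, 3))
    stair[:, 0] = np.arange(7)
    assert intra_distance(stair) == pytest.approx(1.0)


def test_intra_distance_random_walk_chi_mean():
    """Steps ~ N(0, s^2 I_D): mean step length = s*sqrt(2)*G((D+1)/2)/G(D/2)."""
    rng = np.random.default_rng(2)
    D, s, T = 24, 0.7, 20000
    X = np.cumsum(rng.normal(0, s, (T, D)), axis=0)
    expected = s * np.sqrt(2) * np.exp(gammaln((D + 1) / 2) - gammaln(D / 2))
    steps = np.linalg.norm(np.diff(X, axis=0), axis=1)
    sem = steps.std() / np.sqrt(steps.size)
    assert abs(intra_distance(X) - expected) < 3 * sem


def test_inter_distance_offset_and_truncation():
    a = np.zeros((100, 3))
    b = np.full((60, 3), 2.0)
    assert inter_distance(a, a) == 0.0
    assert inter_distance(a, b) == pytest.approx(2.0 * np.sqrt(3))
    # averaged over exactly the shorter length
    b2 = np.vstack([b, np.full((40, 3), 1000.0)])
    assert inter_distance(a[:60], b2[:60]) == inter_distance(a, b)


# --------------------------------------------------------------------------- #
# DTW

def _brute_force_dtw_total(A, B):
    """Minimum total cost over all monotone warping paths (exhaustive)."""
    cost = cdist(A, B)
    Ta, Tb = cost.shape
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + cost[i, j]
        if acc >= best[0]:
            return
        if i == Ta - 1 and j == Tb - 1:
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < Ta and j + dj < Tb:
                walk(i + di, j + dj, acc)

    walk(0, 0, 0.0)
    return best[0]


def test_dtw_equals_exhaustive_enumeration_on_small_instances():
    rng = np.random.default_rng(3)
    for _ in range(100):
        Ta, Tb = rng.integers(2, 7, 2)
        D = rng.integers(1, 4)
        A = rng.normal(0, 1, (Ta, D))
        B = rng.normal(0, 1, (Tb, D))
        mean_cost, path = dtw_distance(A, B)
        total = mean_cost * len(path)
        assert total == pytest.approx(_brute_force_dtw_total(A, B), abs=1e-9)


def test_dtw_identical_trajectories():
    rng = np.random.default_rng(4)
    A = rng.normal(0, 1, (30, 5))
    mean_cost, _ = dtw_distance(A, A)
    assert mean_cost == pytest.approx(0.0, abs=1e-12)
    assert dtw_ratio(A, A) == 0.0


def test_dtw_time_stretch_recovered():
    """b = a stretched 2x: warping matches, so the ratio is far below 1."""
    t = np.linspace(0, 2 * np.pi, 50)
    a = np.column_stack([np.cos(t), np.sin(2 * t)])
    b = np.repeat(a, 2, axis=0)
    assert dtw_ratio(a, b) < 0.1


def test_dtw_mean_cost_not_above_zero_lag_for_equal_lengths():
    rng = np.random.default_rng(5)
    for _ in range(20):
        A = rng.normal(0, 1, (25, 4))
        B = rng.normal(0, 1, (25, 4))
        mean_cost, _ = dtw_distance(A, B)
        assert mean_cost <= inter_distance(A, B) + 1e-12


def test_dtw_degenerate_raises():
    with pytest.raises(ValueError):
        dtw_distance(np.ones((1, 3)), np.ones((5, 3)))


# --------------------------------------------------------------------------- #
# nearest distances

def test_nearest_distances_hand_case_and_containment():
    a = np.array([[0.0, 0.0]])
    b = np.array([[3.0, 4.0], [6.0, 8.0]])
    assert nearest_distances(a, b)[0] == pytest.approx(5.0)
    rng = np.random.default_rng(6)
    A = rng.normal(0, 1, (20, 3))
    B = np.vstack([rng.normal(0, 1, (10, 3)), A])
    assert np.allclose(nearest_distances(A, B), 0.0, atol=1e-7)


def test_nearest_distances_matches_double_loop_oracle():
    rng = np.random.default_rng(7)
    A = rng.normal(0, 1, (40, 6))
    B = rng.normal(0, 1, (30, 6))
    brute = np.array([min(np.linalg.norm(x - y) for y in B) for x in A])
    assert np.allclose(nearest_distances(A, B), brute, atol=1e-9)


def test_nearest_minima_bounded_by_zero_lag_mean():
    rng = np.random.default_rng(8)
    A = rng.normal(0, 1, (30, 4))
    B = rng.normal(0, 1, (30, 4))
    assert nearest_distances(A, B).mean() <= inter_distance(A, B) + 1e-12


# --------------------------------------------------------------------------- #
# parallel analysis

def test_parallel_analysis_recovers_known_rank():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        latent = rng.normal(0, 1, (10000, 5))
        mix = rng.normal(0, 1, (5, 50))
        X = latent @ mix + rng.normal(0, 0.01 * np.abs(latent @ mix).mean(),
                                      (10000, 50))
        est = parallel_analysis(X, n_sample=10000, seed=seed)
        hits += abs(est - 5) <= 1
    assert hits >= 9


def test_parallel_analysis_iid_noise_at_most_one():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(0, 1, (2000, 50))
        hits += parallel_analysis(X, seed=seed) <= 1
    assert hits >= 9


def test_parallel_analysis_needs_two_columns():
    with pytest.raises(ValueError):
        parallel_analysis(np.ones((100, 1)))


def test_parallel_analysis_subsample_seed_stable():
    """Resampling variability over subsample seeds is small at fixed data."""
    rng = np.random.default_rng(9)
    latent = rng.normal(0, 1, (30000, 8))
    mix = rng.normal(0, 1, (8, 40))
    X = latent @ mix + rng.normal(0, 0.05, (30000, 40))
    ests = [parallel_analysis(X, n_sample=5000, seed=s) for s in range(10)]
    assert np.std(ests) <= 0.05 * max(np.mean(ests), 1)


# --------------------------------------------------------------------------- #
# silhouette and wake placement

def test_silhouette_separated_and_overlapping():
    rng = np.random.default_rng(10)
    far = np.vstack([rng.normal(0, 0.1, (300, 8)), rng.normal(50, 0.1, (300, 8))])
    labels = np.repeat(["a", "b"], 300)
    assert silhouette_by_animal(far, labels) > 0.9
    same = np.vstack([rng.normal(0, 1, (500, 8)), rng.normal(0, 1, (500, 8))])
    labels2 = np.repeat(["a", "b"], 500)
    assert abs(silhouette_by_animal(same, labels2, seed=1)) < 0.02


def test_silhouette_requires_two_animals():
    with pytest.raises(ValueError):
        silhouette_by_animal(np.ones((10, 2)), ["a"] * 10)


def test_wake_in_as_trivial_cases():
    rng = np.random.default_rng(11)
    trajs = [PatternTrajectory(np.cumsum(rng.normal(0, 0.5, (100, 6)), axis=0),
                               fps=30.0) for _ in range(3)]
    copied = trajs[0].features[10][None, :]
    rep = wake_in_as_test(copied, trajs)
    assert rep.nearest[0] == pytest.approx(0.0)
    assert rep.within[0]
    outlier = np.full((1, 6), 1e4)
    rep2 = wake_in_as_test(outlier, trajs)
    assert not rep2.within[0]
    with pytest.raises(ValueError):
        wake_in_as_test(np.zeros((0, 6)), trajs)


def test_wake_samples_from_library_fall_within_as_space():
    from cephalosleep.simulate import (PatternSimConfig, gen_pattern_trajectories,
                                       sample_wake_patterns)

    fractions = []
    for seed in range(20):
        cfg = PatternSimConfig(n_animals=2, n_bouts_per_animal=3, dims=64,
                               latent_rank=10, library_size=16, n_visits=12,
                               dwell_frames=12, transition_frames=5, seed=seed)
        trajs, lib, _ = gen_pattern_trajectories(cfg)
        W = sample_wake_patterns(lib, 25, seed=seed, jitter_sd=0.05)
        fractions.append(wake_in_as_test(W, trajs).fraction_within)
    assert np.mean(fractions) >= 0.9


# --------------------------------------------------------------------------- #
# PCA projection

def test_pca_projection_preserves_planar_distances():
    rng = np.random.default_rng(12)
    coords2 = rng.normal(0, 1, (80, 2))
    basis = np.linalg.qr(rng.normal(0, 1, (10, 2)))[0]
    X = coords2 @ basis.T
    projs, evr = pca_project([PatternTrajectory(X, fps=30.0)])
    d_orig = cdist(X, X)
    d_proj = cdist(projs[0], projs[0])
    assert np.allclose(d_orig, d_proj, atol=1e-6 * d_orig.max())
    assert evr[0] >= evr[1]


def test_pca_projection_centres_data():
    rng = np.random.default_rng(13)
    X = rng.normal(5, 1, (200, 6))
    projs, _ = pca_project([PatternTrajectory(X, fps=30.0)])
    assert np.allclose(projs[0].mean(axis=0), 0.0, atol=1e-9)


def test_pca_zero_variance_raises():
    with pytest.raises(ValueError):
        pca_project([PatternTrajectory(np.ones((10, 4)), fps=30.0)])


# --------------------------------------------------------------------------- #
# summary ordering

def test_distance_summary_symmetry_and_selfconsistency():
    rng = np.random.default_rng(14)
    trajs = [PatternTrajectory(np.cumsum(rng.normal(0, 0.5, (60, 5)), axis=0),
                               fps=30.0) for _ in range(3)]
    summ = distance_summary(trajs, compute_dtw=True)
    assert summ.intra.shape == (3,)
    assert summ.inter_zero_lag.shape == (3,)
    assert np.all(summ.nearest <= summ.inter_zero_lag + 1e-12)
    assert np.all(summ.dtw_ratio >= 0)
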