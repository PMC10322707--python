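"""Skin-pattern trajectory statistics in feature space.

Each active-sleep (AS) bout is a trajectory of per-frame pattern feature
vectors (T frames x D dims).  This module provides start alignment, the
three distance statistics of trajectory comparison (intra-trajectory step
distance, zero-lag inter-trajectory distance, nearest-point distance),
dynamic time warping, dimensionality estimation by parallel analysis,
animal-overlap scoring by silhouette, placement of waking patterns in AS
space, and 2-D principal-component projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import PatternTrajectory

__all__ = [
    "FilterBankFeaturizer",
    "default_featurizer",
    "align_start",
    "intra_distance",
    "inter_distance",
    "dtw_distance",
    "dtw_ratio",
    "nearest_distances",
    "DistanceSummary",
    "distance_summary",
    "parallel_analysis",
    "silhouette_by_animal",
    "wake_in_as_test",
    "pca_project",
]


def _features(x) -> np.ndarray:
    if isinstance(x, PatternTrajectory):
        return x.features
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite feature values")
    return arr


# --------------------------------------------------------------------------- #
# featurization

class FilterBankFeaturizer:
    """Deterministic multi-scale oriented filter-bank featurizer (D = 512).

    A stand-in for learned convolutional features: the image is zero-centred
    and convolved with a Gabor bank (4 spatial frequencies x 8 orientations);
    response magnitudes are mean-pooled over a 4 x 4 spatial grid and
    concatenated (4*8*16 = 512 dims).  A uniform image maps to the zero
    vector, and identical images map to bit-identical vectors.
    """

    name = "gabor-bank-512"
    dim = 512

    _frequencies = (0.05, 0.1, 0.2, 0.35)
    _n_orientations = 8
    _grid = 4

    def __init__(self):
        from skimage.filters import gabor_kernel

        self._kernels = [
            gabor_kernel(f, theta=np.pi * k / self._n_orientations)
            for f in self._frequencies
            for k in range(self._n_orientations)
        ]

    def transform(self, image: np.ndarray) -> np.ndarray:
        from scipy.signal import fftconvolve

        img = np.asarray(image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        if not np.all(np.isfinite(img)):
            raise ValueError("image contains non-finite pixels")
        img = img - img.mean()
        h, w = img.shape
        gy = np.linspace(0, h, self._grid + 1).astype(int)
        gx = np.linspace(0, w, self._grid + 1).astype(int)
        feats = np.empty(self.dim)
        i = 0
        for ker in self._kernels:
            mag = np.abs(fftconvolve(img, ker, mode="same"))
            for r in range(self._grid):
                for c in range(self._grid):
                    feats[i] = mag[gy[r]:gy[r + 1], gx[c]:gx[c + 1]].mean()
                    i += 1
        return feats


_default = None


def default_featurizer(image: np.ndarray) -> np.ndarray:
    """Featurize one image with the shared filter-bank featurizer."""
    global _default
    if _default is None:
        _default = FilterBankFeaturizer()
    return _default.transform(image)


# --------------------------------------------------------------------------- #
# start alignment

def align_start(traj, threshold: float = 0.1) -> int | None:
    """Start frame of pattern motion, from the first principal component.

    The PC1 score per frame is computed on the trajectory's own feature
    matrix and standardised to unit SD; the start is the first frame where
    the absolute score difference between neighbouring frames exceeds
    ``threshold``.  Returns None when the threshold is never exceeded
    (distinct from index 0).
    """
    X = _features(traj)
    if X.shape[0] < 3:
        raise ValueError("need at least three frames")
    Xc = X - X.mean(axis=0)
    # leading right singular vector -> PC1 scores
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    score = u[:, 0] * s[0]
    sd = score.std()
    if sd > 0:
        score = score / sd
    d = np.abs(np.diff(score))
    idx = np.flatnonzero(d > threshold)
    return int(idx[0]) if idx.size else None


# --------------------------------------------------------------------------- #
# distances

def intra_distance(traj) -> float:
    """Mean Euclidean distance between neighbouring frames along a trajectory."""
    X = _features(traj)
    return float(np.linalg.norm(np.diff(X, axis=0), axis=1).mean())


def inter_distance(a, b) -> float:
    """Mean element-wise distance at zero lag, up to the shorter trajectory."""
    A, B = _features(a), _features(b)
    t = min(A.shape[0], B.shape[0])
    return float(np.linalg.norm(A[:t] - B[:t], axis=1).mean())


def dtw_distance(a, b) -> tuple[float, list[tuple[int, int]]]:
    """Dynamic time warping with Euclidean local cost.

    Full dynamic program, symmetric step pattern (diagonal / horizontal /
    vertical moves with unit weight), no window constraint.  Returns the
    *mean* cost along the optimal alignment path and the path itself.
    """
    A, B = _features(a), _features(b)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("DTW needs at least two frames per trajectory")
    cost = cdist(A, B)
    Ta, Tb = cost.shape
    D = np.full((Ta + 1, Tb + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, Ta + 1):
        row = cost[i - 1]
        for j in range(1, Tb + 1):
            D[i, j] = row[j - 1] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    # backtrack
    path = [(Ta - 1, Tb - 1)]
    i, j = Ta, Tb
    while (i, j) != (1, 1):
        moves = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        i, j = min((m for m in moves if m[0] >= 1 and m[1] >= 1), key=lambda m: D[m])
        path.append((i - 1, j - 1))
    path.reverse()
    return float(D[Ta, Tb] / len(path)), path


def dtw_ratio(a, b, divisor: str = "inter") -> float:
    """DTW mean path cost divided by a trajectory distance.

    ``divisor='inter'`` (default) normalises by the zero-lag inter-trajectory
    distance, making the ratio comparable with non-warped distances;
    ``divisor='path'`` normalises by the mean cumulative step length of the
    two trajectories instead.
    """
    mean_cost, _ = dtw_distance(a, b)
    if divisor == "inter":
        denom = inter_distance(a, b)
    elif divisor == "path":
        A, B = _features(a), _features(b)
        denom = 0.5 * (np.linalg.norm(np.diff(A, axis=0), axis=1).sum()
                       + np.linalg.norm(np.diff(B, axis=0), axis=1).sum())
    else:
        raise ValueError("divisor must be 'inter' or 'path'")
    if denom == 0:
        return 0.0 if mean_cost == 0 else np.inf
    return float(mean_cost / denom)


def nearest_distances(a, b, chunk: int = 2048) -> np.ndarray:
    """For each frame of ``a``, the minimum distance to any frame of ``b``.

    Computed blockwise from the squared-distance expansion
    ``|x - y|^2 = |x|^2 + |y|^2 - 2 x.y`` (BLAS-backed).
    """
    A, B = _features(a), _features(b)
    b2 = np.einsum("ij,ij->i", B, B)
    out = np.empty(A.shape[0])
    for i in range(0, A.shape[0], chunk):
        Ai = A[i:i + chunk]
        d2 = (np.einsum("ij,ij->i", Ai, Ai)[:, None] + b2[None, :]
              - 2.0 * (Ai @ B.T))
        out[i:i + chunk] = np.sqrt(np.maximum(d2.min(axis=1), 0.0))
    return out


@dataclass
class DistanceSummary:
    """Per-bout / per-pair distance statistics of a set of trajectories."""

    intra: np.ndarray        # mean consecutive-frame distance, per trajectory
    inter_zero_lag: np.ndarray   # zero-lag mean distance, per pair
    nearest: np.ndarray      # mean nearest-point distance, per pair
    dtw_ratio: np.ndarray    # DTW mean cost / zero-lag distance, per pair

    @property
    def inter_intra_ratio(self) -> float:
        return float(self.inter_zero_lag.mean() / self.intra.mean())


def distance_summary(trajectories: Sequence, compute_dtw: bool = False) -> DistanceSummary:
    """All pairwise trajectory distance statistics, averaged per bout pair."""
    trajs = list(trajectories)
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories")
    intra = np.array([intra_distance(t) for t in trajs])
    inter, near, ratios = [], [], []
    for i in range(len(trajs)):
        for j in range(i + 1, len(trajs)):
            inter.append(inter_distance(trajs[i], trajs[j]))
            near.append(nearest_distances(trajs[i], trajs[j]).mean())
            if compute_dtw:
                ratios.append(dtw_ratio(trajs[i], trajs[j]))
    return DistanceSummary(intra, np.array(inter), np.array(near), np.array(ratios))


# --------------------------------------------------------------------------- #
# dimensionality and overlap

def parallel_analysis(
    X: np.ndarray,
    n_sample: int = 10000,
    n_surrogates: int = 20,
    percentile: float = 95.0,
    seed: int = 0,
    criterion: str = "percentile",
) -> int:
    """Dimensionality estimate by parallel analysis.

    Counts eigenvalues of the sample correlation matrix exceeding the
    ``percentile`` of rank-matched eigenvalues from column-wise independently
    permuted surrogates (which preserve the marginals).  ``criterion='mean'``
    uses Horn's original mean-eigenvalue cutoff instead.  Rows are
    subsampled without replacement to ``n_sample`` when more are available.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least two feature columns")
    rng = np.random.default_rng(seed)
    if X.shape[0] > n_sample:
        X = X[rng.choice(X.shape[0], n_sample, replace=False)]
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    n = Z.shape[0]
    ev = np.linalg.eigvalsh(Z.T @ Z / n)[::-1]
    sur = np.empty((n_surrogates, ev.size))
    for s in range(n_surrogates):
        P = rng.permuted(Z, axis=0)
        P = (P - P.mean(axis=0)) / P.std(axis=0)
        sur[s] = np.linalg.eigvalsh(P.T @ P / n)[::-1]
    if criterion == "percentile":
        cutoff = np.percentile(sur, percentile, axis=0)
    elif criterion == "mean":
        cutoff = sur.mean(axis=0)
    else:
        raise ValueError("criterion must be 'percentile' or 'mean'")
    above = ev > cutoff
    # retained components must be consecutive from the top
    n_comp = int(np.argmin(above)) if not above.all() else int(above.size)
    return n_comp


def silhouette_by_animal(
    X: np.ndarray,
    animal_labels: Sequence,
    n_sample: int = 10000,
    seed: int = 0,
) -> float:
    """Silhouette coefficient (Euclidean) of frames labelled by animal.

    Near zero when animals' patterns overlap; near one when each animal
    occupies its own region of pattern space.  Points are subsampled without
    replacement; labels left with a single point are skipped.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(animal_labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two animals")
    rng = np.random.default_rng(seed)
    if X.shape[0] > n_sample:
        idx = rng.choice(X.shape[0], n_sample, replace=False)
        X, labels = X[idx], labels[idx]
    uniq, counts = np.unique(labels, return_counts=True)
    ok = np.isin(labels, uniq[counts > 1])
    return float(silhouette_score(X[ok], labels[ok]))


class WakePlacement(NamedTuple):
    nearest: np.ndarray        # per wake vector, distance to nearest AS frame
    intra_quantile: float      # the within-space distance criterion
    within: np.ndarray         # per wake vector, nearest <= criterion
    fraction_within: float
    median_nearest: float


def wake_in_as_test(
    wake_vectors: np.ndarray,
    as_trajectories: Sequence,
    quantile: float = 0.95,
) -> WakePlacement:
    """Do waking patterns fall within the space of AS patterns?

    For each wake feature vector the nearest distance to any AS frame is
    compared against the ``quantile`` of the pooled intra-trajectory
    (consecutive-frame) distance distribution: a wake pattern "within" AS
    space is no further from it than typical within-trajectory steps.
    """
    W = np.atleast_2d(np.asarray(wake_vectors, dtype=float))
    trajs = list(as_trajectories)
    if W.size == 0 or not trajs:
        raise ValueError("empty inputs")
    pooled = np.vstack([_features(t) for t in trajs])
    steps = np.concatenate(
        [np.linalg.norm(np.diff(_features(t), axis=0), axis=1) for t in trajs]
    )
    crit = float(np.quantile(steps, quantile))
    near = nearest_distances(W, pooled)
    within = near <= crit
    return WakePlacement(near, crit, within, float(within.mean()), float(np.median(near)))


def pca_project(trajectories: Sequence) -> tuple[list[np.ndarray], np.ndarray]:
    """Project trajectories onto the first two PCs of pooled AS pattern space.

    Returns per-trajectory (T, 2) coordinates and the explained variance
    ratio of the two components.
    """
    trajs = list(trajectories)
    pooled = np.vstack([_features(t) for t in trajs])
    if pooled.shape[0] < 3:
        raise ValueError("need at least three pooled frames")
    if np.allclose(pooled.std(axis=0), 0):
        raise ValueError("zero-variance data")
    pca = PCA(n_components=2).fit(pooled)
    return [pca.transform(_features(t)) for t in trajs], pca.explained_variance_ratio_
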