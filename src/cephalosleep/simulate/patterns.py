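"""Synthetic skin-pattern trajectories through a shared pattern library.

The generator emulates the structure inferred from active-sleep (AS)
patterning: a library of macroscopic patterns lying in a ~60-dimensional
latent subspace of the 512-dimensional feature space, shared across animals;
each AS bout is a smoothed itinerary through a random subset of library
patterns in randomised order, starting and ending at the designated "white"
resting pattern.  Animal identity adds a small constant offset; per-frame
jitter and a small full-dimensional observation noise complete the model.

The library's latent coordinates are whitened so the latent subspace is
sampled isotropically — this makes the latent rank a well-defined recovery
target for parallel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..datatypes import PatternTrajectory, SyntheticTruth

__all__ = ["PatternSimConfig", "PatternLibrary", "gen_pattern_trajectories",
           "sample_wake_patterns"]


@dataclass
class PatternSimConfig:
    n_animals: int = 3
    n_bouts_per_animal: int = 8
    dims: int = 512
    #: number of shared macroscopic patterns in the library
    library_size: int = 80
    #: true dimensionality of the pattern space
    latent_rank: int = 60
    #: per-frame jitter SD in latent units
    step_sd: float = 0.1
    #: per-animal constant offset SD in latent units
    animal_offset_sd: float = 0.15
    #: mean frames spent at each visited pattern
    dwell_frames: int = 45
    #: frames per transition between patterns
    transition_frames: int = 12
    #: patterns visited per bout (excluding the white start/end)
    n_visits: int = 25
    #: small isotropic observation noise in the full feature space
    obs_noise_sd: float = 0.02
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.library_size < 2:
            raise ValueError("library_size must be at least 2")
        if self.latent_rank > self.dims:
            raise ValueError("latent_rank must not exceed dims")
        if self.library_size <= self.latent_rank:
            raise ValueError("library_size must exceed latent_rank (whitening)")


@dataclass
class PatternLibrary:
    """Shared pattern library: latent coordinates and their embedding."""

    latent: np.ndarray     # (library_size, latent_rank), whitened
    basis: np.ndarray      # (dims, latent_rank), orthonormal
    white_index: int = 0

    @property
    def features(self) -> np.ndarray:
        return self.latent @ self.basis.T

    def embed(self, latent_points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(latent_points) @ self.basis.T


def _whiten(Z: np.ndarray) -> np.ndarray:
    Zc = Z - Z.mean(axis=0)
    cov = Zc.T @ Zc / Zc.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    W = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    return Zc @ W


def _make_library(cfg: PatternSimConfig, rng: np.random.Generator) -> PatternLibrary:
    Z = _whiten(rng.standard_normal((cfg.library_size, cfg.latent_rank)))
    Q, _ = np.linalg.qr(rng.standard_normal((cfg.dims, cfg.latent_rank)))
    return PatternLibrary(latent=Z, basis=Q)


def _bout_latent_path(cfg: PatternSimConfig, rng: np.random.Generator,
                      lib: PatternLibrary) -> tuple[np.ndarray, np.ndarray]:
    """Latent path of one bout plus the visited-pattern index sequence."""
    others = np.arange(cfg.library_size) != lib.white_index
    pool = np.flatnonzero(others)
    k = min(cfg.n_visits, pool.size)
    visits = rng.choice(pool, size=k, replace=False) if k else np.array([], dtype=int)
    seq = np.r_[lib.white_index, visits, lib.white_index]

    pieces = []
    for a, b in zip(seq, seq[1:]):
        dwell = max(int(rng.poisson(cfg.dwell_frames)), 3)
        pieces.append(np.repeat(lib.latent[[a]], dwell, axis=0))
        if cfg.transition_frames > 0:
            u = np.linspace(0, 1, cfg.transition_frames + 2)[1:-1, None]
            pieces.append(lib.latent[a] * (1 - u) + lib.latent[b] * u)
    pieces.append(np.repeat(lib.latent[[seq[-1]]], max(cfg.dwell_frames, 3), axis=0))
    path = np.vstack(pieces)
    path = gaussian_filter1d(path, sigma=2.0, axis=0, mode="nearest")
    if cfg.step_sd > 0:
        path = path + rng.normal(0, cfg.step_sd, path.shape)
    return path, seq


def gen_pattern_trajectories(
    cfg: PatternSimConfig,
) -> tuple[list[PatternTrajectory], PatternLibrary, SyntheticTruth]:
    """Simulate AS pattern trajectories for several animals.

    Returns the trajectories, the shared library, and a truth record holding
    the visited-pattern sequence per bout, the animal latent offsets, and
    the generating parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    lib = _make_library(cfg, rng)
    offsets = rng.normal(0, cfg.animal_offset_sd, (cfg.n_animals, cfg.latent_rank))

    trajectories, sequences, ids = [], [], []
    for a in range(cfg.n_animals):
        for b in range(cfg.n_bouts_per_animal):
            path, seq = _bout_latent_path(cfg, rng, lib)
            feats = lib.embed(path + offsets[a])
            if cfg.obs_noise_sd > 0:
                feats = feats + rng.normal(0, cfg.obs_noise_sd, feats.shape)
            trajectories.append(
                PatternTrajectory(feats, fps=cfg.fps, animal_id=f"animal{a}",
                                  bout_id=f"animal{a}-bout{b}")
            )
            sequences.append(seq)
            ids.append((a, b))

    truth = SyntheticTruth(
        params=asdict(cfg),
        events={
            "visited_sequences": sequences,
            "animal_offsets_latent": offsets,
            "animal_bout_ids": ids,
        },
    )
    return trajectories, lib, truth


def sample_wake_patterns(lib: PatternLibrary, n: int, seed: int = 0,
                         jitter_sd: float = 0.05) -> np.ndarray:
    """Waking pattern feature vectors drawn from the AS library (plus jitter).

    Emulates flat-posture waking patterns that fall within AS pattern space.
    """
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, lib.latent.shape[0], n)
    latent = lib.latent[idx] + rng.normal(0, jitter_sd, (n, lib.latent.shape[1]))
    return lib.embed(latent)
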