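"""Stage 2: slide the trained encoder over query micrographs and pick.

Every window placement is encoded WITHOUT masking, scored by cosine
similarity against the exemplar latent features (max over exemplars by
default — with varied particle orientations the best-matching exemplar
is the right reference; mean dilutes it), and a per-micrograph cutoff is
chosen by a density rule on the score distribution: compute each score's
average absolute distance to its k nearest neighbors in score space,
walk the scores in descending order, and cut where that average-distance
sequence drops the most (the sparse high-similarity tail ends and the
dense background bulk begins).  Everything above the cutoff (strictly)
is picked.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import Micrograph
from .mae import MaskedAutoencoder
from .train import contrast_scale, resize_crops

logger = logging.getLogger("maepick")


@dataclass
class PickConfig:
    """Sliding-window scan settings."""

    stride: int = 28
    window_size: int = 64  # = stage-1 crop size (particle diameter)
    match_mode: str = "max"  # or "mean"
    k_neighbors: int = 5
    dedupe_radius: float | str | None = "auto"  # "auto" = window_size/2; None = off
    batch_windows: int = 256  # encoder minibatch during the scan

    def __post_init__(self):
        if not 1 <= self.stride <= self.window_size:
            raise ValueError("stride must satisfy 1 <= stride <= window_size")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.match_mode not in ("max", "mean"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if self.dedupe_radius == "auto":
            # one coordinate per particle: windows within half a particle
            # of a stronger pick are duplicates of the same detection
            self.dedupe_radius = self.window_size / 2.0
        if self.dedupe_radius is not None and self.dedupe_radius <= 0:
            self.dedupe_radius = None


@dataclass
class PickSet:
    """Scored candidate centers for one micrograph plus the chosen cutoff.

    ``centers``/``scores`` hold EVERY scanned window; ``picked_idx``
    indexes the final picks (above-threshold, after optional duplicate
    suppression).  Without suppression it is exactly the strict
    above-threshold set.
    """

    micrograph_id: str
    centers: np.ndarray  # (K, 2) float (x, y) candidate window centers
    scores: np.ndarray  # (K,) cosine similarity scores
    threshold: float
    picked_idx: np.ndarray | None = None

    def __post_init__(self):
        if self.picked_idx is None:
            self.picked_idx = np.flatnonzero(self.scores > self.threshold)

    @property
    def picked_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.scores), dtype=bool)
        mask[self.picked_idx] = True
        return mask

    @property
    def picked_centers(self) -> np.ndarray:
        return self.centers[self.picked_idx]

    @property
    def picked_scores(self) -> np.ndarray:
        return self.scores[self.picked_idx]


def enumerate_windows(height: int, width: int, window_size: int,
                      stride: int) -> np.ndarray:
    """Row-major (x0, y0) origins of all fully-inside window placements.

    Margins smaller than one window at the right/bottom edge are never
    scanned (no partial windows, no padding).
    """
    if window_size > min(height, width):
        raise ValueError(
            f"window_size {window_size} exceeds image size {(height, width)}")
    ys = np.arange(0, height - window_size + 1, stride)
    xs = np.arange(0, width - window_size + 1, stride)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def n_windows(height: int, width: int, window_size: int, stride: int) -> int:
    """Closed-form window count (floor((L - w)/s) + 1 per axis)."""
    return ((height - window_size) // stride + 1) * ((width - window_size) // stride + 1)


def score_windows(model: MaskedAutoencoder, micrograph: Micrograph,
                  exemplar_features: np.ndarray, cfg: PickConfig):
    """Encode every window (unmasked) and score it against the exemplars.

    Returns ``(centers, scores)``; the candidate center is the window
    origin + window_size/2.
    """
    feats = np.asarray(exemplar_features, dtype=np.float32)
    if feats.ndim != 2 or len(feats) == 0:
        raise ValueError("score_windows needs a nonempty (m, D) exemplar feature set")
    norms = np.linalg.norm(feats, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm exemplar feature")
    feats = feats / norms
    h, w = micrograph.image.shape
    image = contrast_scale(micrograph.image)
    origins = enumerate_windows(h, w, cfg.window_size, cfg.stride)
    scores = np.empty(len(origins), dtype=np.float32)
    for lo in range(0, len(origins), cfg.batch_windows):
        chunk = origins[lo : lo + cfg.batch_windows]
        windows = np.stack([
            image[y0 : y0 + cfg.window_size, x0 : x0 + cfg.window_size]
            for x0, y0 in chunk])
        latents = model.embed(resize_crops(list(windows), model.cfg.input_size))
        lnorm = np.linalg.norm(latents, axis=1, keepdims=True)
        lnorm[lnorm == 0] = 1.0
        cos = (latents / lnorm) @ feats.T  # (B, m)
        scores[lo : lo + len(chunk)] = (cos.max(axis=1) if cfg.match_mode == "max"
                                        else cos.mean(axis=1))
    centers = origins.astype(float) + cfg.window_size / 2.0
    return centers, scores


def density_threshold(scores: np.ndarray, k_neighbors: int = 5) -> float:
    """Density-based automatic score cutoff.

    For each score, compute the mean absolute difference to its
    ``k_neighbors`` nearest neighbors in score space; order these average
    distances by descending score and place the cutoff at the score where
    the sequence decreases the most (ties resolved toward the higher
    score, i.e. the more conservative cut).  Needs at least
    ``k_neighbors + 2`` scores; otherwise falls back to the midpoint of
    the score range with a warning.
    """
    s = np.sort(np.asarray(scores, dtype=float))[::-1]  # descending
    n = len(s)
    k = int(k_neighbors)
    if n < k + 2:
        warnings.warn(
            f"only {n} scores for k={k} nearest neighbors; "
            "falling back to the score-range midpoint", stacklevel=2)
        return float((s.max() + s.min()) / 2.0) if n else 0.0
    avg_dist = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - k), min(n, i + k + 1)
        d = np.abs(s[lo:hi] - s[i])
        d = np.delete(d, i - lo)  # drop self
        avg_dist[i] = np.sort(d)[:k].mean()
    drops = avg_dist[:-1] - avg_dist[1:]
    cut = int(np.argmax(drops))  # argmax takes the FIRST (= higher score) tie
    return float(s[cut + 1])


def pick_particles(model: MaskedAutoencoder, micrograph: Micrograph,
                   exemplar_features: np.ndarray, cfg: PickConfig) -> PickSet:
    """Scan, score, auto-threshold and (optionally) dedupe one micrograph."""
    centers, scores = score_windows(model, micrograph, exemplar_features, cfg)
    threshold = density_threshold(scores, cfg.k_neighbors)
    idx = np.flatnonzero(scores > threshold)
    if cfg.dedupe_radius is not None and len(idx):
        idx = idx[_dedupe(centers[idx], scores[idx], cfg.dedupe_radius)]
    picks = PickSet(micrograph.micrograph_id, centers, scores, threshold, idx)
    logger.info("%s: picked %d of %d windows (threshold %.4f)",
                micrograph.micrograph_id, len(idx), len(scores), threshold)
    return picks


def _dedupe(centers: np.ndarray, scores: np.ndarray, radius: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices (sorted)."""
    order = np.argsort(-scores, kind="stable")
    kept: list = []
    for i in order:
        c = centers[i]
        if all(np.hypot(*(c - centers[j])) >= radius for j in kept):
            kept.append(i)
    return np.sort(np.asarray(kept, dtype=int))
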