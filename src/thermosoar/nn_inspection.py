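"""Clustering of hidden-layer activations along flight trajectories.

A trained actor network is replayed over the observations of logged
trajectories; the ReLU activations of its hidden layers (nominally
2 x 200 units) are concatenated into one vector per timestep.  k-means
clustering of these vectors, with the cluster count chosen at the knee of
the SSE-versus-k curve, yields a small set of "functional modes"; mapping
the cluster labels onto the flight-phase angle theta shows whether the
modes correspond to phases of the circling motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .training import MLP

__all__ = [
    "ClusterResult",
    "extract_activations",
    "knee_point",
    "cluster_activations",
    "cluster_theta_distribution",
]

THETA_BINS = 24  # fixed binning over (-180, 180]
ASSOCIATION_ARC_BINS = 6  # 90-degree modal arc used by the association score


def extract_activations(actor: MLP, observations: np.ndarray) -> np.ndarray:
    """Hidden-layer activations, one row per timestep.

    ``observations`` is (n, obs_dim) of normalized observation vectors;
    the returned matrix is (n, sum of hidden widths), entries >= 0 by the
    ReLU nonlinearity.
    """
    observations = np.atleast_2d(np.asarray(observations, dtype=float))
    if observations.shape[1] != actor.sizes[0]:
        raise ValueError(
            f"observation dim {observations.shape[1]} does not match the "
            f"actor input dim {actor.sizes[0]}"
        )
    _, hidden = actor.forward(observations, keep=True)
    return np.concatenate(hidden, axis=1)


def knee_point(ks: Sequence[int], sse: Sequence[float]) -> int:
    """Knee of a decreasing SSE curve (Kneedle-style).

    Both axes are normalized to [0, 1]; the knee is the k maximizing the
    gap between the flipped-normalized curve and the diagonal — the point
    where the curve "starts to straighten up".  Degenerate flat curves
    return the smallest k.
    """
    ks = np.asarray(ks, dtype=float)
    y = np.asarray(sse, dtype=float)
    if len(ks) < 3 or np.ptp(y) == 0:
        return int(ks[0])
    xn = (ks - ks.min()) / np.ptp(ks)
    yn = (y - y.min()) / np.ptp(y)
    gap = (1.0 - yn) - xn
    return int(ks[int(np.argmax(gap))])


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray  # in {1..k}, one per timestep
    sse: dict[int, float]  # SSE per candidate k
    rationale: str
    centers: Optional[np.ndarray] = None


def cluster_activations(
    m: np.ndarray,
    k_candidates: Sequence[int] = range(1, 11),
    seed: int = 0,
    standardize: bool = False,
    n_restarts: int = 10,
) -> ClusterResult:
    """k-means over activation vectors with knee-selected cluster count.

    Activations are clustered raw by default (``standardize`` switches on
    per-column z-scoring).  Each candidate k is fit with ``n_restarts``
    seeded restarts, so the SSE sequence is non-increasing in practice;
    all-identical rows short-circuit to k = 1 with a warning.
    """
    m = np.asarray(m, dtype=float)
    ks = sorted(int(k) for k in k_candidates)
    n_distinct = len(np.unique(m, axis=0))
    if n_distinct == 1:
        warnings.warn("degenerate activations: all rows equal; k = 1",
                      stacklevel=2)
        return ClusterResult(
            k=1,
            labels=np.ones(len(m), dtype=int),
            sse={1: 0.0},
            rationale="all activation vectors identical",
            centers=m[:1].copy(),
        )
    if n_distinct < max(ks):
        raise ValueError(
            f"need at least {max(ks)} distinct rows, have {n_distinct}"
        )
    x = m
    if standardize:
        std = m.std(axis=0)
        std[std == 0] = 1.0
        x = (m - m.mean(axis=0)) / std
    sse: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(x)
        sse[k] = float(km.inertia_)
        fits[k] = km
    k_best = knee_point(ks, [sse[k] for k in ks])
    km = fits[k_best]
    return ClusterResult(
        k=k_best,
        labels=km.labels_.astype(int) + 1,
        sse=sse,
        rationale=f"knee of the SSE curve over k in {ks[0]}..{ks[-1]}",
        centers=km.cluster_centers_,
    )


def cluster_theta_distribution(
    labels: np.ndarray,
    theta: np.ndarray,
    n_bins: int = THETA_BINS,
) -> tuple[pd.DataFrame, float]:
    """Per-cluster distribution over theta bins, plus an association score.

    Returns a (cluster x bin) table of normalized histograms (rows sum to
    one; empty clusters give all-zero rows) and a scalar score: the mean
    over non-empty clusters of the fraction of the cluster's mass inside
    its best contiguous 90-degree arc of theta (circularly).  Labels
    perfectly aligned with theta quadrants score ~1; labels independent of
    theta score ~0.25.
    """
    labels = np.asarray(labels)
    theta = np.asarray(theta, dtype=float)
    if len(labels) != len(theta):
        raise ValueError("labels and theta must have equal length")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    clusters = np.unique(labels)
    rows = {}
    scores = []
    arc = max(1, round(n_bins * ASSOCIATION_ARC_BINS / THETA_BINS))
    for c in clusters:
        th = theta[labels == c]
        counts, _ = np.histogram(th, bins=edges)
        total = counts.sum()
        if total == 0:
            rows[c] = np.zeros(n_bins)
            continue
        frac = counts / total
        rows[c] = frac
        wrapped = np.concatenate([frac, frac[: arc - 1]])
        windows = np.convolve(wrapped, np.ones(arc), mode="valid")[:n_bins]
        scores.append(float(windows.max()))
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[
        f"({edges[i]:.0f},{edges[i+1]:.0f}]" for i in range(n_bins)
    ])
    table.index.name = "cluster"
    score = float(np.mean(scores)) if scores else float("nan")
    return table, score
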