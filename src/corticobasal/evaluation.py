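"""Evaluation suite: error densities, mismatch profiles, correspondence
matching and ABX distances.

Distances between MFCC-scale vectors are Euclidean, normalized by
``range * sqrt(M)`` so that a value of 1 corresponds to vectors at opposite
corners of the dynamic-range hypercube.  All nearest-neighbour ties break to
the lowest index and all histograms are normalized to unit mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "prediction_error_density",
    "reconstruction_error",
    "identity_mismatch_profile",
    "correspondence_and_abx",
    "CorrespondenceMatrix",
    "longest_true_run",
]


def _norm(m: int, lo: float, hi: float) -> float:
    return (hi - lo) * np.sqrt(m)


def prediction_error_density(
    e_star: np.ndarray, bins: int = 20, threshold: float = 0.3
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalized histogram of per-unit best prediction errors over [0, 1].

    Returns ``(histogram, bin_edges, fraction_below_threshold)``; the
    histogram sums to 1 and the below/above fractions sum to 1.
    """
    e_star = np.asarray(e_star, dtype=float)
    if e_star.size == 0:
        raise ValueError("empty error vector")
    hist, edges = np.histogram(e_star, bins=bins, range=(0.0, 1.0))
    hist = hist / hist.sum()
    return hist, edges, float((e_star < threshold).mean())


def reconstruction_error(
    retrieved: np.ndarray,
    reference: np.ndarray,
    lo: float = 0.0,
    hi: float = 1200.0,
    bins: int = 20,
    space: str = "value",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-reference normalized distance to the nearest retrieved vector.

    ``space="value"``: Euclidean distance on the MFCC scale divided by
    ``range * sqrt(M)``.  ``space="code"``: distance between the *rank codes*
    of the vectors, normalized by the maximal code distance — the
    representation the network actually learns, and the one the retrieval
    loop improves (rank coding leaves amplitudes unconstrained, so value
    distances bottom out at the random-candidate floor).  Returns
    ``(distances, nearest_indices, histogram)`` with the histogram normalized
    over [0, 1].
    """
    retrieved = np.atleast_2d(np.asarray(retrieved, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if retrieved.shape[0] == 0 or reference.shape[0] == 0:
        raise ValueError("empty input")
    if space == "code":
        from .rank import RankFunction, rank_transform

        f = RankFunction()
        m = reference.shape[1]
        retrieved = np.stack([rank_transform(v, f) for v in retrieved])
        reference = np.stack([rank_transform(v, f) for v in reference])
        base = f.values(m)
        norm = np.sqrt(2 * (base @ base - base @ base[::-1]))  # max code distance
    elif space == "value":
        norm = _norm(reference.shape[1], lo, hi)
    else:
        raise ValueError(f"unknown space {space!r}")
    d = cdist(reference, retrieved)
    nearest = d.argmin(axis=1)  # first-minimum tie rule
    dist = d[np.arange(len(reference)), nearest] / norm
    hist, _ = np.histogram(np.clip(dist, 0, 1), bins=bins, range=(0.0, 1.0))
    return dist, nearest, hist / hist.sum()


def identity_mismatch_profile(retrieved_indices, true_indices) -> np.ndarray:
    """``|retrieved - true|`` per frame; same-index retrievals score zero."""
    r = np.asarray(retrieved_indices, dtype=float)
    t = np.asarray(true_indices, dtype=float)
    if r.shape != t.shape:
        raise ValueError("index sequences must have equal length")
    return np.abs(r - t)


@dataclass
class CorrespondenceMatrix:
    """Ground-truth item ``A`` -> predicted unit ``X`` -> nearest database
    item ``B``; each A maps to exactly one X, an X may receive many A's."""

    a_to_x: np.ndarray
    a_to_b: np.ndarray
    x_distance: np.ndarray   # normalized distance A -> I_opt(X)
    abx: np.ndarray          # normalized distance A -> B
    exact_match_count: int

    @property
    def exact_match_fraction(self) -> float:
        return self.exact_match_count / len(self.a_to_b)


def correspondence_and_abx(
    truth_frames: np.ndarray,
    repertoire_vectors: np.ndarray,
    database_frames: np.ndarray,
    lo: float = 0.0,
    hi: float = 1200.0,
    bins: int = 20,
) -> tuple[CorrespondenceMatrix, np.ndarray]:
    """Correspondence matching and ABX scoring.

    For each ground-truth frame ``A``: ``X`` is the unit whose retrieved
    vector is nearest ``A``; ``B`` the database frame nearest that unit's
    vector; the ABX value is the normalized distance between ``A`` and ``B``.
    ``exact_match_count`` counts index equality ``B == A`` (one-to-one
    correspondences, i.e. successful generalizations).  Returns the matrix
    and the normalized ABX histogram.
    """
    truth = np.atleast_2d(np.asarray(truth_frames, dtype=float))
    rep = np.atleast_2d(np.asarray(repertoire_vectors, dtype=float))
    db = np.atleast_2d(np.asarray(database_frames, dtype=float))
    if db.shape[0] == 0:
        raise ValueError("empty database")
    norm = _norm(truth.shape[1], lo, hi)
    d_ax = cdist(truth, rep)
    a_to_x = d_ax.argmin(axis=1)
    x_dist = d_ax[np.arange(len(truth)), a_to_x] / norm
    d_xb = cdist(rep, db)
    x_to_b = d_xb.argmin(axis=1)
    a_to_b = x_to_b[a_to_x]
    abx = np.linalg.norm(truth - db[a_to_b], axis=1) / norm
    exact = int(np.sum(a_to_b == np.arange(len(truth))))
    hist, _ = np.histogram(np.clip(abx, 0, 1), bins=bins, range=(0.0, 1.0))
    matrix = CorrespondenceMatrix(a_to_x, a_to_b, x_dist, abx, exact)
    return matrix, hist / hist.sum()


def longest_true_run(mask) -> int:
    """Length of the longest run of consecutive True values."""
    best = cur = 0
    for v in np.asarray(mask, dtype=bool):
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best
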