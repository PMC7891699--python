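"""Seeded generators for MFCC-like synthetic data.

The generators emulate the structure the experiments assume: a bank of
well-separated 12-dim prototype vectors standing in for recurring speech
sounds, label paths where each prototype dwells for a number of frames before
a random transition (speech sounds are quasi-stationary over tens of
milliseconds), additive frame-level Gaussian noise, and affine "speaker
transforms" (gain/offset plus a smooth per-coefficient warp) standing in for
the pitch and timbre differences between speakers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import pdist

from .audio import MFCCSequence
from .rank import RankFunction, rank_transform

__all__ = ["PrototypeBank", "make_prototypes", "make_sequence", "speaker_transform"]

MFCC_RANGE = (0.0, 1200.0)


@dataclass
class PrototypeBank:
    """``K`` prototype vectors with enforced minimum pairwise separation."""

    vectors: np.ndarray
    d_min: float
    seed: int | None
    lo: float = MFCC_RANGE[0]
    hi: float = MFCC_RANGE[1]

    @property
    def k(self) -> int:
        return self.vectors.shape[0]

    @property
    def m(self) -> int:
        return self.vectors.shape[1]

    def min_distance(self) -> float:
        if self.k < 2:
            return np.inf
        return float(pdist(self.vectors).min())


def make_prototypes(
    k: int,
    d_min: float = 300.0,
    seed: int | None = None,
    m: int = 12,
    lo: float = MFCC_RANGE[0],
    hi: float = MFCC_RANGE[1],
    max_code_sim: float | None = None,
    max_tries: int = 10_000,
) -> PrototypeBank:
    """Rejection-sample ``k`` uniform vectors with pairwise distance >= d_min.

    ``max_code_sim`` additionally enforces separation in the space a
    rank-coded front-end perceives: candidates whose rank code exceeds that
    normalized dot product (1 = identical ordering) with an already accepted
    prototype are rejected.  Random vectors frequently share their dominant
    components, so banks meant to model *distinct* stimuli for a rank-order
    model should bound this similarity; the tail is fat, which makes the
    constraint practical only for banks of modest size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    f = RankFunction()
    self_match = f.self_match(m)
    tries = 0
    while len(chosen) < k:
        cand = rng.uniform(lo, hi, size=m)
        ok = all(np.linalg.norm(cand - c) >= d_min for c in chosen)
        if ok and max_code_sim is not None:
            code = rank_transform(cand, f)
            ok = all(code @ c / self_match <= max_code_sim for c in codes)
            if ok:
                codes.append(code)
        if ok:
            chosen.append(cand)
        tries += 1
        if tries > max_tries * k:
            raise RuntimeError(
                f"could not place {k} prototypes at separation {d_min}"
            )
    return PrototypeBank(np.stack(chosen), d_min, seed, lo, hi)


def make_sequence(
    bank: PrototypeBank,
    length: int,
    dwell: int = 25,
    noise_sigma: float = 0.02,
    seed: int | None = None,
    balanced: bool = False,
    stride_ms: int = 10,
) -> MFCCSequence:
    """Label path + noisy frames.

    Each prototype persists ``dwell`` frames before a transition.  The
    default path transitions to a uniformly random *different* prototype;
    ``balanced=True`` instead cycles through random permutations of the whole
    bank so every prototype is visited equally often (emulating a database
    that covers all the syllables of the language).  Noise is i.i.d. Gaussian
    per component with sd ``noise_sigma`` times the dynamic range, clamped to
    the range.
    """
    if length < 1 or dwell < 1:
        raise ValueError("length and dwell must be >= 1")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(length / dwell))
    if balanced:
        blocks = []
        while len(blocks) < n_blocks:
            blocks.extend(rng.permutation(bank.k))
        blocks = np.asarray(blocks[:n_blocks])
    else:
        blocks = np.empty(n_blocks, dtype=int)
        blocks[0] = rng.integers(bank.k)
        for i in range(1, n_blocks):
            nxt = rng.integers(bank.k)
            if bank.k > 1:
                while nxt == blocks[i - 1]:
                    nxt = rng.integers(bank.k)
            blocks[i] = nxt
    labels = np.repeat(blocks, dwell)[:length]
    frames = bank.vectors[labels].astype(float)
    if noise_sigma > 0:
        frames = frames + rng.normal(
            0.0, noise_sigma * (bank.hi - bank.lo), size=frames.shape
        )
    frames = np.clip(frames, bank.lo, bank.hi)
    return MFCCSequence(
        frames=frames,
        stride_ms=stride_ms,
        sample_rate=16000,
        labels=labels,
        scale_lo=bank.lo,
        scale_hi=bank.hi,
    )


def speaker_transform(
    seq: MFCCSequence,
    gain: float = 1.0,
    offset: float = 0.0,
    warp_sigma: float = 0.0,
    seed: int | None = None,
) -> MFCCSequence:
    """Affine speaker change: ``frames <- clamp(gain*frames + offset + warp)``.

    The warp is a smooth per-coefficient offset curve (Gaussian draws with sd
    ``warp_sigma`` times the range, smoothed along the coefficient axis),
    constant over time — a cepstral-domain stand-in for a different voice.
    Labels are preserved unchanged.
    """
    rng = np.random.default_rng(seed)
    lo, hi = seq.scale_lo, seq.scale_hi
    warp = np.zeros(seq.frames.shape[1])
    if warp_sigma > 0:
        warp = gaussian_filter1d(
            rng.normal(0.0, warp_sigma * (hi - lo), size=seq.frames.shape[1]),
            sigma=1.5,
            mode="nearest",
        )
    frames = np.clip(gain * seq.frames + offset + warp, lo, hi)
    return MFCCSequence(
        frames=frames,
        frame_ms=seq.frame_ms,
        stride_ms=seq.stride_ms,
        sample_rate=seq.sample_rate,
        labels=None if seq.labels is None else seq.labels.copy(),
        scale_lo=lo,
        scale_hi=hi,
    )
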