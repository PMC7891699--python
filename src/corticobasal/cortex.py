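"""Feedforward cortical stack PAC -> STG -> STR.

The primary auditory cortex (PAC) layer rank-codes each 12-dim MFCC frame.
The superior temporal gyrus (STG) layer adds a recurrent term driven by the
rank code of the mean of its own last ``window`` activation vectors (a 20-step
ring buffer by default), so its state carries the recent temporal context of
the stream.  The striatum (STR) layer categorizes the STG state with one
winner-take-all unit per category; with as many units as distinct stream
states it forms a near-orthogonal representation of the sequence.

Unsupervised training presents frames in file order (no shuffling) and, at
each tick, updates the winner of every layer toward its target rank code:
PAC toward rank(X), STG toward rank(Y_PAC), STR toward rank(Y_STG).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .rank import RankFunction, ROCLayer, rank_transform, select_winner

__all__ = ["STGBuffer", "CorticalStack", "TrainLog", "ProbeResult"]


class STGBuffer:
    """Ring buffer of the last ``window`` STG activation vectors.

    Slots not yet written read as zero vectors, so the buffer mean ramps up
    over the first ``window`` ticks.  ``window=0`` disables temporal context
    entirely (the mean is a constant zero vector), which turns the stack into
    a static, context-free classifier.
    """

    def __init__(self, window: int, dim: int):
        if window < 0 or dim < 1:
            raise ValueError("window must be >= 0 and dim >= 1")
        self.window = window
        self.dim = dim
        self.reset()

    def reset(self) -> None:
        self._data = np.zeros((max(self.window, 1), self.dim))
        self._pos = 0
        self.count = 0

    def push(self, v: np.ndarray) -> None:
        if self.window == 0:
            return
        self._data[self._pos] = v
        self._pos = (self._pos + 1) % self.window
        self.count = min(self.count + 1, self.window)

    def mean(self) -> np.ndarray:
        """Elementwise mean over all ``window`` slots (missing slots zero)."""
        if self.window == 0:
            return np.zeros(self.dim)
        return self._data.sum(axis=0) / self.window

    def snapshot(self) -> tuple[np.ndarray, int, int]:
        return self._data.copy(), self._pos, self.count

    def restore(self, state: tuple[np.ndarray, int, int]) -> None:
        data, pos, count = state
        self._data = data.copy()
        self._pos = pos
        self.count = count


@dataclass
class TrainLog:
    """Per-period winner bookkeeping from a training run."""

    winners: np.ndarray      # (periods, T) STR winner index
    activations: np.ndarray  # (periods, T) winning STR activation
    periods_run: int

    def to_frame(self):
        import pandas as pd

        p, t = np.meshgrid(
            np.arange(self.winners.shape[0]),
            np.arange(self.winners.shape[1]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "period": p.ravel(),
                "frame_index": t.ravel(),
                "winner": self.winners.ravel(),
                "activation": self.activations.ravel(),
            }
        )


@dataclass
class ProbeResult:
    """No-learning pass over a sequence: winners plus the STG buffer state
    *before* each frame, reusable as evaluation context for the actor."""

    winners: np.ndarray
    activations: np.ndarray
    contexts: list


class CorticalStack:
    """The PAC(50x12) -> STG(50x50, 20-step window) -> STR(N_STR x 50) stack."""

    def __init__(
        self,
        n_str: int = 14000,
        m_in: int = 12,
        n_pac: int = 50,
        n_stg: int = 50,
        window: int = 20,
        f: RankFunction | None = None,
        seed: int | None = None,
        alpha_init: float = 0.9,
        alpha_init_cortex: float = 0.5,
        gamma: float = 0.98,
        gamma_cortex: float = 0.9,
        context_gain: float = 0.25,
        init: str = "rankcode",
    ):
        """``context_gain`` scales the recurrent STG term so that temporal
        context modulates the frame-specific feedforward drive instead of
        drowning it (the across-frame spread of the feedforward activations
        must stay dominant for the striatum to discriminate frames).  The
        undercomplete PAC/STG layers (50 units for many more distinct
        frames) get the moderate plasticity schedule ``alpha_init_cortex`` /
        ``gamma_cortex`` so they settle into stable receptive fields, while
        the striatum — sized 1:1 with the states it must separate — keeps
        the fast-snapping schedule ``alpha_init`` / ``gamma``.
        """
        if n_pac != n_stg:
            raise ValueError("STG recurrence assumes n_pac == n_stg")
        if context_gain < 0:
            raise ValueError("context_gain must be >= 0")
        self.f = f or RankFunction()
        rng = np.random.default_rng(seed)
        cx = dict(f=self.f, rng=rng, init=init, alpha_init=alpha_init_cortex,
                  gamma=gamma_cortex)
        self.pac = ROCLayer.create(n_pac, m_in, name="PAC", **cx)
        self.stg = ROCLayer.create(n_stg, n_pac, name="STG", **cx)
        self.str_ = ROCLayer.create(n_str, n_stg, name="STR", f=self.f, rng=rng,
                                    init=init, alpha_init=alpha_init, gamma=gamma)
        self.buffer = STGBuffer(window, n_stg)
        self.context_gain = float(context_gain)
        # recurrent growth guard: twice the self-match bound of a 50-dim code
        self.stg_clip = 2.0 * self.f.self_match(n_stg)

    # -- shapes ------------------------------------------------------------

    @property
    def m_in(self) -> int:
        return self.pac.m

    @property
    def n_str(self) -> int:
        return self.str_.n

    @property
    def y_max_str(self) -> float:
        """Upper bound of a single STR unit's activation (self-match)."""
        return self.str_.y_max

    # -- single-tick dynamics ---------------------------------------------

    def pac_step(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.m_in,):
            raise ValueError(f"expected a {self.m_in}-dim frame, got {x.shape}")
        return self.pac.activate(rank_transform(x, self.f))

    def stg_step(self, y_pac: np.ndarray) -> np.ndarray:
        h = self.buffer.mean()
        y = y_pac + self.context_gain * self.stg.activate(rank_transform(h, self.f))
        y = np.clip(y, 0.0, self.stg_clip)
        self.buffer.push(y)
        return y

    def str_step(self, y_stg: np.ndarray) -> tuple[np.ndarray, int]:
        y = self.str_.activate(rank_transform(y_stg, self.f))
        return y, select_winner(y)

    def step(self, x: np.ndarray, learn: bool = False, str_target: int | None = None):
        """One full tick; returns ``(y_pac, y_stg, y_str, str_winner)``.

        With ``learn=True`` the winner of each layer is updated toward its
        target rank code (PAC<-rank(X), STG<-rank(Y_PAC), STR<-rank(Y_STG)).
        ``str_target`` is an optional teaching signal (PFC-like supervision):
        it bypasses the winner-take-all in STR and makes the designated unit
        the learning winner, as in the serial/forced regime.
        """
        code_x = rank_transform(np.asarray(x, dtype=float), self.f)
        if code_x.shape != (self.m_in,):
            raise ValueError("frame dimension mismatch")
        y_pac = self.pac.activate(code_x)
        y_stg = self.stg_step(y_pac)
        code_stg = rank_transform(y_stg, self.f)
        y_str = self.str_.activate(code_stg)
        b_str = select_winner(y_str)
        if learn:
            self.pac.update_winner(select_winner(y_pac), code_x)
            self.stg.update_winner(select_winner(y_stg), rank_transform(y_pac, self.f))
            self.str_.update_winner(b_str if str_target is None else str_target, code_stg)
        return y_pac, y_stg, y_str, b_str

    def reset_buffer(self) -> None:
        self.buffer.reset()

    # -- training / probing ------------------------------------------------

    def train(
        self,
        frames: np.ndarray,
        periods: int = 4,
        stop_when_stable: bool = False,
        reset_each_period: bool = False,
        reset_every: int | None = None,
        str_targets: np.ndarray | None = None,
    ) -> TrainLog:
        """Feedforward training over ``periods`` passes.

        Frames are presented in order.  By default categorization is
        unsupervised (winner-take-all in every layer).  ``str_targets`` — one
        STR unit index per frame — switches the striatum to the serial
        supervised regime in which a PFC-like teaching signal designates the
        unit that learns each frame (the winner-take-all is bypassed in STR
        only; PAC and STG stay unsupervised).  ``reset_every`` resets the STG
        buffer every that many frames — the stride-free block presentation in
        which every stimulus is judged from its own settled dynamics.  With
        ``stop_when_stable`` the run ends early once the STR winner sequence
        repeats between two consecutive periods (the error-threshold
        alternative to a fixed period count).
        """
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        if frames.shape[0] == 0:
            raise ValueError("empty sequence")
        if periods < 1:
            raise ValueError("periods must be >= 1")
        if str_targets is not None:
            str_targets = np.asarray(str_targets, dtype=int)
            if str_targets.shape[0] != frames.shape[0]:
                raise ValueError("one STR target per frame required")
        winners = np.empty((periods, frames.shape[0]), dtype=int)
        acts = np.empty((periods, frames.shape[0]))
        run = periods
        for p in range(periods):
            if reset_each_period:
                self.reset_buffer()
            for t, x in enumerate(frames):
                if reset_every is not None and t % reset_every == 0:
                    self.reset_buffer()
                tgt = None if str_targets is None else int(str_targets[t])
                _, _, y_str, b = self.step(x, learn=True, str_target=tgt)
                winners[p, t] = b
                acts[p, t] = y_str[b]
            if stop_when_stable and p > 0 and np.array_equal(winners[p], winners[p - 1]):
                run = p + 1
                break
        return TrainLog(winners[:run], acts[:run], run)

    def probe(self, frames: np.ndarray, reset: bool = True) -> ProbeResult:
        """Frozen-weights pass recording, for each frame, the STR winner and
        the STG buffer snapshot *before* the frame was processed."""
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        if reset:
            self.reset_buffer()
        winners = np.empty(frames.shape[0], dtype=int)
        acts = np.empty(frames.shape[0])
        contexts = []
        for t, x in enumerate(frames):
            contexts.append(self.buffer.snapshot())
            _, _, y_str, b = self.step(x, learn=False)
            winners[t] = b
            acts[t] = y_str[b]
        return ProbeResult(winners, acts, contexts)

    # -- checkpointing -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Checkpoint: one weight container per layer + a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for layer, stem in ((self.pac, "pac"), (self.stg, "stg"), (self.str_, "str")):
            layer.save(directory / stem)
        manifest = {
            "m_in": self.m_in,
            "n_pac": self.pac.n,
            "n_stg": self.stg.n,
            "n_str": self.n_str,
            "window": self.buffer.window,
            "context_gain": self.context_gain,
            "rank_function": self.f.to_dict(),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CorticalStack":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        stack = cls.__new__(cls)
        stack.f = RankFunction.from_dict(manifest["rank_function"])
        stack.pac = ROCLayer.load(directory / "pac")
        stack.stg = ROCLayer.load(directory / "stg")
        stack.str_ = ROCLayer.load(directory / "str")
        stack.buffer = STGBuffer(manifest["window"], manifest["n_stg"])
        stack.context_gain = float(manifest["context_gain"])
        stack.stg_clip = 2.0 * stack.f.self_match(manifest["n_stg"])
        return stack
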