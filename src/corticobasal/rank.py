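"""Rank-order coding primitives.

A rank-order coding (ROC) neuron is sensitive to the *order* of amplitudes in
its input rather than to the amplitudes themselves.  An input vector ``x`` of
length ``M`` is first converted to a *rank code*: the component with the
largest amplitude receives ``f(0)``, the second largest ``f(1)``, and so on,
where ``f`` is a strictly decreasing rank function with values in ``(0, 1]``.
A neuron's activation is the dot product of the rank code with its weight row.
When the weight row is itself a rank code, the activation is maximal exactly
when the input's amplitude ordering matches the stored ordering (rearrangement
inequality), which makes ROC neurons behave like receptive fields over
orderings and lets them approximate spike-timing-dependent plasticity in
discrete time.

Learning is winner-take-all: only the most active neuron moves its weight row
toward the presented rank code, with a per-neuron adaptive learning rate that
decays each time the neuron wins so that early categories are not overwritten
(no catastrophic forgetting) while new neurons stay plastic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RankFunction",
    "rank_transform",
    "ROCLayer",
    "select_winner",
    "train_layer",
]


@dataclass(frozen=True)
class RankFunction:
    """Strictly decreasing map from rank index to a value in ``(0, 1]``.

    Two parameterizations are supported:

    * ``"harmonic"`` (default): ``f(i) = 1 / (1 + i)``.
    * ``"power"``: ``f(i) = ((M - i) / M) ** exponent`` — a power law of the
      (descending) argsort position, normalized to ``(0, 1]``.
    """

    kind: str = "harmonic"
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic", "power"):
            raise ValueError(f"unknown rank function kind {self.kind!r}")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")

    def values(self, m: int) -> np.ndarray:
        """The vector ``[f(0), ..., f(m-1)]``."""
        if m < 1:
            raise ValueError("m must be >= 1")
        i = np.arange(m, dtype=float)
        if self.kind == "harmonic":
            return 1.0 / (1.0 + i)
        return ((m - i) / m) ** self.exponent

    def self_match(self, m: int) -> float:
        """Upper bound ``Y_max = sum_i f(i)**2`` of the activation of a
        rank-code weight row; attained when input and stored order match."""
        v = self.values(m)
        return float(v @ v)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "exponent": self.exponent}

    @classmethod
    def from_dict(cls, d: dict) -> "RankFunction":
        return cls(**d)


def rank_transform(x: np.ndarray, f: RankFunction) -> np.ndarray:
    """Encode the descending amplitude order of ``x`` as a rank code.

    Component ``i`` of the output is ``f(rank of x_i)`` where rank 0 is the
    largest amplitude.  Ties are broken lowest-index-first, so a constant
    vector maps to ``[f(0), f(1), ...]`` in index order.  The output is always
    a permutation of ``f(0..M-1)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input must be a non-empty 1-d vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    # stable sort of -x: equal amplitudes keep original index order
    order = np.argsort(-x, kind="stable")
    code = np.empty(x.size, dtype=float)
    code[order] = f.values(x.size)
    return code


def select_winner(y: np.ndarray) -> int:
    """Index of the maximal activation; ties go to the lowest index."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("activation vector must be non-empty and 1-d")
    return int(np.argmax(y))


@dataclass
class ROCLayer:
    """A population of ``N`` rank-order coding neurons with ``M`` afferents.

    ``weights`` is an ``N x M`` matrix with entries in ``[0, 1]``; ``alpha``
    holds the per-neuron adaptive learning rates.  Updates are convex
    combinations of the current row and a rank code, so entries never leave
    ``[0, 1]``.
    """

    weights: np.ndarray
    alpha: np.ndarray
    f: RankFunction
    name: str = ""
    gamma: float = 0.98
    alpha_min: float = 0.01

    #: default initial plasticity; high enough that a handful of wins pins a
    #: row to its category (see docs/methods.md on the decay schedule)
    ALPHA_INIT = 0.9

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-d")
        if self.alpha.shape != (self.weights.shape[0],):
            raise ValueError("alpha must have one entry per neuron")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")

    # -- construction ------------------------------------------------------

    @classmethod
    def create(
        cls,
        n: int,
        m: int,
        f: RankFunction | None = None,
        rng: np.random.Generator | None = None,
        init: str = "rankcode",
        alpha_init: float | None = None,
        name: str = "",
        gamma: float = 0.98,
        alpha_min: float = 0.01,
    ) -> "ROCLayer":
        """Build a layer of ``n`` neurons with ``m`` afferents.

        ``init="rankcode"`` (default) draws each row as a random permutation
        of the rank-function values, so every row has the same norm and the
        self-match bound is the exact winner criterion from the first
        presentation on.  ``init="uniform"`` draws i.i.d. U[0,1] entries.
        """
        if n < 1 or m < 1:
            raise ValueError("layer shape must be at least 1x1")
        f = f or RankFunction()
        rng = rng if rng is not None else np.random.default_rng()
        if init == "rankcode":
            base = f.values(m)
            w = np.stack([base[rng.permutation(m)] for _ in range(n)])
        elif init == "uniform":
            w = rng.uniform(0.0, 1.0, size=(n, m))
        else:
            raise ValueError(f"unknown init {init!r}")
        a = np.full(n, cls.ALPHA_INIT if alpha_init is None else alpha_init)
        return cls(weights=w, alpha=a, f=f, name=name, gamma=gamma, alpha_min=alpha_min)

    # -- shape -------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def m(self) -> int:
        return self.weights.shape[1]

    @property
    def y_max(self) -> float:
        return self.f.self_match(self.m)

    # -- dynamics ----------------------------------------------------------

    def activate(self, code: np.ndarray) -> np.ndarray:
        """``Y_n = sum_m code_m * w_nm`` for every neuron ``n``."""
        code = np.asarray(code, dtype=float)
        if code.shape != (self.m,):
            raise ValueError(f"code length {code.shape} does not match M={self.m}")
        return self.weights @ code

    def update_winner(self, b: int, target: np.ndarray) -> None:
        """Move row ``b`` toward ``target`` by its learning rate, then decay
        the rate (winner-take-all plasticity)."""
        if not 0 <= b < self.n:
            raise IndexError(f"winner index {b} out of range for N={self.n}")
        target = np.asarray(target, dtype=float)
        if target.shape != (self.m,):
            raise ValueError("target length does not match M")
        self.weights[b] += self.alpha[b] * (target - self.weights[b])
        self.alpha[b] = max(self.alpha_min, self.gamma * self.alpha[b])

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights/rates to ``<path>.npz`` and metadata to
        ``<path>.json`` (plain-text sidecar header)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), weights=self.weights, alpha=self.alpha)
        meta = {
            "n": self.n,
            "m": self.m,
            "name": self.name,
            "rank_function": self.f.to_dict(),
            "gamma": self.gamma,
            "alpha_min": self.alpha_min,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ROCLayer":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            w, a = data["weights"], data["alpha"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            weights=w,
            alpha=a,
            f=RankFunction.from_dict(meta["rank_function"]),
            name=meta["name"],
            gamma=meta["gamma"],
            alpha_min=meta["alpha_min"],
        )


def train_layer(
    layer: ROCLayer, inputs: np.ndarray, periods: int = 1
) -> np.ndarray:
    """Winner-take-all training of a single layer on raw input vectors.

    Each period presents every row of ``inputs`` in order; the winning neuron
    is updated toward the input's rank code.  Returns the winner index per
    (period, presentation).
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if periods < 1:
        raise ValueError("periods must be >= 1")
    winners = np.empty((periods, inputs.shape[0]), dtype=int)
    for p in range(periods):
        for t, x in enumerate(inputs):
            code = rank_transform(x, layer.f)
            b = select_winner(layer.activate(code))
            layer.update_winner(b, code)
            winners[p, t] = b
    return winners
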