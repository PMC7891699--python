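"""Basal-ganglia actor-critic: free-energy retrieval of audio primitives.

The striatum (STR) acts as critic: for a desired category (one STR unit), the
prediction error of a candidate input vector ``I`` is

    E = 1 - Y_STR[target] / Y_max,   clamped to [0, 1],

where ``Y_max`` is the self-match bound of an STR row — ``E = 0`` means the
target unit fires maximally, ``E = 1`` that it is silent.  The globus
pallidus (GP) acts as actor: it perturbs its candidate with Gaussian noise,
re-evaluates it through the frozen cortical stack, and keeps the perturbation
if and only if the error strictly decreased (stochastic hill climbing, the
accept/reject form of free-energy minimization).  Whenever a perturbation is
accepted, the GP unit's reinforcement weights move toward the observed STR
activity pattern.

Because the cortical stack is rank-coded, ``E`` depends on a candidate only
through the *ordering* of its 12 components; the optimizer therefore searches
the finite space of orderings, and repeated evaluations of one ordering can
be memoized exactly.

Two evaluation modes exist:

* ``isolated`` (default): the STG buffer is reset and the candidate is held
  at the input for ``settle_steps`` ticks (one full STG window) before the
  STR activity is read.
* ``contextual``: the STG buffer is restored from a snapshot (typically
  recorded during a frozen probe pass over the training sequence) and the
  candidate is evaluated in that running context — this matches the
  continuous dynamics of serial, externally forced recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cortex import CorticalStack
from .rank import rank_transform, select_winner

__all__ = [
    "GPUnit",
    "Goal",
    "OptimizationTrace",
    "Repertoire",
    "evaluate_candidate",
    "propose",
    "fe_step",
    "reinforce",
    "optimize_unit",
    "reset_unit",
    "forced_optimize",
    "babble",
    "serial_recall",
    "RecallResult",
]

MFCC_RANGE = (0.0, 1200.0)


@dataclass
class Goal:
    """Desired STR activation: one-hot on ``unit`` at amplitude ``amplitude``
    (defaults to the layer's self-match bound)."""

    unit: int
    amplitude: float | None = None


@dataclass
class GPUnit:
    """Actor state for one striatal category.

    ``I`` is the candidate input vector on the MFCC scale; ``w_gp`` the
    reinforcement weights over STR units; ``e_star`` the best error achieved
    so far (non-increasing over the unit's lifetime).
    """

    I: np.ndarray
    w_gp: np.ndarray
    e_star: float = 1.0
    converged: bool = False
    evaluated: bool = False


class OptimizationTrace:
    """Per-iteration record of a free-energy run.

    The subsequence of accepted errors is non-increasing by construction of
    the accept rule; :meth:`accepted_errors` exposes it for verification.
    """

    def __init__(self):
        self.iteration: list[int] = []
        self.unit: list[int] = []
        self.error: list[float] = []
        self.accepted: list[bool] = []
        self.reset: list[bool] = []
        self._n = 0

    def record(self, unit: int, error: float, accepted: bool, reset: bool = False):
        self.iteration.append(self._n)
        self.unit.append(unit)
        self.error.append(error)
        self.accepted.append(accepted)
        self.reset.append(reset)
        self._n += 1

    def mark_reset(self, unit: int):
        self.record(unit, 1.0, False, reset=True)

    def __len__(self) -> int:
        return self._n

    def accepted_errors(self, unit: int | None = None) -> np.ndarray:
        acc = np.asarray(self.accepted)
        err = np.asarray(self.error)
        if unit is not None:
            acc = acc & (np.asarray(self.unit) == unit)
        return err[acc]

    def cycles(self) -> list[np.ndarray]:
        """Accepted-error subsequences split at reset markers."""
        out, cur = [], []
        for e, a, r in zip(self.error, self.accepted, self.reset):
            if r:
                if cur:
                    out.append(np.asarray(cur))
                cur = []
            elif a:
                cur.append(e)
        if cur:
            out.append(np.asarray(cur))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "unit": self.unit,
                "E": self.error,
                "accepted": self.accepted,
                "reset": self.reset,
            }
        )

    def export(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class NullTrace(OptimizationTrace):
    """Counts iterations without storing them (for large serial runs)."""

    def record(self, unit, error, accepted, reset=False):
        self._n += 1


class Repertoire:
    """One GP unit per striatal category."""

    def __init__(self, n_str: int, m: int = 12, rng: np.random.Generator | None = None,
                 lo: float = MFCC_RANGE[0], hi: float = MFCC_RANGE[1]):
        rng = rng if rng is not None else np.random.default_rng()
        self.lo, self.hi = float(lo), float(hi)
        self.units = [
            GPUnit(I=rng.uniform(lo, hi, size=m), w_gp=np.zeros(n_str))
            for _ in range(n_str)
        ]

    def __len__(self) -> int:
        return len(self.units)

    def __getitem__(self, i: int) -> GPUnit:
        return self.units[i]

    @property
    def I(self) -> np.ndarray:
        return np.stack([u.I for u in self.units])

    @property
    def e_star(self) -> np.ndarray:
        return np.array([u.e_star for u in self.units])

    @property
    def converged(self) -> np.ndarray:
        return np.array([u.converged for u in self.units])

    def converged_fraction(self) -> float:
        return float(self.converged.mean())

    def save(self, path: str | Path) -> None:
        np.savez(
            Path(path),
            I=self.I,
            e_star=self.e_star,
            converged=self.converged,
            w_gp=np.stack([u.w_gp for u in self.units]),
            range=np.array([self.lo, self.hi]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Repertoire":
        with np.load(Path(path)) as d:
            rep = cls.__new__(cls)
            rep.lo, rep.hi = map(float, d["range"])
            rep.units = [
                GPUnit(I=i.copy(), w_gp=w.copy(), e_star=float(e), converged=bool(c),
                       evaluated=True)
                for i, w, e, c in zip(d["I"], d["w_gp"], d["e_star"], d["converged"])
            ]
        return rep


# ---------------------------------------------------------------------------
# evaluation through the frozen stack
# ---------------------------------------------------------------------------


def _settle_code(stack: CorticalStack, I: np.ndarray, settle_steps: int, context):
    """Hold ``I`` at the input for ``settle_steps`` ticks on a scratch copy of
    the STG buffer; return the rank code of the final STG state."""
    f = stack.f
    y_pac = stack.pac.activate(rank_transform(I, f))
    window = stack.buffer.window
    dim = stack.stg.n
    if context is None:
        data = np.zeros((max(window, 1), dim))
        pos = 0
    else:
        data, pos, _ = context
        data = data.copy()
    w_stg = stack.stg.weights
    clip_hi = stack.stg_clip
    kappa = stack.context_gain
    y_stg = None
    for _ in range(settle_steps):
        h = data.sum(axis=0) / window if window > 0 else np.zeros(dim)
        y_stg = np.clip(y_pac + kappa * (w_stg @ rank_transform(h, f)), 0.0, clip_hi)
        if window > 0:
            data[pos] = y_stg
            pos = (pos + 1) % window
    return rank_transform(y_stg, f)


def evaluate_candidate(
    stack: CorticalStack,
    I: np.ndarray,
    target_unit: int,
    settle_steps: int = 20,
    context=None,
    return_code: bool = False,
):
    """Prediction error of candidate ``I`` for the desired STR unit.

    ``context=None`` gives isolated evaluation (buffer reset); passing a
    buffer snapshot evaluates in that running context.  The stack's own
    buffer is never disturbed.
    """
    if not 0 <= target_unit < stack.n_str:
        raise IndexError(f"target unit {target_unit} out of range")
    if settle_steps < 1:
        raise ValueError("settle_steps must be >= 1")
    I = np.asarray(I, dtype=float)
    code = _settle_code(stack, I, settle_steps, context)
    y = float(stack.str_.weights[target_unit] @ code)
    e = float(np.clip(1.0 - y / stack.y_max_str, 0.0, 1.0))
    return (e, code) if return_code else e


def evaluate_winner(
    stack: CorticalStack, I: np.ndarray, settle_steps: int = 20, context=None
) -> tuple[int, np.ndarray]:
    """STR winner (and full activation vector) for a candidate input."""
    code = _settle_code(stack, np.asarray(I, dtype=float), settle_steps, context)
    y_str = stack.str_.activate(code)
    return select_winner(y_str), y_str


# ---------------------------------------------------------------------------
# actor moves
# ---------------------------------------------------------------------------


def propose(
    I: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
    lo: float = MFCC_RANGE[0],
    hi: float = MFCC_RANGE[1],
    grid: float | None = None,
    kick_prob: float = 0.0,
    swap_prob: float = 0.0,
) -> np.ndarray:
    """Gaussian perturbation of the candidate, clamped to the dynamic range.

    ``sigma`` is expressed as a fraction of the range.  Two optional
    heavy-tailed moves complement the Gaussian step, which essentially never
    reorders components whose values are far apart even though the rank-coded
    network only perceives the ordering:

    * with probability ``kick_prob`` one randomly chosen component is redrawn
      uniformly over the whole range;
    * with probability ``swap_prob`` the values of two randomly chosen
      components are exchanged — the natural unit move in ordering space.

    ``grid`` optionally snaps the result to a quantized lattice (used by the
    toy search-space benchmarks).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    I = np.asarray(I, dtype=float)
    u = rng.random()
    if swap_prob > 0 and u < swap_prob and len(I) >= 2:
        cand = I.copy()
        i, j = rng.choice(len(I), size=2, replace=False)
        cand[i], cand[j] = cand[j], cand[i]
    elif kick_prob > 0 and u < swap_prob + kick_prob:
        cand = I.copy()
        cand[rng.integers(len(I))] = rng.uniform(lo, hi)
    else:
        cand = I + rng.normal(0.0, sigma * (hi - lo), size=len(I))
    cand = np.clip(cand, lo, hi)
    if grid is not None:
        cand = np.clip(np.round(cand / grid) * grid, lo, hi)
    return cand


def reinforce(unit: GPUnit, y_str: np.ndarray, beta: float) -> None:
    """Move the GP unit's reinforcement weights toward the observed STR
    activity; fires only on accepted (reinforced) steps."""
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    unit.w_gp += beta * (np.asarray(y_str, dtype=float) - unit.w_gp)


def fe_step(
    unit: GPUnit,
    stack: CorticalStack,
    target_unit: int,
    sigma: float,
    rng: np.random.Generator,
    settle_steps: int = 20,
    context=None,
    beta: float = 0.5,
    lo: float = MFCC_RANGE[0],
    hi: float = MFCC_RANGE[1],
    grid: float | None = None,
    cache: dict | None = None,
    kick_prob: float = 0.0,
    swap_prob: float = 0.0,
    adopt_threshold: float | None = None,
) -> tuple[bool, float]:
    """One propose/evaluate/accept-or-reject move of the free-energy loop.

    Acceptance requires strict improvement (``E < E*``); ties are rejected so
    traces are deterministic given the RNG.  On acceptance the candidate is
    kept, the best error updated and the reinforcement rule applied.

    ``adopt_threshold`` implements the firing trigger: a rejected candidate
    whose error is below the threshold and which makes the target unit win
    the striatal WTA is adopted outright (the unit is marked converged and
    reinforced).  Strict descent alone can overshoot the firing region into
    a deeper, non-firing cone from which it can never return; the firing
    trigger ends the search the moment the unit actually discharges.
    """
    if not unit.evaluated:
        e0, code0 = evaluate_candidate(
            stack, unit.I, target_unit, settle_steps, context, return_code=True
        )
        unit.e_star = e0
        unit.evaluated = True
    cand = propose(unit.I, sigma, rng, lo, hi, grid, kick_prob=kick_prob,
                   swap_prob=swap_prob)
    key = None
    if cache is not None:
        # spend the iteration on a novel ordering: orderings already in the
        # memo table were evaluated before and, by monotonicity of E*, can
        # only be rejected again — re-draw a few times before giving up
        key = np.argsort(-cand, kind="stable").tobytes()
        for _ in range(20):
            if key not in cache:
                break
            cand = propose(unit.I, sigma, rng, lo, hi, grid,
                           kick_prob=kick_prob, swap_prob=swap_prob)
            key = np.argsort(-cand, kind="stable").tobytes()
        if key in cache:
            e = cache[key]
            if e < unit.e_star:  # pragma: no cover - defensive
                cache.pop(key)
            else:
                return False, e
    e, code = evaluate_candidate(
        stack, cand, target_unit, settle_steps, context, return_code=True
    )
    if cache is not None:
        cache[key] = e
    if e < unit.e_star:
        unit.I = cand
        unit.e_star = e
        reinforce(unit, stack.str_.activate(code), beta)
        return True, e
    if adopt_threshold is not None and e <= adopt_threshold and not unit.converged:
        y_str = stack.str_.activate(code)
        if select_winner(y_str) == target_unit:
            unit.I = cand
            unit.e_star = e
            unit.converged = True
            reinforce(unit, y_str, beta)
    return False, e


def optimize_unit(
    stack: CorticalStack,
    target_unit: int,
    budget: int = 2000,
    threshold: float = 0.3,
    sigma: float = 0.05,
    rng: np.random.Generator | None = None,
    unit: GPUnit | None = None,
    settle_steps: int = 20,
    context=None,
    beta: float = 0.5,
    lo: float = MFCC_RANGE[0],
    hi: float = MFCC_RANGE[1],
    grid: float | None = None,
    memoize: bool = True,
    require_winner: bool = False,
    patience: int | None = None,
    kick_prob: float = 0.0,
    swap_prob: float = 0.0,
    trace: OptimizationTrace | None = None,
) -> tuple[GPUnit, OptimizationTrace]:
    """Hill-climb the candidate of one STR unit until ``E* <= threshold`` or
    the iteration budget is exhausted (non-convergence is an outcome, not an
    error).

    ``require_winner=True`` additionally demands that the candidate makes the
    target unit *fire*, i.e. win the striatal winner-take-all — the condition
    under which, in the loop's own terms, the unit "discharges maximally".
    Serial-recall pipelines use this form since recall is verified by the
    winner.

    ``patience`` enables exploration resets: after that many consecutive
    rejections the candidate is redrawn uniformly (a GP reset, marked in the
    trace) and the climb restarts, all within the same budget; the best
    candidate seen is restored at the end.  Accepted errors are monotone
    within each reset cycle.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    if unit is None:
        unit = GPUnit(I=rng.uniform(lo, hi, size=stack.m_in), w_gp=np.zeros(stack.n_str))
    trace = trace if trace is not None else OptimizationTrace()
    cache: dict | None = {} if memoize else None

    def _fires() -> bool:
        if not require_winner:
            return True
        w, _ = evaluate_winner(stack, unit.I, settle_steps, context)
        return w == target_unit

    best_i, best_e = unit.I.copy(), unit.e_star
    best_firing: tuple[np.ndarray, float] | None = None
    done = unit.e_star <= threshold and (not unit.evaluated or _fires())
    stall = 0
    spent = 0

    def _register_accept() -> None:
        nonlocal best_i, best_e, best_firing, done
        if unit.e_star < best_e:
            best_i, best_e = unit.I.copy(), unit.e_star
        if unit.e_star <= threshold:
            done = _fires()
            if done:
                best_firing = (unit.I.copy(), unit.e_star)

    while spent < budget and not done:
        accepted, e = fe_step(
            unit, stack, target_unit, sigma, rng,
            settle_steps=settle_steps, context=context, beta=beta,
            lo=lo, hi=hi, grid=grid, cache=cache, kick_prob=kick_prob,
            swap_prob=swap_prob,
            adopt_threshold=threshold if require_winner else None,
        )
        spent += 1
        trace.record(target_unit, e, accepted)
        if unit.converged:  # firing trigger adopted a candidate
            best_firing = (unit.I.copy(), unit.e_star)
            done = True
            break
        if accepted:
            stall = 0
            _register_accept()
        else:
            stall += 1
            if patience is not None and stall >= patience and not done:
                # greedy escape: iterate full 1-swap-neighbourhood sweeps of
                # the current candidate to a local optimum (within budget)
                # before giving up and resetting
                any_improved = False
                m = len(unit.I)
                sweeping = True
                while sweeping and spent < budget and not done:
                    sweeping = False
                    for a in range(m - 1):
                        for b_ in range(a + 1, m):
                            if spent >= budget or done:
                                break
                            cand = unit.I.copy()
                            cand[a], cand[b_] = cand[b_], cand[a]
                            e_sw, code_sw = evaluate_candidate(
                                stack, cand, target_unit, settle_steps, context,
                                return_code=True,
                            )
                            spent += 1
                            acc = e_sw < unit.e_star
                            trace.record(target_unit, e_sw, acc)
                            if acc:
                                unit.I, unit.e_star = cand, e_sw
                                reinforce(unit, stack.str_.activate(code_sw), beta)
                                sweeping = any_improved = True
                                _register_accept()
                            elif (require_winner and e_sw <= threshold):
                                y_sw = stack.str_.activate(code_sw)
                                if select_winner(y_sw) == target_unit:
                                    unit.I, unit.e_star = cand, e_sw
                                    reinforce(unit, y_sw, beta)
                                    best_firing = (unit.I.copy(), unit.e_star)
                                    done = True
                if not any_improved and not done and spent < budget:
                    reset_unit(unit, rng, lo, hi, trace=trace, target_unit=target_unit)
                stall = 0
    if done:
        unit.converged = True
    elif require_winner and best_firing is not None:
        # keep the best candidate that actually fired, even if a later reset
        # cycle found a lower error that was never fire-checked
        unit.I, unit.e_star = best_firing
        unit.evaluated = True
        unit.converged = True
    else:
        if best_e < unit.e_star:
            unit.I, unit.e_star = best_i, best_e
            unit.evaluated = True
        unit.converged = unit.e_star <= threshold and _fires()
    return unit, trace


def reset_unit(
    unit: GPUnit,
    rng: np.random.Generator,
    lo: float = MFCC_RANGE[0],
    hi: float = MFCC_RANGE[1],
    trace: OptimizationTrace | None = None,
    target_unit: int = -1,
) -> GPUnit:
    """Redraw the candidate uniformly and forget the best error, to
    demonstrate re-convergence (possibly to a different solution)."""
    unit.I = rng.uniform(lo, hi, size=len(unit.I))
    unit.e_star = 1.0
    unit.converged = False
    unit.evaluated = False
    if trace is not None:
        trace.mark_reset(target_unit)
    return unit


# ---------------------------------------------------------------------------
# training regimes
# ---------------------------------------------------------------------------


def forced_optimize(
    stack: CorticalStack,
    repertoire: Repertoire,
    rng: np.random.Generator,
    order: np.ndarray | None = None,
    budget: int = 2000,
    threshold: float = 0.3,
    sigma: float = 0.05,
    settle_steps: int = 20,
    contexts: dict | None = None,
    beta: float = 0.5,
    require_winner: bool = False,
    patience: int | None = None,
    kick_prob: float = 0.0,
    swap_prob: float = 0.0,
    trace: OptimizationTrace | None = None,
) -> OptimizationTrace:
    """Forced (serial, externally supervised) regime: units are selected one
    by one in the given order and each is optimized until threshold/budget.

    ``contexts`` optionally maps unit -> STG buffer snapshot for contextual
    evaluation of each unit in the stream position where it categorizes.
    """
    trace = trace if trace is not None else OptimizationTrace()
    units = np.arange(len(repertoire)) if order is None else np.asarray(order)
    for u in units:
        ctx = contexts.get(int(u)) if contexts else None
        steps = 1 if ctx is not None else settle_steps
        optimize_unit(
            stack, int(u), budget=budget, threshold=threshold, sigma=sigma,
            rng=rng, unit=repertoire[int(u)], settle_steps=steps, context=ctx,
            beta=beta, lo=repertoire.lo, hi=repertoire.hi,
            require_winner=require_winner, patience=patience,
            kick_prob=kick_prob, swap_prob=swap_prob, trace=trace,
        )
    return trace


def babble(
    stack: CorticalStack,
    repertoire: Repertoire,
    total_iterations: int,
    sigma: float = 0.05,
    rng: np.random.Generator | None = None,
    threshold: float = 0.3,
    cycle_max: int = 200,
    settle_steps: int = 20,
    beta: float = 0.5,
    trace: OptimizationTrace | None = None,
) -> OptimizationTrace:
    """Self-supervised motor babbling with random exploration.

    The GP holds one continuously evolving candidate.  Each cycle lets the
    striatal winner-take-all pick the unit the candidate excites most and
    runs the free-energy loop on that unit until its error drops below the
    cycle threshold (or the cycle cap); the next cycle is then engaged from
    a noise perturbation of the current candidate, so exploration wanders
    rather than teleporting — no external signal ever chooses the unit.  All
    touched GP units are updated in place.  Iterations are counted per stack
    evaluation so the regime is budget-comparable with
    :func:`forced_optimize`.
    """
    rng = rng if rng is not None else np.random.default_rng()
    trace = trace if trace is not None else OptimizationTrace()
    lo, hi = repertoire.lo, repertoire.hi
    spent = 0
    cand = rng.uniform(lo, hi, size=stack.m_in)  # GP state persists across cycles
    while spent < total_iterations:
        u, y_str = evaluate_winner(stack, cand, settle_steps)
        spent += 1
        unit = repertoire[u]
        e_cand = float(np.clip(1.0 - y_str[u] / stack.y_max_str, 0.0, 1.0))
        if not unit.evaluated or e_cand < unit.e_star:
            unit.I = cand
            unit.e_star = e_cand
            unit.evaluated = True
        cache: dict = {}
        for _ in range(cycle_max):
            if spent >= total_iterations or unit.e_star <= threshold:
                break
            accepted, e = fe_step(
                unit, stack, u, sigma, rng, settle_steps=settle_steps,
                beta=beta, lo=lo, hi=hi, cache=cache,
            )
            trace.record(u, e, accepted)
            spent += 1
        unit.converged = unit.e_star <= threshold
        if spent < total_iterations:
            trace.mark_reset(u)
        # engage the next exploration cycle from a perturbed candidate
        cand = propose(unit.I, sigma, rng, lo, hi)
    return trace


# ---------------------------------------------------------------------------
# serial recall
# ---------------------------------------------------------------------------


@dataclass
class RecallResult:
    frames: np.ndarray    # (T, M) emitted candidate vectors
    winners: np.ndarray   # (T,) STR winner under each emission
    matches: np.ndarray   # (T,) bool, winner == goal
    gaps: np.ndarray      # (T,) bool, unit was not converged

    def longest_match_run(self) -> int:
        best = cur = 0
        for m in self.matches:
            cur = cur + 1 if m else 0
            best = max(best, cur)
        return best


def serial_recall(
    stack: CorticalStack,
    repertoire: Repertoire,
    goal_sequence,
    dwell: int = 1,
    reset_each: bool = False,
) -> RecallResult:
    """Externally ordered (PFC-like) recall: emit each goal unit's retrieved
    vector in order and drive the stack with it to verify that the recalled
    STR winner equals the goal index.

    ``dwell`` holds each emission for that many ticks (the winner is read at
    the last tick); ``reset_each`` resets the STG buffer at each emission
    onset, matching the stride-free block presentation used in training.
    Non-converged units are flagged as gaps (their best-so-far vector is
    still emitted so the stream dynamics continue).  Unknown indices raise.
    """
    goal_sequence = list(goal_sequence)
    for g in goal_sequence:
        if not 0 <= g < len(repertoire):
            raise IndexError(f"goal unit {g} outside repertoire")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    t_len = len(goal_sequence)
    frames = np.zeros((t_len, stack.m_in))
    winners = np.zeros(t_len, dtype=int)
    matches = np.zeros(t_len, dtype=bool)
    gaps = np.zeros(t_len, dtype=bool)
    stack.reset_buffer()
    for t, g in enumerate(goal_sequence):
        unit = repertoire[g]
        gaps[t] = not unit.converged
        frames[t] = unit.I
        if reset_each:
            stack.reset_buffer()
        for _ in range(dwell):
            _, _, _, b = stack.step(unit.I, learn=False)
        winners[t] = b
        matches[t] = b == g
    return RecallResult(frames, winners, matches, gaps)
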