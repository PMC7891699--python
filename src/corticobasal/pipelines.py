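"""End-to-end benchmark workflows on synthetic data.

These functions reproduce, at desk scale, the study conditions of the two
experiments: categorization of a prototype stream with one striatal unit per
item (the 1:1 "orthogonal representation" of experiment 1), free-energy
retrieval of the prototypes (forced and babbling regimes), per-period
reconstruction improvement, serial recall of a long sequence, and
correspondence matching across synthetic "speakers".

Stimuli are presented stride-free, in blocks: each prototype is held at the
input for one STG window while the buffer is reset at stimulus onset, so
every item is categorized from its own settled dynamics — the regime in
which evaluation, training and recall see identical dynamics and retrieval
can be verified deterministically.  The striatum is taught serially (one
unit per item, the PFC-like teaching signal); PAC and STG remain
unsupervised throughout.

All randomness flows from a single seed; child seeds are derived with
``numpy`` seed spawning so every stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bg import (
    NullTrace,
    OptimizationTrace,
    Repertoire,
    babble,
    evaluate_winner,
    forced_optimize,
    serial_recall,
)
from .cortex import CorticalStack
from .evaluation import correspondence_and_abx, reconstruction_error
from .synth import PrototypeBank, make_prototypes, make_sequence, speaker_transform

__all__ = [
    "CategorizationResult",
    "categorization_benchmark",
    "forced_repertoire",
    "planted_recovery",
    "per_period_reconstruction",
    "forced_vs_babble",
    "serial_recall_benchmark",
    "speaker_generalization",
]

#: stimulus dwell = one STG window (stride-free block presentation)
DWELL = 20


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _block_frames(vectors: np.ndarray, dwell: int, noise_sigma: float,
                  rng: np.random.Generator | None, lo: float, hi: float):
    frames = np.repeat(vectors, dwell, axis=0)
    if noise_sigma > 0:
        frames = np.clip(
            frames + rng.normal(0.0, noise_sigma * (hi - lo), size=frames.shape),
            lo, hi,
        )
    targets = np.repeat(np.arange(len(vectors)), dwell)
    return frames, targets


@dataclass
class CategorizationResult:
    bank: PrototypeBank
    stack: CorticalStack
    train_log: object
    goals: np.ndarray  # winner unit per prototype under settled evaluation


def categorization_benchmark(
    seed: int,
    k: int = 100,
    n_str: int | None = None,
    dwell: int = DWELL,
    periods: int = 4,
    noise_sigma: float = 0.0,
    d_min: float = 300.0,
) -> CategorizationResult:
    """Train the stack on ``k`` prototypes, one STR unit per item, and map
    each prototype to the unit that categorizes it (settled evaluation)."""
    s_bank, s_noise, s_stack = _child_seeds(seed, 3)
    n_str = k if n_str is None else n_str
    bank = make_prototypes(k, d_min=d_min, seed=s_bank)
    rng = np.random.default_rng(s_noise)
    frames, targets = _block_frames(
        bank.vectors, dwell, noise_sigma, rng, bank.lo, bank.hi
    )
    stack = CorticalStack(n_str=n_str, seed=s_stack)
    log = stack.train(frames, periods=periods, reset_every=dwell, str_targets=targets)
    goals = np.array(
        [evaluate_winner(stack, v, dwell)[0] for v in bank.vectors]
    )
    return CategorizationResult(bank, stack, log, goals)


def forced_repertoire(
    stack: CorticalStack,
    seed: int,
    budget: int = 2000,
    threshold: float = 0.3,
    sigma: float = 0.05,
    settle_steps: int = DWELL,
    order: np.ndarray | None = None,
    require_winner: bool = True,
    patience: int | None = 400,
    kick_prob: float = 0.2,
    swap_prob: float = 0.2,
    record_trace: bool = True,
) -> tuple[Repertoire, OptimizationTrace]:
    """Forced serial optimization of the STR units (all, or a given order)."""
    rng = np.random.default_rng(seed)
    rep = Repertoire(stack.n_str, m=stack.m_in, rng=rng)
    trace = OptimizationTrace() if record_trace else NullTrace()
    forced_optimize(
        stack, rep, rng, order=order, budget=budget, threshold=threshold,
        sigma=sigma, settle_steps=settle_steps, require_winner=require_winner,
        patience=patience, kick_prob=kick_prob, swap_prob=swap_prob, trace=trace,
    )
    return rep, trace


def planted_recovery(
    seed: int,
    k: int = 100,
    budget: int = 2000,
    threshold: float = 0.3,
    **bench_kwargs,
) -> dict:
    """Planted-prototype benchmark: train on ``k`` prototypes with one STR
    unit each, retrieve every unit's input, and measure convergence and the
    normalized distance between each retrieved vector and the prototype its
    unit categorizes."""
    bench = categorization_benchmark(seed, k=k, **bench_kwargs)
    rep, _ = forced_repertoire(
        bench.stack, _child_seeds(seed + 1, 1)[0], budget=budget,
        threshold=threshold, record_trace=False,
    )
    norm = (bench.bank.hi - bench.bank.lo) * np.sqrt(bench.bank.m)
    dist = np.linalg.norm(rep.I[bench.goals] - bench.bank.vectors, axis=1) / norm
    return {
        "bench": bench,
        "repertoire": rep,
        "converged_fraction": rep.converged_fraction(),
        "proto_unit_distances": dist,
        "injective": len(set(bench.goals.tolist())) == bench.bank.k,
    }


def per_period_reconstruction(
    seed: int,
    k: int = 50,
    dwell: int = DWELL,
    periods: int = 4,
    budget_per_period: int = 40,
    threshold: float = 0.3,
    sigma: float = 0.05,
    noise_sigma: float = 0.02,
) -> np.ndarray:
    """Mean normalized reconstruction error after each training period.

    Each period interleaves one noisy training pass with one forced
    optimization round (the repertoire persists across periods), then
    measures the mean distance from each prototype to its nearest retrieved
    vector — the per-period refinement of the retrieved repertoire.
    """
    s_bank, s_noise, s_stack, s_opt = _child_seeds(seed, 4)
    bank = make_prototypes(k, seed=s_bank)
    rng_noise = np.random.default_rng(s_noise)
    stack = CorticalStack(n_str=k, seed=s_stack)
    rng = np.random.default_rng(s_opt)
    rep = Repertoire(stack.n_str, m=stack.m_in, rng=rng)
    errors = np.empty(periods)
    for p in range(periods):
        frames, targets = _block_frames(
            bank.vectors, dwell, noise_sigma, rng_noise, bank.lo, bank.hi
        )
        stack.train(frames, periods=1, reset_every=dwell, str_targets=targets)
        forced_optimize(
            stack, rep, rng, budget=budget_per_period, threshold=threshold,
            sigma=sigma, settle_steps=dwell, patience=400, kick_prob=0.2,
            swap_prob=0.2, trace=NullTrace(),
        )
        dist, _, _ = reconstruction_error(rep.I, bank.vectors, bank.lo, bank.hi,
                                          space="code")
        errors[p] = dist.mean()
    return errors


def forced_vs_babble(
    seed: int,
    k: int = 100,
    budget_per_unit: int = 60,
    threshold: float = 0.3,
    sigma: float = 0.05,
    **bench_kwargs,
) -> dict:
    """Converged-unit fractions of the two regimes at equal total budget."""
    bench = categorization_benchmark(seed, k=k, **bench_kwargs)
    s_forced, s_babble = _child_seeds(seed + 1, 2)
    dwell = bench_kwargs.get("dwell", DWELL)

    # both regimes use the same convergence notion (error below threshold)
    rep_f, _ = forced_repertoire(
        bench.stack, s_forced, budget=budget_per_unit, threshold=threshold,
        sigma=sigma, settle_steps=dwell, require_winner=False,
        record_trace=False,
    )
    rng = np.random.default_rng(s_babble)
    rep_b = Repertoire(bench.stack.n_str, m=bench.stack.m_in, rng=rng)
    babble(
        bench.stack, rep_b, total_iterations=budget_per_unit * k,
        sigma=sigma, rng=rng, threshold=threshold, settle_steps=dwell,
        trace=NullTrace(),
    )
    return {
        "forced_fraction": rep_f.converged_fraction(),
        "babble_fraction": rep_b.converged_fraction(),
        "bench": bench,
    }


def serial_recall_benchmark(
    seed: int,
    n: int = 1200,
    periods: int = 8,
    budget: int = 2000,
    threshold: float = 0.3,
    sigma: float = 0.05,
    d_min: float = 300.0,
    dwell: int = DWELL,
) -> dict:
    """Serial recall of a long noiseless sequence through the actor loop.

    ``n`` distinct well-separated vectors are presented in temporal order
    with one STR unit per item (orthogonal representation); the goal
    sequence is the trained stack's own categorization of the stream; every
    goal unit's input vector is retrieved by forced free-energy optimization
    and the whole sequence is then recalled by driving the stack with the
    emissions.  Reports the longest run of consecutive frames whose recalled
    STR winner matches the goal.
    """
    bench = categorization_benchmark(
        seed, k=n, dwell=dwell, periods=periods, noise_sigma=0.0, d_min=d_min
    )
    goals = bench.goals
    rep, _ = forced_repertoire(
        bench.stack, _child_seeds(seed + 1, 1)[0], budget=budget,
        threshold=threshold, sigma=sigma, settle_steps=dwell,
        order=np.unique(goals), record_trace=False,
    )
    result = serial_recall(bench.stack, rep, goals, dwell=dwell, reset_each=True)
    return {
        "longest_run": result.longest_match_run(),
        "match_fraction": float(result.matches.mean()),
        "n": n,
        "goals": goals,
        "recall": result,
        "repertoire": rep,
        "converged_fraction": float(
            np.mean([rep[int(g)].converged for g in goals])
        ),
    }


def speaker_generalization(
    seed: int,
    k: int = 60,
    n_speakers: int = 3,
    budget: int = 800,
    threshold: float = 0.3,
    gain_jitter: float = 0.08,
    offset_sigma: float = 0.03,
    warp_sigma: float = 0.05,
    **bench_kwargs,
) -> dict:
    """Correspondence matching on unheard synthetic speakers.

    The stack and repertoire are learned from one clean "speaker"; the test
    database concatenates affine/warped renditions of the prototype bank from
    ``n_speakers`` unheard voices.  Exact matches (B == A) are compared with
    the chance level of a random assignment, 1/#database.
    """
    bench = categorization_benchmark(seed, k=k, **bench_kwargs)
    rep, _ = forced_repertoire(
        bench.stack, _child_seeds(seed + 1, 1)[0], budget=budget,
        threshold=threshold, record_trace=False,
    )
    rng = np.random.default_rng(_child_seeds(seed + 2, 1)[0])
    base = make_sequence(bench.bank, length=bench.bank.k, dwell=1,
                         noise_sigma=0.0, seed=0, balanced=True)
    base.frames = bench.bank.vectors.copy()
    base.labels = np.arange(bench.bank.k)
    db_frames = []
    full_range = bench.bank.hi - bench.bank.lo
    for _ in range(n_speakers):
        tr = speaker_transform(
            base,
            gain=1.0 + rng.normal(0.0, gain_jitter),
            offset=rng.normal(0.0, offset_sigma * full_range),
            warp_sigma=warp_sigma,
            seed=int(rng.integers(2**31)),
        )
        db_frames.append(tr.frames)
    database = np.vstack(db_frames)
    matrix, hist = correspondence_and_abx(
        database, rep.I, database, bench.bank.lo, bench.bank.hi
    )
    chance = 1.0 / len(database)
    return {
        "matrix": matrix,
        "abx_hist": hist,
        "exact_match_fraction": matrix.exact_match_fraction,
        "chance_level": chance,
        "mean_abx": float(matrix.abx.mean()),
        "bench": bench,
        "repertoire": rep,
    }
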