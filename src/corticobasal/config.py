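"""Run configuration: one plain-text (YAML) file, validated, CLI-overridable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid configuration: {msg}")


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline with documented ranges."""

    # layer sizes
    n_pac: int = 50
    n_stg: int = 50
    n_str: int = 100
    m_in: int = 12
    window: int = 20
    # rank function
    rank_kind: str = "harmonic"      # harmonic | power
    rank_exponent: float = 1.0
    # plasticity schedule
    alpha_init: float = 0.9          # (0, 1]
    gamma: float = 0.98              # (0, 1]
    alpha_min: float = 0.01          # (0, alpha_init]
    beta: float = 0.5                # GP reinforcement rate, (0, 1]
    # actor search
    sigma: float = 0.05              # noise sd as fraction of range, > 0
    settle_steps: int = 20           # >= 1
    threshold: float = 0.3           # convergence error level, [0, 1]
    budget: int = 2000               # iterations per unit, >= 1
    # training
    periods: int = 4                 # >= 1
    dwell: int = 25
    noise_sigma: float = 0.02
    k_prototypes: int = 100
    d_min: float = 300.0
    # audio framing
    frame_ms: int = 25
    stride_ms: int = 10              # in {10, 25}, <= frame_ms
    range_lo: float = 0.0
    range_hi: float = 1200.0
    # run
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        _check(self.n_pac >= 1 and self.n_stg >= 1 and self.n_str >= 1, "layer sizes >= 1")
        _check(self.n_pac == self.n_stg, "n_pac must equal n_stg")
        _check(self.m_in >= 1, "m_in >= 1")
        _check(self.window >= 0, "window >= 0")
        _check(self.rank_kind in ("harmonic", "power"), "rank_kind")
        _check(self.rank_exponent > 0, "rank_exponent > 0")
        for name in ("alpha_init", "gamma", "beta"):
            v = getattr(self, name)
            _check(0 < v <= 1, f"{name} in (0, 1]")
        _check(0 < self.alpha_min <= self.alpha_init, "alpha_min in (0, alpha_init]")
        _check(self.sigma > 0, "sigma > 0")
        _check(self.settle_steps >= 1, "settle_steps >= 1")
        _check(0 <= self.threshold <= 1, "threshold in [0, 1]")
        _check(self.budget >= 1 and self.periods >= 1, "budget and periods >= 1")
        _check(self.dwell >= 1 and self.k_prototypes >= 1, "dwell and k >= 1")
        _check(self.noise_sigma >= 0 and self.d_min >= 0, "noise/d_min >= 0")
        _check(self.stride_ms <= self.frame_ms, "stride_ms <= frame_ms")
        _check(self.range_hi > self.range_lo, "range_hi > range_lo")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load, rejecting unknown keys; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
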