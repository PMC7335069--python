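"""Shared permutation-test plumbing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: allowed one-sided / two-sided alternatives for permutation tests
DIRECTIONS = ("high", "low", "most_extreme")


@dataclass
class PermutationResult:
    """Outcome of a permutation test.

    ``p`` always uses the add-one estimator ``(1 + #{null at least as
    extreme}) / (n_perm + 1)`` so it can never be exactly zero and respects
    the floor ``1 / (n_perm + 1)``.  ``direction`` is declared a priori:
    ``"high"`` tests for statistics above the null, ``"low"`` below, and
    ``"most_extreme"`` is two-sided on the magnitude.
    """

    statistic: str
    observed: float
    null_sample: np.ndarray
    p: float
    direction: str
    n_perm: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.null_sample = np.asarray(self.null_sample, dtype=float)

    @property
    def floor(self) -> float:
        return 1.0 / (self.n_perm + 1)


def count_extreme(null: np.ndarray, observed: float, direction: str) -> int:
    """Number of null draws at least as extreme as ``observed``.

    Ties count as extreme, which keeps the estimator valid (conservative).
    """
    null = np.asarray(null, dtype=float)
    if direction == "high":
        return int(np.sum(null >= observed))
    if direction == "low":
        return int(np.sum(null <= observed))
    if direction == "most_extreme":
        return int(np.sum(np.abs(null) >= abs(observed)))
    raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def add_one_p(null: np.ndarray, observed: float, direction: str) -> float:
    """Add-one permutation p-value; never returns 0."""
    null = np.asarray(null, dtype=float)
    return (1 + count_extreme(null, observed, direction)) / (null.size + 1)


def permutation_result(
    statistic: str,
    observed: float,
    null: np.ndarray,
    direction: str,
    seed: int | None = None,
    **meta,
) -> PermutationResult:
    null = np.asarray(null, dtype=float)
    return PermutationResult(
        statistic=statistic,
        observed=float(observed),
        null_sample=null,
        p=add_one_p(null, observed, direction),
        direction=direction,
        n_perm=int(null.size),
        seed=seed,
        meta=dict(meta),
    )
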