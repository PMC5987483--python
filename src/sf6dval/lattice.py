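"""The SF-6D health-state lattice.

The SF-6D classifies health along six dimensions — physical functioning,
role limitation, social functioning, bodily pain, mental health and
vitality — with (6, 4, 5, 6, 5, 5) levels respectively, level 1 being
the best on every dimension.  Choosing one level per dimension defines a
health state, written as a six-digit code: ``111111`` is full health,
``645655`` (every dimension at its worst) is the "pits" state, and the
default lattice contains 6*4*5*6*5*5 = 18,000 states.

This module provides the combinatorial backbone used everywhere else:
parsing and validating state codes, enumerating the lattice in a single
canonical (lexicographic, dimension 1 slowest) order, Hamming-1
adjacency (states differing by exactly one level in exactly one
dimension, giving each state 6-12 neighbours), the dominance partial
order (``a`` dominates ``b`` when ``a`` is at least as healthy on every
dimension and strictly healthier on at least one), and seeded sampling
of states without replacement.

Levels are stored 1-based, exactly as they appear in state codes; any
centering needed for regression happens in the model layer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DIMENSIONS",
    "DEFAULT_LEVEL_COUNTS",
    "HealthState",
    "LatticeSpec",
    "StateFormatError",
    "StateDomainError",
    "parse_state",
    "enumerate_states",
    "neighbors",
    "dominates",
    "sample_states_without_replacement",
    "levels_array",
    "state_index",
]

DIMENSIONS = (
    "physical functioning",
    "role limitation",
    "social functioning",
    "bodily pain",
    "mental health",
    "vitality",
)

DEFAULT_LEVEL_COUNTS = (6, 4, 5, 6, 5, 5)


class StateFormatError(ValueError):
    """Raised for a state code that is not six digit characters."""


class StateDomainError(ValueError):
    """Raised for a syntactically valid code whose level is out of range."""


@dataclass(frozen=True, order=True)
class HealthState:
    """A point on the SF-6D lattice, stored as a 6-tuple of 1-based levels."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != 6 or any(
            not isinstance(l, (int, np.integer)) or l < 1 for l in self.levels
        ):
            raise StateDomainError(
                f"levels must be six integers >= 1, got {self.levels!r}"
            )
        # normalise numpy ints so states hash/compare uniformly
        object.__setattr__(self, "levels", tuple(int(l) for l in self.levels))

    @property
    def code(self) -> str:
        """Six-character digit string, e.g. ``'645655'``."""
        return "".join(str(l) for l in self.levels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


@dataclass(frozen=True)
class LatticeSpec:
    """Level counts per dimension; the default is the SF-6D's (6,4,5,6,5,5)."""

    level_counts: tuple[int, ...] = DEFAULT_LEVEL_COUNTS

    def __post_init__(self) -> None:
        if len(self.level_counts) != 6 or any(
            not isinstance(c, (int, np.integer)) or c < 1 for c in self.level_counts
        ):
            raise ValueError(
                f"level_counts must be six positive integers, got {self.level_counts!r}"
            )
        object.__setattr__(
            self, "level_counts", tuple(int(c) for c in self.level_counts)
        )

    @property
    def n_states(self) -> int:
        return math.prod(self.level_counts)

    @property
    def full_health(self) -> HealthState:
        return HealthState((1,) * 6)

    @property
    def pits(self) -> HealthState:
        return HealthState(self.level_counts)

    def contains(self, state: HealthState) -> bool:
        return all(1 <= l <= c for l, c in zip(state.levels, self.level_counts))

    def validate(self, state: HealthState) -> None:
        for d, (l, c) in enumerate(zip(state.levels, self.level_counts)):
            if not 1 <= l <= c:
                raise StateDomainError(
                    f"level {l} out of range 1..{c} on dimension {d + 1} "
                    f"({DIMENSIONS[d]}) in state {state.levels!r}"
                )


DEFAULT_LATTICE = LatticeSpec()


def parse_state(code: str, spec: LatticeSpec = DEFAULT_LATTICE) -> HealthState:
    """Parse a six-digit state code, validating each level against ``spec``.

    Raises :class:`StateFormatError` for malformed input and
    :class:`StateDomainError` (naming the offending dimension) for a
    digit outside its dimension's range.
    """
    if not isinstance(code, str) or len(code) != 6 or not code.isdigit():
        raise StateFormatError(
            f"state code must be exactly 6 digit characters, got {code!r}"
        )
    levels = tuple(int(ch) for ch in code)
    for d, (l, c) in enumerate(zip(levels, spec.level_counts)):
        if not 1 <= l <= c:
            raise StateDomainError(
                f"digit {l} exceeds range 1..{c} on dimension {d + 1} "
                f"({DIMENSIONS[d]}) in code {code!r}"
            )
    return HealthState(levels)


def enumerate_states(spec: LatticeSpec = DEFAULT_LATTICE) -> list[HealthState]:
    """All states of the lattice in lexicographic order, dimension 1 slowest.

    The order is canonical: covariance matrices, fixtures and serialized
    artefacts all index states this way.
    """
    ranges = [range(1, c + 1) for c in spec.level_counts]
    return [HealthState(t) for t in itertools.product(*ranges)]


def neighbors(state: HealthState, spec: LatticeSpec = DEFAULT_LATTICE) -> list[HealthState]:
    """States differing from ``state`` by exactly +-1 level in exactly one dimension.

    Every state has between 6 and 12 neighbours: the minimum when every
    dimension sits at an endpoint of its range, the maximum when none does.
    """
    spec.validate(state)
    out: list[HealthState] = []
    for d, (l, c) in enumerate(zip(state.levels, spec.level_counts)):
        if l > 1:
            out.append(HealthState(state.levels[:d] + (l - 1,) + state.levels[d + 1:]))
        if l < c:
            out.append(HealthState(state.levels[:d] + (l + 1,) + state.levels[d + 1:]))
    return out


def dominates(a: HealthState, b: HealthState) -> bool:
    """True iff ``a`` is at least as healthy as ``b`` on every dimension and
    strictly healthier on at least one (lower level = better health)."""
    return a.levels != b.levels and all(x <= y for x, y in zip(a.levels, b.levels))


def sample_states_without_replacement(
    spec: LatticeSpec,
    n: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    exclude: Iterable[HealthState] = (),
) -> list[HealthState]:
    """Draw ``n`` distinct states uniformly at random, reproducibly under ``seed``.

    ``exclude`` removes specific states (e.g. full health, which the model
    anchors rather than estimates) from the sampling frame.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    excluded = {state_index(s, spec) for s in exclude}
    total = spec.n_states - len(excluded)
    if n > total:
        raise ValueError(
            f"cannot sample {n} distinct states from a lattice of {total} "
            f"(after {len(excluded)} exclusions)"
        )
    if excluded:
        pool = np.setdiff1d(np.arange(spec.n_states), np.fromiter(excluded, dtype=int))
        idx = rng.choice(pool, size=n, replace=False)
    else:
        idx = rng.choice(spec.n_states, size=n, replace=False)
    return [index_to_state(int(i), spec) for i in idx]


# -- array helpers used by the model layer ---------------------------------

def levels_array(states: Sequence[HealthState]) -> np.ndarray:
    """(n, 6) integer array of 1-based levels."""
    return np.array([s.levels for s in states], dtype=np.int64)


def state_index(state: HealthState, spec: LatticeSpec = DEFAULT_LATTICE) -> int:
    """Position of ``state`` in the canonical enumeration order."""
    spec.validate(state)
    idx = 0
    for l, c in zip(state.levels, spec.level_counts):
        idx = idx * c + (l - 1)
    return idx


def index_to_state(index: int, spec: LatticeSpec = DEFAULT_LATTICE) -> HealthState:
    """Inverse of :func:`state_index`."""
    if not 0 <= index < spec.n_states:
        raise ValueError(f"index {index} outside 0..{spec.n_states - 1}")
    levels = []
    for c in reversed(spec.level_counts):
        levels.append(index % c + 1)
        index //= c
    return HealthState(tuple(reversed(levels)))
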