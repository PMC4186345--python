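"""Stimulus protocol: sequence enumeration, pulse schedules, presentation order.

A stimulus is an ordered list of distinct item indices (1-based), length 1..Lmax.
Each item in a sequence is delivered to the working memory as a rectangular unit
pulse of duration ``alpha``, separated by silent inter-stimulus intervals of
duration ``beta``: the item at position j occupies the half-open interval
``[(j-1)(alpha+beta), j*alpha + (j-1)*beta)``.  Half-open intervals make the
total input gate I(t) well defined at pulse boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, factorial
from typing import Iterable

import numpy as np

__all__ = [
    "SequenceSpec",
    "PulseSchedule",
    "enumerate_sequences",
    "count_chunks",
    "build_schedule",
    "input_vector",
    "presentation_schedule",
    "read_sequences",
    "write_sequences",
]

#: pulse duration and inter-stimulus interval used in every simulation
DEFAULT_ALPHA = 0.75
DEFAULT_BETA = 0.75
#: longest list that can be stored as a primacy gradient (transient memory span)
DEFAULT_LMAX = 4


@dataclass(frozen=True, order=True)
class SequenceSpec:
    """An ordered list of distinct item indices; the stimulus for one trial."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise ValueError("sequence must contain at least one item")
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"item indices must be distinct: {self.items}")
        if any(i < 1 for i in self.items):
            raise ValueError(f"item indices are 1-based: {self.items}")

    @property
    def length(self) -> int:
        return len(self.items)

    @property
    def itemset(self) -> frozenset[int]:
        """The unordered set of items (the chunk receptive set J)."""
        return frozenset(self.items)

    @classmethod
    def from_string(cls, text: str) -> "SequenceSpec":
        """Parse the hyphenated notation, e.g. ``"1-2-3"``."""
        return cls(tuple(int(tok) for tok in text.strip().split("-")))

    def __str__(self) -> str:
        return "-".join(str(i) for i in self.items)


@dataclass(frozen=True)
class PulseSchedule:
    """Onset/offset times of the rectangular input pulses for one sequence."""

    seq: SequenceSpec
    alpha: float
    beta: float
    onsets: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("pulse duration alpha must be positive")
        if self.beta < 0:
            raise ValueError("inter-stimulus interval beta must be non-negative")
        onsets = tuple(
            (j - 1) * (self.alpha + self.beta) for j in range(1, self.seq.length + 1)
        )
        object.__setattr__(self, "onsets", onsets)

    @property
    def offsets(self) -> tuple[float, ...]:
        return tuple(t + self.alpha for t in self.onsets)

    @property
    def duration(self) -> float:
        """Total stimulus duration L*alpha + (L-1)*beta."""
        return self.seq.length * self.alpha + (self.seq.length - 1) * self.beta

    def active_item(self, t: float) -> int | None:
        """Item index whose pulse contains time t, or None during gaps."""
        period = self.alpha + self.beta
        if t < 0:
            return None
        j = int(t // period)  # 0-based position candidate
        if j < self.seq.length and t - j * period < self.alpha:
            return self.seq.items[j]
        return None


def enumerate_sequences(m: int, lmax: int = DEFAULT_LMAX) -> list[SequenceSpec]:
    """All ordered tuples of distinct items from 1..m, lengths 1..lmax.

    Canonical order: by length, then lexicographically.  The count equals
    ``sum(k! * C(m, k) for k in 1..lmax)``.
    """
    if m < 1:
        raise ValueError("item count m must be >= 1")
    if not 1 <= lmax <= m:
        raise ValueError(f"need 1 <= lmax <= m, got lmax={lmax}, m={m}")
    out: list[SequenceSpec] = []
    for k in range(1, lmax + 1):
        for tup in itertools.permutations(range(1, m + 1), k):
            out.append(SequenceSpec(tup))
    return out


def count_chunks(m: int, lmax: int = DEFAULT_LMAX, redundancy: int = 1) -> int:
    """Number of list-chunk cells for m items, lists up to lmax, with
    ``redundancy`` total copies per ordered-list slot."""
    if m < 1 or lmax > m or redundancy < 1:
        raise ValueError("require m >= 1, lmax <= m, redundancy >= 1")
    return redundancy * sum(
        factorial(k) * comb(m, k) for k in range(1, lmax + 1)
    )


def build_schedule(
    seq: SequenceSpec,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> PulseSchedule:
    """Rectangular pulse schedule for one sequence presentation."""
    return PulseSchedule(seq=seq, alpha=alpha, beta=beta)


def input_vector(schedule: PulseSchedule, t: float, m: int) -> np.ndarray:
    """Binary input vector I(t) of length m; at most one entry is 1."""
    out = np.zeros(m)
    item = schedule.active_item(t)
    if item is not None:
        if item > m:
            raise ValueError(f"item {item} exceeds item count m={m}")
        out[item - 1] = 1.0
    return out


def presentation_schedule(
    n_sequences: int,
    trial_index: int,
    mode: str = "cyclic",
    seed: int | None = None,
) -> int:
    """1-based sequence index presented on 1-based ``trial_index``.

    Cyclic mode returns ((trial_index - 1) mod n) + 1.  Shuffled mode permutes
    the order independently within each cycle under a seed, so each cycle still
    presents every sequence exactly once.
    """
    if trial_index < 1:
        raise ValueError("trial_index is 1-based")
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    cycle, pos = divmod(trial_index - 1, n_sequences)
    if mode == "cyclic":
        return pos + 1
    if mode == "shuffled":
        if seed is None:
            raise ValueError("shuffled mode requires a seed")
        rng = np.random.default_rng(np.random.SeedSequence((seed, cycle)))
        return int(rng.permutation(n_sequences)[pos]) + 1
    raise ValueError(f"unknown schedule mode {mode!r}")


def write_sequences(sequences: Iterable[SequenceSpec], path) -> None:
    """One sequence per line, hyphen-separated items."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f"{seq}\n")


def read_sequences(path) -> list[SequenceSpec]:
    with open(path) as fh:
        return [SequenceSpec.from_string(line) for line in fh if line.strip()]
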