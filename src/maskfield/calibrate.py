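"""Calibration of the unpublished off-surround parameters E, F, L, H.

The published parameter set fixes the decay A, bottom-up gain B, on-center
gain D, signal half-maxima f0 and g0, the time constant tau, and the firing
threshold, but not the four inhibitory constants.  Their contract is a
property, not a value: with one parameter set, presenting the probe lists
"1", "1-2", "1-2-3", "1-2-3-4" must select a chunk of matching size on every
catalog size tested, and after selection the field must settle on that
single winner (all other cells below threshold at trial end).

The objective has two parts, both evaluated on the 4- and 5-item catalogs:

* *naive state*: with balanced initial weights, every probe must select a
  matching-size winner and quench all rivals below threshold by trial end;
* *converged state*: with every chunk committed to a distinct sequence and
  its weights at the instar equilibrium (the hardest regime — learned
  weights concentrate on early list items, strengthening large chunks'
  response to their leading sublists), every probe must select its own
  committed chunk, first, with no mismatch resets.  This encodes the
  requirement that classification stays error-free as weights converge.

This module ships the coarse grid search used to fix the packaged defaults
(E = 5, F = 0.5, L = 6, H = 10): the first grid point passing both parts is
accepted.  Re-running it is only needed when changing structural settings
(e.g. the feedforward-inhibition reading).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .field import MFParams, WeightMatrix, build_catalog, init_weights
from .integrate import IntegratorConfig
from .learning import LearningParams, run_trial
from .protocol import SequenceSpec, enumerate_sequences

__all__ = [
    "CalibrationResult",
    "selectivity_objective",
    "converged_selectivity_objective",
    "full_objective",
    "grid_search",
]

#: coarse grid; ordered so the search sweeps H (late-stage competition)
#: fastest and E (overall inhibitory scale) slowest
DEFAULT_GRID = {
    "E": (5.0, 2.0, 10.0),
    "F": (0.5, 0.2, 1.0),
    "L": (6.0, 3.0, 10.0),
    "H": (10.0, 5.0, 20.0, 40.0),
}


@dataclass
class CalibrationResult:
    params: MFParams | None
    n_evaluated: int
    log: list[tuple[dict, bool, str]]

    @property
    def succeeded(self) -> bool:
        return self.params is not None


def selectivity_objective(
    params: MFParams,
    ms: tuple[int, ...] = (4, 5),
    seed: int = 0,
    integ: IntegratorConfig = IntegratorConfig(),
    quench_margin: float = 0.0,
) -> tuple[bool, str]:
    """True iff every probe selects a matching-size winner and quenches.

    Quench: at trial end (five time units after selection) every non-winner
    activity is below threshold minus ``quench_margin``.
    """
    for m in ms:
        catalog = build_catalog(m, lmax=min(4, m))
        weights = init_weights(catalog, rng=np.random.default_rng(seed))
        for length in range(1, min(4, m) + 1):
            seq = SequenceSpec(tuple(range(1, length + 1)))
            try:
                res = run_trial(
                    seq, catalog, weights, mf_params=params,
                    learn_params=LearningParams(eta=0.0),
                    integ=integ, learn=False, record_c=True,
                )
            except FloatingPointError:
                return False, f"m={m} {seq}: diverged"
            if res.winner is None:
                return False, f"m={m} {seq}: no winner in budget"
            if res.winner_size != length:
                return False, (
                    f"m={m} {seq}: winner size {res.winner_size} != {length}"
                )
            c_end = res.c_trace[-1]  # type: ignore[attr-defined]
            others = np.delete(c_end, res.winner)
            if others.size and others.max() >= params.threshold - quench_margin:
                return False, (
                    f"m={m} {seq}: no quench (max rival {others.max():.3f})"
                )
    return True, "ok"


def converged_selectivity_objective(
    params: MFParams,
    ms: tuple[int, ...] = (4, 5),
    integ: IntegratorConfig = IntegratorConfig(),
) -> tuple[bool, str]:
    """Probe the field with fully learned weights and full commitments.

    Every chunk is committed to a distinct sequence over its item set with
    weights at the instar equilibrium (the normalized stored pattern of that
    sequence).  Each probe must select its own committed chunk, first, with
    no mismatch resets — classification must remain error-free once weights
    have converged.
    """
    from .experiments import ground_truth_map

    for m in ms:
        lmax = min(4, m)
        catalog = build_catalog(m, lmax=lmax)
        sequences = enumerate_sequences(m, lmax)
        targets = ground_truth_map(sequences, m=m, dt=integ.dt)
        W = np.zeros((m, catalog.n_chunks))
        taken: set[int] = set()
        for seq in sequences:
            j = next(
                j for j, c in enumerate(catalog.chunks)
                if c.itemset == seq.itemset and j not in taken
            )
            taken.add(j)
            catalog.chunks[j].committed_to = seq
            W[:, j] = targets[str(seq)]
        weights = WeightMatrix(W=W, catalog=catalog)
        lp = LearningParams(eta=0.0, mode="supervised")
        for length in range(1, lmax + 1):
            seq = SequenceSpec(tuple(range(1, length + 1)))
            try:
                res = run_trial(
                    seq, catalog, weights, mf_params=params,
                    learn_params=lp, integ=integ, learn=False,
                )
            except FloatingPointError:
                return False, f"m={m} {seq}: diverged"
            if res.winner is None:
                return False, f"m={m} {seq}: no winner in budget"
            if res.resets:
                first = catalog.chunks[res.resets[0].chunk]
                return False, (
                    f"m={m} {seq}: {len(res.resets)} resets "
                    f"(first a {first.size}-chunk)"
                )
            if catalog.chunks[res.winner].committed_to != seq:
                return False, (
                    f"m={m} {seq}: selected chunk committed to "
                    f"{catalog.chunks[res.winner].committed_to}"
                )
    return True, "ok"


def full_objective(
    params: MFParams,
    ms: tuple[int, ...] = (4, 5),
    seed: int = 0,
    integ: IntegratorConfig = IntegratorConfig(),
) -> tuple[bool, str]:
    """Naive-state and converged-state selectivity combined."""
    ok, msg = selectivity_objective(params, ms=ms, seed=seed, integ=integ)
    if not ok:
        return False, f"naive: {msg}"
    ok, msg = converged_selectivity_objective(params, ms=ms, integ=integ)
    if not ok:
        return False, f"converged: {msg}"
    return True, "ok"


def grid_search(
    grid: dict[str, tuple[float, ...]] | None = None,
    base: MFParams = MFParams(),
    ms: tuple[int, ...] = (4, 5),
    seed: int = 0,
    integ: IntegratorConfig = IntegratorConfig(),
    stop_at_first: bool = True,
) -> CalibrationResult:
    """Coarse grid search; accepts the first passing (E, F, L, H)."""
    grid = dict(DEFAULT_GRID if grid is None else grid)
    names = ("E", "F", "L", "H")
    log: list[tuple[dict, bool, str]] = []
    found: MFParams | None = None
    for values in itertools.product(*(grid[n] for n in names)):
        candidate = dict(zip(names, values))
        params = replace(base, **candidate)
        ok, msg = full_objective(params, ms=ms, seed=seed, integ=integ)
        log.append((candidate, ok, msg))
        if ok:
            found = params
            if stop_at_first:
                break
    return CalibrationResult(params=found, n_evaluated=len(log), log=log)
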