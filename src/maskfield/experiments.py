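"""The three simulation campaigns: selectivity, unsupervised and supervised
learning, plus combinatorial sanity numbers and ground-truth weight targets.

Scale tiers: the fast tier (m = 4, 64 chunks) is what the test suite runs;
the full five-item tier (205 chunks) is minutes-scale and used by the
acceptance script and examples; six to nine items (516-3609 chunks) are
overnight scripts because the all-to-all inhibition grows as the square of
the cell count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import (
    ChunkCatalog,
    GateParams,
    MFParams,
    WeightMatrix,
    build_catalog,
    init_weights,
)
from .integrate import IntegratorConfig
from .learning import LearningParams, LearningReport, run_campaign, run_trial
from .protocol import SequenceSpec, enumerate_sequences
from .store import WMParams, run_wm

__all__ = [
    "SelectivityProbe",
    "SelectivityReport",
    "ground_truth_weights",
    "ground_truth_map",
    "selectivity_experiment",
    "interaction_count",
    "unsupervised_campaign",
    "supervised_campaign",
    "PROBE_SEQUENCES",
]

#: the four probe lists; balanced weights make all same-length lists equivalent
PROBE_SEQUENCES = ("1", "1-2", "1-2-3", "1-2-3-4")


@dataclass
class SelectivityProbe:
    """Outcome of one probe presentation."""

    m: int
    redundancy: int
    sequence: str
    winner: int | None
    winner_size: int | None
    selection_time: float | None

    @property
    def passed(self) -> bool:
        return self.winner_size == len(self.sequence.split("-"))


@dataclass
class SelectivityReport:
    """Winner sizes for the probe lists across (m, redundancy) settings."""

    probes: list[SelectivityProbe]
    params: MFParams

    @property
    def passed(self) -> bool:
        return all(p.passed for p in self.probes)

    def winner_sizes(self, m: int, redundancy: int = 1) -> tuple[int | None, ...]:
        return tuple(
            p.winner_size
            for p in self.probes
            if p.m == m and p.redundancy == redundancy
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "m": p.m,
                    "redundancy": p.redundancy,
                    "sequence": p.sequence,
                    "winner": p.winner,
                    "winner_size": p.winner_size,
                    "selection_time": p.selection_time,
                    "passed": p.passed,
                }
                for p in self.probes
            ]
        )


def ground_truth_weights(
    seq: SequenceSpec,
    wm_params: WMParams = WMParams(),
    m: int | None = None,
    dt: float = 0.005,
) -> np.ndarray:
    """Expected post-learning weight vector for a chunk committed to ``seq``.

    Runs the working memory on the sequence, takes the end-of-presentation
    activity pattern, and normalizes it to sum 1: the instar equilibrium
    x_i / sum_k x_k.  Returned as a length-m vector (zeros off the sequence's
    items).
    """
    m = m if m is not None else max(seq.items)
    traj = run_wm(seq, params=wm_params, m=m, dt=dt)
    x = traj.final_x.copy()
    total = x.sum()
    if total <= 0:
        raise RuntimeError(f"working memory stored no activity for {seq}")
    return x / total


def ground_truth_map(
    sequences: list[SequenceSpec],
    wm_params: WMParams = WMParams(),
    m: int | None = None,
    dt: float = 0.005,
) -> dict[str, np.ndarray]:
    m = m if m is not None else max(max(s.items) for s in sequences)
    return {
        str(s): ground_truth_weights(s, wm_params, m=m, dt=dt)
        for s in sequences
    }


def interaction_count(n_chunks: int) -> int:
    """Inhibitory signals per step in an n-cell all-to-all Masking Field."""
    if n_chunks < 0:
        raise ValueError("n_chunks must be >= 0")
    return n_chunks * n_chunks


def selectivity_experiment(
    ms: tuple[int, ...] = (4, 5),
    redundancies: tuple[int, ...] = (1,),
    mf_params: MFParams = MFParams(),
    gate_params: GateParams = GateParams(),
    wm_params: WMParams = WMParams(),
    integ: IntegratorConfig = IntegratorConfig(),
    p: float = 3e-3,
    seed: int = 0,
) -> SelectivityReport:
    """Present the probe lists with balanced weights and learning off.

    Passes iff every probe of length L selects a winner of size L, for every
    (m, redundancy) pair, under the single frozen parameter set.
    """
    probes: list[SelectivityProbe] = []
    for m in ms:
        for red in redundancies:
            catalog = build_catalog(m, lmax=min(4, m), redundancy=red)
            weights = init_weights(
                catalog, p=p, mode="balanced_permuted",
                rng=np.random.default_rng(seed),
            )
            lp = LearningParams(eta=0.0)
            for text in PROBE_SEQUENCES[: min(4, m)]:
                seq = SequenceSpec.from_string(text)
                result = run_trial(
                    seq, catalog, weights,
                    mf_params=mf_params, gate_params=gate_params,
                    wm_params=wm_params, learn_params=lp, integ=integ,
                    learn=False,
                )
                probes.append(
                    SelectivityProbe(
                        m=m, redundancy=red, sequence=text,
                        winner=result.winner,
                        winner_size=result.winner_size,
                        selection_time=result.selection_time,
                    )
                )
    return SelectivityReport(probes=probes, params=mf_params)


def _campaign(
    m: int,
    init_mode: str,
    learn_mode: str,
    cycles: int,
    seed: int,
    lmax: int = 4,
    eta: float = 0.001,
    learn_during_search: bool = False,
    p: float = 3e-3,
    mf_params: MFParams = MFParams(),
    gate_params: GateParams = GateParams(),
    wm_params: WMParams = WMParams(),
    integ: IntegratorConfig = IntegratorConfig(),
    early_stop: bool = True,
    track_ground_truth: bool = True,
    schedule_mode: str = "cyclic",
) -> LearningReport:
    catalog = build_catalog(m, lmax=lmax)
    sequences = enumerate_sequences(m, lmax)
    rng = np.random.default_rng(seed)
    weights = init_weights(catalog, p=p, mode=init_mode, rng=rng)
    lp = LearningParams(
        eta=eta, mode=learn_mode, learn_during_search=learn_during_search
    )
    gt = (
        ground_truth_map(sequences, wm_params, m=m, dt=integ.dt)
        if track_ground_truth
        else None
    )
    return run_campaign(
        catalog, sequences, weights, cycles,
        mf_params=mf_params, gate_params=gate_params, wm_params=wm_params,
        learn_params=lp, integ=integ, schedule_mode=schedule_mode, seed=seed,
        early_stop=early_stop, ground_truth=gt,
    )


def unsupervised_campaign(
    m: int = 5,
    condition: str = "strict",
    cycles: int = 10,
    seed: int = 0,
    **kwargs,
) -> LearningReport:
    """Unsupervised learning: strict (balanced noise) or weak (free noise).

    Strict at m = 5 targets unique categorization of all 205 sequences; the
    weak condition relaxes the balanced-noise construction and only a
    fraction of sequences end up with a unique chunk.
    """
    if condition not in ("strict", "weak"):
        raise ValueError(f"unknown condition {condition!r}")
    init_mode = "balanced_permuted" if condition == "strict" else "free_random"
    return _campaign(
        m, init_mode=init_mode, learn_mode="unsupervised",
        cycles=cycles, seed=seed, **kwargs,
    )


def supervised_campaign(
    m: int = 5,
    cycles: int = 40,
    seed: int = 0,
    eta: float = 0.1,
    learn_during_search: bool = False,
    **kwargs,
) -> LearningReport:
    """Supervised learning: free-random weights with mismatch reset search.

    Defaults differ from the unsupervised campaign in two ways.  The
    learning rate is ten times larger: supervised weight convergence is
    reported after roughly forty presentations per sequence versus roughly
    four hundred forty unsupervised, and with an identical rate the (same)
    instar law in the (same) post-selection window could not be faster.
    And learning is restricted to the selected winner: letting transiently
    suprathreshold cells learn during the reset search teaches wrongly
    selected chunks the presented sequence, which at this rate destabilizes
    the search instead of merely slowing it.
    """
    return _campaign(
        m, init_mode="free_random", learn_mode="supervised",
        cycles=cycles, seed=seed, eta=eta,
        learn_during_search=learn_during_search, **kwargs,
    )
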