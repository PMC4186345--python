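"""Adaptive-filter learning, trial execution, and campaign bookkeeping.

The bottom-up weights adapt by competitive instar learning,

    dW_ij/dt = eta * f(c_j) * [ (1 - W_ij) x_i - W_ij Σ_{k≠i} x_k ]
             = eta * f(c_j) * [ x_i - W_ij Σ_k x_k ],

so each active chunk's weight vector is attracted to the normalized pattern
x_i / Σ_k x_k stored in working memory while the chunk is active.  Learning
is gated postsynaptically by f(c_j): only a chunk with substantial activity
(in practice, the winner after its threshold crossing) learns at a
meaningful rate.

A trial co-integrates working memory, habituative gates, Masking Field, and
(optionally) the instar law on one clock.  In unsupervised mode the first
cell to cross the firing threshold is the winner.  In supervised mode a
crossing by a cell already committed to a *different* sequence is a
predictive error: the cell's reset gate is switched off for the rest of the
trial (removing its bottom-up input and self-excitation) and the search
continues until an admissible cell crosses.  The trial ends a fixed time
after the winner is selected, and the winner becomes committed to the
presented sequence if it was uncommitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import (
    ChunkCatalog,
    GateParams,
    MFParams,
    MFState,
    WeightMatrix,
    f_signal,
    feedforward_inhibition,
    g_signal,
    gate_derivatives,
    inhibitory_coefficients,
)
from ._core import HAVE_NUMBA, trial_core
from .integrate import IntegratorConfig
from .protocol import (
    SequenceSpec,
    build_schedule,
    input_vector,
    presentation_schedule,
)
from .store import WMParams, WMState, wm_derivatives

__all__ = [
    "LearningParams",
    "ResetEvent",
    "TrialResult",
    "LearningReport",
    "instar_derivatives",
    "reset_gate_update",
    "run_trial",
    "run_campaign",
    "WMCache",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class LearningParams:
    """Instar learning settings."""

    eta: float = 0.001              # learning rate
    post_selection_time: float = 5.0  # trial continues this long after selection
    mode: str = "unsupervised"      # "unsupervised" | "supervised"
    # Restrict learning to the selected winner (the protocol's "learning
    # occurred only when ... a list chunk was selected").  The literal
    # alternative — instar updates for every cell whenever f(c_j) > 0 —
    # is available as True, but lets the co-climbing cohort absorb a
    # little of every presented pattern, and the resulting drift makes
    # committed chunks' weight error grow instead of shrink.
    learn_during_search: bool = False
    wta_on_selection: bool = True   # selection closes competitors' gates (see run_trial)

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.post_selection_time <= 0:
            raise ValueError("post_selection_time must be positive")
        if self.mode not in ("unsupervised", "supervised"):
            raise ValueError(f"unknown learning mode {self.mode!r}")


@dataclass(frozen=True)
class ResetEvent:
    """A supervised mismatch reset: a committed cell selected by the wrong list."""

    time: float
    chunk: int
    presented: SequenceSpec
    committed_to: SequenceSpec


@dataclass
class TrialResult:
    """Outcome of one sequence presentation."""

    seq: SequenceSpec
    winner: int | None
    winner_size: int | None
    selection_time: float | None
    resets: list[ResetEvent]
    failed: bool
    trial_time: float

    @property
    def n_resets(self) -> int:
        return len(self.resets)


def instar_derivatives(
    W: np.ndarray,
    x: np.ndarray,
    c: np.ndarray,
    support: np.ndarray,
    eta: float = 0.001,
    f0: float = 0.75,
) -> np.ndarray:
    """Competitive instar right-hand side dW (zero off each chunk's support)."""
    gate = eta * f_signal(c, f0)
    return support * gate[None, :] * (x[:, None] - W * x.sum())


def reset_gate_update(
    state: MFState,
    catalog: ChunkCatalog,
    presented: SequenceSpec,
    newly_crossed: np.ndarray,
    t: float,
    threshold: float = 0.2,
) -> tuple[int | None, list[ResetEvent]]:
    """Supervised selection step for cells that just crossed threshold.

    Processes crossings in descending activity order (the most active cell is
    the one "selected").  A cell committed to a different sequence is reset
    (R_j = 0 for the rest of the trial) and logged; the first admissible cell
    (uncommitted, or committed to the presented sequence) is returned as the
    winner.  Mutates ``state.R`` in place.
    """
    events: list[ResetEvent] = []
    order = newly_crossed[np.argsort(-state.c[newly_crossed], kind="stable")]
    for j in order:
        j = int(j)
        committed = catalog.chunks[j].committed_to
        if committed is not None and committed != presented:
            state.R[j] = 0.0
            events.append(
                ResetEvent(time=t, chunk=j, presented=presented,
                           committed_to=committed)
            )
        else:
            return j, events
    return None, events


class WMCache:
    """Per-sequence cache of working-memory layer-1 trajectories.

    x(t) is independent of the Masking Field and of learning, and is frozen
    (dx = 0) once the last pulse ends, so it is integrated once per sequence
    over the presentation window and held constant afterwards.
    """

    def __init__(
        self,
        m: int,
        wm_params: WMParams,
        integ: IntegratorConfig,
        alpha: float,
        beta: float,
    ) -> None:
        self.m = m
        self.wm_params = wm_params
        self.integ = integ
        self.alpha = alpha
        self.beta = beta
        self._store: dict[tuple[int, ...], np.ndarray] = {}

    def trajectory(self, seq: SequenceSpec) -> np.ndarray:
        """(T_pres + 1, m) array of x over [0, L*(alpha+beta)]."""
        key = seq.items
        if key not in self._store:
            schedule = build_schedule(seq, self.alpha, self.beta)
            self.integ.check_divides(self.alpha, "alpha")
            self.integ.check_divides(self.beta, "beta")
            t_end = seq.length * (self.alpha + self.beta)
            n_steps = int(round(t_end / self.integ.dt))
            xs = np.zeros((n_steps + 1, self.m))
            state = WMState.zeros(self.m)
            for k in range(n_steps):
                inputs = input_vector(schedule, k * self.integ.dt, self.m)
                dx, dy = wm_derivatives(state, inputs, self.wm_params)
                state.x = state.x + self.integ.dt * dx
                state.y = state.y + self.integ.dt * dy
                xs[k + 1] = state.x
            self._store[key] = xs
        return self._store[key]


def run_trial(
    seq: SequenceSpec,
    catalog: ChunkCatalog,
    weights: WeightMatrix,
    mf_params: MFParams = MFParams(),
    gate_params: GateParams = GateParams(),
    wm_params: WMParams = WMParams(),
    learn_params: LearningParams = LearningParams(),
    integ: IntegratorConfig = IntegratorConfig(),
    masking: np.ndarray | None = None,
    wm_cache: WMCache | None = None,
    alpha: float = 0.75,
    beta: float = 0.75,
    learn: bool = True,
    record_c: bool = False,
    use_jit: bool | None = None,
) -> TrialResult:
    """Run one presentation trial, mutating ``weights.W`` if learning is on.

    Dynamic state (x, y, c, Z, R) starts from rest; weights and commitments
    persist across trials.  Returns a :class:`TrialResult`; a trial with no
    winner inside the time budget is flagged failed, never silent.

    ``use_jit`` selects the compiled trial loop (default: whenever available
    and no activity trace is requested); both loops implement the identical
    update.
    """
    if wm_cache is None:
        wm_cache = WMCache(catalog.m, wm_params, integ, alpha, beta)
    if masking is None:
        masking = inhibitory_coefficients(catalog)
    xs = wm_cache.trajectory(seq)
    t_pres = xs.shape[0] - 1  # step index where presentation ends
    dt = integ.dt
    n = catalog.n_chunks
    state = MFState.resting(catalog.m, n)
    W = weights.W
    masking_T = np.ascontiguousarray(masking.T)
    support = catalog.support
    sizes = catalog.sizes.astype(float)
    p = mf_params
    supervised = learn_params.mode == "supervised"
    threshold = p.threshold

    winner: int | None = None
    selection_time: float | None = None
    resets: list[ResetEvent] = []
    processed = np.zeros(n, dtype=bool)
    c_samples: list[np.ndarray] = []
    z_samples: list[np.ndarray] = []
    max_steps = int(round(integ.max_trial_time / dt))

    if use_jit is None:
        use_jit = HAVE_NUMBA and not record_c
    if use_jit:
        admissible = np.array(
            [
                chunk.committed_to is None or chunk.committed_to == seq
                for chunk in catalog.chunks
            ]
        )
        w_id, sel_t, r_chunks, r_times, end_step, status = trial_core(
            xs, W, support, sizes, masking_T, admissible,
            p.A, p.B, p.D, p.E, p.F, p.L, p.H, p.f0, p.g0, p.tau,
            threshold, p.ffi_mode == "weighted",
            gate_params.epsilon, gate_params.lam, gate_params.mu,
            learn_params.eta if learn else 0.0,
            learn_params.post_selection_time, dt, max_steps,
            learn, learn_params.learn_during_search,
            learn_params.wta_on_selection, supervised,
        )
        if status == -2:
            raise FloatingPointError(
                f"Masking Field diverged during trial for sequence {seq}"
            )
        winner = None if w_id < 0 else int(w_id)
        selection_time = None if w_id < 0 else float(sel_t)
        for rc, rt in zip(r_chunks, r_times):
            resets.append(
                ResetEvent(
                    time=float(rt), chunk=int(rc), presented=seq,
                    committed_to=catalog.chunks[int(rc)].committed_to,
                )
            )
        failed = winner is None
        if not failed and learn:
            chunk = catalog.chunks[winner]
            if chunk.committed_to is None:
                chunk.committed_to = seq
        return TrialResult(
            seq=seq,
            winner=winner,
            winner_size=None if failed else int(sizes[winner]),
            selection_time=selection_time,
            resets=resets,
            failed=failed,
            trial_time=min(end_step * dt, integ.max_trial_time),
        )

    for step in range(max_steps):
        t = step * dt
        x = xs[step] if step <= t_pres else xs[t_pres]
        c, Z, R = state.c, state.Z, state.R
        u = x * Z
        bottom_up = p.B * (W.T @ u)
        exc = R * (bottom_up + p.D * sizes * f_signal(c, p.f0))
        ffi = feedforward_inhibition(x, Z, W, catalog, p.ffi_mode)
        inh = p.L * ffi + p.H * (masking_T @ g_signal(c, p.g0))
        dc = (-p.A * c + (1.0 - c) * exc - p.E * (c + p.F) * inh) / p.tau
        dZ = gate_derivatives(Z, x, gate_params)
        if learn and learn_params.eta > 0 and (
            learn_params.learn_during_search or winner is not None
        ):
            if winner is not None and not learn_params.learn_during_search:
                gate = np.zeros(n)
                gate[winner] = f_signal(c[winner], p.f0)
                dW = support * (learn_params.eta * gate)[None, :] * (
                    x[:, None] - W * x.sum()
                )
            else:
                dW = instar_derivatives(
                    W, x, c, support, learn_params.eta, p.f0
                )
            W += dt * dW
        state.c = c + dt * dc
        state.Z = Z + dt * dZ
        if not np.all(np.isfinite(state.c)):
            raise FloatingPointError(
                f"Masking Field diverged at t={t:.3f} for sequence {seq}"
            )
        if record_c and step % integ.sample_stride == 0:
            c_samples.append(state.c.copy())
            z_samples.append(state.Z.copy())
        t_next = (step + 1) * dt

        if winner is None:
            crossed = (state.c >= threshold) & (state.R > 0) & ~processed
            if crossed.any():
                ids = np.nonzero(crossed)[0]
                processed[ids] = True
                if supervised:
                    winner, events = reset_gate_update(
                        state, catalog, seq, ids, t_next, threshold
                    )
                    resets.extend(events)
                else:
                    # first crossing wins; highest activity, lowest id on ties
                    order = ids[np.argsort(-state.c[ids], kind="stable")]
                    winner = int(order[0])
                if winner is not None:
                    selection_time = t_next
                    if learn_params.wta_on_selection:
                        # Reaching the firing threshold ensures the cell wins
                        # the competition and inhibits all other cells: the
                        # competitors' gates close (as in a mismatch reset),
                        # removing their bottom-up input and self-excitation,
                        # and decay plus the winner's asymmetric inhibition
                        # quenches them below threshold.
                        state.R[:] = 0.0
                        state.R[winner] = 1.0
        elif t_next >= selection_time + learn_params.post_selection_time:
            break

    failed = winner is None
    if not failed and learn:
        chunk = catalog.chunks[winner]
        if chunk.committed_to is None:
            chunk.committed_to = seq
    result = TrialResult(
        seq=seq,
        winner=winner,
        winner_size=None if failed else int(sizes[winner]),
        selection_time=selection_time,
        resets=resets,
        failed=failed,
        trial_time=min((step + 1) * dt, integ.max_trial_time),
    )
    if record_c:
        result.c_trace = np.asarray(c_samples)  # type: ignore[attr-defined]
        result.z_trace = np.asarray(z_samples)  # type: ignore[attr-defined]
    return result


@dataclass
class LearningReport:
    """Summary of a multi-trial learning campaign."""

    n_sequences: int
    cycles_run: int
    winner_map: dict[str, int | None]          # sequence -> final winner chunk
    n_uniquely_learned: int
    fraction_unique: float
    reset_series: list[int]                    # per-trial reset counts
    selection_times: dict[str, list[float]]    # per-sequence selection times
    weight_error_series: list[float]           # per-cycle mean L1 error
    unique_series: list[int]                   # per-cycle uniquely-mapped count
    n_failed_trials: int
    seed: int | None
    trial_rows: list[dict] = dc_field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "cycles_run": self.cycles_run,
            "n_uniquely_learned": self.n_uniquely_learned,
            "fraction_unique": self.fraction_unique,
            "n_failed_trials": self.n_failed_trials,
            "seed": self.seed,
            "winner_map": {k: (int(v) if v is not None else None)
                           for k, v in self.winner_map.items()},
            "reset_series": self.reset_series,
            "weight_error_series": self.weight_error_series,
            "unique_series": self.unique_series,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trial_rows)


def _unique_count(winner_map: dict[str, int | None]) -> int:
    """Sequences whose final winner is shared with no other sequence."""
    from collections import Counter

    counts = Counter(v for v in winner_map.values() if v is not None)
    return sum(
        1 for v in winner_map.values() if v is not None and counts[v] == 1
    )


def run_campaign(
    catalog: ChunkCatalog,
    sequences: list[SequenceSpec],
    weights: WeightMatrix,
    cycles: int,
    mf_params: MFParams = MFParams(),
    gate_params: GateParams = GateParams(),
    wm_params: WMParams = WMParams(),
    learn_params: LearningParams = LearningParams(),
    integ: IntegratorConfig = IntegratorConfig(),
    alpha: float = 0.75,
    beta: float = 0.75,
    schedule_mode: str = "cyclic",
    seed: int | None = None,
    early_stop: bool = True,
    ground_truth: dict[str, np.ndarray] | None = None,
    checkpoint_dir: str | None = None,
    start_cycle: int = 0,
) -> LearningReport:
    """Run ``cycles`` full passes over ``sequences`` with persistent weights.

    Presentation order follows :func:`maskfield.protocol.presentation_schedule`.
    With ``early_stop``, the campaign ends once the sequence -> winner map has
    been stable (and, in supervised mode, reset-free) for two consecutive
    cycles.  ``ground_truth`` optionally maps sequence strings to normalized
    target weight vectors for the per-cycle weight-error series.

    ``checkpoint_dir`` writes the weights and commitments after every cycle;
    a stopped campaign resumes by restoring them with
    :func:`load_checkpoint` and passing the recorded next cycle as
    ``start_cycle`` (which only offsets the presentation-schedule trial
    index; reports cover the resumed portion).
    """
    n_seq = len(sequences)
    masking = inhibitory_coefficients(catalog)
    wm_cache = WMCache(catalog.m, wm_params, integ, alpha, beta)
    winner_map: dict[str, int | None] = {}
    selection_times: dict[str, list[float]] = {str(s): [] for s in sequences}
    reset_series: list[int] = []
    weight_errors: list[float] = []
    unique_series: list[int] = []
    trial_rows: list[dict] = []
    n_failed = 0
    prev_maps: list[dict[str, int | None]] = []
    cycles_run = 0

    for cycle in range(start_cycle, start_cycle + cycles):
        cycle_resets = 0
        for pos in range(n_seq):
            trial_index = cycle * n_seq + pos + 1
            seq_idx = presentation_schedule(
                n_seq, trial_index, mode=schedule_mode, seed=seed
            )
            seq = sequences[seq_idx - 1]
            result = run_trial(
                seq, catalog, weights,
                mf_params=mf_params, gate_params=gate_params,
                wm_params=wm_params, learn_params=learn_params,
                integ=integ, masking=masking, wm_cache=wm_cache,
                alpha=alpha, beta=beta, learn=True,
            )
            winner_map[str(seq)] = result.winner
            if result.selection_time is not None:
                selection_times[str(seq)].append(result.selection_time)
            reset_series.append(result.n_resets)
            cycle_resets += result.n_resets
            n_failed += int(result.failed)
            trial_rows.append(
                {
                    "trial": trial_index,
                    "sequence": str(seq),
                    "winner": result.winner,
                    "selection_time": result.selection_time,
                    "n_resets": result.n_resets,
                    "failed": result.failed,
                }
            )
        cycles_run = cycle + 1 - start_cycle
        unique_series.append(_unique_count(winner_map))
        if ground_truth is not None:
            weight_errors.append(
                _weight_error(catalog, weights, ground_truth)
            )
        if checkpoint_dir is not None:
            save_checkpoint(checkpoint_dir, weights, catalog, cycle + 1)
        prev_maps.append(dict(winner_map))
        if early_stop and len(prev_maps) >= 2:
            stable = prev_maps[-1] == prev_maps[-2] and len(winner_map) == n_seq
            if learn_params.mode == "supervised":
                recent = reset_series[-2 * n_seq:]
                stable = stable and sum(recent) == 0
            if stable:
                break

    n_unique = _unique_count(winner_map)
    return LearningReport(
        n_sequences=n_seq,
        cycles_run=cycles_run,
        winner_map=winner_map,
        n_uniquely_learned=n_unique,
        fraction_unique=n_unique / n_seq if n_seq else 0.0,
        reset_series=reset_series,
        selection_times=selection_times,
        weight_error_series=weight_errors,
        unique_series=unique_series,
        n_failed_trials=n_failed,
        seed=seed,
        trial_rows=trial_rows,
    )


def save_checkpoint(
    directory, weights: WeightMatrix, catalog: ChunkCatalog, next_cycle: int
) -> None:
    """Persist the adaptive state (weights + commitments) after a cycle."""
    import json
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "weights.npy", weights.W)
    payload = {
        "next_cycle": next_cycle,
        "commitments": {
            str(j): str(c.committed_to)
            for j, c in enumerate(catalog.chunks)
            if c.committed_to is not None
        },
    }
    (out / "commitments.json").write_text(json.dumps(payload, indent=2))


def load_checkpoint(
    directory, catalog: ChunkCatalog
) -> tuple[WeightMatrix, int]:
    """Restore weights and commitments written by :func:`save_checkpoint`.

    Commitments are applied to ``catalog`` in place; returns the weight
    matrix and the cycle index at which to resume.
    """
    import json
    from pathlib import Path

    out = Path(directory)
    W = np.load(out / "weights.npy")
    payload = json.loads((out / "commitments.json").read_text())
    for j_str, seq_str in payload["commitments"].items():
        catalog.chunks[int(j_str)].committed_to = SequenceSpec.from_string(
            seq_str
        )
    return WeightMatrix(W=W, catalog=catalog), int(payload["next_cycle"])


def _weight_error(
    catalog: ChunkCatalog,
    weights: WeightMatrix,
    ground_truth: dict[str, np.ndarray],
) -> float:
    """Mean L1 distance between committed chunks' weights and their targets."""
    errors = []
    for j, chunk in enumerate(catalog.chunks):
        if chunk.committed_to is None:
            continue
        target_full = ground_truth.get(str(chunk.committed_to))
        if target_full is None:
            continue
        errors.append(float(np.abs(weights.W[:, j] - target_full).sum()))
    return float(np.mean(errors)) if errors else float("nan")
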