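"""Masking Field: a self-similar multiple-scale winner-take-all network.

Each cell (a "list chunk") receives bottom-up input from a fixed set J of
working-memory items, through habituative transmitter gates and adaptive
weights, and competes with every other cell through a recurrent shunting
on-center off-surround interaction.  Self-similarity enters twice:

* the on-center self-excitation scales with the cell size |J| (larger cells,
  coding longer lists, excite themselves more strongly once active), and
* the off-surround coefficient from cell k onto cell j scales with
  |K| * (1 + |K ∩ J|), divisively normalized so that the total inhibitory
  strength converging on any cell is exactly 1 (conserved synaptic sites).

Activity of cell j obeys (tau = 4):

    tau dc_j/dt = -A c_j
                  + (1 - c_j) R_j [ B Σ_{i∈J} x_i Z_i W_ij + D |J| f(c_j) ]
                  - E (c_j + F) [ L FFI_j + H Σ_{k≠j} g(c_k) M_kj ]

which keeps every trajectory in [-F, 1].  FFI_j is feedforward inhibition
from item cells outside J (a contrast-normalizing on-center off-surround in
the bottom-up pathway); M is the normalized masking-coefficient matrix.  The
gates Z_i deplete in an activity-dependent way and recover passively,
weakening long-stored items so newly arriving ones can redirect the
competition toward larger chunks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from math import factorial, sqrt

import numpy as np

from .protocol import SequenceSpec, count_chunks

__all__ = [
    "Chunk",
    "ChunkCatalog",
    "MFParams",
    "GateParams",
    "MFState",
    "WeightMatrix",
    "build_catalog",
    "inhibitory_coefficients",
    "f_signal",
    "g_signal",
    "fluctuation_coefficient",
    "init_weights",
    "gate_derivatives",
    "mf_derivatives",
    "select_winner",
]


@dataclass
class Chunk:
    """One list-chunk cell: its receptive item set and commitment record."""

    id: int
    itemset: frozenset[int]
    committed_to: SequenceSpec | None = None

    @property
    def size(self) -> int:
        return len(self.itemset)


@dataclass
class ChunkCatalog:
    """The enumerated set of Masking Field cells for m items, lists <= lmax.

    One cell slot exists per (itemset, within-set permutation slot, redundant
    copy): an itemset of size s owns s! * redundancy slots, one per potential
    ordered list it may come to code.  Cells are dynamically identical within
    an itemset; the slots matter for counting and for balanced-noise
    initialization.
    """

    m: int
    lmax: int
    redundancy: int
    chunks: list[Chunk]
    support: np.ndarray = dc_field(repr=False)   # (m, n) float 0/1
    sizes: np.ndarray = dc_field(repr=False)     # (n,) int
    slot: np.ndarray = dc_field(repr=False)      # (n,) permutation-slot index

    def __post_init__(self) -> None:
        expected = count_chunks(self.m, self.lmax, self.redundancy)
        if len(self.chunks) != expected:
            raise ValueError(
                f"catalog has {len(self.chunks)} chunks, expected {expected}"
            )

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def overlap(self) -> np.ndarray:
        """|K ∩ J| for all cell pairs (symmetric; diagonal is |J|)."""
        s = self.support
        return (s.T @ s).astype(int)

    def itemset_members(self, j: int) -> list[int]:
        """Sorted 1-based item indices of chunk j's receptive set."""
        return sorted(self.chunks[j].itemset)

    def to_frame(self):
        """Tabular view (chunk id, itemset, size, committed sequence)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "chunk": [c.id for c in self.chunks],
                "itemset": ["-".join(map(str, sorted(c.itemset))) for c in self.chunks],
                "size": [c.size for c in self.chunks],
                "committed_to": [
                    str(c.committed_to) if c.committed_to else "" for c in self.chunks
                ],
            }
        )


def build_catalog(m: int, lmax: int = 4, redundancy: int = 1) -> ChunkCatalog:
    """Enumerate all chunk slots for m items with lists up to length lmax.

    ``redundancy`` counts *total* copies per ordered-list slot (1 = no
    redundant coding).  Order: by size, itemset (lexicographic), then slot.
    """
    if lmax > m:
        raise ValueError(f"lmax={lmax} exceeds item count m={m}")
    chunks: list[Chunk] = []
    slots: list[int] = []
    for k in range(1, lmax + 1):
        for combo in itertools.combinations(range(1, m + 1), k):
            for q in range(factorial(k) * redundancy):
                chunks.append(Chunk(id=len(chunks), itemset=frozenset(combo)))
                slots.append(q)
    n = len(chunks)
    support = np.zeros((m, n))
    for j, c in enumerate(chunks):
        for i in c.itemset:
            support[i - 1, j] = 1.0
    sizes = support.sum(axis=0).astype(int)
    return ChunkCatalog(
        m=m, lmax=lmax, redundancy=redundancy, chunks=chunks,
        support=support, sizes=sizes, slot=np.asarray(slots),
    )


def inhibitory_coefficients(catalog: ChunkCatalog) -> np.ndarray:
    """Normalized masking coefficients M[k, j] (inhibition of cell j by k).

    Unnormalized strength |K| (1 + |K ∩ J|): larger source cells, and cells
    sharing more items with the target, inhibit more.  Each column is divided
    by its sum over k != j, so the total inhibitory strength onto every cell
    is exactly 1 (a cell is not in its own off-surround).
    """
    sizes = catalog.sizes.astype(float)
    raw = sizes[:, None] * (1.0 + catalog.overlap.astype(float))
    np.fill_diagonal(raw, 0.0)
    colsum = raw.sum(axis=0)
    if catalog.n_chunks == 1:
        # a lone cell has an empty off-surround; by convention M = [[1]]
        return np.ones((1, 1))
    return raw / colsum


def f_signal(w, f0: float = 0.75):
    """Excitatory sigmoid f(w) = w^2 / (w^2 + f0^2); f(f0) = 0.5."""
    w2 = np.square(w)
    return w2 / (w2 + f0 * f0)


def g_signal(w, g0: float = 1.0):
    """Inhibitory sigmoid g(w) = w^2 / (w^2 + g0^2); g(g0) = 0.5.

    g0 > f0 lets contrast enhancement begin before inhibition sets in
    strongly.
    """
    w2 = np.square(w)
    return w2 / (w2 + g0 * g0)


@dataclass(frozen=True)
class MFParams:
    """Masking Field constants.

    A, B, D, f0, g0, tau and the selection threshold follow the published
    model; E, F, L, H are the off-surround shunt gain, lower-bound offset,
    feedforward and recurrent inhibition gains, fixed here by the packaged
    calibration (see :mod:`maskfield.calibrate`) so that size-selectivity
    holds on the 4- and 5-item catalogs with one parameter set.
    """

    A: float = 0.5        # passive decay
    B: float = 3.0        # bottom-up gain
    D: float = 30.0       # on-center (self-excitation) gain, scaled by |J|
    E: float = 5.0        # off-surround shunt gain        [calibrated]
    F: float = 0.5        # lower activity bound offset    [calibrated]
    L: float = 6.0        # feedforward inhibition gain    [calibrated]
    H: float = 10.0       # recurrent inhibition gain      [calibrated]
    f0: float = 0.75      # half-max of excitatory sigmoid
    g0: float = 1.0       # half-max of inhibitory sigmoid
    tau: float = 4.0      # left-hand-side time constant
    threshold: float = 0.2  # selection (firing) threshold
    ffi_mode: str = "simple"  # "simple" | "weighted" feedforward inhibition

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.D, self.E, self.F, self.L, self.H,
               self.f0, self.g0, self.tau, self.threshold) <= 0:
            raise ValueError("all Masking Field parameters must be positive")
        if self.g0 <= self.f0:
            raise ValueError("need g0 > f0 (contrast enhancement before "
                             "strong inhibition)")
        if self.ffi_mode not in ("simple", "weighted"):
            raise ValueError(f"unknown ffi_mode {self.ffi_mode!r}")


@dataclass(frozen=True)
class GateParams:
    """Habituative transmitter gate constants."""

    epsilon: float = 0.01  # passive recovery rate toward 1
    lam: float = 0.1       # linear activity-dependent depletion
    mu: float = 3.0        # quadratic depletion (enables non-monotone throughput)

    def __post_init__(self) -> None:
        if min(self.epsilon, self.lam, self.mu) <= 0:
            raise ValueError("all gate parameters must be positive")


@dataclass
class MFState:
    """Dynamic Masking Field state for one trial."""

    c: np.ndarray  # (n,) chunk activities in [-F, 1]
    Z: np.ndarray  # (m,) habituative gates in [0, 1]
    R: np.ndarray  # (n,) reset gates, 1 = enabled

    @classmethod
    def resting(cls, m: int, n: int) -> "MFState":
        return cls(c=np.zeros(n), Z=np.ones(m), R=np.ones(n))


@dataclass
class WeightMatrix:
    """Adaptive bottom-up weights W (items x chunks), zero off support."""

    W: np.ndarray
    catalog: ChunkCatalog

    def column_sums(self) -> np.ndarray:
        return self.W.sum(axis=0)


def fluctuation_coefficient(p: float, size: int) -> float:
    """Size-compensated fluctuation coefficient p_|J|.

    Chosen so the coefficient of variation of the initial weights is
    independent of |J|:  p_|J| = p * sqrt((|J|+1)/(|J|-1)) for |J| >= 2.  A
    size-1 cell's single weight is forced to 1 by the sum constraint, so
    p_1 = 0 (noise is vacuous there).
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if size == 1:
        return 0.0
    return p * sqrt((size + 1) / (size - 1))


def init_weights(
    catalog: ChunkCatalog,
    p: float = 3e-3,
    mode: str = "balanced_permuted",
    rng: np.random.Generator | int | None = 0,
) -> WeightMatrix:
    """Initial adaptive weights W_ij = (1/|J|)(1 - p_|J|) + r_ij p_|J|.

    The deterministic part conserves synaptic sites (each column sums to 1
    with the noise, since the r_ij are normalized to sum to 1 per chunk).

    ``balanced_permuted`` (unsupervised init): one noise vector is drawn per
    chunk size and each same-size chunk receives one of its permutations, so
    no chunk starts with an advantage — the multiset of weights is identical
    across all same-size cells.  ``free_random`` (supervised init): every
    chunk draws its own independent noise.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not 0.0 <= p <= 1.0:
        raise ValueError("base fluctuation p must be in [0, 1]")
    m, n = catalog.m, catalog.n_chunks
    W = np.zeros((m, n))
    sizes_present = sorted(set(int(s) for s in catalog.sizes))
    noise_by_size: dict[int, np.ndarray] = {}
    perms_by_size: dict[int, list[tuple[int, ...]]] = {}
    if mode == "balanced_permuted":
        for s in sizes_present:
            r = rng.uniform(size=s)
            noise_by_size[s] = r / r.sum()
            perms_by_size[s] = list(itertools.permutations(range(s)))
    elif mode != "free_random":
        raise ValueError(f"unknown init mode {mode!r}")
    for j, chunk in enumerate(catalog.chunks):
        members = catalog.itemset_members(j)
        s = len(members)
        ps = fluctuation_coefficient(p, s)
        if mode == "balanced_permuted":
            perm = perms_by_size[s][int(catalog.slot[j]) % factorial(s)]
            r = noise_by_size[s][list(perm)]
        else:
            r = rng.uniform(size=s)
            r = r / r.sum()
        for pos, i in enumerate(members):
            W[i - 1, j] = (1.0 - ps) / s + r[pos] * ps
    return WeightMatrix(W=W, catalog=catalog)


def gate_derivatives(
    Z: np.ndarray, x: np.ndarray, gp: GateParams = GateParams()
) -> np.ndarray:
    """dZ_i = eps (1 - Z_i) - Z_i (lam x_i + mu x_i^2)."""
    return gp.epsilon * (1.0 - Z) - Z * (gp.lam * x + gp.mu * np.square(x))


def feedforward_inhibition(
    x: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    catalog: ChunkCatalog,
    mode: str = "simple",
) -> np.ndarray:
    """Feedforward off-surround onto each chunk from items outside its set.

    ``simple``: FFI_j = Σ_{k∉J} x_k Z_k.  ``weighted``: each outside item's
    signal is weighted by its mean learned weight across the chunks it feeds.
    """
    u = x * Z
    if mode == "weighted":
        with np.errstate(invalid="ignore", divide="ignore"):
            wbar = np.where(
                catalog.support.sum(axis=1) > 0,
                (W * catalog.support).sum(axis=1)
                / np.maximum(catalog.support.sum(axis=1), 1.0),
                0.0,
            )
        u = u * wbar
    return u.sum() - catalog.support.T @ u


def mf_derivatives(
    state: MFState,
    x: np.ndarray,
    weights: WeightMatrix,
    catalog: ChunkCatalog,
    params: MFParams = MFParams(),
    masking: np.ndarray | None = None,
) -> np.ndarray:
    """Right-hand side dc of the Masking Field shunting network."""
    if masking is None:
        masking = inhibitory_coefficients(catalog)
    c, Z, R = state.c, state.Z, state.R
    u = x * Z
    bottom_up = params.B * (weights.W.T @ u)
    exc = R * (bottom_up + params.D * catalog.sizes * f_signal(c, params.f0))
    ffi = feedforward_inhibition(x, Z, weights.W, catalog, params.ffi_mode)
    rec = masking.T @ g_signal(c, params.g0)
    inh = params.L * ffi + params.H * rec
    dc = (-params.A * c + (1.0 - c) * exc
          - params.E * (c + params.F) * inh) / params.tau
    if not np.all(np.isfinite(dc)):
        raise FloatingPointError("Masking Field derivative is non-finite")
    return dc


def select_winner(
    state: MFState, threshold: float = 0.2
) -> int | None:
    """Id of the enabled chunk with the highest suprathreshold activity.

    Returns None if no enabled cell exceeds threshold.  Exact ties break to
    the lowest chunk id (ties are measure-zero with noisy weights).  During a
    trial the integration engine records the *first* admissible crossing; this
    helper answers the same question for a single state snapshot.
    """
    enabled = (state.R > 0) & (state.c >= threshold)
    if not enabled.any():
        return None
    ids = np.nonzero(enabled)[0]
    best = ids[np.argmax(state.c[ids])]
    # lowest id on exact ties
    ties = ids[state.c[ids] == state.c[best]]
    return int(ties.min())
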