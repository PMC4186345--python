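# maskfield

Real-time learning of *list chunks* — categories selectively tuned to ordered
sequences of items — from sequences stored in an Item-and-Order (competitive
queuing) working memory, by a self-similar Masking Field categorization
network connected through a habituative, competitively learned adaptive
filter.

The package is for computational-neuroscience and cognitive-modelling work on
serial order: it simulates, in one real-time clock, how a temporal stream of
discrete items (phonemes, syllables, movements, locations) is stored as a
spatial activity gradient and then unitized, through unsupervised or
supervised learning, into recognition categories for every ordering of up to
four items.

## The model

**Working memory (STORE 2).** Item `i`'s two-layer activities obey gated
shunting dynamics,

    dx_i/dt = (g·I_i + y_i − x_i·Σ_k x_k − d·x_i) · I
    dy_i/dt = r·(x_i − y_i) · (1 − I)

with binary input pulses `I_i` (duration α = 0.75, gap β = 0.75), total-input
gate `I = Σ I_k`, gain g = 0.01, decay d = 0.7 and tracking rate r = 5.  A
list of length ≤ 4 is stored as a *primacy gradient* (earlier item → higher
activity), and because every stored activity relaxes toward `y_k/(Σx + d)`
while a new item is integrated, the *ratios* of stored activities are
invariant — new items cannot corrupt the code that earlier learning attached
to (the LTM Invariance Principle).

**Masking Field.** Chunk `j`, wired to item set `J`, obeys

    τ dc_j/dt = −A c_j + (1 − c_j) R_j [ B Σ_{i∈J} x_i Z_i W_ij + D|J| f(c_j) ]
                − E (c_j + F) [ L Σ_{k∉J} x_k Z_k + H Σ_{k≠j} g(c_k) M_kj ]

with τ = 4, A = 0.5, B = 3, D = 30, sigmoids `f(w) = w²/(w² + 0.75²)`,
`g(w) = w²/(w² + 1)`, masking coefficients `M_kj ∝ |K|(1 + |K∩J|)` normalized
so each column sums to 1 (conserved synaptic sites), habituative gates
`dZ_i/dt = ε(1−Z_i) − Z_i(λx_i + μx_i²)` (ε = 0.01, λ = 0.1, μ = 3), and
reset gates `R_j`.  Larger cells self-excite in proportion to `|J|` and
inhibit smaller cells more strongly (self-similarity), letting a novel long
list outcompete its familiar sublists; a cell crossing the firing threshold
0.2 wins the competition.  The four inhibitory constants not fixed by the
published set are calibrated by the packaged grid search
(`maskfield.calibrate`): E = 5, F = 0.5, L = 6, H = 10.

**Learning.**  The bottom-up weights adapt by competitive instar learning,

    dW_ij/dt = η f(c_j) [ x_i − W_ij Σ_k x_k ]

whose fixed point is the normalized stored pattern `x_i/Σx`.  In supervised
mode, a threshold-crossing by a cell already committed to a *different*
sequence is a predictive error: the cell is reset (R_j = 0) and the search
continues until an admissible cell wins.

## Worked example

`python examples/04_supervised_learning.py` (about half a minute) runs
supervised learning of all 64 sequences over four items from free random
weights and prints:

```
uniquely committed:  64/64
cycles run:          26
resets per cycle:    [125, 94, 74, 52, 40, 29, 24, 19, 16, 12, 9, 7, 6, 5,
                      4, 4, 3, 1, 1, 1, 1, 1, 1, 1, 0, 0]
mean selection-time rank trend: -0.967 (negative = faster selection on later presentations)
```

Every sequence ends committed to its own category cell; mismatch resets die
out (two consecutive reset-free cycles end the run) and the rank trend shows
selection getting faster with practice.  The other examples cover gradient
storage (`01`), size-selectivity (`02`), unsupervised learning (`03`) and
ground-truth weight targets (`05`); `scripts/selectivity_large.py` and
`scripts/overnight_m5.py` run the large-catalog and long-horizon variants.

A thin CLI mirrors the library: `maskfield enumerate | selectivity |
train-unsupervised | train-supervised | calibrate`, each writing a run
directory with config snapshot, tables and a checksummed manifest.

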