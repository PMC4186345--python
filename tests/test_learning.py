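"""Instar learning, mismatch reset, and trial/campaign behaviour."""

import numpy as np
import pytest

from maskfield import (
    LearningParams,
    MFState,
    SequenceSpec,
    WeightMatrix,
    build_catalog,
    f_signal,
    init_weights,
    instar_derivatives,
    run_campaign,
    run_trial,
)
from maskfield.learning import reset_gate_update


class TestInstar:
    def test_no_learning_without_activity(self, catalog_m4, weights_m4):
        dW = instar_derivatives(
            weights_m4.W, np.full(4, 0.01), np.zeros(catalog_m4.n_chunks),
            catalog_m4.support,
        )
        assert np.all(dW == 0)

    def test_equilibrium_matches_closed_form(self):
        # frozen input pattern: weights converge to x_i / sum_k x_k
        cat = build_catalog(3, lmax=3)
        w = init_weights(cat, rng=np.random.default_rng(0))
        x = np.array([0.5, 0.3, 0.2])
        c = np.full(cat.n_chunks, 0.9)  # every chunk strongly active
        dt, eta = 0.01, 0.5
        W = w.W.copy()
        for _ in range(20_000):
            W += dt * instar_derivatives(W, x, c, cat.support, eta)
        j = next(i for i, ch in enumerate(cat.chunks)
                 if ch.itemset == frozenset({1, 2, 3}))
        np.testing.assert_allclose(W[:, j], x / x.sum(), atol=1e-4)
        # the learned vector parallels the primacy gradient
        assert W[0, j] > W[1, j] > W[2, j]

    def test_weights_stay_in_unit_interval(self, catalog_m4):
        w = init_weights(catalog_m4, rng=np.random.default_rng(1))
        x = np.array([0.02, 0.015, 0.01, 0.005])
        c = np.full(catalog_m4.n_chunks, 0.8)
        W = w.W.copy()
        for _ in range(5000):
            W += 0.01 * instar_derivatives(W, x, c, catalog_m4.support, 1.0)
        assert np.all(W >= 0) and np.all(W <= 1)

    def test_two_forms_agree(self, catalog_m4, weights_m4):
        # (1-W)x_i - W sum_{k!=i} x_k == x_i - W sum_k x_k
        x = np.array([0.02, 0.01, 0.0, 0.005])
        c = np.linspace(0, 1, catalog_m4.n_chunks)
        W = weights_m4.W
        gate = 0.001 * f_signal(c)
        literal = catalog_m4.support * gate[None, :] * (
            (1 - W) * x[:, None] - W * (x.sum() - x[:, None])
        )
        np.testing.assert_allclose(
            literal,
            instar_derivatives(W, x, c, catalog_m4.support),
            atol=1e-15,
        )


class TestResetGate:
    def _state(self, catalog, c_val, j):
        n = catalog.n_chunks
        c = np.zeros(n)
        c[j] = c_val
        return MFState(c=c, Z=np.ones(catalog.m), R=np.ones(n))

    def test_uncommitted_crossing_is_admissible(self, catalog_m4):
        state = self._state(catalog_m4, 0.25, 5)
        winner, events = reset_gate_update(
            state, catalog_m4, SequenceSpec((1, 2)), np.array([5]), t=1.0
        )
        assert winner == 5 and events == [] and state.R[5] == 1.0

    def test_mismatch_is_reset_and_logged(self, catalog_m4):
        catalog = build_catalog(4, 4)
        catalog.chunks[5].committed_to = SequenceSpec((1, 2))
        state = self._state(catalog, 0.25, 5)
        winner, events = reset_gate_update(
            state, catalog, SequenceSpec((2, 1)), np.array([5]), t=1.0
        )
        assert winner is None
        assert state.R[5] == 0.0
        assert len(events) == 1 and events[0].chunk == 5
        assert events[0].committed_to == SequenceSpec((1, 2))

    def test_matching_commitment_wins(self):
        catalog = build_catalog(4, 4)
        seq = SequenceSpec((1, 2))
        catalog.chunks[7].committed_to = seq
        state = self._state(catalog, 0.3, 7)
        winner, events = reset_gate_update(
            state, catalog, seq, np.array([7]), t=2.0
        )
        assert winner == 7 and not events


class TestTrials:
    def test_unsupervised_never_resets(self, catalog_m4, weights_m4):
        res = run_trial(SequenceSpec((2, 1)), catalog_m4, weights_m4,
                        learn=False, learn_params=LearningParams(eta=0.0))
        assert res.resets == []
        assert not res.failed

    def test_winner_matches_length_and_commits(self):
        cat = build_catalog(4, 4)
        w = init_weights(cat, rng=np.random.default_rng(2))
        seq = SequenceSpec((3, 1))
        res = run_trial(seq, cat, w)
        assert res.winner_size == 2
        assert cat.chunks[res.winner].committed_to == seq
        assert 0 <= w.W.min() and w.W.max() <= 1
        # instar conserves each column's total only approximately during
        # transients (exactly at equilibrium)
        np.testing.assert_allclose(w.column_sums(), 1.0, atol=1e-4)

    def test_jit_and_reference_paths_identical(self):
        results = {}
        for use_jit in (True, False):
            cat = build_catalog(3, 3)
            w = init_weights(cat, mode="free_random",
                             rng=np.random.default_rng(3))
            res = run_trial(SequenceSpec((1, 3, 2)), cat, w,
                            learn_params=LearningParams(eta=0.01),
                            use_jit=use_jit)
            results[use_jit] = (res.winner, res.selection_time, w.W.copy())
        assert results[True][0] == results[False][0]
        assert results[True][1] == results[False][1]
        np.testing.assert_array_equal(results[True][2], results[False][2])

    def test_supervised_reset_search_runs_to_admissible_winner(self):
        cat = build_catalog(3, 3)
        seq = SequenceSpec((1, 2))
        other = SequenceSpec((2, 1))
        w = init_weights(cat, mode="free_random", rng=np.random.default_rng(4))
        lp = LearningParams(eta=0.01, mode="supervised")
        first = run_trial(seq, cat, w, learn_params=lp)
        # re-present the *other* ordering: the chunk committed to seq must
        # not be selected for it
        second = run_trial(other, cat, w, learn_params=lp)
        assert not second.failed
        assert second.winner != first.winner
        for ev in second.resets:
            assert ev.committed_to is not None
            assert ev.committed_to != other


class TestCampaign:
    def test_zero_cycles_learns_nothing(self, catalog_m4, weights_m4):
        from maskfield import enumerate_sequences

        rep = run_campaign(catalog_m4, enumerate_sequences(4, 4),
                           weights_m4, cycles=0)
        assert rep.n_uniquely_learned == 0
        assert rep.cycles_run == 0

    def test_checkpoint_round_trip_resumes_identically(self, tmp_path):
        from maskfield import enumerate_sequences, load_checkpoint

        seqs = enumerate_sequences(3, 2)

        def fresh():
            cat = build_catalog(3, 2)
            w = init_weights(cat, mode="free_random",
                             rng=np.random.default_rng(7))
            return cat, w

        # one uninterrupted 4-cycle run
        cat_a, w_a = fresh()
        rep_a = run_campaign(cat_a, seqs, w_a, cycles=4, seed=7,
                             early_stop=False)
        # the same run split 2 + 2 through a checkpoint
        cat_b, w_b = fresh()
        run_campaign(cat_b, seqs, w_b, cycles=2, seed=7, early_stop=False,
                     checkpoint_dir=tmp_path / "ck")
        cat_c = build_catalog(3, 2)
        w_c, next_cycle = load_checkpoint(tmp_path / "ck", cat_c)
        assert next_cycle == 2
        rep_c = run_campaign(cat_c, seqs, w_c, cycles=2, seed=7,
                             early_stop=False, start_cycle=next_cycle)
        assert rep_c.winner_map == rep_a.winner_map
        np.testing.assert_array_equal(w_c.W, w_a.W)

    def test_small_campaign_commitments_are_consistent(self):
        from maskfield import enumerate_sequences

        cat = build_catalog(3, lmax=2)
        seqs = enumerate_sequences(3, 2)
        w = init_weights(cat, rng=np.random.default_rng(5))
        rep = run_campaign(cat, seqs, w, cycles=3, seed=5)
        assert rep.n_failed_trials == 0
        # a committed chunk's sequence never changes; winners map within catalog
        committed = [c.committed_to for c in cat.chunks if c.committed_to]
        assert len(set(map(str, committed))) == len(committed)
        assert rep.n_uniquely_learned == len(seqs)
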