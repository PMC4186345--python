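"""Masking Field topology, signals, weight initialization, and gates."""

from collections import Counter

import numpy as np
import pytest

from maskfield import (
    GateParams,
    MFParams,
    MFState,
    SequenceSpec,
    WeightMatrix,
    build_catalog,
    f_signal,
    fluctuation_coefficient,
    g_signal,
    gate_derivatives,
    init_weights,
    inhibitory_coefficients,
    mf_derivatives,
    select_winner,
)


class TestCatalog:
    @pytest.mark.parametrize(
        "m, lmax, red, expected",
        [(5, 4, 1, 205), (4, 4, 3, 192), (1, 1, 1, 1), (4, 4, 1, 64)],
    )
    def test_sizes(self, m, lmax, red, expected):
        cat = build_catalog(m, lmax, red)
        assert cat.n_chunks == expected

    def test_slots_per_itemset(self, catalog_m4):
        # an itemset of size k owns k! ordered-list slots
        by_itemset = Counter(c.itemset for c in catalog_m4.chunks)
        for itemset, count in by_itemset.items():
            import math

            assert count == math.factorial(len(itemset))

    def test_overlap_symmetric_with_size_diagonal(self, catalog_m4):
        ov = catalog_m4.overlap
        assert np.array_equal(ov, ov.T)
        assert np.array_equal(np.diag(ov), catalog_m4.sizes)

    def test_lmax_exceeding_m_rejected(self):
        with pytest.raises(ValueError):
            build_catalog(3, lmax=4)


class TestInhibitoryCoefficients:
    def test_columns_sum_to_one_exactly(self, catalog_m4):
        M = inhibitory_coefficients(catalog_m4)
        np.testing.assert_allclose(M.sum(axis=0), 1.0, rtol=0, atol=1e-12)

    def test_single_chunk_catalog(self):
        M = inhibitory_coefficients(build_catalog(1, 1, 1))
        assert M.tolist() == [[1.0]]

    def test_hand_computed_m2(self, catalog_m2):
        # unnormalized strength |K|(1+|K∩J|): {1,2}->{1} is 2*(1+1)=4,
        # {2}->{1} is 1*(1+0)=1, {1,2}<->{2,1} is 2*(1+2)=6
        cat = catalog_m2
        sizes = cat.sizes
        raw = sizes[:, None] * (1.0 + cat.overlap)
        np.fill_diagonal(raw, 0.0)
        ids = {frozenset({1}): None, frozenset({2}): None}
        j1 = next(j for j, c in enumerate(cat.chunks) if c.itemset == frozenset({1}))
        j12 = next(j for j, c in enumerate(cat.chunks) if c.itemset == frozenset({1, 2}))
        j2 = next(j for j, c in enumerate(cat.chunks) if c.itemset == frozenset({2}))
        assert raw[j12, j1] == 4.0
        assert raw[j2, j1] == 1.0
        M = inhibitory_coefficients(cat)
        assert M[j12, j1] > M[j2, j1]  # larger/overlapping source inhibits more


class TestSignals:
    def test_half_maximum_points(self):
        assert f_signal(0.75, 0.75) == pytest.approx(0.5)
        assert g_signal(1.0, 1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "fn, w, expected",
        [
            (f_signal, 0.0, 0.0),
            (g_signal, 0.0, 0.0),
            (f_signal, 3.0, 9 / 9.5625),
            (g_signal, 0.5, 0.2),
        ],
    )
    def test_values(self, fn, w, expected):
        assert fn(w) == pytest.approx(expected)

    def test_monotone(self):
        w = np.linspace(0, 5, 100)
        assert np.all(np.diff(f_signal(w)) > 0)


class TestInitWeights:
    def test_columns_sum_to_one_exactly(self, catalog_m4):
        for mode in ("balanced_permuted", "free_random"):
            w = init_weights(catalog_m4, mode=mode, rng=np.random.default_rng(1))
            np.testing.assert_allclose(w.column_sums(), 1.0, rtol=0, atol=1e-12)
            assert np.all(w.W >= 0) and np.all(w.W <= 1)

    def test_deterministic_limit(self, catalog_m4):
        w = init_weights(catalog_m4, p=0.0)
        for j, chunk in enumerate(catalog_m4.chunks):
            members = [i - 1 for i in chunk.itemset]
            np.testing.assert_allclose(w.W[members, j], 1.0 / chunk.size)

    def test_support_respected(self, catalog_m4):
        w = init_weights(catalog_m4, rng=np.random.default_rng(2))
        assert np.all(w.W[catalog_m4.support == 0] == 0)

    def test_balanced_mode_is_fair(self, catalog_m4):
        # every same-size chunk receives the same multiset of weights
        w = init_weights(catalog_m4, rng=np.random.default_rng(3))
        for size in (2, 3, 4):
            multisets = set()
            for j, chunk in enumerate(catalog_m4.chunks):
                if chunk.size == size:
                    vals = tuple(sorted(np.round(w.W[w.W[:, j] > 0, j], 12)))
                    multisets.add(vals)
            assert len(multisets) == 1

    def test_size2_chunks_get_swapped_noise(self, catalog_m2):
        # the two orderings of {1,2} receive (r1, r2) and (r2, r1)
        w = init_weights(catalog_m2, rng=np.random.default_rng(4))
        cols = [w.W[:, j] for j, c in enumerate(catalog_m2.chunks) if c.size == 2]
        assert cols[0] == pytest.approx(cols[1][::-1])
        assert cols[0][0] != pytest.approx(cols[0][1])

    def test_free_random_mode_is_unbalanced(self, catalog_m4):
        w = init_weights(catalog_m4, mode="free_random",
                         rng=np.random.default_rng(5))
        size4 = [tuple(np.round(sorted(w.W[w.W[:, j] > 0, j]), 12))
                 for j, c in enumerate(catalog_m4.chunks) if c.size == 4]
        assert len(set(size4)) > 1

    def test_fluctuation_coefficient_rule(self):
        assert fluctuation_coefficient(0.003, 1) == 0.0
        assert fluctuation_coefficient(0.003, 2) == pytest.approx(
            0.003 * np.sqrt(3.0)
        )
        assert fluctuation_coefficient(0.003, 4) == pytest.approx(
            0.003 * np.sqrt(5.0 / 3.0)
        )


class TestHabituativeGates:
    def test_rest_is_equilibrium(self):
        dZ = gate_derivatives(np.ones(3), np.zeros(3))
        assert np.all(dZ == 0)

    def test_closed_form_equilibrium(self):
        # eps/(eps + lam*x + mu*x^2) vs long Euler integration, within 1e-6
        gp = GateParams()
        x = np.array([0.1])
        Z = np.ones(1)
        dt = 0.005
        for _ in range(400_000):
            Z = Z + dt * gate_derivatives(Z, x, gp)
        expected = gp.epsilon / (gp.epsilon + gp.lam * 0.1 + gp.mu * 0.01)
        assert expected == pytest.approx(0.2)
        assert abs(Z[0] - expected) < 1e-6

    def test_gated_throughput_non_monotone(self):
        # equilibrium x * Z*(x) rises then falls: a single interior maximum
        gp = GateParams()
        x = np.linspace(0, 2, 400)
        through = x * gp.epsilon / (gp.epsilon + gp.lam * x + gp.mu * x**2)
        d = np.diff(through)
        sign_changes = np.count_nonzero(np.diff(np.sign(d[d != 0])))
        assert sign_changes == 1
        assert through.argmax() not in (0, len(x) - 1)


class TestFieldDerivatives:
    def test_rest_is_equilibrium(self, catalog_m4, weights_m4):
        state = MFState.resting(4, catalog_m4.n_chunks)
        dc = mf_derivatives(state, np.zeros(4), weights_m4, catalog_m4)
        np.testing.assert_allclose(dc, 0.0, atol=1e-15)

    def test_upper_shunt_bound(self, catalog_m4, weights_m4):
        # at c = 1 the excitatory shunt vanishes, so dc <= 0
        n = catalog_m4.n_chunks
        state = MFState(c=np.ones(n), Z=np.ones(4), R=np.ones(n))
        dc = mf_derivatives(state, np.full(4, 0.01), weights_m4, catalog_m4)
        assert np.all(dc <= 0)

    def test_reset_gate_removes_excitation(self, catalog_m4, weights_m4):
        n = catalog_m4.n_chunks
        x = np.full(4, 0.01)
        on = MFState(c=np.zeros(n), Z=np.ones(4), R=np.ones(n))
        off = MFState(c=np.zeros(n), Z=np.ones(4), R=np.zeros(n))
        dc_on = mf_derivatives(on, x, weights_m4, catalog_m4)
        dc_off = mf_derivatives(off, x, weights_m4, catalog_m4)
        assert np.all(dc_off <= dc_on)
        assert np.any(dc_off < dc_on)


class TestSelectWinner:
    def test_none_below_threshold(self):
        state = MFState(c=np.array([0.1, 0.19]), Z=np.ones(2), R=np.ones(2))
        assert select_winner(state) is None

    def test_highest_enabled_wins(self):
        state = MFState(
            c=np.array([0.5, 0.9, 0.3]), Z=np.ones(2), R=np.array([1.0, 0.0, 1.0])
        )
        assert select_winner(state) == 0

    def test_tie_breaks_to_lowest_id(self):
        state = MFState(c=np.array([0.4, 0.4]), Z=np.ones(2), R=np.ones(2))
        assert select_winner(state) == 0
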