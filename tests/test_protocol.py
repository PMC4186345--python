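"""Sequence enumeration, pulse schedules, and presentation order."""

import itertools
from math import comb, factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maskfield import (
    SequenceSpec,
    build_schedule,
    count_chunks,
    enumerate_sequences,
    input_vector,
    presentation_schedule,
)
from maskfield.protocol import read_sequences, write_sequences


def brute_force_sequences(m, lmax):
    """Independent oracle: filter all item tuples for distinctness."""
    out = []
    for k in range(1, lmax + 1):
        for tup in itertools.product(range(1, m + 1), repeat=k):
            if len(set(tup)) == k:
                out.append(tup)
    return sorted(out, key=lambda t: (len(t), t))


class TestEnumeration:
    @pytest.mark.parametrize(
        "m, lmax, expected",
        [(5, 4, 205), (4, 4, 64), (1, 1, 1), (9, 4, 3609)],
    )
    def test_counts(self, m, lmax, expected):
        seqs = enumerate_sequences(m, lmax)
        assert len(seqs) == expected
        assert len(set(seqs)) == expected

    def test_matches_brute_force(self):
        for m, lmax in [(3, 3), (4, 4), (5, 3)]:
            got = [s.items for s in enumerate_sequences(m, lmax)]
            assert got == brute_force_sequences(m, lmax)

    def test_single_item_universe(self):
        assert enumerate_sequences(1, 1) == [SequenceSpec((1,))]

    def test_lmax_exceeding_m_rejected(self):
        with pytest.raises(ValueError):
            enumerate_sequences(3, 4)

    @pytest.mark.parametrize(
        "m, lmax, red, expected",
        [(5, 4, 1, 205), (5, 4, 2, 410), (5, 4, 3, 615), (9, 4, 1, 3609),
         (2, 1, 1, 2), (4, 4, 2, 128), (4, 4, 3, 192)],
    )
    def test_count_chunks(self, m, lmax, red, expected):
        assert count_chunks(m, lmax, red) == expected

    def test_count_matches_enumeration(self):
        for m in range(1, 7):
            for lmax in range(1, min(m, 4) + 1):
                assert count_chunks(m, lmax, 1) == len(
                    enumerate_sequences(m, lmax)
                ) == sum(factorial(k) * comb(m, k) for k in range(1, lmax + 1))


class TestSequenceSpec:
    def test_repeats_rejected(self):
        with pytest.raises(ValueError):
            SequenceSpec((1, 2, 1))

    def test_string_round_trip(self):
        seq = SequenceSpec.from_string("4-3-2-1")
        assert seq.items == (4, 3, 2, 1)
        assert str(seq) == "4-3-2-1"

    def test_file_round_trip(self, tmp_path):
        seqs = enumerate_sequences(3, 2)
        path = tmp_path / "seqs.txt"
        write_sequences(seqs, path)
        assert read_sequences(path) == seqs


class TestPulseSchedule:
    def test_stated_timing(self):
        # alpha = beta = 0.75: position 1 on [0, 0.75), position 2 on [1.5, 2.25)
        sched = build_schedule(SequenceSpec((1, 2)))
        assert sched.onsets == (0.0, 1.5)
        assert sched.offsets == (0.75, 2.25)

    def test_single_pulse(self):
        sched = build_schedule(SequenceSpec((3,)), alpha=1.25, beta=0.5)
        assert sched.onsets == (0.0,)
        assert sched.offsets == (1.25,)

    def test_fourth_position_window(self):
        # position j occupies [(j-1)(a+b), ja+(j-1)b): j=4 -> [4.5, 5.25)
        sched = build_schedule(SequenceSpec((4, 3, 2, 1)))
        assert sched.onsets[3] == pytest.approx(4.5)
        assert sched.offsets[3] == pytest.approx(5.25)
        assert sched.active_item(4.5) == 1
        assert sched.active_item(5.2499) == 1
        assert sched.active_item(5.25) is None

    @given(
        length=st.integers(1, 4),
        alpha=st.floats(0.1, 2.0),
        beta=st.floats(0.0, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_pulses_disjoint_and_ordered(self, length, alpha, beta):
        seq = SequenceSpec(tuple(range(1, length + 1)))
        sched = build_schedule(seq, alpha=alpha, beta=beta)
        intervals = list(zip(sched.onsets, sched.offsets))
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            assert a1 <= b0  # no overlap
        assert sched.duration == pytest.approx(
            length * alpha + (length - 1) * beta
        )

    def test_input_vector(self):
        sched = build_schedule(SequenceSpec((1, 2)))
        assert input_vector(sched, 0.3, 4).tolist() == [1, 0, 0, 0]
        # 0.75 < 1.0 < 1.5 falls in the inter-stimulus gap
        assert input_vector(sched, 1.0, 4).sum() == 0
        assert input_vector(sched, 1.6, 4).tolist() == [0, 1, 0, 0]
        assert input_vector(sched, 99.0, 4).sum() == 0


class TestPresentationSchedule:
    @pytest.mark.parametrize(
        "n, trial, expected", [(205, 206, 1), (205, 1, 1), (64, 130, 2)]
    )
    def test_cyclic(self, n, trial, expected):
        assert presentation_schedule(n, trial) == expected

    @pytest.mark.parametrize("mode", ["cyclic", "shuffled"])
    def test_bijection_within_cycle(self, mode):
        n = 17
        for cycle in range(3):
            seen = {
                presentation_schedule(
                    n, cycle * n + pos + 1, mode=mode, seed=42
                )
                for pos in range(n)
            }
            assert seen == set(range(1, n + 1))

    def test_shuffled_deterministic_under_seed(self):
        a = [presentation_schedule(9, t, "shuffled", seed=7) for t in range(1, 19)]
        b = [presentation_schedule(9, t, "shuffled", seed=7) for t in range(1, 19)]
        assert a == b
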