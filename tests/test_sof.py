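import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from edgestrand.masses import CANONICAL_RESIDUES, residue_mass
from edgestrand.sof import (
    SkipReport,
    SOFInterval,
    coverage_profile,
    enumerate_sof,
    is_perfect_square,
    sequence_from_text,
    sof_table_tsv,
)

codes = st.sampled_from(CANONICAL_RESIDUES)


def naive_sof(sequence, min_span=1, max_span=20):
    """Independent oracle: recompute every interval mass from scratch."""
    out = []
    L = len(sequence)
    for i in range(1, L + 1):
        for j in range(i, L + 1):
            if not min_span <= j - i <= max_span:
                continue
            mass = sum(residue_mass(c) for c in sequence[i - 1 : j]) + 18
            if math.isqrt(mass) ** 2 == mass:
                out.append(SOFInterval(i, j, mass))
    return out


class TestPerfectSquare:
    @pytest.mark.parametrize("n, expected", [(121, True), (132, False), (0, True), (1, True)])
    def test_examples(self, n, expected):
        assert is_perfect_square(n) is expected

    @given(k=st.integers(min_value=0, max_value=10**9))
    def test_squares_and_their_neighbours(self, k):
        assert is_perfect_square(k * k)
        if k > 1:
            assert not is_perfect_square(k * k + 1)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            is_perfect_square(-1)


class TestEnumerate:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            (["ASP", "ARG"], [SOFInterval(1, 2, 289)]),
            (["CYS"], []),  # span-0 excluded by default: no single-Cys SOF
            (["GLY", "GLY"], []),  # 132 is not a square
        ],
    )
    def test_examples(self, seq, expected):
        assert enumerate_sof(seq) == expected

    def test_matches_naive_oracle_on_random_sequences(self):
        rng = random.Random(2024)
        for _ in range(100):
            seq = [rng.choice(CANONICAL_RESIDUES) for _ in range(30)]
            assert enumerate_sof(seq) == naive_sof(seq)

    def test_single_cysteine_is_the_unique_length1_sof(self):
        squares = [c for c in CANONICAL_RESIDUES if enumerate_sof([c], min_span=0)]
        assert squares == ["CYS"]

    @given(seq=st.lists(codes, min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_enlarging_max_span_never_removes_intervals(self, seq):
        small = set(enumerate_sof(seq, max_span=5))
        large = set(enumerate_sof(seq, max_span=20))
        assert small <= large

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            enumerate_sof([])

    def test_unknown_residues_skip_intervals_not_masses(self):
        # ASP-ARG on both sides of an unknown residue: intervals spanning
        # UNK are dropped, the flanking squares survive.
        seq = ["ASP", "ARG", "UNK", "ASP", "ARG"]
        report = SkipReport()
        intervals = enumerate_sof(seq, skip_report=report)
        assert intervals == [SOFInterval(1, 2, 289), SOFInterval(4, 5, 289)]
        assert report.unknown_codes == {"UNK"}
        assert report.skipped_intervals > 0


class TestCoverage:
    def test_single_interval(self):
        prof = coverage_profile(2, [SOFInterval(1, 2, 289)])
        assert prof.values == (1, 1)

    def test_empty_sof_list(self):
        assert coverage_profile(5, []).values == (0,) * 5

    def test_overlapping_intervals(self):
        prof = coverage_profile(3, [SOFInterval(1, 2, 0), SOFInterval(2, 3, 0)])
        assert prof.values == (1, 2, 1)

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError):
            coverage_profile(3, [SOFInterval(2, 4, 0)])

    @given(seq=st.lists(codes, min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_total_coverage_equals_total_interval_length(self, seq):
        sof = enumerate_sof(seq)
        prof = coverage_profile(len(seq), sof)
        assert sum(prof.values) == sum(iv.n_residues for iv in sof)

    def test_mean_over_range(self):
        prof = coverage_profile(4, [SOFInterval(1, 2, 0)])
        assert prof.mean(1, 4) == 0.5
        assert prof.mean(3, 4) == 0.0
        with pytest.raises(IndexError):
            prof.mean(0, 4)


class TestSequenceInput:
    def test_fasta_one_letter(self):
        assert sequence_from_text(">h\nDR\n") == ["ASP", "ARG"]

    def test_three_letter_tokens(self):
        assert sequence_from_text("ASP ARG\nGLY") == ["ASP", "ARG", "GLY"]

    def test_unknown_letters_become_unk(self):
        assert sequence_from_text("DXR") == ["ASP", "UNK", "ARG"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_from_text(">only a header\n")


def test_sof_tsv_contains_sqrt_column():
    tsv = sof_table_tsv([SOFInterval(1, 2, 289)])
    assert tsv.splitlines()[1] == "1\t2\t1\t289\t17"
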