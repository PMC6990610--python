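import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, strategies as st

from intronsim.core import (
    InfeasibleEventError,
    InvalidLengthError,
    MutationLedger,
    RangeError,
    Sequence,
    SubstitutionSampler,
    cap_termini,
    delete_block,
    draw_from_range,
    insert_block,
    mutate,
    random_sequence,
    substitute_base,
)

dna = st.text(alphabet="ACGT", min_size=4, max_size=60)


class TestCapping:
    @pytest.mark.parametrize(
        "raw,expected",
        [("AAAAAA", "GTAAAG"), ("GTCCAG", "GTCCAG"), ("CCCC", "GTAG"), ("TTTT", "GTAG")],
    )
    def test_examples(self, raw, expected):
        assert cap_termini(Sequence(raw)).bases == expected

    @given(dna)
    def test_idempotent_and_preserves_interior(self, bases):
        once = cap_termini(Sequence(bases))
        assert cap_termini(once).bases == once.bases
        assert once.bases[2:-2] == bases[2:-2]
        assert once.is_capped and len(once) == len(bases)

    def test_too_short(self):
        with pytest.raises(InvalidLengthError):
            cap_termini(Sequence("GTA"))


class TestRandomSequence:
    def test_capped_at_any_length(self, rng):
        seq = random_sequence(6000, rng)
        assert len(seq) == 6000 and seq.is_capped
        assert random_sequence(4, rng).bases == "GTAG"

    def test_base_frequencies_uniform(self, rng):
        seq = random_sequence(100_000, rng)
        for base in "ACGT":
            assert 0.24 < seq.bases.count(base) / 100_000 < 0.26

    def test_length_error(self, rng):
        with pytest.raises(InvalidLengthError):
            random_sequence(3, rng)


class TestSubstitution:
    @given(st.sampled_from("ACGT"), st.integers(0, 1000))
    def test_never_returns_input(self, base, seed):
        sampler = SubstitutionSampler(1.5, np.random.default_rng(seed))
        assert substitute_base(base, sampler) != base

    def test_transition_fraction_matches_ratio(self, rng):
        # P(transition) = R/(R+1) = 0.6 at R=1.5
        sampler = SubstitutionSampler(1.5, rng)
        draws = [substitute_base("A", sampler) for _ in range(20_000)]
        frac_g = draws.count("G") / len(draws)
        assert 0.58 < frac_g < 0.62
        # the two transversions are equiprobable
        assert abs(draws.count("C") - draws.count("T")) < 4 * np.sqrt(len(draws) * 0.2)

    def test_zero_ratio_never_transitions(self, rng):
        sampler = SubstitutionSampler(0.0, rng)
        assert all(substitute_base("A", sampler) != "G" for _ in range(500))

    def test_ledger_ratio_converges(self, rng):
        sampler = SubstitutionSampler(1.5, rng)
        codes = rng.integers(0, 4, 100_000).astype(np.uint8)
        _, n_ts, n_tv = sampler.substitute_codes(codes)
        assert n_ts + n_tv == 100_000
        assert 1.4 < n_ts / n_tv < 1.6


class TestMutate:
    def test_zero_is_identity(self, rng):
        seq = random_sequence(100, rng)
        out, ledger = mutate(seq, 0, SubstitutionSampler(1.5, rng))
        assert out.bases == seq.bases and ledger.total == 0

    def test_exact_hamming_distance_and_ledger(self, rng):
        seq = random_sequence(500, rng)
        out, ledger = mutate(seq, 20, SubstitutionSampler(1.5, rng))
        diff = sum(a != b for a, b in zip(seq.bases, out.bases))
        assert diff == 20 == ledger.total
        assert len(out) == len(seq)

    def test_termini_protected(self, rng):
        seq = random_sequence(30, rng)
        out, _ = mutate(seq, 20, SubstitutionSampler(1.5, rng), protect_termini=True)
        assert out.bases[:2] == "GT" and out.bases[-2:] == "AG"

    def test_infeasible(self, rng):
        with pytest.raises(InfeasibleEventError):
            mutate(random_sequence(10, rng), 7, SubstitutionSampler(1.5, rng))

    def test_ledgers_conserve_across_calls(self, rng):
        seq = random_sequence(200, rng)
        total = MutationLedger()
        for n in (5, 7, 11):
            seq, led = mutate(seq, n, SubstitutionSampler(1.5, rng))
            total.absorb(led)
        assert total.total == 23 and len(total.positions) == 23


class TestIndels:
    @given(st.integers(10, 80), st.integers(0, 40), st.integers(0, 100))
    def test_length_arithmetic(self, length, block, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(length, rng)
        grown = insert_block(seq, block, rng)
        assert len(grown) == length + block
        assert grown.bases[:2] == "GT" and grown.bases[-2:] == "AG"
        if block <= length - 4:
            shrunk = delete_block(seq, block, rng)
            assert len(shrunk) == length - block
            assert shrunk.bases[:2] == "GT" and shrunk.bases[-2:] == "AG"

    def test_zero_block_identity(self, rng):
        seq = random_sequence(50, rng)
        assert delete_block(seq, 0, rng).bases == seq.bases
        assert insert_block(seq, 0, rng).bases == seq.bases

    def test_deletion_is_contiguous_cut(self, rng):
        seq = random_sequence(200, rng)
        out = delete_block(seq, 40, rng)
        # result must be prefix + suffix of the input for some cut point
        assert any(
            seq.bases[:i] + seq.bases[i + 40 :] == out.bases
            for i in range(2, len(seq) - 41)
        )

    def test_deletion_too_large(self, rng):
        with pytest.raises(InfeasibleEventError):
            delete_block(random_sequence(20, rng), 17, rng)

    def test_insertion_junction_uniform(self, rng):
        # junctions 2..len-2 of a length-12 sequence: 9 possible positions.
        # An inserted base equal to its neighbour makes several junctions
        # produce the same string; all class members are a priori
        # equiprobable, so spreading each observation over its compatible
        # junctions keeps the expected histogram uniform.
        seq = Sequence("GTACGTACGTAG")
        counts = np.zeros(13)
        for _ in range(9000):
            out = insert_block(seq, 1, rng)
            compatible = [
                j
                for j in range(2, 11)
                if seq.bases[:j] + out.bases[j] + seq.bases[j:] == out.bases
            ]
            for j in compatible:
                counts[j] += 1.0 / len(compatible)
        observed = counts[2:11]
        p = sps.chisquare(observed).pvalue
        assert p > 0.01

    def test_repeated_capped_deletion_hits_exact_target(self):
        # shrink 6000 -> 376 with draws from 31..50, final draw capped
        for seed in range(300):
            rng = np.random.default_rng(seed)
            seq = random_sequence(6000, rng)
            while len(seq) > 376:
                block = min(draw_from_range(31, 50, rng), len(seq) - 376)
                seq = delete_block(seq, block, rng)
            assert len(seq) == 376


class TestDrawFromRange:
    def test_degenerate_and_bounds(self, rng):
        assert draw_from_range(31, 31, rng) == 31
        assert all(11 <= draw_from_range(11, 20, rng) <= 20 for _ in range(500))

    def test_uniformity(self, rng):
        draws = [draw_from_range(31, 50, rng) for _ in range(100_000)]
        freqs = np.bincount(draws, minlength=51)[31:51] / 100_000
        assert freqs.min() > 0.04 and freqs.max() < 0.06

    def test_empty_range(self, rng):
        with pytest.raises(RangeError):
            draw_from_range(5, 4, rng)
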