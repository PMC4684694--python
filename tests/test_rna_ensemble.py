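"""The folding engine against its exhaustive-enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polarix.rna_ensemble import (
    EnergyModel,
    base_pair_probabilities,
    count_structures,
    ensemble_relative_entropy,
    enumerate_structures,
    enumeration_reference,
    extract_window,
    log_partition_function,
    mfe,
    partition_function,
    score_structural_effect,
    structural_distance,
)

MODEL = EnergyModel()


def _random_case(rng, nmin=5, nmax=14):
    n = int(rng.integers(nmin, nmax + 1))
    seq = "".join(rng.choice(list("ACGU"), n))
    pos = int(rng.integers(n))
    alt = str(rng.choice([c for c in "ACGU" if c != seq[pos]]))
    return seq, pos, alt


class TestEnumeration:
    def test_no_admissible_pair(self):
        structs = enumerate_structures("ACGU", MODEL)
        assert structs == [((), 0)]

    def test_single_closing_pair(self):
        structs = sorted(enumerate_structures("GAAAC", MODEL))
        assert structs == [((), 0), (((0, 4),), -3.0)]

    @pytest.mark.parametrize("seq", ["GGGAAACCC", "GCGCAAAGCGC", "AUGCUAGCUAGG"])
    def test_count_matches_independent_recursion(self, seq):
        assert len(enumerate_structures(seq, MODEL)) == count_structures(seq, MODEL)

    def test_length_guard(self):
        with pytest.raises(ValueError):
            enumerate_structures("A" * 21, MODEL)


class TestMFE:
    def test_empty_structure_for_unpairable(self):
        assert mfe("ACGU", MODEL) == (0.0, ())

    def test_single_hairpin(self):
        assert mfe("GAAAC", MODEL) == (-3.0, ((0, 4),))

    def test_never_positive(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            seq, _, _ = _random_case(rng)
            assert mfe(seq, MODEL)[0] <= 0.0

    def test_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            seq, _, _ = _random_case(rng)
            emin = min(e for _, e in enumerate_structures(seq, MODEL))
            assert mfe(seq, MODEL)[0] == pytest.approx(emin, abs=1e-12)


class TestPartitionFunction:
    def test_unpairable_sequence(self):
        assert partition_function("ACGU", MODEL) == pytest.approx(1.0)

    def test_single_hairpin_value(self):
        assert partition_function("GAAAC", MODEL) == pytest.approx(1 + math.e**3, rel=1e-12)

    def test_bounded_below_by_mfe_term(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            seq, _, _ = _random_case(rng)
            logZ = log_partition_function(seq, MODEL)
            assert logZ >= -MODEL.beta * mfe(seq, MODEL)[0] - 1e-9


class TestBPP:
    def test_single_hairpin_probability(self):
        p = base_pair_probabilities("GAAAC", MODEL).p
        assert p[0, 4] == pytest.approx(math.e**3 / (1 + math.e**3), rel=1e-12)

    def test_no_pairs_inside_min_loop(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            seq, _, _ = _random_case(rng, 8, 14)
            p = base_pair_probabilities(seq, MODEL).p
            for i in range(len(seq)):
                for j in range(i, min(i + MODEL.min_loop + 1, len(seq))):
                    assert p[i, j] == 0.0

    def test_row_sums_are_probabilities(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq, _, _ = _random_case(rng, 14, 14)
            p = base_pair_probabilities(seq, MODEL).p
            full = p + p.T
            assert (full.sum(axis=1) <= 1 + 1e-9).all()
            assert (p >= 0).all() and (p <= 1).all()


class TestRelativeEntropy:
    def test_identical_alleles_zero(self):
        assert ensemble_relative_entropy("GAAAC", "GAAAC", 2, MODEL) == 0.0

    def test_worked_example(self):
        # closed form: ln((1+e^-8)/(1+e^3)) + p(0,4) * (8 - (-3))
        p = math.e**3 / (1 + math.e**3)
        expected = math.log((1 + math.exp(-8)) / (1 + math.exp(3))) + 11 * p
        d = ensemble_relative_entropy("GAAAC", "GAAAA", 4, MODEL)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(7.43, abs=0.01)
        ref = enumeration_reference("GAAAC", "GAAAA", MODEL)
        assert ref["relative_entropy"] == pytest.approx(d, abs=1e-9)

    def test_nonnegative_on_random_draws(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            seq, pos, alt = _random_case(rng, 12, 12)
            mut = seq[:pos] + alt + seq[pos + 1 :]
            assert ensemble_relative_entropy(seq, mut, pos, MODEL) >= 0.0

    def test_direction_flag(self):
        seq, mut = "GAAAC", "GAAAA"
        fwd = ensemble_relative_entropy(seq, mut, 4, MODEL)
        rev = ensemble_relative_entropy(seq, mut, 4, MODEL, direction="mut||wt")
        ref = enumeration_reference(mut, seq, MODEL)
        assert rev == pytest.approx(ref["relative_entropy"], abs=1e-9)
        assert fwd != pytest.approx(rev)  # KL is asymmetric here

    def test_invariant_to_temperature_energy_rescaling(self):
        # the ensemble depends on beta*E only, so (beta, E) -> (2beta, E/2)
        # leaves every probability and hence D unchanged
        half = EnergyModel(
            pair_energy={k: v / 2 for k, v in MODEL.pair_energy.items()},
            noncanonical_energy=MODEL.noncanonical_energy / 2,
            beta=2.0,
        )
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq, pos, alt = _random_case(rng, 10, 12)
            mut = seq[:pos] + alt + seq[pos + 1 :]
            d1 = ensemble_relative_entropy(seq, mut, pos, MODEL)
            d2 = ensemble_relative_entropy(seq, mut, pos, half)
            assert d2 == pytest.approx(d1, rel=1e-9, abs=1e-12)

    def test_rejects_multi_site_difference(self):
        with pytest.raises(ValueError):
            ensemble_relative_entropy("GAAAC", "CAAAG", 0, MODEL)


class TestStructuralDistance:
    def test_identity_and_symmetry(self):
        b1 = base_pair_probabilities("GAAAC", MODEL)
        b2 = base_pair_probabilities("GAAAA", MODEL)
        assert structural_distance(b1, b1) == 0.0
        assert structural_distance(b1, b2) == structural_distance(b2, b1)

    def test_worked_value(self):
        b1 = base_pair_probabilities("GAAAC", MODEL)
        b2 = base_pair_probabilities("GAAAA", MODEL)
        p1 = math.e**3 / (1 + math.e**3)
        p2 = math.exp(-8) / (1 + math.exp(-8))
        assert structural_distance(b1, b2) == pytest.approx(abs(p1 - p2), abs=1e-12)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            seqs = ["".join(rng.choice(list("ACGU"), 12)) for _ in range(3)]
            a, b, c = (base_pair_probabilities(s, MODEL) for s in seqs)
            assert structural_distance(a, c) <= (
                structural_distance(a, b) + structural_distance(b, c) + 1e-12
            )


class TestWindow:
    def test_centered(self):
        seq = "A" * 1000
        win, off = extract_window(seq, 200, 150)
        assert (len(win), off) == (150, 75)
        assert 200 - off == 125  # window [125, 275)

    def test_truncated_at_start(self):
        win, off = extract_window("A" * 1000, 10, 150)
        assert (len(win), off) == (85, 10)  # [0, 85)

    def test_width_exceeds_transcript(self):
        win, off = extract_window("A" * 50, 20, 150)
        assert (len(win), off) == (50, 20)


class TestScoreStructuralEffect:
    def test_identity_substitution_is_all_zero(self):
        eff = score_structural_effect("GAAACGGG", 2, "A", "A", MODEL, width=11)
        assert (eff.relative_entropy, eff.mfe_gap, eff.bpp_distance) == (0, 0, 0)

    def test_reference_mismatch_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            score_structural_effect("GAAAC", 2, "G", "C", MODEL, width=11)

    def test_oracle_equivalence_on_short_windows(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            seq, pos, alt = _random_case(rng, 8, 14)
            mut = seq[:pos] + alt + seq[pos + 1 :]
            ref = enumeration_reference(seq, mut, MODEL)
            eff = score_structural_effect(seq, pos, seq[pos], alt, MODEL, width=30)
            assert eff.relative_entropy == pytest.approx(
                ref["relative_entropy"], rel=1e-9, abs=1e-9
            )
            assert eff.mfe_gap == pytest.approx(
                abs(ref["mfe_wt"] - ref["mfe_mut"]), abs=1e-9
            )
            assert eff.bpp_distance == pytest.approx(
                ref["bpp_distance"], rel=1e-9, abs=1e-9
            )

    def test_deterministic(self):
        a = score_structural_effect("GCGCAAAGCGCAU", 6, "A", "U", MODEL, width=13)
        b = score_structural_effect("GCGCAAAGCGCAU", 6, "A", "U", MODEL, width=13)
        assert a == b


@given(st.integers(0, 2**31 - 1))
def test_bpp_matches_enumeration_property(seed):
    rng = np.random.default_rng(seed)
    seq, _, _ = _random_case(rng, 5, 12)
    ref_bpp = enumeration_reference(seq, seq[:-1] + seq[-1], MODEL)["bpp_wt"]
    dp_bpp = base_pair_probabilities(seq, MODEL).p
    assert np.max(np.abs(ref_bpp - dp_bpp)) < 1e-9
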