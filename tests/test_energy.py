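import math

import pytest

import oracles
from conftest import random_rna
from starpick.energy import (
    ConstraintError,
    ViennaEngine,
    bundle,
    get_engine,
    open_energy,
)


class TestToyDuplex:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("GGG", "CCC", -9.0),  # three G-C pairs
            ("GAG", "CUC", -8.0),  # G-C, A-U, G-C
            ("AAAA", "AAAA", None),  # A.A cannot pair
        ],
    )
    def test_small_cases(self, toy_engine, a, b, expected):
        d = toy_engine.duplex_energy(a, b)
        assert d.energy == expected
        assert d.interacting == (expected is not None)

    def test_matches_enumeration_oracle(self, toy_engine, rng):
        for _ in range(60):
            n = int(rng.integers(2, 13))
            m = int(rng.integers(2, 25 - n))
            a, b = random_rna(rng, n), random_rna(rng, m)
            expected = oracles.duplex_mfe_enumeration(a, b)
            got = toy_engine.duplex_energy(a, b).energy
            assert got == expected, (a, b)

    def test_pairs_are_antiparallel_and_valid(self, toy_engine, rng):
        for _ in range(20):
            a, b = random_rna(rng, 10), random_rna(rng, 10)
            d = toy_engine.duplex_energy(a, b)
            prev = None
            for i, j in d.pairs:
                assert (a[i - 1], b[j - 1]) in oracles.PAIR_E
                if prev:
                    assert i > prev[0] and j < prev[1]
                prev = (i, j)


class TestToyEnsembleEnergy:
    def test_unstructured_sequence_is_zero(self, toy_engine):
        assert toy_engine.ensemble_energy("AAAAAAAAAA") == 0.0

    def test_constraint_vacuous_when_no_structure(self, toy_engine):
        assert toy_engine.ensemble_energy("AAAAAAAA", (2, 5)) == 0.0

    def test_matches_enumeration(self, toy_engine, rng):
        for _ in range(25):
            n = int(rng.integers(6, 17))
            s = random_rna(rng, n)
            expected = oracles.ensemble_free_energy_enumeration(s)
            assert toy_engine.ensemble_energy(s) == pytest.approx(expected, abs=1e-9)

    def test_constrained_matches_enumeration(self, toy_engine, rng):
        for _ in range(15):
            s = random_rna(rng, 14)
            lo = int(rng.integers(1, 10))
            hi = lo + int(rng.integers(0, 4))
            expected = oracles.ensemble_free_energy_enumeration(s, (lo, hi))
            assert toy_engine.ensemble_energy(s, (lo, hi)) == pytest.approx(
                expected, abs=1e-9
            )

    def test_constraint_never_lowers_free_energy(self, toy_engine, rng):
        for _ in range(30):
            s = random_rna(rng, int(rng.integers(8, 40)))
            lo = int(rng.integers(1, len(s) - 2))
            hi = lo + int(rng.integers(0, len(s) - lo))
            assert toy_engine.ensemble_energy(s, (lo, hi)) >= toy_engine.ensemble_energy(s) - 1e-9

    def test_region_out_of_bounds(self, toy_engine):
        with pytest.raises(ValueError):
            toy_engine.ensemble_energy("ACGU", (2, 9))


class TestOpenEnergy:
    def test_unstructured_context_is_zero(self, toy_engine):
        assert open_energy(toy_engine, "A" * 30, (5, 10)) == 0.0

    def test_nonnegative_on_random_inputs(self, toy_engine, rng):
        for _ in range(40):
            s = random_rna(rng, int(rng.integers(10, 60)))
            lo = int(rng.integers(1, len(s) - 4))
            hi = lo + int(rng.integers(0, 5))
            for policy in ("full_length", "flank_100"):
                assert open_energy(toy_engine, s, (lo, hi), policy) >= 0.0

    def test_hairpin_stem_matches_enumeration_difference(self, toy_engine):
        s = "GGGGAAAACCCC"
        region = (1, 4)
        expected = oracles.ensemble_free_energy_enumeration(
            s, region
        ) - oracles.ensemble_free_energy_enumeration(s)
        assert open_energy(toy_engine, s, region) == pytest.approx(expected, abs=1e-9)
        assert expected > 0

    def test_flank_policy_truncates_at_ends(self, toy_engine):
        s = "GGGGAAAACCCC" * 2
        full = open_energy(toy_engine, s, (5, 8), "flank_100")
        assert full >= 0.0  # flank longer than molecule: silently truncated


class TestBundle:
    @pytest.mark.parametrize(
        "h,s,t,ddg", [(-10, 3, 2, -5), (-10, 0, 0, -10)]
    )
    def test_sum(self, h, s, t, ddg):
        assert bundle(h, s, t).ddg == ddg

    def test_sentinel_marks_non_interacting(self):
        b = bundle(None, 1.0, 2.0)
        assert not b.interacting and b.ddg is None

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            bundle(math.inf, 0.0, 0.0)


class TestDeterminismAndCofold:
    def test_identical_calls_bit_identical(self, toy_engine, rng):
        s = random_rna(rng, 30)
        assert toy_engine.ensemble_energy(s) == toy_engine.ensemble_energy(s)
        a, b = random_rna(rng, 12), random_rna(rng, 12)
        assert toy_engine.duplex_energy(a, b) == toy_engine.duplex_energy(a, b)

    def test_cofold_forced_pairs_present(self, toy_engine):
        a, b = "GGGAAAA", "AAAACCC"
        forced = [(1, 7), (2, 6), (3, 5)]
        table, energy = toy_engine.cofold(a, b, forced)
        for i, j in forced:
            assert table.partner[i - 1] == len(a) + j - 1
        assert energy <= -9.0

    def test_cofold_matches_enumeration_on_small_instances(self, toy_engine, rng):
        for _ in range(15):
            a = random_rna(rng, 8) + "GGG"
            b = "CCC" + random_rna(rng, 8)
            forced = [(9, 3), (10, 2), (11, 1)]
            expected = oracles.cofold_mfe_enumeration(a, b, forced)
            table, energy = toy_engine.cofold(a, b, forced)
            assert energy == pytest.approx(expected[0], abs=1e-9)

    def test_cofold_unsatisfiable_raises(self, toy_engine):
        with pytest.raises((ConstraintError, ValueError)):
            toy_engine.cofold("AAA", "AAA", [(1, 3)])  # A-A cannot pair


@pytest.fixture(scope="module")
def vienna():
    return ViennaEngine()


class TestViennaAdapter:
    """Smoke coverage of the production nearest-neighbor engine."""

    def test_duplex_sign_and_sentinel(self, vienna):
        assert vienna.duplex_energy("GGGGG", "CCCCC").energy < 0
        assert not vienna.duplex_energy("AAAA", "AAAA").interacting

    def test_open_energy_nonnegative(self, vienna, rng):
        for _ in range(5):
            s = random_rna(rng, 60)
            assert open_energy(vienna, s, (20, 27), "flank_100") >= 0.0

    def test_cofold_honors_forced_pairs(self, vienna):
        a = "GGGAGAGAGAGAAAA"
        b = "AAAAGAGAGAGACCC"
        forced = [(1, 15), (2, 14), (3, 13)]
        table, _ = vienna.cofold(a, b, forced)
        for i, j in forced:
            assert table.partner[i - 1] == len(a) + j - 1

    def test_get_engine_dispatch(self, vienna, toy_engine):
        assert get_engine("toy").engine_id == toy_engine.engine_id
        assert get_engine("vienna").engine_id.startswith("vienna")
        with pytest.raises(ValueError):
            get_engine("nupack")
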