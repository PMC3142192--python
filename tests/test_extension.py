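import pytest

from starpick.extension import (
    JointStructure,
    cofold_with_seed,
    extend_seed,
    scan_outward,
    score_binding_site,
)
from starpick.io_formats import RnaSequence, dotbracket_to_table
from starpick.seeds import enumerate_helices, score_seed


def _planted_pair():
    # GACGUC pairs its own reverse complement in register only, so exactly
    # one helix is enumerated
    srna = RnaSequence("s", "A" * 10 + "GACGUC" + "A" * 10)
    window = RnaSequence("w", "A" * 30 + "GACGUC" + "A" * 30)
    (seed,) = enumerate_helices(srna, window)
    return srna, window, seed


class TestCofoldWithSeed:
    def test_seed_pairs_enforced(self, toy_engine):
        srna, window, seed = _planted_pair()
        joint = cofold_with_seed(srna, window, seed, toy_engine)
        n1 = len(srna)
        c_lo = joint.context_interval[0]
        for i, j in seed.pairs():
            assert joint.table.partner[i - 1] == n1 + (j - c_lo)

    def test_context_is_seed_plus_flank(self, toy_engine):
        srna, window, seed = _planted_pair()
        joint = cofold_with_seed(srna, window, seed, toy_engine, context_flank=10)
        assert joint.context_interval == (21, 46)  # truncation-free case

    def test_fully_complementary_pair_forms_full_duplex(self, toy_engine):
        srna = RnaSequence("s", "GCGCGCGCAU")
        window = RnaSequence("w", "AUGCGCGCGC")
        seed = max(enumerate_helices(srna, window), key=lambda s: s.length)
        joint = cofold_with_seed(srna, window, seed, toy_engine)
        inter = sum(
            1
            for i in range(1, len(joint.table) + 1)
            if joint.table.is_intermolecular(i)
        )
        assert inter == 20


def _joint_from_dotbracket(db: str, context_interval=None) -> JointStructure:
    """Hand-built joint structure; '&' separates sRNA and target context."""
    n1 = db.index("&")
    table = dotbracket_to_table(db)
    ctx = context_interval or (1, len(table) - n1)
    return JointStructure(table, n1, ctx, 0.0)


def _seed_for(joint: JointStructure, srna_iv, target_iv):
    from starpick.seeds import SeedMatch

    ln = srna_iv[1] - srna_iv[0] + 1
    return SeedMatch(
        srna_interval=srna_iv,
        target_interval=target_iv,
        length=ln,
        n_gc=ln,
        n_gu=0,
        n_au=0,
        max_consecutive_gc=ln,
    )


class TestScanOutward:
    def test_no_intramolecular_pairs_site_spans_outermost_inter(self):
        #        srna: 1-10, seed 4-6 paired to target 6-8, extra pair 2<->10
        db = ".(.(((...)&....))).)...."
        # positions:  srna 2 pairs target ...; build explicitly instead
        db = "..((((....&..))))......."
        joint = _joint_from_dotbracket(db)
        seed = _seed_for(joint, (3, 6), (3, 6))
        site = scan_outward(joint, seed)
        assert site.srna_site == (3, 6)
        assert site.target_site == (3, 6)

    def test_hairpin_left_of_seed_halts_left_scan(self):
        # sRNA: hairpin (1..2 with 6..7), then seed at 8-10
        srna_part = "((...))((("
        target_part = ")))....."
        joint = _joint_from_dotbracket(srna_part + "&" + target_part)
        seed = _seed_for(joint, (8, 10), (1, 3))
        site = scan_outward(joint, seed)
        # left boundary stops at the seed edge: position 7 is intramolecular
        assert site.srna_site[0] == 8

    def test_mixed_structure_matches_manual_trace(self):
        # sRNA: seed 3-5; inter pair at 7; intramolecular hairpin at 9..14
        #        1 2 3 4 5 6 7 8 9...14
        srna_part = "..(((.(.((...))"
        target_part = "...).)))......."
        # target: inter ) at 4 (pairs srna 7), 6,7,8 close seed; rest dots
        joint = _joint_from_dotbracket(srna_part + "&" + target_part)
        seed = _seed_for(joint, (3, 5), (6, 8))
        site = scan_outward(joint, seed)
        # manual trace: right scan on sRNA passes unpaired 6, inter 7,
        # unpaired 8, halts at 9 (intramolecular); site clipped to
        # outermost inter pair = 7
        assert site.srna_site == (3, 7)
        # target: left scan passes unpaired 5, inter 4 ... down to 1
        # (all unpaired); clipped to outermost inter pair = 4
        assert site.target_site == (4, 8)
        assert (7, 4) in site.hybrid_pairs

    def test_returned_site_never_contains_intramolecular_pairs(self, toy_engine, rng):
        from starpick.fixtures import PlantSpec, generate_pair

        checked = 0
        for k in range(8):
            spec = PlantSpec(seed_len=7, n_gc=5, rng_seed=200 + k)
            srna, target, truth = generate_pair(spec)
            for seed in enumerate_helices(srna, target):
                joint = cofold_with_seed(srna, target, seed, toy_engine)
                site = scan_outward(joint, seed)
                n1 = len(srna)
                c_lo = joint.context_interval[0]
                for p in range(site.srna_site[0], site.srna_site[1] + 1):
                    assert not joint.table.is_intramolecular(p)
                for w in range(site.target_site[0], site.target_site[1] + 1):
                    assert not joint.table.is_intramolecular(n1 + (w - c_lo) + 1)
                # site always contains its seed
                assert site.srna_site[0] <= seed.srna_interval[0]
                assert site.srna_site[1] >= seed.srna_interval[1]
                checked += 1
        assert checked >= 8

    def test_deterministic(self, toy_engine):
        srna, window, seed = _planted_pair()
        a = extend_seed(srna, window, seed, toy_engine)
        b = extend_seed(srna, window, seed, toy_engine)
        assert (a.srna_site, a.target_site, a.hybrid_pairs) == (
            b.srna_site,
            b.target_site,
            b.hybrid_pairs,
        )


class TestScoreBindingSite:
    def test_site_identical_to_seed_equals_seed_scores(self, toy_engine):
        srna, window, seed = _planted_pair()
        score_seed(seed, srna, window, toy_engine)
        site = extend_seed(srna, window, seed, toy_engine)
        assert (site.srna_site, site.target_site) == (
            seed.srna_interval,
            seed.target_interval,
        )
        score_binding_site(site, srna, window, toy_engine)
        assert site.dg_binding == seed.dg_hybrid_seed
        assert site.ddg_binding == seed.ddg_seed

    def test_unstructured_context_ddg_equals_dg(self, toy_engine):
        # neither molecule can pair intramolecularly (G/A vs C/A alphabets)
        srna = RnaSequence("s", "A" * 10 + "GGGGGG" + "A" * 10)
        window = RnaSequence("w", "A" * 30 + "CCCCCC" + "A" * 30)
        seed = max(enumerate_helices(srna, window), key=lambda s: s.length)
        site = extend_seed(srna, window, seed, toy_engine)
        score_binding_site(site, srna, window, toy_engine)
        assert site.ddg_binding == site.dg_binding == -18.0
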