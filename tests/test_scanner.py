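import random

import pytest

from zfndesign.archive import FingerModule, ModuleArchive
from zfndesign.grammar import (
    Arch,
    DimerConfiguration,
    SkipPlan,
    enumerate_configurations,
    enumerate_skip_plans,
)
from zfndesign.scanner import (
    BindingSite,
    count_designs,
    find_zfp_sites,
    pair_dimers,
    targeting_density,
)
from zfndesign.simulate import plant_design, random_genome

from ._oracles import brute_force_pairs, brute_force_sites
from .conftest import random_archive

NOSKIP6 = SkipPlan(6)


def _site_key(s: BindingSite):
    return (s.start, s.end, s.strand, s.skip_plan, s.module_ids)


class TestFindSites:
    def test_polyg_top_strand_site(self, gnn_archive):
        sites = find_zfp_sites("G" * 18, gnn_archive, 6, [NOSKIP6])
        hits = [s for s in sites if s.start == 0 and s.strand == "+"]
        assert len(hits) == 1
        assert hits[0].matched_triplets == ("GGG",) * 6
        assert hits[0].end == 18

    def test_empty_and_short_sequences(self, gnn_archive):
        assert find_zfp_sites("", gnn_archive, 6, [NOSKIP6]) == []
        assert find_zfp_sites("G" * 17, gnn_archive, 6, [NOSKIP6]) == []

    def test_non_g_first_base_blocks_offset_zero(self, gnn_archive):
        seq = "T" + "G" * 17
        sites = find_zfp_sites(seq, gnn_archive, 6, [NOSKIP6])
        assert not any(s.start == 0 and s.strand == "+" for s in sites)

    def test_invalid_finger_count(self, gnn_archive):
        with pytest.raises(ValueError):
            find_zfp_sites("G" * 18, gnn_archive, 4)

    def test_empty_archive_rejected(self):
        with pytest.raises(ValueError):
            find_zfp_sites("G" * 18, ModuleArchive(name="e"), 6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = random.Random(seed)
        archive = random_archive(rng)
        n = rng.randrange(25, 120)
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        fc = rng.choice([5, 6])
        plans = enumerate_skip_plans(fc)
        got = {_site_key(s) for s in find_zfp_sites(seq, archive, fc, plans)}
        expected = brute_force_sites(seq, archive, fc, plans)
        assert got == expected

    def test_deterministic_order_and_repeatability(self, gnn_archive):
        seq = random_genome(150, 0.6, 3)
        a = find_zfp_sites(seq, gnn_archive, 6)
        b = find_zfp_sites(seq, gnn_archive, 6)
        assert a == b
        assert a == sorted(a, key=lambda s: (s.start, s.strand, s.skip_plan.sort_key(), s.module_ids))


class TestPairDimers:
    def _two_opposite_sites(self, gnn_archive, gap):
        # plant a CC geometry and rediscover the two sites
        cfg = DimerConfiguration(Arch.CC, gap, NOSKIP6, NOSKIP6)
        genome, _ = plant_design(random_genome(120, 0.5, 4), 60, cfg, gnn_archive, seed=5)
        sites = find_zfp_sites(genome, gnn_archive, 6, [NOSKIP6])
        return sites, cfg

    def test_cc_pair_found_exactly_once(self, gnn_archive):
        sites, cfg = self._two_opposite_sites(gnn_archive, 6)
        designs = pair_dimers(sites, [cfg])
        planted = [d for d in designs if d.cleavage_base_step == 60]
        assert len(planted) == 1
        assert planted[0].left.strand == "-" and planted[0].right.strand == "+"

    def test_nc_only_configs_reject_opposite_strands(self, gnn_archive):
        sites, _ = self._two_opposite_sites(gnn_archive, 6)
        nc = DimerConfiguration(Arch.NC, 6, NOSKIP6, NOSKIP6)
        assert pair_dimers(sites, [nc]) == []

    def test_one_planted_design_per_architecture(self, gnn_archive):
        configs = [
            DimerConfiguration(a, g, NOSKIP6, NOSKIP6)
            for a, g in [(Arch.CC, 6), (Arch.NC, 6), (Arch.CN, 7), (Arch.NN, 8)]
        ]
        for cfg in configs:
            genome, _ = plant_design(random_genome(120, 0.5, 8), 60, cfg, gnn_archive, seed=6)
            sites = find_zfp_sites(genome, gnn_archive, 6, [NOSKIP6])
            designs = pair_dimers(sites, configs)
            archs = {d.layout.config.arch for d in designs if d.cleavage_base_step == 60}
            assert cfg.arch in archs

    def test_input_order_invariance(self, gnn_archive):
        sites, cfg = self._two_opposite_sites(gnn_archive, 6)
        shuffled = list(sites)
        random.Random(1).shuffle(shuffled)
        assert pair_dimers(sites, [cfg]) == pair_dimers(shuffled, [cfg])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = random.Random(100 + seed)
        archive = random_archive(rng, n_two=3, n_one=2)
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randrange(40, 120)))
        configs = enumerate_configurations(list(Arch), [6], skips_enabled=True)
        sites = find_zfp_sites(seq, archive, 6)
        got = {
            (
                (d.left.start, d.left.end, d.left.strand, d.left.module_ids),
                (d.right.start, d.right.end, d.right.strand, d.right.module_ids),
                d.layout.config.label(),
            )
            for d in pair_dimers(sites, configs)
        }
        expected = brute_force_pairs([_site_key(s) for s in sites], configs)
        assert got == expected


class TestDensity:
    def test_no_designs_zero(self):
        prof = targeting_density([], (100, 128))
        assert prof.density == 0.0 and len(prof.counts) == 28

    def test_full_coverage_one(self, gnn_archive):
        cfg = DimerConfiguration(Arch.CC, 6, NOSKIP6, NOSKIP6)
        designs = []
        for step in range(100, 105):
            genome, _ = plant_design(random_genome(250, 0.5, step), step, cfg, gnn_archive, seed=step)
            sites = find_zfp_sites(genome, gnn_archive, 6, [NOSKIP6])
            designs.extend(d for d in pair_dimers(sites, [cfg]) if d.cleavage_base_step == step)
        prof = targeting_density(designs, (100, 105))
        assert prof.density == 1.0

    def test_partial_coverage_arithmetic(self, gnn_archive):
        # 25 covered of 28 base steps, the printed-scan fixture arithmetic
        cfg = DimerConfiguration(Arch.CC, 6, NOSKIP6, NOSKIP6)
        designs = []
        for step in range(100, 128):
            if step in (103, 110, 120):
                continue
            genome, _ = plant_design(random_genome(250, 0.5, step), step, cfg, gnn_archive, seed=step)
            sites = find_zfp_sites(genome, gnn_archive, 6, [NOSKIP6])
            designs.extend(d for d in pair_dimers(sites, [cfg]) if d.cleavage_base_step == step)
        prof = targeting_density(designs, (100, 128))
        assert prof.covered == 25
        assert prof.density == pytest.approx(25 / 28)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            targeting_density([], (5, 5))


class TestInvariants:
    def test_monotone_in_configs_and_archive(self, gnn_archive):
        seq = random_genome(300, 0.6, 42)
        canonical = enumerate_configurations([Arch.CC], [6], skips_enabled=False)
        expanded = enumerate_configurations(list(Arch), [6], skips_enabled=True)
        assert count_designs(seq, gnn_archive, canonical) <= count_designs(
            seq, gnn_archive, expanded
        )
        smaller = ModuleArchive(name="half", modules=gnn_archive.modules[::2])
        if any(m.n_fingers == 2 for m in smaller.modules):
            assert count_designs(seq, smaller, expanded) <= count_designs(
                seq, gnn_archive, expanded
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_reverse_complement_mirrors_designs_with_nc_cn_swapped(self, seed):
        from zfndesign._iupac import revcomp

        rng = random.Random(200 + seed)
        archive = random_archive(rng, n_two=3, n_one=0, degenerate=False)
        # force gap sets equal across mirrored pairs so the swap is exact
        gap_sets = {a: (5, 6, 7) for a in Arch}
        configs = enumerate_configurations(
            list(Arch), [6], skips_enabled=True, gap_sets=gap_sets
        )
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randrange(50, 120)))
        L = len(seq)
        fwd = pair_dimers(find_zfp_sites(seq, archive, 6), configs)
        rev = pair_dimers(find_zfp_sites(revcomp(seq), archive, 6), configs)
        swap = {"CC": "CC", "NN": "NN", "NC": "CN", "CN": "NC"}
        flip = {"+": "-", "-": "+"}

        def mirror(d):
            l, r = d.left, d.right
            return (
                (L - r.end, L - r.start, flip[r.strand], r.module_ids),
                (L - l.end, L - l.start, flip[l.strand], l.module_ids),
                swap[d.layout.config.arch.value],
                d.layout.config.gap_bp,
            )

        def key(d):
            l, r = d.left, d.right
            return (
                (l.start, l.end, l.strand, l.module_ids),
                (r.start, r.end, r.strand, r.module_ids),
                d.layout.config.arch.value,
                d.layout.config.gap_bp,
            )

        assert {mirror(d) for d in fwd} == {key(d) for d in rev}
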