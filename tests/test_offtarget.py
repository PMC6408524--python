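import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfndesign.offtarget import (
    EventCluster,
    FilterParams,
    IntegrationEvent,
    apply_filters,
    call_candidate_loci,
    cluster_events,
    dedupe_events,
    replicate_consensus,
)
from zfndesign.simulate import simulate_capture_events

from ._oracles import brute_force_clusters


def ev(chrom="chr1", pos=0, strand="+", n_best=1, rep="rep1", arm="treated"):
    return IntegrationEvent(chrom, pos, strand, n_best, rep, arm)


def _cluster(chrom, start, end, n_events, rep="rep1", n_best=1):
    events = [ev(chrom, start + i % max(1, end - start), rep=rep, n_best=n_best) for i in range(n_events)]
    return EventCluster(chrom, start, end, events)


ON_TARGET = ("chr9", 1_000_000, 1_000_100)


class TestDedupe:
    def test_identical_events_collapse(self):
        assert len(dedupe_events([ev(pos=5), ev(pos=5)])) == 1

    def test_opposite_strands_both_kept(self):
        assert len(dedupe_events([ev(pos=5, strand="+"), ev(pos=5, strand="-")])) == 2

    def test_counting(self):
        events = [ev(pos=p) for p in [1, 2, 3, 4, 5, 6, 7, 1, 2, 3]]
        assert len(dedupe_events(events)) == 7

    def test_replicate_and_arm_distinguish(self):
        events = [ev(pos=1, rep="rep1"), ev(pos=1, rep="rep2"), ev(pos=1, arm="control")]
        assert len(dedupe_events(events)) == 3


class TestClustering:
    def test_within_window_joins(self):
        clusters = cluster_events([ev(pos=1000), ev(pos=1050)])
        assert len(clusters) == 1
        assert clusters[0].count == 2

    def test_beyond_window_splits(self):
        assert len(cluster_events([ev(pos=1000), ev(pos=1150)])) == 2

    def test_single_linkage_chain(self):
        clusters = cluster_events([ev(pos=0), ev(pos=90), ev(pos=180)])
        assert len(clusters) == 1

    def test_chromosomes_never_mix(self):
        clusters = cluster_events([ev("chr1", 100), ev("chr2", 100)])
        assert len(clusters) == 2

    @given(st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(0, 2000)),
        max_size=30,
    ), st.randoms())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_matches_components_and_order_invariant(self, points, rnd):
        events = dedupe_events([ev(c, p) for c, p in points])
        shuffled = list(events)
        rnd.shuffle(shuffled)
        clusters = cluster_events(shuffled, window_bp=100)
        # partition: every event in exactly one cluster
        assert sum(c.count for c in clusters) == len(events)
        got = {
            frozenset((e.chrom, e.pos, e.strand, e.replicate, e.arm) for e in c.events)
            for c in clusters
        }
        assert got == brute_force_clusters(events, 100)


class TestFilters:
    def test_fivefold_boundary(self):
        params = FilterParams()
        controls = [ev("chr1", 100 + i, arm="control") for i in range(2)]
        passing = apply_filters([_cluster("chr1", 100, 150, 10)], controls, ON_TARGET, params)
        assert len(passing) == 1  # 10 >= 5*2
        failing = apply_filters([_cluster("chr1", 100, 150, 9)], controls, ON_TARGET, params)
        assert failing == []  # 9 < 10

    def test_zero_control_passes(self):
        assert apply_filters([_cluster("chr1", 100, 150, 1)], [], ON_TARGET) != []

    def test_multimap_rule_excludes_three_best_hits(self):
        c = _cluster("chr1", 100, 150, 8, n_best=3)
        assert apply_filters([c], [], ON_TARGET) == []
        assert not c.filter_flags["multimap_pass"]
        c2 = _cluster("chr1", 100, 150, 8, n_best=2)
        assert apply_filters([c2], [], ON_TARGET) != []

    def test_distance_rule(self):
        near = _cluster(ON_TARGET[0], ON_TARGET[2] + 5_000, ON_TARGET[2] + 5_050, 8)
        far = _cluster(ON_TARGET[0], ON_TARGET[2] + 50_000, ON_TARGET[2] + 50_050, 8)
        passed = apply_filters([near, far], [], ON_TARGET)
        assert passed == [far]
        assert not near.filter_flags["distance_pass"]

    def test_unknown_chromosome_excluded(self):
        weird = _cluster("chrUn_KI270442v1", 100, 150, 8)
        assert apply_filters([weird], [], ON_TARGET) == []
        assert apply_filters([_cluster("chr12", 100, 150, 8)], [], ON_TARGET) != []

    def test_relaxing_thresholds_is_monotone(self):
        rng = random.Random(7)
        clusters = [
            _cluster("chr1", p, p + 50, rng.randrange(1, 12), n_best=rng.choice([1, 2, 3]))
            for p in range(0, 100_000, 5_000)
        ]
        controls = [ev("chr1", p + 10, arm="control") for p in range(0, 100_000, 10_000)]
        strict = FilterParams(fold=5, max_best_hits=3, min_distance=10_000)
        lax = FilterParams(fold=2, max_best_hits=10, min_distance=1_000)
        kept_strict = {(c.chrom, c.start) for c in apply_filters(clusters, controls, ON_TARGET, strict)}
        kept_lax = {(c.chrom, c.start) for c in apply_filters(clusters, controls, ON_TARGET, lax)}
        assert kept_strict <= kept_lax


class TestConsensus:
    def _candidates(self, support, chrom="chr1", start=100):
        return {
            f"rep{i}": [_cluster(chrom, start, start + 60, 10, rep=f"rep{i}")]
            for i in range(1, support + 1)
        }

    def test_two_of_four_retained(self):
        per_rep = self._candidates(2)
        per_rep.update({"rep3": [], "rep4": []})
        loci = replicate_consensus(per_rep)
        assert len(loci) == 1 and loci[0].replicate_support == 2

    def test_one_of_four_dropped(self):
        per_rep = self._candidates(1)
        per_rep.update({"rep2": [], "rep3": [], "rep4": []})
        assert replicate_consensus(per_rep) == []

    def test_ranking_with_stable_tie_break(self):
        per_rep = {
            "rep1": [
                _cluster("chr1", 100, 160, 60, "rep1"),
                _cluster("chr2", 500, 560, 4, "rep1"),
                _cluster("chr1", 9_000, 9_060, 4, "rep1"),
            ],
            "rep2": [
                _cluster("chr1", 120, 180, 60, "rep2"),
                _cluster("chr2", 510, 570, 3, "rep2"),
                _cluster("chr1", 9_010, 9_070, 3, "rep2"),
            ],
        }
        loci = replicate_consensus(per_rep)
        assert [l.rank for l in loci] == [1, 2, 3]
        assert loci[0].capture_events == 120
        # tie at 7 events: ordered by (chrom, start)
        assert (loci[1].chrom, loci[1].start) == ("chr1", 9_000)
        assert (loci[2].chrom, loci[2].start) == ("chr2", 500)

    def test_on_target_ranked_first(self):
        per_rep = {
            "rep1": [
                _cluster("chr1", 100, 160, 60, "rep1"),
                _cluster(*ON_TARGET[:1], ON_TARGET[1], ON_TARGET[2], 5, "rep1"),
            ],
            "rep2": [
                _cluster("chr1", 100, 160, 60, "rep2"),
                _cluster(*ON_TARGET[:1], ON_TARGET[1], ON_TARGET[2], 5, "rep2"),
            ],
        }
        loci = replicate_consensus(per_rep, on_target=ON_TARGET)
        assert loci[0].is_on_target and loci[0].rank == 1


class TestPipelineOnSimulatedData:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_exactly_the_planted_set(self, seed):
        true_loci = [("chr1", 2_000_000, 2_000_060, 15.0), ("chr5", 800_000, 800_060, 10.0)]
        treated, control, _ = simulate_capture_events(
            true_loci,
            control_rate=0.0,
            n_replicates=4,
            seed=seed,
            shared_loci=[("chr2", 3_000_000, 3_000_060, 8.0, 8.0)],
            multimap_loci=[("chr3", 4_000_000, 4_000_060, 12.0)],
        )
        # a decoy inside the 10 kb exclusion zone around the on-target
        near = [
            ev(ON_TARGET[0], ON_TARGET[1] + 2_000 + i, rep=f"rep{r}")
            for r in range(1, 5)
            for i in range(8)
        ]
        loci = call_candidate_loci(treated + near, control, ON_TARGET)
        assert {(l.chrom,) for l in loci} == {("chr1",), ("chr5",)}
        assert all(l.replicate_support >= 2 for l in loci)
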