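import numpy as np
import pandas as pd
import pytest

from apoclust import cluster_detect as cd
from apoclust import neighbor_graph as ng
from oracles import components_bruteforce, death_pairs_bruteforce

from conftest import make_fates


def chain_graph(ids, spacing=10.0):
    """Static path graph 0-1-2-... at the given spacing."""
    positions = {cid: (k * spacing, 0.0) for k, cid in enumerate(ids)}
    edges = {tuple(sorted((ids[k], ids[k + 1]), key=str)) for k in range(len(ids) - 1)}
    return ng.NeighborGraph(0, frozenset(ids), frozenset(edges), positions, 2 * spacing)


class TestFindDeathPairs:
    def test_adjacent_one_frame_apart_pairs(self):
        fates = make_fates([("A", 12, 0, 0), ("B", 13, 10, 0)], movie_end_frame=30)
        g = chain_graph(["A", "B"])
        pairs = cd.find_death_pairs(fates, g)
        assert len(pairs) == 1
        assert {pairs[0].cell_a, pairs[0].cell_b} == {"A", "B"}

    def test_margin_exceeded_no_pair(self):
        fates = make_fates([("A", 12, 0, 0), ("B", 14, 10, 0)], movie_end_frame=30)
        assert cd.find_death_pairs(fates, chain_graph(["A", "B"])) == []

    def test_nonadjacent_same_frame_no_pair(self):
        fates = make_fates([("A", 12, 0, 0), ("B", 12, 10, 0), ("C", 12, 20, 0)],
                           movie_end_frame=30)
        pairs = cd.find_death_pairs(fates, chain_graph(["A", "B", "C"]))
        assert all({p.cell_a, p.cell_b} != {"A", "C"} for p in pairs)

    def test_censored_cells_never_pair(self):
        fates = make_fates([("A", 12, 0, 0), ("B", 12, 10, 0), ("C", 30, 20, 0)],
                           movie_end_frame=30)
        pairs = cd.find_death_pairs(fates, chain_graph(["A", "B", "C"]))
        assert all("C" not in (p.cell_a, p.cell_b) for p in pairs)

    def test_margin_monotonicity(self):
        rng = np.random.default_rng(0)
        recs = [(i, int(rng.integers(0, 15)), 10.0 * i, 0.0) for i in range(12)]
        fates = make_fates(recs, movie_end_frame=20)
        g = chain_graph(list(range(12)))
        paired = []
        for margin in (0, 1, 2, 4):
            pairs = cd.find_death_pairs(fates, g, margin_frames=margin)
            paired.append(len({c for p in pairs for c in (p.cell_a, p.cell_b)}))
        assert paired == sorted(paired)


class TestMergePairs:
    @staticmethod
    def pair(a, b, fa, fb):
        return cd.DeathPair(a, b, fa, fb, 10.0)

    def test_interconnected_pairs_form_cluster(self):
        clusters = cd.merge_pairs([self.pair("A", "B", 5, 5), self.pair("B", "C", 5, 6)])
        assert len(clusters) == 1
        c = clusters[0]
        assert c.members == frozenset("ABC") and c.size == 3 and c.clustered
        assert c.onset_frame == 5

    def test_isolated_pair_not_clustered(self):
        clusters = cd.merge_pairs([self.pair("A", "B", 5, 6)])
        assert len(clusters) == 1
        assert clusters[0].size == 2 and not clusters[0].clustered

    def test_disjoint_pairs_stay_separate(self):
        clusters = cd.merge_pairs([self.pair("A", "B", 5, 5), self.pair("C", "D", 7, 7)])
        assert len(clusters) == 2
        assert all(c.size == 2 and not c.clustered for c in clusters)

    def test_components_partition_paired_cells(self):
        rng = np.random.default_rng(4)
        pairs = [self.pair(int(a), int(b), 3, 3)
                 for a, b in rng.integers(0, 20, size=(25, 2)) if a != b]
        clusters = cd.merge_pairs(pairs)
        all_members = [m for c in clusters for m in c.members]
        assert len(all_members) == len(set(all_members))
        assert sum(c.size for c in clusters) == len(
            {x for p in pairs for x in (p.cell_a, p.cell_b)}
        )

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(9)
        pairs = [self.pair(int(a), int(b), 2, 2)
                 for a, b in rng.integers(0, 15, size=(20, 2)) if a != b]
        got = {c.members for c in cd.merge_pairs(pairs)}
        want = components_bruteforce(
            {tuple(sorted((p.cell_a, p.cell_b))) for p in pairs}
        )
        assert got == want


class TestCuration:
    @staticmethod
    def clusters():
        pairs = [cd.DeathPair("A", "B", 5, 5, 10.0), cd.DeathPair("B", "C", 5, 5, 10.0),
                 cd.DeathPair("X", "Y", 9, 9, 10.0), cd.DeathPair("Y", "Z", 9, 9, 10.0)]
        return cd.merge_pairs(pairs)

    def test_no_curation_accepts_all(self):
        assert all(c.accepted for c in cd.apply_curation(self.clusters()))

    def test_rejection_drops_counts(self):
        clusters = cd.apply_curation(self.clusters(), {1: False})
        assert cd.clustered_cells(clusters) == 3
        assert len(clusters) == 2  # rejected cluster retained in the report

    def test_unknown_id_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = cd.apply_curation(self.clusters(), {99: False})
        assert any("unknown" in r.message for r in caplog.records)
        assert all(c.accepted for c in out)

    def test_curation_file_parsed(self, tmp_path):
        p = tmp_path / "curation.csv"
        p.write_text("cluster_id,decision\n0,reject\n1,accept\n")
        out = cd.apply_curation(self.clusters(), str(p))
        assert [c.accepted for c in sorted(out, key=lambda c: c.cluster_id)] == [False, True]


class TestTimecourseAndProportions:
    @staticmethod
    def cluster(members, onset, clustered=True):
        return cd.DeathCluster(0, frozenset(members), {m: onset for m in members},
                               onset, clustered)

    def test_single_cluster_binned_at_onset(self):
        # onset frame 39 -> 26.5 hAPF with 10-min frames from 20 hAPF
        tc = cd.cluster_timecourse([self.cluster("ABC", 39)], end_hAPF=30.0)
        assert tc.loc[26.0] == 3
        assert tc.drop(26.0).sum() == 0

    def test_no_clusters_all_zero(self):
        tc = cd.cluster_timecourse([], end_hAPF=25.0)
        assert (tc == 0).all()

    def test_same_bin_clusters_sum(self):
        a = self.cluster("ABC", 36)
        b = cd.DeathCluster(1, frozenset("VWXYZ"), {m: 38 for m in "VWXYZ"}, 38, True)
        tc = cd.cluster_timecourse([a, b], end_hAPF=30.0)
        assert tc.loc[26.0] == 8

    def test_proportion_basic(self):
        # 10 early deaths, one size-3 cluster -> 0.3 early
        recs = [(i, 6 + i % 3, float(i), 0.0) for i in range(10)]
        fates = make_fates(recs, movie_end_frame=200)
        clusters = [self.cluster([0, 1, 2], 6)]
        props = cd.clustered_proportion(clusters, fates)
        assert props["early"] == pytest.approx(0.3)
        assert np.isnan(props["late"])  # zero deaths there -> missing, not 0

    def test_all_deaths_clustered_is_one(self):
        recs = [(i, 6, float(i), 0.0) for i in range(3)]
        fates = make_fates(recs, movie_end_frame=200)
        props = cd.clustered_proportion([self.cluster([0, 1, 2], 6)], fates)
        assert props["early"] == 1.0


class TestEliminationCurve:
    def test_no_deaths_constant_100(self):
        fates = make_fates([(i, 30, float(i), 0.0) for i in range(5)], movie_end_frame=30)
        curve = cd.elimination_curve(fates)
        assert (curve["percent_remaining"] == 100.0).all()

    def test_reference_exact_and_fraction(self):
        recs = [(i, 10 if i < 10 else 60, float(i), 0.0) for i in range(50)]
        fates = make_fates(recs, movie_end_frame=60)
        curve = cd.elimination_curve(fates)
        assert curve.loc[curve["frame"] == 0, "percent_remaining"].iloc[0] == 100.0
        assert curve.loc[curve["frame"] == 11, "percent_remaining"].iloc[0] == 80.0

    def test_monotone_non_increasing(self, small_random_movie):
        _, _, fates, _ = small_random_movie
        curve = cd.elimination_curve(fates)
        assert (np.diff(curve["percent_remaining"]) <= 1e-12).all()

    def test_zero_reference_cells_rejected(self):
        fates = make_fates([(1, 3, 0.0, 0.0)], movie_end_frame=30)
        with pytest.raises(ValueError, match="reference"):
            cd.elimination_curve(fates, reference_time_hAPF=50.0)


class TestFastPathAgreement:
    def test_fast_components_match_object_path(self):
        rng = np.random.default_rng(12)
        for trial in range(10):
            n = 25
            recs = []
            for i in range(n):
                dead = rng.random() < 0.7
                last = int(rng.integers(0, 18)) if dead else 19
                recs.append((i, last, *rng.uniform(0, 50, 2)))
            fates = make_fates(recs, movie_end_frame=19)
            graph = ng.static_initial_graph(fates, max_dist_um=18.0)
            pairs = cd.find_death_pairs(fates, graph)
            clusters = cd.merge_pairs(pairs)
            want = sorted(c.size for c in clusters)
            ea, eb = ng.edge_index_arrays(graph, fates.index)
            sizes, onsets = cd.concurrent_components_fast(
                cd.static_death_frames(fates), ea, eb
            )
            assert sorted(sizes.tolist()) == want
            assert cd.clustered_cell_count_fast(
                cd.static_death_frames(fates), ea, eb
            ) == cd.clustered_cells(cd.apply_curation(clusters))

    def test_pairs_match_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            recs = [(i, int(rng.integers(0, 15)), *rng.uniform(0, 60, 2))
                    for i in range(20)]
            fates = make_fates(recs, movie_end_frame=15)
            graph = ng.static_initial_graph(fates, max_dist_um=25.0)
            got = {tuple(sorted((p.cell_a, p.cell_b), key=str))
                   for p in cd.find_death_pairs(fates, graph)}
            want = death_pairs_bruteforce(fates, lambda f: graph)
            assert got == want
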