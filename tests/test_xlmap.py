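"""Core mapping: chain-pair enumeration, shortest-combination rule,
replicate filtering, distance summaries, overlap statistics."""

import numpy as np
import pytest
from igxlink import (
    AnalysisConfig,
    CrossLink,
    CrossLinkTable,
    deduplicate_and_filter,
    distance_summary,
    enumerate_assignments,
    map_table,
    overlap_stats,
)
from igxlink.xlmap import ConfigError, MappingError, SummaryError
from tests.conftest import make_links


def brute_force_shortest(link, structure, offsets=None):
    """Independent reference: minimum Cα–Cα distance over every chain
    combination and residue placement, by exhaustive loops."""
    link = link.canonical()
    best = None
    for ca in structure.chains_for(link.protein_a):
        for cb in structure.chains_for(link.protein_b):
            for (c1, p1), (c2, p2) in [((ca, link.pos_a), (cb, link.pos_b)),
                                       ((cb, link.pos_a), (ca, link.pos_b))]:
                if c1 == c2 and p1 == p2:
                    continue
                off1 = 0 if offsets is None else offsets.get(c1, 0)
                off2 = 0 if offsets is None else offsets.get(c2, 0)
                x1 = structure.chains[c1].ca(p1 + off1)
                x2 = structure.chains[c2].ca(p2 + off2)
                if x1 is None or x2 is None:
                    continue
                d = float(np.linalg.norm(x1 - x2))
                best = d if best is None else min(best, d)
    return best


class TestEnumerateAssignments:
    def test_homodimer_gives_three_assignments(self, toy_dimer):
        link = CrossLink("P1", 1, "P1", 3)
        assignments, reason = enumerate_assignments(link, toy_dimer)
        assert reason is None
        assert len(assignments) == 3
        pairs = {(a, b) for a, b, _ in assignments}
        assert pairs == {("A", "A"), ("B", "B"), ("A", "B")}
        # intra distance: |1->3| = 7.6; inter: sqrt(7.6^2+10^2)=12.56 min placement
        dists = sorted(d for _, _, d in assignments)
        np.testing.assert_allclose(dists[:2], [7.6, 7.6])

    def test_shortest_equals_brute_force_on_ring(self, ring7):
        model, table, _, _ = ring7
        for link in list({l.key: l for l in table.links}.values())[:20]:
            assignments, _ = enumerate_assignments(link, model)
            expected = brute_force_shortest(link, model)
            assert abs(assignments[0][2] - expected) < 1e-9

    def test_missing_residue_yields_reason(self, toy_dimer):
        link = CrossLink("P1", 1, "P1", 99)
        assignments, reason = enumerate_assignments(link, toy_dimer)
        assert assignments == [] and reason == "missing Cα"

    def test_unknown_protein_raises_mapping_error(self, toy_dimer):
        with pytest.raises(MappingError, match="P9"):
            enumerate_assignments(CrossLink("P9", 1, "P1", 2), toy_dimer)

    def test_distance_symmetric_under_endpoint_swap(self, ring7):
        model, table, _, _ = ring7
        for link in table.links[:10]:
            fwd, _ = enumerate_assignments(link, model)
            swapped = CrossLink(link.protein_b, link.pos_b,
                                link.protein_a, link.pos_a)
            rev, _ = enumerate_assignments(swapped, model)
            assert abs(fwd[0][2] - rev[0][2]) < 1e-12


class TestMapTable:
    def test_mapping_reproduces_planted_truth(self, ring7):
        model, table, truth, spec = ring7
        mapped = map_table(table, model)
        truth_by_key = {t.key: t for t in truth}
        for m in mapped:
            t = truth_by_key[m.link.key]
            assert abs(m.distance - t.min_distance) < 1e-9
            assert m.overlength == t.is_decoy

    def test_row_order_invariance(self, ring7):
        model, table, _, _ = ring7
        fwd = map_table(table, model)
        rev = map_table(CrossLinkTable(links=table.links[::-1]), model)
        assert [(m.link.key, m.distance) for m in fwd] == \
               [(m.link.key, m.distance) for m in rev]

    def test_shortest_is_minimum_of_assignments(self, ring7):
        model, table, _, _ = ring7
        for m in map_table(table, model):
            dists = [d for _, _, d in m.assignments]
            assert dists == sorted(dists)
            assert m.distance == min(dists)

    def test_unknown_protein_table_all_unmapped(self, toy_dimer):
        table = make_links([("OTHER", 1, "OTHER", 2)])
        mapped = map_table(table, toy_dimer)
        assert not mapped[0].is_mapped and "OTHER" in mapped[0].unmapped_reason

    def test_threshold_monotonicity(self, ring7, two_domain):
        model, _ = two_domain
        from igxlink import SimSpec, simulate_crosslinks
        spec = SimSpec(seed=5, decoy_fraction=0.3, n_links=60,
                       protein_id="SYNMULTI", detect_prob=1.0)
        table, _ = simulate_crosslinks(model, spec)
        counts = []
        for thr in (10.0, 20.0, 30.0, 50.0, 120.0):
            mapped = map_table(table, model,
                               AnalysisConfig(distance_threshold=thr))
            counts.append(sum(m.overlength for m in mapped))
        assert counts == sorted(counts, reverse=True)


class TestBruteForceOracleEquivalence:
    def test_all_outputs_match_brute_force_on_small_fixture(self, small_ring):
        """On <=4 chains x <=50 residues the whole mapping pipeline must
        agree exactly with an independent exhaustive implementation."""
        model, spec = small_ring
        from igxlink import simulate_crosslinks
        spec2 = type(spec)(seed=13, n_subunits=3, n_residues_per_chain=30,
                           ring_radius=28.0, linkable_fraction=0.5, n_links=30)
        table, _ = simulate_crosslinks(model, spec2)
        cfg = AnalysisConfig()
        mapped = map_table(table, model, cfg)
        # distances
        for m in mapped:
            assert abs(m.distance - brute_force_shortest(m.link, model)) < 1e-9
        # summary statistics recomputed independently
        dists = [brute_force_shortest(m.link, model) for m in mapped
                 if not m.is_self]
        summary = distance_summary(mapped, cfg)
        assert summary.n_unique == len(dists)
        assert abs(summary.mean_distance - np.mean(dists)) < 1e-12
        assert summary.n_overlength == sum(d > 30.0 for d in dists)
        hist = {}
        for d in dists:
            hist[5.0 * np.floor(d / 5.0)] = hist.get(5.0 * np.floor(d / 5.0), 0) + 1
        assert summary.histogram == hist


class TestReplicateFilter:
    def test_two_of_three_kept_one_removed(self):
        table = make_links([
            ("P", 1, "P", 10, 1, 1), ("P", 1, "P", 10, 2, 3),
            ("P", 2, "P", 20, 1, 2),
        ])
        out = deduplicate_and_filter(table, AnalysisConfig(min_replicates=2))
        assert out.unique_keys() == {("P", 1, "P", 10)}
        assert sum(l.csm_count for l in out.links) == 3  # summed downstream

    def test_filter_is_idempotent(self, ring7):
        _, table, _, _ = ring7
        cfg = AnalysisConfig(min_replicates=2)
        once = deduplicate_and_filter(table, cfg)
        twice = deduplicate_and_filter(once, cfg)
        assert once.links == twice.links

    def test_min_replicates_above_available_raises(self):
        table = make_links([("P", 1, "P", 10, 1, 1)])
        with pytest.raises(ConfigError):
            deduplicate_and_filter(table, AnalysisConfig(min_replicates=2))


class TestDistanceSummary:
    def test_two_links_mean_and_overlength(self, toy_dimer):
        # plant two links at known distances using a fabricated mapped set
        from igxlink.xlmap import MappedLink
        mapped = [
            MappedLink(CrossLink("P", 1, "P", 2), [("A", "A", 10.0)], False),
            MappedLink(CrossLink("P", 1, "P", 3), [("A", "A", 50.0)], True),
        ]
        s = distance_summary(mapped, AnalysisConfig())
        assert s.n_unique == 2 and s.n_overlength == 1
        assert s.mean_distance == 30.0

    def test_half_open_bin_convention(self):
        from igxlink.xlmap import MappedLink
        mapped = [
            MappedLink(CrossLink("P", 1, "P", 2), [("A", "A", 4.9)], False),
            MappedLink(CrossLink("P", 1, "P", 3), [("A", "A", 5.0)], False),
        ]
        s = distance_summary(mapped, AnalysisConfig())
        assert s.histogram == {0.0: 1, 5.0: 1}

    def test_all_unmapped_raises(self):
        from igxlink.xlmap import MappedLink
        mapped = [MappedLink(CrossLink("P", 1, "P", 2), [],
                             unmapped_reason="missing Cα")]
        with pytest.raises(SummaryError):
            distance_summary(mapped)


class TestOverlapStats:
    def test_identical_sets_full_overlap(self):
        s = overlap_stats({1, 2, 3}, {1, 2, 3})
        assert s.pct_of_a == 100.0 and s.pct_of_b == 100.0

    def test_directional_percentage(self):
        s = overlap_stats({1, 2, 3, 4, 5}, {1, 2, 3})
        assert s.n_intersection == 3
        assert s.pct_of_a == 60.0 and s.pct_of_b == 100.0

    def test_empty_set_gives_undefined_percentage(self):
        s = overlap_stats(set(), {1})
        assert s.n_intersection == 0 and s.pct_of_a is None

    def test_three_way_regions_partition(self):
        s = overlap_stats({1, 2, 3}, {2, 3, 4}, {3, 4, 5})
        total = sum(s.three_way.values())
        assert total == len({1, 2, 3, 4, 5})

    def test_replicate_overlap_tracks_detection_probability(self):
        """Two replicate draws at detect_prob p from planted links overlap
        at ~p (binomial CI) in the directional percentage."""
        from igxlink import SimSpec, make_ring_oligomer, simulate_crosslinks
        p = 0.8
        spec = SimSpec(seed=17, n_subunits=7, n_residues_per_chain=150,
                       ring_radius=32.0, linkable_fraction=0.5,
                       detect_prob=p, n_replicates=2, n_links=500)
        model = make_ring_oligomer(spec)
        table, _ = simulate_crosslinks(model, spec)
        rep = {r: {l.key for l in table.links if l.replicate == r}
               for r in (1, 2)}
        s = overlap_stats(rep[1], rep[2])
        ci = 1.96 * np.sqrt(p * (1 - p) / len(rep[1]))
        assert abs(s.pct_of_a / 100.0 - p) < ci + 0.01
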