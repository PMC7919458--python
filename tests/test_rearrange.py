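import itertools

import pytest

from dcj_oracle import adjacency_state, all_signed_orders, bfs_distances
from genostruct.phylo import ANCESTRAL, DERIVED, MISSING, Phylogeny
from genostruct.rearrange import (
    RearrangementCall,
    SignedPermutation,
    blocks_to_permutation,
    call_inversions,
    classify_compartment,
    count_breakpoints,
    dcj_distance,
    identity_genome,
    permutation_to_genome,
    polarize_events,
)
from genostruct.synteny import AlignmentMap, SyntenyBlock


def make_perm(order, n=None):
    """SignedPermutation on one chromosome with synthetic 10-kb blocks."""
    n = n or max(abs(x) for x in order)
    blocks = {
        ("c", i): SyntenyBlock(i, "c", (i - 1) * 10_000, i * 10_000, "c", 0, 0, 1)
        for i in range(1, n + 1)
    }
    return SignedPermutation(orders={"c": list(order)}, blocks=blocks)


def oracle_breakpoints(order):
    """Independent adjacency scan: count broken identity adjacencies."""
    n = len(order)
    ext = [0] + list(order) + [n + 1]
    conserved = 0
    for x, y in zip(ext, ext[1:]):
        if (x >= 0 and y == x + 1) or (x < 0 and y == x + 1):
            conserved += 1
    return (n + 1) - conserved


class TestPermutation:
    def test_collinear_is_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        amap = AlignmentMap.build({"c": seq}, {"c": seq}, k=15)
        perm = blocks_to_permutation(amap)
        assert perm.orders["c"] == [1]

    def test_middle_inversion_signs(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        ref = "".join(rng.choice(list("ACGT"), size=60_000))
        qry = ref[:20_000] + ref[20_000:40_000].translate(comp)[::-1] + ref[40_000:]
        amap = AlignmentMap.build({"c": ref}, {"c": qry}, k=15, min_block=1_000)
        perm = blocks_to_permutation(amap)
        assert perm.orders["c"] == [1, -2, 3]


class TestBreakpoints:
    @pytest.mark.parametrize(
        "order,expected",
        [([1, 2, 3], 0), ([1, -2, 3], 2), ([], 0), ([-1], 2), ([2, 1], 3)],
    )
    def test_known_cases(self, order, expected):
        assert count_breakpoints(make_perm(order, n=max(3, len(order)))) == expected

    def test_matches_adjacency_scan_oracle(self, rng):
        for _ in range(100):
            n = 8
            perm = list(rng.permutation(range(1, n + 1)))
            order = [int(p) * int(s) for p, s in zip(perm, rng.choice([1, -1], n))]
            assert count_breakpoints(make_perm(order)) == oracle_breakpoints(order)


class TestInversionCalls:
    def test_single_reversed_run(self):
        calls = call_inversions(make_perm([1, -3, -2, 4]))
        assert len(calls) == 1
        assert calls[0].block_ids == (2, 3)
        assert (calls[0].start, calls[0].end) == (10_000, 30_000)

    def test_identity_has_no_calls(self):
        assert call_inversions(make_perm([1, 2, 3])) == []

    def test_two_separate_inversions(self):
        calls = call_inversions(make_perm([-1, 2, -4, -3, 5]))
        assert [c.block_ids for c in calls] == [(1,), (3, 4)]


class TestDCJ:
    def test_identical_circular_zero(self):
        g = identity_genome(5, circular=True)
        assert dcj_distance(g, g) == 0

    def test_single_inversion_is_one_step(self):
        a = identity_genome(4, circular=True)
        b = permutation_to_genome([1, -2, 3, 4], circular=True)
        assert dcj_distance(a, b) == 1

    def test_marker_set_mismatch(self):
        with pytest.raises(ValueError):
            dcj_distance(identity_genome(3), permutation_to_genome([1, 2, 4]))

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_equals_bfs_oracle_small(self, n):
        for circular in (False, True):
            dist = bfs_distances(adjacency_state(list(range(1, n + 1)), circular), n)
            ident = identity_genome(n, circular)
            for order in all_signed_orders(n):
                expected = dist[adjacency_state(order, circular)]
                got = dcj_distance(ident, permutation_to_genome(order, circular))
                assert got == expected, (order, circular)

    def test_metric_properties(self, rng):
        for _ in range(30):
            n = 5
            genomes = []
            for _ in range(3):
                perm = list(rng.permutation(range(1, n + 1)))
                order = [int(p) * int(s) for p, s in zip(perm, rng.choice([1, -1], n))]
                genomes.append(permutation_to_genome(order))
            a, b, c = genomes
            assert dcj_distance(a, a) == 0
            assert dcj_distance(a, b) == dcj_distance(b, a)
            assert dcj_distance(a, c) <= dcj_distance(a, b) + dcj_distance(b, c)

    def test_dcj_bounded_by_breakpoints(self, rng):
        for _ in range(50):
            n = 7
            perm = list(rng.permutation(range(1, n + 1)))
            order = [int(p) * int(s) for p, s in zip(perm, rng.choice([1, -1], n))]
            d = dcj_distance(identity_genome(n), permutation_to_genome(order))
            assert d <= count_breakpoints(make_perm(order))


class TestPolarization:
    def test_spec_patterns(self, phylo):
        import pandas as pd

        taxa = phylo.taxa
        rows = {
            "stem_event": {
                t: DERIVED if t in phylo.ingroup else ANCESTRAL for t in taxa
            },
            "reference_lineage": {
                t: ANCESTRAL if t == phylo.reference else DERIVED for t in taxa
            },
            "terminal": {t: DERIVED if t == "mau" else ANCESTRAL for t in taxa},
        }
        matrix = pd.DataFrame(rows).T
        out = polarize_events(matrix, phylo)
        assert out["stem_event"] == "stem"
        assert out["reference_lineage"] == phylo.reference
        assert out["terminal"] == "mau"

    def test_all_missing_skipped(self, phylo):
        import pandas as pd

        matrix = pd.DataFrame(
            {t: [MISSING] for t in phylo.taxa}, index=["ghost"]
        )
        out = polarize_events(matrix, phylo)
        assert "ghost" not in out.index

    def test_outgroup_required(self, phylo):
        import pandas as pd

        matrix = pd.DataFrame({t: [DERIVED] for t in phylo.ingroup})
        with pytest.raises(ValueError):
            polarize_events(matrix, phylo)


class TestCompartment:
    comps = {"c": [(0, 50_000, "het"), (50_000, 100_000, "eu")]}

    def call(self, start, end):
        return RearrangementCall("inversion", "c", start, end)

    def test_fully_eu(self):
        assert classify_compartment(self.call(60_000, 70_000), self.comps) == "eu"

    def test_fully_het(self):
        assert classify_compartment(self.call(1_000, 2_000), self.comps) == "het"

    def test_boundary_spanning_is_het(self):
        assert classify_compartment(self.call(49_000, 60_000), self.comps) == "het"

    def test_unknown_chromosome(self):
        with pytest.raises(ValueError):
            classify_compartment(self.call(0, 10), {"other": []})

    def test_simulated_het_enrichment(self, small_bundle, small_maps):
        """With a 20x het placement weight, most inversion calls are het."""
        from genostruct.pipeline import inversion_analysis

        clusters = inversion_analysis(small_bundle, small_maps)
        if len(clusters) >= 3:
            het = sum(1 for c in clusters if c.compartment == "het")
            assert het / len(clusters) >= 0.5
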