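import numpy as np
import pytest

from conftest import random_seq, small_config
from genostruct.pipeline import simulate, reference_maps
from genostruct.synteny import (
    AlignmentMap,
    CoordinateError,
    chain_anchors,
    find_anchors,
    summarize_alignment,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def brute_force_anchors(ref: str, qry: str, k: int):
    """Independent oracle: canonical k-mer tables, unique-in-both matching."""

    def canon_counts(seq):
        counts = {}
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            canon = min(km, revcomp(km))
            counts[canon] = counts.get(canon, 0) + 1
        return counts

    rcounts, qcounts = canon_counts(ref), canon_counts(qry)
    qpos = {}
    for i in range(len(qry) - k + 1):
        km = qry[i : i + k]
        qpos[min(km, revcomp(km))] = (i, km)
    out = []
    for i in range(len(ref) - k + 1):
        km = ref[i : i + k]
        canon = min(km, revcomp(km))
        if rcounts[canon] != 1 or qcounts.get(canon, 0) != 1:
            continue
        j, qkm = qpos[canon]
        out.append((i, j, 1 if qkm == km else -1))
    return sorted(out)


class TestFindAnchors:
    def test_identical_sequences_tile(self, rng):
        seq = random_seq(rng, 10_000)
        anchors = find_anchors({"c": seq}, {"c": seq}, k=15)
        covered = sum(a.length for a in anchors)
        assert covered >= 10_000 - 2 * (15 - 1)
        assert all(a.orient == 1 for a in anchors)

    def test_reverse_complement_all_minus(self, rng):
        seq = random_seq(rng, 5_000)
        anchors = find_anchors({"c": seq}, {"c": revcomp(seq)}, k=15)
        assert anchors
        assert all(a.orient == -1 for a in anchors)

    def test_snp_splits_anchor_runs(self, rng):
        ref = random_seq(rng, 1_000)
        qry = ref[:500] + ("A" if ref[500] != "A" else "C") + ref[501:]
        anchors = find_anchors({"c": ref}, {"c": qry}, k=15)
        assert not any(a.ref_start < 500 < a.ref_end - 1 for a in anchors)
        assert len(anchors) == 2

    def test_matches_brute_force_window_set(self, rng):
        ref = random_seq(rng, 400)
        qry = ref[:150] + revcomp(ref[150:260]) + ref[260:]
        k = 15
        anchors = find_anchors({"c": ref}, {"c": qry}, k=k)
        expanded = set()
        for a in anchors:
            for off in range(a.length - k + 1):
                if a.orient == 1:
                    expanded.add((a.ref_start + off, a.qry_start + off, 1))
                else:
                    expanded.add(
                        (a.ref_start + off, a.qry_start + a.length - k - off, -1)
                    )
        oracle = set(brute_force_anchors(ref, qry, k))
        assert expanded == oracle

    @pytest.mark.parametrize("k", [10, 14, 9])
    def test_k_validation(self, k):
        with pytest.raises(ValueError):
            find_anchors({"c": "ACGT" * 10}, {"c": "ACGT" * 10}, k=k)


class TestChaining:
    def test_identical_chromosomes_one_block(self, rng):
        seq = random_seq(rng, 20_000)
        anchors = find_anchors({"c": seq}, {"c": seq}, k=15)
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].orient == 1

    def test_planted_inversion_three_blocks(self, rng):
        ref = random_seq(rng, 60_000)
        qry = ref[:20_000] + revcomp(ref[20_000:40_000]) + ref[40_000:]
        amap = AlignmentMap.build({"c": ref}, {"c": qry}, k=15, min_block=1_000)
        orients = [b.orient for b in sorted(amap.blocks, key=lambda b: b.ref_start)]
        assert orients == [1, -1, 1]
        middle = sorted(amap.blocks, key=lambda b: b.ref_start)[1]
        tol = 15 + 20_000
        assert abs(middle.ref_start - 20_000) <= tol
        assert abs(middle.ref_end - 40_000) <= tol

    def test_max_gap_zero_splits_at_snp(self, rng):
        ref = random_seq(rng, 4_000)
        qry = ref[:2_000] + ("A" if ref[2_000] != "A" else "C") + ref[2_001:]
        anchors = find_anchors({"c": ref}, {"c": qry}, k=15)
        blocks = chain_anchors(anchors, max_gap=0, min_block=500)
        assert len(blocks) == 2

    def test_blocks_disjoint_on_simulated_genomes(self, small_maps):
        for amap in small_maps.values():
            for side in ("ref", "qry"):
                by_chrom = {}
                for b in amap.blocks:
                    key = b.ref_chrom if side == "ref" else b.qry_chrom
                    iv = (
                        (b.ref_start, b.ref_end)
                        if side == "ref"
                        else (b.qry_start, b.qry_end)
                    )
                    by_chrom.setdefault(key, []).append(iv)
                for ivs in by_chrom.values():
                    ivs.sort()
                    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                        assert e1 <= s2

    def test_substitutions_only_gives_one_block_per_chromosome(self):
        cfg = small_config(
            seed=9, rates={}, branch_rates={}, n_satellites=0, n_ancestral_tes=0
        )
        bundle = simulate(cfg)
        maps = reference_maps(bundle)
        for amap in maps.values():
            assert len(amap.blocks) == len(cfg.chrom_lengths)


class TestProjection:
    def test_identity_projection(self, rng):
        seq = random_seq(rng, 10_000)
        amap = AlignmentMap.build({"c": seq}, {"c": seq}, k=15)
        (img,) = amap.project_interval("c", 2_000, 2_500)
        assert (img["qry_start"], img["qry_end"]) == (2_000, 2_500)
        assert not img["split"]

    def test_minus_block_reverses_offsets(self, rng):
        seq = random_seq(rng, 10_000)
        amap = AlignmentMap.build({"c": seq}, {"c": revcomp(seq)}, k=15)
        (img,) = amap.project_interval("c", 1_000, 1_100)
        assert img["orient"] == -1
        assert img["qry_start"] == pytest.approx(10_000 - 1_100, abs=2)
        assert img["qry_end"] == pytest.approx(10_000 - 1_000, abs=2)

    def test_interval_spanning_blocks_is_split(self, rng):
        ref = random_seq(rng, 60_000)
        qry = ref[:30_000] + revcomp(ref[30_000:])
        amap = AlignmentMap.build({"c": ref}, {"c": qry}, k=15, min_block=1_000)
        images = amap.project_interval("c", 29_000, 31_000)
        assert len(images) == 2
        assert all(im["split"] for im in images)

    def test_round_trip_through_inverse_map(self, rng):
        ref = random_seq(rng, 30_000)
        qry = ref[:10_000] + revcomp(ref[10_000:20_000]) + ref[20_000:]
        amap = AlignmentMap.build({"c": ref}, {"c": qry}, k=15, min_block=1_000)
        inv = amap.invert()
        for start, end in [(2_000, 2_400), (12_000, 12_500), (25_000, 25_200)]:
            images = amap.project_interval("c", start, end)
            assert len(images) == 1
            im = images[0]
            back = inv.project_interval("c", im["qry_start"], im["qry_end"])
            assert len(back) == 1
            assert back[0]["qry_start"] == pytest.approx(start, abs=3)
            assert back[0]["qry_end"] == pytest.approx(end, abs=3)

    def test_out_of_bounds_raises(self, rng):
        seq = random_seq(rng, 1_000)
        amap = AlignmentMap.build({"c": seq}, {"c": seq}, k=15, min_block=100)
        with pytest.raises(CoordinateError):
            amap.project_interval("c", 500, 2_000)
        with pytest.raises(CoordinateError):
            amap.project_interval("missing", 0, 10)


class TestSummary:
    def test_identical_genomes(self, rng):
        seq = random_seq(rng, 30_000)
        amap = AlignmentMap.build({"c": seq}, {"c": seq}, k=15)
        s = summarize_alignment(amap, {"c": seq}, {"c": seq})
        assert s["ref_aligned_fraction"] > 0.99
        assert s["mean_block_identity"] == pytest.approx(1.0, abs=1e-6)

    def test_jukes_cantor_divergence_recovered(self, rng):
        """5% expected difference between genomes gives identity 0.95 +/- 0.01."""
        ref = random_seq(rng, 120_000)
        arr = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
        hits = rng.random(len(arr)) < 0.05
        lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
        qry = list(ref)
        for i in np.nonzero(hits)[0]:
            qry[i] = lut[arr[i]][rng.integers(3)]
        qry = "".join(qry)
        amap = AlignmentMap.build({"c": ref}, {"c": qry}, k=21)
        s = summarize_alignment(amap, {"c": ref}, {"c": qry})
        assert s["mean_block_identity"] == pytest.approx(0.95, abs=0.01)

    def test_planted_te_load_reduces_unique_alignment(self, small_bundle, small_maps):
        """Taxon-specific repeat insertions leave unaligned sequence."""
        amap = small_maps["sim"]
        s = summarize_alignment(
            amap, small_bundle.seqs("mel"), small_bundle.seqs("sim")
        )
        assert 0.0 < s["qry_unaligned_fraction"] < 0.5
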