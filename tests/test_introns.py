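import pandas as pd
import pytest

from genostruct import introns
from genostruct.models import Gene
from genostruct.phylo import Phylogeny
from genostruct.pipeline import (
    intron_analysis,
    planted_intron_shift,
    simulate,
)
from genostruct.simgen import SimConfig


def gene_with_exons(gid, exon_lens, intron_lens, chrom="c", start=1_000):
    exons = []
    cursor = start
    for i, xl in enumerate(exon_lens):
        exons.append((cursor, cursor + xl))
        cursor += xl
        if i < len(intron_lens):
            cursor += intron_lens[i]
    return Gene(gid, chrom, "+", exons, (exons[0][0], exons[-1][1]))


def taxa_models(per_taxon):
    return {t: {g.gene_id: g for g in genes} for t, genes in per_taxon.items()}


TAXA = ["mel", "sim", "mau", "sec"]


class TestMatching:
    def test_similar_flanks_retained(self):
        per = {
            t: [gene_with_exons("g", [100, 200, 300], [500, 600])] for t in TAXA[1:]
        }
        per["mel"] = [gene_with_exons("g", [100, 210, 300], [500, 600])]
        out = introns.match_conserved_introns(taxa_models(per), "mel")
        # flanks 100/100 (0%) and 200/210 (~5%) pass; 210/200 + 300/300 pass
        assert [(ci.gene_id, ci.intron_index) for ci in out] == [("g", 0), ("g", 1)]

    def test_dissimilar_flank_excluded(self):
        per = {t: [gene_with_exons("g", [200, 300], [400])] for t in TAXA[1:]}
        per["mel"] = [gene_with_exons("g", [250, 300], [400])]
        out = introns.match_conserved_introns(taxa_models(per), "mel")
        assert out == []  # 250 vs 200 is a 20% difference

    def test_exon_count_mismatch_excluded(self):
        per = {t: [gene_with_exons("g", [100, 100, 100], [50, 50])] for t in TAXA[1:]}
        per["mel"] = [gene_with_exons("g", [100, 100], [50])]
        assert introns.match_conserved_introns(taxa_models(per), "mel") == []

    def test_symmetric_in_taxon_order(self):
        per = {t: [gene_with_exons("g", [100, 150], [700])] for t in TAXA}
        a = introns.match_conserved_introns(taxa_models(per), "mel")
        rev = dict(reversed(list(taxa_models(per).items())))
        b = introns.match_conserved_introns(rev, "mel")
        assert len(a) == len(b) == 1

    def test_untouched_exons_keep_all_introns(self, small_bundle):
        """Planted intron indels never remove introns from the conserved set;
        exclusions only arise from genes whose exons gained a TE insertion."""
        out = intron_analysis(small_bundle)
        n_genes = len(small_bundle.ancestor.genes)
        per_gene = small_bundle.config.exons_per_gene - 1
        exonic_hits = sum(
            1
            for ev in small_bundle.truth.by_type("te_insertion")
            if ev.payload.get("exonic")
        )
        # each exonic hit can remove at most its gene's introns
        assert len(out["conserved"]) >= (n_genes - exonic_hits) * per_gene


class TestClassification:
    def test_one_bp_te_overlap_is_complex(self):
        reps = pd.DataFrame(
            [("c", 999, 1_001, "+", "roo", "LTR", "r")],
            columns=["chrom", "start", "end", "strand", "family", "klass", "repeat_id"],
        )
        assert introns.classify_intron((1_000, 1_500), "c", reps) == "complex"

    def test_no_overlap_is_simple(self):
        reps = pd.DataFrame(
            [("c", 2_000, 2_400, "+", "roo", "LTR", "r")],
            columns=["chrom", "start", "end", "strand", "family", "klass", "repeat_id"],
        )
        assert introns.classify_intron((1_000, 1_500), "c", reps) == "simple"

    def test_complex_and_simple_partition(self, small_bundle):
        out = intron_analysis(small_bundle)
        for ci in out["conserved"]:
            for taxon in ci.interval:
                assert ci.klass[taxon] in ("complex", "simple")


class TestComparison:
    def conserved(self, lengths_by_taxon):
        out = []
        for i, lens in enumerate(zip(*lengths_by_taxon.values())):
            ci = introns.ConservedIntron("g%d" % i, 0)
            for t, L in zip(lengths_by_taxon, lens):
                ci.chrom[t] = "c"
                ci.interval[t] = (0, L)
                ci.length[t] = L
                ci.klass[t] = "simple"
            out.append(ci)
        return out

    def test_identical_lengths_degenerate_null(self):
        cons = self.conserved({"mel": [100, 200, 300], "sim": [100, 200, 300]})
        c = introns.compare_lengths(cons, "mel", "sim")
        assert c.mean_diff == 0.0
        assert c.result.p_value == 1.0

    def test_constant_shift_reported_degenerate(self):
        cons = self.conserved({"mel": [102, 202, 302], "sim": [100, 200, 300]})
        c = introns.compare_lengths(cons, "mel", "sim")
        assert c.result.degenerate
        assert c.mean_diff == pytest.approx(2.0)

    def test_too_few_pairs(self):
        cons = self.conserved({"mel": [100], "sim": [100]})
        with pytest.raises(ValueError):
            introns.compare_lengths(cons, "mel", "sim")

    def test_planted_length_effect_recovered(self):
        """Insertions planted on the reference branch are detected and the
        mean shift is estimated within 10%."""
        cfg = SimConfig(
            seed=7, chrom_lengths={"chr2": 800_000}, het_fraction=0.2,
            n_genes=80, n_trnas=0, n_trna_clusters=0, n_satellites=0,
            n_ancestral_tes=0, rates={},
            branch_rates={"mel": {"intron_indel": 40.0}},
            intron_indel_ins_prob=1.0, intron_indel_len_median=500.0,
            intron_indel_len_sigma=0.1, intron_te_prob=0.3,
        )
        bundle = simulate(cfg)
        out = intron_analysis(bundle)
        truth_shift = planted_intron_shift(bundle, "mel", out["conserved"])
        assert truth_shift > 0
        for taxon in bundle.phylogeny.ingroup:
            c = introns.compare_lengths(out["conserved"], "mel", taxon)
            assert c.result.p_value < 0.01
            assert c.mean_diff == pytest.approx(truth_shift, rel=0.10)

    def test_type_i_error_under_null(self):
        """Substitution-only evolution leaves intron lengths identical, so
        the paired test never rejects; the rejection rate over 100
        replicates stays within alpha + 2 points."""
        alpha = 0.05
        rejections = 0
        n_tests = 0
        for seed in range(100):
            cfg = SimConfig(
                seed=seed, chrom_lengths={"chr2": 120_000}, het_fraction=0.2,
                n_genes=12, n_trnas=0, n_trna_clusters=0, n_satellites=0,
                n_ancestral_tes=0, rates={},
            )
            bundle = simulate(cfg)
            out = intron_analysis(bundle)
            try:
                c = introns.compare_lengths(out["conserved"], "mel", "sim")
            except ValueError:
                continue
            n_tests += 1
            if c.result.p_value is not None and c.result.p_value < alpha:
                rejections += 1
        assert n_tests >= 90
        assert rejections / n_tests <= alpha + 0.02
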