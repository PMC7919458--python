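import json

import numpy as np
import pytest

from conftest import small_config
from genostruct import io as gio
from genostruct.phylo import Phylogeny
from genostruct.simgen import (
    ANTICODON_TO_AA,
    PlacementError,
    SimConfig,
    evolve_tree,
    simulate_ancestor,
)
from genostruct.pipeline import simulate


def tiny_config(**overrides):
    base = dict(
        seed=1,
        chrom_lengths={"chr2": 200_000},
        het_fraction=0.3,
        n_genes=10,
        n_trnas=8,
        n_trna_clusters=2,
        n_satellites=2,
        n_ancestral_tes=5,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestAncestor:
    def test_empty_annotation_case(self):
        cfg = tiny_config(n_genes=0, n_trnas=0, n_trna_clusters=0, n_satellites=0,
                          n_ancestral_tes=0)
        anc = simulate_ancestor(cfg)
        assert not anc.genes and not anc.trnas and not anc.repeats
        assert len(anc.seqs["chr2"]) == 200_000

    def test_determinism_byte_identical(self):
        a = simulate_ancestor(tiny_config())
        b = simulate_ancestor(tiny_config())
        assert a.sequences() == b.sequences()

    def test_trna_count_and_clusters(self):
        cfg = tiny_config(n_trnas=20, n_trna_clusters=4)
        anc = simulate_ancestor(cfg)
        assert len(anc.trnas) == 20
        assert len({t.cluster for t in anc.trnas}) == 4
        for t in anc.trnas:
            assert t.isotype == ANTICODON_TO_AA[t.anticodon]

    def test_heterochromatin_fraction(self):
        anc = simulate_ancestor(tiny_config(het_fraction=0.4))
        assert anc.het_end["chr2"] == 80_000

    def test_infeasible_density_raises(self):
        cfg = tiny_config(chrom_lengths={"chr2": 20_000}, n_genes=100)
        with pytest.raises(PlacementError):
            simulate_ancestor(cfg)

    def test_negative_rate_rejected(self):
        cfg = tiny_config()
        cfg.rates["inversion"] = -1.0
        with pytest.raises(ValueError):
            cfg.validate()


class TestEvolution:
    def test_zero_rate_identity(self):
        cfg = tiny_config(rates={}, branch_rates={}, substitution_rate=0.0)
        anc = simulate_ancestor(cfg)
        genomes, truth = evolve_tree(anc, Phylogeny(), cfg)
        assert truth.events == []
        for state in genomes.values():
            assert state.sequences() == anc.sequences()

    def test_determinism_across_runs(self):
        b1 = simulate(small_config(seed=11))
        b2 = simulate(small_config(seed=11))
        for taxon in b1.genomes:
            assert b1.seqs(taxon) == b2.seqs(taxon)
        assert [e.event_id for e in b1.truth.events] == [
            e.event_id for e in b2.truth.events
        ]

    def test_event_inheritance_follows_tree_paths(self):
        phy = Phylogeny()
        cfg = tiny_config(
            rates={}, branch_rates={"stem": {"inversion": 12.0}},
            substitution_rate=0.0,
        )
        anc = simulate_ancestor(cfg)
        genomes, truth = evolve_tree(anc, phy, cfg)
        assert truth.events, "expected at least one stem inversion at this rate"
        for ev in truth.events:
            assert ev.branch == "stem"
            assert set(ev.taxa) == set(phy.ingroup)
        for taxon in phy.ingroup:
            assert genomes[taxon].sequences() != anc.sequences()
        assert genomes[phy.reference].sequences() == anc.sequences()
        assert genomes[phy.outgroup].sequences() == anc.sequences()
        # carriers share the event: identical derived sequences
        assert genomes["sim"].sequences() == genomes["mau"].sequences()

    def test_planted_counts_match_poisson_expectation(self):
        """Stem TE counts over 20 seeds stay within 3 sigma of the mean."""
        lam = 30.0
        rate = lam / (2.5 * 0.2)  # branch 2.5 Myr x 0.2 Mb genome
        counts = []
        for seed in range(20):
            cfg = tiny_config(
                seed=seed, rates={}, substitution_rate=0.0,
                branch_rates={"stem": {"te_dna": rate}},
                n_genes=0, n_trnas=0, n_trna_clusters=0, n_satellites=0,
                n_ancestral_tes=0,
            )
            anc = simulate_ancestor(cfg)
            _, truth = evolve_tree(anc, Phylogeny(), cfg)
            counts.append(len(truth.by_branch("stem", "te_insertion")))
        mean = np.mean(counts)
        assert abs(mean - lam) <= 3 * np.sqrt(lam / len(counts))

    def test_truth_coords_point_at_planted_te_sequence(self, small_bundle):
        """Lifted coordinates still delimit the planted element."""
        for ev in small_bundle.truth.by_type("te_insertion")[:10]:
            for taxon in ev.taxa:
                iv = small_bundle.truth.coords[taxon].get(ev.event_id)
                if iv is None:
                    continue
                chrom, s, e = iv
                assert e - s == ev.payload["length"]


class TestOutputs:
    def test_write_read_round_trip(self, small_bundle, tmp_path):
        from genostruct.simgen import write_outputs

        write_outputs(small_bundle.genomes, small_bundle.truth, tmp_path)
        for taxon, state in small_bundle.genomes.items():
            seqs = gio.read_fasta(tmp_path / f"{taxon}.fasta")
            assert seqs == state.sequences()
            genes, trnas = gio.read_gff3(tmp_path / f"{taxon}.gff3")
            assert len(genes) == len(state.genes)
            assert len(trnas) == len(state.trnas)
        truth_df = gio.read_tsv(tmp_path / "truth.tsv")
        assert len(truth_df) == len(small_bundle.truth.events)
        for payload in truth_df["payload"]:
            json.loads(payload)

    def test_bed_intervals_within_bounds(self, small_bundle, tmp_path):
        from genostruct.simgen import write_outputs

        write_outputs(small_bundle.genomes, small_bundle.truth, tmp_path)
        for taxon, state in small_bundle.genomes.items():
            bed = gio.read_bed(tmp_path / f"{taxon}.repeats.bed",
                               extra_columns=("klass", "repeat_id"))
            lengths = {c: len(s) for c, s in state.seqs.items()}
            assert (bed["start"] >= 0).all()
            assert (bed["start"] < bed["end"]).all()
            for _, row in bed.iterrows():
                assert row.end <= lengths[row.chrom]

    def test_compartments_partition_chromosomes(self, small_bundle):
        for state in small_bundle.genomes.values():
            for chrom, parts in state.compartments().items():
                assert parts[0][0] == 0
                assert parts[-1][1] == len(state.seqs[chrom])
                for (s1, e1, _), (s2, e2, _) in zip(parts, parts[1:]):
                    assert e1 == s2
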