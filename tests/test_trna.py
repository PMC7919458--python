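import itertools

import pandas as pd
import pytest

from genostruct import trna
from genostruct.phylo import Phylogeny


def trna_frame(rows):
    """rows: (taxon, chrom, start, isotype, anticodon, pseudo)"""
    return pd.DataFrame(
        [
            (t, c, s, s + 72, "+", iso, ac, pseudo, "cl0", f"{t}.{i}")
            for i, (t, c, s, iso, ac, pseudo) in enumerate(rows)
        ],
        columns=trna.TRNA_COLUMNS,
    )


def brute_force_score(a, b, match=2, mismatch=-1, gap=-2):
    """Exhaustive recursion over all global alignments."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -10**9
        if i < len(a) and j < len(b):
            best = max(best, rec(i + 1, j + 1) + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            best = max(best, rec(i + 1, j) + gap)
        if j < len(b):
            best = max(best, rec(i, j + 1) + gap)
        return best

    return rec(0, 0)


class TestIsotypeString:
    def test_basic_string(self):
        df = trna_frame(
            [("mel", "c", 100, "A", "AGC", False),
             ("mel", "c", 300, "A", "AGC", False),
             ("mel", "c", 500, "R", "ACG", False)]
        )
        s = trna.build_isotype_string(df, "mel", "c")
        assert s.text == "AAR"

    def test_empty_chromosome(self):
        df = trna_frame([("mel", "c", 100, "A", "AGC", False)])
        assert trna.build_isotype_string(df, "mel", "other").text == ""

    def test_pseudogene_lower_case(self):
        df = trna_frame([("mel", "c", 100, "S", "AGA", True)])
        assert trna.build_isotype_string(df, "mel", "c").text == "s"

    def test_cluster_boundaries(self):
        df = trna_frame(
            [("mel", "c", 0, "A", "AGC", False),
             ("mel", "c", 200, "A", "AGC", False),
             ("mel", "c", 20_000, "R", "ACG", False)]
        )
        s = trna.build_isotype_string(df, "mel", "c", cluster_gap=5_000)
        assert s.cluster_breaks == [2]


class TestAlignment:
    def test_identical_strings(self):
        score, cols = trna.align_isotype_strings("AAR", "AAR")
        assert score == 6
        assert cols == [(0, 0), (1, 1), (2, 2)]

    def test_deterministic_gap_placement(self):
        score, cols = trna.align_isotype_strings("AAR", "AR")
        assert score == 2
        gap_cols = [c for c in cols if c[1] is None]
        assert len(gap_cols) == 1
        # tie broken deterministically: the gap sits at the first A
        assert cols[0] == (0, None)

    def test_case_insensitive_scoring(self):
        s1, _ = trna.align_isotype_strings("aar", "AAR")
        s2, _ = trna.align_isotype_strings("AAR", "AAR")
        assert s1 == s2

    def test_matches_exhaustive_oracle(self, rng):
        alphabet = "ACDE"
        for _ in range(40):
            a = "".join(rng.choice(list(alphabet), size=rng.integers(0, 9)))
            b = "".join(rng.choice(list(alphabet), size=rng.integers(0, 9)))
            score, _ = trna.align_isotype_strings(a, b)
            assert score == brute_force_score(a.upper(), b.upper()), (a, b)


class TestOrthology:
    phy = Phylogeny()

    def five_taxon_frame(self, per_taxon):
        rows = []
        for taxon, genes in per_taxon.items():
            for i, (iso, ac) in enumerate(genes):
                rows.append((taxon, "c", 100 + 500 * i, iso, ac, False))
        return trna_frame(rows)

    def test_conserved_column(self):
        df = self.five_taxon_frame({t: [("A", "AGC")] for t in self.phy.taxa})
        cols = trna.call_orthology(df, self.phy, "c")
        assert len(cols) == 1
        assert cols[0].call == "conserved"

    def test_terminal_copy_loss(self):
        per = {t: [("A", "AGC"), ("R", "ACG")] for t in self.phy.taxa}
        per["sec"] = [("A", "AGC")]
        cols = trna.call_orthology(self.five_taxon_frame(per), self.phy, "c")
        losses = [c for c in cols if c.call == "copy_loss"]
        assert len(losses) == 1
        assert losses[0].branch == "sec"

    def test_every_gene_in_exactly_one_column(self, small_bundle):
        from genostruct.pipeline import trna_analysis

        out = trna_analysis(small_bundle)
        seen = []
        for col in out["columns"]:
            seen.extend(i for i in col.members.values() if i is not None)
        assert sorted(seen) == sorted(out["frame"].index)

    def test_membership_independent_of_row_order(self, small_bundle):
        from genostruct.pipeline import trna_analysis

        base = trna_analysis(small_bundle)
        df = base["frame"].sample(frac=1.0, random_state=0)
        chroms = sorted(df["chrom"].unique())
        cols = []
        for chrom in chroms:
            cols.extend(trna.call_orthology(df, self.phy, chrom))

        def membership(columns, frame):
            out = set()
            for c in columns:
                ids = frozenset(
                    frame.loc[i, "gene_id"] + "@" + t
                    for t, i in c.members.items()
                    if i is not None
                )
                out.add(ids)
            return out

        assert membership(cols, df) == membership(base["columns"], base["frame"])


class TestShifts:
    phy = Phylogeny()

    def column_for(self, per_taxon):
        rows = []
        for taxon, (iso, ac) in per_taxon.items():
            rows.append((taxon, "c", 100, iso, ac, False))
        df = trna_frame(rows)
        members = {row.taxon: i for i, row in df.iterrows()}
        col = trna.OrthologyColumn("c", members)
        return trna.classify_shift(col, df, self.phy)

    def test_isoacceptor_same_isotype(self):
        per = {t: ("S", "AGA") for t in self.phy.taxa}
        per["sec"] = ("S", "TGA")
        shift = self.column_for(per)
        assert shift.kind == "isoacceptor"
        assert shift.branch == "sec"

    def test_alloacceptor_met_to_thr(self):
        """Met CAT > Thr CGT at an orthologous position changes the isotype."""
        per = {t: ("M", "CAT") for t in self.phy.taxa}
        per["sim"] = ("T", "CGT")
        shift = self.column_for(per)
        assert shift.kind == "alloacceptor"
        assert shift.ancestral == ("M", "CAT")
        assert shift.derived == ("T", "CGT")
        assert shift.branch == "sim"

    def test_identical_members_no_shift(self):
        per = {t: ("S", "AGA") for t in self.phy.taxa}
        assert self.column_for(per) is None
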