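"""Conserved-intron matching, complex/simple classification, and paired
length comparisons between taxa.

Orthologous genes (same gene id across taxa, or an explicit ortholog table)
are compared on their longest-isoform models: introns are retained when all
taxa have the same exon count and both flanking exons are within 10% length
difference of the reference taxon's (|a-b| / max(a,b) <= 0.10, symmetric).
An intron is "complex" in a taxon when it overlaps >= 1 bp of annotated TE
or satellite sequence there, else "simple".  Length differences between a
species pair are tested with a paired t-test on per-intron differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from . import stats
from .models import Gene


@dataclass
class ConservedIntron:
    gene_id: str
    intron_index: int
    chrom: dict[str, str] = field(default_factory=dict)
    interval: dict[str, tuple[int, int]] = field(default_factory=dict)
    length: dict[str, int] = field(default_factory=dict)
    klass: dict[str, str] = field(default_factory=dict)  # complex | simple per taxon


def _similar(a: int, b: int, tol: float) -> bool:
    return abs(a - b) / max(a, b) <= tol if max(a, b) > 0 else True


def match_conserved_introns(
    genes_by_taxon: dict[str, dict[str, Gene]],
    reference: str,
    max_exon_diff: float = 0.10,
    all_pairs: bool = False,
) -> list[ConservedIntron]:
    """Introns at the same position in all taxa with similar flanking exons.

    By default each non-reference taxon is compared to the reference taxon;
    ``all_pairs`` requires the flanking-exon rule between every taxon pair.
    """
    taxa = sorted(genes_by_taxon)
    if reference not in taxa:
        raise ValueError("reference taxon missing from gene models")
    shared_ids = set.intersection(*(set(g) for g in genes_by_taxon.values()))
    out: list[ConservedIntron] = []
    for gid in sorted(shared_ids):
        models = {t: genes_by_taxon[t][gid] for t in taxa}
        n_exons = {len(m.exons) for m in models.values()}
        if len(n_exons) != 1 or n_exons == {1}:
            continue
        k = n_exons.pop()
        for i in range(k - 1):
            lens = {
                t: (
                    m.exons[i][1] - m.exons[i][0],
                    m.exons[i + 1][1] - m.exons[i + 1][0],
                )
                for t, m in models.items()
            }
            if all_pairs:
                pairs = [(a, b) for a in taxa for b in taxa if a < b]
            else:
                pairs = [(reference, t) for t in taxa if t != reference]
            ok = all(
                _similar(lens[a][0], lens[b][0], max_exon_diff)
                and _similar(lens[a][1], lens[b][1], max_exon_diff)
                for a, b in pairs
            )
            if not ok:
                continue
            ci = ConservedIntron(gene_id=gid, intron_index=i)
            for t, m in models.items():
                s, e = m.introns[i]
                ci.chrom[t] = m.chrom
                ci.interval[t] = (s, e)
                ci.length[t] = e - s
            out.append(ci)
    return out


def classify_introns(
    introns: list[ConservedIntron],
    repeats_by_taxon: dict[str, pd.DataFrame],
    complex_classes: tuple[str, ...] = ("DNA", "LTR", "non-LTR", "satellite"),
) -> None:
    """Label each conserved intron complex/simple per taxon, in place."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for taxon, df in repeats_by_taxon.items():
        trees[taxon] = {}
        for _, r in df[df["klass"].isin(complex_classes)].iterrows():
            trees[taxon].setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    for ci in introns:
        for taxon in ci.interval:
            tree = trees.get(taxon, {}).get(ci.chrom[taxon])
            s, e = ci.interval[taxon]
            hit = bool(tree is not None and tree.overlap(s, e))
            ci.klass[taxon] = "complex" if hit else "simple"


def classify_intron(
    interval: tuple[int, int], chrom: str, repeats: pd.DataFrame,
    complex_classes: tuple[str, ...] = ("DNA", "LTR", "non-LTR", "satellite"),
) -> str:
    """Complex iff the intron overlaps >= 1 bp of TE/complex-satellite sequence."""
    sub = repeats[(repeats["chrom"] == chrom) & repeats["klass"].isin(complex_classes)]
    s, e = interval
    hit = ((sub["start"] < e) & (sub["end"] > s)).any()
    return "complex" if hit else "simple"


@dataclass
class IntronLengthComparison:
    taxon_a: str
    taxon_b: str
    klass: str
    compartment: str
    n: int
    mean_diff: float
    result: stats.PairedTResult


def compare_lengths(
    introns: list[ConservedIntron],
    taxon_a: str,
    taxon_b: str,
    klass: str = "all",
    compartment: str = "all",
    compartments: dict[str, list[tuple[int, int, str]]] | None = None,
) -> IntronLengthComparison:
    """Paired t-test of per-intron length differences (taxon_a - taxon_b).

    ``klass`` filters on the intron's class in taxon_a ('complex', 'simple'
    or 'all'); ``compartment`` filters on the compartment of the taxon_a
    midpoint ('eu', 'het', 'all'; requires taxon_a compartment annotation).
    """
    diffs = []
    for ci in introns:
        if taxon_a not in ci.length or taxon_b not in ci.length:
            continue
        if klass != "all" and ci.klass.get(taxon_a) != klass:
            continue
        if compartment != "all":
            if compartments is None:
                raise ValueError("compartment filter requires compartment intervals")
            s, e = ci.interval[taxon_a]
            mid = (s + e) // 2
            label = None
            for cs, ce, lab in compartments.get(ci.chrom[taxon_a], []):
                if cs <= mid < ce:
                    label = lab
                    break
            if label != compartment:
                continue
        diffs.append(ci.length[taxon_a] - ci.length[taxon_b])
    if len(diffs) < 2:
        raise ValueError("need at least 2 paired introns for a comparison")
    res = stats.paired_t(diffs)
    return IntronLengthComparison(
        taxon_a, taxon_b, klass, compartment, res.n, res.mean_diff, res
    )


def comparison_table(
    introns: list[ConservedIntron], reference: str, taxa: list[str]
) -> pd.DataFrame:
    """Reference-vs-each-taxon comparisons for complex and simple introns."""
    rows = []
    for taxon in taxa:
        if taxon == reference:
            continue
        for klass in ("complex", "simple"):
            try:
                c = compare_lengths(introns, reference, taxon, klass=klass)
            except ValueError:
                continue
            rows.append(
                (reference, taxon, klass, c.n, c.mean_diff, c.result.t, c.result.p_value)
            )
    return pd.DataFrame(
        rows, columns=["taxon_a", "taxon_b", "class", "n", "mean_diff", "t", "p_value"]
    )
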