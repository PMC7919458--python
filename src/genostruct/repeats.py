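"""Branch assignment of repeat content by syntenic containment + set algebra.

The procedure mirrors the pairwise-sharing design: repeats of a focal taxon
are first filtered to those fully contained in syntenic blocks of each
pairwise alignment, then an element is "shared" with another taxon when its
projection reciprocally overlaps a same-class repeat there.  Sharing with
both sister ingroup taxa but not the reference taxon places an element on
the ingroup stem; sharing with all three places it in the complex-wide
(pre-reference-split) category.  Categories describe *detected* sharing,
not true absence: an element called taxon-specific may simply have escaped
detection elsewhere.

Satellites are excluded from the branch algebra by default (the sharing
analysis concerns TEs); euchromatin-only scope is applied by the caller
via :func:`euchromatic_subset`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .models import TE_CLASSES
from .synteny import AlignmentMap

REPEAT_COLUMNS = ["repeat_id", "chrom", "start", "end", "strand", "family", "klass"]


def repeats_frame(repeats) -> pd.DataFrame:
    """Normalize a list of Repeat objects (or a frame) to the working frame."""
    if isinstance(repeats, pd.DataFrame):
        df = repeats.copy()
    else:
        df = pd.DataFrame(
            [
                (r.repeat_id, r.chrom, r.start, r.end, r.strand, r.family, r.klass)
                for r in repeats
            ],
            columns=REPEAT_COLUMNS,
        )
    return df.reset_index(drop=True)


def euchromatic_subset(
    df: pd.DataFrame, compartments: dict[str, list[tuple[int, int, str]]]
) -> pd.DataFrame:
    """Repeats whose midpoint lies in a 'eu' compartment interval."""
    keep = []
    for _, row in df.iterrows():
        mid = (row.start + row.end) // 2
        for s, e, lab in compartments.get(row.chrom, []):
            if s <= mid < e:
                keep.append(lab == "eu")
                break
        else:
            keep.append(False)
    return df[pd.Series(keep, index=df.index)].reset_index(drop=True)


def contained_repeats(
    df: pd.DataFrame, amap: AlignmentMap, side: str = "ref"
) -> pd.DataFrame:
    """Repeats 100% contained within a single synteny block (containment = 1.0)."""
    blocks: dict[str, list[tuple[int, int]]] = {}
    for b in amap.blocks:
        if side == "ref":
            blocks.setdefault(b.ref_chrom, []).append((b.ref_start, b.ref_end))
        else:
            blocks.setdefault(b.qry_chrom, []).append((b.qry_start, b.qry_end))
    trees = {c: IntervalTree.from_tuples(iv) for c, iv in blocks.items()}
    keep = []
    for _, row in df.iterrows():
        tree = trees.get(row.chrom)
        ok = False
        if tree is not None:
            for hit in tree.overlap(row.start, row.end):
                if hit.begin <= row.start and row.end <= hit.end:
                    ok = True
                    break
        keep.append(ok)
    return df[pd.Series(keep, index=df.index)].reset_index(drop=True)


def shared_repeat_content(
    rep_a: pd.DataFrame,
    rep_b: pd.DataFrame,
    map_ab: AlignmentMap,
    min_reciprocal: float = 0.5,
    same_class: bool = True,
) -> pd.DataFrame:
    """Element pairs shared between taxon A (map reference) and taxon B.

    An A element is shared with B when its projected image reciprocally
    overlaps a B repeat of the same class by at least ``min_reciprocal`` of
    each element's length.  Returns one row per (a_id, b_id) pair with the
    overlapping bp.
    """
    trees: dict[str, IntervalTree] = {}
    for i, row in rep_b.iterrows():
        trees.setdefault(row.chrom, IntervalTree())
        trees[row.chrom].addi(row.start, row.end, i)
    rows = []
    for _, a in rep_a.iterrows():
        images = map_ab.project_interval(a.chrom, int(a.start), int(a.end))
        for im in images:
            tree = trees.get(im["qry_chrom"])
            if tree is None:
                continue
            for hit in tree.overlap(im["qry_start"], im["qry_end"]):
                b = rep_b.loc[hit.data]
                if same_class and b.klass != a.klass:
                    continue
                ov = min(im["qry_end"], b.end) - max(im["qry_start"], b.start)
                len_a = a.end - a.start
                len_b = b.end - b.start
                if ov <= 0:
                    continue
                if ov / len_a >= min_reciprocal and ov / len_b >= min_reciprocal:
                    rows.append((a.repeat_id, b.repeat_id, ov, len_a, len_b))
    return pd.DataFrame(
        rows, columns=["a_id", "b_id", "overlap_bp", "a_len", "b_len"]
    ).drop_duplicates(subset=["a_id", "b_id"])


@dataclass
class BranchAssignment:
    """Per focal-taxon element: sharing category (mutually exclusive)."""

    table: pd.DataFrame  # columns: repeat_id, category

    def counts(self) -> pd.Series:
        return self.table["category"].value_counts()


def assign_branches(
    elements: pd.DataFrame,
    shared_with: dict[str, set],
    sister_taxa: tuple[str, str],
    reference_taxon: str,
) -> BranchAssignment:
    """Categorize focal-taxon elements from pairwise sharing sets.

    ``shared_with`` maps a partner taxon to the set of focal element ids
    shared with it.  Shared with both sisters and the reference ->
    complex-wide; with both sisters only -> ingroup stem; with exactly one
    partner -> pair-shared; with none -> taxon-specific.
    """
    s1 = shared_with.get(sister_taxa[0], set())
    s2 = shared_with.get(sister_taxa[1], set())
    sr = shared_with.get(reference_taxon, set())
    cats = []
    for rid in elements["repeat_id"]:
        in1, in2, inr = rid in s1, rid in s2, rid in sr
        if in1 and in2 and inr:
            cat = "complex_wide"
        elif in1 and in2:
            cat = "stem"
        elif in1 or in2 or inr:
            partner = sister_taxa[0] if in1 else (sister_taxa[1] if in2 else reference_taxon)
            cat = f"pair:{partner}"
        else:
            cat = "specific"
        cats.append(cat)
    return BranchAssignment(
        pd.DataFrame({"repeat_id": elements["repeat_id"], "category": cats})
    )


def composition_summary(
    assignment: BranchAssignment, elements: pd.DataFrame
) -> pd.DataFrame:
    """bp totals and within-category class proportions (base-level accounting)."""
    df = elements.merge(assignment.table, on="repeat_id")
    df["bp"] = df["end"] - df["start"]
    out = (
        df.groupby(["category", "klass"])["bp"].sum().reset_index(name="bp")
    )
    totals = out.groupby("category")["bp"].transform("sum")
    out["proportion"] = out["bp"] / totals
    return out


def class_proportions(summary: pd.DataFrame, category: str) -> dict[str, float]:
    sub = summary[summary["category"] == category]
    props = dict(zip(sub["klass"], sub["proportion"]))
    return {k: props.get(k, 0.0) for k in TE_CLASSES}


def exonic_overlap(
    elements: pd.DataFrame, assignment: BranchAssignment, genes
) -> pd.DataFrame:
    """Exonic vs non-exonic repeat bp per sharing category."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        for s, e in g.exons:
            trees.setdefault(g.chrom, IntervalTree()).addi(s, e)
    df = elements.merge(assignment.table, on="repeat_id")
    rows = []
    for cat, sub in df.groupby("category"):
        exonic = 0
        total = 0
        for _, r in sub.iterrows():
            total += r.end - r.start
            tree = trees.get(r.chrom)
            if tree is None:
                continue
            covered: set[int] = set()
            for hit in tree.overlap(r.start, r.end):
                covered.update(range(max(hit.begin, r.start), min(hit.end, r.end)))
            exonic += len(covered)
        rows.append((cat, exonic, total - exonic))
    return pd.DataFrame(rows, columns=["category", "exonic_bp", "non_exonic_bp"])
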