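"""Positional tRNA orthology via isotype-string alignment, plus copy-number
and anticodon-shift calls.

Each taxon's tRNA genes on a chromosome are written as a string of isotype
letters (lower-case for pseudogenes) in positional order.  Strings are
globally aligned pairwise to the reference taxon with a deterministic
Needleman-Wunsch (match +2, mismatch -1, gap -2; ties resolved
match > gap-in-A > gap-in-B) and merged into multi-taxon columns anchored
on reference positions.  A column whose members differ in presence is a
copy gain/loss polarized against the outgroup; a column whose members
differ in anticodon at an orthologous position is an isoacceptor shift
(same isotype) or an alloacceptor shift (isotype change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import ANCESTRAL, DERIVED, Phylogeny, dollo_assign

logger = logging.getLogger(__name__)

TRNA_COLUMNS = [
    "taxon", "chrom", "start", "end", "strand", "isotype", "anticodon",
    "pseudo", "cluster", "gene_id",
]

MATCH, MISMATCH, GAP = 2, -1, -2


@dataclass
class IsotypeString:
    taxon: str
    chrom: str
    text: str
    index: list[int]  # position in text -> row index into the source frame
    cluster_breaks: list[int] = field(default_factory=list)


def build_isotype_string(
    trnas: pd.DataFrame, taxon: str, chrom: str, cluster_gap: int = 5_000
) -> IsotypeString:
    """One character per gene in positional order; pseudogenes lower-case."""
    sub = trnas[(trnas["taxon"] == taxon) & (trnas["chrom"] == chrom)].sort_values(
        "start"
    )
    chars, idx, breaks = [], [], []
    prev_end = None
    for pos, (i, row) in enumerate(sub.iterrows()):
        iso = str(row.isotype)
        if len(iso) != 1 or not iso.isalpha():
            logger.warning("unknown isotype %r for %s; using 'X'", iso, row.gene_id)
            iso = "X"
        chars.append(iso.lower() if row.pseudo else iso.upper())
        idx.append(i)
        if prev_end is not None and row.start - prev_end > cluster_gap:
            breaks.append(pos)
        prev_end = row.end
    return IsotypeString(taxon, chrom, "".join(chars), idx, breaks)


def align_isotype_strings(
    s_a: str, s_b: str, match: int = MATCH, mismatch: int = MISMATCH, gap: int = GAP
) -> tuple[int, list[tuple[int | None, int | None]]]:
    """Global alignment; returns (score, columns of (a_index|None, b_index|None)).

    Scoring is case-insensitive (pseudogene case is annotation only).  The
    traceback is deterministic: on score ties prefer the diagonal move, then
    the gap-in-A column, then gap-in-B.
    """
    a, b = s_a.upper(), s_b.upper()
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = score[i - 1, j] + gap  # consumes A -> gap in B
            left = score[i, j - 1] + gap  # consumes B -> gap in A
            score[i, j] = max(diag, up, left)
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif j > 0 and score[i, j] == score[i, j - 1] + gap:
            cols.append((None, j - 1))
            j -= 1
        else:
            cols.append((i - 1, None))
            i -= 1
    cols.reverse()
    return int(score[n, m]), cols


@dataclass
class OrthologyColumn:
    chrom: str
    members: dict[str, int | None]  # taxon -> row index into the tRNA frame
    call: str = "conserved"
    branch: str | None = None
    shift: "ShiftCall | None" = None
    low_confidence: bool = False


@dataclass
class ShiftCall:
    kind: str  # isoacceptor | alloacceptor
    ancestral: tuple[str, str]  # (isotype, anticodon)
    derived: tuple[str, str]
    branch: str | None = None


def _merge_on_reference(
    ref_string: IsotypeString,
    others: dict[str, IsotypeString],
) -> list[OrthologyColumn]:
    """Progressive merge: pairwise alignments to the reference, then columns.

    Insertions relative to the reference (gap-in-reference runs) are keyed by
    (reference gap position, offset) and merged across taxa at equal offsets —
    a deterministic simplification of full multiple alignment that is exact
    for single-gene gains.
    """
    n_ref = len(ref_string.text)
    ref_taxon = ref_string.taxon
    # spine columns, one per reference gene
    spine = [
        OrthologyColumn(ref_string.chrom, {ref_taxon: ref_string.index[i]})
        for i in range(n_ref)
    ]
    inserts: dict[tuple[int, int], OrthologyColumn] = {}
    for taxon in sorted(others):
        s = others[taxon]
        _, cols = align_isotype_strings(ref_string.text, s.text)
        ref_cursor = 0
        offset = 0
        for ai, bi in cols:
            if ai is not None:
                ref_cursor = ai + 1
                offset = 0
                spine[ai].members[taxon] = s.index[bi] if bi is not None else None
            else:
                key = (ref_cursor, offset)
                col = inserts.setdefault(
                    key, OrthologyColumn(ref_string.chrom, {})
                )
                col.members[taxon] = s.index[bi]
                offset += 1
    ordered: list[OrthologyColumn] = []
    for pos in range(n_ref + 1):
        off = 0
        while (pos, off) in inserts:
            ordered.append(inserts[(pos, off)])
            off += 1
        if pos < n_ref:
            ordered.append(spine[pos])
    return ordered


def call_orthology(
    trnas: pd.DataFrame,
    phylogeny: Phylogeny,
    chrom: str,
    maps: dict | None = None,
    flank: int = 1_000,
    flank_slop: int = 10_000,
) -> list[OrthologyColumn]:
    """Orthology columns for one chromosome across all five taxa.

    ``maps`` optionally provides reference->taxon AlignmentMaps used to
    confirm each column by projecting the reference member's flanks; columns
    whose projection lands far from the member gene are flagged
    low-confidence.
    """
    ref_taxon = phylogeny.reference
    ref_string = build_isotype_string(trnas, ref_taxon, chrom)
    others = {
        t: build_isotype_string(trnas, t, chrom)
        for t in (*phylogeny.ingroup, phylogeny.outgroup)
    }
    columns = _merge_on_reference(ref_string, others)
    for col in columns:
        _classify_column(col, trnas, phylogeny)
        if maps:
            _flank_check(col, trnas, maps, ref_taxon, flank, flank_slop)
    return columns


def _classify_column(col: OrthologyColumn, trnas: pd.DataFrame, phy: Phylogeny) -> None:
    present = {t for t, i in col.members.items() if i is not None}
    absent = set(phy.taxa) - present
    if not present:
        col.call = "empty"
        return
    rows = {t: trnas.loc[i] for t, i in col.members.items() if i is not None}
    if absent:
        og = phy.outgroup
        og_present = og in present
        states = {
            t: (DERIVED if (t in present) != og_present else ANCESTRAL)
            for t in phy.taxa
            if t != og
        }
        states[og] = ANCESTRAL
        col.call = "copy_gain" if not og_present else "copy_loss"
        col.branch = dollo_assign(states, phy)
        return
    if any(bool(r.pseudo) for r in rows.values()) and not all(
        bool(r.pseudo) for r in rows.values()
    ):
        col.call = "pseudogenized"
        return
    idents = {(str(r.isotype).upper(), str(r.anticodon).upper()) for r in rows.values()}
    if len(idents) == 1:
        col.call = "conserved"
        return
    col.shift = classify_shift(col, trnas, phy)
    col.call = (
        "isotype_change"
        if col.shift is not None and col.shift.kind == "alloacceptor"
        else "anticodon_change"
    )


def classify_shift(
    col: OrthologyColumn, trnas: pd.DataFrame, phy: Phylogeny
) -> ShiftCall | None:
    """Isoacceptor vs alloacceptor shift at an orthologous column.

    The ancestral state is the outgroup-supported identity; without an
    outgroup member the shift is reported unpolarized with the majority
    state as ancestral.
    """
    rows = {t: trnas.loc[i] for t, i in col.members.items() if i is not None}
    if len(rows) < 2:
        return None
    ident = {
        t: (str(r.isotype).upper(), str(r.anticodon).upper()) for t, r in rows.items()
    }
    if len(set(ident.values())) < 2:
        return None
    og = phy.outgroup
    if og in ident:
        ancestral = ident[og]
    else:
        counts = pd.Series(list(ident.values())).value_counts()
        ancestral = counts.index[0]
    derived_states = [v for v in ident.values() if v != ancestral]
    derived = derived_states[0]
    kind = "isoacceptor" if derived[0] == ancestral[0] else "alloacceptor"
    branch = None
    if og in ident:
        states = {
            t: (DERIVED if v != ancestral else ANCESTRAL) for t, v in ident.items()
        }
        branch = dollo_assign(states, phy)
    return ShiftCall(kind=kind, ancestral=ancestral, derived=derived, branch=branch)


def _flank_check(col, trnas, maps, ref_taxon, flank, slop) -> None:
    ref_i = col.members.get(ref_taxon)
    if ref_i is None:
        return
    ref_row = trnas.loc[ref_i]
    for taxon, amap in maps.items():
        i = col.members.get(taxon)
        if i is None:
            continue
        row = trnas.loc[i]
        try:
            images = amap.project_interval(
                ref_row.chrom, max(int(ref_row.start) - flank, 0), int(ref_row.end) + flank
            )
        except ValueError:
            continue
        if not images:
            col.low_confidence = True
            continue
        near = any(
            im["qry_chrom"] == row.chrom
            and im["qry_start"] - slop <= row.start <= im["qry_end"] + slop
            for im in images
        )
        if not near:
            col.low_confidence = True


def orthology_summary(columns: list[OrthologyColumn]) -> pd.DataFrame:
    rows = [
        (
            c.chrom,
            c.call,
            c.branch,
            c.shift.kind if c.shift else None,
            c.low_confidence,
            sum(1 for v in c.members.values() if v is not None),
        )
        for c in columns
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "call", "branch", "shift_kind", "low_confidence",
                       "n_members"]
    )
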