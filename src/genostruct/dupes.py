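"""Tandem/dispersed duplication detection, gene-overlap classes, outgroup
polarization, X-enrichment proportion tests, and fixation-rate arithmetic.

Detection works from the pairwise alignment map between a reference-state
genome and a query.  A duplicated segment has no unique k-mers in the query
(two identical copies), so the region drops out of the anchor set on both
sides: the reference shows an unaligned source interval R and the query
shows a gap Q between the same flanking blocks that is about twice as long.
A call is made when the sequence of R matches two or more disjoint
high-identity images inside Q (tandem) or one image in Q plus a
high-identity unaligned insertion elsewhere (dispersed).  Copy number comes
from the alignment images only; intervals annotated as repeats are excluded
so that TE insertions are not re-reported as duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd
from intervaltree import IntervalTree

from . import stats
from .models import Gene, reciprocal_overlap
from .phylo import Phylogeny
from .synteny import AlignmentMap

OVERLAP_CLASSES = ("intergenic", "exonic", "full_CDS", "full_gene")

_COMP_TABLE = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP_TABLE)[::-1]


def _insertion_runs(cigar: str, min_run: int) -> list[tuple[int, int]]:
    """(query_offset, length) of 'I' runs >= min_run in an edlib NW cigar."""
    runs = []
    qpos = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in ("=", "X", "M"):
            qpos += n
        elif ch == "I":  # present in query, absent in target
            if n >= min_run:
                runs.append((qpos, n))
            qpos += n
        # 'D' consumes target only
    return runs


@dataclass
class DuplicationCall:
    taxon: str
    ref_chrom: str
    ref_start: int  # ancestral-state (single-copy) source interval
    ref_end: int
    qry_copies: list[tuple[str, int, int]] = field(default_factory=list)
    arrangement: str = "tandem"  # tandem | dispersed
    identity: float = 1.0
    overlap_class: str | None = None
    branch: str | None = None

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)


def _repeat_trees(repeats: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if repeats is None:
        return trees
    for _, r in repeats.iterrows():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def _masked_fraction(trees, chrom: str, start: int, end: int) -> float:
    tree = trees.get(chrom)
    if tree is None or end <= start:
        return 0.0
    ivs = sorted(
        (max(h.begin, start), min(h.end, end)) for h in tree.overlap(start, end)
    )
    covered = 0
    cursor = start
    for s, e in ivs:
        if e > cursor:
            covered += e - max(s, cursor)
            cursor = e
    return covered / (end - start)


def _count_copies(needle: str, hay: str, min_identity: float) -> list[tuple[int, int]]:
    """Non-overlapping high-identity images of needle inside hay (greedy)."""
    hits = []
    remaining = [(0, hay)]
    max_dist = int(len(needle) * (1.0 - min_identity))
    while remaining:
        off, seg = remaining.pop()
        if len(seg) < len(needle) * min_identity:
            continue
        res = edlib.align(needle, seg, mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > max_dist:
            continue
        s, e = res["locations"][0]
        e += 1
        hits.append((off + s, off + e))
        remaining.append((off, seg[: max(s, 0)]))
        remaining.append((off + e, seg[e:]))
    return sorted(hits)


def detect_duplications(
    amap: AlignmentMap,
    ref_seqs: dict[str, str],
    qry_seqs: dict[str, str],
    taxon: str = "qry",
    min_len: int = 100,
    max_len: int = 20_000,
    tandem_gap: int = 10_000,
    min_identity: float = 0.8,
    ref_repeats: pd.DataFrame | None = None,
    qry_repeats: pd.DataFrame | None = None,
    repeat_mask_fraction: float = 0.5,
) -> list[DuplicationCall]:
    """Call duplications present in the query relative to the reference state."""
    ref_mask = _repeat_trees(ref_repeats)
    qry_mask = _repeat_trees(qry_repeats)
    calls: list[DuplicationCall] = []

    # Within a block, a query-side duplication shifts the alignment diagonal
    # by the copy length; anchors inside the duplicated region are an
    # unreliable mosaic (the reference matches either copy).  Compress
    # anchors into stable diagonal runs; each positive diagonal step gives a
    # candidate region together with the surplus length directly.
    gap_pairs = []  # (ref_chrom, rs, re, qry_chrom, q_lo, q_hi, orient, delta)
    stable_bp = 200
    for b in amap.blocks:
        runs = []  # [diag, ref_lo, ref_hi, q_min, q_max, anchored_bp]
        for a in b.anchors:
            d = (a.qry_start - a.ref_start) if b.orient > 0 else (
                a.qry_start + a.ref_end
            )
            if runs and abs(d - runs[-1][0]) <= 25:
                runs[-1][2] = max(runs[-1][2], a.ref_end)
                runs[-1][3] = min(runs[-1][3], a.qry_start)
                runs[-1][4] = max(runs[-1][4], a.qry_end)
                runs[-1][5] += a.length
            else:
                runs.append([d, a.ref_start, a.ref_end, a.qry_start, a.qry_end,
                             a.length])
        stable = [
            r
            for i, r in enumerate(runs)
            if r[5] >= stable_bp or i == 0 or i == len(runs) - 1
        ]
        # fine steps between all consecutive runs resolve compound regions
        # (several nearby events); coarse steps between stable runs catch
        # events whose interior is an anchor mosaic.  Duplicate candidates
        # are collapsed downstream by source-interval dedup.
        pair_iter = list(zip(runs, runs[1:])) + [
            p for p in zip(stable, stable[1:]) if p not in zip(runs, runs[1:])
        ]
        for r1, r2 in pair_iter:
            delta = (r2[0] - r1[0]) if b.orient > 0 else (r1[0] - r2[0])
            if delta < min_len:
                continue  # not a query-side surplus
            rs, re_ = r1[2], r2[1]
            if b.orient > 0:
                q_lo, q_hi = r1[4], r2[3]
            else:
                q_lo, q_hi = r2[4], r1[3]
            gap_pairs.append(
                (b.ref_chrom, rs, re_, b.qry_chrom, q_lo, q_hi, b.orient, delta)
            )
    by_chrom: dict[str, list] = {}
    for b in amap.blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    for blocks in by_chrom.values():
        blocks.sort(key=lambda b: b.ref_start)
        for b1, b2 in zip(blocks, blocks[1:]):
            if b1.qry_chrom != b2.qry_chrom or b1.orient != b2.orient:
                continue
            if b1.orient > 0:
                q_lo, q_hi = b1.qry_end, b2.qry_start
            else:
                q_lo, q_hi = b2.qry_end, b1.qry_start
            delta = (q_hi - q_lo) - (b2.ref_start - b1.ref_end)
            if delta < min_len:
                continue
            gap_pairs.append(
                (b1.ref_chrom, b1.ref_end, b2.ref_start, b1.qry_chrom, q_lo, q_hi,
                 b1.orient, delta)
            )

    insertions = []  # unexplained query surplus: dispersed-copy candidates
    seen_src: list[tuple[str, int, int]] = []
    for chrom, rs, re_, qchrom, q_lo, q_hi, orient, delta in gap_pairs:
        if delta > max_len:
            continue
        qlen = len(qry_seqs[qchrom])
        if q_hi <= q_lo or _masked_fraction(
            qry_mask, qchrom, max(q_lo, 0), min(q_hi, qlen)
        ) > repeat_mask_fraction:
            continue
        # two placements of the surplus copy within the unanchored window
        cand = []
        for xs in (max(q_hi - delta, 0), max(q_lo, 0)):
            xe = min(xs + delta, qlen)
            if xe - xs >= min_len:
                cand.append((xs, xe))
        ext = delta + tandem_gap
        s_lo = max(rs - ext, 0)
        s_hi = min(re_ + ext, len(ref_seqs[chrom]))
        hay = ref_seqs[chrom][s_lo:s_hi]
        best = None
        for xs, xe in cand:
            x = qry_seqs[qchrom][xs:xe]
            needle = x if orient > 0 else _revcomp(x)
            hit = edlib.align(needle, hay, mode="HW", task="locations")
            d = hit["editDistance"]
            if d < 0 or d > int(len(x) * (1.0 - min_identity)):
                continue
            if best is None or d < best[0]:
                best = (d, xs, xe, hit["locations"][0])
        if best is None:
            # compound region (several nearby events): decompose by local
            # alignment and test each query-side insertion run separately
            v_lo = max(q_lo - 200, 0)
            v_hi = min(q_hi + 200, qlen)
            r_lo = max(rs - 200, 0)
            r_hi = min(re_ + 200, len(ref_seqs[chrom]))
            if v_hi - v_lo <= 40_000:
                v_seq = qry_seqs[qchrom][v_lo:v_hi]
                if orient < 0:
                    v_seq = _revcomp(v_seq)
                res = edlib.align(v_seq, ref_seqs[chrom][r_lo:r_hi], mode="NW",
                                  task="path")
                for vi, ilen in _insertion_runs(res["cigar"], min_len):
                    if orient > 0:
                        xs2, xe2 = v_lo + vi, v_lo + vi + ilen
                    else:
                        xs2, xe2 = v_hi - vi - ilen, v_hi - vi
                    x2 = qry_seqs[qchrom][xs2:xe2]
                    needle2 = x2 if orient > 0 else _revcomp(x2)
                    hit2 = edlib.align(needle2, hay, mode="HW", task="locations")
                    d2 = hit2["editDistance"]
                    if d2 < 0 or d2 > int(len(x2) * (1.0 - min_identity)):
                        insertions.append((qchrom, xs2, xe2))
                        continue
                    ls2, le2 = hit2["locations"][0]
                    src2 = (chrom, s_lo + ls2, s_lo + le2 + 1)
                    if _masked_fraction(ref_mask, *src2) > repeat_mask_fraction:
                        continue
                    if any(
                        c == src2[0] and reciprocal_overlap((s, e), src2[1:]) >= 0.5
                        for c, s, e in seen_src
                    ):
                        continue
                    seen_src.append(src2)
                    calls.append(
                        DuplicationCall(
                            taxon=taxon,
                            ref_chrom=src2[0],
                            ref_start=src2[1],
                            ref_end=src2[2],
                            qry_copies=[(qchrom, xs2, xe2)],
                            arrangement="tandem",
                            identity=1.0 - d2 / max(len(x2), 1),
                        )
                    )
            else:
                insertions.append((qchrom, max(q_hi - delta, 0), q_hi))
            continue
        d, xs, xe, (ls, le) = best
        src = (chrom, s_lo + ls, s_lo + le + 1)
        if _masked_fraction(ref_mask, *src) > repeat_mask_fraction:
            continue
        if any(
            c == src[0] and reciprocal_overlap((s, e), src[1:]) >= 0.5
            for c, s, e in seen_src
        ):
            continue  # same source already reported from an adjacent step
        seen_src.append(src)
        src_seq = ref_seqs[chrom][src[1] : src[2]]
        needle = src_seq if orient > 0 else _revcomp(src_seq)
        hay_lo = max(q_lo - delta - 200, 0)
        hay_hi = min(q_hi + delta + 200, qlen)
        copies = _count_copies(needle, qry_seqs[qchrom][hay_lo:hay_hi], min_identity)
        spans = sorted((hay_lo + s, hay_lo + e) for s, e in copies)
        if len(spans) < 2:
            spans = sorted(set(spans) | {(xs, xe)})
        gaps_ok = all(
            spans[i + 1][0] - spans[i][1] <= tandem_gap
            for i in range(len(spans) - 1)
        )
        calls.append(
            DuplicationCall(
                taxon=taxon,
                ref_chrom=src[0],
                ref_start=src[1],
                ref_end=src[2],
                qry_copies=[(qchrom, s, e) for s, e in spans],
                arrangement="tandem" if gaps_ok else "dispersed",
                identity=1.0 - d / max(xe - xs, 1),
            )
        )

    # dispersed calls: unexplained insertions matched against the whole
    # reference (bounded; a duplication's source locus is aligned elsewhere)
    for qchrom, qs, qe in insertions[:30]:
        if qe - qs > max_len:
            continue
        if _masked_fraction(qry_mask, qchrom, qs, qe) > repeat_mask_fraction:
            continue
        seg = qry_seqs[qchrom][qs:qe]
        max_dist = int(len(seg) * (1.0 - min_identity))
        best = None
        for chrom, rseq in ref_seqs.items():
            for needle in (seg, _revcomp(seg)):
                hit = edlib.align(needle, rseq, mode="HW", task="locations")
                d = hit["editDistance"]
                if 0 <= d <= max_dist and (best is None or d < best[0]):
                    ls, le = hit["locations"][0]
                    best = (d, chrom, ls, le + 1)
        if best is None:
            continue
        d, chrom, rs, re_ = best
        if _masked_fraction(ref_mask, chrom, rs, re_) > repeat_mask_fraction:
            continue
        calls.append(
            DuplicationCall(
                taxon=taxon,
                ref_chrom=chrom,
                ref_start=rs,
                ref_end=re_,
                qry_copies=[(qchrom, qs, qe)],
                arrangement="dispersed",
                identity=1.0 - d / max(len(seg), 1),
            )
        )
    return [c for c in calls if c.length >= min_len]


# ------------------------------------------------------------ classification

def classify_overlap(call: DuplicationCall, genes: list[Gene]) -> str:
    """Maximal gene-model overlap class of the source interval."""
    iv = call.ref_interval
    best = "intergenic"
    rank = {c: i for i, c in enumerate(OVERLAP_CLASSES)}
    for g in genes:
        if g.chrom != call.ref_chrom:
            continue
        span = g.span
        if iv[0] <= span[0] and span[1] <= iv[1]:
            cls = "full_gene"
        elif iv[0] <= g.cds[0] and g.cds[1] <= iv[1]:
            cls = "full_CDS"
        elif any(min(iv[1], e) > max(iv[0], s) for s, e in g.exons):
            cls = "exonic"
        else:
            continue
        if rank[cls] > rank[best]:
            best = cls
    call.overlap_class = best
    return best


# ------------------------------------------------------------ polarization

def polarize_duplications(
    calls_by_taxon: dict[str, list[DuplicationCall]],
    outgroup_calls: list[DuplicationCall],
    phylogeny: Phylogeny,
    min_reciprocal: float = 0.5,
) -> dict:
    """Stem assignment by Dollo logic on reference-frame source intervals.

    Calls shared by all three ingroup taxa (reciprocal-overlap clustering in
    the shared reference coordinate frame) are stem candidates; candidates
    that also overlap an outgroup call predate the stem (or reflect loss in
    the reference lineage) and are set aside; the remainder are assigned to
    the stem.  Calls seen in a single taxon go to that terminal branch.
    """
    ingroup = list(phylogeny.ingroup)
    clusters: list[dict] = []  # {chrom, start, end, members: {taxon: call}}
    for taxon in ingroup:
        for call in calls_by_taxon.get(taxon, []):
            placed = False
            for cl in clusters:
                if cl["chrom"] != call.ref_chrom or taxon in cl["members"]:
                    continue
                if (
                    reciprocal_overlap((cl["start"], cl["end"]), call.ref_interval)
                    >= min_reciprocal
                ):
                    cl["members"][taxon] = call
                    cl["start"] = min(cl["start"], call.ref_start)
                    cl["end"] = max(cl["end"], call.ref_end)
                    placed = True
                    break
            if not placed:
                clusters.append(
                    {
                        "chrom": call.ref_chrom,
                        "start": call.ref_start,
                        "end": call.ref_end,
                        "members": {taxon: call},
                    }
                )

    def in_outgroup(cl) -> bool:
        return any(
            o.ref_chrom == cl["chrom"]
            and reciprocal_overlap((cl["start"], cl["end"]), o.ref_interval)
            >= min_reciprocal
            for o in outgroup_calls
        )

    stem, older, terminal, other = [], [], [], []
    for cl in clusters:
        n = len(cl["members"])
        if n == len(ingroup):
            (older if in_outgroup(cl) else stem).append(cl)
        elif n == 1:
            taxon = next(iter(cl["members"]))
            for call in cl["members"].values():
                call.branch = taxon
            terminal.append(cl)
        else:
            other.append(cl)
    for cl in stem:
        for call in cl["members"].values():
            call.branch = "stem"
    for cl in older:
        for call in cl["members"].values():
            call.branch = "older_than_stem"
    return {
        "clusters": clusters,
        "ingroup_shared": len(stem) + len(older),
        "outgroup_overlapping": len(older),
        "stem": len(stem),
        "stem_clusters": stem,
        "terminal_clusters": terminal,
        "partial_clusters": other,
    }


# ------------------------------------------------------------ statistics

def x_enrichment(
    n_x: int,
    n_total: int,
    null_prop: float,
    alternative: str = stats.TWO_SIDED,
    continuity: bool = True,
) -> stats.PropTestResult:
    """Proportion test of X-linked duplication count against a null fraction."""
    if n_total == 0:
        raise ValueError("no duplication calls to test")
    return stats.prop_test_one_sample(
        n_x, n_total, null_prop, alternative=alternative, continuity=continuity
    )


def duplication_rate(count: int, branch_myr: float) -> dict:
    """New-duplicate fixation rate per Myr and waiting time per gene."""
    out = stats.rate_per_myr(count, branch_myr)
    return {"rate_per_myr": out["rate"], "years_per_gene": out["years_per_event"]}
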