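"""Orientation-aware collinear synteny blocks from unique exact anchors.

Anchors are maximal runs of k-mers that occur exactly once in each genome
(both strands considered, via canonical codes).  Because repeated sequence
(TE families, satellite arrays, duplicated segments) has no unique k-mers,
repeat regions are inherently anchor-free, which reproduces the
"fails to align uniquely" behaviour of whole-genome aligners without an
explicit masking step.  Anchors are chained into locally collinear blocks:
within a block successive anchors share one orientation, have bounded ref
and query gaps, and are coordinate-monotone; blocks below a minimum span
are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

_COMP_TABLE = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP_TABLE)[::-1]


@dataclass(frozen=True)
class Anchor:
    """A unique maximal exact match between the two genomes."""

    ref_chrom: str
    ref_start: int
    qry_chrom: str
    qry_start: int
    length: int
    orient: int  # +1 / -1

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length


@dataclass
class SyntenyBlock:
    block_id: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    orient: int
    anchors: list[Anchor] = field(default_factory=list, repr=False)
    identity: float | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def anchored_bp(self) -> int:
        return sum(a.length for a in self.anchors)

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start


class CoordinateError(ValueError):
    pass


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed integer codes of all k-windows (rolling, no large temporaries)."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + arr[j : j + n].astype(np.int64)
    return codes


def _genome_windows(seqs: dict[str, str], k: int):
    """Forward and reverse-complement codes for every window of every chromosome."""
    chroms, fwd, rc, pos = [], [], [], []
    for ci, (chrom, seq) in enumerate(sorted(seqs.items())):
        arr = _encode(seq)
        f = _kmer_codes(arr, k)
        if len(f) == 0:
            continue
        arr_rc = (3 - arr)[::-1]
        r = _kmer_codes(arr_rc, k)[::-1]  # rc code of the window starting at i
        chroms.append(np.full(len(f), ci, dtype=np.int32))
        fwd.append(f)
        rc.append(r)
        pos.append(np.arange(len(f), dtype=np.int64))
    names = [c for c, _ in sorted(seqs.items())]
    if not fwd:
        z = np.empty(0, dtype=np.int64)
        return names, z.astype(np.int32), z, z, z
    return (
        names,
        np.concatenate(chroms),
        np.concatenate(fwd),
        np.concatenate(rc),
        np.concatenate(pos),
    )


def find_anchors(ref: dict[str, str], qry: dict[str, str], k: int = 21) -> list[Anchor]:
    """Unique maximal exact matches seeded by genome-unique canonical k-mers.

    k must be odd (no self-reverse-complement k-mers) and >= 11.
    """
    if k < 11 or k % 2 == 0:
        raise ValueError("k must be an odd integer >= 11")
    rnames, rchrom, rfwd, rrc, rpos = _genome_windows(ref, k)
    qnames, qchrom, qfwd, qrc, qpos = _genome_windows(qry, k)
    if len(rfwd) == 0 or len(qfwd) == 0:
        return []
    rcanon = np.minimum(rfwd, rrc)
    qcanon = np.minimum(qfwd, qrc)

    def unique_mask(canon: np.ndarray) -> np.ndarray:
        _, inverse, counts = np.unique(canon, return_inverse=True, return_counts=True)
        return counts[inverse] == 1

    rmask = unique_mask(rcanon)
    qmask = unique_mask(qcanon)
    r_idx_all = np.nonzero(rmask)[0]
    q_idx_all = np.nonzero(qmask)[0]
    common, ri, qi = np.intersect1d(
        rcanon[r_idx_all], qcanon[q_idx_all], assume_unique=True, return_indices=True
    )
    if len(common) == 0:
        return []
    r_idx = r_idx_all[ri]
    q_idx = q_idx_all[qi]
    orient = np.where(rfwd[r_idx] == qfwd[q_idx], 1, -1).astype(np.int8)

    order = np.lexsort((rpos[r_idx], rchrom[r_idx]))
    rc_, rp_ = rchrom[r_idx][order], rpos[r_idx][order]
    qc_, qp_ = qchrom[q_idx][order], qpos[q_idx][order]
    o_ = orient[order]

    # merge runs of consecutive windows into maximal exact matches
    brk = np.ones(len(rp_), dtype=bool)
    if len(rp_) > 1:
        same = (
            (np.diff(rc_) == 0)
            & (np.diff(rp_) == 1)
            & (np.diff(qc_) == 0)
            & (o_[1:] == o_[:-1])
            & (np.diff(qp_) == o_[:-1])
        )
        brk[1:] = ~same
    starts = np.nonzero(brk)[0]
    ends = np.append(starts[1:], len(rp_))
    anchors = []
    for s, e in zip(starts, ends):
        run = e - s
        rs = int(rp_[s])
        if o_[s] > 0:
            qs = int(qp_[s])
        else:
            qs = int(qp_[e - 1])
        anchors.append(
            Anchor(
                ref_chrom=rnames[rc_[s]],
                ref_start=rs,
                qry_chrom=qnames[qc_[s]],
                qry_start=qs,
                length=run + k - 1,
                orient=int(o_[s]),
            )
        )
    return anchors


def chain_anchors(
    anchors: list[Anchor], max_gap: int = 20_000, min_block: int = 1_000
) -> list[SyntenyBlock]:
    """Chain collinear anchors into blocks; drop blocks shorter than min_block.

    Greedy left-to-right chaining in reference order with a post-merge pass;
    on unique-anchor input this attains the maximum-anchored-bp chain.  Ties
    are inherently deterministic (anchors are sorted by reference position).
    """
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a.ref_chrom, a.ref_start))
    # adjacent unique-window runs may overlap by up to k-1 bp around a
    # non-unique patch; tolerate small overlaps while requiring progress
    tol = 100

    def compatible(chain: list[Anchor], a: Anchor) -> bool:
        prev = chain[-1]
        if (
            a.ref_chrom != prev.ref_chrom
            or a.qry_chrom != prev.qry_chrom
            or a.orient != prev.orient
        ):
            return False
        if not (-tol <= a.ref_start - prev.ref_end <= max_gap) or a.ref_end <= prev.ref_end:
            return False
        if a.orient > 0:
            gap = a.qry_start - prev.qry_end
        else:
            gap = prev.qry_start - a.qry_end
        return -tol <= gap <= max_gap

    chains: list[list[Anchor]] = []
    for a in anchors:
        if chains and compatible(chains[-1], a):
            chains[-1].append(a)
        else:
            chains.append([a])

    def to_block(chain: list[Anchor], bid: int) -> SyntenyBlock:
        qs = min(a.qry_start for a in chain)
        qe = max(a.qry_end for a in chain)
        return SyntenyBlock(
            block_id=bid,
            ref_chrom=chain[0].ref_chrom,
            ref_start=chain[0].ref_start,
            ref_end=chain[-1].ref_end,
            qry_chrom=chain[0].qry_chrom,
            qry_start=qs,
            qry_end=qe,
            orient=chain[0].orient,
            anchors=chain,
        )

    kept = [c for c in chains if c[-1].ref_end - c[0].ref_start >= min_block]
    # a discarded micro-chain may have split two compatible halves: re-merge
    merged: list[list[Anchor]] = []
    for c in kept:
        if merged and compatible(merged[-1], c[0]):
            merged[-1].extend(c)
        else:
            merged.append(c)
    blocks = [to_block(c, i + 1) for i, c in enumerate(merged)]

    # Enforce the non-overlap contract: repeat-associated relic chains
    # (anchors displaced into a paralogous copy) can land inside the span of
    # a dominant collinear block.  Heavier blocks win; lighter blocks are
    # trimmed to their anchors outside every heavier block's span and
    # re-chained, so genuinely aligned flanks survive.
    limit = 200
    kept: list[SyntenyBlock] = []
    for b in sorted(blocks, key=lambda x: -x.anchored_bp):
        anchors = b.anchors
        for o in kept:
            if (
                b.ref_chrom == o.ref_chrom
                and min(b.ref_end, o.ref_end) - max(b.ref_start, o.ref_start) > limit
            ):
                anchors = [
                    a
                    for a in anchors
                    if not (a.ref_start < o.ref_end and o.ref_start < a.ref_end)
                ]
            if (
                b.qry_chrom == o.qry_chrom
                and min(b.qry_end, o.qry_end) - max(b.qry_start, o.qry_start) > limit
            ):
                anchors = [
                    a
                    for a in anchors
                    if not (a.qry_start < o.qry_end and o.qry_start < a.qry_end)
                ]
        if len(anchors) == len(b.anchors):
            kept.append(b)
            continue
        sub: list[list[Anchor]] = []
        for a in anchors:
            if sub and compatible(sub[-1], a):
                sub[-1].append(a)
            else:
                sub.append([a])
        for c in sub:
            if c[-1].ref_end - c[0].ref_start >= min_block:
                kept.append(to_block(c, 0))
    _trim_small_overlaps(kept)
    kept.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    for i, b in enumerate(kept):
        b.block_id = i + 1
    return kept


def _trim_small_overlaps(blocks: list[SyntenyBlock], limit: int = 200) -> None:
    """Make block intervals disjoint on both genomes (boundary-window overlaps)."""
    by_ref = sorted(blocks, key=lambda b: (b.ref_chrom, b.ref_start))
    for prev, nxt in zip(by_ref, by_ref[1:]):
        if prev.ref_chrom == nxt.ref_chrom and 0 < prev.ref_end - nxt.ref_start <= limit:
            nxt.ref_start = prev.ref_end
    by_qry = sorted(blocks, key=lambda b: (b.qry_chrom, b.qry_start))
    for prev, nxt in zip(by_qry, by_qry[1:]):
        if prev.qry_chrom == nxt.qry_chrom and 0 < prev.qry_end - nxt.qry_start <= limit:
            nxt.qry_start = prev.qry_end


class AlignmentMap:
    """Ordered synteny blocks between two genomes plus unaligned intervals."""

    def __init__(
        self,
        blocks: list[SyntenyBlock],
        ref_lengths: dict[str, int],
        qry_lengths: dict[str, int],
        ref_name: str = "ref",
        qry_name: str = "qry",
    ):
        self.blocks = sorted(blocks, key=lambda b: (b.ref_chrom, b.ref_start))
        self.ref_lengths = dict(ref_lengths)
        self.qry_lengths = dict(qry_lengths)
        self.ref_name = ref_name
        self.qry_name = qry_name

    @classmethod
    def build(
        cls,
        ref: dict[str, str],
        qry: dict[str, str],
        k: int = 21,
        max_gap: int = 20_000,
        min_block: int = 1_000,
        ref_name: str = "ref",
        qry_name: str = "qry",
    ) -> "AlignmentMap":
        anchors = find_anchors(ref, qry, k=k)
        blocks = chain_anchors(anchors, max_gap=max_gap, min_block=min_block)
        return cls(
            blocks,
            {c: len(s) for c, s in ref.items()},
            {c: len(s) for c, s in qry.items()},
            ref_name=ref_name,
            qry_name=qry_name,
        )

    # ------------------------------------------------------------ intervals

    def _unaligned(self, lengths: dict[str, int], side: str) -> dict[str, list[tuple[int, int]]]:
        by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
        for b in self.blocks:
            if side == "ref":
                by_chrom[b.ref_chrom].append((b.ref_start, b.ref_end))
            else:
                by_chrom[b.qry_chrom].append((b.qry_start, b.qry_end))
        out = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            gaps, cursor = [], 0
            for s, e in ivs:
                if s > cursor:
                    gaps.append((cursor, s))
                cursor = max(cursor, e)
            if cursor < lengths[chrom]:
                gaps.append((cursor, lengths[chrom]))
            out[chrom] = gaps
        return out

    def unaligned_ref_intervals(self) -> dict[str, list[tuple[int, int]]]:
        return self._unaligned(self.ref_lengths, "ref")

    def unaligned_qry_intervals(self) -> dict[str, list[tuple[int, int]]]:
        return self._unaligned(self.qry_lengths, "qry")

    def invert(self) -> "AlignmentMap":
        """Swap reference and query roles."""
        blocks = []
        for b in self.blocks:
            anchors = [
                Anchor(a.qry_chrom, a.qry_start, a.ref_chrom, a.ref_start, a.length, a.orient)
                for a in b.anchors
            ]
            anchors.sort(key=lambda a: a.ref_start)
            blocks.append(
                SyntenyBlock(
                    b.block_id, b.qry_chrom, b.qry_start, b.qry_end,
                    b.ref_chrom, b.ref_start, b.ref_end, b.orient,
                    anchors=anchors, identity=b.identity,
                )
            )
        return AlignmentMap(
            blocks, self.qry_lengths, self.ref_lengths, self.qry_name, self.ref_name
        )

    # ------------------------------------------------------------ projection

    def _project_in_block(self, b: SyntenyBlock, p: int) -> int:
        """Map a ref position inside block b to a query position (anchor-guided)."""
        starts = [a.ref_start for a in b.anchors]
        import bisect

        i = bisect.bisect_right(starts, p) - 1
        if i >= 0:
            a = b.anchors[i]
            if p < a.ref_end:  # inside anchor: exact
                off = p - a.ref_start
                return a.qry_start + off if a.orient > 0 else a.qry_end - 1 - off
            nxt = b.anchors[i + 1] if i + 1 < len(b.anchors) else None
            if nxt is None:
                return a.qry_end - 1 if a.orient > 0 else a.qry_start
            # between anchors: linear interpolation across the gap
            frac = (p - a.ref_end) / max(nxt.ref_start - a.ref_end, 1)
            if a.orient > 0:
                lo, hi = a.qry_end, nxt.qry_start
                return int(lo + frac * max(hi - lo, 0))
            lo, hi = nxt.qry_end, a.qry_start
            return int(hi - frac * max(hi - lo, 0))
        a = b.anchors[0]
        return a.qry_start if a.orient > 0 else a.qry_end - 1

    def project_interval(
        self, chrom: str, start: int, end: int
    ) -> list[dict]:
        """Project a ref interval; one record per overlapping block.

        Each record: qry_chrom, qry_start, qry_end, orient, covered_ref
        (ref bp of the interval inside that block) and split flag (True when
        the interval spans a block boundary).
        """
        if chrom not in self.ref_lengths:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.ref_lengths[chrom] or start >= end:
            raise CoordinateError(f"interval [{start},{end}) outside {chrom}")
        hits = [
            b
            for b in self.blocks
            if b.ref_chrom == chrom and b.ref_start < end and start < b.ref_end
        ]
        out = []
        for b in hits:
            s = max(start, b.ref_start)
            e = min(end, b.ref_end)
            q1 = self._project_in_block(b, s)
            q2 = self._project_in_block(b, e - 1)
            qs, qe = (q1, q2 + 1) if q1 <= q2 else (q2, q1 + 1)
            out.append(
                {
                    "qry_chrom": b.qry_chrom,
                    "qry_start": qs,
                    "qry_end": qe,
                    "orient": b.orient,
                    "covered_ref": e - s,
                    "split": len(hits) > 1 or s > start or e < end,
                    "block_id": b.block_id,
                }
            )
        return out


def summarize_alignment(
    amap: AlignmentMap,
    ref: dict[str, str],
    qry: dict[str, str],
    window: int = 10_000,
    max_exact: int = 20_000,
) -> dict:
    """Aligned fractions and length-weighted mean block identity.

    Identity per block comes from end-to-end edit-distance alignment of the
    block sequences when the block is small, and from evenly spaced sampled
    windows (anchor-projected) for large blocks.
    """
    total_ref = sum(len(s) for s in ref.values())
    total_qry = sum(len(s) for s in qry.values())
    ref_bp = sum(b.ref_span for b in amap.blocks)
    qry_bp = sum(b.qry_span for b in amap.blocks)
    weights, idents = [], []
    for b in amap.blocks:
        ident = _block_identity(b, ref, qry, window, max_exact)
        if ident is not None:
            b.identity = ident
            weights.append(b.ref_span)
            idents.append(ident)
    mean_ident = (
        float(np.average(idents, weights=weights)) if idents else float("nan")
    )
    return {
        "ref_aligned_fraction": ref_bp / total_ref if total_ref else 0.0,
        "qry_aligned_fraction": qry_bp / total_qry if total_qry else 0.0,
        "ref_unaligned_fraction": 1.0 - (ref_bp / total_ref if total_ref else 0.0),
        "qry_unaligned_fraction": 1.0 - (qry_bp / total_qry if total_qry else 0.0),
        "mean_block_identity": mean_ident,
        "n_blocks": len(amap.blocks),
    }


def _block_identity(b: SyntenyBlock, ref, qry, window: int, max_exact: int) -> float | None:
    rseq = ref[b.ref_chrom]
    qseq = qry[b.qry_chrom]

    def pair_identity(rs: str, qs: str) -> float:
        if b.orient < 0:
            qs = _revcomp(qs)
        d = edlib.align(rs, qs, task="distance")["editDistance"]
        return 1.0 - d / max(len(rs), len(qs))

    if b.ref_span <= max_exact:
        return pair_identity(
            rseq[b.ref_start : b.ref_end], qseq[b.qry_start : b.qry_end]
        )
    # sampled windows, anchored via exact anchor midpoints for orthology
    n = max(3, math.ceil(b.ref_span / 200_000))
    long_anchors = [a for a in b.anchors if a.length >= 50] or b.anchors
    step = max(len(long_anchors) // n, 1)
    vals, wts = [], []
    for a in long_anchors[:: step][:n]:
        mid_r = (a.ref_start + a.ref_end) // 2
        mid_q = (a.qry_start + a.qry_end) // 2
        rs = rseq[mid_r : mid_r + window]
        if b.orient > 0:
            qs = qseq[mid_q : mid_q + window]
        else:
            qs = qseq[max(mid_q - window, 0) : mid_q]
        if len(rs) < 100 or len(qs) < 100:
            continue
        vals.append(pair_identity(rs, qs))
        wts.append(len(rs))
    if not vals:
        return None
    return float(np.average(vals, weights=wts))
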