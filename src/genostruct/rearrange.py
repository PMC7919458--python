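"""Signed permutations, breakpoint counts, inversion calls, DCJ distance,
Dollo polarization onto branches, and chromatin-compartment classification.

The rearrangement count between two genomes is reported as the breakpoint
count of the shared-block signed permutation (adjacencies broken relative
to the reference order, chromosome ends included).  The DCJ distance is
computed from the adjacency graph as d = N - (C + I/2), with N markers,
C cycles and I odd paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .phylo import ANCESTRAL, DERIVED, MISSING, Phylogeny, dollo_assign
from .synteny import AlignmentMap, SyntenyBlock

logger = logging.getLogger(__name__)


@dataclass
class SignedPermutation:
    """Per-chromosome query order of reference-ordered signed block ids."""

    orders: dict[str, list[int]]
    blocks: dict[tuple[str, int], SyntenyBlock] = field(default_factory=dict)
    topology: str = "linear"

    def chromosomes(self) -> list[str]:
        return sorted(self.orders)


@dataclass
class RearrangementCall:
    kind: str  # inversion | unclassified_break
    chrom: str
    start: int
    end: int
    block_ids: tuple[int, ...] = ()
    taxa: tuple[str, ...] = ()
    compartment: str | None = None
    branch: str | None = None


def blocks_to_permutation(amap: AlignmentMap) -> SignedPermutation:
    """Number blocks by reference order per chromosome; read off query order.

    Blocks whose query chromosome differs from their reference chromosome
    (no 1:1 partner) are excluded and logged.
    """
    orders: dict[str, list[int]] = {}
    registry: dict[tuple[str, int], SyntenyBlock] = {}
    for chrom in sorted({b.ref_chrom for b in amap.blocks}):
        blocks = [b for b in amap.blocks if b.ref_chrom == chrom]
        same = [b for b in blocks if b.qry_chrom == chrom]
        dropped = len(blocks) - len(same)
        if dropped:
            logger.warning("%d block(s) on %s map to another chromosome; excluded",
                           dropped, chrom)
        same.sort(key=lambda b: b.ref_start)
        ids = {id(b): i + 1 for i, b in enumerate(same)}
        for b in same:
            registry[(chrom, ids[id(b)])] = b
        by_qry = sorted(same, key=lambda b: b.qry_start)
        orders[chrom] = [ids[id(b)] * b.orient for b in by_qry]
    return SignedPermutation(orders=orders, blocks=registry)


def count_breakpoints(perm: SignedPermutation) -> int:
    """Broken adjacencies vs the identity, chromosome ends included."""
    total = 0
    for order in perm.orders.values():
        n = len(order)
        if n == 0:
            continue
        ext = [0] + list(order) + [n + 1]
        total += sum(1 for x, y in zip(ext, ext[1:]) if y - x != 1)
    return total


def call_inversions(perm: SignedPermutation) -> list[RearrangementCall]:
    """Each maximal run of sign-reversed, order-reversed blocks is one call."""
    calls = []
    for chrom, order in perm.orders.items():
        i = 0
        while i < len(order):
            if order[i] >= 0:
                i += 1
                continue
            j = i
            while j + 1 < len(order) and order[j + 1] < 0 and order[j + 1] == order[j] + 1:
                j += 1
            ids = tuple(sorted(-x for x in order[i : j + 1]))
            members = [perm.blocks[(chrom, bid)] for bid in ids]
            calls.append(
                RearrangementCall(
                    kind="inversion",
                    chrom=chrom,
                    start=min(b.ref_start for b in members),
                    end=max(b.ref_end for b in members),
                    block_ids=ids,
                )
            )
            i = j + 1
    return calls


# --------------------------------------------------------------- DCJ

Chromosome = tuple[tuple[int, ...], bool]  # (signed markers, circular flag)


def _adjacencies(genome: list[Chromosome]):
    """Adjacency set + telomere set over marker extremities.

    Extremity encoding: (m, 0) = tail, (m, 1) = head of marker m; a marker
    traversed as +m contributes tail->head.
    """
    adj: set[frozenset] = set()
    telo: set[tuple[int, int]] = set()
    markers: set[int] = set()
    for chrom, circular in genome:
        if not chrom:
            continue
        ends = []
        for x in chrom:
            m = abs(x)
            if m in markers:
                raise ValueError(f"marker {m} appears more than once")
            markers.add(m)
            left, right = ((m, 0), (m, 1)) if x > 0 else ((m, 1), (m, 0))
            ends.append((left, right))
        for (l1, r1), (l2, r2) in zip(ends, ends[1:]):
            adj.add(frozenset((r1, l2)))
        if circular:
            adj.add(frozenset((ends[-1][1], ends[0][0])))
        else:
            telo.add(ends[0][0])
            telo.add(ends[-1][1])
    return adj, telo, markers


def dcj_distance(genome_a: list[Chromosome], genome_b: list[Chromosome]) -> int:
    """DCJ distance via the adjacency graph: d = N - (C + I/2)."""
    adj_a, _, markers_a = _adjacencies(genome_a)
    adj_b, _, markers_b = _adjacencies(genome_b)
    if markers_a != markers_b:
        raise ValueError("genomes must share the same marker set")
    n = len(markers_a)
    nbr_a: dict = {}
    nbr_b: dict = {}
    for adj, nbr in ((adj_a, nbr_a), (adj_b, nbr_b)):
        for pair in adj:
            u, v = tuple(pair)
            nbr[u] = v
            nbr[v] = u
    vertices = {(m, side) for m in markers_a for side in (0, 1)}
    seen: set = set()
    cycles = 0
    odd_paths = 0
    for v0 in sorted(vertices):
        if v0 in seen:
            continue
        # walk the alternating component containing v0
        component = {v0}
        frontier = [v0]
        while frontier:
            u = frontier.pop()
            for nbr in (nbr_a, nbr_b):
                w = nbr.get(u)
                if w is not None and w not in component:
                    component.add(w)
                    frontier.append(w)
        seen |= component
        if all(u in nbr_a and u in nbr_b for u in component):
            cycles += 1
        elif len(component) % 2 == 1:
            # in the adjacency-graph formulation each extremity contributes
            # one edge, so path parity follows the extremity count
            odd_paths += 1
    assert odd_paths % 2 == 0, "odd paths must pair up for a valid instance"
    return n - cycles - odd_paths // 2


def permutation_to_genome(order: list[int], circular: bool = False) -> list[Chromosome]:
    return [(tuple(order), circular)]


def identity_genome(n: int, circular: bool = False) -> list[Chromosome]:
    return [(tuple(range(1, n + 1)), circular)]


# --------------------------------------------------------- polarization

def polarize_events(matrix: pd.DataFrame, phylogeny: Phylogeny) -> pd.Series:
    """Dollo-assign each event (row) to a branch from its taxon states.

    Matrix entries are 'derived' / 'ancestral' / 'missing'; columns must
    include the outgroup.  Events without a single consistent origin get
    None (ambiguous).  All-missing rows are skipped with a warning.
    """
    if phylogeny.outgroup not in matrix.columns:
        raise ValueError("presence matrix must include the outgroup column")
    out = {}
    for idx, row in matrix.iterrows():
        states = {t: row[t] for t in matrix.columns}
        if all(s == MISSING for s in states.values()):
            logger.warning("event %s has no scored taxa; skipped", idx)
            continue
        out[idx] = dollo_assign(states, phylogeny)
    return pd.Series(out, dtype=object)


def inversion_presence(
    call: RearrangementCall,
    maps: dict[str, AlignmentMap],
    reference: str,
    min_projected: float = 0.5,
) -> dict[str, str]:
    """Score an inversion's orientation state in every taxon.

    ``maps`` are reference->taxon alignment maps.  A taxon is 'derived' when
    the majority of the projected interval lies in reverse-orientation
    blocks, 'ancestral' for forward, 'missing' when less than
    ``min_projected`` of the interval projects.  The reference taxon is
    'ancestral' by construction (calls are made in its coordinates).
    """
    states = {reference: ANCESTRAL}
    length = call.end - call.start
    for taxon, amap in maps.items():
        images = amap.project_interval(call.chrom, call.start, call.end)
        covered = sum(im["covered_ref"] for im in images)
        if covered < min_projected * length:
            states[taxon] = MISSING
            continue
        rev = sum(im["covered_ref"] for im in images if im["orient"] < 0)
        states[taxon] = DERIVED if rev > covered / 2 else ANCESTRAL
    return states


# --------------------------------------------------------- compartments

def classify_compartment(
    call: RearrangementCall, compartments: dict[str, list[tuple[int, int, str]]]
) -> str:
    """Compartment of the call midpoint; boundary-spanning calls are 'het'."""
    if call.chrom not in compartments:
        raise ValueError(f"no compartment annotation for {call.chrom}")
    parts = compartments[call.chrom]
    overlapping = [lab for s, e, lab in parts if s < call.end and call.start < e]
    if len(overlapping) > 1:
        return "het"
    mid = (call.start + call.end) // 2
    for s, e, lab in parts:
        if s <= mid < e:
            return lab
    raise ValueError(f"midpoint {mid} outside annotated {call.chrom}")
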