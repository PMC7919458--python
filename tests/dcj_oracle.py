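"""Independent brute-force DCJ oracle: BFS over the space of genomes
(perfect/partial matchings of marker extremities) under single DCJ moves."""

from __future__ import annotations

import itertools
from collections import deque


def adjacency_state(order, circular: bool) -> frozenset:
    ends = []
    for x in order:
        m = abs(x)
        left, right = ((m, 0), (m, 1)) if x > 0 else ((m, 1), (m, 0))
        ends.append((left, right))
    adj = set()
    for (_, r1), (l2, _) in zip(ends, ends[1:]):
        adj.add(frozenset((r1, l2)))
    if circular and ends:
        adj.add(frozenset((ends[-1][1], ends[0][0])))
    return frozenset(adj)


def bfs_distances(start: frozenset, n: int) -> dict[frozenset, int]:
    """Distance from start to every reachable genome state by BFS."""
    extremities = [(m, s) for m in range(1, n + 1) for s in (0, 1)]

    def neighbors(state):
        adjs = list(state)
        matched = set()
        for a in adjs:
            matched |= set(a)
        telos = [e for e in extremities if e not in matched]
        out = []
        for i, ai in enumerate(adjs):
            a, b = tuple(ai)
            out.append(state - {ai})  # cut into two telomeres
            for j in range(i + 1, len(adjs)):
                c, d = tuple(adjs[j])
                base = state - {ai, adjs[j]}
                out.append(base | {frozenset((a, c)), frozenset((b, d))})
                out.append(base | {frozenset((a, d)), frozenset((b, c))})
            for t in telos:
                base = state - {ai}
                out.append(base | {frozenset((a, t))})
                out.append(base | {frozenset((b, t))})
        for ti, tj in itertools.combinations(telos, 2):
            out.append(state | {frozenset((ti, tj))})
        return out

    dist = {start: 0}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        d = dist[s]
        for nb in neighbors(s):
            if nb not in dist:
                dist[nb] = d + 1
                queue.append(nb)
    return dist


def all_signed_orders(n: int):
    for perm in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            yield [p * s for p, s in zip(perm, signs)]
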