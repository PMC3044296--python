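"""Independent oracles for the test suite.

A genome (possibly with circular chromosomes, which arise as intermediates
of double-cut-and-join scenarios) is represented as a partial matching on
the 2n gene extremities: the set of its adjacencies.  One DCJ operation
replaces at most two adjacencies/telomeres by a rejoined pair, so the
operation graph over all matchings supports brute-force breadth-first
search for true rearrangement distances, independent of the package's
cycle-counting formula.
"""

from __future__ import annotations

import itertools
from collections import deque

from pathgroups import Genome
from pathgroups.breakpoint import adjacency_map


def adjset(genome: Genome) -> frozenset:
    amap = adjacency_map(genome)
    return frozenset(
        frozenset((v, amap[v]))
        for v in range(1, 2 * genome.n + 1)
        if amap[v] and v < amap[v]
    )


def neighbors(state: frozenset, n: int) -> set[frozenset]:
    """All matchings one DCJ away: swap partners of two adjacencies, attach
    a telomere, cut an adjacency, or join two telomeres.  Circular products
    are allowed (they are legitimate DCJ intermediates)."""
    adjs = [tuple(sorted(a)) for a in state]
    covered = {v for a in state for v in a}
    telos = [v for v in range(1, 2 * n + 1) if v not in covered]
    out: set[frozenset] = set()
    for (a, b), (c, d) in itertools.combinations(adjs, 2):
        rest = state - {frozenset((a, b)), frozenset((c, d))}
        out.add(rest | {frozenset((a, c)), frozenset((b, d))})
        out.add(rest | {frozenset((a, d)), frozenset((b, c))})
    for a, b in adjs:
        rest = state - {frozenset((a, b))}
        for t in telos:
            out.add(rest | {frozenset((a, t))})
            out.add(rest | {frozenset((b, t))})
        out.add(rest)  # cut into two telomeres
    for t1, t2 in itertools.combinations(telos, 2):
        out.add(state | {frozenset((t1, t2))})
    out.discard(state)
    return out


def bfs_distances(source: frozenset, n: int) -> dict[frozenset, int]:
    """True DCJ distance from ``source`` to every reachable matching."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        s = queue.popleft()
        d = dist[s] + 1
        for t in neighbors(s, n):
            if t not in dist:
                dist[t] = d
                queue.append(t)
    return dist


def all_states(n: int) -> list[frozenset]:
    """Every partial matching on the 2n extremities."""
    out: list[frozenset] = []

    def rec(rem: tuple[int, ...], acc: frozenset) -> None:
        if not rem:
            out.append(acc)
            return
        v, rest = rem[0], rem[1:]
        rec(rest, acc)  # v stays a telomere
        for i, w in enumerate(rest):
            rec(rest[:i] + rest[i + 1 :], acc | {frozenset((v, w))})

    rec(tuple(range(1, 2 * n + 1)), frozenset())
    return out


def is_linear(state: frozenset, n: int) -> bool:
    """True when no chromosome of the matching is circular."""
    adj: dict[int, int] = {}
    for a in state:
        x, y = tuple(a)
        adj[x] = y
        adj[y] = x
    seen: set[int] = set()
    for g in range(1, n + 1):
        v = 2 * g - 1
        if v in seen:
            continue
        comp: set[int] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            mate = u + 1 if u % 2 else u - 1
            stack.append(mate)
            w = adj.get(u)
            if w is not None:
                stack.append(w)
        seen |= comp
        if all(u in adj for u in comp):
            return False
    return True


def num_chromosomes(state: frozenset, n: int) -> int:
    """For a linear matching, components = n - |adjacencies|."""
    return n - len(state)


def state_to_genome(state: frozenset, n: int, name: str = "S") -> Genome:
    """Chromosome lists of a linear matching."""
    adj: dict[int, int] = {}
    for a in state:
        x, y = tuple(a)
        adj[x] = y
        adj[y] = x
    telos = sorted(v for v in range(1, 2 * n + 1) if v not in adj)
    used: set[int] = set()
    chroms = []
    for t in telos:
        if t in used:
            continue
        genes = []
        v = t
        while True:
            g = (v + 1) // 2
            genes.append(g if v % 2 else -g)
            exit_v = v + 1 if v % 2 else v - 1
            used.add(v)
            used.add(exit_v)
            nxt = adj.get(exit_v)
            if nxt is None:
                break
            v = nxt
        chroms.append(genes)
    if len(used) != 2 * n:
        raise ValueError("matching contains a circular chromosome")
    return Genome(name, chroms, n)


def linear_states(n: int, max_chromosomes: int | None = None) -> list[frozenset]:
    states = [s for s in all_states(n) if is_linear(s, n)]
    if max_chromosomes is not None:
        states = [s for s in states if num_chromosomes(s, n) <= max_chromosomes]
    return states


def brute_median_total(g1: Genome, g2: Genome, g3: Genome) -> int:
    """Exhaustive optimal median total: minimum over every linear gene
    order of the summed true (BFS) distances to the three inputs."""
    n = g1.n
    dists = [bfs_distances(adjset(g), n) for g in (g1, g2, g3)]
    best = None
    for s in linear_states(n):
        tot = sum(d[s] for d in dists)
        if best is None or tot < best:
            best = tot
    return best
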