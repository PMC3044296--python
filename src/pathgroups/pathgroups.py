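"""The pathgroup data structure and the greedy cycle-maximising solver.

The ancestral-reconstruction objective — minimise the summed DCJ distance
from an ancestor to its tree neighbours — is equivalent to maximising the
aggregate number of alternating cycles in the breakpoint graphs between
the ancestor and those neighbours.  The ancestor's adjacencies are the
*red* edges, identical in every breakpoint graph it takes part in; the
neighbours contribute the other colour.

The solver maintains, for every tree edge, a partially built breakpoint
graph decomposed into *paths* (connected parts of future cycles; a given
genome's single adjacency is already a path).  A *pathgroup* is the bundle
of paths — one per incident tree branch — currently ending at one
ancestral vertex; it is the unit of greedy choice.  A *fragment* is a
maximal run of genes already joined by red edges; fragments grow into the
ancestor's chromosomes and are never allowed to close into circles.

Each greedy step picks the pathgroup from which adding one red edge
creates the most cycles, breaking ties by a one- or two-step look-ahead
(priority schemes ``basic``/``refined``/``lookahead2`` with 7, 55 and 165
levels).  Adding the red edge deletes the chosen pathgroup and its partner
at the other end of the edge, so the number of pathgroups falls by exactly
two per step, and only a bounded neighbourhood (at most four *secondary*
groups whose paths changed, at most eight *tertiary* partners of those,
and the two groups at the ends of the extended fragment) needs its
priority recomputed — which is what makes the whole solve linear in the
number of genes.

Internally one vertex-side endpoint of a path is encoded as the integer
``vertex << 1 | side`` where ``side`` selects which of the tree edge's two
nodes still has to contribute an edge at that vertex.  ``far`` maps every
live endpoint to the endpoint at the other end of its path (or to a cap
marker); a vertex with neither side decided is an isolated path whose two
endpoints are its own two sides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .breakpoint import adjacency_map, dcj_distance
from .genomes import GeneContentError, Genome, PhylogenyTree, star_tree

#: far-value marker for a path end sitting on a cap (telomere of a given genome)
CAPK = -1

_MISS = object()

SCHEMES = ("basic", "refined", "lookahead2")

#: net potential-cycle changes are clamped to this symmetric range; the up to
#: four secondary pathgroups dominate the net change, so wider swings are
#: binned at the extremes to keep the priority table finite.
NET_DELTA_CLAMP = 4


def priority_levels(scheme: str) -> list[tuple[int, ...]]:
    """All priority classes of a scheme, in decreasing priority order.

    A class is a tuple compared lexicographically, larger first:

    * ``basic``      — ``(cycles, best_next)``; the 3-cycle class is not
      sub-classified: 1 + 2*3 = 7 levels.
    * ``refined``    — adds the clamped net change in potential cycles over
      the affected pathgroups: 1 + 2*3*9 = 55 levels.
    * ``lookahead2`` — sub-classifies every refined class by the best cycle
      count achievable two steps ahead (1..3): 55*3 = 165 levels.
    """
    if scheme == "basic":
        levels = [(3, 0)]
        levels += [(c, b) for c in (2, 1) for b in (3, 2, 1)]
        return levels
    if scheme == "refined":
        levels = [(3, 0, 0)]
        levels += [
            (c, b, d)
            for c in (2, 1)
            for b in (3, 2, 1)
            for d in range(NET_DELTA_CLAMP, -NET_DELTA_CLAMP - 1, -1)
        ]
        return levels
    if scheme == "lookahead2":
        levels = [(3, 0, 0, s) for s in (3, 2, 1)]
        levels += [
            (c, b, d, s)
            for c in (2, 1)
            for b in (3, 2, 1)
            for d in range(NET_DELTA_CLAMP, -NET_DELTA_CLAMP - 1, -1)
            for s in (3, 2, 1)
        ]
        return levels
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


class PathGraph:
    """The evolving breakpoint graph of one tree edge.

    ``far`` maps live path-endpoint keys to the opposite endpoint of their
    path (or ``CAPK``).  ``slot[s][v]`` records the edge contributed at
    vertex ``v`` by the tree node on side ``s`` once decided.
    """

    __slots__ = ("idx", "u", "v", "far", "slot", "cycles")

    def __init__(self, idx: int, u: str, v: str):
        self.idx = idx
        self.u = u
        self.v = v
        self.far: dict[int, int] = {}
        self.slot: tuple[dict[int, int], dict[int, int]] = ({}, {})
        self.cycles = 0

    def side_of(self, node: str) -> int:
        if node == self.u:
            return 0
        if node == self.v:
            return 1
        raise KeyError(node)


@dataclass(frozen=True)
class StepReport:
    """What one greedy step did."""

    node: str
    anchor: int
    target: int
    cycles: int
    n_secondary: int
    n_tertiary: int


@dataclass(frozen=True)
class PathGroupView:
    """Read-only snapshot of one pathgroup (for inspection and tests)."""

    node: str
    anchor: int
    #: one entry per incident branch: (vertex, node) for a live far end,
    #: "T" for a cap-bounded path
    far_ends: tuple
    priority: tuple | None
    target: int | None


@dataclass(frozen=True)
class MedianResult:
    ancestor: Genome
    distances: tuple[int, int, int]
    total: int


class ReconstructionState:
    """Pathgroups, fragments and priority buckets for every ancestor of a tree.

    The median problem is the special case of a 3-leaf star tree; the same
    structure handles any unrooted binary tree, in which case the red edge
    an ancestor fixes on a branch towards another ancestor immediately
    becomes given ("blue") material in that neighbour's pathgroups, because
    the two ancestors share the branch's path graph.
    """

    def __init__(
        self,
        tree: PhylogenyTree,
        leaf_genomes: Mapping[str, Genome],
        scheme: str = "refined",
    ):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
        if set(leaf_genomes) != set(tree.leaves):
            raise GeneContentError(
                f"leaf genomes {sorted(leaf_genomes)} do not match tree leaves "
                f"{sorted(tree.leaves)}"
            )
        sizes = {g.n for g in leaf_genomes.values()}
        if len(sizes) != 1:
            raise GeneContentError(f"leaf genomes carry different universes: {sorted(sizes)}")
        self.tree = tree
        self.scheme = scheme
        self.n = sizes.pop()
        n2 = 2 * self.n
        self.ancestors: tuple[str, ...] = tree.internal_nodes

        # one path graph per tree edge
        self.graphs: list[PathGraph] = []
        by_edge: dict[tuple[str, str], PathGraph] = {}
        for idx, (u, v) in enumerate(tree.edges):
            g = PathGraph(idx, u, v)
            self.graphs.append(g)
            by_edge[(u, v)] = g
            for side, node in ((0, u), (1, v)):
                if node in leaf_genomes:
                    amap = adjacency_map(leaf_genomes[node])
                    other = 1 - side
                    for w in range(1, n2 + 1):
                        p = amap[w]
                        g.slot[side][w] = p
                        key = (w << 1) | other
                        g.far[key] = CAPK if p == 0 else ((p << 1) | other)
            if u not in leaf_genomes and v not in leaf_genomes:
                for w in range(1, n2 + 1):
                    g.far[(w << 1)] = (w << 1) | 1
                    g.far[(w << 1) | 1] = w << 1

        # incident (graph, side-of-ancestor) triples, in sorted-neighbour order
        self.incident: dict[str, list[tuple[PathGraph, int]]] = {}
        for a in self.ancestors:
            inc = []
            for nbr in tree.neighbors(a):
                g = by_edge[tuple(sorted((a, nbr)))]
                inc.append((g, g.side_of(a)))
            self.incident[a] = inc

        # fragments (every gene starts as its own), red edges, live anchors
        self.other_end: dict[str, dict[int, int]] = {}
        self.red: dict[str, dict[int, int]] = {}
        self.free: dict[str, set[int]] = {}
        for a in self.ancestors:
            oe = {}
            for gene in range(1, self.n + 1):
                oe[2 * gene - 1] = 2 * gene
                oe[2 * gene] = 2 * gene - 1
            self.other_end[a] = oe
            self.red[a] = {}
            self.free[a] = set(range(1, n2 + 1))

        self.pathgroup_count = n2 * len(self.ancestors)
        self.initial_pathgroups = self.pathgroup_count
        self.steps_taken = 0
        self.cycles_made = 0
        self.max_secondary = 0
        self.max_tertiary = 0

        self.level_order = priority_levels(scheme)
        self.buckets: dict[tuple, dict[tuple[str, int], None]] = {}
        self.pri: dict[tuple[str, int], tuple[tuple, int]] = {}
        for a in self.ancestors:
            for x in range(1, n2 + 1):
                self._set_priority(a, x, self._priority(a, x))

    # -- low-level lookups ------------------------------------------------

    def _far_get(self, g: PathGraph, key: int, over: dict | None):
        if over is not None:
            val = over.get((g.idx, key), _MISS)
            if val is not _MISS:
                return val
        return g.far.get(key)

    def _oe(self, node: str, v: int, frag: dict | None):
        if frag is not None:
            r = frag.get((node, v), _MISS)
            if r is not _MISS:
                return r
        return self.other_end[node][v]

    def _candidates(self, node: str, x: int, over: dict | None = None, frag: dict | None = None):
        """Candidate red-edge targets ``e`` of the pathgroup at ``x`` mapped
        to the number of cycles edge ``x-e`` would close.  Targets that would
        bend the fragment containing ``x`` into a circular chromosome, and
        cap-bounded path ends, are excluded."""
        counts: dict[int, int] = {}
        for g, s in self.incident[node]:
            f = self._far_get(g, (x << 1) | s, over)
            if f is None or f == CAPK:
                continue
            if (f & 1) != s:
                continue
            fv = f >> 1
            counts[fv] = counts.get(fv, 0) + 1
        if counts:
            forb = self._oe(node, x, frag)
            if forb in counts:
                del counts[forb]
        return counts

    def _cycles_of(self, node: str, x: int, over: dict | None = None, frag: dict | None = None) -> int:
        counts = self._candidates(node, x, over, frag)
        return max(counts.values()) if counts else 0

    # -- simulated application (for look-ahead) ---------------------------

    def _simulate_edge(self, node: str, x: int, e: int, over: dict | None = None, frag: dict | None = None):
        """Overlay describing the state after red edge ``x-e`` at ``node``,
        without mutating anything.  Returns (far-overlay, fragment-overlay,
        secondary pathgroups, cycles closed)."""
        over2 = dict(over) if over else {}
        frag2 = dict(frag) if frag else {}
        sec: dict[tuple[str, int], None] = {}
        closed = 0
        for g, s in self.incident[node]:
            kx = (x << 1) | s
            ke = (e << 1) | s
            fx = self._far_get(g, kx, over2)
            fe = self._far_get(g, ke, over2)
            gi = g.idx
            over2[(gi, kx)] = None
            over2[(gi, ke)] = None
            if fx == ke:
                closed += 1
                continue
            if fx != CAPK:
                over2[(gi, fx)] = fe
                owner = g.u if (fx & 1) == 0 else g.v
                if owner in self.free:
                    sec[(owner, fx >> 1)] = None
            if fe != CAPK:
                over2[(gi, fe)] = fx
                owner = g.u if (fe & 1) == 0 else g.v
                if owner in self.free:
                    sec[(owner, fe >> 1)] = None
        px = self._oe(node, x, frag2)
        pe = self._oe(node, e, frag2)
        frag2[(node, x)] = None
        frag2[(node, e)] = None
        frag2[(node, px)] = pe
        frag2[(node, pe)] = px
        return over2, frag2, list(sec), closed

    def _net_delta(self, node, x, e, sec, over, frag) -> int:
        """Net change in potential cycles over the pathgroups affected by
        red edge ``x-e``: the secondary groups plus the two groups at the
        extended fragment's endpoints.  (Tertiary groups keep their paths
        and fragment constraints, so their potential-cycle count is
        invariant and contributes nothing.)"""
        affected = dict.fromkeys(sec)
        affected[(node, self._oe(node, x, None))] = None
        affected[(node, self._oe(node, e, None))] = None
        affected.pop((node, x), None)
        affected.pop((node, e), None)
        delta = 0
        for b, w in affected:
            delta += self._cycles_of(b, w, over, frag) - self._cycles_of(b, w)
        return max(-NET_DELTA_CLAMP, min(NET_DELTA_CLAMP, delta))

    def _second_step(self, sec_counts, bn_raw, over, frag) -> int:
        """Best cycle count achievable two steps ahead: process the best
        secondary group's best edge (in simulation) and look at the groups
        that sets up."""
        if bn_raw <= 0:
            return 1
        ss = 0
        for (b, w), counts in sec_counts:
            if not counts or max(counts.values()) != bn_raw:
                continue
            e2 = min(v for v, c in counts.items() if c == bn_raw)
            o2, f2, sec2, _ = self._simulate_edge(b, w, e2, over, frag)
            for b2, w2 in sec2:
                v2 = self._cycles_of(b2, w2, o2, f2)
                if v2 > ss:
                    ss = v2
            if ss == 3:
                break
        return min(3, max(1, ss))

    # -- priorities --------------------------------------------------------

    def _priority(self, node: str, x: int):
        """Priority key and chosen red-edge target of the pathgroup at
        ``x``, or ``None`` when no red edge is addable (all far ends are
        caps or missing, or every completion closes a circle)."""
        counts = self._candidates(node, x)
        if not counts:
            return None
        cmax = max(counts.values())
        cand = sorted(e for e, c in counts.items() if c == cmax)
        scheme = self.scheme
        if cmax == 3:
            # every path closes: no secondary group is set up
            if scheme == "basic":
                return (3, 0), cand[0]
            if scheme == "refined":
                return (3, 0, 0), cand[0]
            return (3, 0, 0, 1), cand[0]
        best_key = None
        best_e = None
        for e in cand:
            over, frag, sec, _closed = self._simulate_edge(node, x, e)
            sec_counts = [(bw, self._candidates(bw[0], bw[1], over, frag)) for bw in sec]
            bn_raw = 0
            for _, c2 in sec_counts:
                if c2:
                    m = max(c2.values())
                    if m > bn_raw:
                        bn_raw = m
            bn = min(3, max(1, bn_raw))
            if scheme == "basic":
                key: tuple = (cmax, bn)
            else:
                nd = self._net_delta(node, x, e, sec, over, frag)
                if scheme == "refined":
                    key = (cmax, bn, nd)
                else:
                    ss = self._second_step(sec_counts, bn_raw, over, frag)
                    key = (cmax, bn, nd, ss)
            if best_key is None or key > best_key:
                best_key, best_e = key, e
        return best_key, best_e

    def priority_of(self, node: str, x: int):
        """Current (priority key, chosen target) of a live pathgroup, or None."""
        return self.pri.get((node, x))

    def pathgroup(self, node: str, x: int) -> PathGroupView:
        ends = []
        for g, s in self.incident[node]:
            f = g.far.get((x << 1) | s)
            if f is None:
                ends.append(None)
            elif f == CAPK:
                ends.append("T")
            else:
                ends.append((f >> 1, g.u if (f & 1) == 0 else g.v))
        entry = self.pri.get((node, x))
        key, target = entry if entry else (None, None)
        return PathGroupView(node, x, tuple(ends), key, target)

    def _set_priority(self, node: str, x: int, p) -> None:
        old = self.pri.get((node, x))
        if old is not None:
            bucket = self.buckets.get(old[0])
            if bucket is not None:
                bucket.pop((node, x), None)
        if p is None:
            self.pri.pop((node, x), None)
        else:
            self.pri[(node, x)] = p
            self.buckets.setdefault(p[0], {})[(node, x)] = None

    def _pop_best(self):
        for level in self.level_order:
            bucket = self.buckets.get(level)
            if bucket:
                return next(iter(bucket))
        return None

    # -- the greedy step ---------------------------------------------------

    def apply_step(self, node: str, x: int) -> StepReport:
        """Add the chosen red edge of the pathgroup at ``x``: close cycles,
        concatenate leftover paths, join fragments, delete the group and its
        partner, and refresh the priorities of the bounded neighbourhood."""
        entry = self.pri.get((node, x))
        if entry is None:
            raise ValueError(f"pathgroup {node}:{x} has no priority")
        _key, e = entry

        sec: dict[tuple[str, int], None] = {}
        closed = 0
        for g, s in self.incident[node]:
            kx = (x << 1) | s
            ke = (e << 1) | s
            fx = g.far.pop(kx)
            fe = g.far.pop(ke)
            g.slot[s][x] = e
            g.slot[s][e] = x
            if fx == ke:
                g.cycles += 1
                closed += 1
                continue
            if fx != CAPK:
                g.far[fx] = fe
                owner = g.u if (fx & 1) == 0 else g.v
                if owner in self.free:
                    sec[(owner, fx >> 1)] = None
            if fe != CAPK:
                g.far[fe] = fx
                owner = g.u if (fe & 1) == 0 else g.v
                if owner in self.free:
                    sec[(owner, fe >> 1)] = None

        oe = self.other_end[node]
        px = oe.pop(x)
        pe = oe.pop(e)
        oe[px] = pe
        oe[pe] = px
        self.red[node][x] = e
        self.red[node][e] = x

        for anchor in (x, e):
            self._set_priority(node, anchor, None)
            self.free[node].discard(anchor)
        self.steps_taken += 1
        self.cycles_made += closed
        self.pathgroup_count -= 2
        assert self.pathgroup_count == sum(len(f) for f in self.free.values()), (
            "pathgroup conservation violated: count must fall by exactly 2 per step"
        )

        # tertiary groups: partners of the secondary ones
        tert: dict[tuple[str, int], None] = {}
        for b, w in sec:
            for g2, s2 in self.incident[b]:
                f = g2.far.get((w << 1) | s2)
                if f is None or f == CAPK:
                    continue
                owner = g2.u if (f & 1) == 0 else g2.v
                bw2 = (owner, f >> 1)
                if owner in self.free and bw2 not in sec:
                    tert[bw2] = None

        recompute = dict(sec)
        recompute.update(tert)
        recompute[(node, px)] = None
        recompute[(node, pe)] = None
        recompute.pop((node, x), None)
        recompute.pop((node, e), None)
        for b, w in recompute:
            self._set_priority(b, w, self._priority(b, w))

        if len(sec) > self.max_secondary:
            self.max_secondary = len(sec)
        if len(tert) > self.max_tertiary:
            self.max_tertiary = len(tert)
        return StepReport(node, x, e, closed, len(sec), len(tert))

    def run(self) -> "ReconstructionState":
        """Greedy main loop: process the globally best pathgroup until no
        pathgroup anywhere has a priority."""
        while True:
            item = self._pop_best()
            if item is None:
                break
            self.apply_step(*item)
        return self

    @property
    def live_pathgroups(self) -> int:
        return sum(len(f) for f in self.free.values())

    # -- output --------------------------------------------------------------

    def assemble(self, node: str, name: str | None = None) -> Genome:
        """Build the ancestor at ``node`` from its red fragments; each
        surviving fragment becomes one linear chromosome."""
        red = self.red[node]
        oe = self.other_end[node]
        chroms = []
        seen: set[int] = set()
        for start in sorted(oe):
            if start in seen:
                continue
            genes = []
            v = start
            while True:
                g = (v + 1) // 2
                if v & 1:  # tail first: forward orientation
                    genes.append(g)
                    exit_v = 2 * g
                else:
                    genes.append(-g)
                    exit_v = 2 * g - 1
                seen.add(v)
                seen.add(exit_v)
                nxt = red.get(exit_v)
                if nxt is None:
                    break
                v = nxt
            chroms.append(genes)
        return Genome(name or node, chroms, self.n)


# ---------------------------------------------------------------------------
# Median front end

#: alias kept for the median-specific entry points below
MedianState = ReconstructionState


def init_median(g1: Genome, g2: Genome, g3: Genome, scheme: str = "refined") -> ReconstructionState:
    """Pathgroup state for the median of three genomes (a 3-leaf star)."""
    genomes = [g1, g2, g3]
    names = [g.name for g in genomes]
    if len(set(names)) < 3:
        names = ["G1", "G2", "G3"]
        genomes = [g.renamed(nm) for g, nm in zip(genomes, names)]
    center = "M1"
    while center in names:
        center += "_"
    state = ReconstructionState(
        star_tree(names, center=center),
        dict(zip(names, genomes)),
        scheme=scheme,
    )
    state.median_inputs = tuple(genomes)  # type: ignore[attr-defined]
    return state


def make_cycles(state: ReconstructionState) -> MedianResult:
    """Run the greedy to completion on a median state and assemble the result."""
    state.run()
    center = state.ancestors[0]
    ancestor = state.assemble(center, name="median")
    inputs = getattr(state, "median_inputs", None)
    if inputs is None:
        raise ValueError("make_cycles expects a state built by init_median")
    dists = tuple(dcj_distance(ancestor, g).d for g in inputs)
    return MedianResult(ancestor, dists, sum(dists))


def solve_median(
    g1: Genome, g2: Genome, g3: Genome, scheme: str = "refined"
) -> MedianResult:
    """Convenience wrapper: initialise and run the median solver."""
    return make_cycles(init_median(g1, g2, g3, scheme=scheme))
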