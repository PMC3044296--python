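"""Breakpoint graphs and the DCJ (double-cut-and-join) distance.

Every gene ``g`` contributes two extremities, a tail and a head, encoded as
integers ``2g - 1`` and ``2g``.  A positive gene reads tail-then-head, a
negative one head-then-tail.  Consecutive extremities of neighbouring genes
on a chromosome form *adjacencies*; the first and last extremity of each
chromosome are *telomeres*.

For two genomes on the same ``n`` genes, the breakpoint graph colours one
genome's adjacencies blue and the other's red.  Telomeres are capped:
each becomes an adjacency with an artificial cap vertex (T1 on the blue
side, T2 on the red side); a path between two T1 caps is closed by a red
edge, one between two T2 caps by a blue edge, and a mixed T1/T2 path has
its caps collapsed into a single vertex.  After capping, every vertex has
exactly one blue and one red edge, and the graph decomposes uniquely into
alternating cycles.  With ``n'`` the number of blue edges and ``kappa``
the number of cycles, the DCJ distance is

    d = n' - kappa

which counts the minimum number of double-cut-and-join operations
(inversions, reciprocal translocations, fusions, fissions, and
excisions/reintegrations through circular intermediates) transforming one
genome into the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .genomes import GeneContentError, Genome, PhylogenyTree

#: sentinel partner for a telomeric extremity (cap)
CAP = 0


def gene_tail(g: int) -> int:
    return 2 * g - 1


def gene_head(g: int) -> int:
    return 2 * g


def vertex_gene(v: int) -> int:
    """Gene id owning extremity ``v``."""
    return (v + 1) // 2


def vertex_label(v: int) -> str:
    g = vertex_gene(v)
    return f"{g}{'t' if v % 2 else 'h'}"


def gene_extremities(g: int) -> tuple[int, int]:
    """(entry, exit) extremities of a signed gene read left to right."""
    if g > 0:
        return gene_tail(g), gene_head(g)
    return gene_head(-g), gene_tail(-g)


def adjacency_map(genome: Genome) -> list[int]:
    """Partner extremity of every vertex, ``CAP`` for telomeres.

    Returned as a list indexed ``1..2n`` (index 0 unused).
    """
    amap = [CAP] * (2 * genome.n + 1)
    for chrom in genome.chromosomes:
        prev_exit = None
        for g in chrom:
            entry, exit_ = gene_extremities(g)
            if prev_exit is not None:
                amap[prev_exit] = entry
                amap[entry] = prev_exit
            prev_exit = exit_
    return amap


@dataclass(frozen=True)
class AdjacencySet:
    """The adjacencies and telomeres of one genome."""

    adjacencies: frozenset[frozenset[int]]
    telomeres: frozenset[int]


def build_adjacencies(genome: Genome) -> AdjacencySet:
    """Adjacency set of a genome: ``n - c`` adjacencies and ``2c`` telomeres
    for ``n`` genes in ``c`` chromosomes."""
    amap = adjacency_map(genome)
    adjs = set()
    telo = set()
    for v in range(1, 2 * genome.n + 1):
        w = amap[v]
        if w == CAP:
            telo.add(v)
        else:
            adjs.add(frozenset((v, w)))
    return AdjacencySet(frozenset(adjs), frozenset(telo))


@dataclass(frozen=True)
class DistanceResult:
    """DCJ distance ``d = n_prime - kappa`` plus the two graph statistics."""

    d: int
    n_prime: int
    kappa: int


def dcj_distance(g1: Genome, g2: Genome) -> DistanceResult:
    """DCJ distance between two genomes on the same gene universe.

    ``g1`` provides the blue edges (so ``n_prime`` counts ``g1``'s capped
    adjacencies plus blue closing edges), ``g2`` the red ones.  The value
    ``d`` is symmetric in the two genomes.
    """
    if g1.n != g2.n:
        raise GeneContentError(
            f"gene universes differ: {g1.name!r} has n={g1.n}, {g2.name!r} has n={g2.n}"
        )
    n = g1.n
    blue = adjacency_map(g1)
    red = adjacency_map(g2)
    size = 2 * n + 1
    visited = bytearray(size)

    cycles = 0
    p11 = p22 = p12 = 0  # paths by the colours of their two cap ends

    # Trace every capped path once, starting from a telomere of either colour.
    for v in range(1, size):
        if visited[v]:
            continue
        if blue[v] != CAP and red[v] != CAP:
            continue
        # cap colour at the starting end: blue telomere -> T1, red -> T2
        start_cap = 1 if blue[v] == CAP else 2
        colour = 2 if start_cap == 1 else 1  # next edge colour to follow
        cur = v
        visited[cur] = 1
        while True:
            nxt = blue[cur] if colour == 1 else red[cur]
            if nxt == CAP:
                end_cap = colour
                break
            cur = nxt
            visited[cur] = 1
            colour = 3 - colour
        pair = (start_cap, end_cap)
        if pair == (1, 1):
            p11 += 1
        elif pair == (2, 2):
            p22 += 1
        else:
            p12 += 1

    # Remaining unvisited vertices lie on proper alternating cycles.
    for v in range(1, size):
        if visited[v]:
            continue
        cycles += 1
        cur = v
        colour = 1
        while True:
            visited[cur] = 1
            cur = blue[cur] if colour == 1 else red[cur]
            colour = 3 - colour
            if cur == v and colour == 1:
                break

    c1 = g1.num_chromosomes
    # blue edges: internal adjacencies + telomere caps + closing edges of
    # paths whose both ends carry red-side caps
    n_prime = (n - c1) + 2 * c1 + p22
    kappa = cycles + p11 + p22 + p12
    return DistanceResult(n_prime - kappa, n_prime, kappa)


def tree_length(tree: PhylogenyTree, genomes_at_nodes: Mapping[str, Genome]) -> int:
    """Sum of DCJ distances over all tree edges."""
    total = 0
    for u, v in tree.edges:
        if u not in genomes_at_nodes or v not in genomes_at_nodes:
            missing = u if u not in genomes_at_nodes else v
            raise GeneContentError(f"no genome assigned to tree node {missing!r}")
        total += dcj_distance(genomes_at_nodes[u], genomes_at_nodes[v]).d
    return total
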