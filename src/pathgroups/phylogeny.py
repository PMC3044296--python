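"""Small phylogeny: simultaneous multi-ancestor reconstruction and
median-based iterative improvement.

Given leaf genomes on a fixed unrooted binary tree, the single-pass solver
runs the greedy over the union of all ancestors' pathgroups: whichever
pathgroup anywhere in the tree currently has the highest priority is
processed next.  A red edge fixed at one ancestor is instantly visible as
given material to the neighbouring ancestors because adjacent ancestors
share each branch's path graph.  Pathgroups next to two given genomes
naturally rise to the top first, so the reconstruction spreads inward from
the leaves.

The refinement pass revisits each ancestor in seeded random order and
re-solves the median of its three current neighbours, accepting the new
genome whenever its local objective (the sum of the three incident branch
distances) is *no worse* than before.  Accepting equal-cost moves is the
annealing ingredient that lets the search drift out of shallow local
minima; there is no temperature schedule.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping

from .breakpoint import dcj_distance, tree_length
from .genomes import Genome, PhylogenyTree
from .pathgroups import ReconstructionState, init_median, make_cycles


@dataclass(frozen=True)
class PhylogenyResult:
    ancestors: dict[str, Genome]
    total: int
    state: ReconstructionState


@dataclass(frozen=True)
class RefinementTrace:
    """One median proposal during refinement."""

    iteration: int
    node: str
    old_local: int
    new_local: int
    accepted: bool
    total: int


def solve_small_phylogeny(
    tree: PhylogenyTree,
    leaf_genomes: Mapping[str, Genome],
    scheme: str = "refined",
) -> PhylogenyResult:
    """Single-pass greedy reconstruction of every ancestral genome.

    Returns the ancestors, the summed DCJ length over all ``2N - 3``
    branches, and the final solver state (useful for instrumentation).
    """
    state = ReconstructionState(tree, leaf_genomes, scheme=scheme).run()
    ancestors = {a: state.assemble(a) for a in state.ancestors}
    total = tree_length(tree, {**dict(leaf_genomes), **ancestors})
    return PhylogenyResult(ancestors, total, state)


def _local_objective(genome: Genome, neighbours: list[Genome]) -> int:
    return sum(dcj_distance(genome, g).d for g in neighbours)


def refine_by_medians(
    tree: PhylogenyTree,
    leaf_genomes: Mapping[str, Genome],
    initial_ancestors: Mapping[str, Genome],
    iterations: int = 50,
    seed: int = 0,
    scheme: str = "refined",
) -> tuple[dict[str, Genome], list[RefinementTrace]]:
    """Iterative local improvement: re-median each ancestor, accept if the
    local objective does not increase, for a fixed number of sweeps.

    The total tree length is non-increasing across accepted proposals; the
    trace records every proposal.
    """
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    rng = random.Random(seed)
    ancestors = {a: g.renamed(a) for a, g in initial_ancestors.items()}
    if set(ancestors) != set(tree.internal_nodes):
        raise ValueError("initial ancestors must cover every internal node")

    def current(node: str) -> Genome:
        return leaf_genomes[node] if node in leaf_genomes else ancestors[node]

    total = tree_length(tree, {**dict(leaf_genomes), **ancestors})
    trace: list[RefinementTrace] = []
    nodes = list(tree.internal_nodes)
    for sweep in range(iterations):
        order = rng.sample(nodes, len(nodes))
        for node in order:
            nbrs = [current(m) for m in tree.neighbors(node)]
            proposal = make_cycles(init_median(*nbrs, scheme=scheme))
            old_local = _local_objective(ancestors[node], nbrs)
            new_local = proposal.total
            accepted = new_local <= old_local
            if accepted:
                ancestors[node] = proposal.ancestor.renamed(node)
                total += new_local - old_local
            trace.append(
                RefinementTrace(sweep, node, old_local, new_local, accepted, total)
            )
    return ancestors, trace


def random_initial_ancestors(
    tree: PhylogenyTree,
    leaf_genomes: Mapping[str, Genome],
    seed: int = 0,
    chromosomes: int | None = None,
) -> dict[str, Genome]:
    """Independent uniform random signed gene orders for every ancestor.

    ``chromosomes`` defaults to 10 (or ``n`` when the universe is smaller),
    matching the usual multichromosomal study setup.
    """
    from .simulate import random_genome  # deferred: avoids an import cycle

    n = next(iter(leaf_genomes.values())).n
    c = chromosomes if chromosomes is not None else min(10, n)
    rng = random.Random(seed)
    return {
        a: random_genome(n, c, rng, name=a) for a in tree.internal_nodes
    }
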