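"""Random rearrangement simulation and the d/tau accuracy harness.

Trees are generated from a random multichromosomal ancestor (10
chromosomes by default) placed at an internal node; every branch then
receives a fixed number ``tau`` of rearrangement operations — 90%
chromosomal inversions at independently chosen breakpoints and 10%
reciprocal translocations by default.  Hiding the simulated ancestors and
reconstructing them measures accuracy as ``d / tau``: the reconstructed
total tree length over the number of operations actually performed.  A
ratio near 1 means the reconstruction recovers scenarios as short as the
true one.
"""

from __future__ import annotations

import random
import statistics
from dataclasses import dataclass, field, replace
from typing import Sequence

from .breakpoint import tree_length
from .genomes import Genome, PhylogenyTree
from .phylogeny import refine_by_medians, solve_small_phylogeny


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated phylogeny.

    ``ops_per_branch`` is the per-branch operation count (the horizontal
    axis of accuracy curves is ``ops_per_branch / n``); ``tau`` in the
    reported ratio is the total over all branches.
    """

    n: int
    ops_per_branch: int
    leaves: int = 3
    chromosomes: int = 10
    inversion_fraction: float = 0.9
    topology: str = "balanced"
    replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.inversion_fraction <= 1.0:
            raise ValueError("inversion_fraction must lie in [0, 1]")
        if self.ops_per_branch < 0:
            raise ValueError("ops_per_branch must be non-negative")
        if self.leaves < 3:
            raise ValueError("at least 3 leaves are required")
        if self.n < self.chromosomes or self.chromosomes < 1:
            raise ValueError("need n >= chromosomes >= 1")
        if self.topology not in ("balanced", "random"):
            raise ValueError("topology must be 'balanced' or 'random'")


def _as_rng(seed: int | random.Random) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


def random_genome(
    n: int, chromosomes: int, seed: int | random.Random, name: str = "R"
) -> Genome:
    """Uniform random signed order of ``1..n`` cut into the requested
    number of non-empty chromosomes."""
    if not 1 <= chromosomes <= n:
        raise ValueError("need n >= chromosomes >= 1")
    rng = _as_rng(seed)
    genes = [g if rng.random() < 0.5 else -g for g in rng.sample(range(1, n + 1), n)]
    cuts = sorted(rng.sample(range(1, n), chromosomes - 1))
    bounds = [0, *cuts, n]
    chroms = [genes[a:b] for a, b in zip(bounds, bounds[1:])]
    return Genome(name, chroms, n)


def _invert(chroms: list[list[int]], rng: random.Random) -> tuple:
    # genome-wide uniform breakpoints: a chromosome is hit in proportion to
    # its length, then the two cut positions are uniform within it
    ci = rng.choices(range(len(chroms)), weights=[len(c) for c in chroms])[0]
    m = len(chroms[ci])
    while True:
        i = rng.randint(0, m)
        j = rng.randint(0, m)
        if i != j:
            break
    if i > j:
        i, j = j, i
    chroms[ci][i:j] = [-g for g in reversed(chroms[ci][i:j])]
    return ("inv", ci, i, j)


def _translocate(chroms: list[list[int]], rng: random.Random) -> tuple:
    weights = [len(c) + 1 for c in chroms]
    while True:
        c1 = rng.choices(range(len(chroms)), weights=weights)[0]
        c2 = rng.choices(range(len(chroms)), weights=weights)[0]
        if c1 == c2:
            continue
        i = rng.randint(0, len(chroms[c1]))
        j = rng.randint(0, len(chroms[c2]))
        orient = rng.randrange(2)
        a1, a2 = chroms[c1][:i], chroms[c1][i:]
        b1, b2 = chroms[c2][:j], chroms[c2][j:]
        if orient == 0:
            p, q = a1 + b2, b1 + a2
        else:
            p = a1 + [-g for g in reversed(b1)]
            q = [-g for g in reversed(a2)] + b2
        if p and q:  # reciprocal exchange must keep both chromosomes
            chroms[c1], chroms[c2] = p, q
            return ("tra", c1, c2, i, j, orient)


def apply_rearrangements(
    genome: Genome,
    k: int,
    inversion_fraction: float = 0.9,
    seed: int | random.Random = 0,
) -> tuple[Genome, list[tuple]]:
    """Apply ``k`` random operations (inversions or reciprocal
    translocations) and return the rearranged genome plus the op list.

    Zero-length inversions are redrawn so every counted operation actually
    cuts the genome; a translocation drawn on a single-chromosome genome is
    resampled as an inversion.
    """
    if k < 0:
        raise ValueError("operation count must be non-negative")
    rng = _as_rng(seed)
    chroms = [list(c) for c in genome.chromosomes]
    ops: list[tuple] = []
    for _ in range(k):
        if rng.random() < inversion_fraction or len(chroms) < 2:
            ops.append(_invert(chroms, rng))
        else:
            ops.append(_translocate(chroms, rng))
    return Genome(genome.name, chroms, genome.n), ops


# ---------------------------------------------------------------------------
# Topologies


def _balanced_topology(leaves: Sequence[str]) -> PhylogenyTree:
    """Balanced-as-possible unrooted binary tree over the given leaves."""
    counter = 0
    adj: dict[str, set[str]] = {}

    def link(a: str, b: str) -> None:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def build(group: Sequence[str]) -> str:
        nonlocal counter
        if len(group) == 1:
            return group[0]
        half = len(group) // 2
        counter += 1
        node = f"M{counter}"
        link(node, build(group[:half]))
        link(node, build(group[half:]))
        return node

    if len(leaves) == 3:
        link("M1", leaves[0])
        link("M1", leaves[1])
        link("M1", leaves[2])
    else:
        half = len(leaves) // 2
        root_a = build(leaves[:half])
        root_b = build(leaves[half:])
        link(root_a, root_b)
    return PhylogenyTree({v: tuple(nb) for v, nb in adj.items()})


def _random_topology(leaves: Sequence[str], rng: random.Random) -> PhylogenyTree:
    """Uniformly insert each new leaf onto a random existing edge."""
    adj: dict[str, set[str]] = {"M1": set(leaves[:3])}
    for leaf in leaves[:3]:
        adj[leaf] = {"M1"}
    counter = 1
    for leaf in leaves[3:]:
        edges = sorted(
            tuple(sorted((u, v))) for u in adj for v in adj[u]
        )
        u, v = rng.choice(edges)
        counter += 1
        node = f"M{counter}"
        adj[u].discard(v)
        adj[v].discard(u)
        adj[u].add(node)
        adj[v].add(node)
        adj[node] = {u, v, leaf}
        adj[leaf] = {node}
    return PhylogenyTree({v: tuple(nb) for v, nb in adj.items()})


@dataclass(frozen=True)
class SimulatedTree:
    """A simulated phylogeny with genomes at every node (true ancestors
    included) and the operation counts actually performed per branch."""

    tree: PhylogenyTree
    genomes: dict[str, Genome]
    branch_ops: dict[tuple[str, str], int]

    @property
    def tau_total(self) -> int:
        return sum(self.branch_ops.values())

    @property
    def leaf_genomes(self) -> dict[str, Genome]:
        return {v: g for v, g in self.genomes.items() if v in self.tree.leaves}

    @property
    def true_ancestors(self) -> dict[str, Genome]:
        return {v: g for v, g in self.genomes.items() if v not in self.tree.leaves}


def simulate_tree(config: SimulationConfig) -> SimulatedTree:
    """Evolve a random root ancestor outward along the topology, applying
    ``ops_per_branch`` operations on every branch."""
    rng = random.Random(config.seed)
    leaves = [f"L{i + 1}" for i in range(config.leaves)]
    if config.topology == "balanced":
        tree = _balanced_topology(leaves)
    else:
        tree = _random_topology(leaves, rng)
    root = tree.internal_nodes[0]
    genomes = {root: random_genome(config.n, config.chromosomes, rng, name=root)}
    branch_ops: dict[tuple[str, str], int] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        for nbr in tree.neighbors(node):
            if nbr in genomes:
                continue
            child, ops = apply_rearrangements(
                genomes[node], config.ops_per_branch, config.inversion_fraction, rng
            )
            genomes[nbr] = child.renamed(nbr)
            branch_ops[tuple(sorted((node, nbr)))] = len(ops)
            stack.append(nbr)
    return SimulatedTree(tree, genomes, branch_ops)


@dataclass(frozen=True)
class ReplicateResult:
    replicate: int
    d: int
    tau: int
    ratio: float | None  # None flags the degenerate tau == 0 case


@dataclass(frozen=True)
class ExperimentResult:
    config: SimulationConfig
    scheme: str
    iterate: int
    replicates: list[ReplicateResult] = field(default_factory=list)

    @property
    def mean_ratio(self) -> float | None:
        ratios = [r.ratio for r in self.replicates if r.ratio is not None]
        return statistics.fmean(ratios) if ratios else None


def run_experiment(
    config: SimulationConfig, scheme: str = "refined", iterate: int = 0
) -> ExperimentResult:
    """Simulate, hide the ancestors, reconstruct, and report d/tau per
    replicate.  ``iterate`` > 0 adds that many median-refinement sweeps
    after the single-pass solve."""
    rng = random.Random(config.seed)
    rows: list[ReplicateResult] = []
    for rep in range(config.replicates):
        sub_seed = rng.randrange(2**31)
        sim = simulate_tree(replace(config, seed=sub_seed))
        result = solve_small_phylogeny(sim.tree, sim.leaf_genomes, scheme=scheme)
        d = result.total
        if iterate > 0:
            ancestors, _ = refine_by_medians(
                sim.tree,
                sim.leaf_genomes,
                result.ancestors,
                iterations=iterate,
                seed=sub_seed,
                scheme=scheme,
            )
            d = tree_length(sim.tree, {**sim.leaf_genomes, **ancestors})
        tau = sim.tau_total
        rows.append(ReplicateResult(rep, d, tau, (d / tau) if tau else None))
    return ExperimentResult(config, scheme, iterate, rows)
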