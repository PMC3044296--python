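"""Signed gene orders, GRIMM-style I/O, and unrooted binary trees.

A genome is modelled as a set of linear chromosomes over a shared universe
of ``n`` distinct signed genes, numbered ``1..n``.  The sign of a gene
records its reading direction (strand).  Two gene orders are considered
equal when one can be obtained from the other by reordering chromosomes
and/or reversing whole chromosomes while negating their genes — reversing
a chromosome does not change the molecule it describes.

The file dialect is the GRIMM one: a line starting with ``>`` opens a
genome and carries its name, whitespace-separated signed integers are
genes, a ``$`` token closes a chromosome, and ``#`` starts a comment line.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy


class GenomeError(ValueError):
    """Base class for gene-order validation failures."""


class InvalidGeneError(GenomeError):
    """A token is not a usable gene identifier (zero, non-integer, out of range)."""


class DuplicateGeneError(GenomeError):
    """The same gene appears more than once within one genome."""


class MissingGeneError(GenomeError):
    """A gene of the universe ``1..n`` does not appear in the genome."""


class GeneContentError(GenomeError):
    """Two genomes that must share a gene universe do not."""


class TreeError(ValueError):
    """Base class for phylogeny validation failures."""


class PolytomyError(TreeError):
    """An internal node does not have degree 3 after unrooting."""


class LeafMismatchError(TreeError):
    """Tree leaf labels and genome names do not coincide."""


def _canonical_chromosome(chrom: tuple[int, ...]) -> tuple[int, ...]:
    # Flip so the first absolute gene id is the smaller end; a single-gene
    # chromosome is canonically positive.
    if len(chrom) == 1:
        return (abs(chrom[0]),)
    if abs(chrom[0]) > abs(chrom[-1]):
        return tuple(-g for g in reversed(chrom))
    return chrom


class Genome:
    """An immutable multichromosomal signed gene order.

    Parameters
    ----------
    name:
        Label used in files and reports; not part of equality.
    chromosomes:
        Iterable of chromosomes, each an iterable of non-zero signed ints.
    n:
        Size of the gene universe.  If omitted it is inferred as the
        largest absolute gene id, and every gene ``1..n`` must be present
        exactly once in exactly one orientation.
    """

    __slots__ = ("name", "chromosomes", "n", "_canonical")

    def __init__(self, name: str, chromosomes: Iterable[Iterable[int]], n: int | None = None):
        chroms = tuple(tuple(int(g) for g in c) for c in chromosomes)
        if not chroms:
            raise GenomeError(f"genome {name!r} has no chromosomes")
        seen: set[int] = set()
        for c in chroms:
            if not c:
                raise GenomeError(f"genome {name!r} contains an empty chromosome")
            for g in c:
                a = abs(g)
                if a == 0:
                    raise InvalidGeneError(f"genome {name!r}: gene id 0 is not allowed")
                if a in seen:
                    raise DuplicateGeneError(f"genome {name!r}: gene {a} appears twice")
                seen.add(a)
        if n is None:
            n = max(seen)
        for c in chroms:
            for g in c:
                if abs(g) > n:
                    raise InvalidGeneError(
                        f"genome {name!r}: gene {abs(g)} exceeds universe size {n}"
                    )
        missing = set(range(1, n + 1)) - seen
        if missing:
            raise MissingGeneError(
                f"genome {name!r}: genes missing from universe 1..{n}: {sorted(missing)[:10]}"
            )
        self.name = str(name)
        self.chromosomes = chroms
        self.n = n
        self._canonical = tuple(
            sorted((_canonical_chromosome(c) for c in chroms), key=lambda c: abs(c[0]))
        )

    @property
    def canonical(self) -> tuple[tuple[int, ...], ...]:
        """Canonical form: each chromosome flipped to its smaller-first-id
        orientation, chromosomes sorted by first absolute gene id."""
        return self._canonical

    @property
    def num_chromosomes(self) -> int:
        return len(self.chromosomes)

    def renamed(self, name: str) -> "Genome":
        return Genome(name, self.chromosomes, self.n)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.n == other.n and self._canonical == other._canonical

    def __hash__(self) -> int:
        return hash((self.n, self._canonical))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        body = " $ ".join(" ".join(str(g) for g in c) for c in self.chromosomes)
        return f"Genome({self.name!r}, n={self.n}: {body} $)"


# ---------------------------------------------------------------------------
# GRIMM-dialect I/O


def _parse_genome_blocks(lines: Iterable[str]) -> Iterator[tuple[str, list[list[int]]]]:
    name: str | None = None
    chroms: list[list[int]] = []
    current: list[int] = []

    def flush() -> tuple[str, list[list[int]]]:
        if current:
            chroms.append(list(current))
            current.clear()
        return name, [c for c in chroms if c]

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None:
                yield flush()
            name = line[1:].strip()
            chroms = []
            current = []
            continue
        if name is None:
            raise GenomeError(f"line {lineno}: gene data before any '>' header")
        for tok in line.split():
            if tok == "$":
                if current:
                    chroms.append(list(current))
                    current = []
                continue
            try:
                g = int(tok)
            except ValueError as exc:
                raise InvalidGeneError(f"line {lineno}: non-integer gene token {tok!r}") from exc
            if g == 0:
                raise InvalidGeneError(f"line {lineno}: gene id 0 is not allowed")
            current.append(g)
    if name is not None:
        yield flush()


def read_genomes(path: str | Path) -> list[Genome]:
    """Read a multi-genome GRIMM-dialect file.

    All genomes must carry the same gene universe, inferred as ``1..n``
    with ``n`` the largest absolute gene id in the file.
    """
    text = Path(path).read_text()
    blocks = list(_parse_genome_blocks(io.StringIO(text)))
    if not blocks:
        return []
    n = 0
    for _, chroms in blocks:
        for c in chroms:
            for g in c:
                n = max(n, abs(g))
    genomes = []
    for name, chroms in blocks:
        try:
            genomes.append(Genome(name, chroms, n=n))
        except MissingGeneError as exc:
            raise GeneContentError(
                f"genomes in {path} do not share one gene universe: {exc}"
            ) from exc
    return genomes


def write_genomes(genomes: Sequence[Genome], path: str | Path, header: str | None = None) -> None:
    """Write genomes in the GRIMM dialect (one ``$`` per chromosome)."""
    out = []
    if header:
        out.extend(f"# {line}" for line in header.splitlines())
    for g in genomes:
        out.append(f">{g.name}")
        for c in g.chromosomes:
            out.append(" ".join(str(x) for x in c) + " $")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Unrooted binary trees


class PhylogenyTree:
    """An unrooted, strictly binary tree over named leaves.

    ``N`` leaves imply exactly ``N - 2`` internal (ancestral) nodes and
    ``2N - 3`` edges; both are enforced at construction.
    """

    def __init__(self, adjacency: Mapping[str, Sequence[str]]):
        adj = {node: tuple(sorted(set(nbrs))) for node, nbrs in adjacency.items()}
        for node, nbrs in adj.items():
            for m in nbrs:
                if node not in adj.get(m, ()):
                    raise TreeError(f"adjacency is not symmetric at edge {node!r}-{m!r}")
        leaves = sorted(v for v, nb in adj.items() if len(nb) == 1)
        internal = sorted(v for v, nb in adj.items() if len(nb) == 3)
        bad = [v for v, nb in adj.items() if len(nb) not in (1, 3)]
        if bad:
            raise PolytomyError(
                f"nodes with degree other than 1 or 3 (not strictly binary): {bad}"
            )
        if len(leaves) < 3:
            raise TreeError(f"need at least 3 leaves, got {len(leaves)}")
        if len(internal) != len(leaves) - 2:
            raise TreeError(
                f"{len(leaves)} leaves require {len(leaves) - 2} internal nodes, "
                f"found {len(internal)}"
            )
        # connectivity
        stack, seen = [leaves[0]], {leaves[0]}
        while stack:
            for m in adj[stack.pop()]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        if len(seen) != len(adj):
            raise TreeError("tree is not connected")
        self._adj = adj
        self.leaves = frozenset(leaves)
        self.internal_nodes = tuple(internal)
        edges = set()
        for v, nbrs in adj.items():
            for m in nbrs:
                edges.add(tuple(sorted((v, m))))
        self.edges = tuple(sorted(edges))

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._adj))

    def neighbors(self, node: str) -> tuple[str, ...]:
        return self._adj[node]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhylogenyTree({len(self.leaves)} leaves, {len(self.internal_nodes)} ancestors)"


def _suppress_degree_two(adj: dict[str, set[str]]) -> None:
    changed = True
    while changed:
        changed = False
        for node, nbrs in list(adj.items()):
            if len(nbrs) == 2:
                a, b = sorted(nbrs)
                adj[a].discard(node)
                adj[b].discard(node)
                adj[a].add(b)
                adj[b].add(a)
                del adj[node]
                changed = True


def read_tree(source: str | Path, genome_names: Iterable[str]) -> PhylogenyTree:
    """Parse a Newick tree whose leaf labels name genomes.

    A rooted input is unrooted by suppressing the degree-2 root.  Branch
    lengths are ignored.  ``source`` may be a path or a Newick string.
    """
    names = set(genome_names)
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "(" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise TreeError(f"could not parse Newick input: {exc}") from exc

    adj: dict[str, set[str]] = {}
    labels: dict[int, str] = {}
    counter = 0
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise TreeError("tree has an unlabelled leaf")
            labels[id(node)] = node.taxon.label
        else:
            counter += 1
            lab = f"M{counter}"
            while lab in names:
                lab += "_"
            labels[id(node)] = lab
    for node in dtree.preorder_node_iter():
        u = labels[id(node)]
        adj.setdefault(u, set())
        for child in node.child_nodes():
            v = labels[id(child)]
            adj.setdefault(v, set())
            adj[u].add(v)
            adj[v].add(u)
    _suppress_degree_two(adj)

    leaf_labels = {v for v, nb in adj.items() if len(nb) == 1}
    if leaf_labels != names:
        raise LeafMismatchError(
            f"tree leaves {sorted(leaf_labels)} do not match genome names {sorted(names)}"
        )
    return PhylogenyTree({v: tuple(nb) for v, nb in adj.items()})


def star_tree(leaf_names: Sequence[str], center: str = "M1") -> PhylogenyTree:
    """The 3-leaf tree of a median instance."""
    if len(leaf_names) != 3:
        raise TreeError("a star (median) tree has exactly 3 leaves")
    adj = {center: tuple(leaf_names)}
    for leaf in leaf_names:
        adj[leaf] = (center,)
    return PhylogenyTree(adj)
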