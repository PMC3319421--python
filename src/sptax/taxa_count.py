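"""Lower-bound taxa counting from marker-anchored amino-acid strings.

All sequences handled here share a single marker peptide; each sequence
carries the offset (*anchor*) of that marker, which puts every sequence
into one common coordinate system (anchored coordinate 0 = first residue
of the marker).  Two sequences are *consistent* when they agree at every
position of their anchored overlap, in which case they may originate from
the same protein and can be *fused* into a longer string.  Inconsistent
sequences must come from different proteins and -- because the marker is
a single-copy-gene signature -- from different taxa.  The minimal number
of mutually inconsistent fused strings is therefore a lower bound on the
number of taxa, and equals the chromatic number of the graph whose edges
are the inconsistency relations.

This module provides

* the consistency relation (:func:`are_consistent`) and fusion
  (:func:`fuse`),
* the inconsistency graph builder (:func:`build_inconsistency_graph`),
* the greedy counting heuristic (:func:`count_taxa_heuristic`),
* an exact chromatic-number oracle for small instances
  (:func:`chromatic_number_exact`), and
* the leading/non-leading lower-bound aggregation
  (:func:`aggregate_lower_bound`).

``'X'`` is an ambiguity wildcard: it matches any residue in consistency
checks and is overwritten by any concrete residue during fusion, so
ambiguity can never create a new taxon.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

WILDCARD = "X"

#: length cutoffs (residues) used when adding non-leading sequences to a
#: leading-marker count, keyed by EC number of the enzyme family
DEFAULT_NONLEADING_CUTOFFS: Mapping[str, int] = {
    "6.1.1.9": 700,   # valyl-tRNA synthetase
    "6.1.1.18": 500,  # glutaminyl-tRNA synthetase
    "6.1.1.3": 450,   # threonyl-tRNA synthetase
}


@dataclass(frozen=True)
class AnchoredSequence:
    """An amino-acid string with the offset of its single marker occurrence.

    Attributes
    ----------
    id :
        Caller-chosen identifier, unique within one analysis group.
    sequence :
        Uppercase amino-acid string (may contain the wildcard ``'X'``).
    anchor :
        0-based offset of the marker peptide's first residue.
    """

    id: str
    sequence: str
    anchor: int

    def __post_init__(self) -> None:
        if not 0 <= self.anchor <= max(len(self.sequence) - 1, 0):
            raise ValueError(
                f"anchor {self.anchor} outside sequence of length "
                f"{len(self.sequence)} for {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> tuple[int, int]:
        """Covered half-open interval in anchored coordinates."""
        return (-self.anchor, len(self.sequence) - self.anchor)

    def residue(self, pos: int) -> str:
        """Residue at anchored coordinate ``pos`` (must lie in :attr:`span`)."""
        return self.sequence[pos + self.anchor]


@dataclass(frozen=True)
class FusedString:
    """A merged string of mutually consistent anchored sequences."""

    sequence: str
    anchor: int
    members: tuple[str, ...]

    @property
    def id(self) -> str:
        return "+".join(self.members)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def span(self) -> tuple[int, int]:
        return (-self.anchor, len(self.sequence) - self.anchor)

    def residue(self, pos: int) -> str:
        return self.sequence[pos + self.anchor]


@dataclass
class TaxaCountResult:
    """Output of :func:`count_taxa_heuristic`.

    ``count`` equals ``len(fused)``; first-pass singletons are included in
    ``fused`` as single-member strings so that every input sequence is a
    member of exactly one fused string.
    """

    count: int
    fused: list[FusedString] = field(default_factory=list)
    singles_first_pass: int = 0


def _residues_match(x: str, y: str) -> bool:
    return x == y or x == WILDCARD or y == WILDCARD


def _overlap(a, b) -> tuple[int, int]:
    lo = max(a.span[0], b.span[0])
    hi = min(a.span[1], b.span[1])
    return lo, hi


def _check_same_marker(a, b, sp: str) -> None:
    for s in (a, b):
        word = s.sequence[s.anchor : s.anchor + len(sp)]
        if word != sp:
            raise ValueError(
                f"sequence {getattr(s, 'id', '?')!r} does not carry marker "
                f"{sp!r} at its anchor (found {word!r})"
            )


def are_consistent(a, b, sp: str | None = None) -> bool:
    """True iff ``a`` and ``b`` agree throughout their anchored overlap.

    Parameters
    ----------
    a, b :
        Objects with ``sequence``/``anchor`` (:class:`AnchoredSequence` or
        :class:`FusedString`).
    sp :
        Optional marker word; when given, both sequences are verified to
        carry it at their anchor and a ``ValueError`` is raised otherwise.

    The relation is reflexive and symmetric but *not* transitive.  An
    empty overlap (impossible when both sequences contain a common marker)
    is vacuously consistent.
    """
    if sp is not None:
        _check_same_marker(a, b, sp)
    lo, hi = _overlap(a, b)
    if hi <= lo:
        return True
    sub_a = a.sequence[lo + a.anchor : hi + a.anchor]
    sub_b = b.sequence[lo + b.anchor : hi + b.anchor]
    if sub_a == sub_b:
        return True
    if WILDCARD not in sub_a and WILDCARD not in sub_b:
        return False
    return all(_residues_match(x, y) for x, y in zip(sub_a, sub_b))


def build_inconsistency_graph(
    seqs: Iterable[AnchoredSequence], sp: str | None = None
) -> nx.Graph:
    """Graph with the sequences as nodes and inconsistent pairs as edges.

    Node keys are sequence ids; each node stores its sequence under the
    ``"seq"`` attribute.  The chromatic number of this graph is the exact
    minimal taxa count for the group.
    """
    seqs = list(seqs)
    g = nx.Graph()
    for s in seqs:
        if g.has_node(s.id):
            raise ValueError(f"duplicate sequence id {s.id!r}")
        g.add_node(s.id, seq=s)
    for a, b in itertools.combinations(seqs, 2):
        if not are_consistent(a, b, sp=sp):
            g.add_edge(a.id, b.id)
    return g


def fuse(seqs: Iterable, sp: str | None = None) -> FusedString:
    """Merge mutually consistent anchored sequences into one string.

    The fused string covers the union of the members' anchored intervals
    (contiguous because every member covers the marker span).  Each
    position takes the unique concrete residue agreed by the covering
    members; the wildcard is overridden by any concrete residue.

    Raises
    ------
    ValueError
        If the collection is empty or any pair disagrees at a shared
        position (contract violation: callers must pass a consistent set).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("cannot fuse an empty collection")
    if sp is not None:
        for s in seqs:
            _check_same_marker(s, s, sp)
    lo = min(s.span[0] for s in seqs)
    hi = max(s.span[1] for s in seqs)
    out: list[str] = []
    for pos in range(lo, hi):
        residue = WILDCARD
        for s in seqs:
            if s.span[0] <= pos < s.span[1]:
                r = s.residue(pos)
                if r == WILDCARD:
                    continue
                if residue != WILDCARD and residue != r:
                    raise ValueError(
                        f"inconsistent pair passed to fuse(): conflict at "
                        f"anchored position {pos} ({residue!r} vs {r!r})"
                    )
                residue = r
        out.append(residue)
    members: list[str] = []
    for s in seqs:
        members.extend(s.members if isinstance(s, FusedString) else [s.id])
    return FusedString(sequence="".join(out), anchor=-lo, members=tuple(sorted(members)))


def _as_fused(s) -> FusedString:
    if isinstance(s, FusedString):
        return s
    return FusedString(sequence=s.sequence, anchor=s.anchor, members=(s.id,))


def _contained(inner, outer) -> bool:
    """True when ``inner``'s anchored span lies within ``outer``'s."""
    return outer.span[0] <= inner.span[0] and inner.span[1] <= outer.span[1]


def _overlap_length(a, b) -> int:
    lo, hi = _overlap(a, b)
    return max(0, hi - lo)


def _greedy_fuse_block(block: list[AnchoredSequence]) -> list[FusedString]:
    """Fuse one connected component of the consistency graph.

    Repeatedly seed a new string with the longest remaining read (ties
    by lowest id), absorb reads that are anchored substrings of it, then
    greedily extend it with consistent remainders.  Extensions prefer
    the candidate with the largest anchored overlap (the
    most-constrained, hence safest, merge), then the longest resulting
    fused string, then the lowest id.  Preferring large overlaps keeps
    barely-overlapping reads from different sources from seeding
    chimeric strings that would inflate the count.
    """
    remaining = sorted(block, key=lambda s: (len(s), s.id))
    fused: list[FusedString] = []
    while remaining:
        seed = min(remaining, key=lambda s: (-len(s), s.id))
        remaining.remove(seed)
        current = _as_fused(seed)
        while True:
            candidates = [r for r in remaining if are_consistent(current, r)]
            if not candidates:
                break
            absorbed = [r for r in candidates if _contained(r, current)]
            if absorbed:
                # one at a time: two absorbed reads may disagree at a
                # position the current string only covers with a wildcard
                current = fuse([current, absorbed[0]])
                remaining.remove(absorbed[0])
                continue
            best = min(
                candidates,
                key=lambda r: (
                    -_overlap_length(current, r),
                    -(max(r.span[1], current.span[1])
                      - min(r.span[0], current.span[0])),
                    r.id,
                ),
            )
            current = fuse([current, best])
            remaining.remove(best)
        fused.append(current)
    return fused


def _coloring_partition(
    seqs: list[AnchoredSequence], graph: nx.Graph
) -> list[FusedString]:
    """Partition via DSATUR colouring of the inconsistency graph.

    Colour classes are independent sets, i.e. pairwise consistent, hence
    jointly fusable; this route sometimes beats the string-greedy one on
    sparsely overlapping read sets.
    """
    colors = nx.coloring.greedy_color(graph, strategy="saturation_largest_first")
    by_id = {s.id: s for s in seqs}
    classes: dict[int, list[AnchoredSequence]] = {}
    for v in sorted(colors):
        classes.setdefault(colors[v], []).append(by_id[v])
    return [fuse(classes[c]) for c in sorted(classes)]


def count_taxa_heuristic(
    seqs: Iterable[AnchoredSequence], sp: str | None = None
) -> TaxaCountResult:
    """Heuristic minimal number of mutually inconsistent fused strings.

    Steps:

    1. Remove (and count as singletons) every sequence inconsistent with
       all others -- each is a taxon on its own.
    2. Partition the remainder into blocks: connected components of the
       consistency graph (reads in different components can never fuse).
    3. Within each block, absorb substrings and greedily extend longest
       strings with consistent remainders (:func:`_greedy_fuse_block`).
    4. While any two resulting strings are still consistent, merge them;
       iterate to a fixpoint (each merge strictly reduces the count, so
       at most ``len(seqs)`` iterations occur).

    A second, independent partition is built by DSATUR colouring of the
    inconsistency graph (:func:`_coloring_partition`, also merged to a
    fixpoint) and the smaller of the two partitions is returned, with
    ties resolved in favour of the string-greedy construction.  Both
    routes produce partitions into mutually consistent classes, so
    either count is an upper bound on the chromatic number of the
    inconsistency graph and hence a valid lower bound on taxa; on
    realistically structured groups the result matches the exact value
    (see :func:`chromatic_number_exact`).
    """
    seqs = list(seqs)
    if not seqs:
        return TaxaCountResult(count=0, fused=[], singles_first_pass=0)
    graph = build_inconsistency_graph(seqs, sp=sp)
    n = len(seqs)

    singles: list[FusedString] = []
    rest: list[AnchoredSequence] = []
    if n == 1:
        rest = seqs
    else:
        for s in seqs:
            if graph.degree(s.id) == n - 1:
                singles.append(_as_fused(s))
            else:
                rest.append(s)

    # blocks: connected components of the *consistency* graph on the rest
    cons = nx.Graph()
    cons.add_nodes_from(s.id for s in rest)
    by_id = {s.id: s for s in rest}
    for a, b in itertools.combinations(rest, 2):
        if not graph.has_edge(a.id, b.id):
            cons.add_edge(a.id, b.id)
    components = sorted(
        (sorted(c) for c in nx.connected_components(cons)),
        key=lambda c: (-len(c), c[0]),
    )

    fused: list[FusedString] = list(singles)
    for comp in components:
        fused.extend(_greedy_fuse_block([by_id[i] for i in comp]))
    fused = _merge_to_fixpoint(fused, n)

    alternative = _merge_to_fixpoint(_coloring_partition(seqs, graph), n)
    if len(alternative) < len(fused):
        fused = alternative

    return TaxaCountResult(
        count=len(fused), fused=fused, singles_first_pass=len(singles)
    )


def _merge_to_fixpoint(
    fused: list[FusedString], bound: int
) -> list[FusedString]:
    """Step 4: merge strings that are still consistent until none are."""
    for _ in range(bound):
        merged = _merge_one_consistent_pair(fused)
        if merged is None:
            return fused
        fused = merged
    raise RuntimeError("fusion fixpoint not reached")  # pragma: no cover


def _merge_one_consistent_pair(
    fused: list[FusedString],
) -> list[FusedString] | None:
    for i, j in itertools.combinations(range(len(fused)), 2):
        if are_consistent(fused[i], fused[j]):
            merged = fuse([fused[i], fused[j]])
            rest = [f for k, f in enumerate(fused) if k not in (i, j)]
            return rest + [merged]
    return None


def chromatic_number_exact(g: nx.Graph, cap: int = 18) -> int:
    """Exact chromatic number of an inconsistency graph by backtracking.

    Uses a maximum clique as the lower bound, a greedy colouring as the
    initial upper bound, and branch-and-bound over vertices ordered by
    degree (clique vertices first).  Refuses graphs larger than ``cap``
    vertices; use :func:`count_taxa_heuristic` for those.
    """
    n = g.number_of_nodes()
    if n > cap:
        raise ValueError(
            f"graph has {n} vertices, above the exact-solver cap of {cap}; "
            "use count_taxa_heuristic for large instances"
        )
    if n == 0:
        return 0
    if g.number_of_edges() == 0:
        return 1

    clique, _ = nx.max_weight_clique(g, weight=None)
    lower = len(clique)
    greedy = nx.coloring.greedy_color(g, strategy="largest_first")
    upper = max(greedy.values()) + 1
    if lower == upper:
        return lower

    order = list(clique) + sorted(
        (v for v in g if v not in set(clique)),
        key=lambda v: -g.degree(v),
    )
    adj = {v: set(g[v]) for v in g}
    colors: dict[str, int] = {v: i for i, v in enumerate(clique)}
    best = upper

    def backtrack(idx: int, used: int) -> None:
        nonlocal best
        if used >= best:
            return
        if idx == len(order):
            best = used
            return
        v = order[idx]
        forbidden = {colors[u] for u in adj[v] if u in colors}
        for c in range(used + 1):  # existing classes plus one fresh class
            if c in forbidden:
                continue
            new_used = max(used, c + 1)
            if new_used >= best:
                continue
            colors[v] = c
            backtrack(idx + 1, new_used)
            del colors[v]

    backtrack(len(clique), lower)
    return best


def aggregate_lower_bound(
    leading_count: int,
    nonleading: Iterable,
    cutoff: int,
) -> int:
    """Add long non-leading sequences to a leading-marker count.

    ``nonleading`` items may be strings, objects with a ``sequence``
    attribute, or plain integer lengths; they must already be verified to
    lack the leading marker.  Only items of length ``>= cutoff`` residues
    are counted -- long enough to exclude being unobserved fragments of
    genes already counted through the leading marker.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be non-negative, got {cutoff}")

    def _length(p) -> int:
        if isinstance(p, int):
            return p
        if hasattr(p, "sequence"):
            return len(p.sequence)
        return len(p)

    return leading_count + sum(1 for p in nonleading if _length(p) >= cutoff)


def max_clique_size(g: nx.Graph) -> int:
    """Size of a maximum clique; a certified floor under any proper count."""
    if g.number_of_nodes() == 0:
        return 0
    clique, _ = nx.max_weight_clique(g, weight=None)
    return len(clique)
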