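"""Distance-based counting of fused strings and subsampling analysis.

Fused strings sharing one marker are compared by *anchored Hamming
distance* -- the number of differing residues over the anchored overlap.
Counting at minimal distance ``d`` removes members of close pairs until
all survivors are at least ``d`` apart; sweeping ``d`` yields a
count-versus-distance curve whose low-``d`` part is sensitive to strains
and sequencing errors while its high-``d`` part counts well-separated
species.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .taxa_count import (
    WILDCARD,
    AnchoredSequence,
    FusedString,
    _overlap,
    count_taxa_heuristic,
)

logger = logging.getLogger(__name__)


def anchored_hamming(a, b, sp: str | None = None) -> int:
    """Residue differences over the anchored overlap of two strings.

    Positions where either string carries the wildcard ``'X'`` are
    excluded from the count.  ``a`` and ``b`` are any objects with
    ``sequence``/``anchor`` attributes; when ``sp`` is given both must
    carry it at their anchor.
    """
    if sp is not None:
        from .taxa_count import _check_same_marker

        _check_same_marker(a, b, sp)
    lo, hi = _overlap(a, b)
    if hi <= lo:
        return 0
    sub_a = a.sequence[lo + a.anchor : hi + a.anchor]
    sub_b = b.sequence[lo + b.anchor : hi + b.anchor]
    if sub_a == sub_b:
        return 0
    return sum(
        x != y and x != WILDCARD and y != WILDCARD
        for x, y in zip(sub_a, sub_b)
    )


@dataclass
class DistanceMatrix:
    """Anchored Hamming distances between fused strings.

    ``order`` holds string ids sorted by length ascending (ties by id),
    fixing the row/column order; ``entries`` is the full symmetric
    matrix (diagonal zero).  ``sp_only_pairs`` flags index pairs whose
    overlap is exactly the marker span -- such pairs carry no
    discriminative signal.
    """

    order: list[str]
    entries: np.ndarray
    sp_only_pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.order)
        if self.entries.shape != (n, n):
            raise ValueError("entries shape does not match order")

    @property
    def n(self) -> int:
        return len(self.order)

    def distance(self, i: int, j: int) -> int:
        return int(self.entries[i, j])


def build_distance_matrix(
    strings: Sequence, sp_length: int | None = None
) -> DistanceMatrix:
    """Distance matrix over fused strings, index-ordered by length.

    ``sp_length`` enables flagging of pairs whose overlap is only the
    marker span.
    """
    ordered = sorted(strings, key=lambda s: (len(s.sequence), s.id))
    n = len(ordered)
    entries = np.zeros((n, n), dtype=int)
    sp_only: set[tuple[int, int]] = set()
    for i, j in itertools.combinations(range(n), 2):
        entries[i, j] = entries[j, i] = anchored_hamming(ordered[i], ordered[j])
        if sp_length is not None:
            lo, hi = _overlap(ordered[i], ordered[j])
            if (lo, hi) == (0, sp_length):
                sp_only.add((i, j))
    if sp_only:
        logger.info("%d pair(s) overlap only on the marker span", len(sp_only))
    return DistanceMatrix(
        order=[s.id for s in ordered], entries=entries, sp_only_pairs=sp_only
    )


def count_at_min_distance(m: DistanceMatrix, d: int) -> int:
    """Survivors after removing members of pairs at distance ``<= d``.

    One pass lists all close pairs as (smaller index, larger index)
    rows, takes the unique values of each column, and removes the
    smaller unique set (ties favour the left column, i.e. the shorter
    strings).  Passes iterate until no close pair remains; the final
    certificate -- every surviving pair at distance ``> d`` -- is
    asserted rather than trusted.  ``d = 0`` removes only identical-
    overlap pairs; pass ``d - 1`` to require pairwise distance ``>= d``.
    """
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    alive = list(range(m.n))
    while True:
        pairs = [
            (i, j)
            for i, j in itertools.combinations(alive, 2)
            if m.distance(i, j) <= d
        ]
        if not pairs:
            break
        left = {i for i, _ in pairs}
        right = {j for _, j in pairs}
        minimal = left if len(left) <= len(right) else right
        alive = [i for i in alive if i not in minimal]
    for i, j in itertools.combinations(alive, 2):
        assert m.distance(i, j) > d, "survivor pair at distance <= d"
    return len(alive)


@dataclass
class CountCurve:
    """Count of surviving strings per minimal distance ``d``.

    ``points[d]`` is the number of strings after enforcing pairwise
    distance ``>= d``; ``points[1]`` equals the base taxa count because
    mutually inconsistent fused strings already differ by at least one
    residue.
    """

    points: dict[int, int]

    def __getitem__(self, d: int) -> int:
        return self.points[d]


def count_curve(strings: Sequence, d_max: int) -> CountCurve:
    """Sweep :func:`count_at_min_distance` over ``d = 1..d_max``.

    Distances are computed once and reused across the sweep.
    """
    if d_max < 1:
        raise ValueError(f"d_max must be >= 1, got {d_max}")
    m = build_distance_matrix(strings)
    return CountCurve(
        points={d: count_at_min_distance(m, d - 1) for d in range(1, d_max + 1)}
    )


def max_distant_set_exact(m: DistanceMatrix, d: int, cap: int = 25) -> int:
    """Exact maximum number of strings with pairwise distance ``> d``.

    Maximum independent set of the close-pair graph (computed as a
    maximum clique of its complement); quantifies how much the removal
    heuristic under-counts.  Capped at ``cap`` strings.
    """
    if m.n > cap:
        raise ValueError(f"{m.n} strings above exact cap of {cap}")
    if m.n == 0:
        return 0
    g = nx.Graph()
    g.add_nodes_from(range(m.n))
    for i, j in itertools.combinations(range(m.n), 2):
        if m.distance(i, j) > d:
            g.add_edge(i, j)
    clique, _ = nx.max_weight_clique(g, weight=None)
    return len(clique)


@dataclass
class SubsampleResult:
    """Mean counts and standard errors from repeated random subsampling."""

    sample_size: int
    trials: int
    mean_count: dict[int, float]
    sem: dict[int, float]
    seed: int


def subsample_counts(
    seqs: Sequence[AnchoredSequence],
    S: int,
    trials: int = 20,
    d_max: int = 10,
    seed: int = 0,
) -> SubsampleResult:
    """Depth analysis: run the full pipeline on random subsets of size S.

    Each trial samples ``S`` sequences without replacement, fuses them
    with :func:`count_taxa_heuristic` and evaluates the count curve up
    to ``d_max``.  Means and standard errors of the mean per ``d`` are
    reproducible for a fixed ``seed``.
    """
    n = len(seqs)
    if not 1 <= S <= n:
        raise ValueError(f"sample size {S} outside 1..{n}")
    rng = np.random.default_rng(seed)
    counts = np.zeros((trials, d_max), dtype=int)
    for t in range(trials):
        idx = rng.choice(n, size=S, replace=False)
        sample = [seqs[i] for i in idx]
        fused = count_taxa_heuristic(sample).fused
        curve = count_curve(fused, d_max)
        counts[t] = [curve[d] for d in range(1, d_max + 1)]
    mean = counts.mean(axis=0)
    if trials > 1:
        sem = counts.std(axis=0, ddof=1) / np.sqrt(trials)
    else:
        sem = np.zeros(d_max)
    return SubsampleResult(
        sample_size=S,
        trials=trials,
        mean_count={d: float(mean[d - 1]) for d in range(1, d_max + 1)},
        sem={d: float(sem[d - 1]) for d in range(1, d_max + 1)},
        seed=seed,
    )
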