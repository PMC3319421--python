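"""Calibration utilities: read-length acuity, error injection, marker
specificity on annotated genomes, and mismatch matching to references.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AA_ALPHABET, RegionAnnotation, SPTable
from .taxa_count import AnchoredSequence, count_taxa_heuristic
from .distance_count import count_curve
from .translate_search import six_frame_translate, find_sp_hits

logger = logging.getLogger(__name__)

_RESIDUES = sorted(AA_ALPHABET)


# ---------------------------------------------------------------------------
# probability of inequality


@dataclass
class InequalityResult:
    """Window-based distinguishability of protein pairs.

    ``p_ine = n_dif / sigma`` where ``n_dif`` counts sliding windows of
    the shorter protein with no exact occurrence in the longer one and
    ``sigma`` is the total number of windows over all pairs.
    """

    window_size: int
    n_dif: int
    sigma: int

    @property
    def p_ine(self) -> float:
        return self.n_dif / self.sigma


def inequality_probability(
    pairs: Iterable[tuple[str, str]], W: int
) -> InequalityResult:
    """Fraction of length-``W`` windows of one protein absent from another.

    For each (shorter, longer) pair every window of the shorter protein
    is looked up as an exact substring of the longer; pairs whose shorter
    member is below ``W`` residues are skipped with a warning.
    """
    if W < 1:
        raise ValueError(f"window size must be >= 1, got {W}")
    n_dif = sigma = 0
    for shorter, longer in pairs:
        if len(shorter) > len(longer):
            shorter, longer = longer, shorter
        if len(shorter) < W:
            logger.warning(
                "skipping pair: shorter protein (%d aa) below window %d",
                len(shorter), W,
            )
            continue
        for start in range(len(shorter) - W + 1):
            sigma += 1
            if longer.find(shorter[start : start + W]) < 0:
                n_dif += 1
    if sigma == 0:
        raise ValueError("no pair admitted any window; cannot form p_ine")
    return InequalityResult(window_size=W, n_dif=n_dif, sigma=sigma)


def pairs_from_taxonomy(
    proteins: Iterable[tuple[str, tuple[str, ...]]],
    higher: int,
    lower: int,
) -> list[tuple[str, str]]:
    """All protein pairs sharing rank ``higher`` but differing at ``lower``.

    ``proteins`` holds (sequence, rank-tuple) items; rank indices address
    the tuple (e.g. phylum=0 ... species=5).
    """
    items = list(proteins)
    out = []
    for (sa, ra), (sb, rb) in itertools.combinations(items, 2):
        if ra[higher] == rb[higher] and ra[lower] != rb[lower]:
            out.append((sa, sb))
    return out


# ---------------------------------------------------------------------------
# error injection


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-residue substitution errors at rate ``p``."""

    p: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"error rate must be in [0, 1], got {self.p}")


@dataclass
class MutatedSet:
    sequences: list[AnchoredSequence]
    n_dropped: int
    n_substitutions: int


def _mutate_sequence(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``p`` by a different one."""
    out = list(seq)
    for i, r in enumerate(out):
        if rng.random() < p:
            choices = [c for c in _RESIDUES if c != r]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def inject_errors(
    seqs: Iterable[AnchoredSequence],
    model: ErrorModel,
    sp_length: int = 0,
) -> MutatedSet:
    """Apply the substitution error model to anchored sequences.

    Anchors are preserved.  Sequences whose marker span (``anchor ..
    anchor + sp_length``) is altered are dropped with a logged count --
    they would no longer be recruited by the exact marker search.  The
    same model/seed is bit-reproducible.
    """
    rng = np.random.default_rng(model.seed)
    kept: list[AnchoredSequence] = []
    dropped = substitutions = 0
    for s in seqs:
        mutated = _mutate_sequence(s.sequence, model.p, rng)
        substitutions += sum(a != b for a, b in zip(s.sequence, mutated))
        if mutated[s.anchor : s.anchor + sp_length] != s.sequence[
            s.anchor : s.anchor + sp_length
        ]:
            dropped += 1
            continue
        kept.append(AnchoredSequence(id=s.id, sequence=mutated, anchor=s.anchor))
    if dropped:
        logger.info("dropped %d sequence(s) with a mutated marker span", dropped)
    return MutatedSet(sequences=kept, n_dropped=dropped, n_substitutions=substitutions)


def error_shift_check(
    original: Sequence[AnchoredSequence],
    model: ErrorModel,
    d_max: int,
    sp_length: int = 0,
) -> pd.DataFrame:
    """Diagnostic: compare mutated counts at ``d+1`` with clean counts at ``d``.

    Columns: ``d``, ``count_original``, ``count_mutated``, ``shift``
    where ``shift = count_mutated(d+1) - count_original(d)`` (NaN at
    ``d = d_max``).  A shift near zero indicates that raising the
    minimal distance by one absorbs the injected errors.
    """
    clean_curve = count_curve(count_taxa_heuristic(list(original)).fused, d_max)
    mutated = inject_errors(original, model, sp_length=sp_length).sequences
    if mutated:
        mut_curve = count_curve(count_taxa_heuristic(mutated).fused, d_max)
        mut_points = mut_curve.points
    else:
        mut_points = {d: 0 for d in range(1, d_max + 1)}
    rows = []
    for d in range(1, d_max + 1):
        shift = (
            mut_points[d + 1] - clean_curve[d] if d + 1 <= d_max else float("nan")
        )
        rows.append(
            {
                "d": d,
                "count_original": clean_curve[d],
                "count_mutated": mut_points[d],
                "shift": shift,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# specificity on an annotated genome


@dataclass
class SpecificityTable:
    """Per-marker-length hit statistics on a genic/intergenic partition."""

    table: pd.DataFrame  # indexed by L: FP, TP, error, intergenic, EFP
    genic_length: int
    intergenic_length: int
    unclassified: int = 0


def _hit_genomic_span(
    frame: int, aa_offset: int, aa_length: int, genome_length: int
) -> tuple[int, int]:
    """Nucleotide span of an amino-acid hit, 0-based half-open."""
    o = abs(frame) - 1
    start_on_strand = o + 3 * aa_offset
    end_on_strand = start_on_strand + 3 * aa_length
    if frame > 0:
        return start_on_strand, end_on_strand
    return genome_length - end_on_strand, genome_length - start_on_strand


def evaluate_specificity(
    genome: str,
    annotation: RegionAnnotation,
    table: SPTable,
    seq_id: str = "genome",
) -> SpecificityTable:
    """Classify marker hits on a genome as TP/FP/intergenic per length L.

    The genome is translated in six modes and searched for all markers;
    hits are mapped back to nucleotide coordinates and classified
    against the annotation: genic hits are true positives when the
    overlapping gene carries the marker's EC, otherwise false
    positives; intergenic hits form the negative set.  Expected false
    positives (EFP) extrapolate the intergenic hit rate to the genic
    fraction: ``EFP(L) = round(intergenic_hits(L) * genic_length /
    intergenic_length)``.
    """
    counters: dict[int, dict[str, int]] = {}
    unclassified = 0
    for pp in six_frame_translate(genome, source_id=seq_id):
        for hit in find_sp_hits(pp, table, all_occurrences=True):
            start, end = _hit_genomic_span(
                pp.frame, hit.offset, hit.sp.length, len(genome)
            )
            row = counters.setdefault(
                hit.sp.length, {"FP": 0, "TP": 0, "intergenic": 0}
            )
            overlapping = annotation.overlapping(seq_id, start, end)
            genic = [iv for iv in overlapping if iv.region_class == "genic"]
            intergenic = [iv for iv in overlapping if iv.region_class == "intergenic"]
            if genic:
                if any(iv.ec == hit.sp.ec for iv in genic):
                    row["TP"] += 1
                else:
                    row["FP"] += 1
            elif intergenic:
                row["intergenic"] += 1
            else:
                unclassified += 1
                logger.warning(
                    "hit at %d..%d not covered by the annotation", start, end
                )
    genic_length = annotation.genic_length
    intergenic_length = annotation.intergenic_length
    rows = []
    for L in sorted(counters):
        row = counters[L]
        fp, tp, inter = row["FP"], row["TP"], row["intergenic"]
        error = fp / (fp + tp) if fp + tp else float("nan")
        efp = (
            round(inter * genic_length / intergenic_length)
            if intergenic_length
            else 0
        )
        rows.append(
            {"L": L, "FP": fp, "TP": tp, "error": error,
             "intergenic": inter, "EFP": efp}
        )
    df = pd.DataFrame(
        rows, columns=["L", "FP", "TP", "error", "intergenic", "EFP"]
    ).set_index("L")
    return SpecificityTable(
        table=df,
        genic_length=genic_length,
        intergenic_length=intergenic_length,
        unclassified=unclassified,
    )


# ---------------------------------------------------------------------------
# mismatch-profile matching


@dataclass
class MatchProfile:
    """Fraction of queries with a reference match at ``<= k`` mismatches."""

    fractions: dict[int, float]

    def __getitem__(self, k: int) -> float:
        return self.fractions[k]


def _best_anchored_mismatches(
    query: AnchoredSequence, ref: str, sp: str
) -> int | None:
    """Minimum mismatches aligning the query anchor to marker sites in ref."""
    best: int | None = None
    pos = ref.find(sp)
    while pos >= 0:
        mm = _mismatches_at(query.sequence, ref, pos - query.anchor)
        if best is None or mm < best:
            best = mm
        pos = ref.find(sp, pos + 1)
    return best


def _mismatches_at(query: str, ref: str, offset: int) -> int:
    """Mismatches over the query length with the query placed at ``offset``.

    Query positions falling outside the reference, and wildcard
    residues, count as mismatches (exact matching only).
    """
    mm = 0
    for i, q in enumerate(query):
        j = offset + i
        if j < 0 or j >= len(ref) or q == "X" or ref[j] != q:
            mm += 1
    return mm


def match_to_reference(
    queries: Sequence[AnchoredSequence],
    reference: Sequence[str],
    k_max: int,
    sp: str | None = None,
    free_offset: bool = False,
) -> MatchProfile:
    """Best-match mismatch profile of anchored queries against references.

    By default the alignment is anchored: the query's marker is placed
    on each marker occurrence in each reference.  With
    ``free_offset=True`` every full-overlap placement is tried instead.
    The profile reports, for each ``k = 0..k_max``, the fraction of
    queries whose best reference match has at most ``k`` mismatches.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("empty reference set")
    queries = list(queries)
    if not free_offset and sp is None:
        raise ValueError("anchored matching requires the marker word (sp=...)")
    bests: list[int] = []
    for q in queries:
        best: int | None = None
        for ref in reference:
            if free_offset:
                offsets = range(len(ref) - len(q.sequence) + 1)
                for off in offsets:
                    mm = _mismatches_at(q.sequence, ref, off)
                    if best is None or mm < best:
                        best = mm
            else:
                mm = _best_anchored_mismatches(q, ref, sp)
                if mm is not None and (best is None or mm < best):
                    best = mm
        bests.append(best if best is not None else len(q.sequence))
    n = len(queries)
    fractions = {
        k: (sum(b <= k for b in bests) / n if n else 0.0)
        for k in range(k_max + 1)
    }
    return MatchProfile(fractions=fractions)
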