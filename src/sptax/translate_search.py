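"""Six-frame translation, marker search and putative-protein extraction.

Nucleotide reads or contigs are translated in the six possible modes
(three frame offsets per strand, standard genetic code) into *putative
peptides*; marker peptides from the look-up table are then located on
them by exact substring search, and the enclosing Met-to-stop segment
can be cut out as a *putative protein*.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .io_formats import SPRecord, SPTable
from .taxa_count import AnchoredSequence

logger = logging.getLogger(__name__)

NT_ALPHABET = frozenset("ACGTN")

#: frame labels: +1..+3 are offsets 0..2 on the forward strand,
#: -1..-3 are offsets 0..2 on the reverse complement
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class PutativePeptide:
    """One of the six conceptual translations of a nucleotide sequence."""

    source_id: str
    frame: int
    sequence: str  # may contain '*' (stop) and 'X' (ambiguous codon)

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")


@dataclass(frozen=True)
class SPHit:
    """An exact occurrence of a marker peptide on a putative peptide."""

    pp: PutativePeptide
    sp: SPRecord
    offset: int

    def __post_init__(self) -> None:
        found = self.pp.sequence[self.offset : self.offset + self.sp.length]
        if found != self.sp.peptide:
            raise ValueError(
                f"hit does not re-validate: expected {self.sp.peptide!r} at "
                f"offset {self.offset}, found {found!r}"
            )


@dataclass(frozen=True)
class PutativeProtein:
    """The Met-to-stop segment of a putative peptide around a marker hit.

    ``start_truncated`` is set when no proper start (a Met after the
    nearest upstream stop) exists and the segment begins at the stop or
    the peptide boundary; ``end_truncated`` when no downstream stop
    exists and the segment runs to the peptide boundary.
    """

    sequence: str
    sp_offset: int
    source_id: str
    frame: int
    start_truncated: bool = False
    end_truncated: bool = False

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("putative protein contains an internal stop")

    def __len__(self) -> int:
        return len(self.sequence)


def _translate_frame(nt: str, offset: int) -> str:
    usable = nt[offset : offset + 3 * ((len(nt) - offset) // 3)]
    if not usable:
        return ""
    aa = list(str(Seq(usable).translate(table=1)))
    # any N-containing codon is ambiguous by contract, even when all its
    # resolutions code for the same residue (e.g. TCN)
    for i in range(len(aa)):
        if "N" in usable[3 * i : 3 * i + 3]:
            aa[i] = "X"
    return "".join(aa)


def six_frame_translate(
    read: str, source_id: str = "read"
) -> list[PutativePeptide]:
    """Translate a nucleotide string in all six modes.

    Stops are rendered ``'*'``; codons containing ``N`` render ``'X'``.
    Reverse frames translate the reverse complement.  Reads shorter than
    3 nt yield six empty-sequence peptides with a warning.
    """
    read = read.upper()
    bad = set(read) - NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in read: {sorted(bad)}")
    if len(read) < 3:
        logger.warning("read %r shorter than one codon; empty frames", source_id)
    rc = str(Seq(read).reverse_complement())
    pps = []
    for offset in range(3):
        pps.append(
            PutativePeptide(source_id, offset + 1, _translate_frame(read, offset))
        )
    for offset in range(3):
        pps.append(
            PutativePeptide(source_id, -(offset + 1), _translate_frame(rc, offset))
        )
    return pps


def find_sp_hits(
    pp: PutativePeptide, table: SPTable, all_occurrences: bool = False
) -> list[SPHit]:
    """Exact marker occurrences on one putative peptide.

    By default only the first occurrence of each marker is recorded;
    additional occurrences (pathological for markers of length >= 9 on
    single-gene reads, which are single-occurrence by construction)
    trigger a warning.  Genome-wide scans pass ``all_occurrences=True``
    to record every occurrence.  ``'X'`` never matches because matching
    is exact and markers contain no ``'X'``.
    """
    hits = []
    for rec in table:
        pos = pp.sequence.find(rec.peptide)
        if pos < 0:
            continue
        hits.append(SPHit(pp=pp, sp=rec, offset=pos))
        nxt = pp.sequence.find(rec.peptide, pos + 1)
        if nxt < 0:
            continue
        if not all_occurrences:
            logger.warning(
                "marker %s occurs more than once on %s frame %+d; "
                "keeping first occurrence",
                rec.peptide, pp.source_id, pp.frame,
            )
            continue
        while nxt >= 0:
            hits.append(SPHit(pp=pp, sp=rec, offset=nxt))
            nxt = pp.sequence.find(rec.peptide, nxt + 1)
    return hits


def extract_putative_protein(pp: PutativePeptide, hit: SPHit) -> PutativeProtein:
    """Cut the enzyme-candidate segment around a marker hit.

    Scan left from the marker start to the nearest stop (or the peptide
    start) and begin at the first Met after it; scan right from the
    marker end to the first stop (or the peptide end).  A stop inside
    the marker span is a contradiction (the hit cannot be genuine).
    """
    seq = pp.sequence
    sp_start, sp_end = hit.offset, hit.offset + hit.sp.length
    if "*" in seq[sp_start:sp_end]:
        raise ValueError("stop codon inside the marker span: hit not genuine")

    left_stop = seq.rfind("*", 0, sp_start)  # -1 when absent
    met = seq.find("M", left_stop + 1, sp_start + 1)
    if met >= 0:
        start, start_truncated = met, False
    else:
        start, start_truncated = left_stop + 1, True

    right_stop = seq.find("*", sp_end)
    if right_stop >= 0:
        end, end_truncated = right_stop, False
    else:
        end, end_truncated = len(seq), True

    return PutativeProtein(
        sequence=seq[start:end],
        sp_offset=sp_start - start,
        source_id=pp.source_id,
        frame=pp.frame,
        start_truncated=start_truncated,
        end_truncated=end_truncated,
    )


def _pp_key(pp: PutativePeptide) -> tuple[str, int]:
    return (pp.source_id, pp.frame)


def select_leading_sp(hits: Iterable[SPHit], ec: str) -> SPRecord:
    """The marker of the given EC hitting the most distinct putative peptides.

    Ties are broken lexicographically by peptide for determinism.
    """
    pps_per_sp: dict[SPRecord, set[tuple[str, int]]] = defaultdict(set)
    for h in hits:
        if h.sp.ec == ec:
            pps_per_sp[h.sp].add(_pp_key(h.pp))
    if not pps_per_sp:
        raise LookupError(f"no hits recorded for EC {ec}")
    return min(pps_per_sp, key=lambda sp: (-len(pps_per_sp[sp]), sp.peptide))


def group_by_sp(hits: Iterable[SPHit]) -> Mapping[SPRecord, list[AnchoredSequence]]:
    """Group hit sequences by marker, anchored at the hit offset.

    Each group's sequences carry ``anchor = hit offset`` so they share
    the marker coordinate system.  All groups are retained; when
    counting one EC, use only the leading marker's group (see
    :func:`select_leading_sp`) to avoid counting one gene through
    several markers.
    """
    groups: dict[SPRecord, list[AnchoredSequence]] = defaultdict(list)
    for h in hits:
        sid = f"{h.pp.source_id}|{h.pp.frame:+d}"
        groups[h.sp].append(
            AnchoredSequence(id=sid, sequence=h.pp.sequence, anchor=h.offset)
        )
    return dict(groups)


def search_reads(
    reads: Iterable[tuple[str, str]], table: SPTable
) -> list[SPHit]:
    """Six-frame translate every read and collect all marker hits."""
    hits: list[SPHit] = []
    for rid, nt in reads:
        for pp in six_frame_translate(nt, source_id=rid):
            hits.extend(find_sp_hits(pp, table))
    return hits
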