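"""Ground-truthed synthetic inputs for every pipeline stage.

Generates families of source proteins that share one planted marker
peptide but are mutually distinguishable, amino-acid or nucleotide
reads covering the marker, and annotated toy genomes with
genic/intergenic partitions -- all seeded and reproducible, so the
whole pipeline can be exercised without external data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_formats import AA_ALPHABET, RegionAnnotation, RegionInterval, SPRecord
from .taxa_count import AnchoredSequence

logger = logging.getLogger(__name__)

_RESIDUES = sorted(AA_ALPHABET)

_TABLE = unambiguous_dna_by_id[1]
#: amino acid -> synonymous codons (standard code)
CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    CODONS.setdefault(aa, []).append(codon)
STOP_CODONS = sorted(_TABLE.stop_codons)


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    taxon_id: str
    start: int  # residue span on the source protein, half-open
    end: int
    sequence: str  # amino acids
    nt: str | None = None  # nucleotide rendering, when requested


@dataclass
class SyntheticTruth:
    """Everything needed to verify a synthetic run end to end."""

    sp: SPRecord
    taxa_proteins: list[tuple[str, str, int]]  # (taxon id, protein, sp offset)
    pair_distances: dict[tuple[str, str], int] = field(default_factory=dict)
    reads: list[SimulatedRead] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.taxa_proteins)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _random_protein(
    length: int, rng: np.random.Generator, forbid: str
) -> list[str]:
    """Random residue list of the given length avoiding the ``forbid`` word."""
    while True:
        seq = [_RESIDUES[i] for i in rng.integers(len(_RESIDUES), size=length)]
        if forbid not in "".join(seq):
            return seq


def simulate_taxa_proteins(
    K: int,
    sp: SPRecord,
    protein_length: int,
    min_pair_distance: int,
    near_sp_fraction: float = 0.8,
    seed: int = 0,
    near_radius: int = 25,
    distinct_flanks: bool = True,
    max_attempts: int = 200,
) -> SyntheticTruth:
    """K source proteins sharing one planted marker, pairwise distinguishable.

    Every protein carries ``sp`` exactly once, at a common offset.  Any
    two proteins differ at ``>= min_pair_distance`` positions, of which
    at least ``near_sp_fraction`` lie within ``near_radius`` residues of
    the marker span (so that short reads covering the marker can tell
    taxa apart).  With ``distinct_flanks`` (honoured for ``K <= 20``)
    the residues immediately flanking the marker are distinct across all
    taxa, guaranteeing that any read extending past the marker on either
    side is informative.  Constraints are enforced by rejection
    sampling.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    free = protein_length - sp.length
    if protein_length <= sp.length:
        raise ValueError(
            f"protein_length {protein_length} must exceed marker length {sp.length}"
        )
    if min_pair_distance > free:
        raise ValueError(
            f"min_pair_distance {min_pair_distance} infeasible for "
            f"{free} non-marker positions"
        )
    if not 0.0 <= near_sp_fraction <= 1.0:
        raise ValueError("near_sp_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sp_offset = (protein_length - sp.length) // 2

    non_sp = [
        i for i in range(protein_length)
        if not sp_offset <= i < sp_offset + sp.length
    ]
    near = [i for i in non_sp if -near_radius <= i - sp_offset < sp.length + near_radius]
    far = [i for i in non_sp if i not in set(near)]

    flanks = []
    if distinct_flanks and K <= len(_RESIDUES):
        flanks = [
            i for i in (sp_offset - 1, sp_offset + sp.length)
            if 0 <= i < protein_length
        ]

    # enough variable positions that random assignments clear the distance bar
    n_var = min(len(non_sp), max(min_pair_distance + 3, int(min_pair_distance / 0.85) + 1))
    n_near = min(len(near), max(int(np.ceil(near_sp_fraction * n_var)), len(flanks)))
    n_far = min(len(far), n_var - n_near)

    for attempt in range(max_attempts):
        base = _random_protein(protein_length, rng, forbid=sp.peptide)
        base[sp_offset : sp_offset + sp.length] = list(sp.peptide)

        near_pool = [i for i in near if i not in flanks]
        chosen_near = list(flanks) + [
            near_pool[i]
            for i in rng.choice(
                len(near_pool), size=max(n_near - len(flanks), 0), replace=False
            )
        ]
        chosen_far = [
            far[i] for i in rng.choice(len(far), size=n_far, replace=False)
        ] if n_far else []
        variable = chosen_near + chosen_far

        flank_residues = {
            i: rng.permutation(_RESIDUES)[:K] for i in flanks
        }
        proteins = []
        for t in range(K):
            prot = list(base)
            for i in variable:
                if i in flank_residues:
                    prot[i] = str(flank_residues[i][t])
                else:
                    prot[i] = _RESIDUES[rng.integers(len(_RESIDUES))]
            proteins.append("".join(prot))

        if any(p.count(sp.peptide) != 1 for p in proteins):
            continue
        ids = [f"taxon{t + 1}" for t in range(K)]
        dists = {
            (ids[i], ids[j]): _hamming(proteins[i], proteins[j])
            for i, j in itertools.combinations(range(K), 2)
        }
        if K > 1 and min(dists.values()) < min_pair_distance:
            continue
        return SyntheticTruth(
            sp=sp,
            taxa_proteins=[
                (ids[t], proteins[t], sp_offset) for t in range(K)
            ],
            pair_distances=dists,
            parameters={
                "K": K,
                "protein_length": protein_length,
                "min_pair_distance": min_pair_distance,
                "near_sp_fraction": near_sp_fraction,
                "near_radius": near_radius,
                "seed": seed,
                "attempts": attempt + 1,
            },
        )
    raise RuntimeError(
        f"could not satisfy constraints in {max_attempts} attempts; "
        "loosen min_pair_distance or enlarge the protein"
    )


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Render a protein as DNA through uniformly chosen synonymous codons."""
    return "".join(
        CODONS[aa][rng.integers(len(CODONS[aa]))] for aa in protein
    )


def simulate_reads(
    truth: SyntheticTruth,
    read_length: int,
    coverage: int,
    require_sp: bool = True,
    nucleotide: bool = False,
    seed: int = 0,
    interior_sp: bool = False,
) -> list[SimulatedRead]:
    """Draw ``coverage`` reads per taxon with uniform start positions.

    With ``require_sp`` the start window is restricted so every read
    contains the full marker; ``interior_sp`` additionally keeps the
    marker strictly away from the read edges, so each read covers both
    flanking residues.  With ``nucleotide`` reads are reverse-translated
    through uniform synonymous codons and emitted on a random strand
    (six-frame translation recovers the amino-acid read in exactly one
    frame).  Reads are recorded on ``truth.reads`` as well as returned.
    """
    sp_len = truth.sp.length
    if require_sp and read_length < sp_len:
        raise ValueError("read_length below marker length with require_sp")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for taxon_id, protein, sp_offset in truth.taxa_proteins:
        if read_length > len(protein):
            raise ValueError("read_length exceeds protein length")
        lo, hi = 0, len(protein) - read_length
        if require_sp:
            lo = max(lo, sp_offset + sp_len - read_length)
            hi = min(hi, sp_offset)
            if interior_sp:
                lo = max(lo, sp_offset + sp_len - read_length + 1)
                hi = min(hi, sp_offset - 1)
        if hi < lo:
            raise ValueError("no admissible read start positions")
        for i in range(coverage):
            start = int(rng.integers(lo, hi + 1))
            aa = protein[start : start + read_length]
            nt = None
            if nucleotide:
                nt = reverse_translate(aa, rng)
                if rng.random() < 0.5:
                    nt = _revcomp(nt)
            reads.append(
                SimulatedRead(
                    id=f"{taxon_id}_r{i + 1}",
                    taxon_id=taxon_id,
                    start=start,
                    end=start + read_length,
                    sequence=aa,
                    nt=nt,
                )
            )
    truth.reads.extend(reads)
    return reads


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def anchored_reads(
    truth: SyntheticTruth, reads: Iterable[SimulatedRead] | None = None
) -> list[AnchoredSequence]:
    """Convert marker-covering reads into anchored sequences."""
    sp_len = truth.sp.length
    offsets = {tid: off for tid, _, off in truth.taxa_proteins}
    out = []
    for r in truth.reads if reads is None else reads:
        sp_offset = offsets[r.taxon_id]
        if not (r.start <= sp_offset and sp_offset + sp_len <= r.end):
            continue
        out.append(
            AnchoredSequence(
                id=r.id, sequence=r.sequence, anchor=sp_offset - r.start
            )
        )
    return out


def simulate_annotated_genome(
    genes: Sequence[tuple[str, str]],
    spacer_length: int,
    seed: int = 0,
    seq_id: str = "genome",
) -> tuple[str, RegionAnnotation]:
    """Toy genome: reverse-translated genes separated by random spacers.

    Each gene is the protein's codons followed by a stop codon; spacers
    of ``spacer_length`` random nucleotides surround the genes (n+1
    spacers for n genes).  The annotation records genic intervals with
    their EC labels and the spacers as intergenic.
    """
    if spacer_length < 0:
        raise ValueError("spacer_length must be >= 0")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    intervals: list[RegionInterval] = []
    pos = 0

    def add_spacer() -> None:
        nonlocal pos
        if spacer_length == 0:
            return
        spacer = "".join("ACGT"[i] for i in rng.integers(4, size=spacer_length))
        parts.append(spacer)
        intervals.append(
            RegionInterval(seq_id, pos, pos + spacer_length, "intergenic")
        )
        pos += spacer_length

    add_spacer()
    for protein, ec in genes:
        nt = reverse_translate(protein, rng) + STOP_CODONS[
            rng.integers(len(STOP_CODONS))
        ]
        parts.append(nt)
        intervals.append(RegionInterval(seq_id, pos, pos + len(nt), "genic", ec))
        pos += len(nt)
        add_spacer()
    return "".join(parts), RegionAnnotation(intervals=intervals)


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    """Machine-readable truth file: taxa, marker, reads and parameters."""
    with open(path, "w") as fh:
        fh.write(f"# sp\t{truth.sp.peptide}\t{truth.sp.ec}\n")
        for key, value in sorted(truth.parameters.items()):
            fh.write(f"# param\t{key}\t{value}\n")
        fh.write("# taxon_id\tprotein\tsp_offset\n")
        for tid, protein, off in truth.taxa_proteins:
            fh.write(f"T\t{tid}\t{protein}\t{off}\n")
        fh.write("# read_id\ttaxon_id\tstart\tend\n")
        for r in truth.reads:
            fh.write(f"R\t{r.id}\t{r.taxon_id}\t{r.start}\t{r.end}\n")
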