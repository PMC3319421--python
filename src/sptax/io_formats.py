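"""Readers and writers for the external formats used by the toolkit.

Formats: FASTA/FASTQ sequence files (via Biopython), the two-column
marker-peptide table (TSV: peptide, EC number), genic/intergenic region
annotations (GFF3 or 4-column BED), count report TSVs and plain
``key=value`` configuration files.  All coordinates are 0-based
half-open internally; GFF input is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: columns of the count report, in canonical order
REPORT_COLUMNS = ("sp", "d", "count", "sample_size", "trials", "mean_count", "sem")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SPRecord:
    """A marker peptide with its EC assignment."""

    peptide: str
    ec: str

    def __post_init__(self) -> None:
        bad = set(self.peptide) - AA_ALPHABET
        if bad:
            raise ParseError(
                f"peptide {self.peptide!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )
        if len(self.peptide) < 7:
            raise ParseError(
                f"peptide {self.peptide!r} shorter than the minimum marker "
                "length of 7 residues"
            )

    @property
    def length(self) -> int:
        return len(self.peptide)


@dataclass
class SPTable:
    """Look-up table of marker peptides, filtered at a length threshold."""

    records: list[SPRecord]
    min_length: int = 9

    def __post_init__(self) -> None:
        peptides = [r.peptide for r in self.records]
        if len(set(peptides)) != len(peptides):
            raise ValueError("duplicate peptides in marker table")
        short = [r for r in self.records if r.length < self.min_length]
        if short:
            raise ValueError(
                f"{len(short)} records below min_length={self.min_length}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_ec(self, ec: str) -> list[SPRecord]:
        return [r for r in self.records if r.ec == ec]


@dataclass(frozen=True)
class RegionInterval:
    seq_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    region_class: str  # "genic" | "intergenic"
    ec: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")
        if self.region_class not in ("genic", "intergenic"):
            raise ValueError(f"unknown region class {self.region_class!r}")


@dataclass
class RegionAnnotation:
    """Genic/intergenic partition of one or more nucleotide sequences."""

    intervals: list[RegionInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_key: dict[tuple[str, str], list[RegionInterval]] = {}
        for iv in self.intervals:
            by_key.setdefault((iv.seq_id, iv.region_class), []).append(iv)
        for (seq_id, cls), ivs in by_key.items():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            for prev, nxt in zip(ivs, ivs[1:]):
                if nxt.start < prev.end:
                    raise ValueError(
                        f"overlapping {cls} intervals on {seq_id}: "
                        f"{prev.start}..{prev.end} and {nxt.start}..{nxt.end}"
                    )

    def total_length(self, region_class: str) -> int:
        return sum(
            iv.end - iv.start
            for iv in self.intervals
            if iv.region_class == region_class
        )

    @property
    def genic_length(self) -> int:
        return self.total_length("genic")

    @property
    def intergenic_length(self) -> int:
        return self.total_length("intergenic")

    def overlapping(self, seq_id: str, start: int, end: int) -> list[RegionInterval]:
        return [
            iv
            for iv in self.intervals
            if iv.seq_id == seq_id and iv.start < end and start < iv.end
        ]


def read_sequences(
    path: str | Path, format: str = "fasta", protein: bool = False
) -> list[tuple[str, str]]:
    """Read a FASTA/FASTQ file into ``(id, sequence)`` pairs.

    Sequences are uppercased.  With ``protein=True`` the rare residues
    ``U``/``O`` are mapped to ``X`` to tolerate real-world dialects.
    Duplicate ids and malformed records raise :class:`ParseError`.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    n = 0
    try:
        for rec in SeqIO.parse(str(path), format):
            n += 1
            if rec.id in seen:
                raise ParseError(f"duplicate record id {rec.id!r} (record {n})")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if protein:
                seq = seq.replace("U", "X").replace("O", "X")
            out.append((rec.id, seq))
    except ParseError:
        raise
    except ValueError as exc:
        raise ParseError(f"malformed {format} record {n + 1}: {exc}") from exc
    if not out:
        logger.warning("no records parsed from %s", path)
    return out


def write_sequences(
    records: Iterable[tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_sp_table(path: str | Path, min_length: int = 9) -> SPTable:
    """Load the marker table (TSV: peptide, EC; ``#`` comments allowed).

    Records shorter than ``min_length`` are dropped (count logged); a
    duplicated peptide keeps its first EC assignment with a warning.
    """
    records: list[SPRecord] = []
    seen: set[str] = set()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected two columns (peptide, EC)"
                )
            peptide, ec = parts[0].upper(), parts[1]
            try:
                rec = SPRecord(peptide=peptide, ec=ec)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if rec.length < min_length:
                dropped += 1
                continue
            if rec.peptide in seen:
                logger.warning(
                    "%s:%d: duplicate peptide %s, keeping first occurrence",
                    path, lineno, rec.peptide,
                )
                continue
            seen.add(rec.peptide)
            records.append(rec)
    if dropped:
        logger.info(
            "dropped %d marker(s) shorter than %d residues", dropped, min_length
        )
    return SPTable(records=records, min_length=min_length)


def write_sp_table(table: SPTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# peptide\tec\n")
        for rec in table:
            fh.write(f"{rec.peptide}\t{rec.ec}\n")


def read_region_annotation(path: str | Path) -> RegionAnnotation:
    """Read a GFF3 or 4-column BED genic/intergenic annotation.

    GFF3 rows with feature type ``gene``/``CDS``/``mRNA`` are genic (an
    ``ec=...`` attribute is honoured); types containing ``intergenic``
    are intergenic.  BED names are ``genic[:EC]`` or ``intergenic``.
    """
    text = Path(path).read_text().splitlines()
    is_gff = any(ln.startswith("##gff-version") for ln in text) or any(
        len(ln.split("\t")) == 9 for ln in text if ln and not ln.startswith("#")
    )
    intervals: list[RegionInterval] = []
    for lineno, ln in enumerate(text, 1):
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if is_gff:
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns")
            seq_id, _, ftype, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            if ftype.lower() in ("gene", "cds", "mrna"):
                cls, ec = "genic", attrs.get("ec")
            elif "intergenic" in ftype.lower():
                cls, ec = "intergenic", None
            else:
                continue
            intervals.append(
                RegionInterval(seq_id, int(start) - 1, int(end), cls, ec)
            )
        else:
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 BED columns")
            seq_id, start, end, name = cols[0], cols[1], cols[2], cols[3]
            if name.startswith("genic"):
                cls = "genic"
                ec = name.split(":", 1)[1] if ":" in name else None
            elif name.startswith("intergenic"):
                cls, ec = "intergenic", None
            else:
                raise ParseError(f"{path}:{lineno}: unknown region name {name!r}")
            intervals.append(RegionInterval(seq_id, int(start), int(end), cls, ec))
    return RegionAnnotation(intervals=intervals)


def write_region_annotation(annotation: RegionAnnotation, path: str | Path) -> None:
    """Write an annotation as 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in annotation.intervals:
            name = iv.region_class
            if iv.ec:
                name = f"{name}:{iv.ec}"
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\n")


def write_count_report(results: Iterable[Mapping], path: str | Path) -> None:
    """Write counting outputs as a TSV with a deterministic column order.

    ``results`` is an iterable of mappings; recognised keys are the
    :data:`REPORT_COLUMNS` plus arbitrary extras (appended in sorted
    order).  An empty iterable yields a header-only file.
    """
    rows = list(results)
    extra = sorted({k for r in rows for k in r} - set(REPORT_COLUMNS))
    columns = [*REPORT_COLUMNS, *extra]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_count_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_anchored_tsv(path: str | Path):
    """Read anchored sequences from a 3-column TSV (id, sequence, anchor)."""
    from .taxa_count import AnchoredSequence

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected id, sequence, anchor"
                )
            out.append(
                AnchoredSequence(
                    id=parts[0], sequence=parts[1].upper(), anchor=int(parts[2])
                )
            )
    return out


def write_anchored_tsv(seqs, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tsequence\tanchor\n")
        for s in seqs:
            fh.write(f"{s.id}\t{s.sequence}\t{s.anchor}\n")


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a ``key=value`` configuration file mirroring the CLI flags."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
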