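"""Bundled miniature example data.

Fourteen translated metagenomic short reads that all carry the marker
peptide ``FYALPQAPQ`` (aspartyl-tRNA synthetase family, EC 6.1.1.12).
This tiny group exercises every stage of the counting pipeline: eight
of the reads are mutually inconsistent with everything else, and the
remaining six collapse into two fused strings, for a lower bound of ten
taxa.
"""

from __future__ import annotations

from .io_formats import SPRecord
from .taxa_count import AnchoredSequence

EXAMPLE_SP = SPRecord(peptide="FYALPQAPQ", ec="6.1.1.12")

#: id -> translated short read (all contain EXAMPLE_SP exactly once)
EXAMPLE_READS: dict[str, str] = {
    "1": "ILTSSSPEGARDFLVPSRLNPGKFYALPQAPQQFKQLI",
    "2": "VFFSFLLGFTKGKFYALPQAPQTILSNLFMVSGFDKYFTNC",
    "3": "PSRLNPGKFYALPQAPQQFKQLIMVSGFDRYFQIAPCFR",
    "4": "DFLVPSRLHKGKFYALPQAPQQFKQLVMVSGFDKYFQI",
    "5": "RFFSSFLGLHKGKFYALPQAPQQFKLTCHGIRVILSN",
    "6": "GARDFLVPSRLNPGKFYALPQAPQQFKQLIMVSGFD",
    "7": "ARDFLVPSRLNPGKFYALPQAPQQFKQLVMVSGFDRYFQI",
    "8": "DFLVPSRLNPGKFYALPQAPQQFKQLIMVSGFDKYFQIA",
    "9": "DFLVPSRLHKGKFYALPQAPQQFKQLVMVSGFDKYFQL",
    "10": "SRLNPGKFYALPQAPQQFKQLIMVSGFDRYFQIAPCF",
    "11": "YFLVPSRLHKGKFYALPQAPQQFKLTCHGIRVILSNC",
    "12": "QAGCGLYCSKQIKSWKFYALPQAPQQFKQLIMI",
    "13": "LNPGKFYALPQAPQQFKQLIMVSGFDRYFQIAPCFR",
    "14": "SFKSRKFYALPQAPQQFKQLIMVSGFDRYFQIAPCFG",
}


def example_anchored_reads() -> list[AnchoredSequence]:
    """The example reads anchored at their unique marker occurrence."""
    out = []
    for rid, seq in EXAMPLE_READS.items():
        anchor = seq.find(EXAMPLE_SP.peptide)
        if anchor < 0 or seq.find(EXAMPLE_SP.peptide, anchor + 1) >= 0:
            raise AssertionError(f"read {rid} must carry the marker exactly once")
        out.append(AnchoredSequence(id=rid, sequence=seq, anchor=anchor))
    return out
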