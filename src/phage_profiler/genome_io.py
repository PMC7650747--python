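"""Reading, writing and summarising phage genome sequences.

This module owns the per-genome features that go into the characterisation
summary: genome length, GC content, a simple six-frame ORF scan, and the
termini / lifestyle annotations attached by the other modules.  The ORF
scan is deliberately minimal (no gene model, no RBS scoring) and is *not*
a replacement for a real gene caller; it exists so that downstream tables
have an ORF-count column computed by a documented, reproducible rule.
"""

from __future__ import annotations

import io
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate_sequence(sequence: str, name: str = "sequence") -> str:
    seq = sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{name} contains invalid characters: {sorted(bad)!r}")
    return seq


@dataclass
class PhageGenomeRecord:
    """One phage genome plus its computed features.

    ``termini_class`` and ``lifestyle_flag`` default to ``"unknown"`` until
    the corresponding analysis has been run.  ``truth_cluster`` carries the
    planted label for synthetic genomes and is ``None`` for real data.
    """

    id: str
    sequence: str
    termini_class: str = "unknown"
    lifestyle_flag: str = "unknown"
    orf_count: int | None = None
    truth_cluster: str | None = None

    def __post_init__(self) -> None:
        self.sequence = _validate_sequence(self.sequence, self.id)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_content(self.sequence)


def gc_content(sequence: str) -> float:
    """Percent G+C of a DNA sequence; N bases are ignored entirely.

    Raises ``ValueError`` for an empty or all-N sequence, where GC content
    is undefined.
    """
    seq = _validate_sequence(sequence)
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("GC content undefined for empty or all-N sequence")
    return 100.0 * gc / (gc + at)


def find_orfs(
    sequence: str,
    min_length_nt: int = 300,
    genetic_code: int = 11,
) -> list[tuple[int, int, str, int]]:
    """Scan both strands for open reading frames.

    An ORF runs from the most upstream in-frame start codon (ATG/GTG/TTG,
    bacterial code 11) to the next in-frame stop codon, stop included, on a
    linear sequence.  Returns ``(start, end, strand, frame)`` tuples with
    0-based half-open coordinates on the forward strand; minus-strand ORFs
    are reported in forward coordinates (mirror image).  Overlapping ORFs
    are all reported.
    """
    if genetic_code != 11:
        raise ValueError(f"unsupported genetic code: {genetic_code}")
    if min_length_nt < 6 or min_length_nt % 3 != 0:
        raise ValueError("min_length_nt must be >= 6 and a multiple of 3")
    seq = _validate_sequence(sequence)
    n = len(seq)
    orfs: list[tuple[int, int, str, int]] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            start: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start is not None and pos + 3 - start >= min_length_nt:
                        a, b = start, pos + 3
                        if strand == "-":
                            a, b = n - b, n - a
                        orfs.append((a, b, strand, frame))
                    start = None
                elif start is None and codon in START_CODONS:
                    start = pos
    orfs.sort()
    return orfs


def read_fasta(path: str | Path) -> list[PhageGenomeRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(PhageGenomeRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[PhageGenomeRecord], path: str | Path) -> None:
    """Write multi-FASTA wrapped at 70 columns."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=70)
        writer.write_file(seqrecords)


def _round_kb(length_bp: int) -> int:
    # round-half-up to nearest kb, avoiding banker's rounding
    return int((length_bp + 500) // 1000)


def summary_table(records: Sequence[PhageGenomeRecord]) -> pd.DataFrame:
    """Per-genome feature table: size (kb), GC %, ORF count, termini, lifestyle.

    Rows are sorted by genome id; features that have not been computed are
    reported as the string ``"unknown"``, never left empty.
    """
    if not records:
        raise ValueError("summary_table requires at least one record")
    rows = []
    for rec in sorted(records, key=lambda r: r.id):
        rows.append(
            {
                "genome_id": rec.id,
                "genome_size_kb": _round_kb(rec.length_bp),
                "gc_percent": round(rec.gc_percent, 1),
                "orf_count": rec.orf_count if rec.orf_count is not None else "unknown",
                "termini_class": rec.termini_class or "unknown",
                "lifestyle_flag": rec.lifestyle_flag or "unknown",
            }
        )
    return pd.DataFrame(rows)


def write_summary_tsv(records: Sequence[PhageGenomeRecord], path: str | Path) -> None:
    summary_table(records).to_csv(path, sep="\t", index=False)


_EFETCH_URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


def fetch_genbank(accession: str, timeout: float = 30.0) -> PhageGenomeRecord:
    """Fetch a nucleotide record from GenBank (sequence only).

    Used for accession-based feature checks against published genomes;
    requires network access to NCBI e-utilities.
    """
    if not re.fullmatch(r"[A-Za-z0-9_.]+", accession):
        raise ValueError(f"malformed accession: {accession!r}")
    url = _EFETCH_URL.format(acc=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    recs = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not recs:
        raise ValueError(f"no FASTA record returned for {accession}")
    return PhageGenomeRecord(id=accession, sequence=str(recs[0].seq))
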