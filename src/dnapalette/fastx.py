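"""FASTA/FASTQ reading and writing (Biopython-backed).

Record ids carry no information in this codec — pools are unordered sets — so
readers return bare sequences, upper-cased, and reject non-ACGT symbols.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

_VALID = set("ACGT")

POOL_HEADER_COMMENT = (
    "record ids are sequential for human convenience only and carry no "
    "information; the decoder never reads them"
)


def _validate(seq: str, record_no: int, path) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ParseError(
            f"{path}: record {record_no} contains non-ACGT symbol {sorted(bad)[0]!r}"
        )
    return seq


def read_fasta(path: str | Path) -> list[str]:
    """Sequences of a FASTA file (ids ignored, wrapping tolerated)."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}")
    return [_validate(str(r.seq), i + 1, path) for i, r in enumerate(records)]


def read_fastq(path: str | Path) -> list[str]:
    """Sequences of a FASTQ file; qualities are discarded."""
    try:
        records = list(SeqIO.parse(str(path), "fastq"))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}")
    return [_validate(str(r.seq), i + 1, path) for i, r in enumerate(records)]


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ, sniffing the format."""
    p = Path(path)
    if p.suffix.lower() in {".fq", ".fastq"}:
        return read_fastq(p)
    if p.suffix.lower() in {".fa", ".fasta", ".fna"}:
        return read_fasta(p)
    with open(p) as fh:
        first = fh.read(1)
    return read_fastq(p) if first == "@" else read_fasta(p)


def write_fasta(sequences: list[str], path: str | Path, prefix: str = "oligo") -> None:
    records = [
        SeqRecord(
            Seq(s),
            id=f"{prefix}_{i + 1:06d}",
            description=POOL_HEADER_COMMENT if i == 0 else "",
        )
        for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(sequences: list[str], path: str | Path, prefix: str = "read") -> None:
    """Write reads with uniform dummy qualities."""
    records = []
    for i, s in enumerate(sequences):
        r = SeqRecord(Seq(s), id=f"{prefix}_{i + 1:06d}", description="")
        r.letter_annotations["phred_quality"] = [40] * len(s)
        records.append(r)
    SeqIO.write(records, str(path), "fastq")
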