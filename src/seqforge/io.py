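"""Sequence and table I/O: strict FASTA/FASTQ reading, deterministic CSV
writing, and the packaged fixtures."""

from __future__ import annotations

import gzip
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_sequences",
    "write_sequences",
    "write_tables",
    "packaged_oligo",
    "SequenceFormatError",
]

_VALID_ALPHABET = set("ACGTNacgtn")


class SequenceFormatError(ValueError):
    """Malformed sequence record, annotated with its position in the file."""


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _guess_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".fastq", ".fq") for s in suffixes):
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path) -> list[SeqRecord]:
    """Read FASTA/FASTQ (gz-transparent) with strict nucleotide validation.

    An empty file yields an empty list; any record containing symbols outside
    ACGTN raises SequenceFormatError naming the record.
    """
    path = Path(path)
    fmt = _guess_format(path)
    records = []
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, fmt)):
            bad = set(str(rec.seq)) - _VALID_ALPHABET
            if bad:
                raise SequenceFormatError(
                    f"record {i} ({rec.id!r}): invalid symbols {sorted(bad)}"
                )
            records.append(rec)
    return records


def write_sequences(records, path: str | Path, wrap: int = 60) -> None:
    """Write FASTA (60-column wrap) or FASTQ depending on the file suffix."""
    path = Path(path)
    fmt = _guess_format(path)
    recs = [r if isinstance(r, SeqRecord) else SeqRecord(Seq(r), id=f"seq_{i}", description="")
            for i, r in enumerate(records)]
    if fmt == "fasta":
        writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
        writer.write_file(recs)
    else:
        SeqIO.write(recs, str(path), "fastq")


def write_tables(results: pd.DataFrame, path: str | Path,
                 columns: list[str] | None = None) -> None:
    """Write a result table as CSV with a deterministic column order."""
    df = pd.DataFrame(results)
    if columns is not None:
        df = df[columns]
    df.to_csv(path, index=False)


def packaged_oligo() -> SeqRecord:
    """The packaged assembled 321-nt degenerate library gene."""
    path = resources.files("seqforge").joinpath("data/library_oligo.fasta")
    with path.open() as fh:
        return next(SeqIO.parse(fh, "fasta"))
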