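"""Readers and writers for the formats the workflow touches.

Reads are handled as ``(read_id, sequence, quality)`` tuples with Sanger
Phred+33 qualities.  Gzip-compressed inputs/outputs are handled
transparently by filename (``.gz``).  Malformed records raise with the
record index so the offending line can be found.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import TerminatorVariant

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_library_fasta",
    "write_library_manifest",
    "write_tsv",
    "read_tsv",
]


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream FASTQ records; validates record framing and length
    consistency, reporting the failing record index."""
    with _open_text(path, "r") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"truncated FASTQ record at index {idx}")
            header, seq, plus, qual = (
                header.rstrip("\n"), seq.rstrip("\n"), plus.rstrip("\n"),
                qual.rstrip("\n"),
            )
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at index {idx}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"FASTQ record at index {idx}: sequence and quality "
                    f"lengths differ ({len(seq)} vs {len(qual)})"
                )
            yield header[1:].split()[0], seq, qual
            idx += 1


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> int:
    """Write reads as FASTQ (Phred+33); returns the record count."""
    n = 0
    with _open_text(path, "w") as fh:
        for read_id, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {n} ({read_id}): sequence and quality lengths differ"
                )
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path) -> list[tuple[str, str]]:
    with _open_text(path, "r") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> int:
    n = 0
    with _open_text(path, "w") as fh:
        for rec_id, seq in records:
            SeqIO.write(SeqRecord(Seq(seq), id=rec_id, description=""), fh, "fasta")
            n += 1
    return n


def write_library_fasta(variants: Sequence[TerminatorVariant], path) -> int:
    """One record per variant; the description carries the stem and the
    orientation loop."""
    n = 0
    with _open_text(path, "w") as fh:
        for v in variants:
            rec = SeqRecord(
                Seq(v.forward_seq),
                id=v.variant_id,
                description=f"stem={v.stem_5arm} loop={v.orientation_loop}",
            )
            SeqIO.write(rec, fh, "fasta")
            n += 1
    return n


def write_library_manifest(variants: Sequence[TerminatorVariant], path) -> None:
    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "stem_5arm": [v.stem_5arm for v in variants],
            "forward_seq": [v.forward_seq for v in variants],
            "reverse_seq": [v.reverse_seq for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
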