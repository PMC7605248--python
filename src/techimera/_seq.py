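"""Small sequence helpers shared across modules.

FASTA parsing goes through Biopython; FASTQ reading uses Biopython's fast
general iterator. FASTQ writing is done with plain text writes (one record is
four fixed lines) because the simulators emit hundreds of thousands of reads.
"""
from __future__ import annotations

import gzip
import io
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _open_maybe_gzip(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # empty filename + mtime=0 keep gzip output byte-identical
            raw = open(path, "wb")
            return io.TextIOWrapper(
                gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0)
            )
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, mode if "b" not in mode else mode)


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (name, seq, qual) triples as FASTQ (gzip if path ends .gz)."""
    with _open_maybe_gzip(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    with _open_maybe_gzip(path, "r") as fh:
        yield from FastqGeneralIterator(fh)


def read_fastq_pairs(path1, path2) -> Iterator[tuple[str, str, str]]:
    """Yield (name, seq1, seq2) from a pair of FASTQ files.

    Names are taken from file 1 with any trailing /1 stripped.
    """
    for (n1, s1, _), (_, s2, _) in zip(read_fastq(path1), read_fastq(path2)):
        name = n1.split()[0]
        if name.endswith("/1"):
            name = name[:-2]
        yield name, s1, s2
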