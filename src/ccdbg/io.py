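"""Sequence I/O and the tab-separated mapping output format.

FASTA/FASTQ (optionally gzip-compressed) go through Biopython's SeqIO.
A *file-of-files* input is a plain text file with one FASTA path per line;
the line order defines reference ids.
"""

from __future__ import annotations

import gzip
from pathlib import Path

from Bio import SeqIO


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a (possibly gzipped) multi-FASTA; names are headers up to the
    first whitespace."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def read_fastq(path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def read_queries(path) -> list[tuple[str, str]]:
    """Reads in FASTA or FASTQ, sniffed from the first character."""
    with _open_text(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


def load_references(path) -> list[tuple[str, str]]:
    """Load references from a multi-FASTA or a file-of-files listing FASTAs."""
    path = Path(path)
    with _open_text(path) as fh:
        head = fh.readline()
    if head.startswith(">"):
        return read_fasta(path)
    refs = []
    base = path.parent
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fp = Path(line)
            if not fp.is_absolute():
                fp = base / fp
            refs.extend(read_fasta(fp))
    return refs


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_fastq(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def format_result(result) -> str:
    """One mapping line: read name, tab, space-separated 0-based ref ids."""
    return f"{result.name}\t{' '.join(str(r - 1) for r in result.refs)}"


def write_mapping(path, results, header: dict) -> None:
    """TSV mapping file with '#' header lines recording the run config."""
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        for r in results:
            fh.write(format_result(r) + "\n")
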