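"""FASTA/FASTQ/BED/TSV input and output (Biopython-backed, gzip transparent)."""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import ReadSet

logger = logging.getLogger("repeatscape")


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered dict id -> uppercased sequence.

    Wrapped or unwrapped lines accepted; duplicate ids raise with the
    offending names; an empty file yields an empty dict with a warning.
    """
    records: dict[str, str] = {}
    dupes = []
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                dupes.append(rec.id)
            records[rec.id] = str(rec.seq).upper()
    if dupes:
        raise ValueError(f"duplicate FASTA ids: {', '.join(sorted(set(dupes)))}")
    if not records:
        logger.warning("empty FASTA file: %s", path)
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> tuple[list[str], list[str], list[str]]:
    """FASTQ -> (ids, sequences, qualities); sequences uppercased.

    Truncated or inconsistent records raise with the record position.
    """
    ids: list[str] = []
    seqs: list[str] = []
    quals: list[str] = []
    with _open_text(path, "r") as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(
            f"{path}: truncated FASTQ record starting at line {len(lines) - len(lines) % 4 + 1}"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed record at line {i + 1}")
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}: sequence/quality length mismatch for record "
                f"{header[1:].split()[0]!r} at line {i + 1}"
            )
        ids.append(header[1:].split()[0])
        seqs.append(seq.upper())
        quals.append(qual)
    if not ids:
        logger.warning("empty FASTQ file: %s", path)
    return ids, seqs, quals


def fastq_to_readset(path, coverage: float = 0.0, seed: int = 0) -> ReadSet:
    ids, seqs, _ = read_fastq(path)
    read_length = max((len(s) for s in seqs), default=0)
    return ReadSet(
        sequences=seqs, read_length=read_length, coverage=coverage, seed=seed, ids=ids
    )


def write_fastq(reads, path, quality_char: str = "I") -> None:
    """Write a ReadSet (constant placeholder quality) or (ids, seqs, quals)."""
    if isinstance(reads, ReadSet):
        ids = reads.read_ids()
        seqs = reads.sequences
        quals = [quality_char * len(s) for s in seqs]
    else:
        ids, seqs, quals = reads
    with _open_text(path, "w") as fh:
        for rid, seq, qual in zip(ids, seqs, quals):
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_contigs_fasta(contigs, path) -> None:
    """Contigs to FASTA with the read count in the description."""
    with _open_text(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id} n_reads={c.n_reads}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")


def records_to_seqrecords(records: dict[str, str]) -> list[SeqRecord]:
    return [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()]
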