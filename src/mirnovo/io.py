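"""Readers and writers for the plain-text formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython's ``SeqIO``; this module adds
sequence validation (via :class:`~mirnovo.seq.NucleotideSequence`), error
context, and deterministic writers (fixed field order, ``"\\n"`` endings,
no line wrapping) so that identical inputs always produce byte-identical
files.  Genomic intervals are 1-based inclusive in memory and converted to
BED's 0-based half-open convention only on disk.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO

from .seq import GenomicLocus, NucleotideSequence

Record = Tuple[str, NucleotideSequence]


class FormatError(ValueError):
    """A malformed record, with file and record context."""


def read_fasta(path: str | os.PathLike) -> List[Record]:
    records: List[Record] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description or rec.id
        try:
            records.append((header, NucleotideSequence(str(rec.seq))))
        except ValueError as exc:
            raise FormatError(f"{path}, record {idx} ({header!r}): {exc}") from exc
    return records


def write_fasta(records: Iterable[Record], path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq.bases}\n")


def read_fastq(
    path: str | os.PathLike,
) -> List[Tuple[str, NucleotideSequence, List[int]]]:
    """Read FASTQ records as (id, sequence, Phred qualities).

    Qualities are validated for length agreement by the parser but are not
    used by any downstream stage.
    """
    out = []
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), "fastq"), start=1):
            quals = list(rec.letter_annotations["phred_quality"])
            try:
                seq = NucleotideSequence(str(rec.seq))
            except ValueError as exc:
                raise FormatError(
                    f"{path}, record {idx} ({rec.id!r}): {exc}"
                ) from exc
            out.append((rec.description or rec.id, seq, quals))
    except ValueError as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(
    records: Iterable[Tuple[str, NucleotideSequence, Sequence[int]]],
    path: str | os.PathLike,
) -> None:
    with open(path, "w", newline="\n") as fh:
        for header, seq, quals in records:
            if len(quals) != len(seq):
                raise FormatError(
                    f"record {header!r}: quality length {len(quals)} != "
                    f"sequence length {len(seq)}"
                )
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{header}\n{seq.bases}\n+\n{qline}\n")


# --- BED (0-based half-open on disk) ---

def read_bed(path: str | os.PathLike) -> List[Tuple[str, GenomicLocus]]:
    """Read BED6 (or BED3) lines into named 1-based inclusive loci."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start0, end0 = fields[0], fields[1], fields[2]
            try:
                start = int(start0) + 1
                end = int(end0)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                out.append((name, GenomicLocus(chrom, start, end, strand)))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    loci: Iterable[Tuple[str, GenomicLocus]], path: str | os.PathLike
) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t"
                f"{name or '.'}\t0\t{locus.strand}\n"
            )


# --- Vienna dot-bracket ---

def write_dot_bracket(
    records: Iterable[Tuple[str, NucleotideSequence, str, float]],
    path: str | os.PathLike,
) -> None:
    """Write (id, sequence, structure, MFE) records in Vienna style.

    Sequences are rendered in the RNA alphabet; the energy is appended to
    the structure line as ``( -10.90)``.
    """
    with open(path, "w", newline="\n") as fh:
        for header, seq, structure, mfe in records:
            if len(structure) != len(seq):
                raise FormatError(
                    f"record {header!r}: structure length != sequence length"
                )
            fh.write(f">{header}\n{seq.as_rna()}\n{structure} ({mfe:6.2f})\n")


def read_dot_bracket(
    path: str | os.PathLike,
) -> List[Tuple[str, NucleotideSequence, str, float]]:
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i]:
            i += 1
            continue
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}:{i + 1}: expected '>' header")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}:{i + 1}: truncated record")
        header = lines[i][1:]
        seq = NucleotideSequence(lines[i + 1])
        struct_line = lines[i + 2]
        lpar = struct_line.rfind(" (")
        if lpar == -1 or not struct_line.endswith(")"):
            raise FormatError(f"{path}:{i + 3}: missing energy annotation")
        structure = struct_line[:lpar].strip()
        mfe = float(struct_line[lpar + 2 : -1])
        if len(structure) != len(seq):
            raise FormatError(f"{path}:{i + 3}: structure/sequence length mismatch")
        out.append((header, seq, structure, mfe))
        i += 3
    return out


# --- Newick ---

def write_newick(newick: str, path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def read_newick(path: str | os.PathLike) -> str:
    with open(path) as fh:
        return fh.read().strip()
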