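"""Core nucleic-acid types and exact-match sequence operations.

All sequences are normalized to an upper-case DNA alphabet (``U`` → ``T``)
on construction; the original alphabet (DNA or RNA) is remembered so that
RNA-facing stages (secondary-structure prediction, dot-bracket output) can
render the sequence back with uracils.  Genomic coordinates are 1-based and
inclusive throughout the library; the 0-based half-open convention appears
only at the BED file boundary (see :mod:`mirnovo.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated nucleotide string in canonical DNA form.

    Parameters
    ----------
    bases:
        The sequence; lower case and ``U`` are accepted and normalized.
    alphabet_tag:
        ``"DNA"`` or ``"RNA"``.  If not given, it is inferred: any ``U``/``u``
        in the input marks the record as RNA.  Normalization is idempotent —
        constructing from an already-normalized string is a no-op.
    """

    bases: str
    alphabet_tag: str = field(default="")

    def __post_init__(self) -> None:
        raw = self.bases
        if not raw:
            raise ValueError("empty sequence")
        tag = self.alphabet_tag
        if not tag:
            tag = "RNA" if ("U" in raw or "u" in raw) else "DNA"
        if tag not in ("DNA", "RNA"):
            raise ValueError(f"alphabet_tag must be DNA or RNA, got {tag!r}")
        norm = raw.upper().replace("U", "T")
        bad = set(norm) - _VALID
        if bad:
            raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
        object.__setattr__(self, "bases", norm)
        object.__setattr__(self, "alphabet_tag", tag)

    def __len__(self) -> int:
        return len(self.bases)

    def __iter__(self) -> Iterator[str]:
        return iter(self.bases)

    def __getitem__(self, item) -> str:
        return self.bases[item]

    def as_rna(self) -> str:
        """The sequence with uracils, regardless of input alphabet."""
        return self.bases.replace("T", "U")

    def as_dna(self) -> str:
        return self.bases

    def subsequence(self, offset: int, length: int) -> "NucleotideSequence":
        """Extract ``length`` bases starting at 1-based ``offset``."""
        if offset < 1 or offset + length - 1 > len(self):
            raise IndexError(
                f"subsequence [{offset}, {offset + length - 1}] outside "
                f"1..{len(self)}"
            )
        return NucleotideSequence(
            self.bases[offset - 1 : offset - 1 + length], self.alphabet_tag
        )


@dataclass(frozen=True)
class GenomicLocus:
    """A 1-based inclusive genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    assembly_tag: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"require 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start + 1


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson–Crick reverse complement, in the DNA alphabet.

    An involution: applying it twice returns the original sequence.
    """
    return NucleotideSequence(
        seq.bases.translate(_COMPLEMENT)[::-1], seq.alphabet_tag
    )


def find_occurrences(
    needle: NucleotideSequence, haystack: NucleotideSequence
) -> List[int]:
    """All 1-based start positions of exact matches, overlapping included.

    Raises ``ValueError`` on an empty needle (``NucleotideSequence`` forbids
    it already; the guard also covers raw-string misuse).
    """
    n, h = needle.bases, haystack.bases
    if not n:
        raise ValueError("empty needle")
    hits: List[int] = []
    pos = h.find(n)
    while pos != -1:
        hits.append(pos + 1)
        pos = h.find(n, pos + 1)
    return hits


def locus_of_subsequence(
    parent_locus: GenomicLocus, offset: int, sub_len: int
) -> GenomicLocus:
    """Genomic interval of a subsequence of a plus-strand parent interval.

    ``offset`` is 1-based within the parent; the result keeps the parent's
    chromosome, strand and assembly tag.
    """
    if parent_locus.strand != "+":
        raise ValueError("parent locus must be on the plus strand")
    if offset < 1 or sub_len < 1 or offset + sub_len - 1 > parent_locus.length():
        raise IndexError(
            f"subsequence [{offset}, +{sub_len}] exceeds parent length "
            f"{parent_locus.length()}"
        )
    start = parent_locus.start + offset - 1
    return GenomicLocus(
        parent_locus.chrom,
        start,
        start + sub_len - 1,
        parent_locus.strand,
        parent_locus.assembly_tag,
    )


def hamming_within(a: str, b: str, max_mismatches: int) -> bool:
    """True if equal-length strings differ at <= max_mismatches positions."""
    if len(a) != len(b):
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mismatches:
                return False
    return True
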