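"""In-package reference fixtures for the n-miR-G665 candidate.

The published candidate comes with three concrete artifacts that the rest of
the pipeline is exercised against: the 135-nt precursor sequence, the 25-nt
capitalized mature subsequence within it, and the GRCh38 genomic interval
(chr12:20551369–20551503, plus strand, intron 1 of PDE3A).  The mature
sequence was described in the discovery report as 19 nt in one place and
printed as 25 capitalized nucleotides in another; both are kept — the 25-nt
printed string is the default mature everywhere, the stated 19 is retained
for the alternate mode.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq import GenomicLocus, NucleotideSequence, find_occurrences

# lower case: precursor flanks; upper case: mature (as printed)
_PRECURSOR_RAW = (
    "cagatcaatttgtcctcttttgtaataaaaaaaaaaagtctttaaaaaaagattta"
    "CGGACAGGATTGACAGATTGATAGC"
    "tctttctcgattccgtgggtggtggtgcatggccgttcttagttggtggagcga"
)
_MATURE_RAW = "CGGACAGGATTGACAGATTGATAGC"


@dataclass(frozen=True)
class ReferenceFixtures:
    """The candidate-miRNA reference sequences and locus, validated."""

    precursor_135: NucleotideSequence
    mature_25: NucleotideSequence
    locus: GenomicLocus
    mature_len_stated: int = 19

    def __post_init__(self) -> None:
        if len(self.precursor_135) != 135:
            raise ValueError("precursor must be 135 nt")
        if self.locus.length() != len(self.precursor_135):
            raise ValueError("locus span must equal precursor length")
        hits = find_occurrences(self.mature_25, self.precursor_135)
        if len(hits) != 1:
            raise ValueError(
                f"mature must occur exactly once in precursor, found {hits}"
            )

    @property
    def mature_offset(self) -> int:
        """1-based start of the mature within the precursor (57)."""
        return find_occurrences(self.mature_25, self.precursor_135)[0]

    @property
    def mature_span(self) -> tuple[int, int]:
        """1-based inclusive span of the 25-nt mature on the precursor."""
        off = self.mature_offset
        return off, off + len(self.mature_25) - 1


def reference_fixtures() -> ReferenceFixtures:
    """Construct (and re-validate) the shipped reference fixtures."""
    return ReferenceFixtures(
        precursor_135=NucleotideSequence(_PRECURSOR_RAW, "DNA"),
        mature_25=NucleotideSequence(_MATURE_RAW, "DNA"),
        locus=GenomicLocus("chr12", 20551369, 20551503, "+", "GRCh38"),
    )
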