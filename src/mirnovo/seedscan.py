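"""7-mer seed-site scanning of 3'UTR sets.

Every contiguous 7-mer of the mature miRNA is a potential seed; a target
site is the Watson–Crick reverse complement of that 7-mer appearing in a
3'UTR (G:U wobble is not admitted in seed matching).  Sites are counted as
raw occurrences — overlaps and per-UTR multiplicity included — and k-mers
are ranked by total occurrence with ties going to the k-mer nearer the
mature 5' end.  A literal-match orientation is available for sensitivity
analysis.  All matching happens in DNA space (U normalized to T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .seq import NucleotideSequence, find_occurrences, reverse_complement


@dataclass(frozen=True)
class SeedRow:
    kmer: str
    mature_offset: int          # 1-based offset of the k-mer on the mature
    site_sequence: str          # what was searched for in the UTRs
    total_occurrences: int
    n_utrs_hit: int
    positions: Dict[str, Tuple[int, ...]]  # utr_id -> 1-based starts


@dataclass(frozen=True)
class SeedMatchTable:
    mature: NucleotideSequence
    k: int
    rows: Tuple[SeedRow, ...]   # ranked: occurrences desc, offset asc

    def as_records(self) -> List[dict]:
        return [
            {
                "rank": i + 1,
                "kmer": r.kmer,
                "mature_offset": r.mature_offset,
                "site_sequence": r.site_sequence,
                "total_occurrences": r.total_occurrences,
                "n_utrs_hit": r.n_utrs_hit,
            }
            for i, r in enumerate(self.rows)
        ]


def enumerate_kmers(
    mature: NucleotideSequence, k: int = 7
) -> List[Tuple[int, str]]:
    """All contiguous k-mers 5'→3' with their 1-based offsets."""
    if len(mature) < k:
        raise ValueError(f"mature ({len(mature)} nt) shorter than k={k}")
    return [
        (off + 1, mature.bases[off : off + k])
        for off in range(len(mature) - k + 1)
    ]


def scan(
    mature: NucleotideSequence,
    utrs: Sequence[Tuple[str, NucleotideSequence]],
    k: int = 7,
    orientation: str = "complement",
) -> SeedMatchTable:
    """Count candidate target sites for every mature k-mer.

    ``orientation="complement"`` (default) searches UTRs for the reverse
    complement of each k-mer — the standard miRNA:mRNA pairing geometry;
    ``"identity"`` searches for the literal k-mer.  An empty UTR set gives
    a table of zero counts.
    """
    if orientation not in ("complement", "identity"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows: List[SeedRow] = []
    for offset, kmer in enumerate_kmers(mature, k):
        if orientation == "complement":
            site = reverse_complement(NucleotideSequence(kmer)).bases
        else:
            site = kmer
        site_seq = NucleotideSequence(site)
        positions: Dict[str, Tuple[int, ...]] = {}
        total = 0
        for utr_id, utr in utrs:
            hits = find_occurrences(site_seq, utr)
            if hits:
                positions[utr_id] = tuple(hits)
                total += len(hits)
        rows.append(
            SeedRow(kmer, offset, site, total, len(positions), positions)
        )
    ranked = tuple(
        sorted(rows, key=lambda r: (-r.total_occurrences, r.mature_offset))
    )
    return SeedMatchTable(mature, k, ranked)


def top_seeds(table: SeedMatchTable, n: int = 2) -> List[SeedRow]:
    """The n best-scoring k-mers (the study highlighted two motifs)."""
    return list(table.rows[:n])
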