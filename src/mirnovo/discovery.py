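"""The read-categorization cascade and candidate discovery.

Collapsed small-RNA reads are assigned to exactly one category by a fixed
priority: length filter, then the exclusion catalogs in order (known
miRNAs, mRNA, structural ncRNA, repeats), then the genome; reads matching
nothing are UNMAPPED.  Matching is exact-substring with an optional
Hamming mismatch allowance (no indels), on both strands by default.
Genome-mapped survivors are clustered by overlapping hit intervals, flank-
extended, and cut into sliding precursor windows which the fold module
evaluates for a mature-in-arm stem-loop; a candidate is novel-miRNA-like
if any of its windows passes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .fold import FoldThresholds, CandidateEvaluation, EnergyModel, evaluate_candidate
from .seq import (
    GenomicLocus,
    NucleotideSequence,
    find_occurrences,
    hamming_within,
    reverse_complement,
)


class ReadCategory(enum.Enum):
    TOO_SHORT_OR_LONG = "TOO_SHORT_OR_LONG"
    KNOWN_MIRNA = "KNOWN_MIRNA"
    MRNA = "MRNA"
    STRUCTURAL_NCRNA = "STRUCTURAL_NCRNA"
    REPEAT = "REPEAT"
    GENOME_CANDIDATE = "GENOME_CANDIDATE"
    UNMAPPED = "UNMAPPED"


CATALOG_ORDER = (
    ReadCategory.KNOWN_MIRNA,
    ReadCategory.MRNA,
    ReadCategory.STRUCTURAL_NCRNA,
    ReadCategory.REPEAT,
)


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed read: unique sequence plus summed copy count."""

    read_id: str
    seq: NucleotideSequence
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass(frozen=True)
class CascadeParams:
    mismatches: int = 0
    len_range: Tuple[int, int] = (18, 26)
    both_strands: bool = True


@dataclass(frozen=True)
class GenomeHit:
    locus: GenomicLocus
    strand: str


@dataclass
class PrecursorWindow:
    seq: NucleotideSequence
    mature_span: Tuple[int, int]  # 1-based within the window
    genome_start: int             # 1-based on the chromosome (plus strand)
    window_len: int


@dataclass
class CandidateLocus:
    """A cluster of genome-mapped reads with its precursor windows."""

    candidate_id: str
    locus: GenomicLocus
    supporting_reads: List[SmallRNARead]
    total_copies: int
    mature: NucleotideSequence
    precursor_windows: List[PrecursorWindow] = field(default_factory=list)
    clipped: bool = False


@dataclass
class CandidateResult:
    candidate: CandidateLocus
    is_novel_mirna_like: bool
    passing_window: Optional[PrecursorWindow]
    evaluation: Optional[CandidateEvaluation]


@dataclass
class DiscoveryResult:
    tally: Dict[ReadCategory, int]
    candidates: List[CandidateResult]
    dominance: List[Tuple[str, float]]  # (candidate_id, share of novel copies)
    categories: Dict[str, ReadCategory]  # read_id -> category


def collapse_reads(
    raw: Iterable[NucleotideSequence | str],
) -> List[SmallRNARead]:
    """Merge identical sequences, summing copies.

    Output is sorted by descending copy count, then lexicographically by
    sequence; ids are assigned in that order.
    """
    counts: Dict[str, int] = {}
    for item in raw:
        seq = item.bases if isinstance(item, NucleotideSequence) else str(item)
        seq = NucleotideSequence(seq).bases
        counts[seq] = counts.get(seq, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        SmallRNARead(f"read_{k + 1:05d}", NucleotideSequence(seq), n)
        for k, (seq, n) in enumerate(ordered)
    ]


def parse_collapsed_fasta(
    records: Iterable[Tuple[str, NucleotideSequence]],
) -> List[SmallRNARead]:
    """Interpret ``id|copies=N`` FASTA headers as collapsed reads."""
    reads = []
    for header, seq in records:
        rid, _, tail = header.partition("|copies=")
        copies = int(tail) if tail else 1
        reads.append(SmallRNARead(rid, seq, copies))
    return reads


def _matches_catalog(
    read_seq: NucleotideSequence,
    catalog: Sequence[Tuple[str, NucleotideSequence]],
    mismatches: int,
    both_strands: bool,
) -> bool:
    queries = [read_seq.bases]
    if both_strands:
        queries.append(reverse_complement(read_seq).bases)
    for _, entry in catalog:
        hay = entry.bases
        for q in queries:
            if mismatches == 0:
                if q in hay:
                    return True
            else:
                for off in range(len(hay) - len(q) + 1):
                    if hamming_within(q, hay[off : off + len(q)], mismatches):
                        return True
    return False


def map_to_genome(
    read_seq: NucleotideSequence,
    genome: Sequence[Tuple[str, NucleotideSequence]],
    both_strands: bool = True,
) -> List[GenomeHit]:
    """Exact-match genomic hits of a read, on plus coordinates.

    Minus-strand hits are reported at the plus-strand interval their
    reverse complement occupies.
    """
    hits: List[GenomeHit] = []
    rc = reverse_complement(read_seq)
    for chrom, seq in genome:
        for start in find_occurrences(read_seq, seq):
            hits.append(
                GenomeHit(
                    GenomicLocus(chrom, start, start + len(read_seq) - 1), "+"
                )
            )
        if both_strands:
            for start in find_occurrences(rc, seq):
                hits.append(
                    GenomeHit(
                        GenomicLocus(chrom, start, start + len(read_seq) - 1),
                        "-",
                    )
                )
    return hits


def categorize(
    read: SmallRNARead,
    catalogs: Sequence[Tuple[ReadCategory, Sequence[Tuple[str, NucleotideSequence]]]],
    genome: Sequence[Tuple[str, NucleotideSequence]],
    params: CascadeParams = CascadeParams(),
) -> ReadCategory:
    """Assign a read to the first matching category in priority order."""
    if not genome:
        raise ValueError("empty genome")
    lo, hi = params.len_range
    if not lo <= len(read.seq) <= hi:
        return ReadCategory.TOO_SHORT_OR_LONG
    for category, catalog in catalogs:
        if _matches_catalog(
            read.seq, catalog, params.mismatches, params.both_strands
        ):
            return (
                category
                if isinstance(category, ReadCategory)
                else ReadCategory(category)
            )
    if map_to_genome(read.seq, genome, params.both_strands):
        return ReadCategory.GENOME_CANDIDATE
    return ReadCategory.UNMAPPED


def cluster_and_extend(
    candidates: Sequence[Tuple[SmallRNARead, GenomeHit]],
    genome: Sequence[Tuple[str, NucleotideSequence]],
    flank: int = 60,
    window_lens: Sequence[int] = tuple(range(50, 151, 10)),
) -> List[CandidateLocus]:
    """Merge overlapping same-strand hits and cut precursor windows.

    The cluster's consensus mature is the highest-copy supporting read
    (ties to the leftmost interval).  Windows of every requested length
    slide at 1-nt steps across the flank-extended span and must fully
    contain the mature interval; on minus-strand clusters window sequences
    are reverse-complemented so the mature reads 5'→3'.  Flank extension
    clipped at chromosome ends is recorded, not an error.
    """
    by_name = dict(genome)
    items = sorted(
        candidates,
        key=lambda rh: (
            rh[1].locus.chrom,
            rh[1].strand,
            rh[1].locus.start,
            rh[1].locus.end,
            rh[0].read_id,
        ),
    )
    clusters: List[List[Tuple[SmallRNARead, GenomeHit]]] = []
    for read, hit in items:
        if clusters:
            last = clusters[-1]
            lh = last[-1][1]
            same = (
                lh.locus.chrom == hit.locus.chrom
                and lh.strand == hit.strand
                and hit.locus.start
                <= max(x[1].locus.end for x in last)
            )
            if same:
                last.append((read, hit))
                continue
        clusters.append([(read, hit)])

    out: List[CandidateLocus] = []
    for k, members in enumerate(clusters):
        chrom = members[0][1].locus.chrom
        strand = members[0][1].strand
        start = min(m[1].locus.start for m in members)
        end = max(m[1].locus.end for m in members)
        reads = [m[0] for m in members]
        total = sum(r.copies for r in reads)
        top = min(
            members, key=lambda m: (-m[0].copies, m[1].locus.start, m[0].read_id)
        )
        mature_locus = top[1].locus
        chrom_seq = by_name[chrom]
        ext_start = max(1, start - flank)
        ext_end = min(len(chrom_seq), end + flank)
        clipped = ext_start != start - flank or ext_end != end + flank
        cand = CandidateLocus(
            candidate_id=f"cand_{k + 1:03d}",
            locus=GenomicLocus(chrom, start, end, strand),
            supporting_reads=reads,
            total_copies=total,
            mature=top[0].seq,
            clipped=clipped,
        )
        for wlen in sorted(window_lens):
            lo = max(ext_start, mature_locus.end - wlen + 1)
            hi = min(mature_locus.start, ext_end - wlen + 1)
            # starts descending: for a 5'-arm mature the stem-loop lies
            # downstream, so right-extended windows tend to pass first and
            # the short-circuiting evaluator stops sooner
            for ws in range(hi, lo - 1, -1):
                window = chrom_seq.subsequence(ws, wlen)
                if strand == "+":
                    span = (
                        mature_locus.start - ws + 1,
                        mature_locus.end - ws + 1,
                    )
                else:
                    window = reverse_complement(window)
                    span = (
                        ws + wlen - mature_locus.end,
                        ws + wlen - mature_locus.start,
                    )
                cand.precursor_windows.append(
                    PrecursorWindow(window, span, ws, wlen)
                )
        out.append(cand)
    return out


def _evaluation_order(
    windows: Sequence[PrecursorWindow],
) -> List[PrecursorWindow]:
    """Order windows so the short-circuit finds a passing one quickly.

    Three probe windows per length (the two extremes and the middle of the
    start range, cheapest lengths first) are tried before the exhaustive
    sweep over the remainder; the window set itself is unchanged.
    """
    by_len: Dict[int, List[PrecursorWindow]] = {}
    for w in windows:
        by_len.setdefault(w.window_len, []).append(w)
    probes: List[PrecursorWindow] = []
    rest: List[PrecursorWindow] = []
    for wlen in sorted(by_len):
        ws = by_len[wlen]
        picks = sorted({0, len(ws) // 2, len(ws) - 1})
        probes.extend(ws[k] for k in picks)
        rest.extend(w for k, w in enumerate(ws) if k not in picks)
    return probes + rest


def discover(
    reads: Sequence[SmallRNARead],
    catalogs: Sequence[Tuple[ReadCategory, Sequence[Tuple[str, NucleotideSequence]]]],
    genome: Sequence[Tuple[str, NucleotideSequence]],
    model: EnergyModel,
    params: CascadeParams = CascadeParams(),
    thresholds: FoldThresholds = FoldThresholds(),
    flank: int = 60,
    window_lens: Sequence[int] = tuple(range(50, 151, 10)),
    stop_at_first_pass: bool = True,
) -> DiscoveryResult:
    """Run the full cascade and hairpin evaluation.

    The category tally always sums to the number of input reads.  The
    dominance report lists each novel-miRNA-like candidate's share of the
    total novel-candidate copy count, descending.
    """
    tally = {cat: 0 for cat in ReadCategory}
    categories: Dict[str, ReadCategory] = {}
    survivors: List[Tuple[SmallRNARead, GenomeHit]] = []
    for read in reads:
        cat = categorize(read, catalogs, genome, params)
        categories[read.read_id] = cat
        tally[cat] += 1
        if cat is ReadCategory.GENOME_CANDIDATE:
            for hit in map_to_genome(read.seq, genome, params.both_strands):
                survivors.append((read, hit))

    loci = cluster_and_extend(survivors, genome, flank, window_lens)
    results: List[CandidateResult] = []
    for cand in loci:
        best_pass: Optional[Tuple[PrecursorWindow, CandidateEvaluation]] = None
        best_any: Optional[Tuple[PrecursorWindow, CandidateEvaluation]] = None
        for window in _evaluation_order(cand.precursor_windows):
            ev = evaluate_candidate(
                window.seq, window.mature_span, model, thresholds
            )
            if best_any is None or (
                ev.fold.mfe_kcal_mol < best_any[1].fold.mfe_kcal_mol
            ):
                best_any = (window, ev)
            if ev.passed:
                if best_pass is None or (
                    ev.fold.mfe_kcal_mol < best_pass[1].fold.mfe_kcal_mol
                ):
                    best_pass = (window, ev)
                if stop_at_first_pass:
                    break
        if best_pass is not None:
            results.append(
                CandidateResult(cand, True, best_pass[0], best_pass[1])
            )
        elif best_any is not None:
            results.append(CandidateResult(cand, False, None, best_any[1]))
        else:
            results.append(CandidateResult(cand, False, None, None))

    novel = [r for r in results if r.is_novel_mirna_like]
    total_novel_copies = sum(r.candidate.total_copies for r in novel)
    dominance = sorted(
        (
            (
                r.candidate.candidate_id,
                r.candidate.total_copies / total_novel_copies
                if total_novel_copies
                else 0.0,
            )
            for r in novel
        ),
        key=lambda t: (-t[1], t[0]),
    )
    return DiscoveryResult(tally, results, dominance, categories)
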