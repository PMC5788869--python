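"""Synthetic study inputs with recorded ground truth.

The discovery study's raw sequencing data are not publicly deposited, so
every pipeline stage is exercised on generated inputs whose planted
features are recorded exactly:

* a toy genome with planted fold-back precursor loci (left arm containing
  the mature, a short loop, and the arm's mutated reverse complement), the
  shipped 135-nt reference precursor included by default;
* a collapsed small-RNA read population in which one designated candidate
  dominates the novel-candidate copy total (the study reported one species
  at 66% of novel copies), plus decoy reads drawn as exact substrings of
  each exclusion catalog;
* 3'UTR sets carrying planted reverse-complement seed sites with exact
  counts (background collisions are re-drawn, not merely counted);
* two-condition expression tables with known true fold changes.

All randomness flows from one integer seed through ``random.Random``;
identical seeds give byte-identical outputs on any platform.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .fixtures import reference_fixtures
from .seq import GenomicLocus, NucleotideSequence, find_occurrences, reverse_complement

CATALOG_CATEGORIES = ("KNOWN_MIRNA", "MRNA", "STRUCTURAL_NCRNA", "REPEAT")

_MAX_REDRAWS = 50


@dataclass(frozen=True)
class PlantedPrecursor:
    locus: GenomicLocus
    precursor: NucleotideSequence
    mature: NucleotideSequence
    mature_offset: int  # 1-based within the precursor
    arm: str            # "5p" or "3p"


@dataclass
class SyntheticTruth:
    """Ground truth for every planted feature of a simulation."""

    rng_seed: int
    planted_precursors: List[PlantedPrecursor] = field(default_factory=list)
    planted_seed_sites: List[Tuple[str, int, str]] = field(default_factory=list)
    catalog_membership: Dict[str, str] = field(default_factory=dict)
    expression_truth: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "rng_seed": self.rng_seed,
            "planted_precursors": [
                {
                    "chrom": p.locus.chrom,
                    "start": p.locus.start,
                    "end": p.locus.end,
                    "strand": p.locus.strand,
                    "assembly_tag": p.locus.assembly_tag,
                    "precursor": p.precursor.bases,
                    "mature": p.mature.bases,
                    "mature_offset": p.mature_offset,
                    "arm": p.arm,
                }
                for p in self.planted_precursors
            ],
            "planted_seed_sites": [list(t) for t in self.planted_seed_sites],
            "catalog_membership": self.catalog_membership,
            "expression_truth": self.expression_truth,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        truth = cls(rng_seed=d["rng_seed"])
        for p in d["planted_precursors"]:
            truth.planted_precursors.append(
                PlantedPrecursor(
                    GenomicLocus(
                        p["chrom"], p["start"], p["end"], p["strand"],
                        p.get("assembly_tag", ""),
                    ),
                    NucleotideSequence(p["precursor"]),
                    NucleotideSequence(p["mature"]),
                    p["mature_offset"],
                    p["arm"],
                )
            )
        truth.planted_seed_sites = [tuple(t) for t in d["planted_seed_sites"]]
        truth.catalog_membership = dict(d["catalog_membership"])
        truth.expression_truth = dict(d["expression_truth"])
        return truth


def _random_bases(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(rng: random.Random, s: str, rate: float) -> str:
    out = []
    for c in s:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


def _build_hairpin(
    rng: random.Random, mutation_rate: float
) -> Tuple[str, str, int]:
    """One planted precursor: (precursor, mature, 1-based mature offset).

    Left arm 20–30 nt containing the mature, loop 6–10 nt, right arm the
    reverse complement of the left arm with per-base mutations.
    """
    mature_len = rng.randint(18, 24)
    arm_len = rng.randint(max(20, mature_len), 30)
    mature_off = rng.randint(0, arm_len - mature_len)
    left = _random_bases(rng, arm_len)
    loop = _random_bases(rng, rng.randint(6, 10))
    right = _mutate(
        rng,
        reverse_complement(NucleotideSequence(left)).bases,
        mutation_rate,
    )
    mature = left[mature_off : mature_off + mature_len]
    # the right arm must not carry an exact reverse complement of the
    # mature, or the mature would map to both strands of its own locus;
    # force at least one substitution in that segment
    lo = arm_len - (mature_off + mature_len)
    hi = arm_len - mature_off
    rc_mature = reverse_complement(NucleotideSequence(mature)).bases
    if right[lo:hi] == rc_mature:
        k = rng.randrange(lo, hi)
        right = (
            right[:k]
            + rng.choice([b for b in "ACGT" if b != right[k]])
            + right[k + 1 :]
        )
    precursor = left + loop + right
    return precursor, mature, mature_off + 1


def make_genome(
    n_chroms: int = 1,
    chrom_len: int = 5000,
    n_planted_hairpins: int = 10,
    seed: int = 0,
    include_reference_precursor: bool = True,
    mutation_rate: float = 0.1,
) -> Tuple[List[Tuple[str, NucleotideSequence]], SyntheticTruth]:
    """A toy genome with planted precursor loci and exact truth.

    Background bases are i.i.d. uniform.  Each planted mature must occur
    exactly once genome-wide; on an accidental background collision the
    entire genome is re-drawn from a successor seed (rejection sampling,
    so recorded truth is exact rather than merely probable).
    """
    fx = reference_fixtures() if include_reference_precursor else None
    if fx is not None and chrom_len < 10 * len(fx.precursor_135):
        raise ValueError("chrom_len must be >= 10x precursor length")

    for attempt in range(_MAX_REDRAWS):
        rng = random.Random((seed, attempt, "genome").__repr__())
        truth = SyntheticTruth(rng_seed=seed)
        chroms = {
            f"chr{k + 1}": list(_random_bases(rng, chrom_len))
            for k in range(n_chroms)
        }
        plantings: List[Tuple[str, str, int]] = []  # precursor, mature, offset
        if fx is not None:
            plantings.append(
                (fx.precursor_135.bases, fx.mature_25.bases, fx.mature_offset)
            )
        for _ in range(n_planted_hairpins):
            plantings.append(_build_hairpin(rng, mutation_rate))

        used: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
        ok = True
        for precursor, mature, moff in plantings:
            placed = False
            for _ in range(_MAX_REDRAWS):
                chrom = f"chr{rng.randint(1, n_chroms)}"
                start = rng.randint(1, chrom_len - len(precursor) + 1)
                end = start + len(precursor) - 1
                if all(e < start - 1 or s > end + 1 for s, e in used[chrom]):
                    placed = True
                    break
            if not placed:
                ok = False
                break
            used[chrom].append((start, end))
            chroms[chrom][start - 1 : end] = list(precursor)
            truth.planted_precursors.append(
                PlantedPrecursor(
                    GenomicLocus(chrom, start, end, "+", "toy"),
                    NucleotideSequence(precursor),
                    NucleotideSequence(mature),
                    moff,
                    "5p",
                )
            )
        if not ok:
            continue

        genome = [
            (name, NucleotideSequence("".join(bases)))
            for name, bases in sorted(chroms.items())
        ]
        if _verify_plantings(genome, truth):
            return genome, truth
    raise RuntimeError("could not build a collision-free genome")


def _verify_plantings(
    genome: Sequence[Tuple[str, NucleotideSequence]], truth: SyntheticTruth
) -> bool:
    by_name = dict(genome)
    for p in truth.planted_precursors:
        hits = []
        for name, seq in genome:
            hits += [(name, h) for h in find_occurrences(p.mature, seq)]
            hits += [
                (name, h)
                for h in find_occurrences(reverse_complement(p.mature), seq)
            ]
        expect = (p.locus.chrom, p.locus.start + p.mature_offset - 1)
        if len(hits) != 1 or hits[0] != expect:
            return False
        window = by_name[p.locus.chrom].subsequence(
            p.locus.start, p.locus.length()
        )
        if window.bases != p.precursor.bases:
            return False
    return True


def make_decoy_catalogs(
    n_entries: int = 5,
    entry_len: int = 80,
    seed: int = 0,
) -> Dict[str, List[Tuple[str, NucleotideSequence]]]:
    """Synthetic stand-ins for the four exclusion catalogs.

    Random sequence sets labelled with the catalog they emulate (known
    miRNAs, mRNA, structural ncRNA, repeats); no external database is
    consulted.
    """
    rng = random.Random((seed, "catalogs").__repr__())
    catalogs: Dict[str, List[Tuple[str, NucleotideSequence]]] = {}
    for cat in CATALOG_CATEGORIES:
        catalogs[cat] = [
            (
                f"{cat.lower()}_{k + 1}",
                NucleotideSequence(_random_bases(rng, entry_len)),
            )
            for k in range(n_entries)
        ]
    return catalogs


def make_reads(
    truth: SyntheticTruth,
    depth_per_mature: int = 100,
    decoy_spec: Optional[Dict[str, Tuple[List[Tuple[str, NucleotideSequence]], int]]] = None,
    seed: int = 0,
    copy_sigma: float = 1.5,
    dominant_fraction: float = 0.66,
) -> Tuple[List[Tuple[str, NucleotideSequence, int]], SyntheticTruth]:
    """Collapsed reads (id, sequence, copies) for a simulated library.

    Every planted mature is emitted verbatim with a log-normal copy count
    (median ``depth_per_mature``, shape ``copy_sigma``); the first planted
    candidate is designated dominant and its count is set so it holds
    ``dominant_fraction`` of all novel-candidate copies.  Decoy reads are
    exact substrings (18–26 nt) of their source catalog entries;
    ``decoy_spec`` maps category → (catalog records, number of decoy
    reads).  Membership of every read is recorded in the returned truth.
    """
    if depth_per_mature <= 0:
        raise ValueError("depth_per_mature must be positive")
    rng = random.Random((seed, "reads").__repr__())
    reads: List[Tuple[str, NucleotideSequence, int]] = []

    matures = [p.mature for p in truth.planted_precursors]
    counts: List[int] = []
    for _ in matures[1:]:
        counts.append(
            max(1, round(rng.lognormvariate(_ln(depth_per_mature), copy_sigma)))
        )
    if matures:
        if counts:
            rest = sum(counts)
            dom = max(
                1, round(rest * dominant_fraction / (1.0 - dominant_fraction))
            )
        else:
            dom = depth_per_mature
        counts = [dom] + counts
    for k, (mature, copies) in enumerate(zip(matures, counts)):
        rid = f"novel_{k + 1}"
        reads.append((rid, mature, copies))
        truth.catalog_membership[rid] = "GENOME_CANDIDATE"

    for cat, (records, n_reads) in sorted((decoy_spec or {}).items()):
        for k in range(n_reads):
            src_id, src = records[rng.randrange(len(records))]
            length = rng.randint(18, 26)
            start = rng.randint(0, len(src) - length)
            rid = f"decoy_{cat.lower()}_{k + 1}"
            reads.append(
                (
                    rid,
                    NucleotideSequence(src.bases[start : start + length]),
                    max(1, round(rng.lognormvariate(_ln(10), copy_sigma))),
                )
            )
            truth.catalog_membership[rid] = cat
    return reads, truth


def _ln(x: float) -> float:
    import math

    return math.log(x)


def reads_to_fasta_records(
    reads: Sequence[Tuple[str, NucleotideSequence, int]],
) -> List[Tuple[str, NucleotideSequence]]:
    """Render (id, seq, copies) as FASTA records with ``id|copies=N`` headers."""
    return [(f"{rid}|copies={copies}", seq) for rid, seq, copies in reads]


def make_utrs(
    n_utrs: int = 10,
    utr_len: int = 1000,
    planted_kmer: str = "CGGACAG",
    n_sites: int = 5,
    seed: int = 0,
) -> Tuple[List[Tuple[str, NucleotideSequence]], SyntheticTruth]:
    """3'UTR set with exactly ``n_sites`` planted seed-complement sites.

    The reverse complement of ``planted_kmer`` is written at recorded
    positions; if the background happens to contain additional copies the
    whole set is re-drawn, so the recorded count is exact.
    """
    if len(planted_kmer) != 7:
        raise ValueError("planted k-mer must be 7 nt")
    site = reverse_complement(NucleotideSequence(planted_kmer)).bases
    for attempt in range(_MAX_REDRAWS):
        rng = random.Random((seed, attempt, "utrs").__repr__())
        truth = SyntheticTruth(rng_seed=seed)
        utrs = {
            f"utr_{k + 1}": list(_random_bases(rng, utr_len))
            for k in range(n_utrs)
        }
        placed: Dict[str, List[int]] = {u: [] for u in utrs}
        ok = True
        for _ in range(n_sites):
            for _ in range(_MAX_REDRAWS):
                uid = f"utr_{rng.randint(1, n_utrs)}"
                pos = rng.randint(1, utr_len - 7 + 1)
                if all(abs(pos - p) >= 7 for p in placed[uid]):
                    break
            else:
                ok = False
                break
            placed[uid].append(pos)
            utrs[uid][pos - 1 : pos + 6] = list(site)
            truth.planted_seed_sites.append((uid, pos, planted_kmer))
        if not ok:
            continue
        records = [
            (uid, NucleotideSequence("".join(bases)))
            for uid, bases in sorted(utrs.items())
        ]
        total = sum(
            len(find_occurrences(NucleotideSequence(site), seq))
            for _, seq in records
        )
        if total == n_sites:
            truth.planted_seed_sites.sort()
            return records, truth
    raise RuntimeError("could not build a collision-free UTR set")


def make_expression_table(
    n_genes: int = 1000,
    n_up_2fold: int = 92,
    n_up_3fold: int = 48,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Two-condition expression values with known true fold changes.

    ``n_up_3fold`` of the ``n_up_2fold`` upregulated genes get true folds
    in [3, 8); the remainder in [2, 3); all other genes in [0.5, 1.8).
    Control values are log-normal; knockout = control x fold x
    exp(N(0, noise_sd^2)).
    """
    if not 0 <= n_up_3fold <= n_up_2fold <= n_genes:
        raise ValueError("require n_up_3fold <= n_up_2fold <= n_genes")
    rng = random.Random((seed, "expression").__repr__())
    truth = SyntheticTruth(rng_seed=seed)
    rows = []
    for g in range(n_genes):
        gene = f"gene_{g + 1:05d}"
        if g < n_up_3fold:
            fold = rng.uniform(3.0, 8.0)
        elif g < n_up_2fold:
            fold = rng.uniform(2.0, 2.95)
        else:
            fold = rng.uniform(0.5, 1.8)
        control = rng.lognormvariate(_ln(100), 1.0)
        noise = rng.gauss(0.0, noise_sd) if noise_sd > 0 else 0.0
        knockout = control * fold * _exp(noise)
        truth.expression_truth[gene] = fold
        rows.append((gene, control, knockout))
    table = pd.DataFrame(
        rows, columns=["gene_id", "control", "knockout"]
    ).set_index("gene_id")
    return table, truth


def _exp(x: float) -> float:
    import math

    return math.exp(x)
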