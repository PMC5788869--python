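"""Read collapsing, the exclusion cascade, clustering and windows."""

import random

import pytest

from mirnovo.discovery import (
    CATALOG_ORDER,
    CascadeParams,
    GenomeHit,
    ReadCategory,
    SmallRNARead,
    categorize,
    cluster_and_extend,
    collapse_reads,
    discover,
    map_to_genome,
    parse_collapsed_fasta,
)
from mirnovo.fixtures import reference_fixtures
from mirnovo.seq import GenomicLocus, NucleotideSequence, reverse_complement
from mirnovo.simulate import make_decoy_catalogs, make_genome, make_reads


def _read(seq, copies=1, rid="r"):
    return SmallRNARead(rid, NucleotideSequence(seq), copies)


class TestCollapseReads:
    def test_merges_and_sums(self):
        out = collapse_reads(["ACGTACGTACGTACGTAC"] * 3)
        assert len(out) == 1
        assert out[0].copies == 3

    def test_sort_contract(self):
        out = collapse_reads(
            ["TTTTTTTTTTTTTTTTTT"] * 2 + ["AAAAAAAAAAAAAAAAAA"] * 5
        )
        assert [r.copies for r in out] == [5, 2]
        assert out[0].seq.bases.startswith("A")

    def test_empty(self):
        assert collapse_reads([]) == []

    def test_header_round_trip(self):
        reads = collapse_reads(["ACGTACGTACGTACGTAC"] * 4)
        records = [
            (f"{r.read_id}|copies={r.copies}", r.seq) for r in reads
        ]
        assert parse_collapsed_fasta(records)[0].copies == 4


class TestCategorize:
    def setup_method(self):
        self.genome = [("chr1", NucleotideSequence("A" * 40 + "CGTACGGATCCAGTTACGGATACAGT" + "A" * 40))]
        self.known = [("mir1", NucleotideSequence("TTGACCGTAGGCATACGGAC"))]
        self.catalogs = [
            (ReadCategory.KNOWN_MIRNA, self.known),
            (ReadCategory.MRNA, []),
            (ReadCategory.STRUCTURAL_NCRNA, []),
            (ReadCategory.REPEAT, []),
        ]

    def test_priority_known_mirna_beats_genome(self):
        genome = [
            (
                "chr1",
                NucleotideSequence(
                    self.known[0][1].bases + self.genome[0][1].bases
                ),
            )
        ]
        cat = categorize(
            _read("TTGACCGTAGGCATACGGAC"), self.catalogs, genome
        )
        assert cat is ReadCategory.KNOWN_MIRNA

    def test_genome_candidate_path(self, model):
        # the discovery path of the reference candidate: absent from every
        # catalog, present in the genome
        fx = reference_fixtures()
        genome = [("chr12", fx.precursor_135)]
        cat = categorize(
            SmallRNARead("m", fx.mature_25, 10), self.catalogs, genome
        )
        assert cat is ReadCategory.GENOME_CANDIDATE

    def test_length_filter_first(self):
        assert (
            categorize(_read("ACGTACGTACGT"), self.catalogs, self.genome)
            is ReadCategory.TOO_SHORT_OR_LONG
        )

    def test_unmapped(self):
        assert (
            categorize(_read("G" * 13 + "TCTCA"), self.catalogs, self.genome)
            is ReadCategory.UNMAPPED
        )

    def test_antisense_genome_hit(self):
        rc = reverse_complement(
            NucleotideSequence("CGTACGGATCCAGTTACG")
        ).bases
        assert (
            categorize(_read(rc), self.catalogs, self.genome)
            is ReadCategory.GENOME_CANDIDATE
        )

    def test_empty_genome_is_error(self):
        with pytest.raises(ValueError):
            categorize(_read("ACGTACGTACGTACGTAC"), self.catalogs, [])

    def test_mismatch_monotonicity(self):
        rng = random.Random(0)
        entry = "".join(rng.choice("ACGT") for _ in range(60))
        catalogs = [
            (ReadCategory.KNOWN_MIRNA, [("e", NucleotideSequence(entry))])
        ]
        reads = []
        for _ in range(40):
            start = rng.randint(0, 40)
            sub = list(entry[start : start + 20])
            for _ in range(rng.randint(0, 3)):
                k = rng.randrange(20)
                sub[k] = rng.choice("ACGT")
            reads.append(_read("".join(sub)))
        hits_by_mm = []
        for mm in range(4):
            params = CascadeParams(mismatches=mm)
            hits_by_mm.append(
                {
                    k
                    for k, r in enumerate(reads)
                    if categorize(r, catalogs, self.genome, params)
                    is ReadCategory.KNOWN_MIRNA
                }
            )
        for a, b in zip(hits_by_mm, hits_by_mm[1:]):
            assert a <= b

    def test_priority_monotone_in_catalog_growth(self):
        # adding an entry can move reads only toward earlier categories
        read = _read("CGTACGGATCCAGTTACG")
        assert (
            categorize(read, self.catalogs, self.genome)
            is ReadCategory.GENOME_CANDIDATE
        )
        richer = [
            (ReadCategory.KNOWN_MIRNA, self.known),
            (
                ReadCategory.MRNA,
                [("m", NucleotideSequence("CGTACGGATCCAGTTACGGATACAGT"))],
            ),
            (ReadCategory.STRUCTURAL_NCRNA, []),
            (ReadCategory.REPEAT, []),
        ]
        assert categorize(read, richer, self.genome) is ReadCategory.MRNA

    def test_partition_sums_to_input(self, model):
        genome, truth = make_genome(1, 2000, 3, seed=13)
        cats = make_decoy_catalogs(seed=13)
        reads, truth = make_reads(
            truth, 20, {c: (r, 4) for c, r in cats.items()}, seed=13
        )
        sr = [SmallRNARead(*r) for r in reads]
        catalogs = [(c, cats[c.value]) for c in CATALOG_ORDER]
        res = discover(sr, catalogs, genome, model)
        assert sum(res.tally.values()) == len(sr)


class TestClusterAndExtend:
    def test_fixture_window_count(self, fx):
        # a read at the mature of the planted 135-nt precursor, 50-nt
        # windows: starts 32..57 of the precursor → 26 windows
        genome = [("chr1", fx.precursor_135)]
        read = SmallRNARead("m", fx.mature_25, 5)
        hit = GenomeHit(GenomicLocus("chr1", 57, 81), "+")
        (cand,) = cluster_and_extend(
            [(read, hit)], genome, flank=60, window_lens=[50]
        )
        assert len(cand.precursor_windows) == 26
        for w in cand.precursor_windows:
            ms, me = w.mature_span
            assert w.seq.bases[ms - 1 : me] == fx.mature_25.bases

    def test_overlapping_reads_merge(self):
        genome = [("chr1", NucleotideSequence("ACGT" * 100))]
        r1 = _read("ACGTACGTACGTACGTACGT", 5, "a")
        r2 = _read("GTACGTACGTACGTACGTAC", 2, "b")
        h1 = GenomeHit(GenomicLocus("chr1", 10, 29), "+")
        h2 = GenomeHit(GenomicLocus("chr1", 20, 39), "+")
        (cand,) = cluster_and_extend([(r1, h1), (r2, h2)], genome)
        assert cand.total_copies == 7
        assert cand.locus.start == 10 and cand.locus.end == 39

    def test_opposite_strands_stay_separate(self):
        genome = [("chr1", NucleotideSequence("ACGT" * 100))]
        r = _read("ACGTACGTACGTACGTACGT", 1, "a")
        h_plus = GenomeHit(GenomicLocus("chr1", 10, 29), "+")
        h_minus = GenomeHit(GenomicLocus("chr1", 10, 29), "-")
        out = cluster_and_extend([(r, h_plus), (r, h_minus)], genome)
        assert len(out) == 2
        assert {c.locus.strand for c in out} == {"+", "-"}

    def test_minus_strand_windows_carry_oriented_mature(self):
        rng = random.Random(3)
        background = "".join(rng.choice("ACGT") for _ in range(200))
        mature = "TCGGAACCTTGGCAATCG"
        genome_seq = background[:90] + mature + background[90:]
        genome = [("chr1", NucleotideSequence(genome_seq))]
        rc = reverse_complement(NucleotideSequence(mature))
        read = SmallRNARead("m", rc, 3)
        hit = GenomeHit(GenomicLocus("chr1", 91, 108), "-")
        (cand,) = cluster_and_extend(
            [(read, hit)], genome, window_lens=[60]
        )
        for w in cand.precursor_windows:
            ms, me = w.mature_span
            assert w.seq.bases[ms - 1 : me] == rc.bases

    def test_clipping_recorded_at_chromosome_edge(self):
        genome = [("chr1", NucleotideSequence("ACGT" * 30))]
        r = _read("ACGTACGTACGTACGTACGT", 1, "a")
        hit = GenomeHit(GenomicLocus("chr1", 1, 20), "+")
        (cand,) = cluster_and_extend([(r, hit)], genome, window_lens=[50])
        assert cand.clipped


class TestDiscover:
    def test_empty_input(self, model):
        genome = [("chr1", NucleotideSequence("ACGT" * 100))]
        res = discover([], [], genome, model)
        assert res.candidates == []
        assert res.dominance == []
        assert sum(res.tally.values()) == 0

    def test_planted_recovery_and_dominance(self, model):
        genome, truth = make_genome(2, 3000, 10, seed=21)
        cats = make_decoy_catalogs(seed=21)
        reads, truth = make_reads(
            truth, 100, {c: (r, 10) for c, r in cats.items()}, seed=21
        )
        sr = [SmallRNARead(*r) for r in reads]
        catalogs = [(c, cats[c.value]) for c in CATALOG_ORDER]
        res = discover(sr, catalogs, genome, model)
        novel = [r for r in res.candidates if r.is_novel_mirna_like]
        planted = {
            (p.locus.chrom, p.locus.start + p.mature_offset - 1)
            for p in truth.planted_precursors
        }
        found = {
            (r.candidate.locus.chrom, r.candidate.locus.start) for r in novel
        }
        assert found == planted          # sensitivity 1, no false candidates
        top_share = res.dominance[0][1]
        assert top_share == pytest.approx(0.66, abs=0.03)


def test_map_to_genome_reports_both_strands(fx):
    genome = [("chr12", fx.precursor_135)]
    hits = map_to_genome(fx.mature_25, genome)
    assert len(hits) == 1 and hits[0].strand == "+"
    rc_hits = map_to_genome(reverse_complement(fx.mature_25), genome)
    assert len(rc_hits) == 1 and rc_hits[0].strand == "-"
    assert rc_hits[0].locus.start == 57
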