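"""Alignment identity, NJ reconstruction, conservation summaries."""

import itertools
import random
import warnings

import dendropy
import numpy as np
import pytest

from mirnovo.conservation import (
    AlignmentScoring,
    DistanceMatrix,
    build_distance_matrix,
    conservation_report,
    make_orthologs,
    neighbor_joining,
    pairwise_identity,
    parse_ortholog_headers,
    tree_to_newick,
)
from mirnovo.fixtures import reference_fixtures
from mirnovo.seq import NucleotideSequence


def _enumerate_alignments(s1, s2, scoring=AlignmentScoring()):
    """Brute-force all global alignments as merge orders; returns the
    lexicographic maximum of (score, matches, diagonal steps)."""
    best = None

    def rec(i, j, score, matches, diags):
        nonlocal best
        if i == len(s1) and j == len(s2):
            key = (score, matches, diags)
            if best is None or key > best:
                best = key
            return
        if i < len(s1) and j < len(s2):
            m = 1 if s1[i] == s2[j] else 0
            sc = scoring.match if m else scoring.mismatch
            rec(i + 1, j + 1, score + sc, matches + m, diags + 1)
        if i < len(s1):
            rec(i + 1, j, score + scoring.gap, matches, diags)
        if j < len(s2):
            rec(i, j + 1, score + scoring.gap, matches, diags)

    rec(0, 0, 0, 0, 0)
    return best


class TestPairwiseIdentity:
    def test_identical(self):
        ident, cols = pairwise_identity(
            NucleotideSequence("ACGTACGT"), NucleotideSequence("ACGTACGT")
        )
        assert ident == 1.0 and cols == 8

    def test_fully_different(self):
        ident, _ = pairwise_identity(
            NucleotideSequence("AAAA"), NucleotideSequence("TTTT")
        )
        assert ident == 0.0

    def test_against_exhaustive_enumeration(self):
        rng = random.Random(0)
        for _ in range(60):
            s1 = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 7)))
            s2 = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 7)))
            score, matches, diags = _enumerate_alignments(s1, s2)
            ident, cols = pairwise_identity(
                NucleotideSequence(s1), NucleotideSequence(s2)
            )
            assert cols == len(s1) + len(s2) - diags
            assert ident == pytest.approx(matches / cols if cols else 1.0)

    def test_single_indel_example(self):
        score, matches, diags = _enumerate_alignments("ACGT", "ACGGT")
        ident, cols = pairwise_identity(
            NucleotideSequence("ACGT"), NucleotideSequence("ACGGT")
        )
        assert ident == pytest.approx(matches / (9 - diags))
        assert ident == pytest.approx(4 / 5)

    def test_identity_bounds_fuzzed(self):
        rng = random.Random(1)
        for _ in range(50):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 30)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 30)))
            ident, _ = pairwise_identity(
                NucleotideSequence(s), NucleotideSequence(t)
            )
            assert 0.0 <= ident <= 1.0
            self_ident, _ = pairwise_identity(
                NucleotideSequence(s), NucleotideSequence(s)
            )
            assert self_ident == 1.0


class TestDistanceMatrix:
    def test_identical_set_zero_matrix(self):
        seqs = [(t, NucleotideSequence("ACGTACGTAC")) for t in "abc"]
        dm = build_distance_matrix(seqs)
        assert np.allclose(dm.d, 0.0)

    def test_elementwise_recomputation(self):
        rng = random.Random(2)
        seqs = [
            (
                f"t{k}",
                NucleotideSequence(
                    "".join(rng.choice("ACGT") for _ in range(20))
                ),
            )
            for k in range(5)
        ]
        dm = build_distance_matrix(seqs)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                ident, _ = pairwise_identity(seqs[i][1], seqs[j][1])
                assert dm.d[i, j] == pytest.approx(1 - ident)

    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "a"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))


def _random_additive(rng, taxa):
    """A random binary tree over taxa and its exact path-length matrix."""
    nodes = [(t, None) for t in taxa]
    children = {}
    lengths = {}
    next_id = 0
    items = [t for t in taxa]
    while len(items) > 1:
        i = rng.randrange(len(items))
        a = items.pop(i)
        j = rng.randrange(len(items))
        b = items.pop(j)
        parent = f"_n{next_id}"
        next_id += 1
        children[parent] = (a, b)
        lengths[a] = rng.uniform(0.01, 0.2)
        lengths[b] = rng.uniform(0.01, 0.2)
        items.append(parent)
    root = items[0]

    def leaf_dists(node):
        if node not in children:
            return {node: 0.0}
        out = {}
        for child in children[node]:
            for leaf, d in leaf_dists(child).items():
                out[leaf] = d + lengths[child]
        return out

    dists = {}

    def fill(node):
        if node not in children:
            return
        a, b = children[node]
        da = {l: d + lengths[a] for l, d in leaf_dists(a).items()}
        db = {l: d + lengths[b] for l, d in leaf_dists(b).items()}
        for la, va in da.items():
            for lb, vb in db.items():
                dists[frozenset((la, lb))] = va + vb
        fill(a)
        fill(b)

    fill(root)
    n = len(taxa)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = dists[frozenset((taxa[i], taxa[j]))]
    newick = _to_newick(root, children, lengths) + ";"
    return mat, newick


def _to_newick(node, children, lengths, top=True):
    if node not in children:
        return node if top else f"{node}:{lengths[node]}"
    a, b = children[node]
    inner = f"({_to_newick(a, children, lengths, False)},{_to_newick(b, children, lengths, False)})"
    return inner if top else f"{inner}:{lengths[node]}"


def _rf_distance(newick1, newick2, taxa):
    tns = dendropy.TaxonNamespace(taxa)
    t1 = dendropy.Tree.get(data=newick1, schema="newick",
                           taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick",
                           taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array(
            [[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]]
        )
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.4 - 0.5))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.4))
        assert lengths["c"] == pytest.approx(0.5 * (0.4 + 0.5 - 0.3))

    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
            )

    def test_additive_four_taxon_recovery(self):
        rng = random.Random(3)
        taxa = ["a", "b", "c", "d"]
        mat, true_newick = _random_additive(rng, taxa)
        tree = neighbor_joining(DistanceMatrix(taxa, mat))
        assert _rf_distance(tree_to_newick(tree), true_newick, taxa) == 0

    def test_additive_eight_taxon_recovery_many(self):
        rng = random.Random(4)
        taxa = [f"t{k}" for k in range(8)]
        for _ in range(20):
            mat, true_newick = _random_additive(rng, taxa)
            tree = neighbor_joining(DistanceMatrix(taxa, mat))
            assert _rf_distance(tree_to_newick(tree), true_newick, taxa) == 0

    def test_permutation_invariance(self):
        rng = random.Random(5)
        taxa = [f"t{k}" for k in range(6)]
        mat, _ = _random_additive(rng, taxa)
        tree_ref = neighbor_joining(DistanceMatrix(taxa, mat))
        for _ in range(5):
            perm = list(range(6))
            rng.shuffle(perm)
            ptaxa = [taxa[k] for k in perm]
            pmat = mat[np.ix_(perm, perm)]
            tree = neighbor_joining(DistanceMatrix(ptaxa, pmat))
            assert (
                _rf_distance(tree_to_newick(tree), tree_to_newick(tree_ref),
                             taxa)
                == 0
            )

    def test_agrees_with_dendropy_nj(self):
        # independent implementation of the same algorithm
        rng = random.Random(6)
        taxa = [f"t{k}" for k in range(7)]
        mat, _ = _random_additive(rng, taxa)
        tree = neighbor_joining(DistanceMatrix(taxa, mat))
        csv = "," + ",".join(taxa) + "\n"
        for i, t in enumerate(taxa):
            csv += t + "," + ",".join(str(mat[i, j]) for j in range(7)) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        ref = pdm.nj_tree()
        assert (
            _rf_distance(tree_to_newick(tree),
                         ref.as_string(schema="newick"), taxa)
            == 0
        )

    def test_negative_branch_clamped_with_warning(self):
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.5],
                [0.1, 0.0, 0.45, 0.55],
                [0.4, 0.45, 0.0, 0.05],
                [0.5, 0.55, 0.05, 0.0],
            ]
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            tree = neighbor_joining(
                DistanceMatrix(["a", "b", "c", "d"], d)
            )
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0

    def test_newick_round_trip(self):
        rng = random.Random(7)
        taxa = [f"t{k}" for k in range(5)]
        mat, _ = _random_additive(rng, taxa)
        tree = neighbor_joining(DistanceMatrix(taxa, mat))
        nwk = tree_to_newick(tree)
        back = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in back.leaf_node_iter()} == set(taxa)
        assert _rf_distance(tree_to_newick(tree), nwk, taxa) == 0


class TestConservationReport:
    def _ortholog_set(self, mutate_one=False):
        fx = reference_fixtures()
        species = [("human", "mammals"), ("mouse", "mammals"),
                   ("dog", "mammals"), ("chicken", "birds")]
        divergence = {"mammals": 0.0, "birds": 0.2}
        seqs = make_orthologs(fx.precursor_135, species, divergence, seed=0)
        if mutate_one:
            taxon, seq = seqs[1]
            mutated = "G" + seq.bases[1:] if seq.bases[0] != "G" else (
                "A" + seq.bases[1:]
            )
            seqs[1] = (taxon, NucleotideSequence(mutated))
        return seqs, {t: g for t, g in species}

    def test_fully_conserved_mammals(self):
        seqs, groups = self._ortholog_set()
        rep = conservation_report(seqs, "human", groups)
        assert rep.groups["mammals"].fully_conserved
        assert rep.groups["mammals"].min_identity == 1.0
        assert not rep.groups["birds"].fully_conserved

    def test_one_mutated_taxon_breaks_full_conservation(self):
        seqs, groups = self._ortholog_set(mutate_one=True)
        rep = conservation_report(seqs, "human", groups)
        assert not rep.groups["mammals"].fully_conserved
        assert rep.groups["mammals"].min_identity < 1.0

    def test_missing_reference_errors(self):
        seqs, groups = self._ortholog_set()
        with pytest.raises(ValueError):
            conservation_report(seqs, "yeti", groups)

    def test_header_parsing(self):
        records = [
            ("human|mammals", NucleotideSequence("ACGT")),
            ("chicken|birds", NucleotideSequence("ACGT")),
        ]
        seqs, groups = parse_ortholog_headers(records)
        assert [t for t, _ in seqs] == ["human", "chicken"]
        assert groups == {"human": "mammals", "chicken": "birds"}
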