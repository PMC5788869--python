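"""Cross-species conservation: pairwise identities, NJ tree, group report.

Orthologous sequences of a short, highly conserved element are compared by
Needleman–Wunsch global alignment (match +1, mismatch −1, gap −2, end gaps
penalized).  Percent identity is matches / alignment columns, computed
over a canonical optimal alignment: among all maximal-score alignments the
one with the most matches, and among those the fewest columns.  Distances
(1 − identity) feed a Saitou–Nei neighbor-joining reconstruction with
deterministic tie-breaking; trees are returned as dendropy objects and
serialized to Newick.  Pairwise distances rather than a full MSA are a
deliberate simplification, adequate for 25–135-nt near-identical
orthologs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import dendropy
import numpy as np

from .seq import NucleotideSequence


@dataclass(frozen=True)
class AlignmentScoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass
class DistanceMatrix:
    taxa: List[str]
    d: np.ndarray  # symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("taxa must be unique")
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")


def pairwise_identity(
    a: NucleotideSequence,
    b: NucleotideSequence,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> Tuple[float, int]:
    """Global-alignment identity and alignment length.

    Maximizes, lexicographically: alignment score, then number of matched
    columns, then number of diagonal steps (i.e. fewest columns).  That
    triple uniquely defines the reported identity, making it checkable by
    exhaustive alignment enumeration on small inputs.
    """
    s1, s2 = a.bases, b.bases
    n1, n2 = len(s1), len(s2)
    NEG = (-(10 ** 9), 0, 0)
    # cell = (score, matches, diagonal steps), maximized lexicographically
    prev = [(j * scoring.gap, 0, 0) for j in range(n2 + 1)]
    for i in range(1, n1 + 1):
        cur = [(i * scoring.gap, 0, 0)] + [NEG] * n2
        ci = s1[i - 1]
        for j in range(1, n2 + 1):
            sc = scoring.match if ci == s2[j - 1] else scoring.mismatch
            m = 1 if ci == s2[j - 1] else 0
            pd = prev[j - 1]
            diag = (pd[0] + sc, pd[1] + m, pd[2] + 1)
            up = (prev[j][0] + scoring.gap, prev[j][1], prev[j][2])
            left = (cur[j - 1][0] + scoring.gap, cur[j - 1][1], cur[j - 1][2])
            cur[j] = max(diag, up, left)
        prev = cur
    score, matches, diags = prev[n2]
    columns = n1 + n2 - diags
    return (matches / columns if columns else 1.0), columns


def build_distance_matrix(
    seqs: Sequence[Tuple[str, NucleotideSequence]],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> DistanceMatrix:
    """d[i][j] = 1 − pairwise identity."""
    taxa = [t for t, _ in seqs]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = pairwise_identity(seqs[i][1], seqs[j][1], scoring)
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(taxa, d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou–Nei neighbor joining.

    Q-criterion minimization; ties broken by the lexicographically
    smallest pair of subtree labels (each active node labelled by the
    smallest leaf name it contains), which makes the result invariant
    under taxon-order permutation.  Negative branch-length estimates are
    clamped to zero with a warning.  Requires >= 3 taxa; the returned tree
    is unrooted (trifurcating seed node).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.taxa)
    nodes: Dict[int, dendropy.Node] = {}
    labels: Dict[int, str] = {}
    for i, name in enumerate(dm.taxa):
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes[i] = node
        labels[i] = name
    D: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.d[i, j])

    def dist(i: int, j: int) -> float:
        return D[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(
                f"negative NJ branch length {x:.4f} clamped to 0",
                stacklevel=2,
            )
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        totals = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist(i, j) - totals[i] - totals[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = dist(i, j)
        li = clamp(0.5 * dij + (totals[i] - totals[j]) / (2 * (r - 2)))
        lj = clamp(dij - (0.5 * dij + (totals[i] - totals[j]) / (2 * (r - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes[next_id] = parent
        labels[next_id] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            D[tuple(sorted((next_id, k)))] = 0.5 * (
                dist(i, k) + dist(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    root = dendropy.Node()
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    for node_id, length in (
        (i, 0.5 * (dij + dik - djk)),
        (j, 0.5 * (dij + djk - dik)),
        (k, 0.5 * (dik + djk - dij)),
    ):
        root.add_child(nodes[node_id])
        nodes[node_id].edge.length = clamp(length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class GroupSummary:
    group: str
    min_identity: float
    mean_identity: float
    fully_conserved: bool


@dataclass(frozen=True)
class ConservationReport:
    reference_taxon: str
    identity_to_reference: Dict[str, float]
    groups: Dict[str, GroupSummary]


def conservation_report(
    seqs: Sequence[Tuple[str, NucleotideSequence]],
    reference_taxon: str,
    group_map: Dict[str, str],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> ConservationReport:
    """Identity of every taxon to the reference, summarized per group.

    A group is ``fully_conserved`` when its minimum identity to the
    reference is exactly 1.0 (the strict reading of "100% conservation").
    """
    by_taxon = dict(seqs)
    if reference_taxon not in by_taxon:
        raise ValueError(f"reference taxon {reference_taxon!r} absent")
    ref = by_taxon[reference_taxon]
    ident: Dict[str, float] = {}
    for taxon, seq in seqs:
        ident[taxon] = (
            1.0
            if taxon == reference_taxon
            else pairwise_identity(ref, seq, scoring)[0]
        )
    groups: Dict[str, GroupSummary] = {}
    for group in sorted(set(group_map.values())):
        members = [t for t, _ in seqs if group_map.get(t) == group]
        vals = [ident[t] for t in members]
        groups[group] = GroupSummary(
            group,
            min(vals),
            sum(vals) / len(vals),
            min(vals) == 1.0,
        )
    return ConservationReport(reference_taxon, ident, groups)


def parse_ortholog_headers(
    records: Sequence[Tuple[str, NucleotideSequence]],
) -> Tuple[List[Tuple[str, NucleotideSequence]], Dict[str, str]]:
    """Split ``taxon|group`` FASTA headers into (taxon, seq) + group map."""
    seqs: List[Tuple[str, NucleotideSequence]] = []
    group_map: Dict[str, str] = {}
    for header, seq in records:
        taxon, _, group = header.partition("|")
        seqs.append((taxon, seq))
        if group:
            group_map[taxon] = group
    return seqs, group_map


def make_orthologs(
    reference: NucleotideSequence,
    species: Sequence[Tuple[str, str]],  # (taxon, group)
    divergence: Dict[str, float],
    seed: int = 0,
) -> List[Tuple[str, NucleotideSequence]]:
    """Synthetic ortholog set: per-taxon point mutations of a reference.

    ``divergence`` maps group → per-base substitution probability (0 for a
    fully conserved group).  Stands in for browser-derived alignments,
    which are outside this package's scope.
    """
    import random

    rng = random.Random((seed, "orthologs").__repr__())
    out: List[Tuple[str, NucleotideSequence]] = []
    for taxon, group in species:
        rate = divergence.get(group, 0.0)
        bases = []
        for c in reference.bases:
            if rate > 0 and rng.random() < rate:
                bases.append(rng.choice([b for b in "ACGT" if b != c]))
            else:
                bases.append(c)
        out.append((taxon, NucleotideSequence("".join(bases))))
    return out
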