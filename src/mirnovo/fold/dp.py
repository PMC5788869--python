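"""Minimum-free-energy folding by Zuker-style dynamic programming.

Four tables over 0-based indices i <= j:

* ``C[i][j]``  — best energy given that (i, j) pair (hairpin, two-pair
  interior loop bounded by ``MAXLOOP`` unpaired bases, or multiloop
  closure);
* ``M[i][j]``  — best energy of a multiloop segment holding >= 1 branch;
* ``M1[i][j]`` — multiloop segment whose single branch starts exactly at
  ``i`` (unpaired tail allowed on the right);
* ``F[i]``    — best energy of the suffix ``i..n-1`` in the exterior loop.

O(n^3) time overall (interior loops are bounded, multiloop and exterior
decompositions contribute the cubic term).

Tie-breaking: co-optimal structures are resolved deterministically by the
traceback, which examines alternatives in a fixed order that prefers
leaving the leftmost undecided position unpaired (suffix-unpaired first in
the exterior and multiloop tables; hairpin before interior loops with
longer 5' unpaired stretches before shorter ones; multiloop last).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

from ..seq import NucleotideSequence
from .energies import e_ext_stem, e_hairpin, e_interior, e_ml_closing, e_ml_stem
from .params import INF, MAXLOOP, PAIR_TYPE, TURN, EnergyModel, encode

MAX_FOLD_LEN = 500


@dataclass(frozen=True)
class HairpinFold:
    """A predicted secondary structure with its minimum free energy."""

    seq: NucleotideSequence
    structure: str
    mfe_kcal_mol: float
    pair_map: Dict[int, int]  # 1-based, both directions

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.seq):
            raise ValueError("structure length != sequence length")
        for i, j in self.pair_map.items():
            if self.pair_map.get(j) != i:
                raise ValueError("pair_map not involutive")


def _fill(model: EnergyModel, s: List[int]):
    n = len(s)
    C = [[INF] * n for _ in range(n)]
    M = [[INF] * n for _ in range(n)]
    M1 = [[INF] * n for _ in range(n)]
    ml_u = model.ml_unpaired

    # hot-loop locals: the interior-loop energy is inlined below because it
    # runs ~n^2 * MAXLOOP^2 times per fold (loops here are bounded by
    # MAXLOOP, so the length tables never need extrapolation)
    stack_t = model.stack
    int11 = model.int11
    int21 = model.int21
    int22 = model.int22
    mm_int = model.mismatch_internal
    mm_1n = model.mismatch_internal_1n
    mm_23 = model.mismatch_internal_23
    bulge_len = model.bulge_len
    internal_len = model.internal_len
    ninio = model.ninio
    max_ninio = model.max_ninio
    term_au = model.terminal_au
    pt = [[PAIR_TYPE[s[i]][s[j]] for j in range(n)] for i in range(n)]

    for span in range(TURN + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- C: (i, j) must be able to pair ---
            t1 = pt[i][j]
            if t1:
                best = e_hairpin(model, s, i, j)
                si1 = s[i + 1]
                sj1 = s[j - 1]
                pmax = min(i + MAXLOOP + 1, j - TURN - 1)
                for p in range(i + 1, pmax + 1):
                    n1 = p - i - 1
                    qmin = max(p + TURN + 1, j - 1 - (MAXLOOP - n1))
                    row_c = C[p]
                    row_pt = pt
                    sp1 = s[p - 1]
                    for q in range(qmin, j):
                        inner = row_c[q]
                        if inner >= INF or not row_pt[p][q]:
                            continue
                        t2 = PAIR_TYPE[s[q]][s[p]]
                        n2 = j - q - 1
                        if n1 == 0 and n2 == 0:
                            e = stack_t[t1][t2]
                        elif n1 == 0 or n2 == 0:
                            nl = n1 or n2
                            e = bulge_len[nl]
                            if nl == 1:
                                e += stack_t[t1][t2]
                            else:
                                if t1 > 2:
                                    e += term_au
                                if t2 > 2:
                                    e += term_au
                        else:
                            sq1 = s[q + 1]
                            if n1 == 1 and n2 == 1:
                                e = int11[t1][t2][si1][sj1]
                            elif n1 == 1 and n2 == 2:
                                e = int21[t1][t2][si1][sq1][sj1]
                            elif n1 == 2 and n2 == 1:
                                e = int21[t2][t1][sq1][si1][sp1]
                            elif n1 == 2 and n2 == 2:
                                e = int22[t1][t2][si1 - 1][sp1 - 1][sq1 - 1][
                                    sj1 - 1
                                ]
                            elif n1 == 1 or n2 == 1:
                                nl = n1 if n1 > n2 else n2
                                e = (
                                    internal_len[nl + 1]
                                    + min(max_ninio, (nl - 1) * ninio)
                                    + mm_1n[t1][si1][sj1]
                                    + mm_1n[t2][sq1][sp1]
                                )
                            elif (n1 == 2 and n2 == 3) or (
                                n1 == 3 and n2 == 2
                            ):
                                e = (
                                    internal_len[5]
                                    + ninio
                                    + mm_23[t1][si1][sj1]
                                    + mm_23[t2][sq1][sp1]
                                )
                            else:
                                asym = n1 - n2 if n1 > n2 else n2 - n1
                                e = (
                                    internal_len[n1 + n2]
                                    + min(max_ninio, asym * ninio)
                                    + mm_int[t1][si1][sj1]
                                    + mm_int[t2][sq1][sp1]
                                )
                        e += inner
                        if e < best:
                            best = e
                # multiloop closure: i+1..k | k+1..j-1
                if j - i - 1 >= 2 * (TURN + 2):
                    close = e_ml_closing(model, s, i, j)
                    row_m = M[i + 1]
                    for k in range(i + 1 + TURN, j - TURN - 2):
                        if row_m[k] < INF and M1[k + 1][j - 1] < INF:
                            e = close + row_m[k] + M1[k + 1][j - 1]
                            if e < best:
                                best = e
                C[i][j] = best

            if i == 0 or j == n - 1:
                continue  # M/M1 segments live strictly inside a closing pair

            # --- M1: single branch starting at i ---
            best = M1[i][j - 1] + ml_u if M1[i][j - 1] < INF else INF
            if C[i][j] < INF:
                e = C[i][j] + e_ml_stem(model, s, i, j)
                if e < best:
                    best = e
            M1[i][j] = best

            # --- M: >= 1 branch in i..j ---
            best = M[i + 1][j] + ml_u if M[i + 1][j] < INF else INF
            if M1[i][j] < best:
                best = M1[i][j]
            for k in range(i + TURN + 1, j - TURN - 1):
                if M[i][k] < INF and M1[k + 1][j] < INF:
                    e = M[i][k] + M1[k + 1][j]
                    if e < best:
                        best = e
            M[i][j] = best

    F = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        best = F[i + 1]
        for j in range(i + TURN + 1, n):
            if C[i][j] < INF:
                e = C[i][j] + e_ext_stem(model, s, i, j) + F[j + 1]
                if e < best:
                    best = e
        F[i] = best
    return C, M, M1, F


def _traceback(model: EnergyModel, s: List[int], C, M, M1, F) -> str:
    n = len(s)
    structure = ["."] * n
    ml_u = model.ml_unpaired

    def trace_C(i: int, j: int) -> None:
        structure[i] = "("
        structure[j] = ")"
        target = C[i][j]
        if e_hairpin(model, s, i, j) == target:
            return
        # interior loops: prefer the longest 5' unpaired stretch (largest p)
        pmax = min(i + MAXLOOP + 1, j - TURN - 1)
        for p in range(pmax, i, -1):
            qmin = max(p + TURN + 1, j - 1 - (MAXLOOP - (p - i - 1)))
            for q in range(qmin, j):
                if PAIR_TYPE[s[p]][s[q]] and C[p][q] < INF:
                    if e_interior(model, s, i, j, p, q) + C[p][q] == target:
                        trace_C(p, q)
                        return
        close = e_ml_closing(model, s, i, j)
        for k in range(i + 1 + TURN, j - TURN - 2):
            if M[i + 1][k] < INF and M1[k + 1][j - 1] < INF:
                if close + M[i + 1][k] + M1[k + 1][j - 1] == target:
                    trace_M(i + 1, k)
                    trace_M1(k + 1, j - 1)
                    return
        raise AssertionError("traceback failed in C")

    def trace_M(i: int, j: int) -> None:
        target = M[i][j]
        if M[i + 1][j] < INF and M[i + 1][j] + ml_u == target:
            trace_M(i + 1, j)
            return
        if M1[i][j] == target:
            trace_M1(i, j)
            return
        for k in range(i + TURN + 1, j - TURN - 1):
            if M[i][k] < INF and M1[k + 1][j] < INF:
                if M[i][k] + M1[k + 1][j] == target:
                    trace_M(i, k)
                    trace_M1(k + 1, j)
                    return
        raise AssertionError("traceback failed in M")

    def trace_M1(i: int, j: int) -> None:
        target = M1[i][j]
        if M1[i][j - 1] < INF and M1[i][j - 1] + ml_u == target:
            trace_M1(i, j - 1)
            return
        if C[i][j] < INF and C[i][j] + e_ml_stem(model, s, i, j) == target:
            trace_C(i, j)
            return
        raise AssertionError("traceback failed in M1")

    i = 0
    while i < n:
        if F[i] == F[i + 1]:
            i += 1
            continue
        hit = False
        for j in range(i + TURN + 1, n):
            if C[i][j] < INF:
                if C[i][j] + e_ext_stem(model, s, i, j) + F[j + 1] == F[i]:
                    trace_C(i, j)
                    i = j + 1
                    hit = True
                    break
        if not hit:
            raise AssertionError("traceback failed in F")
    return "".join(structure)


def mfe_fold(seq: NucleotideSequence, model: EnergyModel) -> HairpinFold:
    """Fold a sequence to its minimum-free-energy nested structure.

    Returns a :class:`HairpinFold`; the MFE is <= 0 because the empty
    structure is always available at zero.  Sequence length is bounded at
    ``MAX_FOLD_LEN`` (this folder targets precursor-scale windows, not
    genome-scale transcripts).
    """
    n = len(seq)
    if n == 0 or n > MAX_FOLD_LEN:
        raise ValueError(f"sequence length must be in 1..{MAX_FOLD_LEN}")
    s = encode(seq.bases)
    if n <= TURN + 1:
        return HairpinFold(seq, "." * n, 0.0, {})
    C, M, M1, F = _fill(model, s)
    structure = _traceback(model, s, C, M, M1, F)
    pair_map: Dict[int, int] = {}
    stack: List[int] = []
    for k, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(k)
        elif c == ")":
            a = stack.pop()
            pair_map[a] = k
            pair_map[k] = a
    return HairpinFold(seq, structure, F[0] / 100.0, pair_map)
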