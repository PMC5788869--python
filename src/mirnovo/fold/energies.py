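"""Loop free energies under the nearest-neighbor model.

All functions work on integer-encoded sequences (``A=1..U=4``, 0-based
indices) and return energies in 0.01 kcal/mol.  The decomposition follows
the standard nearest-neighbor scheme: a secondary structure's energy is the
sum over its loops — stacks, hairpin loops, bulge/interior loops, multi-
branch loops — plus exterior-loop terms.  Dangle handling is the "d2"
approximation: every helix end facing the exterior loop or a multiloop
receives the terminal-mismatch energy of its two adjacent bases (or a
single dangle at a sequence end), regardless of whether those bases also
serve a neighboring helix.
"""

from __future__ import annotations

from typing import List, Tuple

from .params import INF, LXC, PAIR_TYPE, TURN, EnergyModel

_RNA = "NACGU"


def pair_type(s: List[int], i: int, j: int) -> int:
    return PAIR_TYPE[s[i]][s[j]]


def e_hairpin(model: EnergyModel, s: List[int], i: int, j: int) -> int:
    """Energy of a hairpin loop closed by pair (i, j)."""
    size = j - i - 1
    if size < TURN:
        return INF
    ptype = PAIR_TYPE[s[i]][s[j]]
    if ptype == 0:
        return INF
    loop_seq = "".join(_RNA[b] for b in s[i : j + 1])
    if size == 3:
        tri = model.triloops.get(loop_seq)
        if tri is not None:
            return tri
        e = model.hairpin_length_energy(3)
        if ptype > 2:
            e += model.terminal_au
        return e
    if size == 4:
        tetra = model.tetraloops.get(loop_seq)
        if tetra is not None:
            return tetra
    if size == 6:
        hexa = model.hexaloops.get(loop_seq)
        if hexa is not None:
            return hexa
    e = model.hairpin_length_energy(size)
    e += model.mismatch_hairpin[ptype][s[i + 1]][s[j - 1]]
    return e


def e_interior(
    model: EnergyModel, s: List[int], i: int, j: int, p: int, q: int
) -> int:
    """Energy of the two-pair loop (i,j)–(p,q): stack, bulge or interior.

    (i, j) is the outer pair, (p, q) the inner one, i < p < q < j.
    """
    t1 = PAIR_TYPE[s[i]][s[j]]
    t2 = PAIR_TYPE[s[q]][s[p]]  # inner pair read on the reverse strand
    if t1 == 0 or t2 == 0:
        return INF
    n1 = p - i - 1
    n2 = j - q - 1
    if n1 == 0 and n2 == 0:
        return model.stack[t1][t2]
    ns, nl = (n1, n2) if n1 <= n2 else (n2, n1)
    if ns == 0:  # bulge
        e = model.bulge_length_energy(nl)
        if nl == 1:
            e += model.stack[t1][t2]
        else:
            if t1 > 2:
                e += model.terminal_au
            if t2 > 2:
                e += model.terminal_au
        return e
    si1, sj1 = s[i + 1], s[j - 1]
    sp1, sq1 = s[p - 1], s[q + 1]
    if ns == 1:
        if nl == 1:
            return model.int11[t1][t2][si1][sj1]
        if nl == 2:
            if n1 == 1:
                return model.int21[t1][t2][si1][sq1][sj1]
            return model.int21[t2][t1][sq1][si1][sp1]
        # 1 x n (n > 2)
        e = model.internal_length_energy(nl + 1)
        e += min(model.max_ninio, (nl - ns) * model.ninio)
        e += (
            model.mismatch_internal_1n[t1][si1][sj1]
            + model.mismatch_internal_1n[t2][sq1][sp1]
        )
        return e
    if ns == 2:
        if nl == 2:
            return model.int22[t1][t2][si1 - 1][sp1 - 1][sq1 - 1][sj1 - 1]
        if nl == 3:
            e = model.internal_length_energy(5) + model.ninio
            e += (
                model.mismatch_internal_23[t1][si1][sj1]
                + model.mismatch_internal_23[t2][sq1][sp1]
            )
            return e
    e = model.internal_length_energy(n1 + n2)
    e += min(model.max_ninio, (nl - ns) * model.ninio)
    e += (
        model.mismatch_internal[t1][si1][sj1]
        + model.mismatch_internal[t2][sq1][sp1]
    )
    return e


def e_ext_stem(model: EnergyModel, s: List[int], i: int, j: int) -> int:
    """d2 contribution of a helix (i, j) sitting in the exterior loop."""
    ptype = PAIR_TYPE[s[i]][s[j]]
    e = model.terminal_au if ptype > 2 else 0
    if model.dangle_mode == "none":
        return e
    n = len(s)
    s5 = s[i - 1] if i > 0 else -1
    s3 = s[j + 1] if j < n - 1 else -1
    if s5 >= 0 and s3 >= 0:
        e += model.mismatch_exterior[ptype][s5][s3]
    elif s5 >= 0:
        e += model.dangle5[ptype][s5]
    elif s3 >= 0:
        e += model.dangle3[ptype][s3]
    return e


def e_ml_stem(model: EnergyModel, s: List[int], i: int, j: int) -> int:
    """d2 contribution of a branch helix (i, j) inside a multiloop."""
    ptype = PAIR_TYPE[s[i]][s[j]]
    e = model.ml_branch + (model.terminal_au if ptype > 2 else 0)
    if model.dangle_mode != "none":
        # inside a multiloop both neighbors always exist
        e += model.mismatch_multi[ptype][s[i - 1]][s[j + 1]]
    return e


def e_ml_closing(model: EnergyModel, s: List[int], i: int, j: int) -> int:
    """Contribution of the closing pair (i, j) of a multiloop."""
    ptype = PAIR_TYPE[s[j]][s[i]]  # closing pair read from the loop side
    e = model.ml_closing + model.ml_branch
    if ptype > 2:
        e += model.terminal_au
    if model.dangle_mode != "none":
        e += model.mismatch_multi[ptype][s[j - 1]][s[i + 1]]
    return e


def parse_structure(structure: str) -> dict:
    """Dot-bracket → pair map (0-based, both directions).  Errors on
    unbalanced brackets."""
    stack: List[int] = []
    pairs: dict = {}
    for k, c in enumerate(structure):
        if c == "(":
            stack.append(k)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {k + 1}")
            a = stack.pop()
            pairs[a] = k
            pairs[k] = a
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return pairs


def eval_structure(model: EnergyModel, s: List[int], structure: str) -> int:
    """Score an arbitrary nested structure by loop decomposition.

    Independent of the dynamic-programming folder; used as the energy
    arbiter by the exhaustive enumeration oracle and in consistency tests
    (re-scoring a DP traceback must reproduce the DP energy exactly).
    """
    n = len(s)
    if len(structure) != n:
        raise ValueError("structure/sequence length mismatch")
    pairs = parse_structure(structure)

    def children(i: int, j: int) -> List[Tuple[int, int]]:
        out = []
        k = i + 1
        while k < j:
            if k in pairs:
                out.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                k += 1
        return out

    def loop_energy(i: int, j: int) -> int:
        kids = children(i, j)
        if not kids:
            return e_hairpin(model, s, i, j)
        if len(kids) == 1:
            (p, q) = kids[0]
            inner = e_interior(model, s, i, j, p, q)
            return inner + loop_energy(p, q)
        e = e_ml_closing(model, s, i, j)
        unpaired = j - i - 1
        for (p, q) in kids:
            e += e_ml_stem(model, s, p, q) + loop_energy(p, q)
            unpaired -= q - p + 1
        e += model.ml_unpaired * unpaired
        return e

    total = 0
    for (p, q) in children(-1, n):  # exterior loop; virtual bounds
        total += e_ext_stem(model, s, p, q) + loop_energy(p, q)
    return total
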