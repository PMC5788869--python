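"""Exhaustive structure enumeration — the folding test oracle.

Generates every valid nested secondary structure of a short sequence
(minimum hairpin loop of 3, canonical + wobble pairs only) exactly once,
scores each with the same loop-decomposition evaluator the DP uses, and
can report the minimum.  Exponential in length; restricted to n <= 18.
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Tuple

from ..seq import NucleotideSequence
from .energies import eval_structure
from .params import PAIR_TYPE, TURN, EnergyModel, encode

MAX_ENUM_LEN = 18


def enumerate_structures(
    seq: NucleotideSequence, model: EnergyModel
) -> List[Tuple[str, float]]:
    """All valid nested structures with their energies (kcal/mol).

    Deterministic order: structures are generated left to right with "i
    unpaired" explored before each possible partner of i in increasing
    order.
    """
    n = len(seq)
    if n > MAX_ENUM_LEN:
        raise ValueError(f"enumeration limited to n <= {MAX_ENUM_LEN}")
    s = encode(seq.bases)

    @lru_cache(maxsize=None)
    def gen(i: int, j: int) -> Tuple[str, ...]:
        """All structures of the closed interval [i, j)."""
        if j - i <= TURN + 1:
            return ("." * (j - i),)
        out = ["." + rest for rest in gen(i + 1, j)]
        for k in range(i + TURN + 1, j):
            if PAIR_TYPE[s[i]][s[k]]:
                for inner in gen(i + 1, k):
                    for rest in gen(k + 1, j):
                        out.append("(" + inner + ")" + rest)
        return tuple(out)

    structures = gen(0, n)
    gen.cache_clear()
    return [(st, eval_structure(model, s, st) / 100.0) for st in structures]


def enumeration_minimum(
    seq: NucleotideSequence, model: EnergyModel
) -> Tuple[str, float]:
    """The minimum-energy structure over the full enumeration.

    Tie-break: the first structure in generation order among co-optimals
    (the all-dots structure is generated first, so fully unpaired wins a
    tie at zero).
    """
    best_st, best_e = None, None
    for st, e in enumerate_structures(seq, model):
        if best_e is None or e < best_e - 1e-12:
            best_st, best_e = st, e
    return best_st, best_e
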