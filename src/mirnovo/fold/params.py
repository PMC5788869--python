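"""Nearest-neighbor thermodynamic parameters (Turner 2004, 37 °C).

The free-energy tables ship with the package as plain-text files under
``data/`` in units of 0.01 kcal/mol (integers; ``NA`` marks a disallowed
configuration).  The loader pins each file by SHA-256 so a silently edited
table is caught at load time.

Indexing conventions
--------------------
Bases are encoded ``A=1, C=2, G=3, U/T=4`` with ``0`` meaning "no base"
(a missing neighbor at a sequence end).  Pair types follow the canonical
order ``CG=1, GC=2, GU=3, UG=4, AU=5, UA=6``; ``0`` is "cannot pair".
The pair type of a helix end (i, j) is read 5'→3' on the outer strand,
i.e. ``pair_type[base_i][base_j]``.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

INF = 10_000_000  # forbidden / +infinity, in 0.01 kcal/mol
MAXLOOP = 30      # largest interior loop (unpaired total) searched
TURN = 3          # minimum hairpin loop size
LXC = 107.856     # Jacobson–Stockmayer extrapolation prefactor (1.75*RT*100)

_ENCODE = {"A": 1, "C": 2, "G": 3, "U": 4, "T": 4}

# pair_type[b1][b2], bases encoded as above (0 = none)
PAIR_TYPE = [[0] * 5 for _ in range(5)]
for _code, (_a, _b) in enumerate(
    [("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")],
    start=1,
):
    PAIR_TYPE[_ENCODE[_a]][_ENCODE[_b]] = _code

# pinned SHA-256 of the shipped parameter files
_CHECKSUMS = {
    "turner2004.txt":
        "dd4e5b1725499979461d1c38a7a43037938ba4e1d65a4dbccb199d89c6d0d468",
    "turner2004_int21.txt":
        "90eaf7270fb6c5ea327d7523c02039388f3b989b1de2c884674231558c7f920b",
    "turner2004_int22.txt":
        "316f5e81bcb55d800d62f1b22e9f78257834694289b6117b7fa73cdb97996b64",
}


def encode(seq_rna_or_dna: str) -> List[int]:
    """Encode a sequence string to integer base codes (T treated as U)."""
    return [_ENCODE[c] for c in seq_rna_or_dna.upper()]


def _parse_sections(text: str) -> Dict[str, List[str]]:
    sections: Dict[str, List[str]] = {}
    cur = None
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        m = re.match(r"\[(\S+)\]$", line)
        if m:
            cur = m.group(1)
            sections[cur] = []
            continue
        if cur is None:
            raise ValueError("parameter data before first section header")
        sections[cur].extend(line.split())
    return sections


def _vals(tokens: List[str]) -> List[int]:
    return [INF if t == "NA" else int(t) for t in tokens]


@dataclass
class EnergyModel:
    """Loaded Turner free-energy tables plus model-mode switches.

    ``dangle_mode`` is fixed at ``"d2"`` (terminal-mismatch energies applied
    on both sides of every exterior/multiloop helix, the default of the
    RNAfold web server); ``"none"`` disables all dangle contributions.
    """

    stack: list
    mismatch_hairpin: list
    mismatch_internal: list
    mismatch_internal_1n: list
    mismatch_internal_23: list
    mismatch_multi: list
    mismatch_exterior: list
    dangle5: list
    dangle3: list
    hairpin_len: list
    bulge_len: list
    internal_len: list
    int11: list
    int21: list
    int22: list
    ml_unpaired: int
    ml_closing: int
    ml_branch: int
    ninio: int
    max_ninio: int
    terminal_au: int
    tetraloops: Dict[str, int]
    triloops: Dict[str, int]
    hexaloops: Dict[str, int]
    dangle_mode: str = "d2"
    checksums: Dict[str, str] = field(default_factory=dict)

    def hairpin_length_energy(self, size: int) -> int:
        if size <= 30:
            return self.hairpin_len[size]
        return self.hairpin_len[30] + int(LXC * math.log(size / 30.0))

    def bulge_length_energy(self, size: int) -> int:
        if size <= 30:
            return self.bulge_len[size]
        return self.bulge_len[30] + int(LXC * math.log(size / 30.0))

    def internal_length_energy(self, size: int) -> int:
        if size <= 30:
            return self.internal_len[size]
        return self.internal_len[30] + int(LXC * math.log(size / 30.0))


def _reshape(flat: List[int], *dims: int):
    """Nest a flat list into nested lists with the given dimensions."""
    if len(dims) == 1:
        assert len(flat) == dims[0]
        return flat
    step = 1
    for d in dims[1:]:
        step *= d
    return [
        _reshape(flat[i * step : (i + 1) * step], *dims[1:])
        for i in range(dims[0])
    ]


def _pad_pairs(table6, empty):
    """Prepend a row/entry for pair code 0 so tables index by pair type."""
    return [empty] + table6


def load_energy_model(dangle_mode: str = "d2") -> EnergyModel:
    """Load and validate the shipped Turner 2004 parameter files."""
    pkg = resources.files(__package__) / "data"
    texts: Dict[str, str] = {}
    sums: Dict[str, str] = {}
    for name in _CHECKSUMS:
        raw = (pkg / name).read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if _CHECKSUMS[name] is not None and digest != _CHECKSUMS[name]:
            raise ValueError(f"parameter file {name} checksum mismatch")
        texts[name] = raw.decode()
        sums[name] = digest

    sec = _parse_sections(texts["turner2004.txt"])
    sec.update(_parse_sections(texts["turner2004_int21.txt"]))
    sec.update(_parse_sections(texts["turner2004_int22.txt"]))

    stack = _pad_pairs(
        [[INF] + row for row in _reshape(_vals(sec["stack"]), 6, 6)],
        [INF] * 7,
    )

    def mm(name):
        return _pad_pairs(_reshape(_vals(sec[name]), 6, 5, 5), [[INF] * 5] * 5)

    def dang(name):
        return _pad_pairs(_reshape(_vals(sec[name]), 6, 5), [INF] * 5)

    i11 = _reshape(_vals(sec["int11"]), 6, 6, 5, 5)
    i11 = _pad_pairs(
        [_pad_pairs(b, [[INF] * 5] * 5) for b in i11],
        [[[INF] * 5] * 5] * 7,
    )
    i21 = _reshape(_vals(sec["int21"]), 6, 6, 5, 5, 5)
    i21 = _pad_pairs(
        [_pad_pairs(b, [[[INF] * 5] * 5] * 5) for b in i21],
        [[[[INF] * 5] * 5] * 5] * 7,
    )
    # int22 is tabulated for real bases only; index with base-1
    i22 = _reshape(_vals(sec["int22"]), 6, 6, 4, 4, 4, 4)
    empty22 = [[[[INF] * 4] * 4] * 4] * 4
    i22 = _pad_pairs([_pad_pairs(b, empty22) for b in i22], [empty22] * 7)

    ml = _vals(sec["multiloop"])
    ninio = _vals(sec["ninio"])
    misc = _vals(sec["misc"])

    def special(name):
        toks = sec[name]
        return {toks[i]: int(toks[i + 1]) for i in range(0, len(toks), 2)}

    return EnergyModel(
        stack=stack,
        mismatch_hairpin=mm("mismatch_hairpin"),
        mismatch_internal=mm("mismatch_internal"),
        mismatch_internal_1n=mm("mismatch_internal_1n"),
        mismatch_internal_23=mm("mismatch_internal_23"),
        mismatch_multi=mm("mismatch_multi"),
        mismatch_exterior=mm("mismatch_exterior"),
        dangle5=dang("dangle5"),
        dangle3=dang("dangle3"),
        hairpin_len=_vals(sec["hairpin_length"]),
        bulge_len=_vals(sec["bulge_length"]),
        internal_len=_vals(sec["internal_length"]),
        int11=i11,
        int21=i21,
        int22=i22,
        ml_unpaired=ml[0],
        ml_closing=ml[1],
        ml_branch=ml[2],
        ninio=ninio[0],
        max_ninio=ninio[1],
        terminal_au=misc[0],
        tetraloops=special("tetraloops"),
        triloops=special("triloops"),
        hexaloops=special("hexaloops"),
        dangle_mode=dangle_mode,
        checksums=sums,
    )
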