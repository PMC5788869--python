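"""Fold-back hairpin assessment of candidate precursor windows.

A miRNA precursor must fold into a stem-loop with the mature sequence in
one arm: its bases pair away from themselves (no self-pairing), and all
partners lie on one side — 5' arm if the partners sit downstream, 3' arm
if upstream.  ``best_window`` operationalizes "fold a window of the
precursor": every window of the requested length that fully contains the
mature span is folded and the lowest-MFE one reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from ..seq import NucleotideSequence
from .dp import HairpinFold, mfe_fold
from .params import EnergyModel


@dataclass(frozen=True)
class ArmAssignment:
    """Where the mature sequence sits within a folded precursor window."""

    mature_span: Tuple[int, int]  # 1-based inclusive on the folded sequence
    arm: str                      # "5p", "3p" or "NONE"
    paired_fraction: float
    self_pairing: bool


@dataclass(frozen=True)
class FoldThresholds:
    """Pass/fail thresholds for the hairpin candidate test."""

    mfe_max: float = -10.0        # kcal/mol; candidate must fold at least this low
    min_paired: float = 0.6       # fraction of mature bases paired


@dataclass(frozen=True)
class CandidateEvaluation:
    passed: bool
    fold: HairpinFold
    arm: ArmAssignment
    reasons: Tuple[str, ...] = field(default_factory=tuple)


def best_window(
    precursor: NucleotideSequence,
    mature_span: Tuple[int, int],
    model: EnergyModel,
    window_len: int = 50,
) -> Tuple[int, NucleotideSequence, HairpinFold]:
    """Fold every window of ``window_len`` containing the mature span and
    return ``(window_start, window_seq, fold)`` for the lowest MFE.

    ``window_start`` is 1-based on the precursor.  Ties go to the leftmost
    window.  If the window is shorter than the mature sequence, the single
    window anchored at the mature 5' end is used (maximal admissible
    overlap).
    """
    n = len(precursor)
    ms, me = mature_span
    if not (1 <= ms <= me <= n):
        raise ValueError(f"mature span {mature_span} outside precursor 1..{n}")
    if window_len > n:
        raise ValueError("window longer than precursor")
    if window_len >= me - ms + 1:
        lo = max(1, me - window_len + 1)
        hi = min(ms, n - window_len + 1)
        starts = range(lo, hi + 1)
    else:
        starts = range(min(ms, n - window_len + 1), min(ms, n - window_len + 1) + 1)
    best: Optional[Tuple[float, int, NucleotideSequence, HairpinFold]] = None
    for start in starts:
        window = precursor.subsequence(start, window_len)
        fold = mfe_fold(window, model)
        if best is None or fold.mfe_kcal_mol < best[0] - 1e-9:
            best = (fold.mfe_kcal_mol, start, window, fold)
    assert best is not None
    return best[1], best[2], best[3]


def assign_arm(fold: HairpinFold, mature_span: Tuple[int, int]) -> ArmAssignment:
    """Locate the mature span relative to the folded stem-loop."""
    ms, me = mature_span
    if not (1 <= ms <= me <= len(fold.seq)):
        raise ValueError(f"mature span {mature_span} outside folded sequence")
    partners = [
        fold.pair_map[k] for k in range(ms, me + 1) if k in fold.pair_map
    ]
    mature_len = me - ms + 1
    paired_fraction = len(partners) / mature_len
    self_pairing = any(ms <= p <= me for p in partners)
    if partners and not self_pairing:
        if all(p > me for p in partners):
            arm = "5p"
        elif all(p < ms for p in partners):
            arm = "3p"
        else:
            arm = "NONE"
    else:
        arm = "NONE"
    return ArmAssignment(mature_span, arm, paired_fraction, self_pairing)


def evaluate_candidate(
    window: NucleotideSequence,
    mature_span: Tuple[int, int],
    model: EnergyModel,
    thresholds: FoldThresholds = FoldThresholds(),
) -> CandidateEvaluation:
    """The fold-back hairpin test on one precursor window.

    Pass requires all three: MFE at or below ``mfe_max``, the mature in a
    single arm, and at least ``min_paired`` of its bases paired.
    """
    fold = mfe_fold(window, model)
    arm = assign_arm(fold, mature_span)
    reasons = []
    if not fold.mfe_kcal_mol <= thresholds.mfe_max:
        reasons.append(
            f"MFE {fold.mfe_kcal_mol:.2f} above threshold {thresholds.mfe_max:.2f}"
        )
    if arm.arm == "NONE":
        reasons.append("mature not confined to one hairpin arm")
    if arm.paired_fraction < thresholds.min_paired:
        reasons.append(
            f"paired fraction {arm.paired_fraction:.2f} below "
            f"{thresholds.min_paired:.2f}"
        )
    return CandidateEvaluation(
        passed=not reasons, fold=fold, arm=arm, reasons=tuple(reasons)
    )
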