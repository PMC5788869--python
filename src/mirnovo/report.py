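"""miRNA annotation criteria, expression fold-change filters, final report.

The community criteria for annotating a novel miRNA are codified as a
per-candidate checklist:

(a) a ~22-nt transcript traceable to a genomic location (length window,
    default 18–26 nt);
(b) exact match to the source organism's genome;
(c) a fold-back precursor with the mature in one arm at minimum free
    energy — a candidate passes if any of its precursor windows passes
    the hairpin test;
(d) phylogenetic conservation — strict 100%-in-group by default, with a
    soft minimum-identity floor available;
(e) precursor accumulation under reduced Dicer function — biochemical
    evidence that can only be supplied externally, recorded as
    ``not_evaluated`` when absent and never computed here.

Overall status requires (a)–(d); (e) is reported but does not gate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .conservation import ConservationReport
from .discovery import CandidateResult
from .seq import NucleotideSequence, find_occurrences, reverse_complement


@dataclass(frozen=True)
class CriteriaParams:
    len_range: Tuple[int, int] = (18, 26)
    cons_group: str = "mammals"
    cons_min: float = 0.9  # soft identity floor; set to 1.0 for the strict reading


@dataclass(frozen=True)
class Criterion:
    status: str   # "pass" | "fail" | "not_evaluated"
    evidence: str


@dataclass
class CandidateReport:
    candidate_id: str
    criteria: Dict[str, Criterion]
    mature_len: int
    locus: str
    best_fold: Optional[Dict]
    conservation_summary: Optional[Dict]
    dominance_share: Optional[float]

    @property
    def overall(self) -> str:
        needed = ["a_length", "b_genome_match", "c_hairpin_arm", "d_conservation"]
        return (
            "pass"
            if all(self.criteria[k].status == "pass" for k in needed)
            else "fail"
        )


def evaluate_criteria(
    result: CandidateResult,
    genome: Sequence[Tuple[str, NucleotideSequence]],
    conservation: Optional[ConservationReport] = None,
    params: CriteriaParams = CriteriaParams(),
    dicer_evidence: Optional[bool] = None,
    dominance_share: Optional[float] = None,
) -> CandidateReport:
    """Apply the annotation checklist to one discovery result."""
    cand = result.candidate
    mature = cand.mature
    crit: Dict[str, Criterion] = {}

    lo, hi = params.len_range
    ok = lo <= len(mature) <= hi
    crit["a_length"] = Criterion(
        "pass" if ok else "fail",
        f"mature length {len(mature)} nt vs window [{lo}, {hi}]",
    )

    hits = 0
    for _, chrom_seq in genome:
        hits += len(find_occurrences(mature, chrom_seq))
        hits += len(find_occurrences(reverse_complement(mature), chrom_seq))
    crit["b_genome_match"] = Criterion(
        "pass" if hits > 0 else "fail",
        f"{hits} exact genomic occurrence(s)",
    )

    if result.is_novel_mirna_like and result.evaluation is not None:
        ev = result.evaluation
        crit["c_hairpin_arm"] = Criterion(
            "pass",
            f"window MFE {ev.fold.mfe_kcal_mol:.2f} kcal/mol, arm "
            f"{ev.arm.arm}, paired fraction {ev.arm.paired_fraction:.2f}",
        )
    else:
        reasons = (
            "; ".join(result.evaluation.reasons)
            if result.evaluation is not None
            else "no window evaluated"
        )
        crit["c_hairpin_arm"] = Criterion("fail", f"no passing window ({reasons})")

    if conservation is None:
        crit["d_conservation"] = Criterion(
            "not_evaluated", "no ortholog set supplied"
        )
    else:
        summary = conservation.groups.get(params.cons_group)
        if summary is None:
            crit["d_conservation"] = Criterion(
                "fail", f"group {params.cons_group!r} absent from report"
            )
        else:
            ok = (
                summary.fully_conserved
                or summary.min_identity >= params.cons_min
            )
            crit["d_conservation"] = Criterion(
                "pass" if ok else "fail",
                f"group {summary.group}: min identity "
                f"{summary.min_identity:.3f}, fully_conserved="
                f"{summary.fully_conserved}",
            )

    if dicer_evidence is None:
        crit["e_dicer_evidence"] = Criterion(
            "not_evaluated", "external biochemical evidence not supplied"
        )
    else:
        crit["e_dicer_evidence"] = Criterion(
            "pass" if dicer_evidence else "fail",
            "externally supplied Dicer-dependence flag",
        )

    best_fold = None
    if result.evaluation is not None:
        win = result.passing_window
        best_fold = {
            "mfe_kcal_mol": result.evaluation.fold.mfe_kcal_mol,
            "structure": result.evaluation.fold.structure,
            "arm": result.evaluation.arm.arm,
            "paired_fraction": result.evaluation.arm.paired_fraction,
            "window_len": win.window_len if win else None,
            "window_genome_start": win.genome_start if win else None,
        }
    cons_summary = None
    if conservation is not None:
        cons_summary = {
            g: {
                "min_identity": s.min_identity,
                "mean_identity": s.mean_identity,
                "fully_conserved": s.fully_conserved,
            }
            for g, s in conservation.groups.items()
        }
    loc = cand.locus
    return CandidateReport(
        candidate_id=cand.candidate_id,
        criteria=crit,
        mature_len=len(mature),
        locus=f"{loc.chrom}:{loc.start}-{loc.end}({loc.strand})",
        best_fold=best_fold,
        conservation_summary=cons_summary,
        dominance_share=dominance_share,
    )


# --- expression fold-change filter ---

class ExpressionTable:
    """Two-condition expression values with derived fold changes.

    Wraps a DataFrame indexed by gene with ``control`` and ``knockout``
    columns; ``fold_change = knockout / control`` (upregulation in the
    knockout reads as fold change > 1).  All values must be positive.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = {"control", "knockout"} - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (frame[["control", "knockout"]] <= 0).any().any():
            raise ValueError("expression values must be positive")
        df = frame.copy()
        df["fold_change"] = df["knockout"] / df["control"]
        bad = (
            df["fold_change"] - df["knockout"] / df["control"]
        ).abs() > 1e-9
        if bad.any():
            raise ValueError("fold_change inconsistent with values")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)


def fold_change_filter(
    table: ExpressionTable, threshold: float
) -> List[str]:
    """Genes whose fold change is >= threshold, sorted descending.

    Monotone in the threshold: raising it can only shrink the result.
    """
    df = table.frame
    hits = df[df["fold_change"] >= threshold].sort_values(
        by=["fold_change", "control"], ascending=[False, True],
        kind="mergesort",
    )
    return list(hits.index)


# --- final pipeline report ---

def assemble_report(
    candidate_reports: Sequence[CandidateReport],
    tally: Optional[Dict] = None,
    config: Optional[Dict] = None,
    seed: Optional[int] = None,
    parameter_checksums: Optional[Dict[str, str]] = None,
) -> Dict:
    """Deterministic structured summary of a pipeline run.

    The same inputs always serialize to the same JSON text (sorted keys,
    fixed ordering), so reports can be diffed across runs.
    """
    payload = {
        "config": config or {},
        "seed": seed,
        "parameter_checksums": parameter_checksums or {},
        "category_tally": {
            (k.value if hasattr(k, "value") else str(k)): v
            for k, v in (tally or {}).items()
        },
        "n_candidates": len(candidate_reports),
        "candidates": [
            {
                "candidate_id": r.candidate_id,
                "overall": r.overall,
                "mature_len": r.mature_len,
                "locus": r.locus,
                "criteria": {
                    k: {"status": c.status, "evidence": c.evidence}
                    for k, c in sorted(r.criteria.items())
                },
                "best_fold": r.best_fold,
                "conservation_summary": r.conservation_summary,
                "dominance_share": r.dominance_share,
            }
            for r in sorted(candidate_reports, key=lambda r: r.candidate_id)
        ],
    }
    return payload


def report_to_json(report: Dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True)


def report_to_markdown(report: Dict) -> str:
    lines = ["# Candidate miRNA report", ""]
    tally = report.get("category_tally") or {}
    if tally:
        lines.append("## Read categories")
        for k in sorted(tally):
            lines.append(f"- {k}: {tally[k]}")
        lines.append("")
    lines.append(f"## Candidates ({report['n_candidates']})")
    for cand in report["candidates"]:
        lines.append(
            f"- {cand['candidate_id']} [{cand['overall']}] "
            f"{cand['locus']} mature {cand['mature_len']} nt"
        )
        for key, c in cand["criteria"].items():
            lines.append(f"    - {key}: {c['status']} — {c['evidence']}")
    return "\n".join(lines) + "\n"
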