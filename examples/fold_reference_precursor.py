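"""Fold the shipped 135-nt precursor and find its best 50-nt window.

Slides every 50-nt window that fully contains the 25-nt mature sequence
across the precursor, folds each under the Turner 2004 model, and reports
the window with the lowest minimum free energy — the fold that makes the
candidate look like a miRNA precursor.
"""

from mirnovo.fixtures import reference_fixtures
from mirnovo.fold import assign_arm, best_window, load_energy_model

fx = reference_fixtures()
model = load_energy_model()

start, window, fold = best_window(fx.precursor_135, fx.mature_span, model,
                                  window_len=50)
ms, me = fx.mature_span
arm = assign_arm(fold, (ms - start + 1, me - start + 1))

print(f"precursor: {len(fx.precursor_135)} nt at "
      f"{fx.locus.chrom}:{fx.locus.start}-{fx.locus.end}({fx.locus.strand})")
print(f"best 50-nt window starts at precursor position {start}")
print(window.as_rna())
print(fold.structure)
print(f"MFE = {fold.mfe_kcal_mol:.2f} kcal/mol")
print(f"mature arm: {arm.arm}, paired fraction {arm.paired_fraction:.2f}")
print()
print("The negative MFE and the mature sitting in the 5' arm of the")
print("stem-loop are what qualify this window as a fold-back precursor.")
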