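"""Run the full discovery cascade on a synthetic small-RNA library.

Builds a toy genome with ten planted hairpin precursors (plus the shipped
reference precursor), a read population dominated by one candidate, and
decoy reads from four exclusion catalogs; then categorizes every read,
folds candidate windows, and prints the category tally and dominance
report.
"""

from mirnovo.discovery import CATALOG_ORDER, SmallRNARead, discover
from mirnovo.fold import load_energy_model
from mirnovo.simulate import make_decoy_catalogs, make_genome, make_reads

SEED = 17

genome, truth = make_genome(n_chroms=2, chrom_len=3000,
                            n_planted_hairpins=10, seed=SEED)
catalogs = make_decoy_catalogs(seed=SEED)
reads, truth = make_reads(truth, depth_per_mature=100,
                          decoy_spec={c: (r, 10)
                                      for c, r in catalogs.items()},
                          seed=SEED)

model = load_energy_model()
result = discover(
    [SmallRNARead(*r) for r in reads],
    [(c, catalogs[c.value]) for c in CATALOG_ORDER],
    genome, model,
)

print("read categories:")
for cat, n in result.tally.items():
    if n:
        print(f"  {cat.value:20s} {n}")
novel = [r for r in result.candidates if r.is_novel_mirna_like]
print(f"novel-miRNA-like candidates: {len(novel)} "
      f"(planted: {len(truth.planted_precursors)})")
print("dominance report (share of novel-candidate copies):")
for cid, share in result.dominance[:3]:
    print(f"  {cid}: {share:.2%}")
print()
print("Decoy reads are absorbed by their catalogs before mapping, so only")
print("planted precursors reach the hairpin test; the top candidate holds")
print("roughly two thirds of all novel copies, as in the modeled library.")
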