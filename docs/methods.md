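# Methods

## Scope and data model

The package reconstructs, as testable code, the desk side of a
novel-miRNA discovery: read categorization, fold-back validation, seed
scanning, conservation analysis and criteria scoring. Sequences are held
as validated DNA-alphabet strings (`U` normalized to `T` on input, with
the original alphabet remembered for RNA-facing output); genomic
coordinates are 1-based inclusive everywhere except the on-disk BED
boundary (0-based half-open). The study's raw sequencing data are not
publicly deposited, so the package ships the three concrete artifacts
available — the 135-nt precursor, its 25-nt capitalized mature
subsequence (1-based offset 57, i.e. span 57–81), and the GRCh38 locus
chr12:20551369–20551503(+) — and generates everything else synthetically
with recorded ground truth. The mature length is given as 19 nt in one
part of the source description and printed as 25 capitalized nt in
another; the printed 25-nt string is the default everywhere and the
stated 19 is retained as an alternate parameter.

## Thermodynamic folding

Minimum-free-energy structures are computed by Zuker-style dynamic
programming: `C[i][j]` (best energy with (i, j) paired: hairpin loop,
two-pair interior loop bounded at 30 unpaired nt, or multiloop closure),
`M`/`M1` (multiloop segments), `F` (exterior). Time is O(n³); length is
capped at 500 nt — the folder targets precursor windows, not
transcripts.

Energy parameters are the Turner 2004 free energies at 37 °C,
transcribed into three plain-text tables under `src/mirnovo/fold/data/`
(units 0.01 kcal/mol, schema documented in the file headers) and pinned
by SHA-256 at load time. All components of the published set are
implemented: stacking; hairpin length table with terminal mismatches and
special tri/tetra/hexaloop sequences; bulge and interior length tables
with Jacobson–Stockmayer log extrapolation beyond 30 nt; 1×1, 2×1 and
2×2 special interior loops; 1×n and 2×3 mismatch classes; Ninio
asymmetry (capped); affine multiloop scoring; terminal-AU penalties.
Dangles follow the "d2" convention — terminal-mismatch energies on both
sides of every exterior-loop and multiloop helix, single dangles at
sequence ends — matching the default of the folding web server the
original analysis used; lonely pairs are allowed; temperature is fixed
at 37 °C (no enthalpies are shipped). Partition function, pseudoknots
and coaxial stacking are out of scope.

Co-optimal structures are resolved deterministically by the traceback,
which examines alternatives in a fixed order that prefers leaving the
leftmost undecided position unpaired (suffix-unpaired first in the
exterior and multiloop decompositions; hairpin before interior loops,
longer 5′ unpaired stretches first; multiloop last).

Two independent checks pin the implementation: an exhaustive enumeration
oracle (every valid nested structure of sequences ≤ 18 nt, scored by the
same loop evaluator, must reach the same minimum as the DP), and a
cross-check against the ViennaRNA `RNAfold` implementation of the same
model on random sequences, which agrees to the printed precision. On the
shipped precursor, the minimum over the 26 fifty-nt windows containing
the mature span is −10.90 kcal/mol (window start 52).

### Hairpin candidate test

`evaluate_candidate` passes a window when (i) MFE ≤ −10 kcal/mol,
(ii) the mature bases pair only with bases on one side of the mature
span (5′ or 3′ arm, no self-pairing), and (iii) at least 60 % of mature
bases are paired. Which window to fold is genuinely underdetermined for
a 135-nt precursor: at full length the shipped mature straddles two
stems (arm = NONE at paired fraction 0.80), while the best 50-nt window
folds it cleanly into the 5′ arm at paired fraction 0.52 — below the
0.6 floor. Discovery therefore evaluates the full sweep of window
lengths (50–150 nt, step 10, sliding by 1 nt) and calls a candidate
novel-miRNA-like if **any** window passes; the annotation criterion (c)
uses the same any-window semantics. For the shipped precursor, 80-nt
windows pass all three thresholds.

## Synthetic data generation

All generators draw from `random.Random(seed)` (platform-stable), and
identical seeds give byte-identical outputs.

* **Genome** — i.i.d. uniform background; each planted precursor is a
  left arm (20–30 nt, containing a mature of 18–24 nt), a 6–10 nt loop,
  and the arm's reverse complement mutated at 10 % per base (with at
  least one forced substitution opposite the mature, so the mature maps
  to exactly one strand of one locus). Planted matures are verified
  unique genome-wide post hoc; collisions trigger a full re-draw
  (rejection sampling), so truth counts are exact rather than merely
  probable. The shipped 135-nt precursor is planted by default.
* **Reads** — every planted mature is emitted verbatim with a log-normal
  copy count (median = configured depth, σ = 1.5; the source data's
  copy-number distribution is unreported, so any heavy-tailed choice is
  an emulation and the parameters live in configuration). One designated
  candidate's count is set so it holds 66 % of all novel-candidate
  copies, emulating the reported dominance of the lead candidate. Decoy
  reads are exact 18–26-nt substrings of synthetic stand-in catalogs
  (known-miRNA / mRNA / structural-ncRNA / repeat); no external database
  is consulted. No sequencing-error or quality model is simulated.
* **3′UTRs** — the reverse complement of a chosen 7-mer is written at
  recorded positions over uniform background; accidental extra
  occurrences cause a re-draw, so the recorded site count is exact.
* **Expression tables** — control values log-normal; knockout = control
  × true fold × exp(N(0, σ²)). Planted folds: [3, 8) for the ≥ 3-fold
  genes, [2, 2.95) for the remaining ≥ 2-fold genes, [0.5, 1.8) for the
  background, so noise-free filtering recovers the planted counts
  exactly.

What passing tests on these inputs do *not* show: performance on real
libraries with sequencing error, expression-dependent length
heterogeneity, repeat-rich genomes, or catalogs with near-miss homologs;
the generator's uniform background is far friendlier than a real
genome.

## Discovery cascade

Priority order: length filter (default retained range 18–26 nt; the raw
protocol only bounds reads at 40 nt) → known miRNA → mRNA → structural
ncRNA → repeat → genome → unmapped. Matching is Hamming-only (no
indels), default 0 mismatches, both strands — exact matching is the
reproducible baseline for a proprietary upstream pipeline, and both the
allowance and the strand handling are parameters. Clusters merge
overlapping same-strand hits; the consensus mature is the highest-copy
read. Flanks of 60 nt and window lengths 50–150 bracket both fold
lengths the source analysis used (50-nt window and 135-nt printed
precursor). Window evaluation short-circuits at the first passing
window, probing three windows per length (extremes and middle of the
start range) before the exhaustive sweep — an ordering choice only;
the window set is unchanged.

## Seed scanning

"7-mer pair match" is interpreted as the UTR carrying the reverse
complement of the mature 7-mer (standard seed semantics; G:U not
admitted); a literal-identity mode is retained because the source
wording is ambiguous. Raw occurrence totals rank the k-mers (ties to the
smaller mature offset); per-UTR presence counts (`n_utrs_hit`) are
reported alongside since either reading of "most occurrence" is
defensible. No thermodynamic or context scoring — the procedure is pure
counting.

## Conservation

Pairwise global alignment (NW, +1/−1/−2, end gaps penalized) rather than
a full MSA: adequate for 25–135-nt near-identical orthologs and
dependency-free; a documented limitation for divergent sets. Reported
identity is defined canonically as the optimal-score alignment
maximizing matches then minimizing columns (lexicographic DP), which
makes it checkable by exhaustive alignment enumeration. NJ follows
Saitou–Nei with Q-criterion; ties break on the lexicographically
smallest pair of subtree labels (each subtree labelled by its smallest
leaf), giving taxon-order invariance; negative branch estimates are
clamped to zero with a warning. Trees are dendropy objects serialized as
Newick; radial layout is presentation, not computation, and is out of
scope. A real ortholog set from a genome browser cannot be bundled, so a
synthetic ortholog generator (per-group point-mutation rates) stands in.

## Annotation criteria and filters

Criterion (a): mature length within 18–26 nt. (b): exact genomic match
exists. (c): any precursor window passes the hairpin test (see above).
(d): the designated group is fully conserved **or** its minimum identity
is ≥ 0.9 (set the floor to 1.0 for the strict reading; no printed cutoff
exists for "phylogenetic conservation"). (e): Dicer-dependence is
biochemical evidence — supplied externally as a boolean or reported as
`not_evaluated`, never computed, and never gating the overall call.
Upregulation is knockout/control. The fold-change filter applies only
the threshold rule; whatever array QC preceded the original counts is
not modeled.

## Problem sizes and numerical choices

Energies are exact integer arithmetic in 0.01 kcal/mol (ties are exact,
no floating-point comparisons inside the DP); identities and distances
are floats with tolerance 1e-9 in tests. Default test-suite problem
sizes: toy genomes of 2 × 3 kb with 10 planted hairpins, 20 seeded
discovery replicates, 200 folder-vs-oracle sequences (8–18 nt), 50
seed-scan replicates plus 500 brute-force comparisons, 50 random 8-taxon
additive matrices — sizes chosen so the full suite runs in well under a
minute per stage while leaving each property no room for coincidence.
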