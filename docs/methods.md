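# Methods

## The analysis pipeline

### Quantification

Each mate of a read pair is expected to contain a constant region (the
"anchor", the vector sequence immediately upstream of the spacer) followed by
one cassette's spacer. Anchors are design-specific and are user input; the
package never hard-codes them.

1. **Anchor search** — the best infix occurrence of the anchor in the read by
   edit distance (substitutions + indels, via edlib's semi-global mode). An
   occurrence qualifies if its edit distance is ≤ floor(tolerance × |anchor|);
   the default tolerance is 0.1. Reads without a qualifying occurrence, or
   with fewer than spacer-length bases after it, are discarded ("no_anchor").
   Among equally good occurrences the leftmost is used.
2. **Spacer matching** — the extracted fixed-length spacer (20 nt for SpCas9,
   23 nt for AsCas12a) is matched against the position's library spacers:
   exact match wins immediately, otherwise the unique guide within Hamming
   distance ≤ 1 (default); a tie at the minimal distance is "ambiguous", no
   qualifying guide is "no_match". Spacer extraction itself is
   substitution-free — errors are absorbed by the matching budget, not by
   moving the extraction window.
3. **Pair assignment** — a pair counts iff both mates match unambiguously and
   the ordered guide pair exists in the designed library; pairs mapping to
   undesigned combinations (e.g. recombination artifacts) are tallied
   separately as "not_in_library". A failed pair is tallied once, under the
   strongest failing category in the order no_anchor < no_match < ambiguous,
   evaluated across both mates with mate 1 breaking ties. Assigned +
   unassigned always equals the input pair count.

This replaces the adapter-trimmer + local-aligner chain customary for such
data with a native, fully deterministic procedure: library spacers are short,
fixed-length and known, so seeded local alignment adds nothing but
heuristics. No quality trimming is performed.

### Library QC

Per sample: the Lorenz curve of the count distribution (counts sorted
ascending, cumulative read share vs cumulative combination share) with its
area as a summary (0.5 = perfectly uniform), and the skew ratio P90/P10.
Percentiles use the **nearest-rank** convention (the ceil(p·n)-th order
statistic) — no interpolation, hence no convention ambiguity; the convention
is recorded in the QC report. Skew is flagged undefined (not an exception)
when P10 = 0. A skew below 2.5 is the conventional uniformity criterion for
pooled CRISPR libraries.

### Normalization and LFC

Per sample: `value = (count / sample_total) / median_NHT-NHT(count /
sample_total)`. After this the median NHT-NHT (double non-targeting control)
combination sits at exactly 1 in every sample, so neutral combinations have
LFC 0 by construction. The operation is scale-invariant and idempotent on
its own output; a zero sample total or zero NHT-NHT median is an error
naming the sample.

Per-combination LFC = log2(end / reference) on normalized values. A
pseudocount (default 0.5) is applied **per comparison and only where a zero
is present** ("on_zero" mode), leaving nonzero data untouched; an "always"
mode is available. With several end replicates, per-replicate LFCs are
combined by arithmetic **mean** (default); "median" and "pooled" (raw
replicate counts summed before normalization) are selectable. The mean of
log-ratios is the symmetric default; because published screen tables rarely
state which convention was used, all three modes are first-class so that
recomputations can be run under each and the matching mode reported.

### Aggregation and screen metrics

Gene-pair LFC = median over all constituent guide-pair LFCs (4 × 4 = 16 for
complete libraries); all NHT guides collapse into a single pseudo-gene so
NHT–gene pairs aggregate across every control partner. Screen-level metrics:

* **Effect-size range** = max − min LFC, at guide and gene level, over all
  pairs (mixed CE-TS pairs included — the range is over everything).
* **Class separation** — mean/median LFC of single-target pairs (NHT-CE,
  NHT-TS) per targeted class; TS summaries default to the genes with an
  actual proliferation phenotype (TP53, NF2) and can be widened.
* **Single-guide decomposition** — per guide, the median LFC over its
  NHT-partnered combinations; position 1 and position 2 are never swapped
  because the two cassettes behave differently in hybrid designs.
* **Correlations** — Pearson/Spearman with non-finite pairs dropped and
  counted, plus the least-squares line for cross-screen scatter; zero
  variance yields a flagged undefined result.

### ROC benchmarking

The gold standard declares positive CE genes, positive TS genes and negative
(non-essential) genes; the bundled default is a 6 CE / 5 TS / 9 negative
split as established for RPE1 cells from conserved DepMap Chronos dependency
scores, and arbitrary standards can be thresholded from any gene→score table
(score ≤ ce_cut → CE positive, ≥ ts_cut → TS positive, NHT never
classified). AUC is computed by scikit-learn's ROC machinery and equals the
Mann–Whitney probability that a positive record outranks a negative one with
ties counted ½ (property-tested against an exhaustive pairwise oracle). CE
uses low-is-positive orientation (depletion), TS high-is-positive. Record
unit default: guide-pair LFCs where one guide targets a gold-labeled gene
and the partner is NHT or a negative-set gene; "all_pairs" and "nht_single"
(per-guide NHT-partner medians) units are selectable, because published AUC
values rarely state which records entered the curve. An all-tied score set
returns AUC 0.5 with a degeneracy flag.

## The simulator

The generator emulates the screening setup this package targets: a dual-
cassette library of 10 CE + 10 TS genes × 4 guides plus 80 NHT controls per
cassette (160 × 160 = 25,600 combinations), screened at 100× coverage for 10
population doublings in duplicate.

**Effect model.** Gene fitness `f` is log2 abundance change per doubling at
full activity. Defaults: strong CE genes `f ~ N(-0.43, 0.08)`, strong TS
genes `f ~ N(+0.23, 0.05)` — chosen so a fully active guide reaches ≈ −4.3 /
+2.3 LFC over 10 doublings, the magnitude of class separation seen in
efficient SpCas9 screens. Only the first 6 CE and 5 TS genes carry strong
effects; the remaining 9 genes get fitness scaled by 0.25 and form the ROC
negative class, mirroring the benchmark reality that only part of a
library's nominal CE/TS genes have conserved strong dependencies. Guide
activity `a` is Beta(6, 2) on [0, 1] by default — this distribution is an
arbitrary modeling choice, not an estimate from any dataset, and is fully
exposed in the config. NHT guides exist as sequences but contribute zero
fitness. The per-combination expectation is `mu = d·(f_A·a_i·π1 +
f_B·a_j·π2)` (additive rule; a "max" rule and an interaction hook exist, the
interaction defaults to 0).

**Design penalties.** Each named design carries per-position multipliers
π ∈ [0, 1] emulating RNA-processing losses of hybrid-transcript constructs
(reported processed-RNA fractions for such constructs are limited to ~60%,
and their SpCas9 guides are largely inactive in screens):

| design          | π1 (cassette 1) | π2 (cassette 2) | notes |
|-----------------|------|------|-------|
| SpCas9          | 1.00 | 1.00 | two SpCas9 guides, separate promoters |
| enAsCas12a      | 0.90 | 0.90 | two Cas12a guides |
| CHyMErA         | 0.25 | 0.60 | hybrid transcript; SpCas9 position largely inactive |
| enAsCas12a_dual | 0.75 | 0.75 | arrayed dual-gRNAs per cassette |
| CHyMErA_v2      | 0.42 | 0.95 | hybrid + Cas12a dual arrays compensating processing |
| multiSPAS       | 1.00 | 0.90 | SpCas9 + Cas12a from separate promoters |

These values are this package's own calibration of the qualitative design
behaviour (ordering and rough magnitude of range compression), not measured
constants. Dual-gene-array designs combine their two same-gene guides per
Cas12a slot as `a_eff = 1 − (1−a1)(1−a2)` (the slot cuts if either guide
does). `apply_design_penalty` re-derives `mu` under any design's penalties
from the same drawn fitness/activity, which is what makes matched-seed
design comparisons meaningful.

**Sampling.** Initial abundances are lognormal(0, σ = 0.3), giving a P90/P10
skew of ≈ 2.2 — a library that passes the < 2.5 uniformity criterion, as the
emulated screens' libraries do. The reference sample is a multinomial draw
of depth = coverage × library size; each end replicate draws from abundances
reweighted by `2^mu`. Options: Dirichlet-multinomial overdispersion
(real screens are overdispersed; off by default), and a noiseless mode that
returns exact expected real-valued counts — on noiseless data the full
pipeline returns `mu` exactly, which anchors the recovery tests.
`emit_reads` realizes any integer count column as paired reads
(anchor + spacer + random tail, deterministic shuffle, optional substitution
channel), closing the loop for end-to-end quantification tests.

**What the simulator does not model:** lentiviral recombination between
repeated elements, MOI-driven multiple integrations, cell-cycle or TP53
dynamics, batch effects, and position-specific PCR biases. Passing tests on
synthetic data therefore demonstrate the correctness of the analysis math
and the pipeline's recovery behaviour under the stated noise model — not the
biological fidelity of any particular screen.

## Numerical and design choices

* Percentile convention: nearest-rank, recorded in every QC report.
* Pseudocount 0.5 "on_zero": avoids infinite LFCs without perturbing
  nonzero data; recorded in LFC provenance.
* Tie handling in AUC: midrank (ties ½), matching the Mann–Whitney identity.
* Pair classes: mixed CE-TS pairs get their own label and stay in range
  computations; position order is never canonicalized away.
* Cross-position duplicate spacers are permitted (the two cassettes are
  sequenced separately); within-position duplicates are an error naming the
  guides.
* Sample roles (library_reference / screen_end, replicate index) live in an
  explicit sample sheet, never parsed from sample names; external count
  tables are adapted via a column map plus sample sheet.
* All outputs are delimited text with headers and round-trip through their
  own readers; a pipeline rerun with the same config and seed is
  byte-identical.
* Seeds: every stochastic component takes an explicit seed;
  `simulate_screen` derives library/effects/counts sub-seeds from one master
  seed via `SeedSequence`.

## Problem sizes used in the test and acceptance runs

Unit tests run on miniature libraries (tens of combinations) where expected
values are hand-computable. Recovery and benchmark checks run the full
default condition — 25,600 combinations at 100× depth (2.56 M reads per
sample, 3 samples) — which completes in a few seconds per screen; the
acceptance script runs one default, one strong-effect, one null and six
matched per-design screens in ~2 s total.

## Known limitations

* The bounded-Hamming matcher considers substitutions only; an indel inside
  a spacer (rare in amplicon sequencing) reads as no_match rather than being
  rescued.
* AUC confidence intervals are not computed; records sharing a guide are
  correlated, so naive Hanley–McNeil errors understate uncertainty (the null
  test accounts for this with a cluster-level bound).
* The gene-level class summaries use single-target (NHT-partnered) pairs;
  fully general marginal effects from double-target pairs would require an
  epistasis model, which is out of scope.
* Replicate-aggregation and ROC-record-unit conventions differ across
  published pipelines; this package exposes all modes rather than asserting
  one as canonical.
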