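# duoscreen

Analysis of **dual-cassette combinatorial CRISPR dropout screens** — the
pooled experiments in which every vector expresses two gRNAs (SpCas9,
enAsCas12a, hybrid CHyMErA-type or orthogonal multiSPAS designs) and gene
dependencies are read out as the depletion or enrichment of guide pairs over
cell doublings.

The package is for screen analysts who need, from paired-end reads or a raw
count table, the full quantitative readout of such a screen:

* **Quantification** — anchored spacer extraction from both mates (bounded
  edit-distance anchor search, exact / 1-mismatch spacer matching) into a
  combination × sample count table with per-category unassigned tallies.
* **Library QC** — Lorenz curves and the P90/P10 skew ratio (a library with
  skew < 2.5 is conventionally called uniform).
* **Screen math** — per-sample normalization to depth and to the median of
  the NHT-NHT double-control combinations; per-combination
  LFC = log2(end / reference); median aggregation to gene pairs; effect-size
  range (max − min LFC); per-class mean/median separation; single-guide
  decomposition via NHT-partnered pairs; replicate and cross-screen
  correlations.
* **Benchmarking** — gold standards of positive core-essential (CE),
  positive tumor-suppressor (TS) and negative genes (declared directly or
  thresholded from a dependency-score table) and Mann–Whitney ROC/AUC of CE
  recovery (depletion) and TS recovery (enrichment).
* **Simulation** — a ground-truth generator for the full screening setup
  (160 × 160 combination library, representation skew, multinomial sampling
  at configurable coverage, per-guide activity, per-design RNA-processing
  penalties), so every stage is testable end to end without data downloads.

## Model

For a guide pair (i, j) targeting genes A and B, the expected log2 fold
change after *d* population doublings is modeled additively:

```
mu_ij = d * ( f_A * a_i * pi_1  +  f_B * a_j * pi_2 )
```

where `f` is gene fitness (log2 per doubling at full activity; CE < 0,
TS > 0, NHT = 0), `a in [0, 1]` is guide activity, and `pi` are per-position
processing penalties (1 for separate-promoter designs; < 1 for
hybrid-transcript designs whose guides must be released by Cas12a RNA
processing). Observed counts are multinomial draws from initial abundances
reweighted by `2^mu`. The analysis estimates LFC as

```
LFC_ij = log2( n_end,ij / n_ref,ij ),   n = (count / depth) / median_NHT-NHT
```

and AUC as `P(score_pos outranks score_neg)` with ties counted ½.

## Worked example

```python
from duoscreen import SimulationConfig, screen_metrics, simulate_screen, evaluate_screen, screen_lfc
from duoscreen.simulate import synthetic_gold_standard

config = SimulationConfig()            # 25,600 combinations, 10 doublings, 100x coverage
library, effects, counts = simulate_screen(config, seed=1)
metrics, lfc, gene_pairs = screen_metrics(counts, library, ts_genes=None)
ev = evaluate_screen(lfc, synthetic_gold_standard(config))
```

Running `python examples/03_screen_metrics.py` (which does the above) prints:

```
effect-size range, guide level: 12.43
effect-size range, gene level:  9.65

mean LFC of single-target (NHT-partnered) pairs per class:
        n  mean  median
CE   6400 -2.61   -2.87
TS   6400  0.94    0.75
NHT  6400 -0.01   -0.01

Spearman(true effect mu, estimated LFC): 0.973
replicate correlations: {'guide_counts': 0.994, 'gene_counts': 1.0, 'guide_lfc': 0.933}
```

The effect-size range is the spread between the strongest dropout and the
strongest enrichment; CE-targeting pairs deplete (negative mean LFC), TS
pairs enrich, and the NHT-NHT baseline sits at 0 by construction. The
Spearman correlation shows how faithfully the pipeline recovers the known
simulated effects at screen-realistic sequencing depth.

The other scripts in `examples/` each demonstrate one capability: library
combinatorics and PAM subsetting, read quantification with QC, ROC
benchmarking, and the per-design comparison in which hybrid-transcript
designs show compressed effect-size ranges.

A thin CLI mirrors the library (`duoscreen simulate | count | qc | analyze |
roc | compare | run`).

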