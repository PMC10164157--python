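"""Benchmark a screen against a gold standard of known gene dependencies.

The gold standard declares positive CE genes (strong conserved negative
dependency scores), positive TS genes (strong positive scores) and a
negative class of non-essential genes.  AUC is the Mann-Whitney probability
that a positive record outranks a negative one: depletion ranks CE positives
(low LFC = positive), enrichment ranks TS positives.
"""

from duoscreen import evaluate_screen, gold_standard_from_scores, screen_lfc, simulate_screen
from duoscreen.simulate import SimulationConfig, synthetic_gold_standard

config = SimulationConfig()
library, effects, counts = simulate_screen(config, seed=1)
lfc = screen_lfc(counts, library)

gold = synthetic_gold_standard(config)
print(f"gold standard: {len(gold.ce_positive)} CE positives, "
      f"{len(gold.ts_positive)} TS positives, {len(gold.negatives)} negatives")

ev = evaluate_screen(lfc, gold)
print(f"AUC (CE recovery, depletion):  {ev.auc_ce:.3f}  on {ev.roc_ce.n_positive}+/{ev.roc_ce.n_negative}- records")
print(f"AUC (TS recovery, enrichment): {ev.auc_ts:.3f}  on {ev.roc_ts.n_positive}+/{ev.roc_ts.n_negative}- records")
print("(1.0 = perfect ranking of true dependencies; 0.5 = no signal)")

# gold standards can also be thresholded from a dependency-score table
scores = effects.gene_fitness.drop("NHT") * 2.5  # stand-in for a score table
gold2 = gold_standard_from_scores(scores, ce_cut=-0.5, ts_cut=0.3)
print(f"\nfrom scores (cuts -0.5 / +0.3): CE={sorted(gold2.ce_positive)}")
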