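"""Screen microRNA target sets for repression of non-germ-cell genes.

A microRNA whose predicted targets concentrate among low-probability
(non-germ) genes is a candidate repressor: each target set is scored by
the ROC AUC of 1 - p with the targets as positives, and a consensus filter
keeps microRNAs that clear the cutoff in every target-prediction source.
"""

import numpy as np
import pandas as pd

import germdeconv as gd

config = gd.SimulationConfig(n_genes=1500, seed=17)
_, truth = gd.simulate_gonad_timecourse(config)
annotations = gd.simulate_annotations(truth, config)

# idealised prediction table: germ-specific genes high, others low
rng = np.random.default_rng(1)
proba = pd.Series(rng.uniform(0.0, 0.35, len(truth.classes)),
                  index=truth.classes.index)
germ = truth.genes_in_class("germ_specific")
proba[germ] = rng.uniform(0.65, 1.0, len(germ))

# the generator planted 3 repressor microRNAs (80% of targets non-germ)
table = gd.mirna_auc(proba, annotations.mirna_sets, min_targets=10)
print(table.head(5).to_string(index=False))

# consensus across two sources (second source = same sets, subsampled)
subsampled = {
    m: set(rng.choice(sorted(t), size=max(10, len(t) // 2), replace=False))
    for m, t in annotations.mirna_sets.items()
}
tables = {
    "sourceA": table,
    "sourceB": gd.mirna_auc(proba, subsampled, min_targets=10),
}
consensus = gd.consensus_filter(tables, auc_cutoff=0.6)
print(f"\nconsensus repressor microRNAs (AUC > 0.6 in both sources): "
      f"{list(consensus['mirna'])}")
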