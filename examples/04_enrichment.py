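"""Characterise a ranked prediction list: chromosome, GO, essential genes.

Enrichment uses the hypergeometric upper tail P(X >= k) over a genome
universe of N genes, an m-gene top list, n attribute-bearing genes and an
overlap of k; chromosome tests Bonferroni-correct at a fixed 21
chromosomes, GO tests multiply by the number of terms tested.
"""

import numpy as np
import pandas as pd

import germdeconv as gd

config = gd.SimulationConfig(n_genes=2000, seed=13)
gonad, truth = gd.simulate_gonad_timecourse(config)
annotations = gd.simulate_annotations(truth, config)

# idealised ranking: germ-specific genes first (what a good model produces)
rng = np.random.default_rng(0)
score = pd.Series(rng.uniform(0, 0.4, len(truth.classes)),
                  index=truth.classes.index)
score[truth.genes_in_class("germ_specific")] = rng.uniform(
    0.6, 1.0, len(truth.genes_in_class("germ_specific")))
ranked = score.sort_values(ascending=False, kind="stable")
top = list(ranked.index[:500])

chrom = gd.chromosome_enrichment(top, annotations.chromosomes)
sig = chrom[chrom["significant"]]
print("significant chromosomes (p < 0.05/21):")
print(sig[["chromosome", "n", "k", "p_value"]].to_string(index=False))

go = gd.go_enrichment(top, annotations.go_sets, list(truth.classes.index))
hits = go[go["corrected_p"] < 0.05]
print(f"\nenriched GO-like sets: {list(hits['term'])} "
      f"(planted: GO_SET_001..003)")

essential = set(annotations.essential.index[annotations.essential])
curve = gd.essential_curve(list(ranked.index), essential,
                           bin_size=500, n_random=100, seed=1)
print(f"\nessential fraction, top bin: {curve.observed[0]:.3f} "
      f"vs random {curve.random_mean[0]:.3f} (p = {curve.p_value:.2e})")
print(f"final cumulative fraction (= global rate): {curve.observed[-1]:.3f}")

other_top = list(rng.permutation(list(truth.classes.index))[:500])
print(f"\nJaccard overlap with an unrelated top-500 list: "
      f"{gd.jaccard(top, other_top):.3f}")
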