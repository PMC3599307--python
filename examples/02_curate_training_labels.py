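"""Curate training labels from evidence records and a tissue panel.

Positives come from graded single-gene evidence (Very strong / Strong /
Present); negatives from Absent / Trace records plus strictly
tissue-specific genes of a multi-tissue panel (expressed > 10x the global
median in exactly one non-gonadal tissue, below the median elsewhere).
"""

import germdeconv as gd
from germdeconv.curation import EvidenceRecord

config = gd.SimulationConfig(n_genes=600, n_tissue_specific=25, seed=3)
_, truth = gd.simulate_gonad_timecourse(config)
panel, truth = gd.simulate_tissue_panel(config, truth)

# evidence records for a handful of genes, including one conflict
germ = truth.genes_in_class("germ_specific")[:30]
soma = truth.genes_in_class("soma_specific")[:10]
records = [EvidenceRecord(g, "Present", source="sim") for g in germ]
records += [EvidenceRecord(g, "Absent", source="sim") for g in soma]
records.append(EvidenceRecord(germ[0], "Trace", source="sim"))  # conflict

evidence = gd.label_from_evidence(records)
print(f"evidence labels: {evidence.n_positive} positive, "
      f"{evidence.n_negative} negative "
      f"(conflicting gene {germ[0]} kept positive: "
      f"{evidence.labels[germ[0]] == 1})")

tissue_negs = gd.tissue_specific_negatives(panel)
print(f"tissue-specific negatives recovered from panel: {len(tissue_negs)} "
      f"(planted: {len(truth.planted_tissue_specific)})")

positives = set(evidence.labels.index[evidence.labels == 1])
negatives = set(evidence.labels.index[evidence.labels == -1]) | tissue_negs
train = gd.assemble_training_set(positives, negatives, truth.classes.index)
print(f"assembled training set: N={train.N} "
      f"({train.n_positive}+ / {train.n_negative}-), "
      f"random precision {train.random_precision:.2f}")
# random precision = prevalence: the floor every ranking must beat.
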