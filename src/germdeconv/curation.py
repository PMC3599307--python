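"""Training-label curation.

Positive and negative labels come from two sources: single-gene expression
evidence records (in situ, immunohistochemistry, RT-PCR, ... assays graded on
a five-term strength vocabulary) and a multi-tissue expression panel from
which strictly tissue-specific genes — expressed in exactly one non-gonadal
tissue — are harvested as additional negatives.  The final training set is
restricted to genes measurable on the expression platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

POSITIVE_STRENGTHS = frozenset({"Very strong", "Strong", "Present"})
NEGATIVE_STRENGTHS = frozenset({"Absent", "Trace"})
DEFAULT_EXCLUDED_TISSUES = frozenset({"testis", "ovary"})


@dataclass
class EvidenceRecord:
    """One single-gene expression observation."""

    gene: str
    strength: str
    source: str = ""
    context: str = ""

    def __post_init__(self) -> None:
        if self.strength not in POSITIVE_STRENGTHS | NEGATIVE_STRENGTHS:
            raise ValueError(
                f"unknown strength label {self.strength!r} for gene {self.gene}"
            )


@dataclass
class TrainingSet:
    """Gene -> label in {+1, -1} with per-gene provenance.

    ``N`` is the number of training examples; the implied precision of a
    random classifier is ``n_positive / N`` (the prevalence).
    """

    labels: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate gene ids in training set")
        bad = set(np.unique(self.labels)) - {1, -1}
        if bad:
            raise ValueError(f"labels must be +/-1, got {sorted(bad)}")

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == -1).sum())

    @property
    def random_precision(self) -> float:
        """Prevalence = precision of labelling genes positive at random."""
        return self.n_positive / self.N

    def to_frame(self) -> pd.DataFrame:
        df = self.labels.rename("label").to_frame()
        df["provenance"] = [self.provenance.get(g, "") for g in df.index]
        df.index.name = "gene"
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "TrainingSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        prov = {}
        if "provenance" in df.columns:
            prov = {g: str(v) for g, v in df["provenance"].fillna("").items()}
        return cls(df["label"].astype(int), prov)


def label_from_evidence(records: Iterable[EvidenceRecord]) -> TrainingSet:
    """Map evidence records to labels.

    A gene is +1 if any record grades it Very strong / Strong / Present and
    -1 only if every record grades it Absent / Trace; conflicting genes are
    kept as positives.
    """
    pos, neg = set(), set()
    for rec in records:
        if rec.strength in POSITIVE_STRENGTHS:
            pos.add(rec.gene)
        else:
            neg.add(rec.gene)
    conflicts = pos & neg
    for g in sorted(conflicts):
        log.info("gene %s has conflicting evidence; kept as positive", g)
    genes = sorted(pos | neg)
    labels = pd.Series(
        [1 if g in pos else -1 for g in genes], index=genes, dtype=int
    )
    prov = {
        g: ("evidence:conflict->positive" if g in conflicts
            else "evidence:positive" if g in pos else "evidence:negative")
        for g in genes
    }
    return TrainingSet(labels, prov)


def read_evidence(path) -> list[EvidenceRecord]:
    """Evidence TSV with columns gene, strength[, source, context]."""
    df = pd.read_csv(path, sep="\t")
    return [
        EvidenceRecord(
            gene=str(r["gene"]),
            strength=str(r["strength"]),
            source=str(r.get("source", "")),
            context=str(r.get("context", "")),
        )
        for _, r in df.iterrows()
    ]


def tissue_specific_negatives(
    panel: ExpressionMatrix,
    excluded_tissues: Iterable[str] = DEFAULT_EXCLUDED_TISSUES,
    per_gene_median: bool = False,
) -> set[str]:
    """Genes expressed in exactly one non-gonadal tissue of the panel.

    The panel columns (one per tissue) are concatenated and a single global
    median is taken on the linear scale.  A gene qualifies when its value
    exceeds 10x that median in exactly one tissue outside
    ``excluded_tissues`` and sits below the median in every other tissue.
    ``per_gene_median=True`` switches the reference to each gene's own
    median across tissues (sensitivity-analysis variant, not the default).
    """
    panel = panel.to_linear()
    excluded = set(excluded_tissues)
    missing = excluded - set(panel.samples["tissue"])
    if missing:
        log.warning("excluded tissue(s) %s absent from panel", sorted(missing))

    vals = panel.values.to_numpy(dtype=float)
    tissues = np.asarray(panel.samples["tissue"])
    if per_gene_median:
        median = np.median(vals, axis=1, keepdims=True)
    else:
        median = np.median(vals)

    high = vals > 10.0 * median
    low = vals < median
    excl_mask = np.isin(tissues, sorted(excluded))

    selected: set[str] = set()
    for i, gene in enumerate(panel.genes):
        hi_idx = np.flatnonzero(high[i])
        if len(hi_idx) != 1:
            continue
        j = hi_idx[0]
        if excl_mask[j]:
            continue
        others = np.ones(vals.shape[1], dtype=bool)
        others[j] = False
        if low[i, others].all():
            selected.add(str(gene))
    return selected


def assemble_training_set(
    positives: Iterable[str],
    negatives: Iterable[str],
    array_genes: Iterable[str],
    provenance: dict[str, str] | None = None,
) -> TrainingSet:
    """Union curated positives and negatives, restricted to the array.

    A gene appearing in both inputs is kept positive with the conflict
    logged; genes absent from ``array_genes`` are dropped.
    """
    pos, neg = set(positives), set(negatives)
    array = set(array_genes)
    conflicts = pos & neg
    for g in sorted(conflicts):
        log.warning("gene %s in both positive and negative inputs; kept positive", g)
    neg -= conflicts

    dropped = (pos | neg) - array
    if dropped:
        log.info("%d curated gene(s) not on array; dropped", len(dropped))
    pos &= array
    neg &= array

    genes = sorted(pos | neg)
    labels = pd.Series([1 if g in pos else -1 for g in genes], index=genes, dtype=int)
    prov = dict(provenance or {})
    for g in conflicts & set(genes):
        prov[g] = prov.get(g, "") + "|conflict->positive"
    return TrainingSet(labels, prov)


def read_array_genes(path) -> set[str]:
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}
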