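"""MicroRNA target-set screen against the genome-wide prediction table.

MicroRNAs repress their targets, so a microRNA whose predicted target set
piles up among low-probability (non-germ-cell) genes is a candidate
repressor of somatic/non-germ expression.  Each microRNA is scored by the
ROC AUC of the inverted prediction score ``1 - p`` with its targets as the
positive class; a consensus filter keeps microRNAs that clear the AUC
cutoff in every target-prediction source.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .curation import TrainingSet
from .evaluation import roc_auc

log = logging.getLogger(__name__)

DEFAULT_AUC_CUTOFF = 0.6


def mirna_auc(
    predictions: pd.Series,
    targets: dict[str, set[str]],
    min_targets: int = 10,
) -> pd.DataFrame:
    """AUC of 1 - p for each microRNA's targets vs. the rest of the universe.

    Target sets are intersected with the prediction universe first;
    microRNAs left with fewer than ``min_targets`` usable targets (or with
    no non-target genes) are excluded with a log entry.  The result is
    sorted by descending AUC with a 1-based ``rank`` column.
    """
    if min_targets < 2:
        raise ValueError("min_targets must be >= 2")
    universe = set(predictions.index)
    inverted = 1.0 - predictions

    rows = []
    for mirna, target_set in targets.items():
        usable = target_set & universe
        if len(usable) < min_targets:
            log.warning(
                "microRNA %s has %d usable target(s) (< %d); excluded",
                mirna, len(usable), min_targets,
            )
            continue
        if len(usable) == len(universe):
            log.warning("microRNA %s targets the whole universe; excluded", mirna)
            continue
        labels = pd.Series(
            np.where(predictions.index.isin(list(usable)), 1, -1),
            index=predictions.index, dtype=int,
        )
        _, auc = roc_auc(inverted, TrainingSet(labels))
        rows.append({"mirna": mirna, "n_targets": len(usable), "auc": auc})
    table = pd.DataFrame(rows, columns=["mirna", "n_targets", "auc"])
    table = table.sort_values("auc", ascending=False, kind="stable").reset_index(
        drop=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def consensus_filter(
    tables: dict[str, pd.DataFrame],
    auc_cutoff: float = DEFAULT_AUC_CUTOFF,
) -> pd.DataFrame:
    """MicroRNAs exceeding ``auc_cutoff`` in every target source.

    ``tables`` maps source name -> :func:`mirna_auc` output.  Returns one
    row per consensus microRNA with a per-source AUC column
    (``auc_<source>``); empty (with a warning) if the sources share no
    microRNA ids.
    """
    if len(tables) < 2:
        raise ValueError("consensus needs >= 2 target sources")
    per_source = {
        src: dict(zip(tbl["mirna"], tbl["auc"])) for src, tbl in tables.items()
    }
    shared = set.intersection(*(set(d) for d in per_source.values()))
    if not shared:
        log.warning("target sources share no microRNA ids; empty consensus")
    rows = []
    for mirna in sorted(shared):
        aucs = {src: per_source[src][mirna] for src in per_source}
        if all(a > auc_cutoff for a in aucs.values()):
            row = {"mirna": mirna}
            row.update({f"auc_{src}": a for src, a in aucs.items()})
            rows.append(row)
    cols = ["mirna"] + [f"auc_{src}" for src in tables]
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        out = out.sort_values(
            cols[1], ascending=False, kind="stable"
        ).reset_index(drop=True)
    return out
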