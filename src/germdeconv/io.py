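"""Reading and writing the package's plain-text formats.

Matrices travel as TSV (first column gene id, header row of sample ids) with
a side-car sample-metadata TSV; gene sets travel as GMT (set name, free-text
description, then tab-separated member genes, one set per line).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import SAMPLE_COLUMNS, ExpressionMatrix, ProbeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix, path, metadata_path=None) -> None:
    """Write values TSV and (optionally) a sample-metadata TSV next to it."""
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    if metadata_path is None:
        metadata_path = path.with_suffix(".samples.tsv")
    meta = matrix.samples.copy()
    meta.index.name = "sample"
    meta.insert(0, "scale", matrix.scale)
    meta.to_csv(metadata_path, sep="\t")


def read_matrix(path, metadata_path=None, scale: str | None = None) -> ExpressionMatrix:
    """Read a TSV expression matrix (round-trip inverse of :func:`write_matrix`).

    Raises ``ValueError`` on duplicate gene ids, ragged/non-numeric rows, or
    an empty file.  When no metadata file exists, placeholder metadata is
    synthesised (sample id as tissue, no time/replicate).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate gene ids: {list(dupes[:5])}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    values.index.name = None
    values.columns.name = None
    if values.isna().any().any():
        raise ValueError(f"{path}: missing / ragged cells")

    if metadata_path is None:
        candidate = path.with_suffix(".samples.tsv")
        metadata_path = candidate if candidate.exists() else None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        if scale is None and "scale" in meta.columns:
            scale = str(meta["scale"].iloc[0])
        meta = meta[[c for c in meta.columns if c in SAMPLE_COLUMNS]]
        for col in SAMPLE_COLUMNS:
            if col not in meta.columns:
                meta[col] = pd.NA
    else:
        meta = pd.DataFrame(
            {"tissue": values.columns, "time": pd.NA, "replicate": pd.NA},
            index=values.columns,
        )
    return ExpressionMatrix(values, meta.loc[values.columns], scale or "log2")


def read_probe_matrix(path, annotation_path, scale: str = "log2") -> ProbeMatrix:
    """Read probe-level values plus a (probe, gene, tier) annotation TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    ann["tier"] = ann["tier"].astype(int)
    return ProbeMatrix(values.astype(float), ann, scale=scale)


# ---------------------------------------------------------------------------
# probe collapsing and replicate averaging
# ---------------------------------------------------------------------------

def collapse_probes(probes: ProbeMatrix) -> ExpressionMatrix:
    """Collapse probe-sets to genes using the best annotation tier.

    Per gene, the probe-sets with the minimal tier rank are kept; a single
    winner is copied through, several winners are averaged element-wise.
    Probe-sets without annotation are dropped with a warning carrying the
    count; genes mapped by no probe-set are simply absent from the output.
    """
    ann = probes.annotation
    unannotated = probes.values.index.difference(ann.index)
    if len(unannotated):
        warnings.warn(
            f"{len(unannotated)} probe-set(s) without annotation dropped",
            stacklevel=2,
        )
    ann = ann.loc[ann.index.intersection(probes.values.index)]

    rows = {}
    for gene, grp in ann.groupby("gene", sort=True):
        best = grp[grp["tier"] == grp["tier"].min()]
        rows[gene] = probes.values.loc[best.index].mean(axis=0)
    if not rows:
        values = pd.DataFrame(columns=probes.values.columns)
    else:
        values = pd.DataFrame.from_dict(rows, orient="index")
        values.columns = probes.values.columns
    return ExpressionMatrix(values, probes.samples, probes.scale)


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns sharing (tissue, time) on the stored scale.

    Output has one column per (tissue, time) group, named
    ``{tissue}_t{time}``, ordered by first appearance.
    """
    meta = matrix.samples
    keys = list(zip(meta["tissue"], meta["time"]))
    order = list(dict.fromkeys(keys))  # group order = first appearance

    cols, names, rows = [], [], []
    for tissue, time in order:
        members = [s for s, k in zip(meta.index, keys) if k == (tissue, time)]
        if not members:
            raise ValueError(f"empty replicate group ({tissue}, {time})")
        cols.append(matrix.values[members].mean(axis=1))
        names.append(f"{tissue}_t{time}")
        rows.append({"tissue": tissue, "time": time, "replicate": pd.NA})
    values = pd.concat(cols, axis=1)
    values.columns = names
    samples = pd.DataFrame(rows, index=names)
    return ExpressionMatrix(values, samples, matrix.scale)


# ---------------------------------------------------------------------------
# gene sets (GMT) and simple lists
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if len(list(genes)) else ""))
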