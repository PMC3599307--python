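"""Expression-matrix containers.

The whole package works on log2 expression matrices of shape genes x samples,
with one metadata row per sample (tissue, developmental time point, replicate
id).  ``ExpressionMatrix`` is a thin validated wrapper over two aligned
:class:`pandas.DataFrame` objects; ``ProbeMatrix`` adds a probe-set -> gene
annotation with a tier rank used for probe collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every sample table carries
SAMPLE_COLUMNS = ("tissue", "time", "replicate")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``tissue``, ``time``
        and ``replicate``.  Order must match ``values.columns``.
    scale
        ``"log2"`` (default) or ``"linear"``; operations that care about
        fold changes consult this flag rather than guessing.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample columns do not match metadata rows")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns {missing}")

    # -- convenience ------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row-subset preserving metadata; raises on unknown genes."""
        genes = pd.Index(genes)
        unknown = genes.difference(self.values.index)
        if len(unknown):
            raise KeyError(f"genes absent from matrix: {list(unknown[:5])}")
        return ExpressionMatrix(self.values.loc[genes], self.samples, self.scale)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(2.0 ** self.values, self.samples, "linear")

    def to_log2(self, floor: float = 2.0 ** -10) -> "ExpressionMatrix":
        """Log2 transform; linear values <= 0 are floored at ``floor`` first."""
        if self.scale == "log2":
            return self
        vals = self.values.clip(lower=floor)
        return ExpressionMatrix(np.log2(vals), self.samples, "log2")


@dataclass
class ProbeMatrix:
    """Probe-set level values with a probe -> (gene, tier) annotation.

    ``annotation`` is a DataFrame indexed by probe-set id with columns
    ``gene`` and ``tier`` (positive integer; lower = higher-confidence
    mapping, mirroring array-vendor annotation grades).
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                {c: pd.NA for c in SAMPLE_COLUMNS}, index=self.values.columns
            )
        for col in ("gene", "tier"):
            if col not in self.annotation.columns:
                raise ValueError(f"annotation missing column {col!r}")
        tiers = self.annotation["tier"]
        if (tiers <= 0).any() or not np.issubdtype(np.asarray(tiers).dtype, np.integer):
            raise ValueError("tier ranks must be positive integers")
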