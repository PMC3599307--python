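"""Synthetic mixed-compartment gonad data with known ground truth.

Whole-gonad expression is a mixture of a germ-cell compartment and a somatic
compartment whose relative abundance changes across developmental time.  The
generator emulates that design — a short time course (default 4 time points,
duplicate arrays per point) where the observed log2 value of gene *g* at time
*t* is::

    log2( f(t) * 2**E_germ(g, t) + (1 - f(t)) * 2**E_soma(g, t) ) + eps

with ``f(t)`` the germ-cell fraction at time *t* and ``eps`` Gaussian
replicate noise on the log2 scale (mixing happens on the linear scale
because transcript abundances, not their logs, add).  Four gene classes are
planted: germ-specific (elevated in the germ compartment only, with a rising
time ramp so that profile shape is informative), soma-specific (the
reverse), ubiquitous (elevated in both) and silent (background in both).

A multi-tissue panel (default 61 tissues, including testis and ovary
columns) with planted single-tissue-specific genes supports the negative
training-example curation rule, and an annotation generator plants
chromosome assignments, essential-gene flags and GMT gene sets with known
overlap counts so enrichment statistics can be checked against construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_gene_list, write_gmt, write_matrix
from .matrix import ExpressionMatrix

GENE_CLASSES = ("germ_specific", "soma_specific", "ubiquitous", "silent")

CHROMOSOMES = tuple(str(i) for i in range(1, 20)) + ("X", "Y")

#: tissue names for the specificity panel; padded with generic names as needed
_TISSUE_NAMES = (
    "testis", "ovary", "liver", "kidney", "brain", "heart", "lung", "spleen",
    "muscle", "thymus", "stomach", "intestine", "pancreas", "skin", "bone",
    "eye", "bladder", "uterus", "prostate", "adrenal",
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic gonad time course.

    Defaults mirror the real design the package targets: 4 time points with
    duplicate arrays, a germ-cell pool that expands across the time course,
    and a 61-tissue specificity panel.
    """

    n_genes: int = 2000
    n_timepoints: int = 4
    n_replicates: int = 2
    germ_fraction_trajectory: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "germ_specific": 0.25,
            "soma_specific": 0.25,
            "ubiquitous": 0.25,
            "silent": 0.25,
        }
    )
    germ_effect_log2: float = 3.0
    noise_sd_log2: float = 0.5
    baseline_log2: float = 4.0
    baseline_gene_sd_log2: float = 0.5
    #: when True, the germ-compartment elevation of germ-specific genes ramps
    #: from half to full effect across the time course (shape signal); when
    #: False the elevation is constant (level-only signal).
    germ_time_ramp: bool = True
    n_tissues: int = 61
    n_tissue_specific: int = 40
    n_gonad_specific: int = 4
    essential_base_rate: float = 0.07
    essential_germ_rate: float = 0.12
    x_chromosome_excess: float = 3.0
    n_go_sets: int = 10
    n_planted_go_sets: int = 3
    go_set_size: int = 100
    n_mirna_sets: int = 8
    n_planted_mirna_sets: int = 3
    mirna_set_size: int = 120
    #: fraction of a planted repressor's targets drawn from non-germ classes;
    #: must sit well above the non-germ genome fraction (default 0.75) for
    #: the plant to encode a detectable repression direction
    mirna_nongerm_target_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_timepoints", "n_replicates", "n_tissues"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("germ_effect_log2", "noise_sd_log2", "baseline_log2",
                     "baseline_gene_sd_log2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        traj = np.asarray(self.germ_fraction_trajectory, dtype=float)
        if traj.size != self.n_timepoints:
            raise ValueError(
                f"germ_fraction_trajectory length {traj.size} != "
                f"n_timepoints {self.n_timepoints}"
            )
        if not np.isfinite(traj).all() or (traj < 0).any() or (traj > 1).any():
            raise ValueError("germ fractions must lie in [0, 1]")
        props = np.array([self.class_proportions.get(c, 0.0) for c in GENE_CLASSES])
        if (props < 0).any() or (props > 1).any():
            raise ValueError("class proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream code must recover."""

    classes: pd.Series  # gene id -> class label
    chromosomes: pd.Series | None = None
    essential: pd.Series | None = None  # gene id -> bool
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    #: per planted set: overlap count with the germ-specific class (GO-like
    #: sets) or with the non-germ classes (microRNA target sets)
    set_overlaps: dict[str, int] = field(default_factory=dict)
    planted_tissue_specific: dict[str, str] = field(default_factory=dict)
    planted_gonad_specific: dict[str, str] = field(default_factory=dict)

    def genes_in_class(self, label: str) -> list[str]:
        return list(self.classes.index[self.classes == label])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Deterministic class counts (largest-remainder rounding), shuffled order."""
    n = config.n_genes
    raw = {c: config.class_proportions.get(c, 0.0) * n for c in GENE_CLASSES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(GENE_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    return pd.Series(labels, index=_gene_ids(n), name="class")


def _compartment_means(
    classes: pd.Series, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene, per-time log2 means in each compartment (genes x T)."""
    n, T = len(classes), config.n_timepoints
    base = config.baseline_log2 + rng.normal(
        0.0, config.baseline_gene_sd_log2, size=n
    )
    e_germ = np.tile(base[:, None], (1, T))
    e_soma = e_germ.copy()

    if config.germ_time_ramp and T > 1:
        ramp = np.linspace(0.5, 1.0, T)
    else:
        ramp = np.ones(T)
    effect = config.germ_effect_log2

    cls = classes.to_numpy()
    e_germ[cls == "germ_specific"] += effect * ramp
    e_soma[cls == "soma_specific"] += effect
    e_germ[cls == "ubiquitous"] += effect
    e_soma[cls == "ubiquitous"] += effect
    return e_germ, e_soma


def simulate_gonad_timecourse(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the mixed germ/soma gonadal time course.

    Returns the observed log2 matrix (one column per time point x replicate)
    and the ground truth of planted gene classes.  Deterministic for a fixed
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(config, rng)
    e_germ, e_soma = _compartment_means(classes, config, rng)
    f = np.asarray(config.germ_fraction_trajectory, dtype=float)

    # linear-scale mixture, re-logged; genes x timepoints
    mix = np.log2(f[None, :] * 2.0 ** e_germ + (1.0 - f[None, :]) * 2.0 ** e_soma)

    cols, names, meta = [], [], []
    for t in range(config.n_timepoints):
        for r in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.noise_sd_log2, size=config.n_genes)
            cols.append(mix[:, t] + noise)
            names.append(f"gonad_t{t + 1}_r{r}")
            meta.append({"tissue": "gonad", "time": t + 1, "replicate": r})
    values = pd.DataFrame(
        np.column_stack(cols), index=classes.index, columns=names
    )
    samples = pd.DataFrame(meta, index=names)
    return ExpressionMatrix(values, samples, "log2"), GroundTruth(classes=classes)


def _tissue_names(n: int) -> list[str]:
    names = list(_TISSUE_NAMES[:n])
    names += [f"tissue{i:02d}" for i in range(1, n - len(names) + 1)]
    return names[:n]


def simulate_tissue_panel(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the multi-tissue specificity panel (one column per tissue).

    Plants ``n_tissue_specific`` genes that exceed 10x the panel-wide median
    in exactly one non-gonadal tissue and sit below the median elsewhere
    (guaranteed by construction and re-checked against the realised median),
    plus ``n_gonad_specific`` genes with the same profile in testis/ovary,
    which the curation rule must *not* pick up.  Planted genes are drawn
    from the non-germ-specific classes so they are valid negatives.
    """
    if config.n_tissues < 3:
        raise ValueError("n_tissues must be >= 3 to include testis and ovary")
    rng = np.random.default_rng(config.seed + 1)
    if truth is None:
        classes = _assign_classes(config, np.random.default_rng(config.seed))
        truth = GroundTruth(classes=classes)
    genes = truth.classes.index
    tissues = _tissue_names(config.n_tissues)

    # background: lognormal around ~100 on the linear scale
    values = pd.DataFrame(
        rng.lognormal(mean=np.log(100.0), sigma=0.5, size=(len(genes), len(tissues))),
        index=genes,
        columns=tissues,
    )

    non_germ = [g for g in genes if truth.classes[g] != "germ_specific"]
    n_plant = min(config.n_tissue_specific + config.n_gonad_specific, len(non_germ))
    planted = list(rng.choice(non_germ, size=n_plant, replace=False))
    specific = planted[: config.n_tissue_specific]
    gonadal = planted[config.n_tissue_specific:]

    non_gonadal_tissues = [t for t in tissues if t not in ("testis", "ovary")]
    target = {g: non_gonadal_tissues[int(rng.integers(len(non_gonadal_tissues)))]
              for g in specific}
    target.update(
        {g: ("testis", "ovary")[i % 2] for i, g in enumerate(gonadal)}
    )

    # plant against the realised global median; iterate once or twice since
    # planting itself moves the median slightly
    for _ in range(5):
        med = float(np.median(values.to_numpy()))
        for g, tt in target.items():
            values.loc[g, :] = 0.3 * med
            values.loc[g, tt] = 40.0 * med
        new_med = float(np.median(values.to_numpy()))
        if abs(new_med - med) / med < 1e-12:
            break

    samples = pd.DataFrame(
        {"tissue": tissues, "time": pd.NA, "replicate": 1}, index=tissues
    )
    panel = ExpressionMatrix(values, samples, "linear")
    truth.planted_tissue_specific = {g: target[g] for g in specific}
    truth.planted_gonad_specific = {g: target[g] for g in gonadal}
    return panel, truth


@dataclass
class Annotations:
    """In-memory annotation bundle; :meth:`write` emits the file formats."""

    chromosomes: pd.Series
    essential: pd.Series
    go_sets: dict[str, set[str]]
    mirna_sets: dict[str, set[str]]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chrom = self.chromosomes.rename("chromosome").to_frame()
        chrom.index.name = "gene"
        chrom.to_csv(outdir / "chromosomes.tsv", sep="\t")
        write_gene_list(
            sorted(self.essential.index[self.essential]), outdir / "essential.txt"
        )
        write_gmt(self.go_sets, outdir / "go_sets.gmt")
        write_gmt(self.mirna_sets, outdir / "mirna_targets.gmt")


def simulate_annotations(
    truth: GroundTruth, config: SimulationConfig
) -> Annotations:
    """Plant chromosome map, essential flags, and GMT gene sets.

    * chromosomes: 21 labels (1-19, X, Y); germ-specific genes are placed on
      X with probability inflated by ``x_chromosome_excess``.
    * essential flags: base rate ``essential_base_rate`` genome-wide, raised
      to ``essential_germ_rate`` among germ-specific genes.
    * GO-like sets: first ``n_planted_go_sets`` draw half their members from
      the germ-specific class; the rest are uniform draws.
    * microRNA target sets: planted repressors draw
      ``mirna_nongerm_target_rate`` of their targets from non-germ genes.

    Realised overlap counts are recorded in ``truth.set_overlaps``.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = truth.classes.index
    germ = np.asarray(truth.genes_in_class("germ_specific"))
    non_germ = np.asarray([g for g in genes if truth.classes[g] != "germ_specific"])

    # chromosome assignment
    base_p = np.ones(len(CHROMOSOMES)) / len(CHROMOSOMES)
    germ_p = base_p.copy()
    x = CHROMOSOMES.index("X")
    germ_p[x] *= config.x_chromosome_excess
    germ_p /= germ_p.sum()
    chrom = pd.Series(index=genes, dtype=object, name="chromosome")
    is_germ = truth.classes == "germ_specific"
    chrom[~is_germ] = rng.choice(CHROMOSOMES, size=(~is_germ).sum(), p=base_p)
    chrom[is_germ] = rng.choice(CHROMOSOMES, size=is_germ.sum(), p=germ_p)

    # essential flags
    ess = pd.Series(False, index=genes, name="essential")
    ess[~is_germ] = rng.random((~is_germ).sum()) < config.essential_base_rate
    ess[is_germ] = rng.random(is_germ.sum()) < config.essential_germ_rate

    def _draw(pool: np.ndarray, k: int) -> set[str]:
        k = min(k, len(pool))
        return set(rng.choice(pool, size=k, replace=False))

    go_sets: dict[str, set[str]] = {}
    for i in range(config.n_go_sets):
        name = f"GO_SET_{i + 1:03d}"
        if i < config.n_planted_go_sets and len(germ):
            half = config.go_set_size // 2
            members = _draw(germ, half) | _draw(non_germ, config.go_set_size - half)
        else:
            members = _draw(np.asarray(genes), config.go_set_size)
        go_sets[name] = members
        truth.set_overlaps[name] = len(members & set(germ))

    mirna_sets: dict[str, set[str]] = {}
    for i in range(config.n_mirna_sets):
        name = f"mmu-miR-sim{i + 1:02d}"
        if i < config.n_planted_mirna_sets and len(non_germ):
            k_ng = int(round(config.mirna_set_size * config.mirna_nongerm_target_rate))
            members = _draw(non_germ, k_ng) | _draw(germ, config.mirna_set_size - k_ng)
        else:
            members = _draw(np.asarray(genes), config.mirna_set_size)
        mirna_sets[name] = members
        truth.set_overlaps[name] = len(members & set(non_germ))

    truth.chromosomes = chrom
    truth.essential = ess
    truth.gene_sets = {**go_sets, **mirna_sets}
    return Annotations(chrom, ess, go_sets, mirna_sets)


def write_truth(truth: GroundTruth, path) -> None:
    """Ground-truth TSV: gene, class, chromosome, essential flag."""
    df = truth.classes.rename("class").to_frame()
    if truth.chromosomes is not None:
        df["chromosome"] = truth.chromosomes
    if truth.essential is not None:
        df["essential"] = truth.essential.astype(int)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def simulate_study(config: SimulationConfig, outdir=None):
    """Run all three generators; optionally write every artefact to a dir."""
    gonad, truth = simulate_gonad_timecourse(config)
    panel, truth = simulate_tissue_panel(config, truth)
    annotations = simulate_annotations(truth, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(gonad, outdir / "gonad.tsv")
        write_matrix(panel, outdir / "tissue_panel.tsv")
        annotations.write(outdir)
        write_truth(truth, outdir / "ground_truth.tsv")
    return gonad, panel, annotations, truth
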