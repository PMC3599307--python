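import numpy as np
import pandas as pd
import pytest

import germdeconv as gd


def make_matrix(values, genes=None, tissue="gonad", times=None, replicates=None,
                scale="log2"):
    """Small ExpressionMatrix builder for hand-written examples."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(1, n_genes + 1)]
    times = times if times is not None else list(range(1, n_samples + 1))
    replicates = replicates if replicates is not None else [1] * n_samples
    names = [f"s{i}" for i in range(1, n_samples + 1)]
    samples = pd.DataFrame(
        {"tissue": tissue, "time": times, "replicate": replicates}, index=names
    )
    return gd.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=names), samples, scale
    )


def labels_from(genes_pos, genes_neg):
    genes = list(genes_pos) + list(genes_neg)
    y = [1] * len(list(genes_pos)) + [-1] * len(list(genes_neg))
    return gd.TrainingSet(pd.Series(y, index=genes, dtype=int))


@pytest.fixture(scope="session")
def small_config():
    return gd.SimulationConfig(n_genes=400, n_tissues=12, n_tissue_specific=15,
                               n_gonad_specific=4, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    gonad, truth = gd.simulate_gonad_timecourse(small_config)
    panel, truth = gd.simulate_tissue_panel(small_config, truth)
    annotations = gd.simulate_annotations(truth, small_config)
    return gonad, panel, annotations, truth


@pytest.fixture(scope="session")
def annotated_truth():
    """Larger simulated genome for enrichment power (chromosomes, GO sets)."""
    cfg = gd.SimulationConfig(n_genes=2000, seed=13)
    _, truth = gd.simulate_gonad_timecourse(cfg)
    annotations = gd.simulate_annotations(truth, cfg)
    return annotations, truth


@pytest.fixture(scope="session")
def small_training(small_study):
    """Germ-specific genes vs. the rest, as a TrainingSet."""
    _, _, _, truth = small_study
    y = pd.Series(
        np.where(truth.classes == "germ_specific", 1, -1),
        index=truth.classes.index, dtype=int,
    )
    return gd.TrainingSet(y)
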