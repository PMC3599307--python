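"""Characterisation of ranked predictions: set enrichment and overlap.

The workhorse is the hypergeometric upper tail

    P(X >= k) = sum_{X=k}^{min(m,n)} C(m,X) C(N-m,n-X) / C(N,n)

for a genome universe of N genes, a top-prediction list of m genes, n genes
bearing an attribute (a chromosome, a GO term) and an overlap of k.
Chromosome enrichment Bonferroni-corrects at a fixed M=21 chromosomes
(1-19, X, Y); GO enrichment multiplies by the number of terms tested.
Essential-gene enrichment is a cumulative curve along the ranking compared
with randomized orderings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

N_MOUSE_CHROMOSOMES = 21  # autosomes 1-19 plus X and Y


@dataclass
class EnrichmentQuery:
    """The (N, m, n, k) quadruple of one hypergeometric tail test."""

    N: int
    m: int
    n: int
    k: int

    def __post_init__(self) -> None:
        vals = (self.N, self.m, self.n, self.k)
        if any(v < 0 for v in vals) or any(int(v) != v for v in vals):
            raise ValueError("N, m, n, k must be non-negative integers")
        if self.m > self.N or self.n > self.N:
            raise ValueError("m and n cannot exceed N")
        if self.k > min(self.m, self.n):
            raise ValueError("k cannot exceed min(m, n)")


def hypergeom_tail(q: EnrichmentQuery) -> float:
    """Upper-tail P(X >= k); exactly 1.0 for k = 0."""
    if q.k == 0:
        return 1.0
    # population N with m marked genes, n draws, X marked among the draws
    return float(stats.hypergeom.sf(q.k - 1, q.N, q.m, q.n))


def chromosome_enrichment(
    top_genes: Iterable[str],
    chrom_map: pd.Series,
    n_chromosomes: int = N_MOUSE_CHROMOSOMES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome hypergeometric tail with fixed Bonferroni denominator.

    ``chrom_map`` (gene -> chromosome label) defines the universe N.  Top
    genes absent from the map are excluded (warned); the Bonferroni divisor
    stays at ``n_chromosomes`` (default 21) regardless of how many
    chromosome labels the map happens to contain.
    """
    top = set(top_genes)
    unmapped = top - set(chrom_map.index)
    if unmapped:
        log.warning("%d top gene(s) missing from chromosome map", len(unmapped))
        top -= unmapped
    N = len(chrom_map)
    m = len(top)
    cutoff = alpha / n_chromosomes

    rows = []
    for chrom, members in chrom_map.groupby(chrom_map):
        genes_on = set(members.index)
        k = len(top & genes_on)
        p = hypergeom_tail(EnrichmentQuery(N=N, m=m, n=len(genes_on), k=k))
        rows.append({
            "chromosome": chrom, "n": len(genes_on), "k": k,
            "p_value": p, "significant": p < cutoff,
        })
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(
        drop=True
    )


def go_enrichment(
    top_genes: Iterable[str],
    annotation_sets: dict[str, set[str]],
    universe: Iterable[str],
    min_set_genes: int = 1,
) -> pd.DataFrame:
    """Per-term hypergeometric tail, Bonferroni-style corrected.

    ``n`` is the term's size within the universe; the corrected p-value is
    the raw p multiplied by the number of terms actually tested (terms with
    >= ``min_set_genes`` genes in the universe), capped at 1.
    """
    if not annotation_sets:
        raise ValueError("empty annotation collection")
    universe = set(universe)
    top = set(top_genes) & universe
    N, m = len(universe), len(top)

    tested = {
        term: members & universe
        for term, members in annotation_sets.items()
        if len(members & universe) >= min_set_genes
    }
    n_tests = len(tested)
    rows = []
    for term, members in tested.items():
        k = len(top & members)
        p = hypergeom_tail(EnrichmentQuery(N=N, m=m, n=len(members), k=k))
        rows.append({
            "term": term, "n": len(members), "k": k,
            "p_value": p, "corrected_p": min(1.0, p * n_tests),
        })
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(
        drop=True
    )


@dataclass
class EssentialCurve:
    """Cumulative essential-gene fraction along a ranking vs. random order."""

    bins: np.ndarray                 # rank cutoffs (bin, 2*bin, ..., universe)
    observed: np.ndarray             # cumulative essential fraction at cutoffs
    random_mean: np.ndarray
    random_sd: np.ndarray
    n_random: int
    p_value: float                   # one-tailed t-test, observed > random
    p_value_per_bin: float           # alternative: bins as paired replicates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank_cutoff": self.bins,
            "observed_fraction": self.observed,
            "random_mean": self.random_mean,
            "random_sd": self.random_sd,
        })


def _cumulative_fractions(flags: np.ndarray, bins: np.ndarray) -> np.ndarray:
    cum = np.cumsum(flags)
    return cum[bins - 1] / bins


def essential_curve(
    ranked_genes: Sequence[str],
    essential_set: Iterable[str],
    bin_size: int = 1000,
    n_random: int = 100,
    seed: int = 0,
    test: str = "rounds",
) -> EssentialCurve:
    """Cumulative essential fraction at rank cutoffs bin, 2*bin, ...

    The observed ranking (descending predicted probability; ties broken by
    the caller's stable order) is compared against ``n_random`` shuffles of
    the same universe.  The final cutoff is the whole universe, where both
    observed and randomized fractions equal the global essential fraction
    exactly.  ``test="rounds"`` (default) treats each randomization's curve
    mean as a replicate and one-tailed-tests the observed curve mean
    against that sample; ``test="bins"`` instead pairs observed bin
    fractions with the per-bin random means across bins (weaker when only
    the first bins are enriched, since late cumulative bins pin to the
    global fraction).
    """
    ranked = list(ranked_genes)
    U = len(ranked)
    if bin_size > U:
        raise ValueError("bin size larger than the ranked universe")
    essential = set(essential_set)
    stray = essential - set(ranked)
    if stray:
        raise ValueError(
            f"{len(stray)} essential gene(s) outside the ranked universe"
        )
    flags = np.fromiter((g in essential for g in ranked), dtype=float, count=U)
    bins = np.arange(bin_size, U + 1, bin_size)
    if bins[-1] != U:
        bins = np.append(bins, U)

    observed = _cumulative_fractions(flags, bins)
    rng = np.random.default_rng(seed)
    random_curves = np.empty((n_random, len(bins)))
    for r in range(n_random):
        random_curves[r] = _cumulative_fractions(rng.permutation(flags), bins)
    random_mean = random_curves.mean(axis=0)
    random_sd = random_curves.std(axis=0, ddof=1)

    if test not in ("rounds", "bins"):
        raise ValueError(f"unknown test {test!r}")
    t_bins = stats.ttest_rel(observed, random_mean, alternative="greater")
    round_means = random_curves.mean(axis=1)
    t_rounds = stats.ttest_1samp(
        round_means, observed.mean(), alternative="less"
    )
    p_bins, p_rounds = float(t_bins.pvalue), float(t_rounds.pvalue)
    return EssentialCurve(
        bins=bins,
        observed=observed,
        random_mean=random_mean,
        random_sd=random_sd,
        n_random=n_random,
        p_value=p_bins if test == "bins" else p_rounds,
        p_value_per_bin=p_bins,
    )


def jaccard(list_a: Iterable[str], list_b: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 0 for two empty sets."""
    a, b = set(list_a), set(list_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
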