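"""Over-representation of a gene class (e.g. transcription factors) near GWAS loci.

The question: among the genes found near risk variants, are members of a gene
class (transcription factors here) drawn more often than chance from the gene
universe? Tested one-sided by the hypergeometric upper tail and two-sided by
Fisher's exact test on the corresponding 2x2 table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .genomic import GeneModel

__all__ = ["LocusGeneUniverse", "genes_near_variants", "tf_set_enrichment", "EnrichmentResult"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusGeneUniverse:
    """Counts for a class-enrichment test.

    N genes in the universe, K of them in the class, n drawn (near loci),
    k of the drawn in the class.
    """

    universe_size: int
    class_size: int
    drawn: int
    class_drawn: int

    def __post_init__(self) -> None:
        N, K, n, k = self.universe_size, self.class_size, self.drawn, self.class_drawn
        if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
            raise ValueError(
                f"inconsistent universe counts N={N}, K={K}, n={n}, k={k}: "
                "require K<=N, n<=N, k<=min(K,n)"
            )


def genes_near_variants(
    variants: pd.DataFrame, genes: Sequence[GeneModel], window: int = 500_000
) -> set[str]:
    """Union of genes whose TSS lies within ±window of any variant position.

    Variants on chromosomes absent from the gene table are skipped and logged.
    """
    if window <= 0:
        raise ValueError("genes_near_variants: window must be > 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    found: set[str] = set()
    n_skipped = 0
    for v in variants.itertuples():
        cands = by_chrom.get(str(v.chrom))
        if cands is None:
            n_skipped += 1
            continue
        pos = int(v.pos_1based)
        found.update(g.gene_id for g in cands if abs(g.tss - pos) <= window)
    if n_skipped:
        logger.info("genes_near_variants: skipped %d variants on chromosomes without genes", n_skipped)
    return found


@dataclass(frozen=True)
class EnrichmentResult:
    p_hyper: float
    p_fisher: float
    fold: float
    universe: LocusGeneUniverse

    def to_dict(self) -> dict:
        u = self.universe
        return {
            "N": u.universe_size, "K": u.class_size, "n": u.drawn, "k": u.class_drawn,
            "p_hyper": self.p_hyper, "p_fisher": self.p_fisher, "fold": self.fold,
        }


def tf_set_enrichment(universe: LocusGeneUniverse) -> EnrichmentResult:
    """Class over-representation among drawn genes.

    ``p_hyper`` is the one-sided upper tail P(X >= k) under
    Hypergeometric(N, K, n); ``p_fisher`` is the two-sided Fisher exact p on
    the table [[k, n-k], [K-k, N-K-n+k]]; ``fold = (k/n) / (K/N)``.
    """
    N, K, n, k = (
        universe.universe_size, universe.class_size, universe.drawn, universe.class_drawn,
    )
    if n == 0:
        raise ValueError("tf_set_enrichment: no drawn genes (n = 0)")
    if K == 0:
        raise ValueError("tf_set_enrichment: empty gene class (K = 0)")
    p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n))
    table = [[k, n - k], [K - k, N - K - n + k]]
    p_fisher = float(stats.fisher_exact(table, alternative="two-sided")[1])
    fold = (k / n) / (K / N)
    return EnrichmentResult(p_hyper, p_fisher, fold, universe)
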