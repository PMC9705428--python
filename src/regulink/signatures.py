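"""Gene signatures: derivation by set intersection and z-score-sum scoring.

A signature is a gene panel with (default unit) weights. A sample's score is
the weighted sum over panel genes of the gene's z-scored expression across the
cohort, so scores are invariant to per-gene affine rescaling of expression.
The derivation helpers mirror the common construction patterns: intersecting
top enriched pathways with up-regulated genes, intersecting up-regulated genes
with peak-annotated target genes, and taking the top-k co-expressed panel.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Signature",
    "SignatureScoreSet",
    "score_signature",
    "derive_pathway_intersection_signature",
    "derive_joint_target_signature",
    "derive_coexpression_panel",
    "correlate_scores",
    "ccp_score",
    "read_gmt",
]


@dataclass
class Signature:
    """A named gene panel with per-gene weights (default 1)."""

    name: str
    genes: list[str]
    weights: np.ndarray = None

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"signature {self.name!r}: needs at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r}: duplicate gene ids")
        if self.weights is None:
            self.weights = np.ones(len(self.genes))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.genes),) or not np.isfinite(self.weights).all():
            raise ValueError(f"signature {self.name!r}: weights must be finite, one per gene")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "weight": self.weights})


@dataclass
class SignatureScoreSet:
    """Per-sample z-score-sum scores for one signature."""

    name: str
    scores: pd.Series
    genes_used: list[str]
    genes_missing: list[str] = field(default_factory=list)


def score_signature(expression: pd.DataFrame, sig: Signature) -> SignatureScoreSet:
    """Score samples: S = sum_g w_g * (x_g - mean_g) / sd_g (sd with n-1).

    Signature genes absent from the matrix, or with zero variance across
    samples, are excluded and listed in ``genes_missing``.
    """
    present, missing = [], []
    for g in sig.genes:
        if g in expression.index and expression.loc[g].std(ddof=1) > 0:
            present.append(g)
        else:
            missing.append(g)
    if not present:
        raise ValueError(f"signature {sig.name!r}: no scoreable gene present in the matrix")
    sub = expression.loc[present].astype(float)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    w = pd.Series(dict(zip(sig.genes, sig.weights)))[present]
    scores = z.mul(w, axis=0).sum(axis=0)
    scores.name = sig.name
    return SignatureScoreSet(sig.name, scores, present, missing)


def derive_pathway_intersection_signature(
    pathway_sets: Mapping[str, set[str]],
    de_up: set[str],
    k_top: int = 5,
    name: str = "pathway_intersection",
) -> Signature:
    """Union of the first ``k_top`` pathway gene sets, intersected with
    up-regulated genes.

    ``pathway_sets`` must be supplied already ordered by enrichment (dicts
    preserve insertion order); enrichment ranking itself is an input.
    """
    top = list(pathway_sets)[:k_top]
    union: set[str] = set()
    for p in top:
        union |= set(pathway_sets[p])
    genes = sorted(union & set(de_up))
    if not genes:
        raise ValueError(
            f"empty intersection of top {k_top} pathways with the up-regulated set; "
            "try a larger k_top"
        )
    return Signature(name, genes)


def derive_joint_target_signature(
    de_up: set[str], common_peak_genes: set[str], name: str = "joint_targets"
) -> Signature:
    """Intersection of up-regulated genes with peak-annotated target genes."""
    if not de_up or not common_peak_genes:
        raise ValueError("derive_joint_target_signature: both input sets must be nonempty")
    genes = sorted(set(de_up) & set(common_peak_genes))
    if not genes:
        raise ValueError("derive_joint_target_signature: empty intersection")
    return Signature(name, genes)


def derive_coexpression_panel(
    ranked: pd.DataFrame, k: int = 25, name: str = "coexpression_panel"
) -> Signature:
    """Top-k genes of a co-expression ranking (Pearson r descending).

    Ties at the boundary break by lexicographic gene id. Fewer than k genes
    returns them all with a warning.
    """
    if len(ranked) < k:
        warnings.warn(
            f"derive_coexpression_panel: only {len(ranked)} genes available for k={k}",
            stacklevel=2,
        )
    ordered = ranked.sort_values(
        ["pearson_r", "gene_b"], ascending=[False, True], kind="mergesort"
    )
    genes = list(ordered["gene_b"].head(k))
    return Signature(name, genes)


@dataclass
class ScoreCorrelation:
    pearson_r: float
    spearman_rho: float
    p_pearson: float
    p_spearman: float
    n: int


def correlate_scores(
    scores_a: SignatureScoreSet | pd.Series, scores_b: SignatureScoreSet | pd.Series
) -> ScoreCorrelation:
    """Pearson and Spearman correlation of two score sets on shared samples."""
    a = scores_a.scores if isinstance(scores_a, SignatureScoreSet) else pd.Series(scores_a)
    b = scores_b.scores if isinstance(scores_b, SignatureScoreSet) else pd.Series(scores_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"correlate_scores: only {len(shared)} shared samples (need >= 3)")
    av, bv = a[shared].astype(float), b[shared].astype(float)
    pr = stats.pearsonr(av, bv)
    sr = stats.spearmanr(av, bv)
    return ScoreCorrelation(
        float(pr.statistic), float(sr.statistic), float(pr.pvalue), float(sr.pvalue), len(shared)
    )


def ccp_score(expression: pd.DataFrame, ccp_genes: Sequence[str]) -> pd.Series:
    """Cell-cycle-progression style score: mean z-score of a cell-cycle panel."""
    genes = list(ccp_genes)
    sig = Signature("CCP", genes, np.full(len(genes), 1.0 / len(genes)))
    return score_signature(expression, sig).scores


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
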