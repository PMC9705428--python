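"""LD proxy expansion, SNP enrichment across binding-site partitions, eGene
lookup and case-control allelic association.

GWAS tag SNPs are expanded with proxies at r² >= 0.8 (inclusive) before
interval work. Enrichment across the unique-A / common / unique-B base-pair
partitions of two factors' binding sites is tested by a chi-squared statistic
against span-proportional expectation, with an optional permutation null that
re-places the observed SNPs uniformly over the partitions' union.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import PeakSet

__all__ = [
    "expand_ld_proxies",
    "PartitionEnrichment",
    "partition_snp_enrichment",
    "egene_lookup",
    "case_control_association",
]

logger = logging.getLogger(__name__)


def expand_ld_proxies(tags: set[str], ld: pd.DataFrame, r2_min: float = 0.8) -> set[str]:
    """Tags plus every proxy in LD at r² >= r2_min with any tag (deduplicated).

    The threshold is inclusive: a proxy at exactly r² = 0.8 is kept.
    """
    if not tags:
        raise ValueError("expand_ld_proxies: empty tag set")
    if not (0.0 < r2_min <= 1.0):
        raise ValueError(f"expand_ld_proxies: r2_min must lie in (0, 1], got {r2_min!r}")
    hits = ld[(ld["tag"].isin(tags)) & (ld["r2"] >= r2_min)]
    return set(tags) | set(hits["proxy"])


def _snp_in_intervals(pos0: np.ndarray, peaks: PeakSet) -> np.ndarray:
    """Boolean membership of 0-based positions in a normalized peak set."""
    out = np.zeros(len(pos0), dtype=bool)
    df = peaks.df
    for chrom, sub in df.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        j = np.searchsorted(starts, pos0, side="right")
        inside = (j > 0) & (pos0 < ends[np.maximum(j - 1, 0)])
        out |= inside
    return out


@dataclass
class PartitionEnrichment:
    """SNP counts across binding-site partitions with a chi-squared test."""

    table: pd.DataFrame  # per partition: observed, span, expected, fold
    chi2: float
    df: int
    p: float
    n_total: int          # SNPs inside any partition
    n_outside: int        # SNPs in none (excluded from the test)
    p_permutation: float | None = None
    n_permutations: int = 0

    def to_dict(self) -> dict:
        d = {
            "chi2": self.chi2, "df": self.df, "p": self.p,
            "n_total": self.n_total, "n_outside": self.n_outside,
            "partitions": self.table.to_dict(orient="index"),
        }
        if self.p_permutation is not None:
            d["p_permutation"] = self.p_permutation
            d["n_permutations"] = self.n_permutations
        return d


def partition_snp_enrichment(
    snps: pd.DataFrame,
    partitions: dict[str, PeakSet],
    n_permutations: int = 0,
    seed: int | None = None,
) -> PartitionEnrichment:
    """Chi-squared enrichment of SNPs across disjoint base-pair partitions.

    ``snps`` needs ``chrom`` and 1-based ``pos_1based`` columns; membership is
    tested at ``pos - 1``. Expected counts are proportional to partition span;
    ``fold_i = (obs_i/total) / (span_i/total_span)``. SNPs outside every
    partition are excluded (conditional-on-binding analysis) but counted.
    With ``n_permutations > 0`` an additional permutation p-value is computed
    by re-placing the in-partition SNPs uniformly over the pooled spans.
    """
    if len(snps) == 0:
        raise ValueError("partition_snp_enrichment: empty SNP table")
    names = list(partitions)
    norm = {k: v.normalize() for k, v in partitions.items()}
    spans = {k: v.total_span for k, v in norm.items()}
    total_span = sum(spans.values())
    if total_span == 0:
        raise ValueError("partition_snp_enrichment: zero total partition span")
    # disjointness check
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = norm[names[i]], norm[names[j]]
            if len(gi) and len(gj) and len(gi._pr().set_intersect(gj._pr()).df):
                raise ValueError(
                    f"partitions {names[i]!r} and {names[j]!r} overlap; they must be disjoint"
                )

    pos0 = snps["pos_1based"].to_numpy(dtype=np.int64) - 1
    member = {k: _snp_in_intervals(pos0, norm[k]) for k in names}
    observed = {k: int(member[k].sum()) for k in names}
    n_total = sum(observed.values())
    n_outside = len(snps) - n_total
    if n_total == 0:
        raise ValueError("partition_snp_enrichment: no SNP falls inside any partition")

    tested = [k for k in names if spans[k] > 0]
    obs = np.array([observed[k] for k in tested], dtype=float)
    exp = np.array([n_total * spans[k] / total_span for k in tested])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = len(tested) - 1
    p = float(stats.chi2.sf(chi2, df=dof)) if dof > 0 else 1.0
    fold = {k: (observed[k] / n_total) / (spans[k] / total_span) for k in tested}

    table = pd.DataFrame(
        {
            "observed": [observed[k] for k in names],
            "span": [spans[k] for k in names],
            "expected": [n_total * spans[k] / total_span for k in names],
            "fold": [fold.get(k, np.nan) for k in names],
        },
        index=pd.Index(names, name="partition"),
    )

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        probs = np.array([spans[k] / total_span for k in tested])
        sims = rng.multinomial(n_total, probs, size=n_permutations).astype(float)
        chi2_sim = ((sims - exp) ** 2 / exp).sum(axis=1)
        p_perm = float((1 + (chi2_sim >= chi2).sum()) / (n_permutations + 1))

    return PartitionEnrichment(table, chi2, dof, p, n_total, n_outside, p_perm, n_permutations)


def egene_lookup(
    proxies: set[str], eqtl_table: pd.DataFrame, p_max: float | None = None
) -> set[str]:
    """Genes linked to any proxy SNP in an external eQTL association table.

    ``eqtl_table`` must carry ``rsid``, ``gene`` and ``p`` columns. With
    ``p_max`` given, associations at p <= p_max count; otherwise the table is
    taken as pre-filtered for significance. An empty overlap warns rather
    than raising.
    """
    missing = {"rsid", "gene", "p"} - set(eqtl_table.columns)
    if missing:
        raise ValueError(f"egene_lookup: eQTL table lacks columns {sorted(missing)}")
    hits = eqtl_table[eqtl_table["rsid"].isin(proxies)]
    if p_max is not None:
        hits = hits[hits["p"] <= p_max]
    genes = set(hits["gene"])
    if not genes:
        warnings.warn("egene_lookup: no proxy SNP found in the eQTL table", stacklevel=2)
    return genes


def case_control_association(
    genotypes: pd.DataFrame, labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Per-SNP allelic association between cases and controls.

    ``labels`` is boolean (True = case) or {"case", "control"} aligned to the
    genotype rows. Alleles are counted from the additive coding (alt-allele
    count per sample); the 2x2 allele x status table gives the odds ratio
    (with Haldane's 0.5 correction when any cell is zero) and a 1-df
    chi-squared p. Monomorphic SNPs are flagged untested.
    """
    labels = pd.Series(labels, index=genotypes.index)
    if labels.dtype == object:
        labels = labels.map({"case": True, "control": False})
        if labels.isna().any():
            raise ValueError("labels must be boolean or 'case'/'control'")
    is_case = labels.astype(bool).to_numpy()
    if not is_case.any() or is_case.all():
        raise ValueError("case_control_association: need at least one case and one control")
    g = genotypes.to_numpy(dtype=float)
    rows = []
    for j, rsid in enumerate(genotypes.columns):
        col = g[:, j]
        ok = ~np.isnan(col)
        gc, cc = col[ok & is_case], col[ok & ~is_case]
        a = float(gc.sum())                 # alt alleles in cases
        b = 2.0 * len(gc) - a               # ref alleles in cases
        c = float(cc.sum())
        d = 2.0 * len(cc) - c
        alt_total = a + c
        if alt_total == 0 or alt_total == 2.0 * (len(gc) + len(cc)):
            rows.append((rsid, a, b, c, d, np.nan, np.nan, np.nan, False))
            continue
        aa, bb, ccx, dd = (a, b, c, d)
        if min(a, b, c, d) == 0:
            aa, bb, ccx, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_ = (aa * dd) / (bb * ccx)
        chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        rows.append((rsid, a, b, c, d, or_, float(chi2), float(p), True))
    return pd.DataFrame(
        rows,
        columns=["rsid", "case_alt", "case_ref", "control_alt", "control_ref",
                 "odds_ratio", "chi2", "p", "tested"],
    ).set_index("rsid")
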