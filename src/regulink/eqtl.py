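"""Genotype QC, cis-pair mapping, additive linear eQTL fitting and co-expression.

The eQTL model is ordinary least squares of (log-scale) expression on the
additive 0/1/2 genotype with an intercept; the test is the two-sided t test on
the slope with n-2 degrees of freedom, i.e. the linear model of standard
matrix-eQTL practice. Stratified fits re-run the same model within clinical
strata (e.g. gene-fusion-positive vs -negative tumours) and pooled.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GeneModel

__all__ = [
    "QCThresholds",
    "qc_genotypes",
    "map_cis_pairs",
    "EqtlResult",
    "fit_additive_eqtl",
    "stratified_eqtl",
    "CorrelationResult",
    "coexpression_rank",
]

logger = logging.getLogger(__name__)


# -- genotype QC -------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """SNP inclusion thresholds: call rate >= 90%, MAF >= 1%, HWE p >= 0.05."""

    cr_min: float = 0.90
    maf_min: float = 0.01
    hwe_min: float = 0.05


def hwe_chi2_p(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Hardy-Weinberg 1-df chi-squared p-value from genotype counts."""
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        return 1.0
    q = (2 * n_alt_hom + n_het) / (2 * n)  # alt allele frequency
    p = 1.0 - q
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_ref_hom, n_het, n_alt_hom], dtype=float)
    if (exp == 0).any():  # monomorphic: HWE trivially satisfied
        return 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_genotypes(
    genotypes: pd.DataFrame,
    cr_min: float = 0.90,
    maf_min: float = 0.01,
    hwe_min: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter SNP columns by call rate, minor allele frequency and HWE.

    ``genotypes`` is samples x SNPs with values in {0, 1, 2, NaN}. Returns the
    filtered matrix and a per-SNP report (call_rate, maf, hwe_p, kept).
    Raises if every SNP fails, with per-filter counts in the message.
    """
    g = genotypes.to_numpy(dtype=float)
    bad = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError("genotype matrix must contain only 0/1/2 or missing values")
    rows = []
    for j, rsid in enumerate(genotypes.columns):
        col = g[:, j]
        obs = col[~np.isnan(col)]
        call_rate = len(obs) / len(col) if len(col) else 0.0
        if len(obs):
            q = obs.mean() / 2.0
            maf = min(q, 1.0 - q)
            counts = [int((obs == k).sum()) for k in (0, 1, 2)]
            hwe_p = hwe_chi2_p(*counts)
        else:
            maf, hwe_p = 0.0, 1.0
        kept = (call_rate >= cr_min) and (maf >= maf_min) and (hwe_p >= hwe_min)
        rows.append((rsid, call_rate, maf, hwe_p, kept))
    report = pd.DataFrame(rows, columns=["rsid", "call_rate", "maf", "hwe_p", "kept"]).set_index("rsid")
    keep = report.index[report["kept"]]
    if len(keep) == 0:
        n_cr = int((report["call_rate"] < cr_min).sum())
        n_maf = int((report["maf"] < maf_min).sum())
        n_hwe = int((report["hwe_p"] < hwe_min).sum())
        raise ValueError(
            "all SNPs removed by QC "
            f"(call rate < {cr_min}: {n_cr}; MAF < {maf_min}: {n_maf}; HWE p < {hwe_min}: {n_hwe})"
        )
    return genotypes[keep], report


# -- cis-pair mapping --------------------------------------------------------

def map_cis_pairs(
    variants: pd.DataFrame, genes: Sequence[GeneModel], window: int = 1_000_000
) -> pd.DataFrame:
    """All SNP-gene pairs with |variant position - TSS| <= window (inclusive).

    Both coordinates are 1-based; chromosomes must match. Returns a DataFrame
    with columns rsid, gene_id, distance.
    """
    if window <= 0:
        raise ValueError("map_cis_pairs: window must be > 0")
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in genes:
        by_chrom.setdefault(gm.chrom, []).append(gm)
    for v in variants.itertuples():
        for gm in by_chrom.get(str(v.chrom), ()):
            d = abs(int(v.pos_1based) - gm.tss)
            if d <= window:
                rows.append((v.rsid, gm.gene_id, d))
    return pd.DataFrame(rows, columns=["rsid", "gene_id", "distance"])


# -- additive eQTL fit -------------------------------------------------------

@dataclass
class EqtlResult:
    """One SNP-gene association in one stratum."""

    rsid: str
    gene_id: str
    stratum: str
    n: int
    beta: float
    se: float
    t: float
    p: float
    testable: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def fit_additive_eqtl(
    genotype: np.ndarray | pd.Series,
    expression: np.ndarray | pd.Series,
    rsid: str = "snp",
    gene_id: str = "gene",
    stratum: str = "all",
) -> EqtlResult:
    """OLS of expression on additive genotype; slope t test with n-2 df.

    Missing genotypes (NaN) are dropped pairwise. With fewer than 3 complete
    pairs or a constant genotype the result is flagged untestable: the slope
    is reported when computable, the p-value is NaN.
    """
    g = np.asarray(genotype, dtype=float)
    e = np.asarray(expression, dtype=float)
    if g.shape != e.shape:
        raise ValueError("genotype and expression vectors must be paired")
    ok = ~(np.isnan(g) | np.isnan(e))
    g, e = g[ok], e[ok]
    n = len(g)
    if n < 3 or np.ptp(g) == 0:
        beta = np.nan
        if n >= 2 and np.ptp(g) > 0:
            beta = float(np.polyfit(g, e, 1)[0])
        return EqtlResult(rsid, gene_id, stratum, n, beta, np.nan, np.nan, np.nan, testable=False)
    res = stats.linregress(g, e)
    return EqtlResult(
        rsid, gene_id, stratum, n,
        float(res.slope), float(res.stderr),
        float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        float(res.pvalue),
    )


def stratified_eqtl(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    strata_by: str,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-stratum and pooled additive eQTL fits for a set of SNP-gene pairs.

    ``genotypes`` is samples x SNPs, ``expression`` genes x samples and
    ``clinical`` indexed by sample with a ``strata_by`` column. Samples with a
    missing stratum label are excluded (and logged). The identical pair set is
    fitted in every stratum and in the pooled cohort; strata with fewer than 3
    complete pairs yield untestable rows. Benjamini-Hochberg q-values are
    reported per stratum alongside nominal p.
    """
    samples = genotypes.index.intersection(expression.columns).intersection(clinical.index)
    if len(samples) == 0:
        raise ValueError("no shared samples between genotypes, expression and clinical tables")
    labels = clinical.loc[samples, strata_by]
    known = labels.notna()
    if (~known).any():
        logger.info("stratified_eqtl: excluding %d samples with unknown %s", int((~known).sum()), strata_by)
    samples = samples[known]
    labels = labels[known]

    if pairs is None:
        pairs = [(r, g) for r in genotypes.columns for g in expression.index]

    results: list[EqtlResult] = []
    strata = [(lab, samples[labels == lab]) for lab in sorted(labels.unique())]
    strata.append(("pooled", samples))
    for rsid, gene_id in pairs:
        for lab, idx in strata:
            results.append(
                fit_additive_eqtl(
                    genotypes.loc[idx, rsid], expression.loc[gene_id, idx],
                    rsid=rsid, gene_id=gene_id, stratum=str(lab),
                )
            )
    out = pd.DataFrame([r.to_dict() for r in results])
    out["q"] = np.nan
    for lab in out["stratum"].unique():
        mask = (out["stratum"] == lab) & out["testable"]
        if mask.any():
            out.loc[mask, "q"] = _bh_q(out.loc[mask, "p"].to_numpy())
    return out


def _bh_q(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


# -- co-expression ranking ---------------------------------------------------

@dataclass
class CorrelationResult:
    gene_a: str
    gene_b: str
    pearson_r: float
    spearman_rho: float
    p_pearson: float
    p_spearman: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation via the t transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def coexpression_rank(expression: pd.DataFrame, query_gene: str) -> pd.DataFrame:
    """Rank all other genes by Pearson correlation with the query gene.

    Genes with zero variance are excluded (and logged). Returns one row per
    gene, sorted by ``pearson_r`` descending, with Pearson and Spearman
    coefficients and their t-approximation p-values.
    """
    if query_gene not in expression.index:
        raise KeyError(f"query gene {query_gene!r} not in expression matrix")
    x = expression.loc[query_gene].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"query gene {query_gene!r} has constant expression")
    others = expression.drop(index=query_gene)
    mat = others.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("coexpression_rank: excluding %d zero-variance genes", int((~keep).sum()))
    others = others.loc[keep]
    mat = mat[keep]
    n = mat.shape[1]

    def _corr_with(vec: np.ndarray, rows: np.ndarray) -> np.ndarray:
        vz = (vec - vec.mean()) / vec.std()
        rz = (rows - rows.mean(axis=1, keepdims=True)) / rows.std(axis=1, keepdims=True)
        return rz @ vz / n

    r = _corr_with(x, mat)
    xr = stats.rankdata(x)
    matr = np.apply_along_axis(stats.rankdata, 1, mat)
    rho = _corr_with(xr, matr)

    out = pd.DataFrame(
        {
            "gene_a": query_gene,
            "gene_b": others.index,
            "pearson_r": r,
            "spearman_rho": rho,
            "p_pearson": _t_pvalue(r, n),
            "p_spearman": _t_pvalue(rho, n),
            "n": n,
        }
    )
    return out.sort_values("pearson_r", ascending=False, kind="mergesort").reset_index(drop=True)
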