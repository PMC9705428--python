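"""Synthetic cohorts with the statistical structure the downstream analyses assume.

The generator plants the features each stage is designed to detect: LD-block
genotypes with controllable r², a target gene whose expression responds to one
eQTL SNP only in fusion-positive samples, a co-regulated partner gene, two
ChIP-seq-like peak sets with controllable co-occupancy and a controllable SNP
enrichment in their shared binding sites, and survival times whose hazard
depends on a signature score. Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genomic import PeakSet

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_expression_cohort",
    "simulate_peak_landscape",
    "simulate_survival",
    "TARGET_GENE",
    "REGULATOR_GENE",
    "EQTL_SNP",
]

TARGET_GENE = "GENE_TARGET"
REGULATOR_GENE = "GENE_REG"
#: rsid of the planted eQTL SNP (first SNP of the first LD block)
EQTL_SNP = "rs1"

CHROM = "chrS"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Fractions are validated to their stated ranges; a fixed ``seed`` makes all
    four generators byte-identical across runs.
    """

    n_samples: int = 500
    n_blocks: int = 10
    snps_per_block: int = 5
    within_block_r2: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.4)
    eqtl_beta: float = 1.0
    fusion_fraction: float = 0.4
    fusion_dependent: bool = True
    coexpr_rho: float = 0.8
    noise_sd: float = 1.0
    cooccupancy_target: float = 0.7
    snp_enrichment_fold: float = 3.0
    surv_lnHR: float = 0.7
    censor_rate: float = 0.2
    seed: int = 0
    # landscape / cohort size knobs
    n_genes: int = 100
    genome_size: int = 10_000_000
    n_peaks: int = 500
    peak_width: int = 200
    n_gwas_snps: int = 1000
    baseline_median_months: float = 60.0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_blocks", "snps_per_block", "n_genes", "n_peaks",
                     "n_gwas_snps", "peak_width", "genome_size"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"SimulationConfig.{name} must be an integer >= 1, got {v!r}")
        for name in ("within_block_r2", "fusion_fraction", "cooccupancy_target", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SimulationConfig.{name} must lie in [0, 1], got {v!r}")
        if not -1.0 <= self.coexpr_rho <= 1.0:
            raise ValueError(f"SimulationConfig.coexpr_rho must lie in [-1, 1], got {self.coexpr_rho!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"SimulationConfig.maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range!r}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"SimulationConfig.noise_sd must be >= 0, got {self.noise_sd!r}")
        if self.snp_enrichment_fold <= 0:
            raise ValueError(
                f"SimulationConfig.snp_enrichment_fold must be > 0, got {self.snp_enrichment_fold!r}"
            )
        if self.baseline_median_months <= 0:
            raise ValueError("SimulationConfig.baseline_median_months must be > 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"SimulationConfig.seed must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator
    return np.random.default_rng([int(config.seed), stream])


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


# -- genotypes ---------------------------------------------------------------

def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """LD-block genotypes in additive 0/1/2 coding.

    Each block has one minor-allele frequency drawn uniformly from
    ``maf_range``. Haplotype alleles follow a Markov copy along the block:
    each SNP copies its left neighbour with probability ``sqrt(within_block_r2)``
    and otherwise redraws from the block MAF, so adjacent genotype columns have
    correlation ``sqrt(r2)`` and squared correlation ``within_block_r2``.

    Returns ``(genotypes, variants, ld_pairs)``: a samples x SNPs DataFrame, a
    variant table (rsid, chrom, pos_1based, ref, alt, block) and an LD table
    with the *empirical* r² of every within-block SNP pair.
    """
    rng = _rng(config, 0)
    n, b, m = config.n_samples, config.n_blocks, config.snps_per_block
    copy_p = math.sqrt(config.within_block_r2)
    cols = []
    rsids = []
    blocks = []
    for bi in range(b):
        p = rng.uniform(*config.maf_range)
        hap = np.empty((n, 2, m), dtype=np.int8)
        hap[:, :, 0] = rng.random((n, 2)) < p
        for j in range(1, m):
            keep = rng.random((n, 2)) < copy_p
            fresh = rng.random((n, 2)) < p
            hap[:, :, j] = np.where(keep, hap[:, :, j - 1], fresh)
        cols.append(hap.sum(axis=1))
        for j in range(m):
            rsids.append(f"rs{bi * m + j + 1}")
            blocks.append(bi)
    geno = pd.DataFrame(
        np.concatenate(cols, axis=1), index=_sample_ids(n), columns=rsids, dtype=np.int8
    )
    geno.index.name = "sample"

    spacing = max(config.genome_size // max(b, 1), m * 100 + 1)
    pos = [bi * spacing + (i % m) * 100 + 1 for i, bi in enumerate(blocks)]
    variants = pd.DataFrame(
        {"rsid": rsids, "chrom": CHROM, "pos_1based": pos, "ref": "A", "alt": "G", "block": blocks}
    )

    ld_rows = []
    g = geno.to_numpy(dtype=float)
    for bi in range(b):
        idx = [i for i, bb in enumerate(blocks) if bb == bi]
        sub = g[:, idx]
        with np.errstate(invalid="ignore"):
            cc = np.corrcoef(sub, rowvar=False)
        for a in range(len(idx)):
            for c in range(a + 1, len(idx)):
                r = cc[a, c]
                r2 = float(r * r) if np.isfinite(r) else 0.0
                ld_rows.append((rsids[idx[a]], rsids[idx[c]], r2))
    ld = pd.DataFrame(ld_rows, columns=["tag", "proxy", "r2"])
    return geno, variants, ld


# -- expression + clinical ---------------------------------------------------

def simulate_expression_cohort(
    genotypes: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) and clinical table with fusion status.

    The designated target gene follows
    ``intercept + beta * genotype * fusion`` (the fusion indicator drops out
    when ``fusion_dependent`` is off) plus Normal(0, noise_sd²) noise. The
    designated regulator gene is built to correlate with the target at
    ``coexpr_rho`` among fusion-positive samples and is independent noise in
    the rest. Remaining genes are standard-normal background.
    """
    if genotypes is None or len(genotypes) == 0:
        raise ValueError("simulate_expression_cohort: empty genotype matrix")
    if EQTL_SNP not in genotypes.columns:
        raise ValueError(
            f"designated eQTL SNP {EQTL_SNP!r} not present in the genotype matrix"
        )
    rng = _rng(config, 1)
    samples = list(genotypes.index)
    n = len(samples)
    fusion = rng.random(n) < config.fusion_fraction
    g = genotypes[EQTL_SNP].to_numpy(dtype=float)

    effect = config.eqtl_beta * g * (fusion if config.fusion_dependent else 1.0)
    target = 1.0 + effect + rng.normal(0.0, config.noise_sd, n)

    regulator = rng.normal(0.0, 1.0, n)
    pos_idx = np.flatnonzero(fusion)
    if len(pos_idx) >= 2:
        t = target[pos_idx]
        sd = t.std()
        z = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
        rho = config.coexpr_rho
        regulator[pos_idx] = rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal(0.0, 1.0, len(pos_idx))

    background = rng.normal(0.0, 1.0, (config.n_genes, n))
    gene_ids = [TARGET_GENE, REGULATOR_GENE] + [f"GENE_{i + 1:04d}" for i in range(config.n_genes)]
    expr = pd.DataFrame(
        np.vstack([target, regulator, background]), index=gene_ids, columns=samples
    )
    expr.index.name = "gene_id"

    clinical = pd.DataFrame(
        {
            "sample": samples,
            "fusion": np.where(fusion, "positive", "negative"),
        }
    ).set_index("sample")
    return expr, clinical


# -- peak landscape ----------------------------------------------------------

def _place_nonoverlapping(rng, n: int, width: int, genome_size: int) -> np.ndarray:
    """Sorted, non-overlapping, non-touching starts for n peaks of given width."""
    slack = genome_size - n * (width + 1)
    if slack <= 0:
        raise ValueError(
            f"genome of {genome_size} bp too small to place {n} peaks of width {width}"
        )
    x = np.sort(rng.choice(slack, size=n, replace=False))
    return x + np.arange(n) * (width + 1)


def simulate_peak_landscape(
    config: SimulationConfig,
) -> tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Two peak sets with planted co-occupancy and SNP enrichment in their overlap.

    A fraction ``cooccupancy_target`` of A peaks receives a B peak nested in
    its central half; the remaining B peaks sit in the background. GWAS SNPs
    are placed so that, among SNPs falling in any binding-site partition, the
    span-normalized share of the common (A∩B) partition equals
    ``snp_enrichment_fold`` in expectation; ``fold = 1`` reduces to uniform
    span-proportional placement. About 40% of SNPs land outside all peaks.
    """
    rng = _rng(config, 2)
    n, w, G = config.n_peaks, config.peak_width, config.genome_size
    if w < 4:
        raise ValueError("simulate_peak_landscape: peak_width must be >= 4")
    a_starts = _place_nonoverlapping(rng, n, w, G)
    n_co = int(round(config.cooccupancy_target * n))
    co_idx = rng.choice(n, size=n_co, replace=False)
    # nested B peaks: central half of the host A peak -> overlap only that peak
    b_nested = np.stack([a_starts[co_idx] + w // 4, a_starts[co_idx] + w // 4 + w // 2], axis=1)

    n_bg_b = n - n_co
    b_bg = np.empty((0, 2), dtype=np.int64)
    if n_bg_b > 0:
        a_ends = a_starts + w
        accepted: list[int] = []  # kept sorted
        tries = 0
        while len(accepted) < n_bg_b:
            tries += 1
            if tries > 1000:
                raise ValueError(
                    f"genome of {G} bp too small to place {n_bg_b} background peaks of width {w}"
                )
            for c in rng.integers(0, G - w, size=4 * n_bg_b):
                c = int(c)
                # peak [c, c+w) must not overlap any A peak or accepted B peak
                j = int(np.searchsorted(a_starts, c))
                if j > 0 and c < a_ends[j - 1]:
                    continue
                if j < n and c + w > a_starts[j]:
                    continue
                k = int(np.searchsorted(accepted, c))
                if k > 0 and c < accepted[k - 1] + w + 1:
                    continue  # +1: avoid touching within the B set
                if k < len(accepted) and c + w + 1 > accepted[k]:
                    continue
                accepted.insert(k, c)
                if len(accepted) >= n_bg_b:
                    break
        starts = np.array(accepted, dtype=np.int64)
        b_bg = np.stack([starts, starts + w], axis=1)
    b_all = np.vstack([b_nested, b_bg]) if len(b_nested) else b_bg
    order = np.argsort(b_all[:, 0]) if len(b_all) else np.array([], dtype=int)
    b_all = b_all[order]

    peaks_a = PeakSet("tf_a", pd.DataFrame({"chrom": CHROM, "start": a_starts, "end": a_starts + w}))
    peaks_b = PeakSet("tf_b", pd.DataFrame({"chrom": CHROM, "start": b_all[:, 0], "end": b_all[:, 1]}))

    # partition spans (B-only peaks are entirely outside A; nested peaks entirely inside)
    span_c = n_co * (w // 2)
    span_a = n * w - span_c
    span_b = n_bg_b * w
    total = span_a + span_b + span_c
    fold = config.snp_enrichment_fold
    if span_c > 0 and fold * span_c > total:
        raise ValueError(
            f"snp_enrichment_fold={fold} too large for this landscape "
            f"(common span {span_c} of {total} partitioned bp)"
        )
    if span_c > 0:
        p_c = fold * span_c / total
        q = (total - fold * span_c) / (span_a + span_b)
        probs = np.array([q * span_a, span_b * q, p_c * total]) / total  # unique_a, unique_b, common
    else:
        probs = np.array([span_a, span_b, 0.0]) / total

    p_in = 0.6  # fraction of SNPs landing in any binding-site partition
    n_snps = config.n_gwas_snps
    dest = rng.choice(4, size=n_snps, p=[p_in * probs[0], p_in * probs[1], p_in * probs[2], 1 - p_in])

    # interval inventories per destination
    ua = np.stack([a_starts, a_starts + w], axis=1).astype(np.int64)  # minus nested cores, handled below
    pos = np.empty(n_snps, dtype=np.int64)
    nested_by_host = {int(a_starts[i]): (int(a_starts[i] + w // 4), int(a_starts[i] + w // 4 + w // 2)) for i in co_idx}

    def _uniform_in(intervals: np.ndarray, k: int) -> np.ndarray:
        lens = intervals[:, 1] - intervals[:, 0]
        cum = np.cumsum(lens)
        u = rng.integers(0, cum[-1], size=k)
        which = np.searchsorted(cum, u, side="right")
        off = u - (cum[which] - lens[which])
        return intervals[which, 0] + off

    # unique_a = A bases minus nested cores
    ua_parts = []
    co_set = set(int(i) for i in co_idx)
    for i in range(n):
        s = int(a_starts[i])
        if i in co_set:
            cs, ce = nested_by_host[s]
            ua_parts.append((s, cs))
            ua_parts.append((ce, s + w))
        else:
            ua_parts.append((s, s + w))
    ua_arr = np.array(ua_parts, dtype=np.int64)
    ub_arr = b_bg.astype(np.int64) if len(b_bg) else np.empty((0, 2), dtype=np.int64)
    cc_arr = b_nested.astype(np.int64) if len(b_nested) else np.empty((0, 2), dtype=np.int64)

    for code, arr in ((0, ua_arr), (1, ub_arr), (2, cc_arr)):
        k = int((dest == code).sum())
        if k == 0:
            continue
        if len(arr) == 0:
            # destination has zero span; respread into background
            dest[dest == code] = 3
            continue
        pos[dest == code] = _uniform_in(arr, k)

    k_bg = int((dest == 3).sum())
    if k_bg:
        # rejection-sample background positions (outside A and B)
        all_iv = np.vstack([np.stack([a_starts, a_starts + w], axis=1), b_all]) if len(b_all) else np.stack([a_starts, a_starts + w], axis=1)
        all_iv = all_iv[np.argsort(all_iv[:, 0])]
        got: list[int] = []
        while len(got) < k_bg:
            cand = rng.integers(0, G, size=2 * k_bg)
            j = np.searchsorted(all_iv[:, 0], cand, side="right")
            inside = (j > 0) & (cand < all_iv[np.maximum(j - 1, 0), 1])
            got.extend(int(c) for c in cand[~inside][: k_bg - len(got)])
        pos[dest == 3] = np.array(got[:k_bg])

    gwas = pd.DataFrame(
        {
            "rsid": [f"gwas{i + 1}" for i in range(n_snps)],
            "chrom": CHROM,
            "pos_1based": pos + 1,
            "ref": "A",
            "alt": "G",
        }
    ).sort_values("pos_1based", kind="stable").reset_index(drop=True)
    return peaks_a, peaks_b, gwas


# -- survival ----------------------------------------------------------------

def simulate_survival(scores: pd.Series, config: SimulationConfig) -> pd.DataFrame:
    """Exponential survival times (months) with hazard tied to a score.

    The per-sample hazard is ``lambda0 * exp(surv_lnHR * z)`` where ``z`` is
    the standardized score and ``lambda0`` gives a baseline median of
    ``baseline_median_months``. Censoring is independent Uniform(0, T_max)
    with ``T_max`` solved numerically so the expected censoring fraction
    matches ``censor_rate``.
    """
    scores = pd.Series(scores).astype(float)
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("simulate_survival: scores must be finite")
    rng = _rng(config, 3)
    z = scores.to_numpy()
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
    lam0 = math.log(2) / config.baseline_median_months
    lam = lam0 * np.exp(config.surv_lnHR * z)
    t_event = rng.exponential(1.0 / lam)

    if config.censor_rate <= 0:
        time, event = t_event, np.ones_like(t_event, dtype=int)
    else:
        def cens_frac(tmax: float) -> float:
            return float(np.mean(np.minimum(t_event, tmax) / tmax)) - config.censor_rate

        hi = float(t_event.max()) * 2
        lo = float(np.quantile(t_event, 0.001)) * 1e-3 + 1e-9
        # cens_frac decreases from ~1 at tmax->0 to ->0 as tmax grows
        while cens_frac(hi) > 0:
            hi *= 2
        tmax = brentq(cens_frac, lo, hi)
        c = rng.uniform(0.0, tmax, size=len(t_event))
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)

    out = pd.DataFrame(
        {"time": time, "event": event, "score": scores.to_numpy()}, index=scores.index
    )
    out.index.name = "sample"
    return out
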