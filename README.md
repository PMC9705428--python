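# regulink

Germline–somatic regulatory integration toolkit for cancer genomics.

GWAS risk loci for prostate (and other) cancers are mostly non-coding, and
their effects are often mediated by transcription factors whose activity
depends on somatic events — classically the TMPRSS2–ERG fusion, which puts
the ERG transcription factor under androgen-responsive control. `regulink`
provides the statistical machinery to chase such a locus from end to end:

- **Locus enrichment** — is a gene class (e.g. transcription factors)
  over-represented among genes near risk variants? One-sided hypergeometric
  tail P(X ≥ k | N, K, n) and two-sided Fisher exact on the 2×2 table, with
  fold (k/n)/(K/N).
- **Stratified cis-eQTL mapping** — additive OLS `e = a + b·g + ε` per
  SNP–gene pair within ±1 Mb of the TSS, fitted per clinical stratum
  (fusion-positive / fusion-negative) and pooled, after call-rate ≥ 90%,
  MAF ≥ 0.01 and HWE p ≥ 0.05 genotype QC.
- **Peak algebra** — BED I/O, union-merge, base-pair partition of two
  factors' binding sites into unique-A / common / unique-B, peak-level
  co-occupancy (≥ 1 bp overlap), nearest-TSS annotation, and a simplified
  PWM allele-delta score for candidate regulatory SNPs.
- **SNP enrichment** — LD expansion of tag SNPs at r² ≥ 0.8, then
  chi-squared enrichment of SNP counts across binding-site partitions
  against span-proportional expectation (optional permutation null), eGene
  lookup, and case–control allelic association.
- **Signatures** — gene panels from set intersections (top pathways ∩
  up-regulated genes; up-regulated ∩ peak-target genes; top-k co-expression),
  scored per sample as the z-score sum Σ_g w_g (x_g − μ_g)/σ_g.
- **Survival** — Kaplan–Meier, log-rank, Cox proportional hazards (Newton on
  the partial likelihood, Breslow/Efron ties), median stratification, and
  fixed-effect inverse-variance meta-analysis of log hazard ratios with
  Cochran Q / I².
- **Assay quantification** — qPCR standard curves, 3C crosslinking
  frequencies 10^((Ct−intercept)/slope) normalized to a loading control,
  ΔΔCt fold changes 2^(−ΔΔCt), dual-luciferase firefly/renilla ratios.
- **Synthetic cohorts** — a generator that plants every signal above
  (LD-block genotypes with controllable r², fusion-conditional eQTL effects,
  a co-regulated partner gene, peak sets with controllable co-occupancy and
  SNP enrichment, score-dependent survival), so the whole pipeline runs and
  is tested without any external data.

## Worked example

```python
import regulink as rl

cfg = rl.SimulationConfig(n_samples=400, seed=7)
geno, variants, ld = rl.simulate_genotypes(cfg)
geno_qc, report = rl.qc_genotypes(geno)
expr, clinical = rl.simulate_expression_cohort(geno_qc, cfg)

res = rl.stratified_eqtl(geno_qc, expr, clinical, "fusion",
                         pairs=[(rl.EQTL_SNP, rl.TARGET_GENE)])
print(res[["stratum", "n", "beta", "se", "p"]].round(4))
```

```
 stratum   n   beta     se      p
negative 237 0.0269 0.0932 0.7734
positive 163 1.0145 0.1305 0.0000
  pooled 400 0.4162 0.0821 0.0000
```

The generator planted an eQTL effect of 1 expression unit per allele that is
active only in fusion-positive samples: the fusion-positive stratum recovers
β ≈ 1.01 at vanishing p, the fusion-negative stratum is null (β ≈ 0.03,
p = 0.77), and the pooled fit dilutes the effect — the signature pattern of a
fusion-conditional eQTL.

Continuing downstream — derive a co-expression panel, score samples, and ask
whether the score predicts survival:

```python
pos = clinical.index[clinical.fusion == "positive"]
ranked = rl.coexpression_rank(expr[pos], rl.TARGET_GENE)
panel = rl.derive_coexpression_panel(ranked, k=25)
scores = rl.score_signature(expr, panel)

surv = rl.simulate_survival(scores.scores, cfg)
strat = rl.median_stratify(scores.scores)
print(rl.logrank_test(surv.assign(group=strat.labels), "group"))
print(rl.cox_fit(surv, ["score"]).summary.round(4))
```

```
log-rank chi2=76.78 p=1.91e-18
             lnHR      se        z    p      HR  ci95_low  ci95_high
score      0.1289  0.0114  11.2888  0.0  1.1375    1.1124     1.1633
```

The per-unit-score hazard ratio of 1.14 corresponds to the planted log
hazard of 0.7 per standard deviation of the score (the 25-gene z-score sum
has an SD of about 5.4 here).

The same analyses are scriptable from a shell — `regulink simulate`,
`regulink eqtl`, `regulink peaks partition|cooccupancy|annotate`,
`regulink snp-enrich`, `regulink signature score`, `regulink survival
km|logrank|cox|meta`, `regulink assay 3c|ddct|luciferase` — and
`regulink run --config cfg.yaml --out DIR` chains them end to end from one
YAML config (see `configs/demo.yaml`).

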