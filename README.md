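# ctnorm

Normalization and normalizer (reference-gene) selection for high-throughput
RT-qPCR miRNA expression data with non-determined values.

## The problem

High-throughput RT-qPCR arrays profile hundreds of miRNA assays per sample
as cycle-threshold (Ct) values — log2-scale abundance readouts in which one
cycle corresponds to a two-fold change, higher Ct meaning less RNA.
Biofluid samples (serum, plasma) carry so little RNA that input amounts
cannot be equalized in advance, so samples arrive with large, unknown
per-sample Ct offsets, and a substantial fraction of reactions never
crosses the detection threshold within the run: these cells are
**non-determined (ND)** — right-censored at the detection cap, Ct > 40 —
not missing at random. Ordinary whole-array normalization (mean-centering,
quantile, MAD-scaling) is biased precisely in this regime, because the
per-sample statistics it relies on are distorted sample-by-sample as the
censoring pattern changes.

`ctnorm` implements two restricted-set strategies plus the standard
comparators and the metrics to benchmark them:

- **MCR (mean-centering restricted)** — per-sample subtraction of the mean
  Ct of the *restricted set*, the assays detected (Ct strictly below the
  threshold) in **every** sample. Writing the measurement model as
  `Ct[i,j] = mu_i + t_j + e[i,j]` with a per-sample technical shift `t_j`,
  the restricted mean in sample j is `mean_i(mu_i) + t_j + noise`, so the
  subtraction removes `t_j` exactly — no censored cell ever contaminates
  the estimate.
- **CCR (concordance correlation restricted)** — greedy forward selection
  of normalizer assays whose averaged Ct maximizes Lin's concordance
  correlation coefficient with the restricted sample means,

      rho_c = 2*s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2),

  with a Fisher-z confidence interval. Unlike Pearson's r, rho_c penalizes
  location and scale shifts, so selected assays *track* the mean expression
  level — what a reference assay must do when a multiplex signature is
  migrated to singleplex RT-qPCR. Selection stops when the concordance gain
  drops below a convergence threshold (default 0.01), or at a fixed count.
- Comparators: whole-array mean-centering (MC), median/MAD scale
  normalization, quantile normalization, delta-Ct against chosen genes, and
  the **geNorm** (pairwise M value) and **NormFinder** (model-based
  intra/intergroup variance decomposition) stability rankings.
- Evaluation: within-origin-group per-gene SD of normalized values
  (technical variance), and the eigenvalue-weighted percent of variance
  explained by sample origin from one-way random-effects fits to the
  leading principal components (biological signal).
- A synthetic titration-series simulator (serial dilutions with
  `log2(dilution factor)` Ct spacing, origin-specific expression, high-Ct
  noise inflation, censoring at Ct 40) so the whole workflow is testable
  end to end with known ground truth.

## Worked example

```python
from ctnorm import (SimulationConfig, simulate_titration, mcr_normalize,
                    mean_center, per_mirna_sd, variance_pca, ccr_select,
                    DetectionConfig)

# three-origin titration study: brain & placenta at 6 ten-fold dilutions,
# serum at 5; 377 assays, censoring at Ct 40
matrix, annotations, truth = simulate_titration(SimulationConfig(seed=42))
print(matrix.shape)                      # (377, 17)

result = mcr_normalize(matrix)           # restricted set has 109 genes here
sd_mcr = per_mirna_sd(result, annotations).mean_sd_all.mean()
sd_mc = per_mirna_sd(mean_center(matrix), annotations).mean_sd_all.mean()
print(round(sd_mcr, 3), round(sd_mc, 3))           # 0.505  0.832

print(round(variance_pca(result, annotations).weighted_percent, 1))   # 61.9

# normalizer selection on a single biofluid series, Ct < 35 detection
serum, _, _ = simulate_titration(
    SimulationConfig(origins=[("serum", 5, 1)], seed=42))
sel = ccr_select(serum, DetectionConfig(35.0))
print(sel.normalizers, sel.stop_reason)  # ['miR-sim-332'] converged
```

About 21% of the simulated reactions are censored, concentrated in the
high-dilution samples. After MCR the mean within-group per-gene SD is 0.51
cycles versus 0.83 for whole-array mean-centering — the censored cells drag
MC's per-sample means differently in each sample. The variance-PCA summary
rises from 4.7% (unnormalized, where dilution shifts dominate the leading
components) to 61.9% after MCR: removing the technical shifts exposes the
origin differences. CCR converges on a single normalizer whose Ct profile
has concordance 0.999 with the restricted sample means.

The same workflow is available from the shell:

```bash
ctnorm simulate --genes 377 --origins brain:6:1,placenta:6:1,serum:5:1 \
    --seed 42 --out sim
ctnorm normalize --method mcr --in sim_ct.csv --out sim_mcr.csv
ctnorm select --method ccr --threshold 35 --in sim_ct.csv --out sim_ccr.tsv
ctnorm evaluate --metric vpca --in sim_mcr.csv --groups sim_annotation.csv \
    --out sim_vpca.tsv
```

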