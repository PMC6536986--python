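# concordx

Cross-platform expression concordance and technical-reproducibility analysis
for targeted RNA panels measured on a digital molecular-counting assay
(nCounter-style "count platform") and a hybridization microarray ("array
platform").

Analytical validation of a custom biomarker panel asks two questions before
any clinical claim: (1) is the assay *reproducible* — do technical
replicates prepared in different labs, on different days, by different
operators agree? and (2) is it *concordant* — do expression **changes**
measured on one platform agree with those measured on another, given that
absolute intensities are known to diverge between technologies?  `concordx`
implements the full analysis chain for a 346-probe breast-cancer panel
study design (10 FFPE tumor cases × 2 labs × 3 days = 60 samples; 325
endogenous + 7 housekeeping + 6 positive + 8 negative probes), together
with a synthetic dual-platform data generator that plants a complete ground
truth so every statistic is testable.

## What it computes

* **Lane QC + normalization** (count platform): imaging ratio, binding
  density, positive-control linearity (R²), limit of detection; then
  positive-control geometric-mean scaling → negative-control mean + 2 sd
  background subtraction → housekeeping geometric-mean scaling.
* **Array QC** (probe level): scale factor, 3′/5′ ratios of control genes,
  RNA-degradation slope.
* **Reproducibility**: boxplot-style outlier flagging, pairwise Pearson
  heatmaps, between-lab pooled correlation, intra-/inter-assay %CV gates
  (<10% / <15%), PCA, correlation-distance hierarchical clustering, and a
  per-gene two-way ANOVA comparing case mean squares with residual mean
  squares.
* **Concordance**: gene-to-probe-set mapping, within- vs between-platform
  sample correlation, ratio-of-means log2 fold changes
  (`log2FC = log2((mean_A + 0.5)/(mean_B + 0.5))`), expression-tertile
  stratified fold-change correlation, the 2-fold concordance tiers
  (within 2-fold / concordant change / discordant), the OLS residual-band
  classifier (|residual| ≤ 1.96·σ̂), and a sample-pooling curve.

## Worked example

```python
import concordx as cx
from concordx import nanostring as ns, concordance as cc

ds = cx.simulate_dataset(cx.SimulationConfig(), seed=1)   # 60 lanes, 346 probes
qc = ns.qc_lanes(ds.lanes, ds.panel)
print(qc.index[~qc["pass"]].tolist())
# ['TNB4-Lab2-D2', 'ER5-Lab2-D2']        <- the two degraded low-input lanes

kept = qc.index[qc["pass"]].tolist()
norm, factors = ns.normalize_chain(ds.count_raw, ds.panel)
gmap = cc.build_gene_map(ds.panel, ds.array_annotation, ds.array_norm)
fc = cc.fold_change_table(norm.subset_samples(kept),
                          ds.array_norm.subset_samples(kept),
                          ds.design.subset(kept), gmap)
print(cc.stratified_fc_correlation(fc))
# {'overall': 0.7555, 'low': 0.6334, 'medium': 0.8505, 'high': 0.7238}

tiers, summary = cc.classify_twofold(fc)
print(summary)
# {'n_genes': 332, 'n_within2fold': 172, 'n_concordant_change': 145,
#  'n_discordant': 15, 'concordant_fraction': 0.9548...}
```

The two flagged lanes are exactly the planted degraded samples; the
fold-change correlation is moderate (~0.76) even though the absolute
between-platform sample correlation is poor (~0.50), because independent
per-probe affinities and the array's compressive response distort levels
but largely preserve changes; and ~95% of mapped genes are concordant, with
the discordant tier recovering the planted opposite-direction genes
(15 of 16 at this seed, no false calls).

## Command line

```bash
concordx simulate --seed 1 --out data/          # RCC-lite files, TSVs, truth JSON
concordx normalize --rcc-dir data/rcc --panel data/panel.csv \
    --out norm.tsv --qc-report qc.csv
concordx array-qc --probe-matrix data/array_probe_level.tsv \
    --positions data/probe_positions.csv --out array_qc.csv
concordx run --config run.yaml --out report/    # full pipeline + manifest
concordx report --report-dir report/            # figures from the stage tables
```

`concordx run` accepts a YAML config whose sections mirror the defaults in
`concordx.pipeline.DEFAULT_CONFIG` (`seed`, `simulate` with any
`SimulationConfig` field, `normalize.background_method`,
`reproducibility.outlier_k`, `concordance.{z,threshold_log2,pool_sizes,
n_resamples}`, `keep_qc_failures`, and an `inputs` section for running on
externally supplied files instead of simulating).

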