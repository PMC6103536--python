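# prism-atac

Cell-to-cell variability of chromatin accessibility from binarized
scATAC-seq data.

Single-cell ATAC-seq measures which regulatory elements are open in each
cell, but the signal is sparse, binary, and high-dimensional. A question
aggregate methods miss is whether cells differ in *which* regions they
open even when their total accessibility is comparable: two cells can
carry the same number of open sites at completely different elements.
`prism-atac` scores exactly that kind of heterogeneity for any peak set
unified by an annotation — the ChIP-seq binding sites of a transcription
factor, motif matches, enhancer catalogs — and calibrates the score
against matched genomic backgrounds so that technical covariates (GC
content, mean accessibility) and the choice of peak set size cancel out.

## Method

Each cell *c* is a binary vector **x**<sub>c</sub> over the peaks of
interest (1 = accessible). The dissimilarity between two cells is the
angular cosine distance

d(**a**, **b**) = arccos( **a**·**b** / (‖**a**‖‖**b**‖) ) / (π/2) ∈ [0, 1],

0 for cells open at the same sites and 1 for cells whose open sites are
disjoint. The pairwise distance matrix is embedded by classical
multidimensional scaling (PCoA, Gower double-centering of squared
distances), and the **raw variability** is the mean Euclidean distance of
cells from their centroid — the typical deviation from the group norm.

Two resampling stages normalize the raw value:

1. **Bias correction.** Background peak sets of equal size — matched
   peak-for-peak on GC content, with overall mean accessibility within
   ±0.01 of the feature set's — are drawn repeatedly (default 30×) from
   non-feature peaks; `bias_corrected = raw / mean(background raws)`.
2. **Negative-control normalization.** Random non-feature peak sets of
   equal size are each bias-corrected the same way (default 30×);
   `final = bias_corrected / mean(control values)`, with a Z-score and an
   empirical p-value from the control distribution.

`final = 1` means the feature carries no more cell-to-cell variation than
a random peak set; above 1, more; below 1, suppressed variation.

A built-in benchmark titrates synthetic heterogeneity by mixing an
original peak block with a GC-matched block across cells at 50
proportions; a correct estimator traces a concave ("inverse-U") curve,
summarized by a concavity U statistic (Spearman correlation of successive
curve differences with a decreasing sequence; 1 = perfectly concave) and
the mean squared residual around a LOESS fit (estimator noise).

## Worked example

```bash
python examples/01_score_feature_variability.py
```

builds a 120-cell × 800-peak synthetic universe in which one 80-peak
block is genuinely heterogeneous (the two halves of the cells open
disjoint sub-blocks, total accessibility held constant) and one block is
a plain null draw, then scores both:

```
 heterogeneous: raw=0.6052  bias_corrected=1.0656  final=1.0687  z=+8.32  p=0.0323
          null: raw=0.5572  bias_corrected=0.9930  final=0.9885  z=-1.05  p=0.8710
```

The heterogeneous block scores above every one of the 30 negative
controls (p = 1/31, the smallest value 30 controls can give), while the
null block is control-like (final ≈ 1). `examples/02_titration_benchmark.py`
runs the benchmark (U = 0.932, LOESS MSE = 4.6 × 10⁻⁷, curve maximum at a
52 % mixture on its default seed), and `examples/03_annotate_and_map.py`
shows GC annotation and feature-to-peak mapping.

The same stages are available from the shell on matrix-market + BED +
barcode bundles:

```bash
prism annotate    --matrix m.mtx --peaks peaks.bed --barcodes bc.txt \
                  --genome genome.fa --out annotated.tsv
prism variability --matrix m.mtx --peaks annotated.tsv --barcodes bc.txt \
                  --feature ctcf.bed --seed 1 --out results.tsv
prism simulate    --fixture --model 1 --subtype A --out curve.tsv
```

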