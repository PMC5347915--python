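# polyprof

Analysis toolkit for polysome-profiling time courses: from paired
total/polysomal expression matrices to polysome-occupancy shift calls,
regulatory-mode classification, and the sequence, structure and motif
features that correlate with translational control.

## The problem

Steady-state mRNA levels are a poor proxy for protein output. Polysome
profiling separates mRNAs by ribosome load on a sucrose gradient and
quantifies, for each gene, both the total mRNA pool (T) and the
polysome-associated pool (P). The **polysome occupancy**

```
PO_g = log2 P_g − log2 T_g
```

is a per-gene proxy for translational efficiency. Comparing PO between
consecutive stages of a developmental time course (here: a
seed-germination-style design with time points 0, 6, 26, 48 and 72 hours
after the start of imbibition, two RNA fractions and three replicates)
identifies *translational shifts* — intervals where the occupancy of many
mRNAs changes — and classifies each shifted gene by whether transcription
(T±), translation (P±), both (T±/P±), sub-threshold additive effects, or
opposing changes drive the shift.

Differential calls use the empirical-Bayes moderated t-statistic: per-gene
variances s²_g (d_g residual df) are shrunk toward a prior s₀² with d₀ df
estimated by a method of moments on the log-variances,

```
s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),    t̃_g = β̂_g / (u_g·s̃_g)  with d₀+d_g df,
```

followed by Benjamini–Hochberg adjustment and a strict call rule
(|log2 FC| > 1 and adjusted p < 0.05). Downstream modules compute GC3 and
the effective number of codons (Nc, pseudocount estimator: per synonymous
family, F = Σᵢ((nᵢ+1)/(n+m))², Nc = Σ 1/F, so Nc ∈ [20, 61] with 61 at
uniform usage), detect upstream ORFs, build 100-bin metagene profiles of
per-nucleotide structure scores, scan PWMs with exact DP p-values
(FIMO-style, hits at p ≤ 0.001), and quantify gradient absorbance traces
(blank-subtracted area, polysome loading) and spike-normalized qPCR rRNA
ratios. A synthetic-data module generates every input with ground truth.

## Worked example

```python
from polyprof import simulate, expression, occupancy

cfg = simulate.SimulationConfig(seed=42)          # default 20,000-gene design
matrix, truth = simulate.simulate_expression(cfg)
kept = expression.noise_filter(matrix).kept       # log2 intensity > 4 rule
po = occupancy.compute_polysome_occupancy(matrix.subset(kept))
print(occupancy.detect_shifts(po).summary)
```

prints

```
            up  down
interval
PO 0->6    448  1115
PO 6->26     0     0
PO 26->48  200   666
PO 48->72    0     0
```

i.e. the planted translational effects (450 up / 1200 down at the first
interval, 200 up / 700 down at the third) are recovered almost completely,
and the quiescent intervals stay quiet — the two-shift temporal structure
the design encodes. `occupancy.classify_regulatory_mode` then labels each
significant gene; `occupancy.pca_variance(po)` reports ≈27% and ≈14% of PO
variance on the first two components for this design.

The same operations are available from the shell:

```
polyprof simulate --seed 42 --outdir data/
polyprof shifts --matrix data/matrix.tsv --meta data/samples.tsv --outdir shifts/
polyprof gradient --trace data/trace.tsv --blank data/blank.tsv --boundary 2.8
```

## Layout

| module | contents |
| --- | --- |
| `polyprof.stats` | BH/Hochberg step-up adjustments, one-tailed Fisher, χ² over-representation, Mann–Whitney, moderated t |
| `polyprof.expression` | matrix + design metadata loading, noise filter, replicate QC |
| `polyprof.occupancy` | PO computation, shift detection, regulatory modes, gene-set ORA, PCA |
| `polyprof.seqfeatures` | region lengths/GC, GC3, Nc, uORFs, feature-distribution comparisons |
| `polyprof.structure` | proportional-overlap 100-bin metagene profiles, region-mean t-tests |
| `polyprof.motifs` | MEME minimal I/O, exact-p PWM scanning, enrichment, positional density |
| `polyprof.gradients` | trace baseline subtraction, polysome loading, spike-normalized qPCR |
| `polyprof.simulate` | ground-truthed generators for every input above |
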