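# Methods

This note documents the statistical models, the defaults and the design
choices behind `polyprof`, and what the synthetic-data generators do and
do not emulate.

## Differential calling and the moderated t

Each contrast (total mRNA, polysomal mRNA, or polysome occupancy between
two time points) is a two-group comparison with ≥ 2 replicates per group.
Per gene we compute the mean difference β̂_g (log2 scale), the pooled
residual variance s²_g with d_g = n_a + n_b − 2 df, and the unscaled
standard error u_g = √(1/n_a + 1/n_b).

The variance prior (s₀², d₀) is fitted by the method of moments on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of var(e) over the
expected sampling variance mean ψ′(d_g/2) is inverted through
ψ′(d₀/2) = excess by Newton iteration (start 0.5 + 1/x, tolerance 1e-8 on
the relative step, ≤ 50 iterations). Three regimes:

- excess > 0: finite d₀, s₀² = exp(mean e + ψ(d₀/2) − log(d₀/2));
- excess ≤ 0 with spread in the log-variances: d₀ = ∞ with the debiased
  location s₀² = exp(mean e) — this keeps null p-values uniform (the
  geometric mean of sample variances would be biased low by Jensen);
- all sample variances numerically identical: the variances are not noisy
  draws, so the prior is pinned at the common value and the moderated t
  coincides with the ordinary statistic.

Posterior variances s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) give moderated t
with d₀+d_g df (normal when d₀ = ∞). `d0=0` disables pooling entirely.
No intensity-dependent trend is fitted: the artifact targets two-group
contrasts on normalized log2 intensities, where a constant prior is the
standard choice, and trend fitting would add a dependency on the
intensity covariate that none of the consumers of this module need.

Calls use strict inequalities: up ⇔ log2 FC > 1 **and** BH-adjusted
p < 0.05 (a gene at exactly FC = 1 is not called). The multiple-testing
family is all noise-filtered genes within one contrast.

## Polysome occupancy

PO is computed per replicate *pair* (total and polysomal replicates
matched by replicate index), not from condition means: pairing preserves
replication so the PO contrast is a proper moderated test on three
independent PO values per condition. Testing PO differences directly is
equivalent to testing the fraction × time interaction. Replicates missing
their fraction partner are dropped with a warning.

Regulatory modes for genes with a significant PO change over an interval:

| dT | dP | consistency | mode |
| --- | --- | --- | --- |
| ns | ns | — | additive (two sub-threshold effects) |
| ns | sig, sign = sign(dPO) | — | P+ / P− |
| sig, sign = −sign(dPO) | ns | — | T+ / T− (ratio moved by the denominator) |
| sig | sig | same sign as dPO | T+/P+ / T−/P− |
| any other significant combination | | | opposite |

Finer subgrouping is available as the emitted `label`
(interval × direction × mode). The classification partitions the
significant-PO genes: every such gene receives exactly one mode.

## Noise filter

A gene is kept iff there is at least one (time point, fraction) condition
in which **every** replicate exceeds log2 intensity 4 (strict). This
replicate-consistent rule is the default because it defines the analysis
set; the looser "any sample > 4" variant is available via
`rule="any_sample"`. The filter is applied jointly across both fractions
(a gene reliably detected in either fraction is analysable in the PO
ratio). Raising the threshold can only remove genes, and the result is
independent of column order.

## Codon-usage bias

Nc uses a pseudocount homozygosity estimator: per synonymous family with
m codons and counts nᵢ (n = Σnᵢ), F = Σᵢ((nᵢ+1)/(n+m))² and
Nc = Σ_families 1/F over the 20 standard families (terminal stop
excluded; Met and Trp contribute exactly 1). Algebraically 1/m ≤ F ≤ 1,
so Nc ∈ [20, 61] always, with Nc = 61 exactly when within-family counts
are equal — including the all-zero families of a short CDS. The three
6-fold amino acids are treated as single 6-codon families by default;
`split_sixfold=True` separates them into 2+4 subfamilies (conventions
vary in the literature). The classic Wright-style estimator
(F̂ = (nΣp̂²−1)/(n−1) with degeneracy-class averaging) is provided for
comparison. Eligibility requires an ATG start, no premature stop, and
≥ 100 codons.

GC3 includes the start codon (its third base is invariant, a negligible
constant) and excludes the terminal stop, whose third base is constrained
by termination rather than synonymous choice; both choices are flags.

## uORFs

A uORF is an ATG in the 5′UTR with an in-frame stop codon downstream in
the transcript, length ≥ 2 codons including the stop. Overlap with the
main CDS is allowed by default (`allow_cds_overlap=False` confines the
whole uORF to the 5′UTR, making the count independent of downstream
sequence). Within one reading frame the first ATG wins: ATGs nested
inside an already-counted uORF do not start another. These defaults are
documented package choices — published uORF catalogues use a variety of
thresholds — and the synthetic generator uses the same definition, so
truth and detection agree exactly.

## Metagene structure profiles

Per-nucleotide structure scores (higher = more double-stranded) are
rescaled per region to 100 bins by proportional overlap: nucleotide i of
a length-L region occupies [i/L, (i+1)/L) and contributes to each bin in
proportion to the overlap. Every bin then carries weight L/100, so the
plain mean of bin values equals the region mean exactly (conservation is
tested to 1e-9) and a length-100 region maps to itself; regions shorter
than 100 nt spread each nucleotide over several bins rather than leaving
gaps. Averaging is two-stage — bin within transcript, then across
transcripts — so the reported SE reflects between-transcript variation.
Transcripts lacking scores or lacking the region are excluded from that
region's profile only. Region-mean comparisons use per-transcript means
as the unit of analysis with a pooled-variance Student's t (Welch flag
available).

## Motif scanning

Scanning is sense-strand only (the sequences are mRNAs). The window score
is the log2 odds Σⱼ log2(p/b) with pseudocount 1e-4 added to the motif
probabilities, against a 0-order background. P-values are exact: scores
are discretized to 1/1000 bit and the null distribution of a
background-generated w-mer is built by dynamic programming
(position-by-position convolution), so the reported p equals the
enumeration over all 4^w words at that granularity. Hits are windows with
p ≤ 0.001 (per-window, no length correction). Enrichment counts genes
with ≥ 1 hit by default (a gene-level unit is robust to repeat-driven
multiple hits); hit-level counting against scannable-window totals is
available. Positional density places each hit at its midpoint relative
position and normalizes over 100 bins.

## Gradient traces and qPCR

Blank-gradient baselines are interpolated onto the trace grid and
subtracted; integration is trapezoidal on the native grid with no
resampling. Total corrected area proxies ribosome abundance; polysome
loading is the area beyond the monosome/polysome boundary divided by the
total. The boundary is supplied by the analyst (it is usually placed by
inspection); `detect_boundary` offers a reproducible stand-in (first
local minimum after the global 80S peak). Loading is monotone
non-increasing in the boundary position.

qPCR quantities are Q = E^(−Cq) with per-target amplification efficiency
E ∈ (1, 2] (default 2.0 with a warning when absent — efficiency
estimation is upstream of this package), normalized to the geometric mean
of the spike-in quantities; rRNA-type fractions are the normalized
non-spike quantities rescaled to sum to 1, which makes them invariant to
global rescaling of the spikes.

## Synthetic data: what it emulates and what it does not

Defaults mirror a germination-style design: time points {0, 6, 26, 48,
72} h, fractions {total, polysomal}, 3 replicates, 20,000 genes, baseline
log2 intensity N(7, 1.5²), homoscedastic replicate noise sd 0.25 (an
inverse-gamma per-gene variance option exercises the variance
moderation). Planted effects are step changes confined to the two
transition intervals — translational sets of 1200 down / 450 up
(hydration) and 700 down / 200 up (germination) at |log2| = 1.5 on the
polysomal fraction only, plus transcriptional sets (both fractions,
|log2| = 2.0) that leave PO unchanged. Set sizes echo the scale reported
for germination translatomes; the effect size 1.5 is mid-range between
the 2-fold call threshold and the large (|log2 FC| ≈ 2–3) exemplar genes
such studies report.

Transcriptomes: UTR lengths gamma-distributed around 130/230 nt, CDS
around 400 codons, UTR GC 0.36 — typical plant-transcriptome magnitudes.
CDSs are valid by construction; codon choice is quota-balanced within
synonymous families so the bias dial maps cleanly to Nc (≈ 61 at 0,
→ 20 for long CDSs at 1), with the G/C-ending codon preferred so bias
correlates with GC3 as optimal-codon usage does. 5′UTRs are scrubbed of
incidental ATGs so the true uORF count equals exactly what the scanner
finds; motif instances are planted verbatim near a configurable relative
position (default 0.8, i.e. close to the start codon).

Structure tracks are region-mean constants with Gaussian dips (depth 0.4,
sd 12 nt) at the CDS start and stop plus N(0, 0.1) noise. Gradient traces
are sums of Gaussian peaks (40S/60S/80S + a decaying polysome series) on
a linear baseline; the true loading is the analytic polysome-peak mass
fraction, so boundary-tail leakage bounds recovery error at well under
0.02 for the default geometry.

Not emulated: probe-level microarray effects and normalization artifacts,
intensity-dependent variance trends, correlated replicate structure,
partial structure-score coverage, isoform mixtures, and sequencing-read
noise. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not robustness to every artifact
of real array data.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the expression pipeline at
the full default 20,000-gene design (seconds of CPU); transcriptome,
structure and motif stages use 25–400 transcripts, which is ample for the
planted-signal checks while keeping the suite quick. Ties in rank tests
use midranks with the variance tie correction; Mann–Whitney switches from
the exact to the normal null at min(n, m) > 8 or in the presence of ties.
The χ² over-representation test applies no continuity correction by
default (flag available) and refuses tables with a zero expected cell,
pointing to the exact Fisher test instead. Degenerate inputs raise
(constant PCA matrix, zero-area traces, empty gene sets) rather than
returning NaN silently.
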