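# Methods

## Data model and transforms

A `CtTable` holds quantification-cycle values (genes × samples), a sample
design (condition group, biological replicate), and optionally a technical
replicate dimension. Cq values must lie in (0, 45] cycles — a 40-cycle
protocol plus margin; the bound is configurable. Technical replicates are
averaged on the Cq scale (the instrument-software convention), ignoring
missing wells; a mean or a median is available.

Relative quantities are q[g,s] = A_g^(−(Cq[g,s] − b_g)) with per-gene
amplification factor A_g (2 unless a measured efficiency is supplied;
A = 1 + E/100) and per-gene baseline b_g. The baseline defaults to the
gene's minimum Cq — the geNorm/qBASE convention, under which each gene's
largest quantity is exactly 1 — with a mean-Cq option. The choice is
immaterial to every stability statistic here (all are ratio- or
dispersion-based and invariant to per-gene constants); it only changes the
scale on which quantities are reported.

Missing Cq propagates as missing. Pairwise statistics (geNorm V, ΔCt pairs,
BestKeeper correlations) use pairwise-complete samples; the model-based
method requires complete cases and records which samples were dropped.

Standard-curve efficiency is an ordinary least-squares fit of Cq on
log10(input amount) over ≥3 distinct dilutions; E% = (10^(−1/slope) − 1)·100,
with R² the squared Pearson correlation. Non-negative slopes are rejected.

## geNorm

V_jk = SD over samples (n−1 denominator) of log2(q_j/q_k); M_j = mean of
V_jk over partners. Log base 2 is used throughout — any base scales all M
proportionally, and base 2 matches the 2^(−ΔCq) input convention. Ranking
is stepwise: recompute M over the remaining subset, drop the highest-M gene,
stop at two. Exact M ties drop the gene later in input order (deterministic,
recorded in the result's tie log). The final pair is algebraically tied —
each member's M is their single mutual V, computed once so the tie is exact
in floating point — and both receive rank 1.5 for downstream aggregation.
M per gene is reported both for the full set and at every exclusion step.
Genes with full-set M > 1.5 are flagged unsuitable.

The normalization factor NF_n is the per-sample geometric mean of the top-n
ranked genes' quantities; V_n/n+1 is the sample SD of log2(NF_n/NF_{n+1})
and the recommended reference count is the smallest n with V below the
cutoff (0.15 by convention). Samples missing any top-(n+1) gene are dropped
from that V with a logged count.

## Model-based stability (NormFinder)

On x = log2 q, per group: two-way centering (gene means, sample means)
leaves residuals whose mean square MS_i estimates gene i's within-group
variance contaminated by the shared sample-mean subtraction; the
cross-gene-corrected estimator is σ̂²_i = (G/(G−2))·(MS_i − M̄S/(G−1)),
clipped at zero (it is affine-increasing in MS_i, so rankings are
unaffected by the correction). Group bias d_ig is the gene's
loading-corrected group mean minus its replicate-weighted overall mean; the
true biases are modelled as N(0, γ²) with γ̂² estimated by method of
moments on (G−1)(K−1) degrees of freedom minus the mean sampling variance,
clipped at zero. Observed biases are shrunk by γ̂²/(γ̂² + σ̂²_ig/n_g) and the
stability value is mean over groups of |d̃_ig| + sqrt(posterior variance).
Degenerate inputs (constant data ⇒ γ̂² = 0 and σ̂² = 0) yield stability 0 by
defining 0/0 shrinkage as 0.

With a single group the bias terms vanish and the ungrouped variant returns
sqrt(σ̂²_i) — equivalent to ranking genes by the variance of their
sample-centered log quantities. At least 3 genes are required (the G−2
factor), and ≥2 complete samples per group.

## BestKeeper and comparative ΔCt

Both operate on raw Cq, never on relative quantities. BestKeeper's default
dispersion is the mean absolute deviation from the arithmetic mean Cq,
matching the original spreadsheet's "SD [± CP]"; the n−1 sample SD ships as
an option because published tables rarely state which convention they used.
Ranking is ascending dispersion; the per-sample geometric-mean index and
each gene's Pearson correlation with it are reported as information only.
The SD > 1 cycle instability flag is applied to whichever dispersion mode
is selected.

The comparative ΔCt score is the mean over partners of SD_samples(Cq_j −
Cq_k). With uniform efficiencies this equals geNorm's M on 2^(−Cq)
quantities exactly (log2 of a quantity ratio is the negated Cq difference);
the test suite asserts the identity to 1e-9. The two methods nevertheless
rank differently in aggregation: geNorm ranks by stepwise exclusion with a
tied top pair, ΔCt by the raw full-set scores.

## Comprehensive ranking

Each method contributes a rank vector (1 = most stable; exact score ties
averaged). The comprehensive value is the geometric mean of a gene's ranks
— "weights" are the raw ranks, with no rescaling, matching the published
aggregation tool's observed behaviour. Ties in the geometric mean are
broken by mean rank, then input order, and logged. The method set is
configurable; the default is all four.

## Target normalization

Relative expression of a target is 2^(−(Cq_target − mean Cq of the
reference pair)); the arithmetic mean of two Cqs is the geometric mean of
the corresponding quantities, so the pair is symmetric. Group comparison
reports the fold change of group means on the linear scale and a two-sample
two-tailed t-test — Student's pooled-variance by default (the usual choice
when only "t-test" is specified), Welch by flag; the test runs on linear
relative expression by default to mirror how such results are plotted
(mean ± SD of 2^(−ΔCt)), with a log-scale option because cycle-scale
normality is the more defensible assumption. Significance is flagged at
p < 0.05.

## Synthetic generator and its calibration

`simulate_ct` draws Cq[g,s,t] = base_cq_g + shift_g·1[s stressed] +
loading_s + b_gs + e_gst with independent Gaussian terms on the Cq scale
(log-normal and multiplicative on abundance — the standard qPCR error
model). The loading term moves all genes of a sample together, emulating
RNA input/RT differences, and is exactly cancelled by every ratio-based
statistic; the tests exploit that for bit-identical invariance checks.
Ground-truth stability is defined operationally as the lexicographic order
of (|shift|, noise_sd): condition bias is worse than scatter because it
biases normalization systematically.

The ten-gene soybean-style preset emulates a single biotic-stress screen:
base Cq 17.5–28 (high expressors near 17–19, the weakest near 28), two
condition groups with 3 biological replicates each and duplicate wells,
loading SD 0.3 cycles, technical SD 0.1 cycles. Two genes (ABCT, FBOX) are
engineered co-stable (no shift, biological SD 0.15); seven mid genes have
SD 0.35–0.50 and shifts 0–0.5; the engineered worst gene (GPDH) combines a
2-cycle condition shift with SD 0.5. That calibration puts the worst gene's
raw-Cq dispersion near one cycle (tripping the BestKeeper SD > 1 flag) and
its full-set M near 1.1–1.4 — clearly the worst of the panel yet below the
1.5 suitability cutoff, the situation actually observed in biotic-stress
reference screens — while keeping it last in the comprehensive ordering in
99 of 100 seeded runs.

What the preset does *not* emulate: plate/run batch effects, PCR
inhibitors, non-Gaussian dropout of weak wells, and efficiency differences
between genes (quantities default to A = 2). Passing recovery tests on it
shows the pipeline's statistics behave correctly under the stated error
model, not that any particular real panel will rank the same way.

## Numerical and design notes

- Problem sizes: the preset pipeline (10 genes × 6 samples × 2 wells) runs
  in milliseconds; recovery suites use 100 fixed seeds and the monotonicity
  suites 5 levels × 100–200 replicates, keeping the whole test run well
  under a minute.
- Sample SDs use the n−1 denominator everywhere (geNorm's own convention);
  BestKeeper's default MAD is the deliberate exception described above.
- With 3 biological replicates per group, variance estimates carry ~5
  degrees of freedom, so single-experiment rankings of genes with similar
  true stability are intrinsically noisy. The engineered clearly-worst gene
  is recovered last ≥95/100 runs, but the engineered best *pair* is only
  the exact comprehensive top-2 in a minority of runs — separating a
  0.15-cycle-SD gene from 0.35-cycle neighbours reliably at n = 6 would
  require implausibly large gaps. This mirrors practice: screens across
  several stressors disagree on the best pair while agreeing on the worst
  gene, and is why recovery guarantees here are stated for the worst gene
  only.
- The comparative ΔCt/geNorm identity means a four-method aggregate
  effectively double-weights pairwise-ratio dispersion; that is inherent to
  the standard four-method protocol, not a choice made here.
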