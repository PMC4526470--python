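# refstab

Reference-gene stability evaluation for RT-qPCR experiments.

## The problem

Quantitative RT-PCR measures a target gene's expression relative to one or
more *reference* ("housekeeping") genes assumed to be stably expressed. When
that assumption fails — and under biotic stress in plants it often does —
every normalized fold change inherits the reference's bias. Candidate
references are therefore screened by running a panel of genes across the
experimental conditions and scoring each candidate's stability with several
complementary statistics. `refstab` implements the four standard methods and
the usual way of combining them, for anyone analysing Cq (Ct) panels:

- **geNorm** — a gene's stability value M is the mean over all other
  candidates k of SD_samples(log2 q_j/q_k), where q are relative quantities
  2^(−ΔCq); genes are ranked by stepwise exclusion of the highest-M gene,
  and M > 1.5 flags a gene as unsuitable.
- **NormFinder** — a model-based decomposition of log2 quantities into
  within-group variance and between-group bias (shrunk toward zero across
  genes); the stability value is mean_g(|d̂_g| + SE(d̂_g)).
- **BestKeeper** — dispersion of each gene's raw Cq (mean absolute
  deviation by default, sample SD optional); SD > 1 cycle flags instability.
- **Comparative ΔCt** — the mean over partner genes of SD_samples(Cq_j −
  Cq_k), algebraically geNorm's M on 2^(−Cq) quantities.
- **Comprehensive ranking** (RefFinder-style) — each gene's geometric mean
  of its four per-method ranks; a gene ranked last (G-th) by every method
  scores exactly G.
- **Optimal reference count** — pairwise variation V_n/n+1 =
  SD_samples(log2 NF_n/NF_{n+1}) between normalization factors built from
  the top n and n+1 genes; V < 0.15 means the extra gene is unnecessary.

Also included: Cq table I/O (wide/long CSV + sample design), technical
replicate aggregation, efficiency-aware relative quantities, standard-curve
efficiency estimation (E = (10^(−1/slope) − 1)·100), target-gene
normalization against a reference pair with a group t-test, and a synthetic
Cq generator with known ground truth for validating the whole pipeline.

## Worked example

```python
from refstab import evaluate_all, simulate_ct, soybean_preset

table, truth = simulate_ct(soybean_preset(seed=1))   # 10 genes, 2 groups, 3x2 reps
ev = evaluate_all(table)
print(ev.comprehensive.ordering)
print(round(ev.comprehensive.gm[truth.least_stable], 2))
print(round(ev.v_series.v[2], 4), ev.v_series.optimal_n)
```

prints

```
['TUA4', 'FBOX', 'ABCT', 'CYP', 'UNK2', 'EF1A', 'TUB4', 'RPL30', 'TUA5', 'GPDH']
10.0
0.0562 2
```

The preset engineers `GPDH` to be clearly unstable (a 2-cycle condition
shift plus the largest scatter): all four methods rank it 10th of 10, so its
comprehensive geometric-mean rank is exactly 10.00 and it lands last in the
ordering. V_2/3 = 0.056 is far below the 0.15 cutoff, so two reference genes
suffice for the normalization factor. The `examples/` directory has one
short script per capability (full four-method report, V series, standard
curves, and normalization against a stable vs an unstable reference pair);
a thin CLI offers the same workflows (`refstab simulate`, `refstab rank`,
`refstab optimal-n`, `refstab normalize`).

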