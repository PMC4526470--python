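"""Raw-Cq dispersion stability: BestKeeper descriptive statistics and the
comparative delta-Ct method.

Both methods work directly on cycle-threshold values, never on relative
quantities.  BestKeeper scores each gene by the dispersion of its own Cq
across samples (default: mean absolute deviation from the mean, the
original spreadsheet's "SD [+/- CP]" convention; sample SD available), with
an SD above 1 cycle flagging the gene as unstable.  It also reports the
BestKeeper index — the per-sample geometric mean Cq over all candidates —
and each gene's Pearson correlation with it.

The comparative delta-Ct method scores a gene by the mean, over every other
candidate, of the SD across samples of their Cq difference.  Up to the log
base this is exactly the geNorm M computed on 2^-Cq quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_data import CtTable, collapse

__all__ = [
    "BestkeeperResult",
    "DeltaCtResult",
    "BESTKEEPER_SD_CUTOFF",
    "bestkeeper_stats",
    "deltact_stability",
]

#: Cq-cycle SD above which BestKeeper considers a gene unstable.
BESTKEEPER_SD_CUTOFF = 1.0


@dataclass
class BestkeeperResult:
    """Per-gene Cq descriptives, instability flags, and index correlations."""

    stats: pd.DataFrame  # n, geo_mean, mean, min, max, sd, cv, unstable
    index: pd.Series  # per-sample geometric mean Cq
    index_correlation: pd.Series
    sd_mode: str

    @property
    def scores(self) -> pd.Series:
        """Dispersion per gene (lower = more stable)."""
        return self.stats["sd"]

    @property
    def unstable(self) -> pd.Series:
        return self.stats["unstable"]

    @property
    def ordering(self) -> list[str]:
        return list(self.scores.sort_values(kind="stable").index)


def bestkeeper_stats(table: CtTable, sd_mode: str = "mad") -> BestkeeperResult:
    """BestKeeper descriptive statistics on raw Cq.

    ``sd_mode="mad"`` (default) computes the mean absolute deviation from
    the arithmetic mean Cq; ``"sample_sd"`` the n-1 standard deviation.
    Missing wells are ignored per gene; a gene needs >=2 values.  The
    ranking (``ordering``) is ascending dispersion; the index and its
    correlations are informational and do not enter the ranking.
    """
    if sd_mode not in ("mad", "sample_sd"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    cq = collapse(table).cq
    rows = {}
    for gene, row in cq.iterrows():
        x = row.dropna().to_numpy(float)
        if x.size < 2:
            raise ValueError(f"gene {gene!r} has {x.size} Cq value(s); need >=2")
        mean = x.mean()
        sd = np.abs(x - mean).mean() if sd_mode == "mad" else x.std(ddof=1)
        rows[gene] = {
            "n": x.size,
            "geo_mean": float(np.exp(np.log(x).mean())),
            "mean": float(mean),
            "min": float(x.min()),
            "max": float(x.max()),
            "sd": float(sd),
            "cv": float(100.0 * sd / mean),
        }
    stats = pd.DataFrame.from_dict(rows, orient="index").loc[list(cq.index)]
    stats["unstable"] = stats["sd"] > BESTKEEPER_SD_CUTOFF

    index = np.exp(np.log(cq).mean(axis=0, skipna=True)).rename("bk_index")
    corr = {}
    for gene, row in cq.iterrows():
        ok = ~(row.isna() | index.isna())
        if ok.sum() >= 2 and row[ok].std() > 0 and index[ok].std() > 0:
            corr[gene] = float(np.corrcoef(row[ok], index[ok])[0, 1])
        else:
            corr[gene] = np.nan
    return BestkeeperResult(
        stats=stats,
        index=index,
        index_correlation=pd.Series(corr, name="r_vs_index").loc[list(cq.index)],
        sd_mode=sd_mode,
    )


@dataclass
class DeltaCtResult:
    """Comparative delta-Ct stability: mean pairwise Cq-difference SD."""

    mean_sd: pd.Series
    pair_sd: pd.DataFrame  # symmetric gene x gene SD matrix (diagonal NaN)
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def scores(self) -> pd.Series:
        return self.mean_sd

    @property
    def ordering(self) -> list[str]:
        return list(self.mean_sd.sort_values(kind="stable").index)


def deltact_stability(table: CtTable) -> DeltaCtResult:
    """Score each gene by the mean SD of its pairwise Cq differences.

    For every gene pair the SD across samples (n-1 denominator, pairwise
    complete) of Cq_j - Cq_k is computed; a gene's score averages over its
    partners.  Pairs with <2 complete samples are skipped with a warning; a
    gene left without any usable partner is an error.  Adding a constant to
    one sample's Cq across all genes changes nothing.
    """
    cq = collapse(table).cq
    genes = list(cq.index)
    if len(genes) < 2:
        raise ValueError("comparative delta-Ct needs >=2 genes")
    vals = cq.to_numpy(float)
    g = len(genes)
    pair_sd = np.full((g, g), np.nan)
    skipped: list[tuple[str, str]] = []
    for i in range(g):
        for j in range(i + 1, g):
            ok = ~(np.isnan(vals[i]) | np.isnan(vals[j]))
            if ok.sum() < 2:
                skipped.append((genes[i], genes[j]))
                warnings.warn(
                    f"delta-Ct pair ({genes[i]}, {genes[j]}) skipped: "
                    f"{ok.sum()} complete sample(s)",
                    stacklevel=2,
                )
                continue
            pair_sd[i, j] = pair_sd[j, i] = float(
                np.std(vals[i][ok] - vals[j][ok], ddof=1)
            )
    scores = {}
    for i, gene in enumerate(genes):
        partners = pair_sd[i][~np.isnan(pair_sd[i])]
        if partners.size == 0:
            raise ValueError(f"gene {gene!r} has no usable partner pair")
        scores[gene] = float(partners.mean())
    return DeltaCtResult(
        mean_sd=pd.Series(scores, name="mean_sd").loc[genes],
        pair_sd=pd.DataFrame(pair_sd, index=genes, columns=genes),
        skipped_pairs=skipped,
    )
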