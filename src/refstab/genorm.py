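"""geNorm reference-gene stability: M values, stepwise ranking, and the
pairwise-variation analysis of the optimal number of reference genes.

geNorm rests on the idea that the expression ratio of two ideal reference
genes is constant across samples.  For genes j and k the pairwise variation
V_jk is the standard deviation over samples of log2(q_j / q_k); a gene's
stability M_j is the average V_jk over all other candidates.  The ranking
is produced by stepwise exclusion of the highest-M gene until two remain —
those two share a single V and are reported as a tied top pair.

The companion analysis asks how many reference genes a normalization factor
needs: NF_n is the per-sample geometric mean of the n most stable genes'
quantities, and V_{n/n+1} is the SD across samples of log2(NF_n / NF_{n+1}).
Below a cutoff (0.15 by convention) the (n+1)-th gene adds nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_data import RelQuantMatrix

__all__ = [
    "GenormResult",
    "PairwiseVariationSeries",
    "UNSUITABLE_M",
    "DEFAULT_V_CUTOFF",
    "pairwise_variation",
    "m_values",
    "genorm_ranking",
    "optimal_reference_count",
]

#: Genes with full-set M above this are flagged unsuitable for normalization.
UNSUITABLE_M = 1.5

#: Conventional pairwise-variation cutoff for the optimal gene count.
DEFAULT_V_CUTOFF = 0.15


def _as_q(q: RelQuantMatrix | pd.DataFrame) -> pd.DataFrame:
    return q.q if isinstance(q, RelQuantMatrix) else q


def pairwise_variation(q_j, q_k) -> float:
    """SD over samples of log2(q_j / q_k) for two quantity vectors.

    Uses the sample standard deviation (n-1 denominator) over the samples
    where both genes are present.  Multiplying either vector by a constant
    — or both by arbitrary per-sample loadings — leaves the value unchanged.
    """
    a = np.asarray(q_j, dtype=float)
    b = np.asarray(q_k, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError(
            f"pairwise variation needs >=2 complete sample pairs, got {ok.sum()}"
        )
    ratio = np.log2(a[ok] / b[ok])
    return float(np.std(ratio, ddof=1))


def m_values(
    q: RelQuantMatrix | pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.Series:
    """Per-gene geNorm stability M over a candidate subset.

    M_j is the arithmetic mean of V_jk over every other gene k in the
    subset; lower M means more stable.  For exactly two genes both M equal
    their mutual V.  Compare against :data:`UNSUITABLE_M` to flag genes too
    variable for normalization use.
    """
    mat = _as_q(q)
    if genes is not None:
        mat = mat.loc[list(genes)]
    names = list(mat.index)
    g = len(names)
    if g < 2:
        raise ValueError("M values need a subset of >=2 genes")
    vals = mat.to_numpy(float)
    # symmetric V matrix, each pair computed once (so a two-gene subset
    # yields bit-identical M for both members)
    v = np.zeros((g, g))
    for i in range(g):
        for k in range(i + 1, g):
            v[i, k] = v[k, i] = pairwise_variation(vals[i], vals[k])
    m = (v.sum(axis=1)) / (g - 1)
    return pd.Series(m, index=names, name="M")


@dataclass
class GenormResult:
    """Stepwise geNorm ranking.

    ``m_by_step`` holds the per-remaining-gene M at every exclusion step
    (step 0 = full set); ``exclusion_order`` lists genes from least stable
    (excluded first) onwards; the ``final_pair`` cannot be resolved further
    and shares one M.  ``ranking`` orders genes most -> least stable with
    the tied pair first, in input order.
    """

    m_by_step: list[pd.Series]
    exclusion_order: list[str]
    final_pair: tuple[str, str]
    ranking: list[str]
    full_set_m: pd.Series
    tie_log: list[str] = field(default_factory=list)

    @property
    def scores(self) -> pd.Series:
        """Full-set M per gene (lower = more stable)."""
        return self.full_set_m

    @property
    def unsuitable(self) -> pd.Series:
        """Genes whose full-set M exceeds the 1.5 suitability cutoff."""
        return self.full_set_m > UNSUITABLE_M

    @property
    def ranks(self) -> pd.Series:
        """Stability ranks, 1 = most stable; the tied final pair gets 1.5."""
        r = pd.Series(0.0, index=pd.Index(self.ranking, name="gene"))
        r.iloc[0] = r.iloc[1] = 1.5
        r.iloc[2:] = np.arange(3, len(self.ranking) + 1, dtype=float)
        return r.loc[self.full_set_m.index]


def genorm_ranking(q: RelQuantMatrix | pd.DataFrame) -> GenormResult:
    """Rank candidates by stepwise exclusion of the highest-M gene.

    At each step M is recomputed over the remaining subset and the single
    worst gene removed; exact M ties remove the gene later in input order
    (recorded in ``tie_log``).  The run stops when two genes remain — they
    report identical M and rank as a tied 1-2.
    """
    mat = _as_q(q)
    names = list(mat.index)
    if len(names) < 3:
        raise ValueError(
            "stepwise geNorm ranking needs >=3 genes; use m_values for a pair"
        )
    remaining = list(names)
    m_by_step: list[pd.Series] = []
    exclusion: list[str] = []
    tie_log: list[str] = []
    while len(remaining) > 2:
        m = m_values(mat, remaining)
        m_by_step.append(m)
        worst_m = m.max()
        ties = [g for g in remaining if m[g] == worst_m]
        drop = ties[-1]  # later in input order
        if len(ties) > 1:
            tie_log.append(
                f"M tie at {worst_m:.6g} among {ties}; removed {drop!r}"
            )
        exclusion.append(drop)
        remaining.remove(drop)
    final_m = m_values(mat, remaining)
    m_by_step.append(final_m)
    pair = (remaining[0], remaining[1])
    ranking = list(remaining) + list(reversed(exclusion))
    return GenormResult(
        m_by_step=m_by_step,
        exclusion_order=exclusion,
        final_pair=pair,
        ranking=ranking,
        full_set_m=m_by_step[0].loc[names],
        tie_log=tie_log,
    )


@dataclass
class PairwiseVariationSeries:
    """V_{n/n+1} between successive normalization factors.

    ``v`` is indexed by n = 2..G-1; ``optimal_n`` is the smallest n with
    V_{n/n+1} below ``cutoff``, or G (with ``satisfied=False``) when no n
    qualifies.  ``dropped_samples`` counts, per n, samples excluded because
    a top-(n+1) gene was missing there.
    """

    v: pd.Series
    cutoff: float
    optimal_n: int
    satisfied: bool
    dropped_samples: dict[int, int] = field(default_factory=dict)


def optimal_reference_count(
    q: RelQuantMatrix | pd.DataFrame,
    ranking: GenormResult | list[str],
    cutoff: float = DEFAULT_V_CUTOFF,
) -> PairwiseVariationSeries:
    """Pairwise variation between NF_n and NF_{n+1} along the geNorm ranking.

    NF_n[s] is the geometric mean of the top-n ranked genes' quantities at
    sample s; V_{n/n+1} is the sample SD over s of log2(NF_n / NF_{n+1}).
    The smallest n with V below ``cutoff`` (default 0.15) is the recommended
    number of reference genes.
    """
    mat = _as_q(q)
    order = ranking.ranking if isinstance(ranking, GenormResult) else list(ranking)
    if len(order) < 3:
        raise ValueError("the V series needs a ranking over >=3 genes")
    logq = np.log2(mat.loc[order].to_numpy(float))
    g = len(order)
    v = {}
    dropped: dict[int, int] = {}
    for n in range(2, g):
        top_n1 = logq[: n + 1]
        ok = ~np.isnan(top_n1).any(axis=0)
        n_drop = int((~ok).sum())
        if n_drop:
            dropped[n] = n_drop
            warnings.warn(
                f"V_{n}/{n + 1}: dropped {n_drop} sample(s) with missing "
                "quantities among the top genes",
                stacklevel=2,
            )
        if ok.sum() < 2:
            raise ValueError(f"V_{n}/{n + 1}: fewer than 2 usable samples")
        nf_n = top_n1[:n, ok].mean(axis=0)  # log2 of geometric mean
        nf_n1 = top_n1[:, ok].mean(axis=0)
        v[n] = float(np.std(nf_n - nf_n1, ddof=1))
    series = pd.Series(v, name="V").rename_axis("n")
    below = [n for n, val in v.items() if val < cutoff]
    if below:
        return PairwiseVariationSeries(series, cutoff, min(below), True, dropped)
    return PairwiseVariationSeries(series, cutoff, g, False, dropped)
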