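"""Model-based (NormFinder-style) reference-gene stability.

The model works on log2 relative quantities and decomposes each gene's
variation into a within-group component (random biological + technical
scatter) and a between-group component (systematic condition bias).  Both
matter for a reference gene: a gene may scatter little yet shift with the
condition, which silently biases every normalized target.

Procedure, per condition group g with n_g samples and G genes:

1. every sample's across-gene mean is an estimate of its RNA-loading
   offset; two-way centering within the group leaves residuals whose mean
   square per gene estimates the within-group variance, after a cross-gene
   bias correction with factor G/(G-2) (subtracting the shared sample mean
   leaks a 1/G share of every gene's variance into every other gene);
2. the group bias d_ig is the gene's loading-corrected group mean relative
   to its overall mean; the true biases are modelled as draws from
   N(0, gamma^2) and the observed d_ig are shrunk toward zero by the
   normal-normal posterior factor gamma^2 / (gamma^2 + var(d_ig));
3. the stability value is the average over groups of |shrunk bias| plus the
   posterior SD of the bias — small only when a gene neither shifts between
   conditions nor scatters within them.  Lower is more stable.

With a single group there is no bias to estimate and the stability value
reduces to the bias-corrected within-group SD (the ungrouped variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_data import RelQuantMatrix

__all__ = ["NormfinderResult", "normfinder_stability", "ungrouped_stability"]


@dataclass
class NormfinderResult:
    """Per-gene stability values and their variance decomposition.

    ``stability`` is in log2-cycle units, >= 0, lower = more stable.
    ``intergroup`` holds the shrunk group-bias estimates d (genes x groups,
    all zero for the ungrouped variant); ``intragroup_var`` the
    bias-corrected within-group variances.
    """

    stability: pd.Series
    intergroup: pd.DataFrame
    intragroup_var: pd.DataFrame
    grouped: bool
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def scores(self) -> pd.Series:
        return self.stability

    @property
    def ordering(self) -> list[str]:
        """Genes most -> least stable (ascending stability, ties by input order)."""
        return list(self.stability.sort_values(kind="stable").index)


def _complete_cases(logq: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    ok = ~logq.isna().any(axis=0)
    dropped = [s for s, keep in ok.items() if not keep]
    if dropped:
        warnings.warn(
            f"dropping incomplete samples for model-based stability: {dropped}",
            stacklevel=3,
        )
    return logq.loc[:, ok], dropped


def _two_way_variances(x: np.ndarray) -> np.ndarray:
    """Bias-corrected per-gene residual variances of one group's log data."""
    g, n = x.shape
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    ms = (resid**2).sum(axis=1) / (n - 1)
    sig2 = (g / (g - 2.0)) * (ms - ms.mean() / (g - 1.0))
    return np.clip(sig2, 0.0, None)


def normfinder_stability(
    q: RelQuantMatrix,
    group: pd.Series | None = None,
) -> NormfinderResult:
    """Model-based stability value per gene, grouped when >=2 groups exist.

    Requires >=3 genes (the decomposition averages across genes) and >=2
    complete samples per group; samples with any missing quantity are
    dropped (complete-case policy, recorded in ``dropped_samples``).  A
    single-group input falls back to :func:`ungrouped_stability` with a
    warning.  Genes are not reordered; use ``result.ordering``.
    """
    labels = (q.group if group is None else group).astype(str)
    logq, dropped = _complete_cases(q.log2())
    labels = labels.loc[logq.columns]
    genes = list(logq.index)
    g = len(genes)
    if g < 3:
        raise ValueError("model-based stability needs >=3 genes")

    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        warnings.warn(
            "single condition group supplied; computing the ungrouped "
            "(pure-variance) stability variant",
            stacklevel=2,
        )
        res = ungrouped_stability(q)
        res.dropped_samples = dropped
        return res

    n_by_group = {}
    for gr in groups:
        n_gr = int((labels == gr).sum())
        if n_gr < 2:
            raise ValueError(f"group {gr!r} has {n_gr} complete sample(s); need >=2")
        n_by_group[gr] = n_gr
    n_total = sum(n_by_group.values())

    # within-group variances and loading-corrected group means
    sig2 = pd.DataFrame(index=genes, columns=groups, dtype=float)
    zbar = pd.DataFrame(index=genes, columns=groups, dtype=float)
    for gr in groups:
        x = logq.loc[:, labels == gr].to_numpy(float)
        sig2[gr] = _two_way_variances(x)
        z = x - x.mean(axis=0, keepdims=True)  # remove per-sample loading
        zbar[gr] = z.mean(axis=1)

    # group-bias estimates d_ig (sum over genes and weighted sum over groups = 0)
    weights = pd.Series(n_by_group, dtype=float) / n_total
    overall = zbar.mul(weights, axis=1).sum(axis=1)
    d = zbar.sub(overall, axis=0)

    # variance of the true biases across genes/groups, minus sampling noise
    k = len(groups)
    samp_var = sig2.div(pd.Series(n_by_group, dtype=float), axis=1)
    gamma2 = max(
        0.0,
        float((d**2).to_numpy().sum() / ((g - 1) * (k - 1))
              - samp_var.to_numpy().mean()),
    )

    denom = gamma2 + samp_var
    with np.errstate(invalid="ignore"):
        shrink = np.where(denom > 0, gamma2 / denom, 0.0)
    d_shrunk = d * shrink
    post_var = samp_var * shrink  # posterior variance of the bias

    stability = (d_shrunk.abs() + np.sqrt(post_var)).mean(axis=1)
    return NormfinderResult(
        stability=stability.rename("stability"),
        intergroup=d_shrunk,
        intragroup_var=sig2,
        grouped=True,
        dropped_samples=dropped,
    )


def ungrouped_stability(q: RelQuantMatrix) -> NormfinderResult:
    """Single-group stability: bias-corrected within-set SD per gene.

    Equivalent to ranking genes by the variance of their sample-centered
    log quantities; the group-bias components are identically zero.
    """
    logq, dropped = _complete_cases(q.log2())
    genes = list(logq.index)
    if len(genes) < 3:
        raise ValueError("model-based stability needs >=3 genes")
    if logq.shape[1] < 2:
        raise ValueError("need >=2 complete samples")
    sig2 = _two_way_variances(logq.to_numpy(float))
    col = "all"
    return NormfinderResult(
        stability=pd.Series(np.sqrt(sig2), index=genes, name="stability"),
        intergroup=pd.DataFrame(0.0, index=genes, columns=[col]),
        intragroup_var=pd.DataFrame(sig2, index=genes, columns=[col]),
        grouped=False,
        dropped_samples=dropped,
    )
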