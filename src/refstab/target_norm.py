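"""Target-gene normalization against a reference pair and group comparison.

Given a validated pair of reference genes, a target's relative expression
in sample s is ``2^-(Cq_target - mean Cq of the pair)`` — normalizing by
the arithmetic mean of the two reference Cqs is the same as dividing by the
geometric mean of their ``2^-Cq`` quantities.  Groups are then compared on
the linear relative-expression scale (fold change of means, two-sample
t-test); normalizing against an unstable pair whose members shift with the
condition visibly distorts both the fold change and the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtTable, collapse

__all__ = ["NormalizedExpression", "normalize_targets", "group_compare"]


@dataclass
class NormalizedExpression:
    """Per-(target, sample) relative expression against a reference pair."""

    expr: pd.DataFrame  # targets x samples, dimensionless > 0
    reference_pair: tuple[str, str]
    design: pd.DataFrame

    @property
    def targets(self) -> list[str]:
        return list(self.expr.index)

    @property
    def group(self) -> pd.Series:
        return self.design.loc[self.expr.columns, "group"]


def normalize_targets(
    targets: CtTable,
    references: CtTable,
    pair: tuple[str, str],
) -> NormalizedExpression:
    """Relative expression of each target against a two-gene reference.

    The per-sample reference level is the arithmetic mean of the pair's
    Cq; relative expression is ``2^-(Cq_target - refmean)``.  Samples are
    matched by identifier across the two tables (target-table order); a
    sample missing any constituent Cq yields a missing output.  The pair is
    symmetric — swapping its genes changes nothing.
    """
    a, b = pair
    refs = collapse(references)
    tgts = collapse(targets)
    missing = [g for g in (a, b) if g not in refs.cq.index]
    if missing:
        raise ValueError(f"reference pair gene(s) not in reference table: {missing}")
    shared = [s for s in tgts.samples if s in refs.cq.columns]
    if not shared:
        raise ValueError("no overlapping samples between target and reference tables")
    ref_mean = refs.cq.loc[[a, b], shared].mean(axis=0, skipna=False)
    expr = np.power(2.0, -(tgts.cq[shared].sub(ref_mean, axis=1)))
    return NormalizedExpression(
        expr=expr, reference_pair=(a, b), design=tgts.design
    )


def group_compare(
    expr: NormalizedExpression,
    control: str = "control",
    treated: str | None = None,
    scale: str = "linear",
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-target fold change and two-sample two-tailed t-test.

    Fold change is mean(treated)/mean(control) on the linear
    relative-expression scale.  The t-test defaults to Student's pooled
    variance on linear values; ``equal_var=False`` gives Welch, and
    ``scale="log"`` tests log2 values instead.  Returns a DataFrame with
    ``fold_change``, ``t_stat``, ``p_value`` and a ``significant`` flag at
    ``alpha``.
    """
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    groups = expr.group
    labels = list(dict.fromkeys(groups))
    if treated is None:
        others = [g for g in labels if g != control]
        if len(others) != 1:
            raise ValueError(
                f"cannot infer the treated group from labels {labels}; "
                "pass treated= explicitly"
            )
        treated = others[0]
    for name in (control, treated):
        if name not in labels:
            raise ValueError(f"group {name!r} not present in the design")

    rows = {}
    for target, vals in expr.expr.iterrows():
        ctl = vals[groups == control].dropna().to_numpy(float)
        trt = vals[groups == treated].dropna().to_numpy(float)
        if ctl.size < 2 or trt.size < 2:
            raise ValueError(
                f"target {target!r}: each group needs >=2 samples "
                f"(got {ctl.size} control, {trt.size} treated)"
            )
        fc = trt.mean() / ctl.mean()
        x_t, x_c = (np.log2(trt), np.log2(ctl)) if scale == "log" else (trt, ctl)
        if np.allclose(x_t, x_t[0]) and np.allclose(x_c, x_c[0]) and np.isclose(
            x_t[0], x_c[0]
        ):
            t_stat, p = 0.0, 1.0  # identical constant groups
        else:
            t_stat, p = stats.ttest_ind(x_t, x_c, equal_var=equal_var)
        rows[target] = {
            "fold_change": float(fc),
            "t_stat": float(t_stat),
            "p_value": float(p),
            "significant": bool(p < alpha),
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[expr.targets]
    out.index.name = "target"
    return out
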