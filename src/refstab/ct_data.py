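"""Cq (Ct) data model, I/O, and elementary qPCR transforms.

The central container is :class:`CtTable`: a rectangular gene x sample matrix
of quantification-cycle values plus a sample design (condition group and
biological replicate).  Technical replicate wells, when present, live in a
second column level and are collapsed with
:func:`aggregate_technical_replicates` before any stability analysis.

Cq values are cycle numbers: lower Cq means higher transcript abundance, and
one cycle corresponds to an ``A``-fold change in template where ``A`` is the
per-gene amplification factor (2 for perfect doubling chemistry).
:func:`relative_quantities` converts Cq to the dimensionless relative
quantities ``A^(-dCt)`` that the ratio-based stability methods consume, and
:func:`standard_curve_efficiency` estimates ``A`` from a dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "RelQuantMatrix",
    "EfficiencyRecord",
    "CtDataError",
    "MISSING_TOKENS",
    "read_ct_table",
    "read_efficiencies",
    "aggregate_technical_replicates",
    "relative_quantities",
    "standard_curve_efficiency",
]

#: Cell contents treated as a missing Cq when reading tables.
MISSING_TOKENS = frozenset({"", "NA", "NaN", "Undetermined"})

#: Default validity window for Cq values, in cycles.  A 40-cycle protocol
#: plus margin; values outside (0, CQ_MAX] are rejected at construction.
CQ_MAX = 45.0


class CtDataError(ValueError):
    """Structured error for invalid Cq tables or designs."""


@dataclass
class CtTable:
    """Rectangular Cq measurements with sample design.

    Parameters
    ----------
    cq
        DataFrame of Cq values, genes in rows.  Columns are either sample
        identifiers, or a two-level MultiIndex ``(sample, tech_rep)`` when
        technical replicate wells have not yet been collapsed.
    design
        DataFrame indexed by sample with columns ``group`` (condition label)
        and optionally ``bio_rep`` (positive integer).
    cq_max
        Upper end of the Cq validity window, in cycles.
    """

    cq: pd.DataFrame
    design: pd.DataFrame
    cq_max: float = CQ_MAX

    def __post_init__(self) -> None:
        self.cq = self.cq.astype(float)
        if self.cq.index.has_duplicates:
            raise CtDataError("duplicate gene identifiers in Cq table")
        if len(self.genes) < 2:
            raise CtDataError("a CtTable needs at least 2 genes")
        if len(self.samples) < 2:
            raise CtDataError("a CtTable needs at least 2 samples")
        if pd.Index(self.samples).has_duplicates:
            raise CtDataError("duplicate sample identifiers in Cq table")
        if "group" not in self.design.columns:
            raise CtDataError("design must have a 'group' column")
        missing = [s for s in self.samples if s not in self.design.index]
        if missing:
            raise CtDataError(
                f"samples not mapped to a group in the design: {missing}"
            )
        vals = self.cq.to_numpy(float)
        present = ~np.isnan(vals)
        if np.any(~np.isfinite(vals[present])):
            raise CtDataError("non-finite Cq value present")
        if np.any((vals[present] <= 0) | (vals[present] > self.cq_max)):
            bad = vals[present][(vals[present] <= 0) | (vals[present] > self.cq_max)]
            raise CtDataError(
                f"Cq values outside (0, {self.cq_max}]: {sorted(bad)[:5]}"
            )

    # -- structure ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def samples(self) -> list[str]:
        """Biological sample identifiers, in column order."""
        if self.has_tech_reps:
            seen: dict[str, None] = {}
            for s, _ in self.cq.columns:
                seen.setdefault(s, None)
            return list(seen)
        return list(self.cq.columns)

    @property
    def has_tech_reps(self) -> bool:
        return isinstance(self.cq.columns, pd.MultiIndex)

    @property
    def group(self) -> pd.Series:
        """Condition label per biological sample, in sample order."""
        return self.design.loc[self.samples, "group"]

    @property
    def n_missing(self) -> int:
        return int(self.cq.isna().to_numpy().sum())

    def subset(self, genes: Sequence[str]) -> "CtTable":
        absent = [g for g in genes if g not in self.cq.index]
        if absent:
            raise CtDataError(f"genes not in table: {absent}")
        return CtTable(self.cq.loc[list(genes)], self.design, self.cq_max)

    # -- I/O ---------------------------------------------------------------

    def to_wide_csv(self, path: str | Path) -> None:
        """Write the (tech-rep-collapsed) table as a wide CSV, genes in rows."""
        df = collapse(self).cq
        df.index.name = "gene"
        df.to_csv(path)

    def write_design_csv(self, path: str | Path) -> None:
        out = self.design.loc[self.samples].copy()
        out.index.name = "sample"
        out.to_csv(path)


def collapse(table: CtTable, method: str = "mean") -> CtTable:
    """Return ``table`` with technical replicates collapsed (no-op if flat)."""
    if not table.has_tech_reps:
        return table
    return aggregate_technical_replicates(table, method=method)


def aggregate_technical_replicates(table: CtTable, method: str = "mean") -> CtTable:
    """Collapse duplicate wells to one Cq per (gene, biological sample).

    Averaging is done on the Cq scale, matching instrument-software
    practice.  Missing wells are ignored; a (gene, sample) whose wells are
    all missing stays missing.  A table without a technical-replicate
    dimension passes through unchanged.
    """
    if method not in ("mean", "median"):
        raise CtDataError(f"unknown aggregation method: {method!r}")
    if not table.has_tech_reps:
        return table
    grouped = table.cq.T.groupby(level=0, sort=False)
    agg = grouped.mean() if method == "mean" else grouped.median()
    flat = agg.T.loc[table.genes, table.samples]
    return CtTable(flat, table.design, table.cq_max)


# ---------------------------------------------------------------------------
# reading

def _parse_cq_token(token: object, where: str) -> float:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return np.nan
    text = str(token).strip()
    if text in MISSING_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise CtDataError(f"non-numeric Cq token {text!r} at {where}") from None


def _read_design(design_path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(design_path, dtype={"sample": str})
    if "sample" not in design.columns or "group" not in design.columns:
        raise CtDataError("design file needs columns sample,group[,bio_rep]")
    if design["sample"].duplicated().any():
        dupes = design.loc[design["sample"].duplicated(), "sample"].tolist()
        raise CtDataError(f"duplicate samples in design: {dupes}")
    design = design.set_index("sample")
    if "bio_rep" in design.columns:
        design["bio_rep"] = design["bio_rep"].astype(int)
    return design


def read_ct_table(
    path: str | Path,
    design_path: str | Path,
    dialect: str = "wide",
) -> CtTable:
    """Read a Cq table plus its sample design from CSV/TSV.

    ``dialect="wide"``: genes in rows, first column headed ``gene``,
    remaining columns one per sample.  ``dialect="long"``: columns
    ``gene,sample,tech_rep,cq``, one row per well.  The tokens in
    :data:`MISSING_TOKENS` become missing values; any other non-numeric
    token is an error.  Row/column order is preserved from the file.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    design = _read_design(design_path)

    if dialect == "wide":
        raw = pd.read_csv(path, sep=sep, dtype=str)
        if raw.columns[0] != "gene":
            raise CtDataError("wide Cq table must have first column 'gene'")
        raw = raw.set_index("gene")
        parsed = pd.DataFrame(
            [
                [_parse_cq_token(v, f"({g}, {s})") for s, v in row.items()]
                for g, row in raw.iterrows()
            ],
            index=raw.index,
            columns=raw.columns,
        )
        return CtTable(parsed, design)

    if dialect == "long":
        raw = pd.read_csv(path, sep=sep, dtype=str)
        needed = {"gene", "sample", "cq"}
        if not needed.issubset(raw.columns):
            raise CtDataError("long Cq table needs columns gene,sample[,tech_rep],cq")
        if "tech_rep" not in raw.columns:
            raw = raw.assign(tech_rep="1")
        key = raw[["gene", "sample", "tech_rep"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_records(index=False).tolist()
            raise CtDataError(f"duplicate (gene,sample,tech_rep) rows: {dupes[:5]}")
        raw = raw.assign(
            _cq=[
                _parse_cq_token(v, f"({g}, {s}, tech {t})")
                for g, s, t, v in zip(
                    raw["gene"], raw["sample"], raw["tech_rep"], raw["cq"]
                )
            ]
        )
        genes = list(dict.fromkeys(raw["gene"]))
        wells = list(dict.fromkeys(zip(raw["sample"], raw["tech_rep"])))
        wide = raw.pivot_table(
            index="gene",
            columns=["sample", "tech_rep"],
            values="_cq",
            aggfunc="first",
            dropna=False,
        )
        wide = wide.reindex(index=genes, columns=pd.MultiIndex.from_tuples(wells))
        if len({t for _, t in wells}) == 1:
            wide.columns = [s for s, _ in wells]
        return CtTable(wide, design)

    raise CtDataError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")


# ---------------------------------------------------------------------------
# relative quantities

@dataclass
class RelQuantMatrix:
    """Per-gene relative quantities ``q = A^-(Cq - baseline)``.

    All quantities are positive and dimensionless; with the default
    per-gene minimum-Cq baseline, each gene's largest quantity is exactly 1.
    Carries the sample design along so that group-aware methods downstream
    need no extra bookkeeping.
    """

    q: pd.DataFrame
    reference_cq: pd.Series
    amplification_factor: pd.Series
    design: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)

    @property
    def group(self) -> pd.Series:
        return self.design.loc[self.samples, "group"]

    def log2(self) -> pd.DataFrame:
        """log2 relative quantities (missing stays missing)."""
        return np.log2(self.q)

    def subset(self, genes: Sequence[str]) -> "RelQuantMatrix":
        return RelQuantMatrix(
            self.q.loc[list(genes)],
            self.reference_cq.loc[list(genes)],
            self.amplification_factor.loc[list(genes)],
            self.design,
        )


@dataclass(frozen=True)
class EfficiencyRecord:
    """Amplification efficiency of one primer pair from a dilution series."""

    gene: str
    slope: float
    efficiency_pct: float
    r_squared: float
    n_points: int

    @property
    def amplification_factor(self) -> float:
        """Per-cycle template gain A = 1 + E/100."""
        return 1.0 + self.efficiency_pct / 100.0


def read_efficiencies(path: str | Path) -> dict[str, EfficiencyRecord]:
    """Read per-gene efficiencies from a CSV with columns
    ``gene,slope,efficiency_pct,r_squared``."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        out[str(row["gene"])] = EfficiencyRecord(
            gene=str(row["gene"]),
            slope=float(row.get("slope", np.nan)),
            efficiency_pct=float(row["efficiency_pct"]),
            r_squared=float(row.get("r_squared", np.nan)),
            n_points=int(row.get("n_points", 0)),
        )
    return out


def relative_quantities(
    table: CtTable,
    efficiencies: Mapping[str, EfficiencyRecord] | None = None,
    baseline: str = "min_cq",
) -> RelQuantMatrix:
    """Transform Cq to relative quantities ``q[g,s] = A_g^-(cq[g,s]-b_g)``.

    ``A_g`` is 2 (efficiency-naive) unless an :class:`EfficiencyRecord` is
    supplied for gene ``g``.  The per-gene baseline ``b_g`` is the minimum
    (default) or mean of the gene's non-missing Cq; with ``min_cq`` every
    gene's largest quantity is exactly 1.  Missing Cq stays missing.
    Technical replicates, if present, are mean-collapsed first.
    """
    if baseline not in ("min_cq", "mean_cq"):
        raise CtDataError(f"unknown baseline {baseline!r}")
    table = collapse(table)
    cq = table.cq
    if cq.isna().all(axis=1).any():
        dead = list(cq.index[cq.isna().all(axis=1)])
        raise CtDataError(f"genes with no Cq values at all: {dead}")

    factors = pd.Series(2.0, index=cq.index, name="amplification_factor")
    if efficiencies:
        for gene, rec in efficiencies.items():
            if gene in factors.index:
                a = rec.amplification_factor
                if a <= 1.0:
                    raise CtDataError(
                        f"efficiency for {gene} implies amplification factor "
                        f"{a:.4g} <= 1"
                    )
                factors.loc[gene] = a

    base = cq.min(axis=1) if baseline == "min_cq" else cq.mean(axis=1)
    delta = cq.sub(base, axis=0)
    q = np.power(factors.to_numpy()[:, None], -delta)
    return RelQuantMatrix(
        q=pd.DataFrame(q, index=cq.index, columns=cq.columns),
        reference_cq=base.rename("reference_cq"),
        amplification_factor=factors,
        design=table.design,
    )


# ---------------------------------------------------------------------------
# standard curves

def standard_curve_efficiency(
    dilutions: Iterable[tuple[float, float]],
    gene: str = "",
) -> EfficiencyRecord:
    """Estimate amplification efficiency from a dilution series.

    ``dilutions`` is an iterable of ``(log10 input amount, mean Cq)`` points.
    An ordinary least-squares line ``Cq = a + slope * log10(input)`` is
    fitted; for a valid curve the slope is negative and

        efficiency_pct = (10 ** (-1 / slope) - 1) * 100

    so a slope of -3.3219 (= -1/log10 2) is 100% efficiency, i.e. perfect
    doubling each cycle.  ``r_squared`` is the squared Pearson correlation.
    """
    pts = [(float(x), float(y)) for x, y in dilutions]
    xs = np.array([p[0] for p in pts])
    if len(np.unique(xs)) < 3:
        raise CtDataError("a standard curve needs >=3 distinct dilution points")
    ys = np.array([p[1] for p in pts])
    fit = stats.linregress(xs, ys)
    if fit.slope >= 0:
        raise CtDataError(
            f"invalid standard curve: slope {fit.slope:.4g} >= 0 "
            "(Cq must decrease with input amount)"
        )
    eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return EfficiencyRecord(
        gene=gene,
        slope=float(fit.slope),
        efficiency_pct=float(eff),
        r_squared=float(fit.rvalue**2),
        n_points=len(pts),
    )
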