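import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab import (
    CtDataError,
    CtTable,
    EfficiencyRecord,
    aggregate_technical_replicates,
    read_ct_table,
    relative_quantities,
    standard_curve_efficiency,
)

from conftest import make_design, make_table


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


DESIGN_4 = """\
    sample,group,bio_rep
    S1,control,1
    S2,control,2
    S3,stressed,1
    S4,stressed,2
"""


class TestReadCtTable:
    def test_wide_complete_load(self, tmp_path):
        ct = write(
            tmp_path,
            "ct.csv",
            """\
            gene,S1,S2,S3,S4
            A,20.0,20.5,21.0,21.5
            B,25.0,25.5,26.0,26.5
            C,18.0,18.1,18.2,18.3
            """,
        )
        design = write(tmp_path, "design.csv", DESIGN_4)
        table = read_ct_table(ct, design, dialect="wide")
        assert table.genes == ["A", "B", "C"]
        assert table.samples == ["S1", "S2", "S3", "S4"]
        assert table.n_missing == 0
        assert table.cq.loc["B", "S3"] == 26.0
        assert list(table.group) == ["control", "control", "stressed", "stressed"]

    def test_long_with_undetermined_well(self, tmp_path):
        ct = write(
            tmp_path,
            "ct.csv",
            """\
            gene,sample,tech_rep,cq
            A,S1,1,20.0
            A,S1,2,Undetermined
            A,S2,1,21.0
            A,S2,2,21.2
            B,S1,1,24.0
            B,S1,2,24.4
            B,S2,1,25.0
            B,S2,2,NA
            """,
        )
        design = write(
            tmp_path, "design.csv", "sample,group,bio_rep\nS1,control,1\nS2,control,2\n"
        )
        table = read_ct_table(ct, design, dialect="long")
        assert table.has_tech_reps
        assert table.n_missing == 2
        assert np.isnan(table.cq.loc["A", ("S1", "2")])
        assert table.cq.loc["B", ("S1", "2")] == 24.4

    def test_unmapped_sample_names_the_sample(self, tmp_path):
        ct = write(
            tmp_path,
            "ct.csv",
            "gene,S1,S2,S3,S4\nA,20,21,22,23\nB,24,25,26,27\n",
        )
        design = write(
            tmp_path,
            "design.csv",
            "sample,group\nS1,control\nS2,control\nS3,stressed\n",
        )
        with pytest.raises(CtDataError, match="S4"):
            read_ct_table(ct, design)

    def test_bad_token_and_duplicate_row_rejected(self, tmp_path):
        design = write(
            tmp_path, "design.csv", "sample,group\nS1,control\nS2,control\n"
        )
        bad = write(tmp_path, "bad.csv", "gene,S1,S2\nA,20,oops\nB,21,22\n")
        with pytest.raises(CtDataError, match="oops"):
            read_ct_table(bad, design)
        dup = write(
            tmp_path,
            "dup.csv",
            "gene,sample,tech_rep,cq\nA,S1,1,20\nA,S1,1,21\nA,S2,1,20\nB,S1,1,22\nB,S2,1,23\n",
        )
        with pytest.raises(CtDataError, match="duplicate"):
            read_ct_table(dup, design, dialect="long")

    def test_cq_window_enforced(self):
        with pytest.raises(CtDataError, match="outside"):
            make_table([[20, 46.0], [21, 22]], ["A", "B"], ["S1", "S2"])


class TestAggregateTechReps:
    def _tech_table(self, wells):
        cols = pd.MultiIndex.from_tuples(
            [("S1", 1), ("S1", 2), ("S1", 3)][: len(wells)] ,
            names=["sample", "tech_rep"],
        )
        df = pd.DataFrame([wells, [30.0] * len(wells)], index=["A", "B"], columns=cols)
        # second sample so the table is valid
        cols2 = pd.MultiIndex.from_tuples(
            [("S2", t) for _, t in cols], names=["sample", "tech_rep"]
        )
        df2 = pd.DataFrame(
            [[25.0] * len(wells), [31.0] * len(wells)], index=["A", "B"], columns=cols2
        )
        full = pd.concat([df, df2], axis=1)
        return CtTable(full, make_design(["S1", "S2"]))

    def test_mean_of_duplicates(self):
        table = aggregate_technical_replicates(self._tech_table([20.0, 20.4]))
        assert table.cq.loc["A", "S1"] == pytest.approx(20.2)

    def test_missing_well_ignored(self):
        table = aggregate_technical_replicates(self._tech_table([20.0, np.nan]))
        assert table.cq.loc["A", "S1"] == pytest.approx(20.0)

    def test_median_mode(self):
        table = aggregate_technical_replicates(
            self._tech_table([18.0, 19.0, 23.0]), method="median"
        )
        assert table.cq.loc["A", "S1"] == pytest.approx(19.0)

    def test_flat_table_passes_through(self):
        flat = make_table([[20, 21], [22, 23]], ["A", "B"], ["S1", "S2"])
        assert aggregate_technical_replicates(flat) is flat


class TestRelativeQuantities:
    def test_min_baseline_maps_minimum_to_one(self):
        table = make_table(
            [[20.0, 21.0, 23.0], [30.0, 28.0, 29.0]], ["A", "B"], ["S1", "S2", "S3"]
        )
        rq = relative_quantities(table)
        assert rq.q.loc["A", "S1"] == 1.0
        assert rq.q.loc["B", "S2"] == 1.0
        assert ((rq.q > 0) & (rq.q <= 1)).all().all()

    def test_known_delta_ct_values(self):
        table = make_table([[20.0, 23.3219], [20.0, 21.0]], ["A", "B"], ["S1", "S2"])
        rq = relative_quantities(table)
        assert rq.q.loc["A", "S2"] == pytest.approx(0.1, abs=1e-5)
        eff = {"B": EfficiencyRecord("B", -3.6, 90.0, 0.999, 5)}
        rq90 = relative_quantities(table, efficiencies=eff)
        assert rq90.q.loc["B", "S2"] == pytest.approx(1 / 1.9, rel=1e-12)

    def test_invalid_efficiency_rejected(self):
        table = make_table([[20, 21], [22, 23]], ["A", "B"], ["S1", "S2"])
        eff = {"A": EfficiencyRecord("A", 1.0, -100.0, 0.9, 4)}
        with pytest.raises(CtDataError, match="<= 1"):
            relative_quantities(table, efficiencies=eff)

    def test_q_monotone_decreasing_in_cq(self):
        rng = np.random.default_rng(0)
        cq = np.sort(rng.uniform(18, 30, size=8))
        table = make_table([cq, cq[::-1]], ["A", "B"], [f"s{i}" for i in range(8)])
        rq = relative_quantities(table)
        assert (np.diff(rq.q.loc["A"]) <= 0).all()

    def test_per_gene_constant_shift_leaves_row_unchanged(self):
        table = make_table(
            [[20.0, 21.0, 23.0], [30.0, 28.0, 29.0]], ["A", "B"], ["S1", "S2", "S3"]
        )
        shifted = make_table(
            [[25.0, 26.0, 28.0], [30.0, 28.0, 29.0]], ["A", "B"], ["S1", "S2", "S3"]
        )
        a = relative_quantities(table).q.loc["A"]
        b = relative_quantities(shifted).q.loc["A"]
        pd.testing.assert_series_equal(a, b)

    def test_missing_propagates_and_all_missing_gene_rejected(self):
        table = make_table(
            [[20.0, np.nan, 23.0], [30.0, 28.0, 29.0]], ["A", "B"], ["S1", "S2", "S3"]
        )
        rq = relative_quantities(table)
        assert np.isnan(rq.q.loc["A", "S2"])
        dead = make_table(
            [[np.nan, np.nan], [20.0, 21.0]], ["A", "B"], ["S1", "S2"]
        )
        with pytest.raises(CtDataError, match="A"):
            relative_quantities(dead)


class TestStandardCurve:
    def test_perfect_doubling_slope_gives_100pct(self):
        pts = [(x, 30.0 - 3.3219 * x) for x in (0.0, 1.0, 2.0, 3.0)]
        rec = standard_curve_efficiency(pts)
        assert rec.efficiency_pct == pytest.approx(100.0, abs=2e-3)
        assert rec.r_squared == pytest.approx(1.0)

    def test_known_slope_closed_form(self):
        pts = [(x, 28.0 - 3.6 * x) for x in (0.0, 1.0, 2.0)]
        rec = standard_curve_efficiency(pts)
        assert rec.efficiency_pct == pytest.approx(
            (10 ** (1 / 3.6) - 1) * 100, rel=1e-12
        )
        assert rec.efficiency_pct == pytest.approx(89.57, abs=0.01)

    def test_error_contracts(self):
        with pytest.raises(CtDataError, match=">=3"):
            standard_curve_efficiency([(0, 30), (1, 27)])
        with pytest.raises(CtDataError, match="slope"):
            standard_curve_efficiency([(0, 20), (1, 22), (2, 24)])

    @given(
        a=st.floats(1.5, 2.4),
        intercept=st.floats(20, 32),
        n=st.integers(3, 8),
    )
    @settings(max_examples=50, deadline=None)
    def test_recovers_generating_efficiency(self, a, intercept, n):
        """Exact recovery when Cq = a0 - log10(input)/log10(A)."""
        slope = -1.0 / np.log10(a)
        pts = [(float(x), intercept + slope * x) for x in range(n)]
        rec = standard_curve_efficiency(pts)
        assert rec.efficiency_pct == pytest.approx((a - 1) * 100, rel=1e-9)
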