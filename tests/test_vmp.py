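"""Variable-methylation pipeline: differences, medians, partition, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinmeth.datamodel import GROUPS, ProbeAnnotation
from twinmeth.errors import AnalysisError, DataValidationError
from twinmeth.vmp import (
    VENN_REGIONS,
    VmpConfig,
    abs_diff_matrix,
    classify_vmps,
    exceedance_fraction,
    feature_category_summary,
    group_medians,
)

from .conftest import make_beta, make_design


def medians_frame(rows, probe_ids=None):
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=list(GROUPS), index=probe_ids)


def make_annotation(entries):
    """entries: list of (probe_id, genes tuple, features tuple)."""
    return ProbeAnnotation(
        pd.DataFrame(
            [(p, "chr1", 100 + i, g, f) for i, (p, g, f) in enumerate(entries)],
            columns=["probe_id", "chromosome", "position", "genes", "features"],
        )
    )


class TestAbsDiffMatrix:
    def test_pair_difference(self):
        design = make_design(1, 1, 1)
        values = np.array([[0.30, 0.42, 0.5, 0.5, 0.7, 0.7]])
        beta = make_beta(values, design, probe_ids=["p"])
        out = abs_diff_matrix(beta, design)
        assert out.loc["p", "C1"] == pytest.approx(0.12)
        assert out.loc["p", "D1"] == 0.0
        assert out.loc["p", "H1"] == 0.0

    def test_swap_invariance(self, rng):
        design = make_design(2, 2, 2)
        values = rng.random((5, 12))
        beta = make_beta(values, design)
        base = abs_diff_matrix(beta, design)
        data = beta.data.copy()
        data[["C2_a", "C2_b"]] = data[["C2_b", "C2_a"]].to_numpy()
        swapped = make_beta(data.to_numpy(), design, probe_ids=beta.probe_ids)
        pd.testing.assert_frame_equal(base, abs_diff_matrix(swapped, design))

    def test_missing_pair_member_named(self, rng):
        design = make_design(1, 1, 1)
        beta = make_beta(rng.random((2, 6)), design)
        crippled = beta.data.drop(columns=["H1_b"])
        from twinmeth.datamodel import BetaMatrix

        with pytest.raises(DataValidationError, match="H1"):
            abs_diff_matrix(BetaMatrix(crippled), design)


class TestGroupMedians:
    def test_even_group_mean_of_central_pair(self):
        design = make_design(4, 2, 2)
        # concordant |deltas| per pair: 0.02, 0.08, 0.12, 0.40
        diffs = pd.DataFrame(
            [[0.02, 0.08, 0.12, 0.40, 0.0, 0.0, 0.0, 0.0]],
            index=["p"],
            columns=[f"C{i}" for i in range(1, 5)] + ["D1", "D2", "H1", "H2"],
        )
        out = group_medians(diffs, design)
        assert out.loc["p", "concordant"] == pytest.approx(0.10)

    def test_odd_group_outlier_insensitive(self):
        design = make_design(3, 2, 2)
        diffs = pd.DataFrame(
            [[0.1, 0.2, 0.9, 0.0, 0.0, 0.0, 0.0]],
            index=["p"],
            columns=["C1", "C2", "C3", "D1", "D2", "H1", "H2"],
        )
        assert group_medians(diffs, design).loc["p", "concordant"] == pytest.approx(0.2)

    def test_single_pair_group(self):
        design = make_design(1, 2, 2)
        diffs = pd.DataFrame(
            [[0.33, 0.0, 0.0, 0.0, 0.0]],
            index=["p"],
            columns=["C1", "D1", "D2", "H1", "H2"],
        )
        assert group_medians(diffs, design).loc["p", "concordant"] == pytest.approx(0.33)

    def test_empty_group_rejected(self):
        design = make_design(0, 2, 2)
        diffs = pd.DataFrame(
            [[0.1, 0.1, 0.1, 0.1]], index=["p"], columns=["D1", "D2", "H1", "H2"]
        )
        with pytest.raises(AnalysisError, match="concordant"):
            group_medians(diffs, design)

    def test_median_breakdown_bound(self):
        # corrupting one of >=3 values moves the median at most to the next
        # order statistic
        design = make_design(3, 2, 2)
        cols = ["C1", "C2", "C3", "D1", "D2", "H1", "H2"]
        clean = pd.DataFrame([[0.1, 0.2, 0.3, 0, 0, 0, 0]], index=["p"], columns=cols)
        corrupt = clean.copy()
        corrupt.loc["p", "C1"] = 1.0
        m0 = group_medians(clean, design).loc["p", "concordant"]
        m1 = group_medians(corrupt, design).loc["p", "concordant"]
        assert m0 == pytest.approx(0.2) and m1 == pytest.approx(0.3)
        assert abs(m1 - m0) <= 0.3 - 0.2 + 1e-12


class TestClassifyVmps:
    @pytest.mark.parametrize(
        "medians,expected",
        [
            ((0.12, 0.05, 0.02), "concordant-only"),
            ((0.12, 0.11, 0.03), "shared"),
            ((0.09, 0.09, 0.09), "none"),
            ((0.05, 0.30, 0.05), "discordant-only"),
            ((0.05, 0.05, 0.10), "healthy-only"),  # inclusive threshold
        ],
    )
    def test_labels(self, medians, expected):
        classification, _ = classify_vmps(medians_frame([medians]))
        assert classification["exclusivity"].iloc[0] == expected

    def test_venn_counts(self):
        g = medians_frame(
            [
                (0.2, 0.0, 0.0),
                (0.0, 0.2, 0.0),
                (0.0, 0.0, 0.2),
                (0.2, 0.2, 0.0),
                (0.2, 0.2, 0.2),
                (0.0, 0.0, 0.0),
                (0.0, 0.0, 0.0),
            ]
        )
        _, venn = classify_vmps(g)
        assert venn == {
            "concordant-only": 1,
            "discordant-only": 1,
            "healthy-only": 1,
            "concordant&discordant": 1,
            "concordant&healthy": 0,
            "discordant&healthy": 0,
            "concordant&discordant&healthy": 1,
            "none": 2,
        }

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_partition_law(self, seed):
        local = np.random.default_rng(seed)
        g = medians_frame(local.random((30, 3)) * 0.3)
        classification, venn = classify_vmps(g)
        assert sum(venn.values()) == 30
        assert set(venn) == set(VENN_REGIONS)
        # labels consistent with the thresholded indicators
        ind = g.to_numpy() >= 0.1
        for row, (_, rec) in zip(ind, classification.iterrows()):
            n = row.sum()
            if n == 0:
                assert rec["exclusivity"] == "none"
            elif n >= 2:
                assert rec["exclusivity"] == "shared"
            else:
                assert rec["exclusivity"] == f"{GROUPS[row.argmax()]}-only"


class TestExceedance:
    def test_all_zero(self):
        a = pd.DataFrame(np.zeros((5, 4)))
        assert exceedance_fraction(a).fraction == 0.0

    def test_inclusive_threshold(self):
        values = np.zeros((10, 5))
        values[0, 0] = 0.10  # exactly at threshold counts
        res = exceedance_fraction(pd.DataFrame(values))
        assert res == (0.02, 1, 50)

    def test_permutation_invariance(self, rng):
        values = rng.random((20, 6))
        a = pd.DataFrame(values)
        base = exceedance_fraction(a)
        shuffled = pd.DataFrame(
            values[rng.permutation(20)][:, rng.permutation(6)]
        )
        assert exceedance_fraction(shuffled) == base

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            exceedance_fraction(pd.DataFrame())


class TestFeatureCategorySummary:
    def _classification(self, labels):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(len(labels))],
                "variable_in": "",
                "exclusivity": labels,
            }
        )

    def test_all_body(self):
        cl = self._classification(["discordant-only"] * 3)
        ann = make_annotation([(f"p{i}", ("G",), ("Body",)) for i in range(3)])
        summary = feature_category_summary(cl, ann)
        assert summary["discordant-only"] == {"Body": 100.0}

    def test_fifty_fifty(self):
        cl = self._classification(["healthy-only", "healthy-only"])
        ann = make_annotation(
            [("p0", ("G",), ("TSS200",)), ("p1", ("G",), ("Body",))]
        )
        summary = feature_category_summary(cl, ann)
        assert summary["healthy-only"] == {"Body": 50.0, "TSS200": 50.0}

    def test_duplicate_category_counted_once(self):
        # annotation dedups at parse time; duplicate categories contribute once
        cl = self._classification(["concordant-only"])
        ann = make_annotation([("p0", ("G",), ("Body",))])
        summary = feature_category_summary(cl, ann)
        assert summary["concordant-only"] == {"Body": 100.0}

    def test_unannotated_bucket(self):
        cl = self._classification(["concordant-only", "concordant-only"])
        ann = make_annotation([("p0", ("G",), ("Body",))])  # p1 missing
        summary = feature_category_summary(cl, ann)
        assert summary["concordant-only"] == {"Body": 50.0, "unannotated": 50.0}

    def test_percentages_sum_to_100(self, rng):
        labels = rng.choice(
            ["concordant-only", "discordant-only", "healthy-only"], size=30
        )
        cl = self._classification(list(labels))
        cats = ["TSS1500", "TSS200", "Body", "3'UTR"]
        ann = make_annotation(
            [
                (
                    f"p{i}",
                    ("G",),
                    tuple(
                        sorted(
                            rng.choice(cats, size=rng.integers(1, 3), replace=False)
                        )
                    ),
                )
                for i in range(30)
            ]
        )
        for group, pcts in feature_category_summary(cl, ann).items():
            if pcts:
                assert sum(pcts.values()) == pytest.approx(100.0, abs=0.1)


class TestVmpConfig:
    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.2])
    def test_invalid_threshold(self, threshold):
        with pytest.raises(AnalysisError):
            VmpConfig(threshold=threshold)
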