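"""Normalization, Go-or-Grow conditions, clustering, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spherowave import (
    ModelParams,
    classify_go_or_grow,
    cluster_cell_lines,
    normalize_parameters,
    partial_correlation,
)
from spherowave.phenotype import LABEL_NONE, LABEL_POP1, LABEL_POP2


def _lines(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    for col in ("D1", "D2", "rho1", "rho2", "K1", "K2", "A2", "alpha"):
        if col not in df.columns:
            df[col] = 0.0
    return df


class TestNormalization:
    def test_identical_lines_normalize_to_one(self):
        fits = {
            f"L{i}": ModelParams("RD_ARD", D1=0.1, rho1=2, K1=0.5, D2=0.1,
                                 rho2=2, K2=0.5, A2=0.3, alpha=0.5)
            for i in range(3)
        }
        table = normalize_parameters(fits)
        np.testing.assert_allclose(table.table.to_numpy(), 1.0)

    def test_hand_arithmetic_two_lines(self):
        df = _lines(
            {
                "A": {"D1": 0.1, "D2": 0.3, "rho1": 1.0, "rho2": 1.0, "A2": 0.2},
                "B": {"D1": 0.2, "D2": 0.4, "rho1": 1.0, "rho2": 1.0, "A2": 0.2},
            }
        )
        table = normalize_parameters(df)
        # D aggregate: mean of (0.2, 0.3) = 0.25; line A's D1 normalizes to 0.4
        assert table.aggregates["D_bar"] == pytest.approx(0.25)
        assert table.table.loc["A", "D1_n"] == pytest.approx(0.1 / 0.25)

    def test_advection_ratio_is_scale_invariant(self):
        df = _lines(
            {
                "A": {"D1": 0.1, "D2": 0.1, "rho1": 1, "rho2": 1, "A2": 0.2},
                "B": {"D1": 0.1, "D2": 0.1, "rho1": 1, "rho2": 1, "A2": 0.6},
            }
        )
        t1 = normalize_parameters(df)
        df10 = df.assign(A2=df["A2"] * 10)
        t2 = normalize_parameters(df10)
        np.testing.assert_allclose(t1.table["A2_n"], t2.table["A2_n"])

    def test_degenerate_aggregate_raises(self):
        df = _lines(
            {
                "A": {"D1": 0.1, "D2": 0.1, "rho1": 1, "rho2": 1, "A2": 0.0},
                "B": {"D1": 0.1, "D2": 0.1, "rho1": 1, "rho2": 1, "A2": 0.0},
            }
        )
        with pytest.raises(ValueError, match="degenerate normalization"):
            normalize_parameters(df)


class TestGoOrGrow:
    def _table(self, rows):
        table = normalize_parameters(_lines(rows))
        return classify_go_or_grow(table, k=5.0)

    def test_migratory_second_population_detected(self):
        rows = {
            # pop 2 migrates 10x more, pop 1 proliferates 10x more
            "gog": {"D1": 0.01, "D2": 0.1, "rho1": 10.0, "rho2": 1.0, "A2": 0.3},
            "ref": {"D1": 0.05, "D2": 0.05, "rho1": 5.0, "rho2": 5.0, "A2": 0.3},
        }
        labels = self._table(rows).table["label"]
        assert labels["gog"] == LABEL_POP2
        assert labels["ref"] == LABEL_NONE

    def test_exact_boundary_is_not_go_or_grow(self):
        t = normalize_parameters(
            _lines(
                {
                    "A": {"D1": 1.0, "D2": 0.0, "rho1": 1.0, "rho2": 1.0, "A2": 1.0},
                    "B": {"D1": 1.0, "D2": 0.0, "rho1": 1.0, "rho2": 1.0, "A2": 1.0},
                }
            )
        )
        # force the exact boundary: migration ratio exactly k, growth ratio > k
        t.table.loc[:, ["D1_n", "D2_n", "A2_n"]] = [[1.0, 0.2, 0.0], [1.0, 0.2, 0.0]]
        t.table.loc[:, ["rho1_n", "rho2_n"]] = [[0.1, 1.0], [0.1, 1.0]]
        labeled = classify_go_or_grow(t, k=5.0)
        assert (labeled.table["label"] == LABEL_NONE).all()

    def test_swapping_population_roles_swaps_conditions(self):
        # the reference line carries the bulk of the advection so the
        # focal line's normalized A2 stays negligible
        rows = {
            "line": {"D1": 0.2, "D2": 0.002, "rho1": 0.1, "rho2": 2.0, "A2": 1e-4},
            "ref": {"D1": 0.05, "D2": 0.05, "rho1": 1.0, "rho2": 1.0, "A2": 0.2},
        }
        fwd = self._table(rows).table["label"]
        swapped = {
            name: {
                "D1": v["D2"] + v["A2"],  # fold advection into the migratory side
                "D2": v["D1"],
                "rho1": v["rho2"],
                "rho2": v["rho1"],
                "A2": 1e-9 if name == "line" else 2e-4,
            }
            for name, v in rows.items()
        }
        back = self._table(swapped).table["label"]
        assert fwd["line"] == LABEL_POP1
        assert back["line"] == LABEL_POP2

    @given(factor=st.floats(0.05, 50.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_labels_invariant_under_common_aggregate_rescaling(self, factor):
        """Sums-over-lines vs means: both sides of each condition rescale."""
        rows = {
            "gog": {"D1": 0.01, "D2": 0.1, "rho1": 10.0, "rho2": 1.0, "A2": 0.3},
            "mid": {"D1": 0.03, "D2": 0.05, "rho1": 3.0, "rho2": 2.0, "A2": 0.1},
            "ref": {"D1": 0.05, "D2": 0.05, "rho1": 5.0, "rho2": 5.0, "A2": 0.3},
        }
        base = normalize_parameters(_lines(rows))
        scaled = normalize_parameters(_lines(rows))
        scaled.table.loc[:, :] = scaled.table.to_numpy() * factor
        a = classify_go_or_grow(base, k=5.0).table["label"]
        b = classify_go_or_grow(scaled, k=5.0).table["label"]
        assert (a == b).all()

    @given(
        d1=st.floats(1e-6, 10.0),
        mig2=st.floats(1e-6, 10.0),
        r1=st.floats(1e-6, 10.0),
        r2=st.floats(1e-6, 10.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conditions_mutually_exclusive_at_k_one(self, d1, mig2, r1, r2):
        cond1 = (d1 > mig2) and (r2 > r1)
        cond2 = (mig2 > d1) and (r1 > r2)
        assert not (cond1 and cond2)


class TestClustering:
    def test_recovers_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0.01, 1.0], 0.002, size=(5, 2))
        b = rng.normal([0.15, 8.0], 0.002, size=(5, 2))
        df = pd.DataFrame(
            np.vstack([a, b]),
            columns=["D1", "rho1"],
            index=[f"L{i}" for i in range(10)],
        )
        res = cluster_cell_lines(df, n_clusters=2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]

    def test_singleton_cut(self):
        df = pd.DataFrame(
            {"D1": [0.1, 0.2, 0.3], "rho1": [1.0, 2.0, 3.0]},
            index=["A", "B", "C"],
        )
        res = cluster_cell_lines(df, n_clusters=3)
        assert sorted(res.labels) == [1, 2, 3]

    def test_duplicated_lines_keep_flat_labels(self):
        df = pd.DataFrame(
            {"D1": [0.01, 0.011, 0.2, 0.21], "rho1": [1.0, 1.1, 9.0, 9.2]},
            index=["A", "B", "C", "D"],
        )
        res1 = cluster_cell_lines(df, n_clusters=2)
        dup = pd.concat([df, df.set_axis(["A2", "B2", "C2", "D2"])])
        res2 = cluster_cell_lines(dup, n_clusters=2)
        # partition structure is preserved under duplication
        for x, y in (("A", "B"), ("C", "D")):
            assert (res1.labels[x] == res1.labels[y]) == (
                res2.labels[x] == res2.labels[y]
            )
        assert res2.labels["A"] == res2.labels["A2"]
        assert res2.labels["A"] != res2.labels["C"]

    def test_zero_variance_feature_dropped(self):
        df = pd.DataFrame(
            {"D1": [0.1, 0.2, 0.3], "K1": [0.5, 0.5, 0.5]},
            index=["A", "B", "C"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cluster_cell_lines(df, n_clusters=2)
        assert res.features == ["D1"]


class TestPartialCorrelation:
    def test_no_confounding_returns_input(self):
        assert partial_correlation(0.37, 0.0, 0.0) == pytest.approx(0.37)

    def test_hand_evaluated_value(self):
        assert partial_correlation(0.5, 0.5, 0.5) == pytest.approx(1 / 3)

    def test_perfectly_correlated_control_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(0.2, 1.0, 0.3)

    @given(
        r_ab=st.floats(-0.99, 0.99),
        r_ac=st.floats(-0.99, 0.99),
        r_bc=st.floats(-0.99, 0.99),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_output_always_in_unit_interval(self, r_ab, r_ac, r_bc):
        assert -1.0 <= partial_correlation(r_ab, r_ac, r_bc) <= 1.0
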