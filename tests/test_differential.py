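import numpy as np
import pandas as pd
import pytest

from mirstress.differential import (
    classify,
    classify_fixture,
    nb_wald,
    primirna_crosstab,
    restoration_summary,
    size_factors,
)
from mirstress.formats import load_table2_fixture


class TestSizeFactors:
    def test_identical_libraries(self):
        matrix = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(size_factors(matrix), [1.0, 1.0])

    def test_hand_computed_median_of_ratios(self):
        # reference row values sqrt(10*20)... -> factors 1/sqrt(2), sqrt(2)
        matrix = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        np.testing.assert_allclose(
            size_factors(matrix), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_scaling_one_library_scales_ratio(self, rng):
        matrix = pd.DataFrame(rng.integers(1, 200, size=(100, 3)), columns=list("abc"))
        base = size_factors(matrix)
        scaled = matrix.copy()
        scaled["b"] = scaled["b"] * 5
        after = size_factors(scaled)
        # scaling a library rescales the per-row reference too, so only
        # factor *ratios* track the scaling exactly
        assert (after["b"] / after["a"]) / (base["b"] / base["a"]) == pytest.approx(5.0)
        assert (after["b"] / after["c"]) / (base["b"] / base["c"]) == pytest.approx(5.0)
        assert after["a"] / after["c"] == pytest.approx(base["a"] / base["c"])

    def test_no_all_positive_row_is_error(self):
        matrix = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(matrix)


def _nb_matrix(rng, n_rows, means, dispersion, design=(3, 3)):
    n = 1.0 / dispersion
    cols = {}
    for j in range(sum(design)):
        cols[f"c{j}" if j < design[0] else f"d{j}"] = rng.negative_binomial(
            n, n / (n + means)
        )
    return pd.DataFrame(cols)


class TestNbWald:
    def test_flat_row_is_null(self, sample_sheet_6):
        libs = list(sample_sheet_6["library_id"])
        # two flat rows pin the size factors at exactly 1
        matrix = pd.DataFrame(
            [[100] * 6, [200] * 6, [30, 40, 50, 60, 70, 80]],
            index=["flat", "flat2", "vary"],
            columns=libs,
        )
        res = nb_wald(matrix, sample_sheet_6, ("drought", "control_1"))
        assert res.loc["flat", "log2fc"] == pytest.approx(0.0)
        assert res.loc["flat", "p"] == pytest.approx(1.0)
        assert res.loc["flat", "call"] == "unchanged"

    def test_missing_condition_is_error(self, sample_sheet_6):
        matrix = pd.DataFrame(
            np.ones((3, 6), dtype=int) * 10, columns=sample_sheet_6["library_id"]
        )
        with pytest.raises(ValueError, match="rehydration"):
            nb_wald(matrix, sample_sheet_6, ("rehydration", "control_1"))

    def test_bh_adjustment_invariants(self, rng, sample_sheet_6):
        means = rng.uniform(20, 500, 300)
        matrix = _nb_matrix(rng, 300, means, 0.1)
        matrix.columns = sample_sheet_6["library_id"]
        res = nb_wald(matrix, sample_sheet_6, ("drought", "control_1"))
        assert (res["padj"] >= res["p"] - 1e-12).all()
        assert (res["padj"] <= 1.0).all()
        ordered = res.sort_values("p")
        assert ordered["padj"].is_monotonic_increasing


class TestClassify:
    @pytest.mark.parametrize(
        "log2fc, padj, expected",
        [
            (1.07, 0.01, "up"),  # printed drought-up example
            (-0.40, 0.50, "unchanged"),  # large-p example
            (0.59, 0.001, "unchanged"),  # below fold-change threshold
            (0.6, 0.05, "up"),  # both boundaries inclusive
            (-0.6, 0.05, "down"),
            (-2.0, 0.051, "unchanged"),
        ],
    )
    def test_rule(self, log2fc, padj, expected):
        results = pd.DataFrame({"log2fc": [log2fc], "p": [padj], "padj": [padj]})
        assert classify(results).iloc[0] == expected

    def test_monotone_in_fold_change(self, rng):
        padj = 0.01
        fcs = np.sort(rng.uniform(0, 5, 50))
        results = pd.DataFrame({"log2fc": fcs, "p": padj, "padj": padj})
        calls = classify(results)
        # once up, stays up as |log2fc| grows
        first_up = np.argmax(calls.to_numpy() == "up")
        assert (calls.to_numpy()[first_up:] == "up").all()


class TestRestoration:
    def test_printed_table_counts(self):
        fixture = load_table2_fixture()
        drought = classify_fixture(fixture, "drought")
        rehyd = classify_fixture(fixture, "rehydration")
        summary = restoration_summary(drought, rehyd)
        assert (summary.n_up_drought, summary.n_down_drought) == (11, 38)
        assert (summary.n_up_rehyd, summary.n_down_rehyd) == (9, 16)
        assert (summary.n_restored_up, summary.n_restored_down) == (6, 27)
        assert (summary.n_common_up, summary.n_common_down) == (5, 11)

    def test_all_unchanged(self):
        calls = pd.Series("unchanged", index=list("abcd"))
        summary = restoration_summary(calls, calls)
        assert summary.n_up_drought == summary.n_down_drought == 0
        assert summary.n_restored == 0
        assert summary.n_common_unchanged == 4

    def test_matches_set_algebra_oracle(self, rng):
        names = [f"m{i}" for i in range(200)]
        calls = np.array(["up", "down", "unchanged"])
        d = pd.Series(rng.choice(calls, 200), index=names)
        r = pd.Series(rng.choice(calls, 200), index=names)
        summary = restoration_summary(d, r)
        up_d = {n for n in names if d[n] == "up"}
        down_d = {n for n in names if d[n] == "down"}
        unc_r = {n for n in names if r[n] == "unchanged"}
        assert summary.n_restored_up == len(up_d & unc_r)
        assert summary.n_restored_down == len(down_d & unc_r)
        assert summary.n_common_up == len(up_d & {n for n in names if r[n] == "up"})

    def test_name_universe_mismatch_is_error(self):
        with pytest.raises(ValueError, match="different miRNA sets"):
            restoration_summary(
                pd.Series({"a": "up"}), pd.Series({"b": "up"})
            )


class TestPrimirnaCrosstab:
    def test_all_const(self):
        calls = {f"m{i}": "const" for i in range(7)}
        table = primirna_crosstab(calls, calls)
        assert table.loc["const", "const"] == 7
        assert table.to_numpy().sum() == 7

    def test_each_cell_once(self):
        states = ["up", "down", "const"]
        pri, mat = {}, {}
        k = 0
        for i in states:
            for j in states:
                pri[f"m{k}"] = i
                mat[f"m{k}"] = j
                k += 1
        table = primirna_crosstab(pri, mat)
        assert (table.to_numpy() == np.ones((3, 3), dtype=int)).all()

    def test_matches_nested_loop_oracle(self, rng):
        states = np.array(["up", "down", "const"])
        names = [f"m{i}" for i in range(100)]
        pri = dict(zip(names, rng.choice(states, 100)))
        mat = dict(zip(names[20:], rng.choice(states, 80)))  # partial overlap
        table = primirna_crosstab(pri, mat)
        for i in states:
            for j in states:
                expected = sum(
                    1 for n in names[20:] if pri[n] == i and mat[n] == j
                )
                assert table.loc[i, j] == expected
        assert table.to_numpy().sum() == 80
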