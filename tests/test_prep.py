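"""Variable derivation, interaction pruning, design matrix, summaries."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from ra_interact import prep
from ra_interact.prep import (
    DegenerateColumnError,
    InteractionTerm,
    ValidationError,
    VariableSpec,
    build_design,
    default_variable_specs,
    derive_variables,
    expand_interactions,
    standardize,
    summarize_groups,
)
from ra_interact.synthetic import Cohort


def pruned_count_formula(c: int, b: int, g: int) -> int:
    """Closed-form pruned multiset count for c continuous, b free binaries,
    and one exclusivity group of g binaries (independent oracle)."""
    v = c + b + g
    n2 = c + comb(v, 2, exact=True) - comb(g, 2, exact=True)
    n3 = (
        c  # x^3
        + c * (v - 1)  # x^2 y
        + comb(v, 3, exact=True)
        - comb(g, 2, exact=True) * (v - g)
        - comb(g, 3, exact=True)
    )
    return n2 + n3


class TestExpandInteractions:
    def test_study_variable_set_counts(self):
        terms = expand_interactions(default_variable_specs())
        orders = Counter(t.order for t in terms)
        assert len(terms) == 475
        assert orders[2] == 91
        assert orders[3] == 384

    def test_two_continuous_variables(self):
        specs = [VariableSpec("x", "continuous"), VariableSpec("y", "continuous")]
        names = {t.name for t in expand_interactions(specs)}
        assert names == {"x*x", "x*y", "y*y", "x*x*x", "x*x*y", "x*y*y", "y*y*y"}

    def test_single_binary_yields_nothing(self):
        assert expand_interactions([VariableSpec("b", "binary")]) == []

    def test_exclusive_pair_pruned(self):
        specs = [
            VariableSpec("b1", "binary", exclusivity_group="e"),
            VariableSpec("b2", "binary", exclusivity_group="e"),
            VariableSpec("x", "continuous"),
        ]
        names = {t.name for t in expand_interactions(specs)}
        assert "b1*b2" not in names
        assert "b1*b2*x" not in names
        assert "b1*x" in names and "b2*x" in names

    def test_canonical_order_deterministic(self):
        specs = default_variable_specs()
        assert expand_interactions(specs) == expand_interactions(list(reversed(specs)))

    @settings(max_examples=20, deadline=None)
    @given(c=st.integers(0, 4), b=st.integers(0, 4), g=st.sampled_from([0, 2, 3, 4]))
    def test_count_matches_closed_form(self, c, b, g):
        if c + b + g < 1:
            return
        specs = [VariableSpec(f"c{i}", "continuous") for i in range(c)]
        specs += [VariableSpec(f"b{i}", "binary") for i in range(b)]
        specs += [VariableSpec(f"g{i}", "binary", exclusivity_group="grp") for i in range(g)]
        assert len(expand_interactions(specs)) == pruned_count_formula(c, b, g)


class TestDeriveVariables:
    def _raw(self, **overrides):
        base = {
            "age": [30.0, 17.0, 50.0],
            "sleep": [8.0, 7.0, 14.0],
            "bmi": [25.0, 22.0, 30.0],
            "ipr": [2.0, 1.0, 3.0],
            "male": [1, 0, 1],
            "gout": [0, 0, 1],
            "diabetes": [0, 1, 0],
            "smoked": [1, 1, 0],
            "eth": ["white", "black", "onh"],
            "ra": [0, 0, 1],
        }
        for i in range(1, 10):
            base[f"phq{i}"] = [3.0, 1.0, 0.0]
        for i in range(1, 5):
            base[f"bp{i}"] = [120.0, 122.0, 118.0]
        base["bp1"] = [120.0, 122.0, 118.0]
        base.update(overrides)
        return pd.DataFrame(base)

    def test_phq_sum_and_bp_mean(self):
        raw = self._raw()
        raw.loc[0, ["bp1", "bp2", "bp3", "bp4"]] = [120.0, 122.0, 118.0, 120.0]
        out = derive_variables(raw).frame
        assert out.loc[0, "phq"] == 27.0  # nine items of 3
        assert out.loc[0, "bp"] == 120.0

    def test_age_seventeen_excluded(self):
        log = []
        out = derive_variables(self._raw(), log=log).frame
        assert 17.0 not in out["age"].to_numpy()
        assert log[0]["excluded_age"] == 1

    def test_complete_case_filter(self):
        raw = self._raw()
        raw.loc[2, "bmi"] = np.nan
        log = []
        out = derive_variables(raw, log=log).frame
        assert len(out) == 1  # row1 dropped by age, row2 by missing BMI
        assert log[0]["excluded_missing"] == 1

    def test_sleep_capped_at_twelve(self):
        out = derive_variables(self._raw()).frame
        assert out["sleep"].max() <= 12.0

    def test_ethnicity_dummies_reference_white(self):
        out = derive_variables(self._raw()).frame
        assert {"eth_ma", "eth_oh", "eth_black", "eth_onh"} <= set(out.columns)
        white_row = out[out["eth_onh"] + out["eth_black"] + out["eth_ma"] + out["eth_oh"] == 0]
        assert len(white_row) == 1  # the age-30 white participant

    def test_phq_item_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            derive_variables(self._raw(phq4=[5.0, 1.0, 0.0]))

    def test_unknown_ethnicity_rejected(self):
        with pytest.raises(ValidationError):
            derive_variables(self._raw(eth=["white", "martian", "onh"]))


class TestBuildDesign:
    def test_study_column_total(self, small_cohort):
        specs = default_variable_specs()
        design = build_design(small_cohort, specs)
        assert len(design.column_names) == 489
        assert design.column_names[:14] == [s.name for s in specs]

    def test_zero_row_zeroes_all_age_terms(self):
        specs = [VariableSpec("age", "continuous"), VariableSpec("bmi", "continuous")]
        frame = pd.DataFrame({"age": [0.0, 2.0], "bmi": [3.0, 4.0]})
        design = build_design(frame, specs)
        row0 = design.values.iloc[0]
        for name in design.column_names:
            if "age" in name:
                assert row0[name] == 0.0

    def test_binary_product(self):
        specs = [VariableSpec("male", "binary"), VariableSpec("gout", "binary")]
        frame = pd.DataFrame({"male": [1, 1, 0], "gout": [1, 0, 1]})
        design = build_design(frame, specs)
        assert design.values["gout*male"].tolist() == [1.0, 0.0, 0.0]

    def test_row_permutation_equivariance(self, small_cohort):
        specs = default_variable_specs()
        design = build_design(small_cohort, specs)
        perm = np.random.default_rng(0).permutation(small_cohort.n)
        shuffled = Cohort(small_cohort.frame.iloc[perm].reset_index(drop=True))
        design_p = build_design(shuffled, specs)
        np.testing.assert_array_equal(
            design.values.to_numpy()[perm], design_p.values.to_numpy()
        )

    def test_unknown_factor_raises(self):
        specs = [VariableSpec("ghost", "continuous"), VariableSpec("x", "continuous")]
        with pytest.raises(KeyError):
            build_design(pd.DataFrame({"x": [1.0, 2.0]}), specs)


class TestStandardize:
    def _design(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            {"age": rng.normal(50, 10, n), "bmi": rng.normal(28, 5, n),
             "male": rng.integers(0, 2, n)}
        )
        specs = [
            VariableSpec("age", "continuous"),
            VariableSpec("bmi", "continuous"),
            VariableSpec("male", "binary"),
        ]
        return build_design(frame, specs)

    def test_training_rows_have_zero_mean_unit_sd(self):
        design = standardize(self._design(), np.arange(100))
        vals = design.values.to_numpy()[:100]
        for j, is_quant in enumerate(design.quantitative):
            if is_quant:
                assert abs(vals[:, j].mean()) < 1e-10
                assert abs(vals[:, j].std(ddof=0) - 1.0) < 1e-10

    def test_validation_rows_use_training_statistics(self):
        design = standardize(self._design(), np.arange(100))
        held = design.values.to_numpy()[100:]
        means = held.mean(axis=0)
        assert np.any(np.abs(means) > 1e-3)  # not re-centered on their own stats

    def test_binary_columns_stay_binary(self):
        design = standardize(self._design(), np.arange(100))
        assert set(np.unique(design.values["male"])) <= {0.0, 1.0}

    def test_round_trip_destandardization(self):
        raw = self._design()
        expected = raw.values.to_numpy().copy()
        design = standardize(raw, np.arange(100))
        back = design.destandardize().to_numpy()
        np.testing.assert_allclose(back, expected, atol=1e-12)

    def test_constant_column_raises_named_error(self):
        design = self._design()
        design.values["age"] = 1.0
        with pytest.raises(DegenerateColumnError, match="age"):
            standardize(design, np.arange(100))

    def test_drop_degenerate_removes_empty_products(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {"age": rng.normal(50, 10, 50), "male": np.zeros(50, dtype=int)}
        )
        specs = [VariableSpec("age", "continuous"), VariableSpec("male", "binary")]
        design = build_design(frame, specs)
        reduced, dropped = prep.drop_degenerate(design, np.arange(50))
        assert "male" in dropped and "age*male" in dropped
        assert all("male" not in n for n in reduced.column_names)
        assert "age" in reduced.column_names


class TestSummarizeGroups:
    def _printed_counts_cohort(self):
        """Cohort reconstructed from the printed per-variable study counts."""
        n_ra, n_none = 1143, 16223
        rows = {"ra": np.r_[np.ones(n_ra, dtype=int), np.zeros(n_none, dtype=int)]}

        def bin_col(count_ra, count_none):
            return np.r_[
                np.r_[np.ones(count_ra), np.zeros(n_ra - count_ra)],
                np.r_[np.ones(count_none), np.zeros(n_none - count_none)],
            ]

        rows["male"] = bin_col(473, 8523)
        rows["gout"] = bin_col(122, 406)
        rows["diabetes"] = bin_col(308, 1480)
        rows["smoked"] = bin_col(643, 6769)
        return Cohort(pd.DataFrame(rows))

    def test_printed_percentages_recomputed(self):
        table = summarize_groups(self._printed_counts_cohort())
        t = table.set_index(["group", "variable"])
        assert t.loc[("case", "male"), "percent"] == pytest.approx(41.4, abs=0.05)
        assert t.loc[("case", "gout"), "percent"] == pytest.approx(10.7, abs=0.05)
        assert t.loc[("case", "diabetes"), "percent"] == pytest.approx(26.9, abs=0.05)
        assert t.loc[("control", "gout"), "percent"] == pytest.approx(2.50, abs=0.005)

    def test_percentages_sum_over_levels(self, small_cohort):
        frame = small_cohort.frame.copy()
        frame["eth_white"] = 1 - frame[["eth_ma", "eth_oh", "eth_black", "eth_onh"]].sum(axis=1)
        table = summarize_groups(Cohort(frame))
        t = table.set_index(["group", "variable"])
        for group in ("case", "control"):
            total = sum(
                t.loc[(group, v), "percent"]
                for v in ("eth_ma", "eth_oh", "eth_black", "eth_onh", "eth_white")
            )
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_single_group_constant_variable(self):
        frame = pd.DataFrame({"ra": [1, 1, 1], "gout": [1, 1, 1], "age": [50.0] * 3})
        table = summarize_groups(Cohort(frame))
        t = table.set_index(["group", "variable"])
        assert t.loc[("case", "gout"), "percent"] == 100.0
        assert t.loc[("case", "age"), "sd"] == 0.0
        assert (table[table["group"] == "control"]["note"] == "empty group").all()

    def test_nonbinary_outcome_rejected(self):
        frame = pd.DataFrame({"ra": [0, 1, 2], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            summarize_groups(Cohort(frame))
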