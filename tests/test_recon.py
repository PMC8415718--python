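"""Coefficient reconstruction, HDIs, direction-probability ranking."""

import numpy as np
import pandas as pd
import pytest

from ra_interact.bayes import BayesianLogit
from ra_interact.famd import FAMD
from ra_interact.recon import (
    binary_effect,
    hdi,
    interaction_report,
    rank_variables,
    reconstruct,
)


def quant_famd(rng, n=300, k=8):
    frame = pd.DataFrame(
        rng.normal(size=(n, k)) @ (np.eye(k) + 0.3 * rng.normal(size=(k, k))),
        columns=[f"q{j}" for j in range(k)],
    )
    return frame, FAMD(quantitative=frame).fit()


class TestReconstruct:
    def test_one_hot_draw_returns_row_of_vt(self):
        rng = np.random.default_rng(0)
        _, res = quant_famd(rng)
        m = res.n_retained
        for j in (0, m - 1):
            A = np.zeros((1, m))
            A[0, j] = 1.0
            rec = reconstruct(A, res)
            np.testing.assert_allclose(rec.B[0], res.V[:, j], atol=1e-12)

    def test_unselected_columns_are_zeroed(self):
        rng = np.random.default_rng(1)
        _, res = quant_famd(rng)
        m = res.n_retained
        A = rng.normal(size=(5, m))
        selected = np.zeros(m, dtype=int)
        selected[:3] = 1
        rec = reconstruct(A, res, selected=selected)
        A_masked = A.copy()
        A_masked[:, 3:] = 0.0
        np.testing.assert_allclose(rec.B, A_masked @ res.V.T, atol=1e-12)

    def test_compact_draw_matrix_expanded(self):
        rng = np.random.default_rng(2)
        _, res = quant_famd(rng)
        m = res.n_retained
        selected = np.zeros(m, dtype=int)
        selected[[1, 4]] = 1
        A_compact = rng.normal(size=(7, 2))
        rec = reconstruct(A_compact, res, selected=selected)
        assert rec.B.shape == (7, len(res.column_names))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        _, res = quant_famd(rng)
        with pytest.raises(ValueError):
            reconstruct(np.zeros((2, res.n_retained + 1)), res)

    def test_linear_predictor_equivalence(self):
        """Defining identity: scores @ a == weighted data @ (V_r a) per draw."""
        rng = np.random.default_rng(4)
        _, res = quant_famd(rng)
        kept = res.retain(0.5)
        S = kept.training_scores().to_numpy()
        A = rng.normal(size=(20, kept.n_retained))
        rec = reconstruct(A, kept)
        lhs = S @ A.T
        rhs = kept._M @ rec.B.T
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_full_rank_round_trip_matches_direct_regression(self):
        """All components + flat-prior MLE in synthetic space reproduces the
        direct original-space regression's predictions and coefficients."""
        rng = np.random.default_rng(5)
        frame, res = quant_famd(rng, n=300, k=8)
        eta = 0.4 * frame["q0"].to_numpy() - 0.3 * frame["q3"].to_numpy()
        y = (rng.random(len(frame)) < 1 / (1 + np.exp(-eta))).astype(int)

        S = res.training_scores().to_numpy()  # all 8 components
        fit_syn = BayesianLogit(y, S).fit_mle()
        rec = reconstruct(fit_syn.params[None, 1:], res)

        Z = res._M  # standardized columns
        fit_dir = BayesianLogit(y, Z).fit_mle()
        np.testing.assert_allclose(rec.B[0], fit_dir.params[1:], atol=1e-6)
        eta_syn = fit_syn.params[0] + S @ fit_syn.params[1:]
        eta_dir = fit_dir.params[0] + Z @ fit_dir.params[1:]
        np.testing.assert_allclose(eta_syn, eta_dir, atol=1e-6)


class TestBinaryEffect:
    def _mixed(self, rng):
        quant = pd.DataFrame({"x": rng.normal(size=200), "z": rng.normal(size=200)})
        qual = pd.DataFrame({"b": rng.integers(0, 2, 200)})
        return FAMD(quant, qual).fit()

    def test_equal_indicator_coefficients_cancel_when_weighted_equally(self):
        rng = np.random.default_rng(6)
        res = self._mixed(rng)
        rec = reconstruct(np.zeros((3, res.n_retained)), res)
        np.testing.assert_allclose(binary_effect(rec, "b=1", "b=0"), 0.0)

    def test_difference_arithmetic(self):
        rng = np.random.default_rng(7)
        res = self._mixed(rng)
        rec = reconstruct(np.zeros((1, res.n_retained)), res)
        j_on = rec.column_names.index("b=1")
        j_off = rec.column_names.index("b=0")
        rec.B[0, j_on] = 0.3 * rec.weights[j_on]
        rec.B[0, j_off] = 0.1 * rec.weights[j_off]
        assert binary_effect(rec, "b=1", "b=0")[0] == pytest.approx(0.2)

    def test_constant_shift_of_deweighted_coefficients_cancels(self):
        rng = np.random.default_rng(8)
        res = self._mixed(rng)
        rec = reconstruct(rng.normal(size=(4, res.n_retained)), res)
        base = binary_effect(rec, "b=1", "b=0")
        j_on = rec.column_names.index("b=1")
        j_off = rec.column_names.index("b=0")
        rec.B[:, j_on] += 1.7 * rec.weights[j_on]
        rec.B[:, j_off] += 1.7 * rec.weights[j_off]
        np.testing.assert_allclose(binary_effect(rec, "b=1", "b=0"), base + 0.0, atol=1e-12)

    def test_missing_indicator_rejected(self):
        rng = np.random.default_rng(9)
        res = self._mixed(rng)
        rec = reconstruct(np.zeros((1, res.n_retained)), res)
        with pytest.raises(KeyError):
            binary_effect(rec, "b=1", "ghost=0")

    def test_flip_effect_matches_fitted_binary_coefficient(self):
        """De-weighted indicator difference recovers the per-flip log-OR of a
        direct logistic fit (full retention)."""
        rng = np.random.default_rng(10)
        quant = pd.DataFrame({"x": rng.normal(size=2000), "z": rng.normal(size=2000)})
        b = rng.integers(0, 2, 2000)
        eta = -0.5 + 0.8 * b + 0.3 * quant["x"].to_numpy()
        y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)
        res = FAMD(quant, pd.DataFrame({"b": b})).fit()
        S = res.training_scores().to_numpy()
        fit_syn = BayesianLogit(y, S).fit_mle()
        rec = reconstruct(fit_syn.params[None, 1:], res)
        flip = binary_effect(rec, "b=1", "b=0")[0]

        direct = BayesianLogit(
            y, np.column_stack([b, quant["x"], quant["z"]])
        ).fit_mle()
        assert flip == pytest.approx(direct.params[1], abs=1e-6)


class TestHDI:
    def test_constant_samples(self):
        assert hdi(np.full(10, 3.3), 0.5) == (3.3, 3.3)

    def test_standard_normal_99(self):
        x = np.random.default_rng(11).standard_normal(1_000_000)
        lo, hi = hdi(x, 0.99)
        assert lo == pytest.approx(-2.576, abs=0.05)
        assert hi == pytest.approx(2.576, abs=0.05)

    def test_exponential_half_mass_starts_at_zero(self):
        x = np.random.default_rng(12).exponential(1.0, 100_000)
        lo, hi = hdi(x, 0.5)
        assert lo == pytest.approx(0.0, abs=0.02)
        assert hi == pytest.approx(np.log(2), abs=0.03)

    def test_nesting_of_masses(self):
        x = np.random.default_rng(13).standard_normal(5_000)
        lo50, hi50 = hdi(x, 0.50)
        lo99, hi99 = hdi(x, 0.99)
        assert lo99 <= lo50 <= hi50 <= hi99

    def test_validation(self):
        with pytest.raises(ValueError):
            hdi([], 0.5)
        with pytest.raises(ValueError):
            hdi([1.0, 2.0], 1.5)


class TestRanking:
    def test_direction_probability_extremes(self):
        draws = pd.DataFrame(
            {
                "age": np.full(100, 0.2),  # all odds > 1
                "bmi": np.r_[np.full(50, 0.1), np.full(50, -0.1)],  # symmetric
            }
        )
        ranked = rank_variables(draws).set_index("variable")
        assert ranked.loc["age", "direction_prob"] == 1.0
        assert ranked.loc["bmi", "direction_prob"] == pytest.approx(0.5)
        assert ranked.loc["age", "rank"] < ranked.loc["bmi", "rank"]

    def test_tie_break_by_median_distance(self):
        draws = pd.DataFrame(
            {"strong": np.full(50, np.log(1.5)), "weak": np.full(50, np.log(1.2))}
        )
        ranked = rank_variables(draws)
        assert ranked.iloc[0]["variable"] == "strong"

    def test_protective_effects_rank_symmetrically(self):
        draws = pd.DataFrame(
            {"protective": np.full(50, np.log(0.5)), "mild_risk": np.full(50, np.log(1.1))}
        )
        ranked = rank_variables(draws)
        assert ranked.iloc[0]["variable"] == "protective"

    def test_hdi_nesting_in_output(self):
        rng = np.random.default_rng(14)
        draws = pd.DataFrame({"age": rng.normal(0.1, 0.05, 2000)})
        row = rank_variables(draws).iloc[0]
        assert row["hdi99_lower"] <= row["hdi50_lower"] <= row["hdi50_upper"] <= row["hdi99_upper"]

    def test_ranks_unique_and_dense(self):
        rng = np.random.default_rng(15)
        draws = pd.DataFrame({f"v{i}": rng.normal(0, 0.1, 200) for i in range(20)})
        ranked = rank_variables(draws)
        assert sorted(ranked["rank"]) == list(range(1, 21))


class TestInteractionReport:
    def _summaries(self):
        rng = np.random.default_rng(16)
        names = ["age", "bmi", "age*bmi", "age*age", "age*bmi*bp", "bmi*bp*phq"]
        draws = pd.DataFrame({n: rng.normal(0, 0.1, 100) for n in names})
        return rank_variables(draws)

    def test_order_filter_and_display_names(self):
        rep = interaction_report(self._summaries(), order=2)
        assert set(rep["variable"]) == {"age*bmi", "age*age"}
        assert set(rep["display"]) == {"age·bmi", "age·age"}

    def test_top_k_larger_than_available(self):
        rep = interaction_report(self._summaries(), order=1, top_k=50)
        assert len(rep) == 2

    def test_orders_partition_summary(self):
        s = self._summaries()
        total = sum(len(interaction_report(s, order=o)) for o in (1, 2, 3))
        assert total == len(s)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            interaction_report(self._summaries(), order=4)


class TestNullCalibration:
    def test_null_pipeline_false_positive_rate(self, schema, null_truth):
        """With no true effects, <= 5% of variables' 99% HDIs exclude 1."""
        from ra_interact import prep, synthetic
        from ra_interact.pipeline import reconstructed_effect_draws

        cohort = synthetic.generate_cohort(schema, null_truth, 3000, seed=21)
        specs = prep.default_variable_specs()
        design = prep.build_design(cohort, specs)
        idx = np.arange(cohort.n)
        design, _ = prep.drop_degenerate(design, idx)
        design = prep.standardize(design, idx)
        quant = [t.name for t, q in zip(design.terms, design.quantitative) if q]
        qual = [t.name for t, q in zip(design.terms, design.quantitative) if not q]
        res = FAMD(design.values[quant], design.values[qual]).fit().retain(1.0)
        S = res.training_scores().to_numpy()
        y = cohort.frame["ra"].to_numpy()
        post = BayesianLogit(y, S).fit(chains=4, draws=200, warmup=300, seed=2)
        rec = reconstruct(post.draws[:, 1:], res)
        draws = reconstructed_effect_draws(rec, design, idx)
        ranked = rank_variables(draws)
        exclude = ((ranked["hdi99_lower"] > 1) | (ranked["hdi99_upper"] < 1)).mean()
        assert exclude <= 0.05
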