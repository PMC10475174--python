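"""Parental-age models: join semantics, OLS correctness against a
normal-equations oracle, CI coverage, and model-form contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from dnvqc import (
    ContractError,
    DNVWarning,
    ParentalAgeRecord,
    SimConfig,
    ValidationError,
    fit_parental_model,
    join_counts_ages,
    simulate_parental_ages,
)


def ages_df(rows):
    return pd.DataFrame(rows, columns=["sample", "fatherAge", "motherAge"])


class TestJoin:
    def test_inner_join(self):
        out = join_counts_ages(
            {"s1": 70, "s2": 55},
            ages_df([("s1", 30.0, 28.0), ("s2", 22.0, 24.0)]),
        )
        assert [r.sample for r in out] == ["s1", "s2"]
        assert out[0] == ParentalAgeRecord("s1", 70, 30.0, 28.0)

    def test_partial_overlap_warns_by_name(self):
        with pytest.warns(DNVWarning) as caught:
            out = join_counts_ages(
                {"s1": 70, "s2": 55}, ages_df([("s1", 30.0, 28.0), ("s3", 40.0, 39.0)])
            )
        assert len(out) == 1
        messages = " ".join(str(w.message) for w in caught)
        assert "s2" in messages and "s3" in messages

    def test_empty_intersection_is_error(self):
        with pytest.warns(DNVWarning), pytest.raises(ValidationError):
            join_counts_ages({"s1": 70}, ages_df([("s9", 30.0, 28.0)]))

    def test_empty_input_is_contract_error(self):
        with pytest.raises(ContractError):
            join_counts_ages({}, ages_df([("s1", 30.0, 28.0)]))


def noiseless_records(intercept=20.0, bf=1.5, bm=0.5, n=10):
    """Counts exactly linear in the ages (ages chosen so counts are ints)."""
    recs = []
    for i in range(n):
        f, m = 20.0 + 2 * i, 24.0 + 2 * ((i * 3) % n)
        recs.append(
            ParentalAgeRecord(
                f"s{i}", int(round(intercept + bf * f + bm * m)), f, m
            )
        )
    return recs


@pytest.fixture(scope="module")
def noisy():
    cfg = SimConfig(seed=42, n_samples=200, age_model=(20.0, 1.2, 0.6, 5.0))
    counts, ages = simulate_parental_ages(cfg)
    return join_counts_ages(counts, ages)


class TestLinearFit:
    def test_noiseless_exact_recovery(self):
        fit = fit_parental_model(noiseless_records(), "linear", "both")
        assert fit.coefficients["intercept"] == pytest.approx(20.0, abs=1e-8)
        assert fit.coefficients["fatherAge"] == pytest.approx(1.5, abs=1e-8)
        assert fit.coefficients["motherAge"] == pytest.approx(0.5, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        for term, (lo, hi) in fit.ci95.items():
            assert lo <= fit.coefficients[term] <= hi

    def test_matches_normal_equations_oracle(self, noisy):
        """OLS coefficients agree with an independent solve of X'Xb = X'y
        to 1e-8, and the residuals are orthogonal to every design column."""
        fit = fit_parental_model(noisy, "linear", "both")
        X = np.column_stack(
            [
                np.ones(len(noisy)),
                [r.fatherAge for r in noisy],
                [r.motherAge for r in noisy],
            ]
        )
        y = np.array([r.dnm_counts for r in noisy], dtype=float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = [
            fit.coefficients["intercept"],
            fit.coefficients["fatherAge"],
            fit.coefficients["motherAge"],
        ]
        np.testing.assert_allclose(got, beta, atol=1e-8)
        resid = y - X @ beta
        assert np.max(np.abs(X.T @ resid)) < 1e-6 * len(noisy)
        # SEs from the unbiased residual variance
        s2 = resid @ resid / (len(noisy) - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(
            [fit.standard_errors[t] for t in ("intercept", "fatherAge", "motherAge")],
            se,
            atol=1e-8,
        )

    def test_cis_cover_true_slopes(self, noisy):
        fit = fit_parental_model(noisy, "linear", "both")
        lo, hi = fit.ci95["fatherAge"]
        assert lo <= 1.2 <= hi
        lo, hi = fit.ci95["motherAge"]
        assert lo <= 0.6 <= hi
        assert fit.n == 200 and fit.residual_df == 197

    def test_pearson_correlations_reported(self, noisy):
        fit = fit_parental_model(noisy, "linear", "both")
        assert set(fit.pearson_r) == {"fatherAge", "motherAge"}
        assert 0 < fit.pearson_r["fatherAge"] <= 1

    def test_single_predictor_is_refit_not_extracted(self, noisy):
        """father_only refits a reduced design; with correlated responses
        its slope differs from the joint fit's fatherAge coefficient and
        matches a direct least-squares solve on [1, fatherAge]."""
        joint = fit_parental_model(noisy, "linear", "both")
        father = fit_parental_model(noisy, "linear", "father_only")
        X = np.column_stack([np.ones(len(noisy)), [r.fatherAge for r in noisy]])
        y = np.array([r.dnm_counts for r in noisy], dtype=float)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert father.coefficients["fatherAge"] == pytest.approx(beta[1], abs=1e-8)
        assert "motherAge" not in father.coefficients
        assert father.coefficients["fatherAge"] != pytest.approx(
            joint.coefficients["fatherAge"], abs=1e-12
        )

    def test_r2_invariant_under_predictor_rescaling(self, noisy):
        fit = fit_parental_model(noisy, "linear", "both")
        scaled = [
            ParentalAgeRecord(r.sample, r.dnm_counts, 2 * r.fatherAge, r.motherAge)
            for r in noisy
        ]
        fit2 = fit_parental_model(scaled, "linear", "both")
        assert fit2.r_squared == pytest.approx(fit.r_squared, abs=1e-10)
        assert fit2.coefficients["fatherAge"] == pytest.approx(
            fit.coefficients["fatherAge"] / 2, abs=1e-10
        )

    def test_ci_coverage_over_replicates(self):
        """Across 200 simulated replicates (true slopes 1.2 and 0.6,
        Gaussian noise sd 5, n=200), the 95% CI covers each true slope
        between 90% and 99% of the time."""
        cover_f = cover_m = 0
        reps = 200
        for i in range(reps):
            cfg = SimConfig(
                seed=10_000 + i, n_samples=200, age_model=(20.0, 1.2, 0.6, 5.0)
            )
            counts, ages = simulate_parental_ages(cfg)
            fit = fit_parental_model(join_counts_ages(counts, ages))
            lo, hi = fit.ci95["fatherAge"]
            cover_f += lo <= 1.2 <= hi
            lo, hi = fit.ci95["motherAge"]
            cover_m += lo <= 0.6 <= hi
        assert 0.90 <= cover_f / reps <= 0.99
        assert 0.90 <= cover_m / reps <= 0.99


class TestExponentialFit:
    def test_log_linear_recovery(self):
        rng = np.random.default_rng(8)
        recs = []
        for i in range(60):
            f = float(rng.uniform(20, 50))
            m = float(rng.uniform(20, 45))
            y = int(round(math.exp(4.0 + 0.02 * f + 0.01 * m)))
            recs.append(ParentalAgeRecord(f"s{i}", y, f, m))
        fit = fit_parental_model(recs, "exponential", "both")
        assert fit.coefficients["fatherAge"] == pytest.approx(0.02, abs=0.002)
        assert fit.coefficients["motherAge"] == pytest.approx(0.01, abs=0.002)
        assert fit.r_squared > 0.98

    def test_zero_count_names_sample(self):
        recs = noiseless_records()
        recs[3] = ParentalAgeRecord("s3", 0, 30.0, 28.0)
        with pytest.raises(ValidationError, match="s3"):
            fit_parental_model(recs, "exponential", "both")


class TestFitContracts:
    def test_rank_deficient_design_rejected(self):
        recs = [ParentalAgeRecord(f"s{i}", 60 + i, 30.0, 20.0 + i) for i in range(9)]
        with pytest.raises(ValidationError, match="rank"):
            fit_parental_model(recs, "linear", "both")
        # but the constant column is fine for the other predictor alone
        fit_parental_model(recs, "linear", "mother_only")

    def test_missing_ages_dropped_with_warning(self):
        recs = noiseless_records()
        recs.append(ParentalAgeRecord("s_na", 75, math.nan, 30.0))
        with pytest.warns(DNVWarning, match="s_na"):
            fit = fit_parental_model(recs, "linear", "both")
        assert fit.n == len(recs) - 1

    def test_too_few_samples(self):
        with pytest.raises(ContractError):
            fit_parental_model(noiseless_records(n=3), "linear", "both")

    def test_unknown_forms_rejected(self):
        recs = noiseless_records()
        with pytest.raises(ContractError):
            fit_parental_model(recs, "poisson", "both")
        with pytest.raises(ContractError):
            fit_parental_model(recs, "linear", "parents")
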