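"""Association strategies: likelihood oracles, symmetry, recovery, QC."""

import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

import ascnassoc as aa
from ascnassoc.model import STATE_INDEX
from ascnassoc.simulate import CALL_MISSING, cohort_from_counts


def _loglik(x, y, alpha, beta):
    eta = alpha + beta * x
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def grid_search_loglik(x, y, half_width=32.0, rounds=10, n=61):
    """Independent maximum-likelihood oracle: nested dense grid search.

    The refinement window shrinks slowly (keeping several coarse cells) so
    the search tracks the diagonal likelihood valley of correlated
    intercept/slope parameters.
    """
    a0, b0, w = 0.0, 0.0, half_width
    for _ in range(rounds):
        alphas = a0 + np.linspace(-w, w, n)
        betas = b0 + np.linspace(-w, w, n)
        lls = np.array([[_loglik(x, y, a, b) for b in betas] for a in alphas])
        i, j = np.unravel_index(np.argmax(lls), lls.shape)
        a0, b0 = alphas[i], betas[j]
        w = 8 * w / (n - 1)
    return float(lls[i, j])


def expected_score_optimum(spec, risk, x_of_state):
    """Pseudo-true (alpha, beta) of a 1-df trend model under the design.

    Maximizes the expected per-individual log-likelihood of the equal-n
    case-control mixture over the analytic state distributions.
    """
    ctrl = np.array(aa.control_state_frequencies(spec).as_vector())
    case = np.array(
        aa.case_state_frequencies(aa.control_state_frequencies(spec), risk).as_vector()
    )
    x = np.asarray(x_of_state, dtype=float)

    def neg(theta):
        eta = theta[0] + theta[1] * x
        log_p = -np.logaddexp(0, -eta)
        log_q = -np.logaddexp(0, eta)
        return -0.5 * float(case @ log_p + ctrl @ log_q)

    res = minimize(neg, [0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    assert res.success
    return res.x


def _balanced_null_cohort():
    counts = np.zeros(15, dtype=int)
    for lab, n in (("AA", 40), ("AB", 30), ("BB", 10), ("A", 10), ("ABB", 10)):
        counts[STATE_INDEX[aa.AscnState.from_label(lab)]] = n
    return cohort_from_counts(counts, counts)


class TestTrendFits:
    def test_balanced_cohort_gives_null(self):
        cohort = _balanced_null_cohort()
        for fit_fn in (aa.fit_cn, aa.fit_allele_multi, aa.fit_joint):
            fit = fit_fn(cohort)
            assert fit.lrt == pytest.approx(0.0, abs=1e-8)
            assert fit.p_value == pytest.approx(1.0)

    def test_constant_covariate_flagged(self):
        counts = np.zeros(15, dtype=int)
        counts[STATE_INDEX[aa.AscnState(2, 0)]] = 30
        counts[STATE_INDEX[aa.AscnState(1, 1)]] = 30
        cohort = cohort_from_counts(counts, counts)  # all CN=2
        fit = aa.fit_cn(cohort)
        assert not fit.converged
        assert fit.p_value is None

    def test_loglik_matches_grid_search_small_cohorts(self, rng):
        """MLE log-likelihood vs a dense nested grid search, cohorts of <= 8."""
        for trial in range(6):
            n = int(rng.integers(4, 9))
            state_idx = rng.integers(0, 15, size=n).astype(np.int8)
            pheno = rng.integers(0, 2, size=n).astype(np.int8)
            if len(set(pheno)) < 2:
                pheno[0], pheno[-1] = 0, 1
            cohort = aa.Cohort(state_idx, pheno)
            for fit_fn, x in (
                (aa.fit_cn, cohort.cn),
                (aa.fit_allele_multi, cohort.b_count),
            ):
                fit = fit_fn(cohort)
                if not fit.converged:
                    continue  # separation: grid oracle unbounded too
                oracle = grid_search_loglik(x.astype(float), pheno.astype(float))
                assert fit.loglik_full == pytest.approx(oracle, abs=1e-4)

    def test_matches_statsmodels_glm(self, spec_both):
        cohort = aa.simulate_cohort(spec_both, aa.RiskModel(1.3, 1.4), 800, 800, 21)
        y = cohort.phenotype.astype(float)
        for fit_fn, X in (
            (aa.fit_cn, cohort.cn[:, None]),
            (aa.fit_allele_multi, cohort.b_count[:, None]),
            (aa.fit_joint, np.column_stack([cohort.cn, cohort.a_count - cohort.b_count])),
        ):
            fit = fit_fn(cohort)
            ref = sm.GLM(y, sm.add_constant(X.astype(float)), family=sm.families.Binomial()).fit()
            coefs = np.array(list(fit.coef.values()))
            assert coefs == pytest.approx(ref.params, abs=1e-6)
            assert fit.loglik_full == pytest.approx(ref.llf, abs=1e-6)

    def test_coefficient_recovery_single_effects(self, spec_both):
        # with a single simulated effect the trend model is correctly
        # specified, so the estimate sits near the simulated log RR
        for risk, fit_fn, truth in (
            (aa.RiskModel(1.5, 1.0), aa.fit_cn, math.log(1.5)),
            (aa.RiskModel(1.0, 1.5), aa.fit_allele_multi, math.log(1.5)),
        ):
            x_of_state = (
                [s.cn for s in aa.STATES]
                if fit_fn is aa.fit_cn
                else [s.b_count for s in aa.STATES]
            )
            opt = expected_score_optimum(spec_both, risk, x_of_state)
            assert opt[1] == pytest.approx(truth, abs=1e-5)
            cohort = aa.simulate_cohort(spec_both, risk, 1000, 1000, 22)
            fit = fit_fn(cohort)
            y = cohort.phenotype.astype(float)
            x = cohort.cn if fit_fn is aa.fit_cn else cohort.b_count
            se = sm.GLM(
                y, sm.add_constant(x.astype(float)), family=sm.families.Binomial()
            ).fit().bse[1]
            assert abs(fit.coef["beta"] - truth) < 3 * se

    def test_allele_label_swap_symmetry(self, spec_both):
        """A<->B relabeling: fit_cn and fit_joint are exactly invariant (the
        covariates cn and (S, D) -> (S, -D) span the same model); the allele
        trend flips its coefficient sign on constant-CN cohorts, where b -> 2-b
        stays inside the model span."""
        cohort = aa.simulate_cohort(spec_both, aa.RiskModel(1.2, 1.5), 500, 500, 23)
        swapped_idx = np.array(
            [STATE_INDEX[aa.AscnState(s.b_count, s.a_count)] for s in cohort.states],
            dtype=np.int8,
        )
        swapped = aa.Cohort(swapped_idx, cohort.phenotype)
        g1, g2 = aa.fit_cn(cohort), aa.fit_cn(swapped)
        assert g1.lrt == pytest.approx(g2.lrt, abs=1e-8)
        assert g1.p_value == pytest.approx(g2.p_value, abs=1e-10)
        j1, j2 = aa.fit_joint(cohort), aa.fit_joint(swapped)
        assert j1.lrt == pytest.approx(j2.lrt, abs=1e-6)
        assert j1.or_allele == pytest.approx(1.0 / j2.or_allele, rel=1e-6)
        # sign flip on a two-copy-only cohort
        hw = aa.simulate_cohort(
            aa.ScenarioSpec(1.0, "both", 0.35), aa.RiskModel(1.0, 1.5), 500, 500, 23
        )
        hw_swapped = aa.Cohort(
            np.array(
                [STATE_INDEX[aa.AscnState(s.b_count, s.a_count)] for s in hw.states],
                dtype=np.int8,
            ),
            hw.phenotype,
        )
        f1, f2 = aa.fit_allele_multi(hw), aa.fit_allele_multi(hw_swapped)
        assert f1.lrt == pytest.approx(f2.lrt, abs=1e-8)
        assert f1.coef["beta"] == pytest.approx(-f2.coef["beta"], abs=1e-6)


class TestAlleleBi:
    def test_equals_allele_multi_when_all_cn2_no_missing(self):
        counts_ctrl = np.zeros(15, dtype=int)
        counts_case = np.zeros(15, dtype=int)
        for lab, nc, ny in (("AA", 50, 30), ("AB", 40, 50), ("BB", 10, 20)):
            counts_ctrl[STATE_INDEX[aa.AscnState.from_label(lab)]] = nc
            counts_case[STATE_INDEX[aa.AscnState.from_label(lab)]] = ny
        cohort = cohort_from_counts(counts_ctrl, counts_case)
        cohort.calls = cohort.b_count.astype(np.int8)  # perfect CN=2 calls
        bi, multi = aa.fit_allele_bi(cohort), aa.fit_allele_multi(cohort)
        assert bi.lrt == pytest.approx(multi.lrt, abs=1e-9)
        assert bi.coef["beta"] == pytest.approx(multi.coef["beta"], abs=1e-9)

    def test_missing_calls_excluded(self, spec_both):
        cohort = aa.simulate_cohort(spec_both, aa.RiskModel(1, 1), 300, 300, 24)
        cohort = aa.degrade_to_genotypes(cohort, aa.default_call_table(), 25)
        fit = aa.fit_allele_bi(cohort)
        assert fit.n_used == int((cohort.calls != CALL_MISSING).sum())

    def test_all_missing_errors(self):
        cohort = _balanced_null_cohort()
        cohort.calls = np.full(cohort.n, CALL_MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            aa.fit_allele_bi(cohort)

    def test_blind_to_pure_cn_effect(self):
        """CN-only effects are invisible after degradation (power collapse)."""
        spec = aa.ScenarioSpec(0.5, "both", 0.35)
        risk = aa.RiskModel(1.5, 1.0)
        table = aa.default_call_table()
        reject_bi = reject_multi = 0
        reps = 120
        ss = np.random.SeedSequence(26)
        for child in ss.spawn(reps):
            s1, s2 = child.spawn(2)
            cohort = aa.simulate_cohort(spec, risk, 1000, 1000, np.random.default_rng(s1))
            cohort = aa.degrade_to_genotypes(cohort, table, np.random.default_rng(s2))
            if aa.fit_allele_multi(cohort).p_value < 0.05:
                reject_multi += 1
            if aa.fit_allele_bi(cohort).p_value < 0.05:
                reject_bi += 1
        assert reject_multi / reps > 0.9
        assert reject_bi / reps < 0.5


class TestJoint:
    def test_df_always_two(self, spec_both):
        for seed in range(3):
            cohort = aa.simulate_cohort(spec_both, aa.RiskModel(1.2, 1.2), 400, 400, seed)
            fit = aa.fit_joint(cohort)
            assert fit.converged and fit.df == 2

    def test_transform_identity(self):
        assert aa.transform_joint(0.0, 0.0) == pytest.approx((1.0, 1.0))

    def test_transform_algebraic_inversion(self):
        beta1 = math.log(1.2) + 0.5 * math.log(1.5)
        beta2 = -0.5 * math.log(1.5)
        or_cn, or_allele = aa.transform_joint(beta1, beta2)
        assert (or_cn, or_allele) == pytest.approx((1.2, 1.5))
        assert aa.transform_joint(math.log(1.5), 0.0) == pytest.approx((1.5, 1.0))

    def test_per_state_odds_ratio_equals_relative_risk(self, spec_both):
        """Case tilting makes every state's OR vs AA equal its RR, so the
        joint fit recovers (rr_cn, rr_allele) on a very large cohort."""
        risk = aa.RiskModel(1.2, 1.5)
        cohort = aa.simulate_cohort(spec_both, risk, 400_000, 400_000, 27)
        fit = aa.fit_joint(cohort)
        assert fit.or_cn == pytest.approx(1.2, abs=0.02)
        assert fit.or_allele == pytest.approx(1.5, abs=0.03)


class TestCodominant:
    def test_df_counts_observed_states(self):
        counts = np.zeros(15, dtype=int)
        for lab in ("AA", "AB", "BB"):
            counts[STATE_INDEX[aa.AscnState.from_label(lab)]] = 20
        fit = aa.fit_codominant(cohort_from_counts(counts, counts))
        assert fit.df == 2
        counts8 = np.zeros(15, dtype=int)
        counts8[:8] = 10
        assert aa.fit_codominant(cohort_from_counts(counts8, counts8)).df == 7

    def test_single_state_errors(self):
        counts = np.zeros(15, dtype=int)
        counts[STATE_INDEX[aa.AscnState(2, 0)]] = 50
        with pytest.raises(ValueError):
            aa.fit_codominant(cohort_from_counts(counts, counts))

    def test_matches_statsmodels_saturated_fit(self, spec_both):
        cohort = aa.simulate_cohort(spec_both, aa.RiskModel(1.4, 1.4), 2000, 2000, 28)
        fit = aa.fit_codominant(cohort)
        # independent route: GLM on state indicators
        observed = sorted(set(cohort.state_idx.tolist()))
        X = np.column_stack([(cohort.state_idx == i).astype(float) for i in observed[1:]])
        ref = sm.GLM(
            cohort.phenotype.astype(float), sm.add_constant(X),
            family=sm.families.Binomial(),
        ).fit()
        assert fit.loglik_full == pytest.approx(ref.llf, abs=1e-5)
        assert fit.df == len(observed) - 1

    def test_empty_cell_flagged_with_finite_lrt(self):
        ctrl = np.zeros(15, dtype=int)
        case = np.zeros(15, dtype=int)
        ctrl[STATE_INDEX[aa.AscnState(2, 0)]] = 50
        case[STATE_INDEX[aa.AscnState(2, 0)]] = 40
        ctrl[STATE_INDEX[aa.AscnState(1, 1)]] = 30
        case[STATE_INDEX[aa.AscnState(1, 1)]] = 40
        case[STATE_INDEX[aa.AscnState(0, 0)]] = 3  # cases only
        fit = aa.fit_codominant(cohort_from_counts(ctrl, case))
        assert "empty_cells" in fit.flags
        assert np.isfinite(fit.lrt) and 0 <= fit.p_value <= 1


class TestHwe:
    def test_perfect_proportions(self):
        assert aa.hwe_test(np.array([0] * 25 + [1] * 50 + [2] * 25)) == pytest.approx(1.0)

    def test_extreme_departure(self):
        assert aa.hwe_test(np.array([0] * 50 + [2] * 50)) < 1e-10

    def test_monomorphic_convention(self):
        assert aa.hwe_test(np.zeros(30, dtype=int)) == 1.0

    def test_exact_matches_combinatorial_enumeration(self, rng):
        """Exact test vs integer-combinatorics enumeration for n <= 50."""
        for _ in range(30):
            n = int(rng.integers(4, 51))
            n_ab = int(rng.integers(0, n + 1))
            rest = n - n_ab
            n_aa = int(rng.integers(0, rest + 1))
            n_bb = rest - n_aa
            n_a, n_b = 2 * n_aa + n_ab, 2 * n_bb + n_ab
            if n_a == 0 or n_b == 0:
                continue
            # oracle: exact rational probabilities via math.comb
            def weight(h):
                na, nb = (n_a - h) // 2, (n_b - h) // 2
                return (
                    math.factorial(n)
                    * 2**h
                    // (math.factorial(na) * math.factorial(h) * math.factorial(nb))
                )
            hets = [h for h in range(min(n_a, n_b) + 1) if (n_a - h) % 2 == 0]
            weights = {h: weight(h) for h in hets}
            total = sum(weights.values())
            p_oracle = sum(w for w in weights.values() if w <= weights[n_ab]) / total
            assert aa.hwe_test(
                np.array([0] * n_aa + [1] * n_ab + [2] * n_bb)
            ) == pytest.approx(p_oracle, rel=1e-9)

    def test_chisq_variant_available(self):
        calls = np.array([0] * 30 + [1] * 20 + [2] * 50)
        p_exact = aa.hwe_test(calls, method="exact")
        p_chi = aa.hwe_test(calls, method="chisq")
        assert 0 < p_exact < 0.05 and 0 < p_chi < 0.05


class TestQc:
    def test_missing_rate(self):
        assert aa.missing_rate(np.array([0, 1, 2])) == 0.0
        assert aa.missing_rate(np.full(10, CALL_MISSING)) == 1.0
        calls = np.array([CALL_MISSING] * 5 + [0] * 95)
        assert aa.missing_rate(calls) == pytest.approx(0.05)

    def test_qc_report_thresholds(self, spec_both, null_risk):
        cohort = aa.simulate_cohort(spec_both, null_risk, 500, 500, 30)
        cohort = aa.degrade_to_genotypes(cohort, aa.default_call_table(), 31)
        report = aa.qc_report(cohort)
        assert 0 <= report.missing_fraction <= 1
        assert 0 <= report.hwe_p <= 1
        assert report.missing_pass == (report.missing_fraction < 0.05)
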