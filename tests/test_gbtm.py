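import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from trajvuln import (
    GeneratorConfig,
    LongCohort,
    PosteriorAssignment,
    TrajectoryModel,
    bic,
    diagnostics,
    fit,
    generate,
    loglikelihood,
    odds_correct_classification,
    select_model,
)
from trajvuln.gbtm import ConvergenceError


def _one_subject(values):
    rows = [
        ("s1", tp, v)
        for tp, v in zip(["BASELINE", "POST_INT1", "M6", "M12"], values)
        if v is not None
    ]
    return LongCohort(pd.DataFrame(rows, columns=["subject", "timepoint", "pain"]))


def enumeration_loglik(model: TrajectoryModel, cohort: LongCohort) -> float:
    """Brute-force oracle: enumerate the group of every subject explicitly."""
    subjects, y = cohort.observation_matrix()
    times = cohort.times
    total = 0.0
    for i in range(len(subjects)):
        mix = 0.0
        for j in range(model.K):
            prod = 1.0
            for t in range(len(times)):
                if np.isnan(y[i, t]):
                    continue
                mu = sum(
                    model.coefficients[j, p] * (times[t] - model.time_center) ** p
                    for p in range(model.order + 1)
                )
                val = y[i, t]
                if model.censored and val <= model.scale_bounds[0]:
                    prod *= norm.cdf((model.scale_bounds[0] - mu) / model.sigma)
                elif model.censored and val >= model.scale_bounds[1]:
                    prod *= norm.cdf((mu - model.scale_bounds[1]) / model.sigma)
                else:
                    prod *= norm.pdf(val, mu, model.sigma)
            mix += model.mixing[j] * prod
        total += np.log(mix)
    return total


class TestLoglikelihood:
    def test_standard_normal_density_at_zero(self):
        model = TrajectoryModel(coefficients=[[0.0]], mixing=[1.0], sigma=1.0, censored=False)
        cohort = _one_subject([0.0, None, None, None])
        assert loglikelihood(model, cohort) == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)), abs=1e-10)

    def test_additivity_over_observations(self):
        model = TrajectoryModel(coefficients=[[0.0]], mixing=[1.0], sigma=1.0, censored=False)
        cohort = _one_subject([0.0, 0.0, None, None])
        assert loglikelihood(model, cohort) == pytest.approx(2 * np.log(1 / np.sqrt(2 * np.pi)), abs=1e-10)

    def test_matches_enumeration_oracle_on_toy_mixture(self):
        rows = [
            ("s1", "BASELINE", 0.5), ("s1", "M6", 1.0), ("s1", "M12", 0.0),
            ("s2", "BASELINE", 2.5), ("s2", "POST_INT1", 3.0),
            ("s3", "M6", 4.0), ("s3", "M12", 5.0),
            ("s4", "BASELINE", 1.0), ("s4", "M6", 2.0), ("s4", "M12", 3.0),
        ]
        cohort = LongCohort(pd.DataFrame(rows, columns=["subject", "timepoint", "pain"]))
        for censored in (False, True):
            model = TrajectoryModel(
                coefficients=[[0.2, 0.1], [2.0, -0.05]], mixing=[0.3, 0.7],
                sigma=0.8, censored=censored, time_center=6.0,
            )
            assert loglikelihood(model, cohort) == pytest.approx(
                enumeration_loglik(model, cohort), abs=1e-6
            )

    def test_bound_observation_contributes_tail_mass(self):
        model = TrajectoryModel(coefficients=[[0.0]], mixing=[1.0], sigma=1.0, censored=True)
        cohort = _one_subject([0.0, None, None, None])
        assert loglikelihood(model, cohort) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_censored_equals_uncensored_on_interior_data(self, two_level_cohort):
        model = TrajectoryModel(
            coefficients=[[0.5], [5.0]], mixing=[0.5, 0.5], sigma=0.3,
            censored=False, time_center=3.0,
        )
        plain = loglikelihood(model, two_level_cohort)
        model.censored = True
        assert abs(loglikelihood(model, two_level_cohort) - plain) < 1e-12

    def test_group_permutation_invariance(self, two_level_cohort):
        a = TrajectoryModel(coefficients=[[0.5], [5.0]], mixing=[0.4, 0.6], sigma=0.3, censored=False)
        b = TrajectoryModel(coefficients=[[5.0], [0.5]], mixing=[0.6, 0.4], sigma=0.3, censored=False)
        assert loglikelihood(a, two_level_cohort) == pytest.approx(
            loglikelihood(b, two_level_cohort), abs=1e-12
        )


def grid_search_loglik(cohort, beta1_rng, beta2_rng, sigma_rng, n_coarse=41, refinements=2):
    """Dense grid-search oracle for a K=2, order-0 mixture (independent of EM)."""
    _, y = cohort.observation_matrix()
    best = (-np.inf, None)
    ranges = (beta1_rng, beta2_rng, sigma_rng, (0.02, 0.98))
    grids = [np.linspace(lo, hi, n_coarse) for lo, hi in ranges]
    for _ in range(refinements + 1):
        b1g, b2g, sg, pg = grids
        sse1 = np.nansum((y[:, :, None] - b1g[None, None, :]) ** 2, axis=1)  # (n, nb1)
        sse2 = np.nansum((y[:, :, None] - b2g[None, None, :]) ** 2, axis=1)
        nobs = (~np.isnan(y)).sum(axis=1)  # (n,)
        for s in sg:
            const = -nobs * (np.log(s) + 0.5 * np.log(2 * np.pi))
            l1 = const[:, None] - sse1 / (2 * s**2)  # (n, nb1)
            l2 = const[:, None] - sse2 / (2 * s**2)
            for p in pg:
                mix = np.logaddexp(
                    np.log(p) + l1[:, :, None], np.log1p(-p) + l2[:, None, :]
                ).sum(axis=0)  # (nb1, nb2)
                idx = np.unravel_index(np.argmax(mix), mix.shape)
                if mix[idx] > best[0]:
                    best = (mix[idx], (b1g[idx[0]], b2g[idx[1]], s, p))
        # refine around the optimum
        steps = [g[1] - g[0] for g in grids]
        center = best[1]
        grids = [
            np.linspace(c - st, c + st, 21) for c, st in zip(center, steps)
        ]
        grids[2] = np.clip(grids[2], 1e-3, None)
        grids[3] = np.clip(grids[3], 1e-3, 1 - 1e-3)
    return best[0]


class TestFit:
    def test_k1_order0_closed_form(self, toy_cohort):
        model, assign = fit(toy_cohort, 1, 0, censored=False, n_starts=2, seed=0)
        pooled = toy_cohort.data["pain"].dropna().values
        assert model.coefficients[0, 0] == pytest.approx(pooled.mean(), abs=1e-8)
        assert model.sigma == pytest.approx(pooled.std(ddof=0), abs=1e-8)
        np.testing.assert_allclose(assign.posterior, 1.0)

    def test_two_group_fit_matches_grid_search_oracle(self, two_level_cohort):
        model, assign = fit(two_level_cohort, 2, 0, censored=False, n_starts=5, seed=0)
        np.testing.assert_allclose(model.mixing, [0.5, 0.5], atol=0.05)
        wide = two_level_cohort.to_wide()
        low_mean = np.nanmean(wide.loc[["a", "b", "c"]].values)
        high_mean = np.nanmean(wide.loc[["d", "e", "f"]].values)
        assert abs(model.coefficients[0, 0] - low_mean) < 0.1
        assert abs(model.coefficients[1, 0] - high_mean) < 0.1
        oracle = grid_search_loglik(
            two_level_cohort, (0.0, 1.0), (4.0, 6.0), (0.05, 1.0)
        )
        assert model.loglik >= oracle - 1e-6  # EM at least as good as the grid
        assert abs(model.loglik - oracle) < 1e-3

    def test_em_monotone_every_iteration(self):
        cohort, _, _ = generate(GeneratorConfig(n_subjects=120, seed=4))
        for censored in (False, True):
            model, _ = fit(cohort, 2, 2, censored=censored, n_starts=1, seed=0)
            diffs = np.diff(model.loglik_history)
            assert np.all(diffs >= -1e-9), f"loglik decreased (censored={censored})"

    def test_recovery_on_synthetic_defaults(self):
        cfg = GeneratorConfig(n_subjects=300, seed=0)
        cohort, _, truth = generate(cfg)
        model, assign = fit(cohort, 2, 3, censored=True, n_starts=3, seed=0)
        g = truth.set_index("subject").loc[assign.subjects, "group"].values
        acc = max((assign.assigned == g).mean(), (assign.assigned != g).mean())
        assert acc >= 0.90
        rec = model.mean_curves(cohort.times)
        true_curves = np.asarray(cfg.group_mean_curves)
        counts = np.array([(g == 0).sum(), (g == 1).sum()])
        se = cfg.residual_sd / np.sqrt(counts)[:, None]
        assert np.all(np.abs(rec - true_curves) <= 3 * se)

    def test_canonical_group_order(self):
        cohort, _, _ = generate(GeneratorConfig(n_subjects=120, seed=4))
        model, _ = fit(cohort, 2, 2, censored=False, n_starts=2, seed=1)
        levels = model.mean_curves(cohort.times).mean(axis=1)
        assert levels[0] < levels[1]

    def test_order_exceeding_timepoints_rejected(self, toy_cohort):
        with pytest.raises(ValueError, match="order"):
            fit(toy_cohort, 1, 4, seed=0)

    def test_seed_required(self, toy_cohort):
        with pytest.raises(ValueError, match="seed"):
            fit(toy_cohort, 1, 0)


class TestBIC:
    def test_zero_case(self):
        m = TrajectoryModel(coefficients=[[0.0]], mixing=[1.0], sigma=1.0, loglik=0.0)
        # k = 2 for K=1, order 0 (one coefficient + sigma)
        assert bic(m, 10) == pytest.approx(2 * np.log(10))

    def test_closed_form_arithmetic(self):
        # -2*(-230.2) + 6*ln(89) = 487.33
        assert -2 * (-230.2) + 6 * np.log(89) == pytest.approx(487.33, abs=0.005)

    def test_one_extra_parameter_costs_ln_n(self):
        m1 = TrajectoryModel(coefficients=[[0.0]], mixing=[1.0], sigma=1.0, loglik=-50.0)
        m2 = TrajectoryModel(coefficients=[[0.0, 0.0]], mixing=[1.0], sigma=1.0, loglik=-50.0)
        assert bic(m2, 89) - bic(m1, 89) == pytest.approx(np.log(89))

    def test_tiny_n_rejected(self):
        m = TrajectoryModel(coefficients=[[0.0]], mixing=[1.0], sigma=1.0, loglik=0.0)
        with pytest.raises(ValueError):
            bic(m, 1)


class TestSelectModel:
    def test_single_cell_returns_trivially(self, two_level_cohort):
        sel = select_model(two_level_cohort, K_range=(1,), order_range=(0,),
                           censored=False, n_starts=2, seed=0)
        assert sel.model.K == 1 and sel.model.order == 0
        assert len(sel.scan) == 1

    def test_alternative_prefers_two_groups(self):
        picks = []
        for r in range(20):
            cohort, _, _ = generate(GeneratorConfig(n_subjects=300, seed=100 + r))
            sel = select_model(cohort, K_range=(1, 2, 3), order_range=(2,),
                               censored=False, n_starts=3, seed=r)
            picks.append(sel.model.K)
        assert np.mean(np.array(picks) == 2) >= 0.90

    def test_null_prefers_one_group(self):
        picks = []
        for r in range(20):
            cohort, _, _ = generate(
                GeneratorConfig(n_subjects=300, seed=200 + r, group_probs=(1.0, 0.0))
            )
            sel = select_model(cohort, K_range=(1, 2), order_range=(2,),
                               censored=False, n_starts=3, seed=r)
            picks.append(sel.model.K)
        assert np.mean(np.array(picks) == 1) >= 0.80

    def test_scan_reports_both_bic_conventions(self, two_level_cohort):
        sel = select_model(two_level_cohort, K_range=(1, 2), order_range=(0,),
                           censored=False, n_starts=3, seed=0)
        row = sel.scan.iloc[0]
        assert row["bic_ll_scale"] == pytest.approx(
            row["loglik"] - 0.5 * row["n_params"] * np.log(6)
        )
        assert row["bic"] == pytest.approx(-2 * row["loglik"] + row["n_params"] * np.log(6))

    def test_empty_range_rejected(self, two_level_cohort):
        with pytest.raises(ValueError):
            select_model(two_level_cohort, K_range=(), order_range=(1,), seed=0)


class TestDiagnostics:
    def test_occ_from_printed_inputs(self):
        assert odds_correct_classification(0.851, 0.415) == pytest.approx(8.05, abs=0.005)
        assert odds_correct_classification(0.902, 0.585) == pytest.approx(6.53, abs=0.005)

    def test_occ_chance_level_is_one(self):
        assert odds_correct_classification(0.3, 0.3) == pytest.approx(1.0)

    def test_diagnostics_on_fitted_pair(self):
        cohort, _, _ = generate(GeneratorConfig(n_subjects=200, seed=9))
        model, assign = fit(cohort, 2, 2, censored=False, n_starts=3, seed=0)
        diag = diagnostics(model, assign)
        w, hard = assign.posterior, assign.assigned
        for j in range(2):
            assert diag.avepp[j] == pytest.approx(w[hard == j, j].mean())
            assert 0 < diag.avepp[j] <= 1
            assert diag.occ[j] > 0
        assert diag.obs_prob.sum() == pytest.approx(1.0)

    def test_empty_group_flagged(self):
        a = PosteriorAssignment(["s1", "s2"], np.array([[0.9, 0.1], [0.8, 0.2]]))
        m = TrajectoryModel(coefficients=[[0.0], [1.0]], mixing=[0.5, 0.5], sigma=1.0, loglik=-1.0)
        with pytest.warns(UserWarning, match="no assigned subjects"):
            diag = diagnostics(m, a)
        assert np.isnan(diag.avepp[1])


class TestPosteriorAssignment:
    def test_rows_must_be_simplex(self):
        with pytest.raises(ValueError):
            PosteriorAssignment(["s1"], np.array([[0.5, 0.6]]))

    def test_tie_breaks_to_lower_index(self):
        a = PosteriorAssignment(["s1"], np.array([[0.5, 0.5]]))
        assert a.assigned[0] == 0
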