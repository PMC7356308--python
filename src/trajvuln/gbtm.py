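"""Group-based trajectory modeling: finite mixtures of polynomial pain curves.

The model: subject *i*'s observed pain ratings ``y_it`` at visit times ``t``
(months) come from one of ``K`` latent groups.  Group *j* has a polynomial
mean curve ``mu_j(t) = sum_p beta_jp * (t - c)^p`` (``c`` a fixed centering
constant) and Gaussian residuals with a shared scale ``sigma``; observations
are conditionally independent given group.  With the censored-normal option,
ratings at a scale bound contribute the corresponding normal tail mass
instead of the density, which lets the model place genuine probability mass
at the floor of a 0-10 rating scale.

Fitting is by EM from multiple starts (one k-means start on per-subject
trajectory vectors plus random-posterior restarts).  Under no censoring the
M-step is closed-form weighted least squares; under censoring the expected
complete-data log-likelihood is maximized numerically (L-BFGS with analytic
gradients, warm-started from the current parameters), with a safeguard that
keeps the current parameters whenever the optimizer fails to improve — so
the observed-data log-likelihood never decreases across iterations in
either case.

Model selection scans a grid of (K, polynomial order) and picks the fit with
the smallest BIC = -2*loglik + k*ln(n_subjects); adequacy is judged by the
usual posterior diagnostics (average posterior probability per assigned
group > 0.70, odds of correct classification > 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, logsumexp
from sklearn.cluster import KMeans

from .cohort_io import LongCohort

__all__ = [
    "TrajectoryModel",
    "PosteriorAssignment",
    "ModelDiagnostics",
    "SelectionResult",
    "ConvergenceError",
    "loglikelihood",
    "fit",
    "bic",
    "select_model",
    "diagnostics",
    "odds_correct_classification",
    "AVEPP_THRESHOLD",
    "OCC_THRESHOLD",
]

AVEPP_THRESHOLD = 0.70  # conventional adequacy bound on average posterior probability
OCC_THRESHOLD = 5.0  # conventional adequacy bound on odds of correct classification

_PI_FLOOR = 1e-6  # mixing-proportion floor; a run hitting it is restarted
_LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """No EM run converged; carries the best partial fit in ``.model``/``.assignment``."""

    def __init__(self, message: str, model=None, assignment=None):
        super().__init__(message)
        self.model = model
        self.assignment = assignment


@dataclass
class TrajectoryModel:
    """A fitted (or hand-set) K-group polynomial trajectory mixture.

    ``coefficients[j, p]`` multiplies ``(t - time_center)^p`` (pain units per
    month^p); groups are canonically ordered by mean fitted level, ascending.
    """

    coefficients: np.ndarray  # (K, P+1)
    mixing: np.ndarray  # (K,)
    sigma: float
    censored: bool = True
    scale_bounds: tuple[float, float] = (0.0, 10.0)
    time_center: float = 0.0
    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0
    loglik_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (self.coefficients.shape[0],):
            raise ValueError("mixing length must equal number of groups")
        if np.any(self.mixing <= 0) or abs(self.mixing.sum() - 1.0) > 1e-8:
            raise ValueError("mixing proportions must be positive and sum to 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def K(self) -> int:
        return self.coefficients.shape[0]

    @property
    def order(self) -> int:
        return self.coefficients.shape[1] - 1

    @property
    def n_params(self) -> int:
        """K(P+1) curve coefficients + (K-1) free mixing weights + 1 scale."""
        return self.K * (self.order + 1) + (self.K - 1) + 1

    def design(self, times: np.ndarray) -> np.ndarray:
        tc = np.asarray(times, dtype=float) - self.time_center
        return np.vander(tc, self.order + 1, increasing=True)

    def mean_curves(self, times: np.ndarray) -> np.ndarray:
        """Group mean pain at the given times, shape (K, len(times))."""
        return self.coefficients @ self.design(times).T

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "order": self.order,
            "coefficients": self.coefficients.tolist(),
            "mixing": self.mixing.tolist(),
            "sigma": self.sigma,
            "censored": self.censored,
            "scale_bounds": list(self.scale_bounds),
            "time_center": self.time_center,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_params": self.n_params,
        }


@dataclass
class PosteriorAssignment:
    """Subject-wise posterior group-membership probabilities and hard labels.

    Rows of ``posterior`` lie on the simplex; ``assigned`` is the argmax with
    ties broken toward the lower group index.
    """

    subjects: list[str]
    posterior: np.ndarray  # (n, K)

    def __post_init__(self) -> None:
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.posterior.ndim != 2 or self.posterior.shape[0] != len(self.subjects):
            raise ValueError("posterior must be (n_subjects, K)")
        rows = self.posterior.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")

    @property
    def assigned(self) -> np.ndarray:
        return np.argmax(self.posterior, axis=1)  # first max -> lower index on ties

    def to_frame(self) -> pd.DataFrame:
        K = self.posterior.shape[1]
        df = pd.DataFrame(
            self.posterior, columns=[f"posterior_{j}" for j in range(K)]
        )
        df.insert(0, "subject", self.subjects)
        df["assigned"] = self.assigned
        return df


@dataclass
class ModelDiagnostics:
    """BIC plus Nagin-style adequacy measures per group."""

    bic: float
    avepp: np.ndarray  # mean posterior among subjects assigned to each group
    occ: np.ndarray  # odds of correct classification per group
    est_prob: np.ndarray  # model mixing proportions pi_j
    obs_prob: np.ndarray  # observed assigned fractions
    avepp_ok: np.ndarray  # avepp > 0.70
    occ_ok: np.ndarray  # occ > 5

    def to_dict(self) -> dict:
        return {
            "bic": self.bic,
            "avepp": self.avepp.tolist(),
            "occ": self.occ.tolist(),
            "est_prob": self.est_prob.tolist(),
            "obs_prob": self.obs_prob.tolist(),
            "avepp_ok": [bool(v) for v in self.avepp_ok],
            "occ_ok": [bool(v) for v in self.occ_ok],
        }


# -- likelihood ------------------------------------------------------------


def _flatten(cohort: LongCohort) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Observed values flattened: subjects, subject index, times, y."""
    subjects, y = cohort.observation_matrix()
    times = cohort.times
    n, T = y.shape
    mask = ~np.isnan(y)
    zero = ~mask.any(axis=1)
    if zero.any():
        dropped = [s for s, z in zip(subjects, zero) if z]
        warnings.warn(f"excluding subject(s) with zero observations: {dropped}")
        keep = ~zero
        subjects = [s for s, k in zip(subjects, keep) if k]
        y, mask = y[keep], mask[keep]
        n = len(subjects)
    subj_idx, t_idx = np.nonzero(mask)
    return subjects, subj_idx, times[t_idx], y[mask]


def _obs_loglik(
    y: np.ndarray, mu: np.ndarray, sigma: float,
    censored: bool, bounds: tuple[float, float],
) -> np.ndarray:
    """Per-observation log-likelihood for each group; mu shape (N_obs, K)."""
    z = (y[:, None] - mu) / sigma
    ll = -0.5 * z**2 - np.log(sigma) - 0.5 * _LOG2PI
    if censored:
        low, high = bounds
        at_low = y <= low
        at_high = y >= high
        if at_low.any():
            ll[at_low] = log_ndtr((low - mu[at_low]) / sigma)
        if at_high.any():
            ll[at_high] = log_ndtr((mu[at_high] - high) / sigma)
    return ll


def _subject_group_loglik(
    cohort_flat, model: TrajectoryModel
) -> np.ndarray:
    subjects, subj_idx, t_obs, y_obs = cohort_flat
    X = model.design(t_obs)  # (N_obs, P+1)
    mu = X @ model.coefficients.T  # (N_obs, K)
    ll_obs = _obs_loglik(y_obs, mu, model.sigma, model.censored, model.scale_bounds)
    out = np.zeros((len(subjects), model.K))
    np.add.at(out, subj_idx, ll_obs)
    return out


def loglikelihood(model: TrajectoryModel, cohort: LongCohort) -> float:
    """Observed-data mixture log-likelihood of the cohort under the model.

    Each subject contributes ``log sum_j pi_j * prod_{t in obs(i)} f_j(y_it)``
    with the censored-normal variant substituting tail mass at scale bounds.
    """
    flat = _flatten(cohort)
    ll_ij = _subject_group_loglik(flat, model)
    return float(logsumexp(ll_ij + np.log(model.mixing), axis=1).sum())


# -- EM --------------------------------------------------------------------


def _e_step(flat, model: TrajectoryModel) -> tuple[np.ndarray, float]:
    ll_ij = _subject_group_loglik(flat, model) + np.log(model.mixing)
    norm = logsumexp(ll_ij, axis=1)
    w = np.exp(ll_ij - norm[:, None])
    return w, float(norm.sum())


def _m_step_uncensored(flat, w, order, time_center):
    """Closed-form weighted least squares; sigma pooled across groups."""
    subjects, subj_idx, t_obs, y_obs = flat
    X = np.vander(t_obs - time_center, order + 1, increasing=True)
    K = w.shape[1]
    beta = np.empty((K, order + 1))
    w_obs = w[subj_idx]  # (N_obs, K)
    sse = 0.0
    for j in range(K):
        wj = w_obs[:, j]
        Xw = X * wj[:, None]
        beta[j] = np.linalg.solve(X.T @ Xw + 1e-12 * np.eye(order + 1), Xw.T @ y_obs)
        resid = y_obs - X @ beta[j]
        sse += float(wj @ resid**2)
    sigma = np.sqrt(max(sse / len(y_obs), 1e-12))
    return beta, sigma


def _q_and_grad(theta, X, y_obs, w_obs, K, P1, bounds):
    """Expected complete-data loglik (negated) and gradient, censored case."""
    beta = theta[: K * P1].reshape(K, P1)
    sigma = np.exp(theta[-1])
    low, high = bounds
    mu = X @ beta.T  # (N_obs, K)
    z = (y_obs[:, None] - mu) / sigma
    at_low = y_obs <= low
    at_high = y_obs >= high
    interior = ~(at_low | at_high)

    ll = np.empty_like(mu)
    dmu = np.empty_like(mu)  # d loglik / d mu
    dls = np.empty_like(mu)  # d loglik / d log sigma

    zi = z[interior]
    ll[interior] = -0.5 * zi**2 - np.log(sigma) - 0.5 * _LOG2PI
    dmu[interior] = zi / sigma
    dls[interior] = zi**2 - 1.0

    if at_low.any():
        a = (low - mu[at_low]) / sigma
        la = log_ndtr(a)
        lam = np.exp(-0.5 * a**2 - 0.5 * _LOG2PI - la)  # phi(a)/Phi(a)
        ll[at_low] = la
        dmu[at_low] = -lam / sigma
        dls[at_low] = -a * lam
    if at_high.any():
        b = (mu[at_high] - high) / sigma
        lb = log_ndtr(b)
        lam = np.exp(-0.5 * b**2 - 0.5 * _LOG2PI - lb)
        ll[at_high] = lb
        dmu[at_high] = lam / sigma
        dls[at_high] = -b * lam

    q = float((w_obs * ll).sum())
    gbeta = ((w_obs * dmu).T @ X).reshape(-1)  # (K*P1,)
    glogsig = float((w_obs * dls).sum())
    grad = np.concatenate([gbeta, [glogsig]])
    return -q, -grad


def _m_step_censored(flat, w, order, time_center, beta0, sigma0, bounds):
    """Numerical maximization of Q, warm-started; returns params improving Q."""
    subjects, subj_idx, t_obs, y_obs = flat
    X = np.vander(t_obs - time_center, order + 1, increasing=True)
    K = w.shape[1]
    P1 = order + 1
    w_obs = w[subj_idx]
    theta0 = np.concatenate([beta0.reshape(-1), [np.log(sigma0)]])
    res = optimize.minimize(
        _q_and_grad, theta0, args=(X, y_obs, w_obs, K, P1, bounds),
        jac=True, method="L-BFGS-B", options={"maxiter": 100},
    )
    q0 = _q_and_grad(theta0, X, y_obs, w_obs, K, P1, bounds)[0]
    if not np.isfinite(res.fun) or res.fun > q0:
        return beta0, sigma0  # safeguard: never move Q downhill
    beta = res.x[: K * P1].reshape(K, P1)
    sigma = float(np.exp(res.x[-1]))
    return beta, max(sigma, 1e-8)


def _canonicalize(model: TrajectoryModel, posterior: np.ndarray, times: np.ndarray):
    """Order groups by mean fitted level (ascending) for deterministic output."""
    levels = model.mean_curves(times).mean(axis=1)
    order = np.argsort(levels, kind="stable")
    model.coefficients = model.coefficients[order]
    model.mixing = model.mixing[order]
    return model, posterior[:, order]


def _kmeans_posterior(cohort: LongCohort, K: int, seed: int) -> np.ndarray:
    """Soft one-hot posteriors from k-means on mean-imputed trajectory vectors."""
    _, y = cohort.observation_matrix()
    if K == 1:
        return np.ones((y.shape[0], 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(y, axis=0)
    col_mean = np.where(np.isnan(col_mean), np.nanmean(y), col_mean)
    y_imp = np.where(np.isnan(y), col_mean, y)
    km = KMeans(n_clusters=K, n_init=5, random_state=seed % (2**31)).fit(y_imp)
    w = np.full((y.shape[0], K), 0.1 / max(K - 1, 1))
    w[np.arange(y.shape[0]), km.labels_] = 0.9
    return w / w.sum(axis=1, keepdims=True)


def _em_run(flat, cohort, w_init, K, order, censored, bounds, time_center, tol, max_iter):
    subjects, subj_idx, t_obs, y_obs = flat
    w = w_init
    beta, sigma = _m_step_uncensored(flat, w, order, time_center)
    prev_ll = -np.inf
    history: list[float] = []
    model = None
    for it in range(1, max_iter + 1):
        pi = np.clip(w.mean(axis=0), 1e-300, None)
        if np.any(pi < _PI_FLOOR):
            raise _DegenerateRun()
        pi = pi / pi.sum()
        if censored:
            beta, sigma = _m_step_censored(flat, w, order, time_center, beta, sigma, bounds)
        else:
            beta, sigma = _m_step_uncensored(flat, w, order, time_center)
        model = TrajectoryModel(
            coefficients=beta, mixing=pi, sigma=sigma, censored=censored,
            scale_bounds=bounds, time_center=time_center,
        )
        w, ll = _e_step(flat, model)
        history.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            model.loglik, model.converged, model.n_iter = ll, True, it
            model.loglik_history = history
            return model, w
        prev_ll = ll
    model.loglik, model.converged, model.n_iter = prev_ll, False, max_iter
    model.loglik_history = history
    return model, w


class _DegenerateRun(Exception):
    pass


def fit(
    cohort: LongCohort,
    K: int,
    order: int,
    censored: bool = True,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[TrajectoryModel, PosteriorAssignment]:
    """Fit a K-group, order-P trajectory mixture by multi-start EM.

    The first start clusters per-subject trajectory vectors with k-means;
    the remaining ``n_starts - 1`` starts draw random posteriors.  The best
    log-likelihood among converged runs wins.  Raises ``ConvergenceError``
    (carrying the best partial fit) if no run converges.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n_distinct = len(cohort.timepoints)
    if order > n_distinct - 1:
        raise ValueError(
            f"order {order} needs more than {n_distinct} distinct timepoints"
        )
    if seed is None:
        raise ValueError("seed is required (stochastic multi-start)")
    times = cohort.times
    time_center = float((times.min() + times.max()) / 2.0)  # mid-span, vs collinearity
    flat = _flatten(cohort)
    n = len(flat[0])
    rng = np.random.default_rng(seed)

    best = None
    best_partial = None
    for s in range(max(n_starts, 1)):
        if s == 0:
            w0 = _kmeans_posterior(cohort, K, seed)
        else:
            w0 = rng.dirichlet(np.ones(K), size=n)
        try:
            model, w = _em_run(
                flat, cohort, w0, K, order, censored, cohort.scale_bounds,
                time_center, tol, max_iter,
            )
        except _DegenerateRun:
            warnings.warn(f"start {s}: empty group (mixing below floor), restarted")
            continue
        except np.linalg.LinAlgError:
            warnings.warn(f"start {s}: singular design, restarted")
            continue
        if model.converged:
            if best is None or model.loglik > best[0].loglik:
                best = (model, w)
        else:
            if best_partial is None or model.loglik > best_partial[0].loglik:
                best_partial = (model, w)

    if best is None:
        if best_partial is None:
            raise ConvergenceError("all EM starts degenerate")
        model, w = best_partial
        model, w = _canonicalize(model, w, times)
        raise ConvergenceError(
            "no EM run converged", model=model,
            assignment=PosteriorAssignment(flat[0], w),
        )
    model, w = best
    model, w = _canonicalize(model, w, times)
    return model, PosteriorAssignment(flat[0], w)


# -- selection & diagnostics ----------------------------------------------


def bic(model: TrajectoryModel, n: int) -> float:
    """Bayesian information criterion, -2*loglik + k*ln(n); smaller is better."""
    if n < 2:
        raise ValueError("BIC needs n >= 2 subjects")
    if not np.isfinite(model.loglik):
        raise ValueError("model has no fitted log-likelihood")
    return float(-2.0 * model.loglik + model.n_params * np.log(n))


def odds_correct_classification(avepp: float, pi: float) -> float:
    """OCC = [AvePP/(1-AvePP)] / [pi/(1-pi)]; 1 means no better than chance."""
    if not (0 < avepp < 1) or not (0 < pi < 1):
        raise ValueError("avepp and pi must lie strictly in (0, 1)")
    return (avepp / (1.0 - avepp)) / (pi / (1.0 - pi))


def diagnostics(model: TrajectoryModel, assignment: PosteriorAssignment) -> ModelDiagnostics:
    """Posterior-based adequacy: AvePP per assigned group, OCC, group proportions."""
    w = assignment.posterior
    hard = assignment.assigned
    n, K = w.shape
    avepp = np.full(K, np.nan)
    occ = np.full(K, np.nan)
    obs_prob = np.zeros(K)
    for j in range(K):
        members = hard == j
        obs_prob[j] = members.mean()
        if members.any():
            avepp[j] = w[members, j].mean()
            if avepp[j] < 1.0 and 0 < model.mixing[j] < 1:
                occ[j] = odds_correct_classification(avepp[j], model.mixing[j])
            elif avepp[j] >= 1.0:
                occ[j] = np.inf
        else:
            warnings.warn(f"group {j} has no assigned subjects; AvePP undefined")
    return ModelDiagnostics(
        bic=bic(model, n),
        avepp=avepp,
        occ=occ,
        est_prob=model.mixing.copy(),
        obs_prob=obs_prob,
        avepp_ok=avepp > AVEPP_THRESHOLD,
        occ_ok=occ > OCC_THRESHOLD,
    )


@dataclass
class SelectionResult:
    model: TrajectoryModel
    assignment: PosteriorAssignment
    diagnostics: ModelDiagnostics
    scan: pd.DataFrame


def select_model(
    cohort: LongCohort,
    K_range: Iterable[int] = (1, 2, 3),
    order_range: Iterable[int] = (1, 2, 3),
    censored: bool = True,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SelectionResult:
    """Scan (K, order) combinations and return the minimum-BIC fit.

    Ties break toward fewer parameters.  Per-cell failures are recorded in
    the scan table and skipped; the scan fails only if every cell fails.
    The table carries both BIC conventions: ``bic`` (-2*ll + k*ln n,
    minimized) and ``bic_ll_scale`` (ll - (k/2)*ln n, maximized), the latter
    matching the convention of some trajectory software.
    """
    K_range = sorted(set(K_range))
    order_range = sorted(set(order_range))
    if not K_range or not order_range:
        raise ValueError("K_range and order_range must be non-empty")
    if seed is None:
        raise ValueError("seed is required")
    rows = []
    fits: dict[tuple[int, int], tuple[TrajectoryModel, PosteriorAssignment]] = {}
    n = cohort.n_subjects
    for K in K_range:
        for order in order_range:
            cell_seed = int(np.random.SeedSequence([seed, K, order]).generate_state(1)[0] % (2**31))
            row = {"K": K, "order": order}
            try:
                model, assign = fit(
                    cohort, K, order, censored=censored, n_starts=n_starts,
                    seed=cell_seed, tol=tol, max_iter=max_iter,
                )
                b = bic(model, n)
                row.update(
                    loglik=model.loglik, n_params=model.n_params, bic=b,
                    bic_ll_scale=model.loglik - 0.5 * model.n_params * np.log(n),
                    converged=True, error="",
                )
                fits[(K, order)] = (model, assign)
            except (ConvergenceError, ValueError) as exc:
                row.update(
                    loglik=np.nan, n_params=np.nan, bic=np.nan,
                    bic_ll_scale=np.nan, converged=False, error=str(exc),
                )
            rows.append(row)
    scan = pd.DataFrame(rows)
    ok = scan.dropna(subset=["bic"])
    if ok.empty:
        raise ConvergenceError("every (K, order) cell failed to fit")
    best_row = ok.sort_values(["bic", "n_params"], kind="stable").iloc[0]
    key = (int(best_row["K"]), int(best_row["order"]))
    model, assign = fits[key]
    return SelectionResult(model, assign, diagnostics(model, assign), scan)
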