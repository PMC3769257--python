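"""The five association strategies for SNPs inside common CNVs.

Each strategy is a logistic regression of case/control status on a summary of
the allele-specific copy-number state, tested with a likelihood-ratio test
(LRT) against the intercept-only model:

* ``cn``            — trend on total copy number A+B (1 df);
* ``allele_multi``  — trend on the B-allele count taken from the ASCN state
  (1 df);
* ``allele_bi``     — trend on the B count of the bi-allelic genotype call,
  missing calls excluded (1 df);
* ``joint``         — both effects at once via the sum S = A+B and difference
  D = A-B of the allele counts (2 df); its coefficients transform back to the
  per-copy and per-B-allele odds ratios (:func:`transform_joint`);
* ``codominant``    — one indicator per observed state, reference AA
  (df = number of observed states - 1).

Because the covariates take at most 15 distinct values, every fit runs on
state-aggregated case/control counts: a small Newton (IRLS) solve for the
trend and joint models, and a closed-form saturated fit for the codominant
model.  The module also provides the bi-allelic QC metrics (exact
Hardy-Weinberg test, missing-call rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .model import STATES, STATE_INDEX, AscnState
from .simulate import CALL_MISSING, Cohort

STRATEGIES = ("cn", "allele_bi", "allele_multi", "joint", "codominant")

_STATE_CN = np.array([s.cn for s in STATES], dtype=float)
_STATE_B = np.array([s.b_count for s in STATES], dtype=float)
_STATE_A = np.array([s.a_count for s in STATES], dtype=float)

_MAX_ITER = 60
_LL_TOL = 1e-10
_BETA_SEPARATION = 30.0  # |coef| beyond this on a 0-4 covariate means separation


@dataclass
class AssocFit:
    """Result of one strategy on one cohort."""

    strategy: str
    n_used: int
    df: int
    coef: dict[str, float] = field(default_factory=dict)
    loglik_null: float = math.nan
    loglik_full: float = math.nan
    lrt: float | None = None
    p_value: float | None = None
    converged: bool = True
    flags: tuple[str, ...] = ()
    or_cn: float | None = None
    or_allele: float | None = None

    def summary_row(self) -> dict:
        row = {
            "strategy": self.strategy,
            "n_used": self.n_used,
            "df": self.df,
            "lrt": self.lrt,
            "p_value": self.p_value,
            "converged": self.converged,
            "or_cn": self.or_cn,
            "or_allele": self.or_allele,
        }
        row.update(self.coef)
        return row


# ---------------------------------------------------------------------------
# Aggregated logistic likelihood machinery
# ---------------------------------------------------------------------------

def _binom_loglik(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    """Bernoulli log-likelihood of y cases out of n at probabilities p
    (combinatorial constant omitted, as in the LRT it cancels)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(p) + (n - y) * np.log1p(-p)
    return float(np.sum(np.where(n > 0, np.nan_to_num(ll, nan=0.0), 0.0)))


def _null_loglik(y_total: float, n_total: float) -> float:
    """Intercept-only maximized log-likelihood (closed form)."""
    if y_total == 0 or y_total == n_total:
        return 0.0
    p = y_total / n_total
    return y_total * math.log(p) + (n_total - y_total) * math.log(1 - p)


def _irls(
    X: np.ndarray, y: np.ndarray, n: np.ndarray
) -> tuple[np.ndarray, float, bool, tuple[str, ...]]:
    """Newton-Raphson MLE of a binomial logistic model on aggregated rows.

    X includes the intercept column.  Returns (beta, loglik, converged,
    flags); convergence fails on rank deficiency or (quasi-)separation.
    """
    keep = n > 0
    X, y, n = X[keep], y[keep], n[keep]
    k, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        return np.full(p, np.nan), math.nan, False, ("rank_deficient",)
    beta = np.zeros(p)
    # start intercept at the marginal log-odds
    ybar = y.sum() / n.sum()
    if 0 < ybar < 1:
        beta[0] = math.log(ybar / (1 - ybar))
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = _binom_loglik(y, n, mu)
    flags: tuple[str, ...] = ()
    for _ in range(_MAX_ITER):
        w = n * mu * (1.0 - mu)
        grad = X.T @ (y - n * mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, ll, False, flags + ("singular_hessian",)
        # step-halving to guarantee likelihood ascent
        for _ in range(30):
            cand = beta + step
            eta = X @ cand
            mu_new = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
            ll_new = _binom_loglik(y, n, mu_new)
            if ll_new >= ll - 1e-13:
                break
            step *= 0.5
        delta = ll_new - ll
        beta, mu, ll = cand, mu_new, ll_new
        if abs(delta) < _LL_TOL:
            break
    else:
        flags += ("max_iter",)
    if np.max(np.abs(beta)) > _BETA_SEPARATION:
        return beta, ll, False, flags + ("separation",)
    converged = "max_iter" not in flags
    return beta, ll, converged, flags


def _lrt_fit(
    strategy: str,
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    coef_names: list[str],
) -> AssocFit:
    """Run the full-vs-intercept LRT for a trend/joint logistic model."""
    n_used = int(n.sum())
    df = X.shape[1] - 1
    fit = AssocFit(strategy=strategy, n_used=n_used, df=df)
    y_total, n_total = float(y.sum()), float(n.sum())
    if y_total == 0 or y_total == n_total:
        fit.converged = False
        fit.flags = ("single_phenotype",)
        return fit
    fit.loglik_null = _null_loglik(y_total, n_total)
    beta, ll_full, converged, flags = _irls(X, y, n)
    fit.loglik_full = ll_full
    fit.converged = converged
    fit.flags = flags
    fit.coef = {name: float(b) for name, b in zip(coef_names, beta)}
    if converged:
        fit.lrt = max(0.0, 2.0 * (ll_full - fit.loglik_null))
        fit.p_value = float(chi2.sf(fit.lrt, df))
    return fit


def _aggregate_counts(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    ctrl, case = cohort.state_counts()
    return ctrl.astype(float), case.astype(float)


def _trend_fit(
    strategy: str, x_by_state: np.ndarray, ctrl: np.ndarray, case: np.ndarray
) -> AssocFit:
    # collapse the 15 states onto the covariate's distinct values
    levels = np.unique(x_by_state)
    y = np.array([case[x_by_state == v].sum() for v in levels])
    nc = np.array([ctrl[x_by_state == v].sum() for v in levels])
    n = y + nc
    X = np.column_stack([np.ones_like(levels, dtype=float), levels])
    return _lrt_fit(strategy, X, y, n, ["alpha", "beta"])


# ---------------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------------

def fit_cn(cohort: Cohort) -> AssocFit:
    """Trend test on total copy number (0-4), 1-df LRT; H0: OR_CN = 1."""
    ctrl, case = _aggregate_counts(cohort)
    return fit_cn_from_counts(ctrl, case)


def fit_cn_from_counts(ctrl: np.ndarray, case: np.ndarray) -> AssocFit:
    return _trend_fit("cn", _STATE_CN, ctrl, case)


def fit_allele_multi(cohort: Cohort) -> AssocFit:
    """Trend test on the B-allele count of the ASCN state (0-4), 1-df LRT."""
    ctrl, case = _aggregate_counts(cohort)
    return fit_allele_multi_from_counts(ctrl, case)


def fit_allele_multi_from_counts(ctrl: np.ndarray, case: np.ndarray) -> AssocFit:
    return _trend_fit("allele_multi", _STATE_B, ctrl, case)


def fit_allele_bi(cohort: Cohort) -> AssocFit:
    """Trend test on the B count of the bi-allelic call (AA=0, AB=1, BB=2).

    Individuals with missing calls are excluded; requires at least one
    non-missing call in each phenotype group.
    """
    if cohort.calls is None:
        raise ValueError("cohort has no bi-allelic calls; degrade it first")
    kept = cohort.calls != CALL_MISSING
    if not kept.any():
        raise ValueError("all calls are missing")
    calls = cohort.calls[kept].astype(float)  # AA=0, AB=1, BB=2 by call code
    pheno = cohort.phenotype[kept]
    levels = np.unique(calls)
    y = np.array([(pheno[calls == v] == 1).sum() for v in levels], dtype=float)
    n = np.array([(calls == v).sum() for v in levels], dtype=float)
    X = np.column_stack([np.ones_like(levels), levels])
    return _lrt_fit("allele_bi", X, y, n, ["alpha", "beta"])


def fit_joint(cohort: Cohort) -> AssocFit:
    """The 2-df joint test: logit(p) = alpha + beta1*(A+B) + beta2*(A-B).

    The sum covariate carries the copy-number effect plus half the allele
    effect; the difference covariate carries minus half the allele effect.
    Converged coefficients are transformed to (or_cn, or_allele).
    """
    ctrl, case = _aggregate_counts(cohort)
    return fit_joint_from_counts(ctrl, case)


def fit_joint_from_counts(ctrl: np.ndarray, case: np.ndarray) -> AssocFit:
    s = _STATE_CN  # A + B
    d = _STATE_A - _STATE_B
    # collapse states sharing an (S, D) pattern (none do, but keep it robust)
    X = np.column_stack([np.ones_like(s), s, d])
    observed = (ctrl + case) > 0
    fit = _lrt_fit(
        "joint", X[observed], case[observed], (ctrl + case)[observed],
        ["alpha", "beta1", "beta2"],
    )
    fit.df = 2
    if fit.converged and fit.lrt is not None:
        fit.p_value = float(chi2.sf(fit.lrt, 2))
        fit.or_cn, fit.or_allele = transform_joint(
            fit.coef["beta1"], fit.coef["beta2"]
        )
    return fit


def fit_codominant(cohort: Cohort) -> AssocFit:
    """Per-state indicator model, reference AA; df = observed states - 1.

    With one indicator per observed state the model is saturated on state
    categories, so the maximized likelihood has the closed form given by the
    per-state case fractions; the LRT is computed from it directly.  Cells
    containing only cases or only controls push their coefficient to ±inf —
    the LRT limit is still finite and is reported, with the fit flagged.
    """
    ctrl, case = _aggregate_counts(cohort)
    return fit_codominant_from_counts(ctrl, case)


def fit_codominant_from_counts(ctrl: np.ndarray, case: np.ndarray) -> AssocFit:
    n = ctrl + case
    observed = np.flatnonzero(n > 0)
    if observed.size < 2:
        raise ValueError("codominant model needs >= 2 observed states")
    y_total, n_total = float(case.sum()), float(n.sum())
    df = int(observed.size - 1)
    fit = AssocFit(strategy="codominant", n_used=int(n_total), df=df)
    if y_total == 0 or y_total == n_total:
        fit.converged = False
        fit.flags = ("single_phenotype",)
        return fit
    # saturated per-state fit
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_cells = case * np.log(case / n) + ctrl * np.log(ctrl / n)
    fit.loglik_full = float(np.nansum(ll_cells[observed]))
    fit.loglik_null = _null_loglik(y_total, n_total)
    fit.lrt = max(0.0, 2.0 * (fit.loglik_full - fit.loglik_null))
    fit.p_value = float(chi2.sf(fit.lrt, df))

    ref = STATE_INDEX[AscnState(2, 0)]  # AA
    flags: list[str] = []
    if n[ref] == 0:
        ref = int(observed[np.argmax(n[observed])])
        flags.append("reference_fallback")
    with np.errstate(divide="ignore", invalid="ignore"):
        logit = np.log(case / ctrl)
    empty = (case[observed] == 0) | (ctrl[observed] == 0)
    if empty.any():
        flags.append("empty_cells")
    coef = {"alpha": float(logit[ref])}
    for i in observed:
        if i == ref:
            continue
        coef[f"beta_{STATES[i].label}"] = float(logit[i] - logit[ref])
    fit.coef = coef
    fit.flags = tuple(flags)
    return fit


def fit_all(cohort: Cohort) -> list[AssocFit]:
    """Run every applicable strategy (allele_bi only when calls exist)."""
    fits = [
        fit_cn(cohort),
        fit_allele_multi(cohort),
        fit_joint(cohort),
        fit_codominant(cohort),
    ]
    if cohort.calls is not None:
        fits.insert(1, fit_allele_bi(cohort))
    return fits


def fit_strategy(cohort: Cohort, strategy: str) -> AssocFit:
    funcs = {
        "cn": fit_cn,
        "allele_multi": fit_allele_multi,
        "allele_bi": fit_allele_bi,
        "joint": fit_joint,
        "codominant": fit_codominant,
    }
    if strategy not in funcs:
        raise ValueError(f"unknown strategy {strategy!r}")
    return funcs[strategy](cohort)


def transform_joint(beta1: float, beta2: float) -> tuple[float, float]:
    """Invert the joint model's coefficients to (OR_CN, OR_allele).

    Substituting S = c and D = c - 2b into the risk linear predictor gives
    beta1 = log OR_CN + 0.5*log OR_allele and beta2 = -0.5*log OR_allele,
    hence OR_allele = exp(-2*beta2) and OR_CN = exp(beta1 + beta2).
    """
    return math.exp(beta1 + beta2), math.exp(-2.0 * beta2)


# ---------------------------------------------------------------------------
# Bi-allelic QC
# ---------------------------------------------------------------------------

def _hwe_log_prob(n_ab: int, n_a: int, n_genotypes: int) -> float:
    """Log P(heterozygote count | allele counts) under HWE (exact null)."""
    n_b = 2 * n_genotypes - n_a
    n_aa = (n_a - n_ab) // 2
    n_bb = (n_b - n_ab) // 2
    return (
        gammaln(n_genotypes + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_ab + 1)
        - gammaln(n_bb + 1)
        + n_ab * math.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n_genotypes + 1)
    )


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test on genotype counts.

    Two-sided in the standard exact-test sense: the p-value sums the
    conditional probabilities (given allele counts) of every heterozygote
    count no more probable than the observed one.  Monomorphic samples
    return 1 by convention.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    n_minor = min(n_a, n_b)
    # heterozygote counts sharing the allele-count parity
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logps = np.array([_hwe_log_prob(int(h), n_a, n) for h in hets])
    logps -= np.logaddexp.reduce(logps)  # guard against rounding drift
    probs = np.exp(logps)
    p_obs = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square HWE test (no continuity correction)."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, 1))


def _call_counts(calls: np.ndarray) -> tuple[int, int, int]:
    calls = np.asarray(calls)
    return (
        int((calls == 0).sum()),
        int((calls == 1).sum()),
        int((calls == 2).sum()),
    )


def hwe_test(calls: np.ndarray, method: str = "exact") -> float:
    """HWE departure p-value from an array of call codes (missing excluded)."""
    n_aa, n_ab, n_bb = _call_counts(calls)
    if n_aa + n_ab + n_bb == 0:
        raise ValueError("no non-missing calls")
    test = {"exact": hwe_exact_test, "chisq": hwe_chisq_test}[method]
    return test(n_aa, n_ab, n_bb)


def missing_rate(calls: np.ndarray) -> float:
    """Fraction of calls that are missing."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("no calls")
    return float((calls == CALL_MISSING).mean())


@dataclass
class QcReport:
    """Bi-allelic QC summary: missing-call fraction and control-HWE p-value."""

    missing_fraction: float
    hwe_p: float
    missing_threshold: float = 0.05
    hwe_threshold: float = 1e-4

    @property
    def missing_pass(self) -> bool:
        return self.missing_fraction < self.missing_threshold

    @property
    def hwe_pass(self) -> bool:
        return self.hwe_p >= self.hwe_threshold


def qc_report(
    cohort: Cohort,
    missing_threshold: float = 0.05,
    hwe_threshold: float = 1e-4,
) -> QcReport:
    """Compute SNP-style QC on a degraded cohort (HWE among controls)."""
    if cohort.calls is None:
        raise ValueError("cohort has no bi-allelic calls")
    ctrl_calls = cohort.calls[cohort.phenotype == 0]
    ctrl_calls = ctrl_calls[ctrl_calls != CALL_MISSING]
    hwe_p = hwe_test(ctrl_calls) if ctrl_calls.size else math.nan
    return QcReport(
        missing_fraction=missing_rate(cohort.calls),
        hwe_p=hwe_p,
        missing_threshold=missing_threshold,
        hwe_threshold=hwe_threshold,
    )
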