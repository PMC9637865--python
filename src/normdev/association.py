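"""Association stage: deviation correlations and Bayesian deviation-domain models.

Pairwise Pearson correlations quantify how much the deviation scores from
the different modalities converge.  Each (deviation, behavioral domain)
pair is then modeled by a Bayesian linear regression::

    z = b0 + b_age * age_std + b_sex * sex + b_dom * domain_std + eps

with independent Normal(0, sd^2) priors on the coefficients (a proper
Normal(0, 1) on the standardized domain coefficient by default -- required
for the Savage-Dickey ratio -- and diffuse Normal(0, 10) on the intercept
and covariates) and a half-Student-t(3, 0, 2.5) prior on the residual SD.

The posterior is computed analytically conditional on the residual SD
(conjugate Gaussian), with the residual SD marginalized numerically over a
grid; seeded exact sampling from the same mixture is available for
cross-checking.  Evidence for/against each association is summarized by the
Savage-Dickey density ratio BF01 = p(b_dom = 0 | y) / p(b_dom = 0), mapped
onto the conventional evidence bands (anecdotal / moderate / strong / very
strong / extreme, toward the alternative for BF01 < 1 and toward the null
for BF01 > 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import logsumexp

COEF_NAMES = ("intercept", "age", "sex", "domain")
DEFAULT_PRIOR_SD = 1.0
COVARIATE_PRIOR_SD = 10.0
SIGMA_PRIOR_DF = 3.0
SIGMA_PRIOR_SCALE = 2.5
_N_SIGMA_GRID = 161


# ---------------------------------------------------------------------------
# Correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    labels: tuple[str, ...]
    r: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    stars: np.ndarray = field(repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.labels), columns=list(self.labels))

    def stars_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stars, index=list(self.labels), columns=list(self.labels)
        )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(deviations: pd.DataFrame) -> CorrelationMatrix:
    """Pearson r with two-sided t-test p-values and significance stars."""
    x = deviations.to_numpy(dtype=float)
    n, m = x.shape
    if m < 2:
        raise ValueError("need at least 2 deviation columns")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite values; correlation requires complete cases")
    if np.any(x.std(axis=0) <= 0):
        raise ValueError("constant deviation column")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    stars = np.vectorize(_stars)(p)
    np.fill_diagonal(stars, "")
    return CorrelationMatrix(
        labels=tuple(deviations.columns), r=r, p=p, stars=stars
    )


def standardize_predictors(*vectors: np.ndarray) -> tuple[np.ndarray, ...]:
    """Center and scale each vector to SD 1 on the analysis sample."""
    out = []
    for v in vectors:
        v = np.asarray(v, dtype=float)
        sd = v.std()
        if sd <= 0:
            raise ValueError("cannot standardize a constant vector")
        out.append((v - v.mean()) / sd)
    return tuple(out)


# ---------------------------------------------------------------------------
# Bayesian linear model with sigma marginalized on a grid
# ---------------------------------------------------------------------------

@dataclass
class AssociationModel:
    """Posterior of the association regression for one (z, domain) pair.

    The posterior of the coefficients is a mixture of conditional Gaussians
    N(m(sigma), V(sigma)) weighted by the grid posterior of the residual SD.
    """

    outcome: str
    coef_names: tuple[str, ...]
    prior_sd: np.ndarray = field(repr=False)
    sigma_grid: np.ndarray = field(repr=False)
    sigma_weights: np.ndarray = field(repr=False)
    cond_means: np.ndarray = field(repr=False)  # (g, d)
    cond_covs: np.ndarray = field(repr=False)  # (g, d, d)
    n_obs: int = 0

    def _idx(self, coefficient: str) -> int:
        return self.coef_names.index(coefficient)

    def posterior_mean(self, coefficient: str = "domain") -> float:
        j = self._idx(coefficient)
        return float(self.sigma_weights @ self.cond_means[:, j])

    def posterior_sd(self, coefficient: str = "domain") -> float:
        j = self._idx(coefficient)
        m = self.cond_means[:, j]
        v = self.cond_covs[:, j, j]
        mean = self.sigma_weights @ m
        return float(np.sqrt(self.sigma_weights @ (v + m**2) - mean**2))

    def posterior_density(self, value: float, coefficient: str = "domain") -> float:
        j = self._idx(coefficient)
        m = self.cond_means[:, j]
        s = np.sqrt(self.cond_covs[:, j, j])
        return float(self.sigma_weights @ stats.norm.pdf(value, loc=m, scale=s))

    def posterior_cdf(self, value: float, coefficient: str = "domain") -> float:
        j = self._idx(coefficient)
        m = self.cond_means[:, j]
        s = np.sqrt(self.cond_covs[:, j, j])
        return float(self.sigma_weights @ stats.norm.cdf(value, loc=m, scale=s))

    def credible_interval(
        self, level: float = 0.95, coefficient: str = "domain"
    ) -> tuple[float, float]:
        mu = self.posterior_mean(coefficient)
        sd = self.posterior_sd(coefficient)
        lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
        lo = brentq(
            lambda b: self.posterior_cdf(b, coefficient) - lo_q,
            mu - 12 * sd,
            mu + 12 * sd,
        )
        hi = brentq(
            lambda b: self.posterior_cdf(b, coefficient) - hi_q,
            mu - 12 * sd,
            mu + 12 * sd,
        )
        return float(lo), float(hi)

    def sample(self, draws: int = 4000, seed: int = 0) -> np.ndarray:
        """Exact seeded draws (draws, d) from the mixture posterior."""
        rng = np.random.default_rng(seed)
        comp = rng.choice(len(self.sigma_grid), size=draws, p=self.sigma_weights)
        d = len(self.coef_names)
        out = np.empty((draws, d))
        chols: dict[int, np.ndarray] = {}
        for i in np.unique(comp):
            chols[i] = np.linalg.cholesky(self.cond_covs[i])
        eps = rng.standard_normal((draws, d))
        for k in range(draws):
            i = comp[k]
            out[k] = self.cond_means[i] + chols[i] @ eps[k]
        return out

    def sigma_posterior_summary(self) -> dict[str, float]:
        mean = float(self.sigma_weights @ self.sigma_grid)
        var = float(self.sigma_weights @ self.sigma_grid**2 - mean**2)
        return {"mean": mean, "sd": float(np.sqrt(max(var, 0.0)))}


def _half_t_logpdf(sigma: np.ndarray) -> np.ndarray:
    return (
        stats.t.logpdf(sigma / SIGMA_PRIOR_SCALE, SIGMA_PRIOR_DF)
        + np.log(2.0)
        - np.log(SIGMA_PRIOR_SCALE)
    )


def fit_bayesian_lm(
    z: np.ndarray,
    age_std: np.ndarray,
    sex: np.ndarray,
    domain_std: np.ndarray,
    prior_sd: float = DEFAULT_PRIOR_SD,
    outcome: str = "z",
) -> AssociationModel:
    """Fit the association regression with the residual SD marginalized.

    With no data (all inputs empty) the posterior equals the prior, which is
    the no-information limit used to validate the Savage-Dickey ratio.
    """
    z = np.asarray(z, dtype=float)
    arrays = [np.asarray(a, dtype=float) for a in (age_std, sex, domain_std)]
    n = z.size
    if any(a.size != n for a in arrays):
        raise ValueError("all inputs must have equal length")
    prior_sds = np.array(
        [COVARIATE_PRIOR_SD, COVARIATE_PRIOR_SD, COVARIATE_PRIOR_SD, prior_sd]
    )
    if not np.all(np.isfinite(prior_sds)) or np.any(prior_sds <= 0):
        raise ValueError("coefficient priors must be proper (finite positive SD)")
    lam_inv = np.diag(1.0 / prior_sds**2)
    d = len(COEF_NAMES)

    if n == 0:
        # prior-only: sigma from its prior on a generic grid
        sigma = np.geomspace(SIGMA_PRIOR_SCALE / 50, SIGMA_PRIOR_SCALE * 50, _N_SIGMA_GRID)
        logw = _half_t_logpdf(sigma) + np.log(sigma)  # trapezoid in log-space
        w = np.exp(logw - logsumexp(logw))
        w /= w.sum()
        cov = np.diag(prior_sds**2)
        return AssociationModel(
            outcome=outcome,
            coef_names=COEF_NAMES,
            prior_sd=prior_sds,
            sigma_grid=sigma,
            sigma_weights=w,
            cond_means=np.zeros((sigma.size, d)),
            cond_covs=np.broadcast_to(cov, (sigma.size, d, d)).copy(),
            n_obs=0,
        )

    x = np.column_stack([np.ones(n), *arrays])
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(z)):
        raise ValueError("non-finite values; complete cases required")
    if np.linalg.matrix_rank(x) < d:
        raise ValueError("rank-deficient predictor set")

    xtx = x.T @ x
    xty = x.T @ z
    zz = float(z @ z)

    # residual-SD grid centered on the OLS residual scale
    beta_ols = np.linalg.solve(xtx + 1e-10 * np.eye(d), xty)
    resid = z - x @ beta_ols
    s_hat = float(np.sqrt(np.mean(resid**2)))
    s_hat = max(s_hat, 1e-8)
    sigma = np.geomspace(s_hat / 4.0, s_hat * 4.0, _N_SIGMA_GRID)

    log_post = np.empty(sigma.size)
    cond_means = np.empty((sigma.size, d))
    cond_covs = np.empty((sigma.size, d, d))
    sign_lam, logdet_lam = np.linalg.slogdet(np.diag(prior_sds**2))
    for i, s in enumerate(sigma):
        prec = lam_inv + xtx / s**2
        v = np.linalg.inv(prec)
        v = 0.5 * (v + v.T)
        m = v @ (xty / s**2)
        sign_v, logdet_v = np.linalg.slogdet(v)
        log_ml = (
            -0.5 * n * np.log(2.0 * np.pi * s**2)
            - 0.5 * logdet_lam
            + 0.5 * logdet_v
            - 0.5 * (zz / s**2 - m @ prec @ m)
        )
        log_post[i] = log_ml + _half_t_logpdf(np.array(s)) + np.log(s)
        cond_means[i] = m
        cond_covs[i] = v
    w = np.exp(log_post - logsumexp(log_post))
    w /= w.sum()
    return AssociationModel(
        outcome=outcome,
        coef_names=COEF_NAMES,
        prior_sd=prior_sds,
        sigma_grid=sigma,
        sigma_weights=w,
        cond_means=cond_means,
        cond_covs=cond_covs,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# Savage-Dickey Bayes factors and evidence bands
# ---------------------------------------------------------------------------

def savage_dickey_bf(
    model: AssociationModel,
    coefficient: str = "domain",
    method: str = "analytic",
    draws: np.ndarray | None = None,
    n_draws: int = 4000,
    seed: int = 0,
) -> float:
    """BF01 = posterior density at 0 / prior density at 0 for a coefficient.

    ``method='analytic'`` evaluates the mixture posterior density exactly;
    ``method='samples'`` uses a Gaussian KDE (Silverman bandwidth) on
    posterior draws, requiring at least 1000 of them.
    """
    j = model._idx(coefficient)
    prior_density0 = stats.norm.pdf(0.0, scale=model.prior_sd[j])
    if method == "analytic":
        post0 = model.posterior_density(0.0, coefficient)
    elif method == "samples":
        if draws is None:
            draws = model.sample(n_draws, seed=seed)[:, j]
        draws = np.asarray(draws, dtype=float).ravel()
        if draws.size < 1000:
            raise ValueError("need at least 1000 draws for a stable density at 0")
        post0 = float(stats.gaussian_kde(draws)(0.0)[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(post0 / prior_density0)


_ALT_BANDS = [(0.01, "extreme"), (0.03, "very strong"), (0.1, "strong"),
              (0.3, "moderate"), (1.0, "anecdotal")]
_NULL_BANDS = [(3.0, "anecdotal"), (10.0, "moderate"), (30.0, "strong"),
               (100.0, "very strong")]


def classify_bf(bf01: float) -> str:
    """Map a BF01 onto the conventional evidence bands.

    Toward the alternative (BF01 < 1): [0.3, 1) anecdotal, [0.1, 0.3)
    moderate, [0.03, 0.1) strong, [0.01, 0.03) very strong, < 0.01 extreme.
    Toward the null (BF01 > 1): (1, 3] anecdotal, (3, 10] moderate, (10, 30]
    strong, (30, 100] very strong, > 100 extreme.  BF01 = 1 is evidence in
    either direction.
    """
    if not np.isfinite(bf01) or bf01 <= 0:
        raise ValueError("BF01 must be a positive finite number")
    if bf01 == 1.0:
        return "evidence in either direction"
    if bf01 < 1.0:
        for upper, label in _ALT_BANDS:
            if bf01 < upper:
                return f"{label} (alternative)"
    for upper, label in _NULL_BANDS:
        if bf01 <= upper:
            return f"{label} (null)"
    return "extreme (null)"


# ---------------------------------------------------------------------------
# Full association grid
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    feature: str
    domain: str
    B: float
    ci95: tuple[float, float]
    BF01: float
    evidence_label: str
    direction: str


def run_association_grid(
    deviations: pd.DataFrame,
    domains: pd.DataFrame,
    cognition: np.ndarray | pd.Series,
    age: np.ndarray,
    sex: np.ndarray,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> pd.DataFrame:
    """One Bayesian model per (deviation feature x behavioral score) pair.

    ``deviations`` holds one column per modeled brain feature's deviation Z;
    behavioral scores are the domain columns of ``domains`` plus the
    cognitive deviation score.  Each model standardizes its own predictor
    and age; sex enters as the raw {0, 1} code.  Results are sorted by
    feature then domain.
    """
    n = len(deviations)
    cognition = np.asarray(cognition, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if not (len(domains) == cognition.size == age.size == sex.size == n):
        raise ValueError("misaligned inputs: all tables must cover the same subjects")
    if (
        "subject_id" in deviations.columns
        or "subject_id" in domains.columns
    ):
        dev_ids = deviations.get("subject_id")
        dom_ids = domains.get("subject_id")
        if dev_ids is not None and dom_ids is not None and not np.array_equal(
            dev_ids.to_numpy(), dom_ids.to_numpy()
        ):
            raise ValueError("misaligned subject IDs between deviations and domains")
        deviations = deviations.drop(columns="subject_id", errors="ignore")
        domains = domains.drop(columns="subject_id", errors="ignore")

    predictors = {c: domains[c].to_numpy(dtype=float) for c in domains.columns}
    predictors["COG_dev"] = cognition
    (age_std,) = standardize_predictors(age)

    rows = []
    for feature in deviations.columns:
        z = deviations[feature].to_numpy(dtype=float)
        for name, pred in predictors.items():
            (pred_std,) = standardize_predictors(pred)
            model = fit_bayesian_lm(
                z, age_std, sex, pred_std, prior_sd=prior_sd, outcome=feature
            )
            b = model.posterior_mean("domain")
            ci = model.credible_interval(0.95, "domain")
            bf = savage_dickey_bf(model, "domain", method="analytic")
            rows.append(
                {
                    "feature": feature,
                    "domain": name,
                    "B": b,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "BF01": bf,
                    "label": classify_bf(bf),
                    "direction": "negative" if b < 0 else "positive",
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["feature", "domain"], kind="stable").reset_index(drop=True)
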