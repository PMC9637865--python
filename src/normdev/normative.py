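"""Normative modeling of global brain features by Bayesian linear regression.

A normative model describes the expected value and uncertainty of a
phenotype as a function of covariates -- here age and sex -- so that each
individual can be referenced against same-aged peers.  The regression is
Bayesian linear regression (BLR) on an intercept, raw age, a sex code and a
clamped cubic B-spline expansion of age.  The weight prior is isotropic
Gaussian with precision ``alpha``; the noise is Gaussian with precision
``beta``.  Both hyperparameters are chosen by maximizing the log marginal
likelihood (model evidence) with Powell's method over log-parameters.

Per-subject deviation scores are Z-statistics computed out-of-fold under
k-fold cross-validation::

    z = (observed - predicted mean) / predictive SD

where the predictive variance includes both the noise variance ``1/beta``
and the posterior uncertainty of the weights.  On data truly generated by
the model the out-of-fold Z-scores are standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

DESIGN_BASE_COLUMNS = ("intercept", "age", "sex")


# ---------------------------------------------------------------------------
# Spline basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis over an age range.

    Boundary knots are repeated ``degree + 1`` times so the basis is a
    partition of unity on ``[boundary[0], boundary[1]]`` and the first/last
    basis function equals 1 at the corresponding boundary.
    """

    degree: int
    interior_knots: tuple[float, ...]
    boundary: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and not (np.all(np.diff(ik) > 0) and ik[0] > lo and ik[-1] < hi):
            raise ValueError(
                "interior knots must be strictly increasing and strictly "
                f"inside the boundary {self.boundary}; got {self.interior_knots}"
            )

    @property
    def n_basis(self) -> int:
        return self.degree + len(self.interior_knots) + 1

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate([
            np.full(self.degree + 1, lo),
            np.asarray(self.interior_knots, dtype=float),
            np.full(self.degree + 1, hi),
        ])

    def evaluate(self, ages: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Return the (n, n_basis) basis matrix at the given ages.

        Ages outside the boundary raise ``ValueError`` unless ``clamp=True``,
        in which case they are clamped to the boundary (used for
        cross-validation test folds that slightly exceed the training range).
        """
        ages = np.asarray(ages, dtype=float)
        lo, hi = self.boundary
        if clamp:
            n_out = int(np.sum((ages < lo) | (ages > hi)))
            if n_out:
                logger.warning(
                    "%d age(s) outside basis boundary [%g, %g]; clamped", n_out, lo, hi
                )
            ages = np.clip(ages, lo, hi)
        elif ages.size and (ages.min() < lo or ages.max() > hi):
            raise ValueError(
                f"age outside basis boundary [{lo}, {hi}]: "
                f"range [{ages.min()}, {ages.max()}]"
            )
        if ages.size == 0:
            return np.empty((0, self.n_basis))
        return BSpline.design_matrix(
            ages, self.knot_vector, self.degree, extrapolate=False
        ).toarray()


def build_spline_basis(
    ages: np.ndarray, n_interior_knots: int = 3, degree: int = 3
) -> SplineBasis:
    """Basis with ``n_interior_knots`` evenly spaced knots between the
    observed min and max age (open interval), cubic by default."""
    ages = np.asarray(ages, dtype=float)
    if np.unique(ages).size < 2:
        raise ValueError("need at least 2 distinct ages to place spline knots")
    if n_interior_knots < 1:
        raise ValueError("n_interior_knots must be >= 1")
    lo, hi = float(ages.min()), float(ages.max())
    interior = np.linspace(lo, hi, n_interior_knots + 2)[1:-1]
    return SplineBasis(degree=degree, interior_knots=tuple(interior), boundary=(lo, hi))


def build_design(
    ages: np.ndarray,
    sexes: np.ndarray,
    basis: SplineBasis,
    clamp_ages: bool = False,
) -> pd.DataFrame:
    """Design matrix [intercept, age, sex, spline_1..spline_m].

    The clamped spline columns span constants and affine-in-age functions, so
    the full design is numerically rank-deficient by construction; the ridge
    prior of the BLR regularizes this (no pseudo-inverse is ever taken).
    """
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    if ages.shape != sexes.shape:
        raise ValueError("ages and sexes must have equal length")
    if ages.size and not np.all(np.isfinite(ages)):
        raise ValueError("non-finite ages in design input")
    if sexes.size and not np.all(np.isin(sexes, [0, 1])):
        raise ValueError("sex must be coded {0, 1}")
    spline = basis.evaluate(ages, clamp=clamp_ages)
    cols = {
        "intercept": np.ones_like(ages),
        "age": ages,
        "sex": sexes.astype(float),
    }
    for j in range(basis.n_basis):
        cols[f"spline_{j + 1}"] = spline[:, j]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Bayesian linear regression
# ---------------------------------------------------------------------------

@dataclass
class NormativeFit:
    """Fitted BLR for one feature.

    weight posterior: N(m, S) with S = (alpha*I + beta*Phi'Phi)^-1 and
    m = beta * S * Phi'y; ``log_evidence`` is log p(y | alpha, beta) in nats.
    """

    basis: SplineBasis | None
    column_names: tuple[str, ...]
    weight_posterior_mean: np.ndarray
    weight_posterior_covariance: np.ndarray
    alpha: float
    beta: float
    log_evidence: float


def log_marginal_likelihood(
    phi: np.ndarray, y: np.ndarray, alpha: float, beta: float
) -> float:
    """Log evidence log p(y | alpha, beta) of the BLR model.

    Equals the log-density of y under N(0, Phi Phi'/alpha + I/beta), computed
    in the weight space (d x d) rather than the data space (n x n).
    """
    n, d = phi.shape
    gram = phi.T @ phi
    hy = phi.T @ y
    return _log_evidence_from_moments(gram, hy, float(y @ y), n, alpha, beta)[0]


def _log_evidence_from_moments(gram, hy, yy, n, alpha, beta):
    """Evidence plus posterior (mean, cov factor) from sufficient statistics."""
    d = gram.shape[0]
    a_mat = alpha * np.eye(d) + beta * gram
    try:
        chol = np.linalg.cholesky(a_mat)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    m = beta * _chol_solve(chol, hy)
    sse = yy - 2.0 * m @ hy + m @ gram @ m
    log_det_a = 2.0 * np.sum(np.log(np.diag(chol)))
    log_ev = (
        0.5 * d * np.log(alpha)
        + 0.5 * n * np.log(beta)
        - 0.5 * n * np.log(2.0 * np.pi)
        - 0.5 * log_det_a
        - 0.5 * beta * sse
        - 0.5 * alpha * (m @ m)
    )
    return float(log_ev), m, chol


def _chol_solve(chol: np.ndarray, b: np.ndarray) -> np.ndarray:
    z = np.linalg.solve(chol, b)
    return np.linalg.solve(chol.T, z)


def fit_blr(
    design: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    alpha: float | None = None,
    beta: float | None = None,
    basis: SplineBasis | None = None,
    max_restarts: int = 3,
) -> NormativeFit:
    """Fit the BLR, optimizing (alpha, beta) by evidence maximization.

    If ``alpha`` and ``beta`` are both given, the posterior is computed at
    those fixed values (no optimization).  Otherwise Powell's method is run
    over (log alpha, log beta) starting at (0, log(1/var(y))), with up to
    ``max_restarts`` jittered restarts if the result is non-finite.
    """
    if isinstance(design, pd.DataFrame):
        col_names = tuple(design.columns)
        phi = design.to_numpy(dtype=float)
    else:
        phi = np.asarray(design, dtype=float)
        col_names = tuple(f"x{j}" for j in range(phi.shape[1]))
    y = np.asarray(y, dtype=float)
    n, d = phi.shape
    if y.shape != (n,):
        raise ValueError("design rows must match length of y")
    if n < d:
        raise ValueError(f"need at least as many rows ({n}) as columns ({d})")
    var_y = float(np.var(y))
    if var_y <= 0.0:
        raise ValueError("y has zero variance; cannot fit a normative model")

    gram = phi.T @ phi
    hy = phi.T @ y
    yy = float(y @ y)

    if alpha is not None and beta is not None:
        a_opt, b_opt = float(alpha), float(beta)
    else:
        def neg_log_ev(log_ab):
            a, b = np.exp(log_ab)
            if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
                return np.inf
            ev = _log_evidence_from_moments(gram, hy, yy, n, a, b)[0]
            return -ev if np.isfinite(ev) else np.inf

        start = np.array([0.0, np.log(1.0 / var_y)])
        rng = np.random.default_rng(0)
        best = None
        x0 = start
        for attempt in range(max_restarts + 1):
            res = optimize.minimize(neg_log_ev, x0, method="Powell")
            if np.isfinite(res.fun) and np.all(np.isfinite(res.x)):
                if best is None or res.fun < best.fun:
                    best = res
                break
            x0 = start + rng.normal(scale=1.0, size=2)
        if best is None:
            raise RuntimeError(
                "evidence optimization failed to return finite hyperparameters"
            )
        a_opt, b_opt = np.exp(best.x)

    log_ev, m, chol = _log_evidence_from_moments(gram, hy, yy, n, a_opt, b_opt)
    if m is None:
        raise RuntimeError("posterior computation failed at the optimum")
    cov = _chol_solve(chol, np.eye(d))
    cov = 0.5 * (cov + cov.T)
    return NormativeFit(
        basis=basis,
        column_names=col_names,
        weight_posterior_mean=m,
        weight_posterior_covariance=cov,
        alpha=float(a_opt),
        beta=float(b_opt),
        log_evidence=log_ev,
    )


def predict(
    fit: NormativeFit, design: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance at new design rows.

    variance = 1/beta + diag(Phi S Phi'), hence always >= 1/beta.
    """
    if isinstance(design, pd.DataFrame):
        if tuple(design.columns) != fit.column_names:
            raise ValueError(
                f"design columns {tuple(design.columns)} do not match "
                f"fit layout {fit.column_names}"
            )
        phi = design.to_numpy(dtype=float)
    else:
        phi = np.asarray(design, dtype=float)
        if phi.ndim != 2 or phi.shape[1] != len(fit.column_names):
            raise ValueError("design column count does not match fit layout")
    if phi.shape[0] == 0:
        return np.empty(0), np.empty(0)
    mean = phi @ fit.weight_posterior_mean
    var = 1.0 / fit.beta + np.einsum(
        "ij,jk,ik->i", phi, fit.weight_posterior_covariance, phi
    )
    return mean, var


def deviation_z(observed, pred_mean, pred_var):
    """Deviation Z-score: (observed - predicted) / predictive SD."""
    observed = np.asarray(observed, dtype=float)
    pred_mean = np.asarray(pred_mean, dtype=float)
    pred_var = np.asarray(pred_var, dtype=float)
    if np.any(pred_var <= 0.0):
        raise ValueError("predictive variance must be strictly positive")
    return (observed - pred_mean) / np.sqrt(pred_var)


# ---------------------------------------------------------------------------
# Metrics and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FitMetrics:
    """Out-of-sample performance summary.

    explained_variance: 1 - var(y - yhat)/var(y)  (population variances)
    smse: mean squared error / var(y)
    msll: mean standardized log loss vs the trivial Gaussian predictor, nats
    rho:  Pearson correlation of predicted vs observed (0 with
          ``rho_degenerate=True`` when the predictions are constant)
    """

    explained_variance: float
    smse: float
    msll: float
    rho: float
    rho_degenerate: bool = False


def fit_metrics(
    y: np.ndarray,
    yhat: np.ndarray,
    yvar: np.ndarray | None = None,
    train_mean: float | None = None,
    train_var: float | None = None,
) -> FitMetrics:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must have equal length >= 2")
    var_y = float(np.var(y))
    if var_y <= 0.0:
        raise ValueError("y has zero variance")
    resid = y - yhat
    ev = 1.0 - float(np.var(resid)) / var_y
    smse = float(np.mean(resid**2)) / var_y
    if np.var(yhat) <= 0.0:
        rho, degenerate = 0.0, True
    else:
        rho = float(np.corrcoef(y, yhat)[0, 1])
        degenerate = False
    msll = np.nan
    if yvar is not None:
        yvar = np.asarray(yvar, dtype=float)
        mu0 = float(np.mean(y)) if train_mean is None else float(train_mean)
        v0 = var_y if train_var is None else float(train_var)
        nll_model = 0.5 * (np.log(2.0 * np.pi * yvar) + resid**2 / yvar)
        nll_trivial = 0.5 * (np.log(2.0 * np.pi * v0) + (y - mu0) ** 2 / v0)
        msll = float(np.mean(nll_model - nll_trivial))
    return FitMetrics(
        explained_variance=ev, smse=smse, msll=msll, rho=rho, rho_degenerate=degenerate
    )


@dataclass
class DeviationScores:
    """Out-of-fold deviation Z-scores for one feature."""

    feature_name: str
    table: pd.DataFrame = field(repr=False)  # subject_id, feature, z, fold

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy()


def crossval_deviations(
    cohort: pd.DataFrame,
    feature: str,
    k: int = 10,
    seed: int = 0,
    n_interior_knots: int = 3,
) -> tuple[DeviationScores, FitMetrics]:
    """k-fold cross-validated deviation Z-scores and pooled metrics.

    Subjects are partitioned by a seeded shuffle into k contiguous folds (no
    stratification).  The spline basis and the BLR are refit on each training
    split; test ages outside the training range are clamped to the training
    boundary with a logged warning.
    """
    if feature not in cohort.columns:
        raise KeyError(f"feature {feature!r} not in cohort table")
    for col in ("age", "sex"):
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks required column {col!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(cohort)
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")

    ages = cohort["age"].to_numpy(dtype=float)
    sexes = cohort["sex"].to_numpy()
    y = cohort[feature].to_numpy(dtype=float)
    subject_ids = (
        cohort["subject_id"].to_numpy()
        if "subject_id" in cohort.columns
        else np.arange(n)
    )

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    z = np.empty(n)
    yhat = np.empty(n)
    yvar = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    msll_parts = np.empty(n)
    for fold_idx, test in enumerate(folds):
        train = np.setdiff1d(order, test, assume_unique=True)
        basis = build_spline_basis(ages[train], n_interior_knots=n_interior_knots)
        fit = fit_blr(
            build_design(ages[train], sexes[train], basis),
            y[train],
            basis=basis,
        )
        test_design = build_design(ages[test], sexes[test], basis, clamp_ages=True)
        mu, var = predict(fit, test_design)
        z[test] = deviation_z(y[test], mu, var)
        yhat[test] = mu
        yvar[test] = var
        fold_of[test] = fold_idx + 1
        mu0, v0 = float(np.mean(y[train])), float(np.var(y[train]))
        msll_parts[test] = 0.5 * (
            np.log(2.0 * np.pi * var) + (y[test] - mu) ** 2 / var
        ) - 0.5 * (np.log(2.0 * np.pi * v0) + (y[test] - mu0) ** 2 / v0)

    metrics = fit_metrics(y, yhat, yvar)
    metrics.msll = float(np.mean(msll_parts))  # per-fold training baselines
    scores = DeviationScores(
        feature_name=feature,
        table=pd.DataFrame(
            {
                "subject_id": subject_ids,
                "feature": feature,
                "z": z,
                "fold": fold_of,
            }
        ),
    )
    return scores, metrics
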