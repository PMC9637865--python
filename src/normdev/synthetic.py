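"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes for a
developmental cohort: six global brain features (skeleton-mean FA, MD, RD,
L1; mean cortical thickness; total surface area) following smooth nonlinear
age trajectories with sex offsets; a cross-feature correlated latent
deviation structure; a 129-item, 7-domain latent questionnaire generating
ordinal symptom items; a one-factor 14-test cognitive battery; and
injectable linear deviation-domain associations of known standardized size.

Every random element derives from a single integer seed expanded into named
substreams, so identical inputs give byte-identical output tables, and every
latent quantity (per-subject deviations, domain scores) is returned
alongside the observable table so parameter recovery can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURES = ("FA", "MD", "RD", "L1", "CT", "SA", "COG")
BRAIN_FEATURES = FEATURES[:6]
N_DOMAINS = 7
N_ITEMS = 129
N_COG_TESTS = 14
AGE_RANGE = (8.0, 22.0)


@dataclass(frozen=True)
class TrajectorySpec:
    """Population mean trajectory of one feature over age.

    The mean at age a, sex s is::

        baseline + sum_k age_coefficients[k-1] * u**k + sex_offset * s

    with ``u = (a - age_range[0]) / (age_range[1] - age_range[0])`` in [0, 1].
    ``noise_sd`` is the measurement noise SD on top of the latent deviation.
    """

    feature_name: str
    baseline: float
    age_coefficients: tuple[float, ...]
    sex_offset: float = 0.0
    noise_sd: float = 0.0
    age_range: tuple[float, float] = AGE_RANGE

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        vals = [self.baseline, self.sex_offset, *self.age_coefficients]
        if not np.all(np.isfinite(vals)):
            raise ValueError("trajectory parameters must be finite")


def trajectory_value(spec: TrajectorySpec, age, sex):
    """Deterministic mean feature value at (age, sex)."""
    age = np.asarray(age, dtype=float)
    lo, hi = spec.age_range
    if np.any(age < lo) or np.any(age > hi):
        raise ValueError(f"age outside configured range [{lo}, {hi}]")
    u = (age - lo) / (hi - lo)
    out = np.full_like(u, spec.baseline, dtype=float)
    for k, c in enumerate(spec.age_coefficients, start=1):
        out += c * u**k
    out += spec.sex_offset * np.asarray(sex, dtype=float)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DeviationStructure:
    """Latent deviation model: unit-variance latents with a target
    correlation matrix, scaled per feature into feature units."""

    feature_names: tuple[str, ...]
    target_correlation: np.ndarray = field(repr=False)
    scale: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.target_correlation, dtype=float)
        m = len(self.feature_names)
        if r.shape != (m, m):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(r, r.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        eigvals = np.linalg.eigvalsh(r)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        s = np.asarray(self.scale, dtype=float)
        if s.shape != (m,) or np.any(s < 0):
            raise ValueError("scale must be a nonnegative vector, one per feature")
        object.__setattr__(self, "target_correlation", r)
        object.__setattr__(self, "scale", s)


@dataclass(frozen=True)
class EffectSpec:
    """Injected linear association between a feature's deviation and a
    psychopathology domain ('general' = the mean-weight general factor).

    ``beta`` is the standardized effect: deviation-Z units per SD of domain
    score -- the quantity the association stage estimates as B.
    """

    domain: int | str
    feature_name: str
    beta: float

    def __post_init__(self) -> None:
        ok = self.domain == "general" or (
            isinstance(self.domain, (int, np.integer)) and 1 <= self.domain <= N_DOMAINS
        )
        if not ok:
            raise ValueError(f"domain must be 1..{N_DOMAINS} or 'general'")
        if self.feature_name not in FEATURES:
            raise ValueError(f"unknown feature {self.feature_name!r}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_trajectories() -> list[TrajectorySpec]:
    """Developmental trajectory library in realistic units.

    FA rises and saturates; MD/RD/L1 (1e-3 mm^2/s) decline; cortical
    thickness (mm) thins monotonically; surface area (1e5 mm^2) follows an
    inverted U peaking in early adolescence; the cognitive latent rises with
    age.  Deviation scales and noise SDs are set so age and sex explain
    roughly a fifth to a third of each feature's variance.
    """
    return [
        TrajectorySpec("FA", 0.40, (0.09, -0.03), sex_offset=0.004, noise_sd=0.013),
        TrajectorySpec("MD", 0.80, (-0.09, 0.03), sex_offset=-0.005, noise_sd=0.013),
        TrajectorySpec("RD", 0.60, (-0.09, 0.03), sex_offset=-0.004, noise_sd=0.013),
        TrajectorySpec("L1", 1.20, (-0.075, 0.025), sex_offset=-0.005, noise_sd=0.014),
        TrajectorySpec("CT", 2.85, (-0.30, 0.05), sex_offset=-0.01, noise_sd=0.055),
        TrajectorySpec("SA", 1.75, (0.10, -0.16), sex_offset=0.15, noise_sd=0.05),
        TrajectorySpec("COG", -1.2, (2.6, -0.8), sex_offset=0.0, noise_sd=0.7),
    ]


# Latent-deviation correlation targets, loosely mirroring the empirical
# pattern in developmental multimodal samples: FA strongly anticorrelated
# with RD, MD tracking RD and L1, cortical thickness nearly independent of
# the diffusion features, surface area moderately tied to FA and cognition.
_DEFAULT_CORR = np.array(
    [
        [1.00, -0.60, -0.88, -0.03, 0.01, 0.27, -0.17],
        [-0.60, 1.00, 0.88, 0.78, 0.02, -0.10, 0.05],
        [-0.88, 0.88, 1.00, 0.45, 0.01, -0.15, 0.09],
        [-0.03, 0.78, 0.45, 1.00, 0.03, 0.05, -0.12],
        [0.01, 0.02, 0.01, 0.03, 1.00, 0.13, -0.07],
        [0.27, -0.10, -0.15, 0.05, 0.13, 1.00, -0.32],
        [-0.17, 0.05, 0.09, -0.12, -0.07, -0.32, 1.00],
    ]
)

_DEFAULT_SCALE = np.array([0.020, 0.020, 0.020, 0.018, 0.09, 0.08, 0.8])


def default_deviation_structure() -> DeviationStructure:
    return DeviationStructure(
        feature_names=FEATURES,
        target_correlation=_DEFAULT_CORR.copy(),
        scale=_DEFAULT_SCALE.copy(),
    )


def default_item_loadings(
    n_items: int = N_ITEMS, n_domains: int = N_DOMAINS
) -> np.ndarray:
    """Simple-structure loading matrix: item i loads on domain i mod 7 with
    loading cycling through 0.6 / 0.7 / 0.8."""
    lam = np.zeros((n_items, n_domains))
    strengths = (0.6, 0.7, 0.8)
    for i in range(n_items):
        lam[i, i % n_domains] = strengths[(i // n_domains) % 3]
    return lam


DEFAULT_ITEM_THRESHOLDS = (0.5, 1.2, 2.0)
DEFAULT_COG_LOADINGS = tuple([0.7] * N_COG_TESTS)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Observable table plus the generating latents (ground truth)."""

    table: pd.DataFrame
    latents: pd.DataFrame


def _domain_weight_matrix(
    effects: list[EffectSpec],
    feature_names: tuple[str, ...],
    scale: np.ndarray,
    noise_sd: dict[str, float],
    corr: np.ndarray,
    cog_attenuation: float,
) -> np.ndarray:
    """Weights C (domains x features) of deviation latents in the domain
    scores, inflated so the induced standardized coefficient on the observed
    deviation Z equals each effect's beta.

    Observed Z approximately equals (scale*u + noise)/sqrt(scale^2+noise^2),
    so corr(Z, u) = scale/sqrt(scale^2+noise^2) and the latent weight must be
    beta divided by that attenuation factor.  For the cognitive feature the
    factor-score extraction adds a further attenuation, approximated from
    the battery's loadings.
    """
    c_mat = np.zeros((N_DOMAINS, len(feature_names)))
    for eff in effects:
        f = feature_names.index(eff.feature_name)
        s, nsd = scale[f], noise_sd[eff.feature_name]
        if s <= 0:
            raise ValueError(
                f"cannot inject an effect on {eff.feature_name}: deviation scale is 0"
            )
        atten = s / np.hypot(s, nsd)
        if eff.feature_name == "COG":
            atten *= cog_attenuation
        target = eff.beta / atten
        if eff.domain == "general":
            # Solve corr(mean of 7 domains, u) = target for the common
            # per-domain weight c:  7c / sqrt(7 + 42 c^2) = target.
            denom = 49.0 - 42.0 * target**2
            if denom <= 0 or abs(target) >= 1:
                raise ValueError(f"general effect beta {eff.beta} too large to inject")
            c = target * np.sqrt(7.0 / denom)
            c_mat[:, f] += c
        else:
            c_mat[eff.domain - 1, f] += target
    # residual domain variance must stay positive
    res_var = 1.0 - np.einsum("df,fg,dg->d", c_mat, corr, c_mat)
    if np.any(res_var <= 0):
        raise ValueError("injected effects are jointly too large (variance > 1)")
    return c_mat


def generate_cohort(
    n: int,
    trajectories: list[TrajectorySpec] | None = None,
    dev_structure: DeviationStructure | None = None,
    effects: list[EffectSpec] | None = None,
    item_loadings: np.ndarray | None = None,
    item_thresholds: tuple[float, ...] = DEFAULT_ITEM_THRESHOLDS,
    cog_loadings: tuple[float, ...] = DEFAULT_COG_LOADINGS,
    match_moments: bool = True,
    seed: int = 0,
) -> SimulatedCohort:
    """Generate a complete synthetic cohort.

    Ages are uniform over the configured range (default 8-22 years), sex is
    Bernoulli(0.5).  Each brain feature is trajectory(age, sex) + scaled
    latent deviation + measurement noise, with latent deviations jointly
    multivariate normal per ``dev_structure``.  The 129 ordinal items arise
    from 7 latent domain scores through ``item_loadings`` and thresholding;
    domain scores are correlated with the deviation latents per ``effects``.
    The 14 cognitive tests load on the latent cognitive trajectory.

    With ``match_moments=True`` (default) the deviation latents are rescaled
    so their empirical mean/covariance equal the target exactly, as in
    ``MASS::mvrnorm(empirical=TRUE)``: the cohort then carries the specified
    deviation structure rather than a Monte Carlo approximation of it.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    trajectories = trajectories if trajectories is not None else default_trajectories()
    dev_structure = (
        dev_structure if dev_structure is not None else default_deviation_structure()
    )
    effects = list(effects) if effects else []
    lam = (
        np.asarray(item_loadings, dtype=float)
        if item_loadings is not None
        else default_item_loadings()
    )
    if lam.shape != (N_ITEMS, N_DOMAINS):
        raise ValueError(
            f"item loading matrix must be {N_ITEMS} x {N_DOMAINS}, got {lam.shape}"
        )
    item_res_var = 1.0 - np.einsum("ij,ij->i", lam, lam)
    if np.any(item_res_var < 0):
        raise ValueError("item loading rows must have squared norm <= 1")
    cog_load = np.asarray(cog_loadings, dtype=float)
    if cog_load.shape != (N_COG_TESTS,):
        raise ValueError(f"need {N_COG_TESTS} cognitive loadings")

    traj = {t.feature_name: t for t in trajectories}
    missing = [f for f in dev_structure.feature_names if f not in traj]
    if missing:
        raise ValueError(f"missing trajectory specs for {missing}")
    noise_sd = {f: traj[f].noise_sd for f in dev_structure.feature_names}

    # factor-score attenuation of the cognitive battery (approximate):
    # mean-score error SD relative to the latent is nu / (lambda * sqrt(p))
    cog_spec = traj["COG"]
    cog_scale = dev_structure.scale[dev_structure.feature_names.index("COG")]
    mean_load = float(np.mean(cog_load))
    if cog_scale > 0 and cog_spec.noise_sd > 0 and mean_load > 0:
        err_sd = cog_spec.noise_sd / (mean_load * np.sqrt(N_COG_TESTS))
        cog_attenuation = cog_scale / np.hypot(cog_scale, err_sd)
    else:
        cog_attenuation = 1.0
    noise_sd = dict(noise_sd)
    noise_sd["COG"] = 0.0  # test noise enters through the battery, handled above
    c_mat = _domain_weight_matrix(
        effects,
        dev_structure.feature_names,
        dev_structure.scale,
        noise_sd,
        dev_structure.target_correlation,
        cog_attenuation,
    )

    ss = np.random.SeedSequence(seed)
    rng_demo, rng_dev, rng_dom, rng_item, rng_cog, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    lo, hi = traj[dev_structure.feature_names[0]].age_range
    ages = rng_demo.uniform(lo, hi, size=n)
    sexes = rng_demo.integers(0, 2, size=n)

    # unit-variance correlated deviation latents (eigh handles semidefinite)
    m = len(dev_structure.feature_names)
    evals, evecs = np.linalg.eigh(dev_structure.target_correlation)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    raw = rng_dev.standard_normal((n, m))
    if match_moments and n > m + 1:
        # whiten the empirical sample before recoloring so the cohort's
        # latent covariance equals the target exactly
        raw = raw - raw.mean(axis=0)
        emp_chol = np.linalg.cholesky(raw.T @ raw / n)
        raw = np.linalg.solve(emp_chol, raw.T).T
    u = raw @ root.T

    # domain scores: injected deviation components + independent residual
    res_sd = np.sqrt(
        1.0
        - np.einsum(
            "df,fg,dg->d", c_mat, dev_structure.target_correlation, c_mat
        )
    )
    domains = u @ c_mat.T + rng_dom.standard_normal((n, N_DOMAINS)) * res_sd

    columns: dict[str, np.ndarray | list] = {
        "subject_id": [f"S{i + 1:05d}" for i in range(n)],
        "age": ages,
        "sex": sexes,
    }
    scale_of = dict(zip(dev_structure.feature_names, dev_structure.scale))
    u_of = {f: u[:, j] for j, f in enumerate(dev_structure.feature_names)}
    for f in BRAIN_FEATURES:
        columns[f] = (
            trajectory_value(traj[f], ages, sexes)
            + scale_of[f] * u_of[f]
            + traj[f].noise_sd * rng_noise.standard_normal(n)
        )

    g = trajectory_value(cog_spec, ages, sexes) + scale_of["COG"] * u_of["COG"]
    for t in range(N_COG_TESTS):
        columns[f"cog_{t + 1:02d}"] = (
            cog_load[t] * g + cog_spec.noise_sd * rng_cog.standard_normal(n)
        )

    item_latent = domains @ lam.T + np.sqrt(item_res_var) * rng_item.standard_normal(
        (n, N_ITEMS)
    )
    thresholds = np.asarray(item_thresholds, dtype=float)
    items = (item_latent[:, :, None] > thresholds).sum(axis=2)
    for i in range(N_ITEMS):
        columns[f"item_{i + 1:03d}"] = items[:, i]
    table = pd.DataFrame(columns)

    latents = pd.DataFrame(
        {f"dev_{f}": u_of[f] for f in dev_structure.feature_names}
        | {f"dom_{d + 1}": domains[:, d] for d in range(N_DOMAINS)}
    )
    latents["general"] = domains.mean(axis=1)
    latents.insert(0, "subject_id", table["subject_id"])
    return SimulatedCohort(table=table, latents=latents)
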