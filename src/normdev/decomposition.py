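"""Behavioral decomposition: cognitive general factor and ICA symptom domains.

Two reductions feed the association stage:

* the first principal component of the 14-test cognitive battery, used as a
  general cognitive function score (later passed through the same normative
  model as the brain features to yield a cognitive deviation score);
* a stability-resampled independent component analysis of the 129
  questionnaire items, retaining 7 domains plus a general-psychopathology
  proxy defined as each subject's mean weight across the 7 components.

The ICA follows the Icasso recipe: FastICA is run many times from different
random initializations, all estimated components are pooled and clustered by
absolute correlation, and each cluster's centrotype is kept as the
representative component.  The cluster-compactness index (mean within-cluster
minus mean between-cluster similarity) quantifies how reproducible each
component is; values near 1 indicate a stable component, values below 0.5
suggest no identifiable non-Gaussian structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)


@dataclass
class CognitiveFactor:
    """First principal component of the cognitive battery.

    ``scores`` are standardized (mean 0, SD 1) over the analysis sample and
    sign-oriented so the mean loading is positive (higher = better when the
    tests are scored higher-is-better).
    """

    scores: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)
    variance_explained: float = 0.0


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd <= 0):
        raise ValueError("constant column in input table")
    return (x - x.mean(axis=0)) / sd


def cognitive_general_factor(tests: pd.DataFrame | np.ndarray) -> CognitiveFactor:
    """Extract the general cognitive factor from an n x 14 test table."""
    x = np.asarray(tests, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite values in cognitive tests")
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than tests ({p})")
    xs = _standardize_columns(x)
    # PC1 via SVD of the standardized data
    u_mat, s, vt = np.linalg.svd(xs, full_matrices=False)
    loadings = vt[0]
    scores = xs @ loadings
    if loadings.mean() < 0:
        loadings = -loadings
        scores = -scores
    scores = (scores - scores.mean()) / scores.std()
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return CognitiveFactor(
        scores=scores, loadings=loadings, variance_explained=var_explained
    )


@dataclass
class DomainScores:
    """Stability-resampled ICA decomposition of the questionnaire items.

    weights: (n, k) subject weights, sign-oriented and ordered by explained
        item variance; ``general`` is the row-wise mean of the 7 weights.
    mixing: (p, k) item loading matrix of the representative components.
    stability: per-component cluster-compactness index in [0, 1].
    """

    weights: np.ndarray = field(repr=False)
    mixing: np.ndarray = field(repr=False)
    general: np.ndarray = field(repr=False)
    stability: np.ndarray = field(repr=False)
    n_converged_runs: int = 0

    def as_frame(self, subject_ids=None) -> pd.DataFrame:
        k = self.weights.shape[1]
        df = pd.DataFrame(
            self.weights, columns=[f"IC{j + 1}" for j in range(k)]
        )
        df["general"] = self.general
        if subject_ids is not None:
            df.insert(0, "subject_id", np.asarray(subject_ids))
        return df


def _abs_corr(signals: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between row vectors (source estimates)."""
    c = signals - signals.mean(axis=1, keepdims=True)
    c /= np.linalg.norm(c, axis=1, keepdims=True)
    return np.abs(np.clip(c @ c.T, -1.0, 1.0))


def ica_domains(
    items: pd.DataFrame | np.ndarray,
    n_components: int = 7,
    n_runs: int = 20,
    seed: int = 0,
    bootstrap: bool = True,
) -> DomainScores:
    """Icasso-style stability ICA of an n x p item table.

    Items are column-standardized; FastICA (tanh/logcosh contrast, whitened)
    is run ``n_runs`` times from seeded random initializations, each run on
    a bootstrap resample of subjects (``bootstrap=False`` refits the full
    sample and then probes only initialization sensitivity).  Every run's
    unmixing is applied to the full sample, and the pooled source estimates
    are clustered by average-linkage agglomeration on 1 - |corr| distance;
    each cluster's centrotype (the member most similar to the rest of its
    cluster) is the representative.  Subject weights are the least-squares
    projection of the standardized data onto the representative mixing
    matrix.
    """
    x = np.asarray(items, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite values in item table")
    n, p = x.shape
    if n <= n_components:
        raise ValueError("need more subjects than components")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    xs = _standardize_columns(x)

    ss = np.random.SeedSequence(seed)
    pooled_sources: list[np.ndarray] = []  # (k, n) source estimates per run
    pooled_mixing: list[np.ndarray] = []  # (k, p) matching loading vectors
    n_converged = 0
    for run_idx, child in enumerate(ss.spawn(n_runs)):
        states = child.generate_state(2)
        rs = int(states[0] % (2**31))
        if bootstrap and run_idx > 0:  # first run keeps the original sample
            boot = np.random.default_rng(states[1]).integers(0, n, size=n)
            x_fit = xs[boot]
        else:
            x_fit = xs
        ica = FastICA(
            n_components=n_components,
            fun="logcosh",
            whiten="unit-variance",
            max_iter=500,
            tol=1e-4,
            random_state=rs,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                ica.fit(x_fit)
            except (ValueError, np.linalg.LinAlgError):
                continue
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        n_converged += converged
        # evaluate every run's sources on the full sample for comparability
        sources = (xs - ica.mean_) @ ica.components_.T  # (n, k)
        pooled_sources.append(sources.T)
        pooled_mixing.append(ica.mixing_.T)
    if not pooled_sources:
        raise RuntimeError("FastICA failed in every run")
    if n_converged == 0:
        logger.warning("no FastICA run converged; estimates may be unstable")
    sources_all = np.vstack(pooled_sources)
    mixing_all = np.vstack(pooled_mixing)
    keep = np.linalg.norm(sources_all, axis=1) > 0
    sources_all, mixing_all = sources_all[keep], mixing_all[keep]
    if sources_all.shape[0] < n_components:
        raise RuntimeError(
            f"only {sources_all.shape[0]} component estimates for "
            f"{n_components} clusters"
        )

    # Icasso similarity: |corr| between the pooled source estimates
    sim = _abs_corr(sources_all)
    labels = AgglomerativeClustering(
        n_clusters=n_components, metric="precomputed", linkage="average"
    ).fit_predict(1.0 - sim)

    mixing_cols = []
    stability = []
    for c in range(n_components):
        members = np.flatnonzero(labels == c)
        others = np.flatnonzero(labels != c)
        within = sim[np.ix_(members, members)]
        if members.size > 1:
            within_mean = (within.sum() - members.size) / (
                members.size * (members.size - 1)
            )
        else:
            within_mean = 1.0
        between_mean = (
            float(sim[np.ix_(members, others)].mean()) if others.size else 0.0
        )
        stability.append(within_mean - between_mean)
        # centrotype: member with maximal total similarity to its cluster
        centro = members[np.argmax(within.sum(axis=1))]
        mixing_cols.append(mixing_all[centro])
    mixing = np.array(mixing_cols).T  # (p, k)
    stability = np.array(stability)
    if np.mean(stability) < 0.5:
        logger.warning(
            "mean component stability %.2f < 0.5: no well-identified "
            "non-Gaussian structure in the items",
            float(np.mean(stability)),
        )

    # subject weights: least-squares projection of data on the components
    weights = xs @ np.linalg.pinv(mixing).T  # (n, k)

    mixing, weights = _orient_components(mixing, weights)

    # order by explained item variance (sum of squared item correlations)
    ev = np.empty(n_components)
    for j in range(n_components):
        w = weights[:, j]
        sd = w.std()
        r = xs.T @ ((w - w.mean()) / (sd if sd > 0 else 1.0)) / n
        ev[j] = float(np.sum(r**2))
    order = np.argsort(-ev)
    mixing, weights, stability = mixing[:, order], weights[:, order], stability[order]

    return DomainScores(
        weights=weights,
        mixing=mixing,
        general=general_psychopathology(weights, n_components=n_components),
        stability=stability,
        n_converged_runs=n_converged,
    )


def _orient_components(
    mixing: np.ndarray, weights: np.ndarray, n_top: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so the sum of its n_top largest-|loading| item
    loadings is positive (higher weight = more symptoms).  Idempotent."""
    mixing = mixing.copy()
    weights = weights.copy()
    for j in range(mixing.shape[1]):
        col = mixing[:, j]
        top = np.argsort(-np.abs(col))[: min(n_top, col.size)]
        if col[top].sum() < 0:
            mixing[:, j] = -col
            weights[:, j] = -weights[:, j]
    return mixing, weights


def general_psychopathology(
    weights: pd.DataFrame | np.ndarray, n_components: int = 7
) -> np.ndarray:
    """General-psychopathology proxy: row-wise mean of the domain weights."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[1] != n_components:
        raise ValueError(f"expected {n_components} weight columns, got {w.shape}")
    return w.mean(axis=1)
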