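"""End-to-end pipeline: simulate -> normative -> decompose -> associate.

A single YAML config drives the four stages; every stage writes delimited
text tables (comma separator, '.' decimal, header row, 17 significant
digits so that written values round-trip exactly) plus a machine-readable
JSON run report.  One global seed is expanded into fixed per-stage
substreams, so re-running any stage, or the whole pipeline, with the same
config reproduces identical numbers.

Analysis is complete-case only: rows with any missing measure are dropped
(and counted) during cohort validation, mirroring an all-measures-available
inclusion rule.  No imputation is performed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import decomposition as decomp
from . import normative
from . import synthetic

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"

COG_COLUMNS = tuple(f"cog_{t + 1:02d}" for t in range(synthetic.N_COG_TESTS))
ITEM_COLUMNS = tuple(f"item_{i + 1:03d}" for i in range(synthetic.N_ITEMS))
REQUIRED_COLUMNS = (
    ("subject_id", "age", "sex") + synthetic.BRAIN_FEATURES + COG_COLUMNS + ITEM_COLUMNS
)

_STAGE_ORDER = ("simulate", "normative", "decompose", "associate")


@dataclass
class PipelineConfig:
    seed: int
    output_dir: Path
    input_path: Path | None = None
    simulate: dict = field(default_factory=dict)
    age_bounds: tuple[float, float] = synthetic.AGE_RANGE
    sex_map: dict | None = None
    k_folds: int = 10
    n_interior_knots: int = 3
    n_components: int = 7
    n_runs: int = 20
    prior_sd: float = 1.0

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | str = ".") -> "PipelineConfig":
        base = Path(base_dir)
        errors: list[str] = []
        if "seed" not in raw:
            errors.append("missing required key 'seed'")
        inp = raw.get("input", {})
        path = inp.get("path")
        sim = inp.get("simulate")
        if path is None and sim is None:
            errors.append("input block must provide either 'path' or 'simulate'")
        if path is not None:
            path = (base / path).resolve() if not Path(path).is_absolute() else Path(path)
            if not path.exists():
                errors.append(f"input table not found: {path}")
        norm = raw.get("normative", {})
        dec = raw.get("decomposition", {})
        asso = raw.get("association", {})
        coh = raw.get("cohort", {})
        k = int(norm.get("k_folds", 10))
        if k < 2:
            errors.append("normative.k_folds must be >= 2")
        n_runs = int(dec.get("n_runs", 20))
        if n_runs < 1:
            errors.append("decomposition.n_runs must be >= 1")
        prior_sd = float(asso.get("prior_sd", 1.0))
        if prior_sd <= 0:
            errors.append("association.prior_sd must be > 0")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        out_dir = raw.get("output_dir", "normdev_out")
        out_dir = (base / out_dir) if not Path(out_dir).is_absolute() else Path(out_dir)
        return cls(
            seed=int(raw["seed"]),
            output_dir=out_dir,
            input_path=path,
            simulate=dict(sim) if sim else {},
            age_bounds=tuple(coh.get("age_bounds", synthetic.AGE_RANGE)),
            sex_map=coh.get("sex_map"),
            k_folds=k,
            n_interior_knots=int(norm.get("n_interior_knots", 3)),
            n_components=int(dec.get("n_components", 7)),
            n_runs=n_runs,
            prior_sd=prior_sd,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(raw, base_dir=path.parent)

    def stage_seed(self, stage: str) -> int:
        idx = _STAGE_ORDER.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGE_ORDER))[idx]
        return int(child.generate_state(1)[0] % (2**31))


def write_table(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: Path | str) -> pd.DataFrame:
    """Read a stage table back with exact float round-tripping."""
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Cohort validation
# ---------------------------------------------------------------------------

def validate_cohort(
    table: pd.DataFrame | str | Path,
    age_bounds: tuple[float, float] = synthetic.AGE_RANGE,
    sex_map: dict | None = None,
) -> tuple[pd.DataFrame, int]:
    """Enforce the cohort header contract and the complete-case rule.

    Returns the validated table and the number of dropped rows.  Raises on
    unparseable input, missing columns, unknown sex codes, duplicate IDs, or
    an empty table after filtering.
    """
    if not isinstance(table, pd.DataFrame):
        try:
            table = read_table(table)
        except Exception as exc:  # noqa: BLE001 - surfaced as config error
            raise ValueError(f"cannot parse cohort table: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        block = "items" if missing[0].startswith("item_") else "columns"
        raise ValueError(f"cohort table missing {block}: {missing[:5]}...")
    df = table.loc[:, list(REQUIRED_COLUMNS)].copy()

    if sex_map:
        known = df["sex"].isin(sex_map) | df["sex"].isin(list(sex_map.values()))
        if not known.all():
            bad = sorted(df.loc[~known, "sex"].unique().tolist())
            raise ValueError(f"unknown sex code(s): {bad}")
        df["sex"] = df["sex"].map(lambda s: sex_map.get(s, s))
    numeric_cols = [c for c in df.columns if c != "subject_id"]
    df[numeric_cols] = df[numeric_cols].apply(pd.to_numeric, errors="coerce")

    n0 = len(df)
    complete = df[numeric_cols].notna().all(axis=1)
    lo, hi = age_bounds
    in_range = df["age"].between(lo, hi) & df["sex"].isin([0, 1])
    keep = complete & in_range
    n_dropped = int(n0 - keep.sum())
    if n_dropped:
        reasons = []
        if (~complete).any():
            reasons.append(f"{int((~complete).sum())} incomplete")
        if (complete & ~in_range).any():
            reasons.append(f"{int((complete & ~in_range).sum())} out of range")
        logger.info("dropped %d/%d rows (%s)", n_dropped, n0, ", ".join(reasons))
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise ValueError("cohort table empty after complete-case filtering")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id values")
    df["sex"] = df["sex"].astype(int)
    return df, n_dropped


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> pd.DataFrame:
    sim = config.simulate
    effects = [
        synthetic.EffectSpec(
            domain=e["domain"], feature_name=e["feature"], beta=float(e["beta"])
        )
        for e in sim.get("effects", [])
    ]
    cohort = synthetic.generate_cohort(
        n=int(sim.get("n", 1280)),
        effects=effects,
        seed=config.stage_seed("simulate"),
    )
    write_table(cohort.table, config.output_dir / "cohort.csv")
    write_table(cohort.latents, config.output_dir / "latents.csv")
    return cohort.table


def stage_normative(
    cohort: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    """Cross-validated deviation scores for the six brain features."""
    seed = config.stage_seed("normative")
    dev_wide = pd.DataFrame({"subject_id": cohort["subject_id"]})
    long_parts = []
    metrics = {}
    for feature in synthetic.BRAIN_FEATURES:
        scores, m = normative.crossval_deviations(
            cohort,
            feature,
            k=config.k_folds,
            seed=seed,
            n_interior_knots=config.n_interior_knots,
        )
        dev_wide[f"{feature}_dev"] = scores.z
        long_parts.append(scores.table)
        metrics[feature] = {
            "explained_variance": m.explained_variance,
            "smse": m.smse,
            "msll": m.msll,
            "rho": m.rho,
        }
    write_table(pd.concat(long_parts, ignore_index=True),
                config.output_dir / "deviations.csv")
    metrics_df = pd.DataFrame(
        [{"feature": f, **v} for f, v in metrics.items()]
    )
    write_table(metrics_df, config.output_dir / "normative_metrics.csv")
    return dev_wide, metrics


def stage_decompose(
    cohort: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Cognitive factor -> COG deviation; items -> ICA domain scores."""
    seed = config.stage_seed("decompose")
    factor = decomp.cognitive_general_factor(cohort[list(COG_COLUMNS)])
    cog_cohort = cohort[["subject_id", "age", "sex"]].copy()
    cog_cohort["COG"] = factor.scores
    cog_scores, cog_metrics = normative.crossval_deviations(
        cog_cohort,
        "COG",
        k=config.k_folds,
        seed=seed,
        n_interior_knots=config.n_interior_knots,
    )
    domains = decomp.ica_domains(
        cohort[list(ITEM_COLUMNS)],
        n_components=config.n_components,
        n_runs=config.n_runs,
        seed=seed,
    )
    domain_df = domains.as_frame(subject_ids=cohort["subject_id"])
    write_table(domain_df, config.output_dir / "domain_scores.csv")
    loading_df = pd.DataFrame(
        domains.mixing,
        columns=[f"IC{j + 1}" for j in range(config.n_components)],
    )
    loading_df.insert(0, "item", list(ITEM_COLUMNS))
    write_table(loading_df, config.output_dir / "item_loadings.csv")
    info = {
        "cognitive_variance_explained": factor.variance_explained,
        "cog_dev_metrics": {
            "explained_variance": cog_metrics.explained_variance,
            "smse": cog_metrics.smse,
            "msll": cog_metrics.msll,
            "rho": cog_metrics.rho,
        },
        "ica_stability": domains.stability.tolist(),
        "ica_converged_runs": domains.n_converged_runs,
    }
    cog_dev = pd.Series(cog_scores.z, name="COG_dev")
    return domain_df, cog_dev, info


def stage_associate(
    deviations: pd.DataFrame,
    domain_df: pd.DataFrame,
    cog_dev: pd.Series,
    cohort: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, assoc.CorrelationMatrix]:
    all_dev = deviations.drop(columns="subject_id").copy()
    all_dev["COG_dev"] = cog_dev.to_numpy()
    corr = assoc.correlation_matrix(all_dev)
    corr_df = corr.as_frame().reset_index(names="deviation")
    write_table(corr_df, config.output_dir / "deviation_correlations.csv")
    stars_df = corr.stars_frame().reset_index(names="deviation")
    stars_df.to_csv(config.output_dir / "deviation_correlation_stars.csv", index=False)

    grid = assoc.run_association_grid(
        deviations,
        domain_df,
        cog_dev.to_numpy(),
        cohort["age"].to_numpy(),
        cohort["sex"].to_numpy(),
        prior_sd=config.prior_sd,
    )
    write_table(grid, config.output_dir / "associations.csv")
    return grid, corr


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _versions() -> dict:
    import importlib.metadata as md

    import scipy
    import sklearn

    try:
        own = md.version("normdev")
    except md.PackageNotFoundError:
        own = "unknown"
    return {
        "normdev": own,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the serializable run report."""
    t0 = time.perf_counter()
    report: dict = {
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_ORDER},
        "versions": _versions(),
        "stages": {},
        "warnings": [],
    }
    config.output_dir.mkdir(parents=True, exist_ok=True)

    def _timed(stage, fn, *args):
        t = time.perf_counter()
        try:
            out = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        report["stages"].setdefault(stage, {})["wall_clock_s"] = (
            time.perf_counter() - t
        )
        return out

    if config.input_path is not None:
        cohort, n_dropped = validate_cohort(
            config.input_path, age_bounds=config.age_bounds, sex_map=config.sex_map
        )
        report["stages"]["input"] = {"n_subjects": len(cohort), "n_dropped": n_dropped}
    else:
        cohort = _timed("simulate", stage_simulate, config)
        report["stages"]["simulate"]["n_subjects"] = len(cohort)

    deviations, norm_metrics = _timed("normative", stage_normative, cohort, config)
    report["stages"]["normative"]["metrics"] = norm_metrics

    domain_df, cog_dev, decomp_info = _timed(
        "decompose", stage_decompose, cohort, config
    )
    report["stages"]["decompose"].update(decomp_info)

    grid, corr = _timed(
        "associate", stage_associate, deviations, domain_df, cog_dev, cohort, config
    )
    report["stages"]["associate"]["n_models"] = len(grid)
    report["stages"]["associate"]["multiple_testing_adjustment"] = (
        "none: raw Bayes factors reported per pair"
    )
    report["association_summary"] = [
        {
            "feature": r.feature,
            "domain": r.domain,
            "B": r.B,
            "ci95": [r.ci_low, r.ci_high],
            "BF01": r.BF01,
            "label": r.label,
        }
        for r in grid.itertuples()
    ]
    report["deviation_correlations"] = {
        "labels": list(corr.labels),
        "r": corr.r.tolist(),
    }
    report["wall_clock_s"] = time.perf_counter() - t0
    with open(config.output_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
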