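"""End-to-end orchestration: simulate, extract features, fit, evaluate.

The analysis chain mirrors the clinical study design it emulates:

1. per-patient tachogram -> ectopic filtering -> 48-segment grid ->
   phase features (early/middle/late) -> delta features (middle - early);
2. univariate NB screen (p < 0.10, with coronary disease and heart failure
   force-included) -> multivariate "basic" clinical model;
3. exhaustive augmentation of the basic model with delta features under
   VIF and mutual-correlation exclusion, ranked by in-sample AUC of the
   linear predictor against "any IDH event";
4. paired DeLong comparison of the basic and best augmented models.

Each stage can run in memory (the functions here) or against a directory
of CSV/JSON intermediates (the ``run_*`` verbs used by the CLI), keyed by
a config hash for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import countmodel, features, preprocess, roc, synthetic
from .series import BeatSeries

log = logging.getLogger(__name__)

#: Basic-model covariates (cohort CSV columns) and their reporting scales.
BASIC_COVARIATES: dict[str, float] = {
    "dm": 1.0,
    "cad": 1.0,
    "chf": 1.0,
    "age": 10.0,       # per 10 years
    "ufr": 1.0,        # per kg
    "ipth": 100.0,     # per 100 pg/mL
    "arb_acei": 1.0,
    "ccb": 1.0,
    "beta_blocker": 1.0,
}

#: Reporting-scale suffix used for scaled basic columns in design matrices.
_SCALED_NAMES = {"age": "age_10y", "ipth": "ipth_100"}


@dataclasses.dataclass(frozen=True)
class AnalysisOptions:
    """Tunable analysis knobs (reporting units and exclusion bounds)."""

    power_delta_unit: float = 100.0  # ms^2 per unit for d_vlf/d_lf/d_hf/d_tp
    delta_rri_unit: float = 100.0    # ms per unit for d_rri
    vif_bound: float = 10.0
    corr_bound: float = 0.8
    max_added: int = 4
    p_threshold: float = 0.10
    force_include: tuple[str, ...] = ("cad", "chf")
    screen_deltas: bool = True  # restrict the search to screened deltas


def basic_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Basic-model design matrix on reporting scales (no intercept)."""
    missing = [c for c in BASIC_COVARIATES if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    out = {}
    for col, scale in BASIC_COVARIATES.items():
        name = _SCALED_NAMES.get(col, col)
        out[name] = cohort[col].to_numpy(dtype=float) / scale
    return pd.DataFrame(out, index=cohort.index)


def delta_design(feats: pd.DataFrame, opts: AnalysisOptions) -> pd.DataFrame:
    """Delta-feature design matrix on reporting scales.

    Spectral-power deltas are divided by ``power_delta_unit`` (default
    100 ms^2) and the RRI delta by ``delta_rri_unit``; the remaining deltas
    keep their natural units.  Columns with any missing value (e.g. an
    undefined LF/HF ratio) are dropped with a warning, since the count
    model cannot use them.
    """
    scales = {
        "d_hr": 1.0,
        "d_rri": opts.delta_rri_unit,
        "d_sdnn": 1.0,
        "d_rmssd": 1.0,
        "d_vlf": opts.power_delta_unit,
        "d_lf": opts.power_delta_unit,
        "d_hf": opts.power_delta_unit,
        "d_tp": opts.power_delta_unit,
        "d_lf_hf": 1.0,
    }
    out = {}
    for col, scale in scales.items():
        if col not in feats.columns:
            continue
        x = feats[col].to_numpy(dtype=float) / scale
        if np.isnan(x).any():
            log.warning("delta column %r has missing values; dropped", col)
            continue
        out[col] = x
    return pd.DataFrame(out, index=feats.index)


def extract_session_features(series: BeatSeries) -> pd.Series:
    """Preprocess one tachogram and compute its phase and delta features."""
    clean = preprocess.filter_ectopic(series)
    if clean.removed_fraction > 0.10:
        log.warning(
            "removed-beat fraction %.1f%% exceeds 10%%", 100 * clean.removed_fraction
        )
    grid = preprocess.segment_series(clean)
    return features.session_features(grid)


def study_features(study: synthetic.Study) -> pd.DataFrame:
    """Per-patient session features for a simulated study (one row each)."""
    rows = []
    for i, pid in enumerate(study.cohort["patient_id"]):
        row = extract_session_features(study.tachogram(i))
        row["patient_id"] = pid
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("patient_id").reset_index()


@dataclasses.dataclass(frozen=True)
class AnalysisResult:
    univariate: pd.DataFrame
    screen: countmodel.ScreenResult
    basic_fit: countmodel.NBFit
    search: countmodel.ModelSearchResult
    comparison: roc.DeLongResult | None
    labels: np.ndarray

    @property
    def basic_auc(self) -> float:
        return self.search.basic.auc

    @property
    def best_auc(self) -> float:
        return self.search.best.auc


def analyze(
    cohort: pd.DataFrame,
    feats: pd.DataFrame,
    opts: AnalysisOptions | None = None,
) -> AnalysisResult:
    """Run the statistical chain on a cohort table and its delta features."""
    opts = opts or AnalysisOptions()
    merged = cohort.merge(feats, on="patient_id", how="inner", validate="1:1")
    if len(merged) < len(cohort):
        log.warning(
            "feature table covers %d of %d patients", len(merged), len(cohort)
        )
    y = merged["idh_count"].to_numpy()
    X_basic = basic_design(merged)
    X_delta = delta_design(merged, opts)
    # a small cohort can draw zero (or all) carriers of a binary covariate;
    # such constant columns carry no information and break the design rank
    for X in (X_basic, X_delta):
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        if constant:
            log.warning("dropping constant design columns: %s", constant)
            X.drop(columns=constant, inplace=True)

    # univariate rate-ratio table over all candidate variables
    X_all = pd.concat([X_basic, X_delta], axis=1)
    uni_rows = []
    for col in X_all.columns:
        try:
            fit = countmodel.fit_negative_binomial(y, X_all[[col]])
            row = countmodel.wald_exp_coefficients(fit).loc[col]
            uni_rows.append(
                {
                    "variable": col,
                    "exp_b": row["exp_b"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                }
            )
        except (ValueError, countmodel.ConvergenceError) as e:
            uni_rows.append(
                {"variable": col, "exp_b": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan}
            )
            log.warning("univariate fit failed for %r: %s", col, e)
    univariate = pd.DataFrame(uni_rows).set_index("variable")

    force = tuple(_SCALED_NAMES.get(c, c) for c in opts.force_include)
    screen = countmodel.univariate_screen(
        y, X_all, p_threshold=opts.p_threshold, force_include=force
    )
    delta_cols = list(X_delta.columns)
    if opts.screen_deltas:
        delta_cols = [c for c in delta_cols if c in screen.selected]
    search = countmodel.model_search(
        y,
        X_basic,
        X_delta[delta_cols],
        max_added=opts.max_added,
        vif_bound=opts.vif_bound,
        corr_bound=opts.corr_bound,
    )
    labels = (y >= 1).astype(int)
    best = search.best
    comparison = None
    if best.added and best.fit is not None:
        comparison = roc.delong_paired_test(
            best.fit.linear_predictor,
            search.basic.fit.linear_predictor,
            labels,
        )
    return AnalysisResult(
        univariate=univariate,
        screen=screen,
        basic_fit=search.basic.fit,
        search=search,
        comparison=comparison,
        labels=labels,
    )


def run_study(
    config: synthetic.StudyConfig | None = None,
    seed: int = 0,
    opts: AnalysisOptions | None = None,
) -> tuple[synthetic.Study, pd.DataFrame, AnalysisResult]:
    """Simulate a study, extract features from its tachograms, and analyze."""
    config = config or synthetic.StudyConfig()
    study = synthetic.simulate_study(config, seed=seed)
    feats = study_features(study)
    result = analyze(study.cohort, feats, opts)
    return study, feats, result


# ---------------------------------------------------------------------------
# Disk-based stage verbs (used by the CLI)
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, config: dict, seed: int) -> None:
    manifest = outdir / "manifest.json"
    entry = {"stage": stage, "config_hash": _config_hash(config), "seed": seed}
    data = json.loads(manifest.read_text()) if manifest.exists() else []
    data.append(entry)
    manifest.write_text(json.dumps(data, indent=2))


def run_simulate(config: dict, outdir: str | Path, force: bool = False) -> Path:
    """Simulate a study and write tachograms, cohort CSV and truth JSON."""
    outdir = Path(outdir)
    seed = int(config.get("seed", 0))
    sim = config.get("simulate", {})
    n = int(sim.get("n_patients", 71))
    if n < 1:
        raise ValueError("n_patients must be positive")
    study_cfg = synthetic.StudyConfig(
        n_patients=n,
        dispersion=float(sim.get("dispersion", 1.5)),
        target_mean_count=float(sim.get("target_mean_count", 1.2)),
    )
    tacho_dir = outdir / "tachograms"
    if tacho_dir.exists() and any(tacho_dir.iterdir()) and not force:
        raise FileExistsError(f"{tacho_dir} is not empty; pass force to overwrite")
    tacho_dir.mkdir(parents=True, exist_ok=True)
    study = synthetic.simulate_study(study_cfg, seed=seed)
    for i, pid in enumerate(study.cohort["patient_id"]):
        study.tachogram(i).to_csv(tacho_dir / f"patient_{pid:03d}.csv")
    study.cohort.to_csv(outdir / "cohort.csv", index=False)
    truth = {
        "delta_betas": study.config.delta_betas,
        "delta_scales": study.config.delta_scales,
        "dispersion": study.config.dispersion,
        "clinical_betas": {c.name: c.beta for c in study.config.clinical},
        "per_patient": study.truth.to_dict(orient="list"),
        "tachogram_seeds": study.tachogram_seeds.tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    _write_manifest(outdir, "simulate", config, seed)
    log.info("wrote %d tachograms to %s", n, tacho_dir)
    return outdir


def run_features(outdir: str | Path) -> Path:
    """Compute per-patient features from the tachograms in ``outdir``."""
    outdir = Path(outdir)
    cohort = pd.read_csv(outdir / "cohort.csv")
    rows = []
    for pid in cohort["patient_id"]:
        path = outdir / "tachograms" / f"patient_{pid:03d}.csv"
        try:
            row = extract_session_features(BeatSeries.from_csv(path))
        except (ValueError, FileNotFoundError) as e:
            raise RuntimeError(f"feature stage failed for patient {pid}: {e}") from e
        row["patient_id"] = pid
        rows.append(row)
    feats = pd.DataFrame(rows)
    cols = ["patient_id"] + [c for c in feats.columns if c != "patient_id"]
    feats[cols].to_csv(outdir / "features.csv", index=False)
    return outdir


def run_fit(outdir: str | Path, config: dict | None = None) -> Path:
    """Fit the models and write univariate/model tables and the score registry."""
    outdir = Path(outdir)
    config = config or {}
    a = config.get("analysis", {})
    opts = AnalysisOptions(
        power_delta_unit=float(a.get("power_delta_unit", 100.0)),
        delta_rri_unit=float(a.get("delta_rri_unit", 100.0)),
        vif_bound=float(a.get("vif_bound", 10.0)),
        corr_bound=float(a.get("corr_bound", 0.8)),
        max_added=int(a.get("max_added", 4)),
    )
    cohort = pd.read_csv(outdir / "cohort.csv")
    feats = pd.read_csv(outdir / "features.csv")
    result = analyze(cohort, feats, opts)
    result.univariate.to_csv(outdir / "univariate.csv")
    result.search.table().to_csv(outdir / "models.csv", index=False)
    registry = {
        "labels": result.labels.tolist(),
        "models": {
            "basic": result.search.basic.fit.linear_predictor.tolist(),
        },
    }
    best = result.search.best
    if best.added and best.fit is not None:
        registry["models"]["+".join(best.added)] = best.fit.linear_predictor.tolist()
    (outdir / "registry.json").write_text(json.dumps(registry, indent=2))
    return outdir


def run_evaluate(outdir: str | Path) -> Path:
    """ROC curves per registered model and the paired DeLong comparison."""
    outdir = Path(outdir)
    registry = json.loads((outdir / "registry.json").read_text())
    labels = np.asarray(registry["labels"])
    names = list(registry["models"])
    report: dict[str, object] = {"auc": {}}
    for name in names:
        scores = np.asarray(registry["models"][name])
        curve = roc.roc_curve(scores, labels)
        curve.to_frame().to_csv(outdir / f"roc_{name.replace('+', '_')}.csv", index=False)
        report["auc"][name] = curve.auc
    if len(names) >= 2:
        res = roc.delong_paired_test(
            np.asarray(registry["models"][names[1]]),
            np.asarray(registry["models"][names[0]]),
            labels,
        )
        report["delong"] = {
            "model_a": names[1],
            "model_b": names[0],
            "auc_a": res.auc_a,
            "auc_b": res.auc_b,
            "z": res.z,
            "p": res.p,
        }
    (outdir / "comparison.json").write_text(json.dumps(report, indent=2))
    lines = [f"AUC[{k}] = {v:.3f}" for k, v in report["auc"].items()]
    if "delong" in report:
        d = report["delong"]
        lines.append(
            f"DeLong {d['model_a']} vs {d['model_b']}: "
            f"z = {d['z']:.3f}, p = {d['p']:.4f}"
        )
    (outdir / "comparison.txt").write_text("\n".join(lines) + "\n")
    return outdir


def run_all(config: dict, outdir: str | Path, force: bool = False) -> Path:
    run_simulate(config, outdir, force=force)
    run_features(outdir)
    run_fit(outdir, config)
    run_evaluate(outdir)
    return Path(outdir)
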