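"""End-to-end repeated-shuffle experiment.

One shuffle is: 4:1 train/test split -> train-derived mean/mode imputation
and z-scoring of both partitions -> random down-sampling of the training
majority class to a uniform class distribution -> 10-fold CV grid search
per model family -> final fit on the balanced training set -> test AUC and
model-tailored feature importance. The whole process repeats ``n_shuffles``
times (50 in the study protocol); performance is summarized by median AUC
and IQR, importance by the mean and SD of the unit-sum-normalized absolute
scores across shuffles.

Per-shuffle seeds derive from the master seed through a counter-based
spawn, so shuffles are independent and individually re-runnable, and the
whole report is a pure function of (config, cohort).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    FEATURES,
    ClinicalCohort,
    CohortSpec,
    generate_cohort,
    read_cohort_csv,
)
from .evaluation import ShuffleResult, roc_auc, summarize_performance
from .interpretability import (
    aggregate_shap,
    confidence_weighted_rating,
    linear_importance,
    lrp_deep_taylor,
    normalize_importance,
    shapley_matrix,
)
from .models import MODEL_FAMILIES, cross_validate, default_grids, fit_model, predict_proba
from .preprocessing import (
    apply_preprocess,
    compute_vif,
    dichotomize_mrs,
    fit_preprocess,
    split_train_test,
    subsample_balance,
)

logger = logging.getLogger("strokexplain")

__all__ = ["ExperimentConfig", "ExperimentReport", "run_shuffle", "run_experiment"]


@dataclass
class ExperimentConfig:
    cohort_path: str | None = None          # CSV; exclusive with cohort_spec
    cohort_spec: CohortSpec | None = None   # generated if no path given
    n_shuffles: int = 50
    cv_folds: int = 10
    models: tuple = MODEL_FAMILIES
    grids: dict = field(default_factory=default_grids)
    seed: int = 0
    background_size: int = 100   # background rows for the Shapley value function
    n_explain: int | None = None  # cap on explained test observations (None = all)
    abs_per_observation: bool = True  # |phi| / |r| per observation before averaging
    lrp_seed_output: str = "bad"      # LRP explanandum: "bad" or "predicted" class
    extra_model_args: dict = field(default_factory=dict)  # family -> fixed kwargs
    output_dir: str | None = None
    make_figures: bool = True

    def validate(self):
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        unknown = set(self.models) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort_spec" in d and d["cohort_spec"] is not None:
            spec = d["cohort_spec"]
            if "latent_correlation" in spec and spec["latent_correlation"] is not None:
                spec["latent_correlation"] = np.asarray(spec["latent_correlation"], float)
            d["cohort_spec"] = CohortSpec(**spec)
        if "models" in d:
            d["models"] = tuple(d["models"])
        grids = default_grids()
        for fam, grid in (d.get("grids") or {}).items():
            grids[fam] = {k: list(v) for k, v in grid.items()}
        d["grids"] = grids
        return cls(**d)


@dataclass
class ExperimentReport:
    performance: pd.DataFrame   # model, partition, median_auc, iqr
    importance: pd.DataFrame    # model, method, feature, mean_rating, sd_rating
    vif: pd.Series
    shuffle_results: list
    failed_shuffles: list
    seeds: dict


def _shuffle_seed(master_seed: int, index: int) -> int:
    """Counter-based derivation; independent streams per shuffle."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


_METHOD = {
    "glm": "coefficients",
    "lasso": "coefficients",
    "elastic_net": "coefficients",
    "gbdt": "shap",
    "mlp": "deep_taylor",
}


def _importance_for(family, model, X_test, y_test, X_train_bal, config, rng):
    if family in ("glm", "lasso", "elastic_net"):
        return linear_importance(model)
    if family == "gbdt":
        n_bg = min(config.background_size, len(X_train_bal))
        bg = X_train_bal[rng.choice(len(X_train_bal), size=n_bg, replace=False)]
        X_exp = X_test
        if config.n_explain is not None and len(X_test) > config.n_explain:
            X_exp = X_test[rng.choice(len(X_test), size=config.n_explain, replace=False)]
        phis = shapley_matrix(model.predict_proba, X_exp, bg)
        if config.abs_per_observation:
            phis = np.abs(phis)
        return aggregate_shap(phis)
    if family == "mlp":
        X_exp, y_exp = X_test, y_test
        if config.n_explain is not None and len(X_test) > config.n_explain:
            keep = rng.choice(len(X_test), size=config.n_explain, replace=False)
            X_exp, y_exp = X_test[keep], y_test[keep]
        rel = np.vstack([
            lrp_deep_taylor(model, x, seed_output=config.lrp_seed_output).input_relevance
            for x in X_exp
        ])
        if config.abs_per_observation:
            rel = np.abs(rel)
        probs = predict_proba(model, X_exp)
        return confidence_weighted_rating(rel, probs, y_exp)
    raise ValueError(family)


def run_shuffle(cohort: ClinicalCohort, config: ExperimentConfig, shuffle_index: int) -> ShuffleResult:
    """Execute the full per-shuffle protocol once."""
    seed = _shuffle_seed(config.seed, shuffle_index)
    rng = np.random.default_rng(seed + 1)
    y_all = dichotomize_mrs(cohort.mrs)
    split = split_train_test(cohort.n_subjects, seed=seed)
    feats = cohort.features
    state = fit_preprocess(feats.iloc[split.train])
    X_train = apply_preprocess(state, feats.iloc[split.train])
    X_test = apply_preprocess(state, feats.iloc[split.test])
    y_train, y_test = y_all[split.train], y_all[split.test]
    keep = subsample_balance(y_train, seed=seed + 2)
    X_bal, y_bal = X_train[keep], y_train[keep]

    result = ShuffleResult(shuffle=shuffle_index, seed=seed)
    for family in config.models:
        extra = dict(config.extra_model_args.get(family, {}))
        best = cross_validate(
            family, X_bal, y_bal, config.grids.get(family, {}),
            k=config.cv_folds, seed=seed + 3, **extra,
        )
        model = fit_model(family, X_bal, y_bal, best, seed=seed + 4, **extra)
        result.hyperparams[family] = best
        result.train_auc[family] = roc_auc(predict_proba(model, X_bal), y_bal)
        result.test_auc[family] = roc_auc(predict_proba(model, X_test), y_test)
        result.importance[family] = _importance_for(
            family, model, X_test, y_test, X_bal, config, rng
        )
    return result


def _importance_table(results, families) -> pd.DataFrame:
    rows = []
    for fam in families:
        raws = [r.importance[fam] for r in results]
        summary = normalize_importance(raws)
        for j, feature in enumerate(FEATURES):
            rows.append(
                dict(model=fam, method=_METHOD[fam], feature=feature,
                     mean_rating=summary["mean"][j], sd_rating=summary["sd"][j])
            )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run all shuffles and summarize; optionally write CSV/figure artifacts.

    A failing shuffle is logged and excluded; more than 20% failures abort
    the experiment.
    """
    config.validate()
    if config.cohort_path is not None:
        cohort = read_cohort_csv(config.cohort_path)
    else:
        spec = config.cohort_spec or CohortSpec(seed=config.seed)
        cohort = generate_cohort(spec)

    results, failed, seeds = [], [], {}
    for s in range(config.n_shuffles):
        seeds[s] = _shuffle_seed(config.seed, s)
        try:
            results.append(run_shuffle(cohort, config, s))
        except Exception as exc:  # noqa: BLE001 - per-shuffle fault isolation
            logger.warning("shuffle %d failed: %s", s, exc)
            failed.append((s, str(exc)))
    if len(failed) > 0.2 * config.n_shuffles:
        raise RuntimeError(f"{len(failed)}/{config.n_shuffles} shuffles failed")

    performance = summarize_performance(results)
    importance = _importance_table(results, list(config.models))
    complete = cohort.features.dropna()
    vif = compute_vif(complete) if len(complete) > len(FEATURES) else pd.Series(dtype=float)

    report = ExperimentReport(
        performance=performance, importance=importance, vif=vif,
        shuffle_results=results, failed_shuffles=failed, seeds=seeds,
    )
    if config.output_dir is not None:
        write_artifacts(report, config)
    return report


def write_artifacts(report: ExperimentReport, config: ExperimentConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.performance.to_csv(out / "performance.csv", index=False)
    report.importance.to_csv(out / "importance.csv", index=False)
    report.vif.rename_axis("feature").to_csv(out / "vif.csv")
    shuffle_dir = out / "shuffles"
    shuffle_dir.mkdir(exist_ok=True)
    for r in report.shuffle_results:
        rows = []
        for fam in config.models:
            row = dict(model=fam, seed=r.seed,
                       train_auc=r.train_auc[fam], test_auc=r.test_auc[fam],
                       hyperparams=yaml.safe_dump(r.hyperparams[fam], default_flow_style=True).strip())
            for j, feature in enumerate(FEATURES):
                row[f"raw_importance_{feature}"] = r.importance[fam].scores[j]
            rows.append(row)
        pd.DataFrame(rows).to_csv(shuffle_dir / f"shuffle_{r.shuffle}.csv", index=False)
    seeds = pd.DataFrame(
        {"shuffle": list(report.seeds), "seed": list(report.seeds.values())}
    )
    seeds.to_csv(out / "seeds.csv", index=False)
    if config.make_figures:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _write_figures(report, out)


def _write_figures(report: ExperimentReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    perf = report.performance
    models = perf["model"].unique()
    fig, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(len(models))
    for off, (partition, color) in enumerate((("train", "tab:blue"), ("test", "tab:orange"))):
        sub = perf[perf.partition == partition].set_index("model").loc[models]
        ax.errorbar(xs + 0.1 * off, sub.median_auc, yerr=sub.iqr / 2,
                    fmt="o", color=color, label=partition, capsize=3)
    ax.set_xticks(xs + 0.05)
    ax.set_xticklabels(models, rotation=20)
    ax.set_ylabel("AUC (median +/- IQR/2)")
    ax.legend()
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(figdir / f"performance.{ext}")
    plt.close(fig)

    imp = report.importance
    fig, ax = plt.subplots(figsize=(9, 4.5))
    width = 0.8 / len(models)
    xs = np.arange(len(FEATURES))
    for i, fam in enumerate(models):
        sub = imp[imp.model == fam].set_index("feature").loc[list(FEATURES)]
        ax.bar(xs + i * width, sub.mean_rating, width=width,
               yerr=sub.sd_rating, label=fam, capsize=2)
    ax.set_xticks(xs + 0.4 - width / 2)
    ax.set_xticklabels(FEATURES, rotation=20)
    ax.set_ylabel("normalized importance (mean +/- SD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    for ext in ("png", "svg"):
        fig.savefig(figdir / f"importance.{ext}")
    plt.close(fig)
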