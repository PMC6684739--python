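"""Study designs: full-model comparison, sample-size scaling, redundancy
groups, and follow-up score prediction.

Every experiment is a pure function of (inputs, config); all randomness is
derived from ``config.master_seed`` so reruns reproduce results exactly (for
the stochastic CNN, per-fold seeds are derived deterministically).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cnn import CNNConfig
from .evaluation import (
    SUBGROUP_FILTERS,
    EvalResult,
    compare_models,
    loocv,
    spec_from_name,
    subgroup_eval,
)
from .exceptions import ConfigurationError, DegeneracyError
from .imaging import CohortManifest
from .redundancy import distance_matrix, redundancy_counts, split_groups


@dataclass
class ExperimentConfig:
    """Shared configuration for the experiment drivers.

    ``models`` are names resolved by :func:`~.evaluation.spec_from_name`
    (``pca+rr``, ``svr``, ``cnn``, ``hybrid``); ``cnn`` carries the training
    hyperparameters used by both the CNN and the hybrid feature extractor.
    """

    models: tuple = ("pca+rr", "svr", "cnn", "hybrid")
    sample_sizes: tuple = (25, 50, 75, 90)
    repeats: int = 40
    master_seed: int = 0
    variance_threshold: float = 0.95
    pca_scope: str = "fold"
    score_column: str = "score"
    cnn: CNNConfig = field(default_factory=CNNConfig)
    n_boot: int = 10_000

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")
        if len(self.models) == 0:
            raise ConfigurationError("at least one model required")

    def specs(self) -> list:
        return [spec_from_name(name, self.cnn) for name in self.models]


def _run_loocv(images, manifest, config: ExperimentConfig, seed=None, score_column=None):
    return loocv(
        images,
        manifest,
        config.specs(),
        master_seed=config.master_seed if seed is None else seed,
        variance_threshold=config.variance_threshold,
        pca_scope=config.pca_scope,
        score_column=score_column or config.score_column,
    )


# ---------------------------------------------------------------------------
# Full-cohort comparison


@dataclass
class FullComparisonReport:
    """LOOCV results for every model, subgroup tables, pairwise comparisons."""

    results: dict  # label -> EvalResult
    subgroups: dict  # label -> {filter -> EvalResult}
    comparisons: dict  # (label_a, label_b) -> (delta_r2, p)

    def summary(self) -> str:
        lines = ["Full-cohort LOOCV comparison", "============================"]
        for res in self.results.values():
            lines.append(res.summary())
        lines.append("")
        lines.append("Subgroups:")
        for label, subs in self.subgroups.items():
            for res in subs.values():
                lines.append("  " + res.summary())
        lines.append("")
        lines.append("Pairwise paired-bootstrap comparisons (delta r2, two-sided p):")
        for (a, b), (delta, p) in self.comparisons.items():
            lines.append(f"  {a} vs {b}: delta={delta:+.3f}  p={p:.4f}")
        return "\n".join(lines)

    def metrics_table(self) -> pd.DataFrame:
        rows = [res.metrics() for res in self.results.values()]
        for subs in self.subgroups.values():
            rows.extend(res.metrics() for res in subs.values())
        return pd.DataFrame(rows)


def run_full_comparison(images, manifest: CohortManifest, config: ExperimentConfig) -> FullComparisonReport:
    """LOOCV every requested model on the full cohort, with subgroup tables
    (left-hemisphere, deficit-only, no-deficit) and all pairwise comparisons."""
    results = _run_loocv(images, manifest, config)
    subgroups: dict = {}
    for label, res in results.items():
        subgroups[label] = {}
        for filt in SUBGROUP_FILTERS:
            try:
                subgroups[label][filt] = subgroup_eval(res, manifest, filt)
            except DegeneracyError:
                continue
    comparisons = {}
    for pair_idx, (a, b) in enumerate(itertools.combinations(results.keys(), 2)):
        seed = int(
            np.random.SeedSequence([config.master_seed, 1000 + pair_idx]).generate_state(1)[0]
            % 2**31
        )
        comparisons[(a, b)] = compare_models(results[a], results[b], config.n_boot, seed)
    return FullComparisonReport(results=results, subgroups=subgroups, comparisons=comparisons)


# ---------------------------------------------------------------------------
# Sample-size scaling


@dataclass
class GapCurveFit:
    """Fit of the r^2 gap (reference minus CNN) against sample size.

    ``exp_params`` are (a, b, c) of the saturating form a + b*exp(-c*size);
    ``linear_params`` are (slope, intercept) of the least-squares line.
    """

    sizes: np.ndarray
    gaps: np.ndarray
    exp_params: tuple | None
    linear_params: tuple

    def predict_exp(self, sizes) -> np.ndarray | None:
        if self.exp_params is None:
            return None
        a, b, c = self.exp_params
        return a + b * np.exp(-c * np.asarray(sizes, dtype=float))

    def predict_linear(self, sizes) -> np.ndarray:
        m, q = self.linear_params
        return m * np.asarray(sizes, dtype=float) + q

    def extrapolated_crossing(self, max_size: int = 150) -> int | None:
        """Smallest size <= max_size where the fitted gap reaches 0, if any."""
        sizes = np.arange(int(self.sizes.min()), max_size + 1)
        pred = self.predict_exp(sizes)
        if pred is None:
            pred = self.predict_linear(sizes)
        below = np.nonzero(pred <= 0)[0]
        return int(sizes[below[0]]) if below.size else None


@dataclass
class ScalingResult:
    """Per-(model, size, repeat) r^2 values and the CNN gap curve."""

    records: pd.DataFrame  # columns: model, size, repeat, r_squared, mae
    gap_fit: GapCurveFit | None

    def summary_table(self) -> pd.DataFrame:
        g = self.records.groupby(["model", "size"])["r_squared"]
        return g.agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        ).reset_index()

    def median_r2(self, model: str, size: int) -> float:
        sel = self.records[(self.records["model"] == model) & (self.records["size"] == size)]
        return float(sel["r_squared"].median())


def run_scaling(
    images,
    manifest: CohortManifest,
    config: ExperimentConfig,
    gap_models: tuple = ("svr", "cnn"),
) -> ScalingResult:
    """Learning-curve experiment: subsample, LOOCV within the subsample.

    For each (size, repeat) a subsample is drawn without replacement and every
    model is evaluated by LOOCV *within* the subsample; subsample membership
    is a deterministic function of (master_seed, size, repeat).
    """
    n = len(images)
    for size in config.sample_sizes:
        if size >= n:
            raise ConfigurationError(f"sample size {size} must be < cohort size {n}")
    rows = []
    for size in config.sample_sizes:
        for rep in range(config.repeats):
            rng = np.random.default_rng([config.master_seed, size, rep])
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub_images = [images[i] for i in idx]
            sub_manifest = manifest.subset(idx)
            seed = int(rng.integers(2**31))
            results = _run_loocv(sub_images, sub_manifest, config, seed=seed)
            for label, res in results.items():
                rows.append(
                    {
                        "model": label,
                        "size": size,
                        "repeat": rep,
                        "r_squared": res.r_squared,
                        "mae": res.mae,
                    }
                )
    records = pd.DataFrame(rows)

    gap_fit = None
    ref, cnn_label = gap_models
    have = set(records["model"])
    if ref in have and cnn_label in have and len(config.sample_sizes) >= 2:
        sizes = np.array(sorted(config.sample_sizes), dtype=float)
        med = records.groupby(["model", "size"])["r_squared"].median()
        gaps = np.array([med[(ref, s)] - med[(cnn_label, s)] for s in sizes])
        lin = np.polyfit(sizes, gaps, 1)
        exp_params = None
        try:
            popt, _ = curve_fit(
                lambda s, a, b, c: a + b * np.exp(-c * s),
                sizes,
                gaps,
                p0=(gaps[-1], max(gaps[0] - gaps[-1], 1e-3), 0.02),
                bounds=([-1, -2, 1e-5], [1, 2, 1.0]),
                maxfev=20000,
            )
            exp_params = tuple(float(v) for v in popt)
        except RuntimeError:
            exp_params = None
        gap_fit = GapCurveFit(
            sizes=sizes,
            gaps=gaps,
            exp_params=exp_params,
            linear_params=(float(lin[0]), float(lin[1])),
        )
    return ScalingResult(records=records, gap_fit=gap_fit)


# ---------------------------------------------------------------------------
# Redundancy groups


@dataclass
class RedundancyReport:
    """Per-redundancy-group metrics for every model under one distance metric."""

    metric_label: str
    group_labels: np.ndarray  # 'high'/'low' per patient
    counts: np.ndarray
    group_results: dict  # group -> {model -> EvalResult}

    def summary(self) -> str:
        n_high = int((self.group_labels == "high").sum())
        n_low = int((self.group_labels == "low").sum())
        lines = [
            f"Redundancy groups ({self.metric_label} distance): "
            f"high n={n_high}, low n={n_low}",
        ]
        for group in ("high", "low"):
            for res in self.group_results[group].values():
                lines.append("  " + res.summary())
        return "\n".join(lines)


def run_redundancy_experiment(
    images, manifest: CohortManifest, config: ExperimentConfig, metric_label: str
) -> RedundancyReport:
    """Median-split the cohort by redundancy and score each group separately.

    Models are trained once in the full-cohort LOOCV; the grouping is applied
    at scoring time to the pooled held-out predictions.
    """
    if len(images) < 20:
        raise ConfigurationError("redundancy experiment needs >= 20 patients")
    results = _run_loocv(images, manifest, config)
    D = distance_matrix(images, metric_label)
    scores = redundancy_counts(D)
    labels = split_groups(scores)
    group_results: dict = {"high": {}, "low": {}}
    for group in ("high", "low"):
        keep = np.nonzero(labels == group)[0]
        for model_label, res in results.items():
            sub = res.predictions.iloc[keep].reset_index(drop=True)
            group_results[group][model_label] = EvalResult(
                predictions=sub,
                model_label=model_label,
                subgroup_label=f"redundancy_{group}",
                extras=dict(res.extras),
            )
    return RedundancyReport(
        metric_label=metric_label,
        group_labels=labels,
        counts=scores.counts,
        group_results=group_results,
    )


# ---------------------------------------------------------------------------
# Follow-up prediction


def run_followup(images, manifest: CohortManifest, config: ExperimentConfig) -> dict:
    """LOOCV on the 3-month follow-up scores, restricted to patients who
    have them; pipeline otherwise identical to the acute analysis."""
    has_fu = ~np.isnan(manifest.followup_scores)
    if not has_fu.any():
        raise ConfigurationError("no follow-up scores in manifest")
    idx = np.nonzero(has_fu)[0]
    sub_images = [images[i] for i in idx]
    sub_manifest = manifest.subset(idx)
    return _run_loocv(sub_images, sub_manifest, config, score_column="followup")


# ---------------------------------------------------------------------------
# Plots


def plot_scaling(result: ScalingResult, path) -> None:
    """Notched box plot of r^2 per (model, size), one panel for all models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    records = result.records
    models = sorted(records["model"].unique())
    sizes = sorted(records["size"].unique())
    fig, ax = plt.subplots(figsize=(1.8 * len(sizes) * max(1, len(models) // 2), 4))
    width = 0.8 / len(models)
    for mi, model in enumerate(models):
        data = [
            records[(records["model"] == model) & (records["size"] == s)]["r_squared"]
            for s in sizes
        ]
        pos = [i + mi * width for i in range(len(sizes))]
        ax.boxplot(
            data, positions=pos, widths=width * 0.9, notch=True,
            patch_artist=True, boxprops={"facecolor": f"C{mi}", "alpha": 0.5},
            medianprops={"color": "black"}, showfliers=False,
        )
    ax.set_xticks([i + 0.4 for i in range(len(sizes))])
    ax.set_xticklabels([str(s) for s in sizes])
    ax.set_xlabel("sample size")
    ax.set_ylabel(r"$r^2$")
    handles = [plt.Line2D([], [], color=f"C{mi}", lw=6, alpha=0.5) for mi in range(len(models))]
    ax.legend(handles, models, loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_predictions(result: EvalResult, path) -> None:
    """Actual-vs-predicted scatter for one model's pooled LOOCV predictions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(result.actual, result.predicted, s=14, alpha=0.7)
    lo = min(result.actual.min(), result.predicted.min())
    hi = max(result.actual.max(), result.predicted.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("actual score")
    ax.set_ylabel("predicted score")
    ax.set_title(f"{result.model_label}  $r^2$={result.r_squared:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
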