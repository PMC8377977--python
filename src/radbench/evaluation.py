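"""Concordance-index scoring and the two-phase benchmarking design.

Pre-validation runs 10 iterations of 10-fold cross-validation on the
discovery cohort: per iteration the full out-of-fold prediction vector is
pooled and scored once, giving 10 concordance values whose mean and
t-based 95% interval are reported.  External validation trains each model
on the full discovery cohort and scores it on the held-out validation
cohort, repeated ten times with fresh seed streams (which matters for the
stochastic fitters; deterministic ones produce zero-variance repeats).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .predictors import ModelSpec, predict

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "BenchmarkReport",
    "concordance_index",
    "cross_validate",
    "external_validate",
    "benchmark",
]


def concordance_index(pred: np.ndarray, obs: np.ndarray) -> float:
    """Probability that the predictions rank a random pair like the outcomes.

    Pairs with tied observations are excluded; pairs with tied predictions
    count one half.  1 is a perfect predictor, 0.5 is random.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-d vectors of equal length")
    if len(pred) < 2:
        raise ValueError("need at least 2 samples")
    dp = np.sign(pred[:, None] - pred[None, :])
    do = np.sign(obs[:, None] - obs[None, :])
    upper = np.triu(np.ones_like(dp, dtype=bool), k=1)
    comparable = (do != 0) & upper
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("all observations tied: concordance undefined")
    concordant = int(((dp == do) & comparable & (dp != 0)).sum())
    pred_ties = int(((dp == 0) & comparable).sum())
    return (concordant + 0.5 * pred_ties) / n_pairs


@dataclass(frozen=True)
class CVPlan:
    """Fold assignments for repeated k-fold cross-validation.

    By default folds are stratified on outcome deciles (sorted-outcome
    blocks receive one sample per fold) so the outcome distribution is
    balanced across folds; fold sizes differ by at most one.
    """

    n_samples: int
    n_folds: int = 10
    n_iterations: int = 10
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_folds > self.n_samples:
            raise ValueError("need 2 <= n_folds <= n_samples")
        if self.n_samples // self.n_folds < 2:
            raise ValueError("folds would contain fewer than 2 samples")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def folds(self, y: np.ndarray | None = None) -> list[np.ndarray]:
        """Per-iteration fold labels (arrays of length n_samples)."""
        rng = np.random.default_rng(self.seed)
        out = []
        for _ in range(self.n_iterations):
            labels = np.empty(self.n_samples, int)
            if self.stratify and y is not None:
                order = np.argsort(y + 1e-12 * rng.standard_normal(self.n_samples))
            else:
                order = rng.permutation(self.n_samples)
            for start in range(0, self.n_samples, self.n_folds):
                block = order[start : start + self.n_folds]
                labels[block] = rng.permutation(self.n_folds)[: len(block)]
            out.append(labels)
        return out


@dataclass
class BenchmarkReport:
    """Per-model concordance summary for one evaluation phase."""

    model: str
    phase: str
    per_iteration: list[float]
    mean_ci: float
    ci_low: float
    ci_high: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkReport":
        return cls(**d)


def _summarize(model: str, phase: str, values: list[float], provenance: dict) -> BenchmarkReport:
    vals = np.asarray(values, float)
    mean = float(vals.mean())
    if len(vals) > 1 and vals.std(ddof=1) > 0:
        half = float(
            stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
        )
    else:
        half = 0.0
    return BenchmarkReport(
        model=model,
        phase=phase,
        per_iteration=[float(v) for v in vals],
        mean_ci=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        provenance=provenance,
    )


def _fit_seed(seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0])


def cross_validate(
    model_spec: ModelSpec, expr: pd.DataFrame, y, plan: CVPlan
) -> BenchmarkReport:
    """Pre-validation: repeated k-fold CV with pooled out-of-fold scoring.

    All gene selection and hyperparameter tuning happen inside each
    training portion unless the spec carries fixed ``prefilter_genes``.
    """
    if isinstance(y, pd.Series):
        y_vec = y.loc[expr.columns].to_numpy(float)
    else:
        y_vec = np.asarray(y, float)
    if len(y_vec) != expr.shape[1] or len(y_vec) != plan.n_samples:
        raise ValueError("expr, y and plan sample counts must agree")

    per_iteration = []
    for it, labels in enumerate(plan.folds(y_vec)):
        oof = np.full(plan.n_samples, np.nan)
        for fold in range(plan.n_folds):
            test = labels == fold
            if test.sum() < 2:
                raise ValueError(f"fold {fold} has fewer than 2 samples")
            train_cols = expr.columns[~test]
            model = model_spec.fit(
                expr[train_cols], y_vec[~test], seed=_fit_seed(plan.seed, it, fold)
            )
            oof[test] = predict(model, expr[expr.columns[test]]).to_numpy()
        assert not np.any(np.isnan(oof)), "out-of-fold predictions incomplete"
        per_iteration.append(concordance_index(oof, y_vec))
    return _summarize(
        model_spec.name,
        "pre_validation",
        per_iteration,
        {
            "seed": plan.seed,
            "n_folds": plan.n_folds,
            "n_iterations": plan.n_iterations,
            "stratified": plan.stratify,
        },
    )


def external_validate(
    model_spec: ModelSpec,
    discovery: tuple[pd.DataFrame, np.ndarray],
    validation: tuple[pd.DataFrame, np.ndarray],
    n_repeats: int = 10,
    seed: int = 0,
) -> BenchmarkReport:
    """Train on the full discovery cohort, score on the validation cohort.

    Gene universes are intersected before fitting; validation samples never
    touch fitting or tuning.  Each repeat uses a fresh seed stream, which
    affects only the stochastic fitters.
    """
    expr_d, y_d = discovery
    expr_v, y_v = validation
    common = expr_d.index.intersection(expr_v.index)
    if len(common) == 0:
        raise ValueError("empty gene intersection between cohorts")
    logger.info("external_validate: %d common genes", len(common))
    expr_d, expr_v = expr_d.loc[common], expr_v.loc[common]
    y_d = np.asarray(y_d, float)
    y_v = np.asarray(y_v, float)

    values = []
    for rep in range(n_repeats):
        model = model_spec.fit(expr_d, y_d, seed=_fit_seed(seed, rep))
        pred = predict(model, expr_v).to_numpy()
        values.append(concordance_index(pred, y_v))
    return _summarize(
        model_spec.name,
        "external_validation",
        values,
        {"seed": seed, "n_repeats": n_repeats, "n_common_genes": int(len(common))},
    )


def benchmark(
    model_specs: list[ModelSpec],
    discovery: tuple[pd.DataFrame, np.ndarray],
    validation: tuple[pd.DataFrame, np.ndarray] | None,
    n_folds: int = 10,
    n_iterations: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[list[BenchmarkReport], pd.DataFrame]:
    """Run pre-validation (and external validation) for every model.

    Returns the raw reports and a ranked comparison table; failures of a
    single model are recorded as NaN rows rather than aborting the run.
    """
    expr_d, y_d = discovery
    plan = CVPlan(
        n_samples=expr_d.shape[1], n_folds=n_folds, n_iterations=n_iterations, seed=seed
    )
    reports: list[BenchmarkReport] = []
    for spec in model_specs:
        try:
            reports.append(cross_validate(spec, expr_d, y_d, plan))
        except Exception as exc:  # pragma: no cover - partial-failure contract
            logger.error("pre-validation failed for %s: %s", spec.name, exc)
            reports.append(
                _summarize(spec.name, "pre_validation", [np.nan], {"error": str(exc)})
            )
        if validation is not None:
            try:
                reports.append(
                    external_validate(spec, discovery, validation, n_repeats, seed)
                )
            except Exception as exc:  # pragma: no cover
                logger.error("external validation failed for %s: %s", spec.name, exc)
                reports.append(
                    _summarize(
                        spec.name, "external_validation", [np.nan], {"error": str(exc)}
                    )
                )
    table = reports_to_frame(reports)
    return reports, table


def reports_to_frame(reports: list[BenchmarkReport]) -> pd.DataFrame:
    rows = [
        {
            "model": r.model,
            "phase": r.phase,
            "mean_ci": r.mean_ci,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            **{f"iter_{i + 1}": v for i, v in enumerate(r.per_iteration)},
        }
        for r in reports
    ]
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["phase", "mean_ci"], ascending=[True, False], ignore_index=True
    )


def reports_to_json(reports: list[BenchmarkReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=1)


def reports_from_json(text: str) -> list[BenchmarkReport]:
    return [BenchmarkReport.from_dict(d) for d in json.loads(text)]
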