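"""Genomic predictor families under a common fit/predict contract.

Six configurations of five families: a single-gene univariate regression,
rank-based ensemble and multivariate models on the top correlated genes,
minimum-redundancy-maximum-relevance (mRMR) selection in exhaustive and
bootstrap flavours followed by multivariate regression, and an elastic net
with the mixing parameter fixed at 0.5 and the penalty strength tuned by
inner 10-fold cross-validation over ``lambda = exp(gamma)``,
``gamma in (-6, 5)``.

Every fitted model reduces to a linear form (coefficients over selected
genes plus an intercept), which keeps serialization and prediction
uniform across families.  Rank/mRMR signatures are capped at 30 genes by
default; the feature space is first reduced to the 1000 highest-variance
genes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .enrichment import _spearman_rows

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorModel",
    "MRMRSolutionSet",
    "ModelSpec",
    "MODEL_NAMES",
    "variance_filter",
    "fit_single_gene",
    "fit_rank_ensemble",
    "fit_rank_multivariate",
    "mrmr_select",
    "fit_mrmr",
    "fit_elastic_net",
    "predict",
]

MODEL_NAMES = (
    "single_gene",
    "rank_ensemble",
    "rank_multivariate",
    "mrmr_exhaustive",
    "mrmr_bootstrap",
    "elastic_net",
)

# cap for the correlation-based mutual information when rho^2 -> 1
_MI_CAP = -0.5 * np.log(1e-12)


@dataclass
class PredictorModel:
    """A fitted linear predictor over a selected gene signature."""

    name: str
    selected_genes: list[str]
    coefficients: dict[str, float]
    intercept: float
    hyperparameters: dict = field(default_factory=dict)
    fitted: bool = False

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PredictorModel":
        d = json.loads(text)
        return cls(**d)


@dataclass
class MRMRSolutionSet:
    """K ordered mRMR gene lists plus the per-step criterion trace."""

    solutions: list[list[str]]
    method: str
    K: int
    criterion_trace: list[list[float]]

    def __post_init__(self) -> None:
        for sol in self.solutions:
            if len(sol) != len(set(sol)):
                raise ValueError("mRMR solution contains repeated genes")
        if self.method == "exhaustive":
            firsts = [sol[0] for sol in self.solutions if sol]
            if len(firsts) != len(set(firsts)):
                raise ValueError("exhaustive solutions must start with distinct genes")


def _as_xy(expr: pd.DataFrame, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(y, pd.Series):
        y_vec = y.loc[expr.columns].to_numpy(float)
    else:
        y_vec = np.asarray(y, float)
        if len(y_vec) != expr.shape[1]:
            raise ValueError("y length must match number of samples")
    return expr.to_numpy(float), y_vec, [str(g) for g in expr.index]


def variance_filter(expr: pd.DataFrame, n_keep: int) -> list[str]:
    """The ``n_keep`` genes with largest sample variance.

    Deterministic; ties broken by gene-ID lexicographic order.
    """
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    if n_keep > expr.shape[0]:
        raise ValueError(f"n_keep={n_keep} exceeds gene count {expr.shape[0]}")
    variances = expr.to_numpy(float).var(axis=1, ddof=1)
    gene_ids = np.asarray([str(g) for g in expr.index])
    order = np.lexsort((gene_ids, -variances))
    return [str(g) for g in gene_ids[order[:n_keep]]]


def _abs_spearman_order(expr: pd.DataFrame, y_vec: np.ndarray) -> np.ndarray:
    """Gene indices sorted by |Spearman rho| desc, ties by gene ID."""
    rho = _spearman_rows(expr.to_numpy(float), y_vec)
    rho = np.nan_to_num(rho, nan=0.0)  # constant genes score 0
    gene_ids = np.asarray([str(g) for g in expr.index])
    return np.lexsort((gene_ids, -np.abs(rho)))


def _univariate_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return 0.0, float(y.mean())
    slope = float(xc @ (y - y.mean())) / sxx
    return slope, float(y.mean() - slope * x.mean())


def fit_single_gene(expr: pd.DataFrame, y) -> PredictorModel:
    """Univariate OLS on the gene most correlated (Spearman) with y."""
    mat, y_vec, genes = _as_xy(expr, y)
    if len(y_vec) < 3:
        raise ValueError("need at least 3 samples")
    if np.all(np.ptp(mat, axis=1) == 0):
        raise ValueError("all genes are constant")
    best = _abs_spearman_order(expr, y_vec)[0]
    gene = genes[best]
    slope, intercept = _univariate_ols(mat[best], y_vec)
    return PredictorModel(
        name="single_gene",
        selected_genes=[gene],
        coefficients={gene: slope},
        intercept=intercept,
        fitted=True,
    )


def fit_rank_ensemble(expr: pd.DataFrame, y, signature_size: int = 30) -> PredictorModel:
    """Mean of per-gene univariate predictions over the top correlated genes.

    The unweighted mean of k univariate OLS predictions is itself linear,
    so the model stores ``slope_g / k`` per gene and the mean intercept;
    the per-gene univariate parameters are kept in the hyperparameters for
    recomposition checks.
    """
    if signature_size <= 0:
        raise ValueError("signature_size must be positive")
    mat, y_vec, genes = _as_xy(expr, y)
    if signature_size > len(genes):
        raise ValueError("signature_size exceeds gene count")
    top = _abs_spearman_order(expr, y_vec)[:signature_size]
    selected = [genes[i] for i in top]
    members = {}
    for i, g in zip(top, selected):
        members[g] = _univariate_ols(mat[i], y_vec)
    k = len(selected)
    coefficients = {g: members[g][0] / k for g in selected}
    intercept = float(np.mean([members[g][1] for g in selected]))
    return PredictorModel(
        name="rank_ensemble",
        selected_genes=selected,
        coefficients=coefficients,
        intercept=intercept,
        hyperparameters={"signature_size": signature_size, "univariate": members},
        fitted=True,
    )


def _multivariate_ols(
    mat: np.ndarray, y_vec: np.ndarray, selected_idx: Sequence[int], genes: Sequence[str]
) -> tuple[dict[str, float], float]:
    x = mat[list(selected_idx)].T
    design = np.column_stack([np.ones(len(y_vec)), x])
    coef, *_ = np.linalg.lstsq(design, y_vec, rcond=None)
    return (
        {genes[i]: float(c) for i, c in zip(selected_idx, coef[1:])},
        float(coef[0]),
    )


def fit_rank_multivariate(
    expr: pd.DataFrame, y, signature_size: int = 30
) -> PredictorModel:
    """Multivariate least squares on the top correlated genes.

    Uses the minimum-norm solution when the design is rank-deficient, so
    collinear (even duplicated) genes still yield finite coefficients.
    """
    if signature_size <= 0:
        raise ValueError("signature_size must be positive")
    mat, y_vec, genes = _as_xy(expr, y)
    if signature_size > len(genes):
        raise ValueError("signature_size exceeds gene count")
    top = _abs_spearman_order(expr, y_vec)[:signature_size]
    coefficients, intercept = _multivariate_ols(mat, y_vec, top, genes)
    return PredictorModel(
        name="rank_multivariate",
        selected_genes=[genes[i] for i in top],
        coefficients=coefficients,
        intercept=intercept,
        hyperparameters={"signature_size": signature_size},
        fitted=True,
    )


def _mi_from_rho(rho: np.ndarray) -> np.ndarray:
    """Correlation-based mutual information -0.5*ln(1 - rho^2), capped."""
    r2 = np.clip(np.square(rho), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = -0.5 * np.log1p(-r2)
    over = ~np.isfinite(mi) | (mi > _MI_CAP)
    if np.any(over):
        mi = np.where(over, _MI_CAP, mi)
    return mi


def _mi_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise gene-gene MI from Spearman correlations."""
    ranks = stats.rankdata(mat, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.nan_to_num(rho, nan=0.0)
    if np.any(constant):
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    return _mi_from_rho(rho)


def _mi_relevance(mat: np.ndarray, y_vec: np.ndarray) -> np.ndarray:
    rho = np.nan_to_num(_spearman_rows(mat, y_vec), nan=0.0)
    return _mi_from_rho(rho)


def _greedy_mrmr(
    relevance: np.ndarray,
    mi: np.ndarray,
    first: int,
    size: int,
    gene_ids: np.ndarray,
) -> tuple[list[int], list[float]]:
    """Greedy MID selection: maximize relevance - mean redundancy.

    Ties broken by gene ID for determinism.
    """
    n = len(relevance)
    selected = [first]
    trace = [float(relevance[first])]
    redundancy_sum = mi[first].copy()
    available = np.ones(n, bool)
    available[first] = False
    while len(selected) < size:
        crit = relevance - redundancy_sum / len(selected)
        crit[~available] = -np.inf
        best = np.lexsort((gene_ids, -crit))[0]
        selected.append(int(best))
        trace.append(float(crit[best]))
        available[best] = False
        redundancy_sum += mi[best]
    return selected, trace


def mrmr_select(
    expr: pd.DataFrame,
    y,
    signature_size: int = 30,
    method: str = "exhaustive",
    K: int = 10,
    seed: int = 0,
) -> MRMRSolutionSet:
    """Produce K mRMR solutions by exhaustive seeding or bootstrapping.

    Relevance and redundancy use the Spearman-based mutual information
    ``-0.5 * ln(1 - rho^2)``.  The exhaustive method starts solution j
    from the j-th most relevant gene (so the first selected features are
    pairwise distinct); the bootstrap method resamples samples with
    replacement K times and runs classical greedy mRMR on each resample.
    """
    if method not in ("exhaustive", "bootstrap"):
        raise ValueError(f"unknown mRMR method {method!r}")
    if K < 1:
        raise ValueError("K must be >= 1")
    mat, y_vec, genes = _as_xy(expr, y)
    n_genes = len(genes)
    if signature_size > n_genes:
        raise ValueError("signature_size exceeds gene count")
    gene_arr = np.asarray(genes)

    solutions: list[list[int]] = []
    traces: list[list[float]] = []
    if method == "exhaustive":
        if K > n_genes:
            raise ValueError("exhaustive method needs K <= gene count")
        relevance = _mi_relevance(mat, y_vec)
        mi = _mi_matrix(mat)
        seeds = np.lexsort((gene_arr, -relevance))[:K]
        for first in seeds:
            sol, tr = _greedy_mrmr(relevance, mi, int(first), signature_size, gene_arr)
            solutions.append(sol)
            traces.append(tr)
    else:
        rng = np.random.default_rng(seed)
        n_samples = mat.shape[1]
        for _ in range(K):
            idx = rng.integers(0, n_samples, size=n_samples)
            bmat, by = mat[:, idx], y_vec[idx]
            if np.ptp(by) == 0:  # degenerate resample: skip to a fresh draw
                idx = rng.integers(0, n_samples, size=n_samples)
                bmat, by = mat[:, idx], y_vec[idx]
            relevance = _mi_relevance(bmat, by)
            mi = _mi_matrix(bmat)
            first = int(np.lexsort((gene_arr, -relevance))[0])
            sol, tr = _greedy_mrmr(relevance, mi, first, signature_size, gene_arr)
            solutions.append(sol)
            traces.append(tr)

    return MRMRSolutionSet(
        solutions=[[genes[i] for i in sol] for sol in solutions],
        method=method,
        K=K,
        criterion_trace=traces,
    )


def aggregate_mrmr_signature(
    solution_set: MRMRSolutionSet, signature_size: int
) -> list[str]:
    """Collapse K solutions into one signature by selection frequency.

    Ties broken by mean within-solution position, then by gene ID.
    """
    freq: dict[str, int] = {}
    pos_sum: dict[str, int] = {}
    for sol in solution_set.solutions:
        for pos, g in enumerate(sol):
            freq[g] = freq.get(g, 0) + 1
            pos_sum[g] = pos_sum.get(g, 0) + pos
    ranked = sorted(
        freq, key=lambda g: (-freq[g], pos_sum[g] / freq[g], g)
    )
    return ranked[:signature_size]


def fit_mrmr(
    expr: pd.DataFrame,
    y,
    signature_size: int = 30,
    method: str = "exhaustive",
    K: int = 10,
    seed: int = 0,
    use_first_solution_only: bool = False,
) -> PredictorModel:
    """mRMR selection followed by multivariate least squares."""
    sols = mrmr_select(expr, y, signature_size, method, K, seed)
    if use_first_solution_only:
        signature = sols.solutions[0][:signature_size]
    else:
        signature = aggregate_mrmr_signature(sols, signature_size)
    mat, y_vec, genes = _as_xy(expr, y)
    index = {g: i for i, g in enumerate(genes)}
    sel_idx = [index[g] for g in signature]
    coefficients, intercept = _multivariate_ols(mat, y_vec, sel_idx, genes)
    return PredictorModel(
        name=f"mrmr_{method}",
        selected_genes=signature,
        coefficients=coefficients,
        intercept=intercept,
        hyperparameters={
            "signature_size": signature_size,
            "method": method,
            "K": K,
            "seed": seed,
        },
        fitted=True,
    )


def fit_elastic_net(
    expr: pd.DataFrame,
    y,
    alpha_mix: float = 0.5,
    gamma_range: tuple[float, float] = (-6.0, 5.0),
    n_lambda: int = 100,
    inner_folds: int = 10,
    seed: int = 0,
    fixed_lambda: float | None = None,
) -> PredictorModel:
    """Elastic net at fixed L1/L2 mixing with CV-tuned penalty strength.

    Features are standardized on the training data; returned coefficients
    are on the original expression scale.  ``lambda`` is chosen among
    ``n_lambda`` log-uniform values over ``exp(gamma_range)`` by
    minimizing inner ``inner_folds``-fold CV mean squared error, unless
    ``fixed_lambda`` pins it.
    """
    mat, y_vec, genes = _as_xy(expr, y)
    if np.ptp(y_vec) == 0:
        logger.warning("constant outcome: returning intercept-only model")
        return PredictorModel(
            name="elastic_net",
            selected_genes=[],
            coefficients={},
            intercept=float(y_vec[0]),
            hyperparameters={"alpha_mix": alpha_mix, "lambda": None},
            fitted=True,
        )
    keep = np.ptp(mat, axis=1) > 0
    if not np.any(keep):
        raise ValueError("all genes are constant")
    mat = mat[keep]
    genes = [g for g, k in zip(genes, keep) if k]
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    x = ((mat - mu) / sd).T

    if fixed_lambda is not None:
        lam = float(fixed_lambda)
        est = ElasticNet(alpha=lam, l1_ratio=alpha_mix, max_iter=10_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x, y_vec)
        coef_std, b0 = est.coef_, float(est.intercept_)
    else:
        lambdas = np.exp(np.linspace(gamma_range[1], gamma_range[0], n_lambda))
        cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        est = ElasticNetCV(
            l1_ratio=alpha_mix, alphas=lambdas, cv=cv, max_iter=10_000, n_jobs=None
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(x, y_vec)
        lam = float(est.alpha_)
        coef_std, b0 = est.coef_, float(est.intercept_)

    coef_orig = coef_std / sd.ravel()
    intercept = b0 - float((coef_std * (mu.ravel() / sd.ravel())).sum())
    nonzero = [(g, float(c)) for g, c in zip(genes, coef_orig) if c != 0.0]
    return PredictorModel(
        name="elastic_net",
        selected_genes=[g for g, _ in nonzero],
        coefficients=dict(nonzero),
        intercept=intercept,
        hyperparameters={
            "alpha_mix": alpha_mix,
            "lambda": lam,
            "gamma_range": list(gamma_range),
            "n_lambda": n_lambda,
            "inner_folds": inner_folds,
            "seed": seed,
        },
        fitted=True,
    )


def predict(model: PredictorModel, expr: pd.DataFrame) -> pd.Series:
    """Predict one value per sample (column) of ``expr``."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    missing = [g for g in model.selected_genes if g not in expr.index]
    if missing:
        raise ValueError(f"expression matrix missing selected genes: {missing}")
    pred = np.full(expr.shape[1], model.intercept, float)
    for g, c in model.coefficients.items():
        pred += c * expr.loc[g].to_numpy(float)
    return pd.Series(pred, index=expr.columns, name="prediction")


@dataclass(frozen=True)
class ModelSpec:
    """Recipe for fitting one family, including the variance prefilter.

    By default the prefilter is computed inside whatever training matrix is
    passed to :meth:`fit` (leakage-safe).  Supplying ``prefilter_genes``
    reproduces the cohort-level filter computed once on the full discovery
    data.
    """

    name: str
    signature_size: int = 30
    n_keep: int = 1000
    K: int = 10
    alpha_mix: float = 0.5
    gamma_range: tuple[float, float] = (-6.0, 5.0)
    n_lambda: int = 100
    inner_folds: int = 10
    prefilter_genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")

    def fit(self, expr: pd.DataFrame, y, seed: int = 0) -> PredictorModel:
        if self.prefilter_genes is not None:
            genes = [g for g in self.prefilter_genes if g in expr.index]
        else:
            genes = variance_filter(expr, min(self.n_keep, expr.shape[0]))
        sub = expr.loc[genes]
        if self.name == "single_gene":
            return fit_single_gene(sub, y)
        if self.name == "rank_ensemble":
            return fit_rank_ensemble(sub, y, self.signature_size)
        if self.name == "rank_multivariate":
            return fit_rank_multivariate(sub, y, self.signature_size)
        if self.name in ("mrmr_exhaustive", "mrmr_bootstrap"):
            return fit_mrmr(
                sub,
                y,
                self.signature_size,
                method=self.name.removeprefix("mrmr_"),
                K=self.K,
                seed=seed,
            )
        return fit_elastic_net(
            sub,
            y,
            alpha_mix=self.alpha_mix,
            gamma_range=self.gamma_range,
            n_lambda=self.n_lambda,
            inner_folds=self.inner_folds,
            seed=seed,
        )


def default_model_specs(**overrides) -> list[ModelSpec]:
    """The six benchmark configurations (five families, mRMR twice)."""
    return [ModelSpec(name=name, **overrides) for name in MODEL_NAMES]
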