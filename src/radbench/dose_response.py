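"""Linear-quadratic dose-response fitting and radiosensitivity summaries.

Clonogenic survival after a single radiation dose ``D`` (in Gy) is modelled
as ``SF(D) = exp(-alpha*D - beta*D**2)`` with non-negative ``alpha``
(Gy^-1) and ``beta`` (Gy^-2).  Fitting is performed on log-survival by
non-negative least squares on the design ``{D, D**2}``, which is convex and
deterministic.  The per-sample summaries are SF2 (surviving fraction at
2 Gy) and the width-normalized area under the fitted survival curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseCurve",
    "LQFit",
    "RadioResponseProfile",
    "fit_lq",
    "survival_at",
    "auc",
    "compute_profiles",
    "curves_from_frame",
    "curves_to_frame",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Observed surviving fractions for one sample across a dose grid."""

    sample_id: str
    doses: tuple[float, ...]
    survival: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(self, "survival", tuple(float(s) for s in self.survival))
        if len(self.doses) != len(self.survival):
            raise ValueError(
                f"{self.sample_id}: doses ({len(self.doses)}) and survival "
                f"({len(self.survival)}) have different lengths"
            )
        if any(d <= 0 for d in self.doses):
            raise ValueError(f"{self.sample_id}: all doses must be > 0")

    @property
    def n_distinct_doses(self) -> int:
        return len(set(self.doses))


@dataclass(frozen=True)
class LQFit:
    """Fitted linear-quadratic parameters for one survival curve."""

    alpha: float
    beta: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "rss"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


@dataclass
class RadioResponseProfile:
    """Per-sample SF2 and normalized AUC; the pipeline's outcome vectors."""

    sample_ids: list[str]
    sf2: np.ndarray
    auc: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    rss: np.ndarray
    excluded: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "sf2": self.sf2,
                "auc": self.auc,
                "alpha": self.alpha,
                "beta": self.beta,
                "rss": self.rss,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RadioResponseProfile":
        required = {"sample_id", "sf2", "auc", "alpha", "beta", "rss"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"profile frame missing columns: {sorted(missing)}")
        return cls(
            sample_ids=[str(s) for s in frame["sample_id"]],
            sf2=frame["sf2"].to_numpy(float),
            auc=frame["auc"].to_numpy(float),
            alpha=frame["alpha"].to_numpy(float),
            beta=frame["beta"].to_numpy(float),
            rss=frame["rss"].to_numpy(float),
        )

    def y(self, endpoint: str = "sf2") -> pd.Series:
        """Outcome vector indexed by sample id."""
        if endpoint not in ("sf2", "auc"):
            raise ValueError(f"unknown endpoint {endpoint!r}")
        return pd.Series(getattr(self, endpoint), index=self.sample_ids, name=endpoint)


def fit_lq(curve: DoseResponseCurve) -> LQFit:
    """Fit ``SF(D)=exp(-aD-bD^2)`` by bounded least squares on log-survival.

    Survival values above 1 are clipped to 1 with a warning; values at
    exactly 1 contribute zero residuals.  Replicate observations at the
    same dose are retained as separate residuals.
    """
    if curve.n_distinct_doses < 2:
        raise ValueError(
            f"{curve.sample_id}: need >=2 distinct doses to fit, "
            f"got {curve.n_distinct_doses}"
        )
    sf = np.asarray(curve.survival, dtype=float)
    if np.any(sf <= 0):
        raise ValueError(f"{curve.sample_id}: survival values must be in (0, 1]")
    if np.any(sf > 1):
        logger.warning(
            "%s: %d survival values > 1 clipped to 1", curve.sample_id, int((sf > 1).sum())
        )
        sf = np.minimum(sf, 1.0)
    d = np.asarray(curve.doses, dtype=float)
    design = np.column_stack([d, d * d])
    target = -np.log(sf)
    coef, nnls_resid = optimize.nnls(design, target)
    alpha, beta = float(coef[0]), float(coef[1])
    return LQFit(alpha=alpha, beta=beta, rss=float(nnls_resid**2), n_points=len(d))


def survival_at(fit: LQFit, dose: float) -> float:
    """Surviving fraction predicted by the fit at ``dose`` Gy."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    return float(np.exp(-fit.alpha * dose - fit.beta * dose * dose))


def auc(fit: LQFit, dose_range: tuple[float, float], normalize: bool = True) -> float:
    """Area under the fitted survival curve over ``dose_range``.

    By default the integral is divided by the range width so the value lies
    in (0, 1] and is comparable across cohorts with different dose grids;
    ``normalize=False`` returns the raw area.
    """
    lo, hi = float(dose_range[0]), float(dose_range[1])
    if lo < 0 or hi < 0 or not lo < hi:
        raise ValueError(f"dose_range must satisfy 0 <= lo < hi, got {dose_range}")
    integrand = lambda d: math.exp(-fit.alpha * d - fit.beta * d * d)  # noqa: E731
    area, _ = integrate.quad(integrand, lo, hi, epsabs=1e-12, epsrel=1e-10)
    return float(area / (hi - lo)) if normalize else float(area)


def compute_profiles(
    curves: Iterable[DoseResponseCurve],
    dose_range: tuple[float, float],
    sf2_dose: float = 2.0,
) -> RadioResponseProfile:
    """Fit every curve and assemble per-sample SF2/AUC summaries.

    Samples whose curve cannot be fitted (e.g. a single dose point) are
    excluded with a logged reason; the remaining samples are unaffected.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no dose-response curves supplied")
    ids: list[str] = []
    sf2s: list[float] = []
    aucs: list[float] = []
    alphas: list[float] = []
    betas: list[float] = []
    rsss: list[float] = []
    excluded: dict[str, str] = {}
    for curve in curves:
        try:
            fit = fit_lq(curve)
        except ValueError as exc:
            logger.warning("excluding %s: %s", curve.sample_id, exc)
            excluded[curve.sample_id] = str(exc)
            continue
        ids.append(curve.sample_id)
        sf2s.append(survival_at(fit, sf2_dose))
        aucs.append(auc(fit, dose_range))
        alphas.append(fit.alpha)
        betas.append(fit.beta)
        rsss.append(fit.rss)
    if not ids:
        raise ValueError("every curve failed to fit")
    return RadioResponseProfile(
        sample_ids=ids,
        sf2=np.asarray(sf2s),
        auc=np.asarray(aucs),
        alpha=np.asarray(alphas),
        beta=np.asarray(betas),
        rss=np.asarray(rsss),
        excluded=excluded,
    )


def curves_from_frame(frame: pd.DataFrame) -> list[DoseResponseCurve]:
    """Group a long-format (sample_id, dose_gy, surviving_fraction) table."""
    required = {"sample_id", "dose_gy", "surviving_fraction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"curve frame missing columns: {sorted(missing)}")
    out = []
    for sample_id, grp in frame.groupby("sample_id", sort=False):
        out.append(
            DoseResponseCurve(
                sample_id=str(sample_id),
                doses=tuple(grp["dose_gy"].astype(float)),
                survival=tuple(grp["surviving_fraction"].astype(float)),
            )
        )
    return out


def curves_to_frame(curves: Sequence[DoseResponseCurve]) -> pd.DataFrame:
    records = [
        (c.sample_id, d, s) for c in curves for d, s in zip(c.doses, c.survival)
    ]
    return pd.DataFrame(records, columns=["sample_id", "dose_gy", "surviving_fraction"])
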