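"""Synthetic radiogenomic cohort generator with known ground truth.

Generates paired discovery/validation cohorts -- a gene-expression matrix,
per-line linear-quadratic dose-response curves, and a ground-truth record
(planted signal genes, true alpha/beta, true SF2) -- so that every
downstream stage (dose-response summarization, enrichment, predictor
fitting, concordance evaluation) can be tested without external data.

Generative model
----------------
Expression is produced on a log2-like scale: per-gene baseline means,
additive per-tissue mean shifts, unit biological variation, and i.i.d.
technical noise.  A latent radiosensitivity score is a signed linear
combination of the standardized expression of the planted signal genes
plus an independent residual.  SF2 is an affine transform of the
standardized latent score, moment-matched so the empirical SF2 mean/sd hit
the configured targets, then truncated to (0, 1].  Alpha follows from
``SF2 = exp(-2a - 4b)`` with ``b = ratio * a``; observed surviving
fractions are the LQ curve perturbed by multiplicative log-normal noise at
every dose in the grid and clipped to (0, 1].

All randomness flows through named child streams of a single seed, so a
cohort is bit-reproducible and the no-signal SF2 draw does not depend on
which genes are designated as signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve
from .enrichment import GeneSet, GeneSetCollection

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_paired_cohorts",
    "generate_gene_sets",
]

_SF2_FLOOR = 1e-4
_STREAMS = (
    "tissue_assignment",
    "gene_means",
    "tissue_effects",
    "base_variation",
    "technical_noise",
    "signal_genes",
    "latent_residual",
    "survival_noise",
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the discovery screen: 511 lines over 23 tissues with
    SF2 targets mean 0.6 / sd 0.2 on the {1,2,3,4,6,8} Gy grid.  The
    validation-screen analogue is 60 lines over 9 tissues on {2,4,6} Gy.
    """

    n_samples: int = 511
    n_tissues: int = 23
    n_genes: int = 2000
    n_signal_genes: int = 30
    signal_effect: float = 1.0
    expression_noise_sd: float = 0.25
    survival_noise_sd: float = 0.05
    dose_grid: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    sf2_target_mean: float = 0.6
    sf2_target_sd: float = 0.2
    seed: int = 0
    # --- secondary knobs (paper-silent; see module docstring) ---
    tissue_effect_sd: float = 0.5
    latent_noise_sd: float = 1.0
    beta_alpha_ratio: float = 0.1
    couple_tissue_to_sf2: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_tissues < 1 or self.n_tissues > self.n_samples:
            raise ValueError("need 1 <= n_tissues <= n_samples")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must be <= n_genes")
        if not self.dose_grid:
            raise ValueError("dose_grid must not be empty")
        if any(d <= 0 for d in self.dose_grid):
            raise ValueError("all doses must be > 0")
        if not 0 < self.sf2_target_mean < 1:
            raise ValueError("sf2_target_mean must lie in (0, 1)")
        if self.sf2_target_sd <= 0:
            raise ValueError("sf2_target_sd must be > 0")
        if self.signal_effect < 0 or self.expression_noise_sd < 0:
            raise ValueError("signal_effect and expression_noise_sd must be >= 0")
        if self.survival_noise_sd < 0 or self.beta_alpha_ratio < 0:
            raise ValueError("survival_noise_sd and beta_alpha_ratio must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted: the oracle for recovery tests."""

    sample_ids: list[str]
    signal_gene_ids: list[str]
    signal_signs: dict[str, int]
    alpha: np.ndarray
    beta: np.ndarray
    true_sf2: np.ndarray
    tissues: list[int]
    planted_set_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "sample_ids": self.sample_ids,
            "signal_gene_ids": self.signal_gene_ids,
            "signal_signs": self.signal_signs,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "true_sf2": self.true_sf2.tolist(),
            "tissues": self.tissues,
            "planted_set_ids": self.planted_set_ids,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            sample_ids=d["sample_ids"],
            signal_gene_ids=d["signal_gene_ids"],
            signal_signs={k: int(v) for k, v in d["signal_signs"].items()},
            alpha=np.asarray(d["alpha"], float),
            beta=np.asarray(d["beta"], float),
            true_sf2=np.asarray(d["true_sf2"], float),
            tissues=list(d["tissues"]),
            planted_set_ids=list(d.get("planted_set_ids", [])),
        )


@dataclass
class Cohort:
    """One generated cohort bundle: expression, curves, and ground truth."""

    name: str
    expression: pd.DataFrame  # genes x samples
    curves: list[DoseResponseCurve]
    truth: GroundTruth
    config: CohortConfig

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _match_sf2_moments(
    z: np.ndarray, mean: float, sd: float, n_iter: int = 60
) -> np.ndarray:
    """Affine-map a standardized score to SF2 with target moments.

    Truncation to (0, 1] is applied last; the affine parameters are
    iteratively adjusted so the *truncated* distribution matches the
    targets (moment matching converges in a handful of steps at these
    truncation levels).
    """
    m, s = mean, sd
    sf2 = np.clip(m + s * z, _SF2_FLOOR, 1.0)
    for _ in range(n_iter):
        emp_mean = sf2.mean()
        emp_sd = sf2.std(ddof=1)
        if emp_sd > 1e-12:
            s *= sd / emp_sd
        m += mean - emp_mean
        sf2 = np.clip(m + s * z, _SF2_FLOOR, 1.0)
    return sf2


def generate_cohort(
    config: CohortConfig,
    *,
    gene_ids: Sequence[str] | None = None,
    signal_genes: Sequence[str] | None = None,
    signal_signs: Mapping[str, int] | None = None,
    sample_prefix: str = "S",
    name: str = "cohort",
) -> Cohort:
    """Generate one cohort; deterministic given the config seed.

    ``gene_ids``/``signal_genes``/``signal_signs`` may be supplied to share
    a gene universe and a gene->effect mapping across paired cohorts;
    otherwise they are drawn from the config.
    """
    rng = _streams(config.seed)
    n, g = config.n_samples, config.n_genes

    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    else:
        gene_ids = [str(x) for x in gene_ids]
        if len(gene_ids) != g:
            raise ValueError(
                f"gene_ids length {len(gene_ids)} != n_genes {g}"
            )
    sample_ids = [f"{sample_prefix}{i + 1:04d}" for i in range(n)]

    tissues = rng["tissue_assignment"].integers(0, config.n_tissues, size=n)
    gene_means = rng["gene_means"].normal(7.0, 2.0, size=g)
    tissue_shift = rng["tissue_effects"].normal(
        0.0, config.tissue_effect_sd, size=(g, config.n_tissues)
    )
    expr = (
        gene_means[:, None]
        + tissue_shift[:, tissues]
        + rng["base_variation"].normal(0.0, 1.0, size=(g, n))
        + rng["technical_noise"].normal(0.0, config.expression_noise_sd, size=(g, n))
    )
    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)

    if signal_genes is None:
        idx = rng["signal_genes"].choice(g, size=config.n_signal_genes, replace=False)
        signal_genes = [gene_ids[i] for i in sorted(idx)]
        signs = rng["signal_genes"].choice([-1, 1], size=config.n_signal_genes)
        signal_signs = {gid: int(s) for gid, s in zip(signal_genes, signs)}
    else:
        signal_genes = [str(x) for x in signal_genes]
        missing = set(signal_genes) - set(gene_ids)
        if missing:
            raise ValueError(f"signal genes not in universe: {sorted(missing)}")
        if signal_signs is None:
            signal_signs = {gid: 1 for gid in signal_genes}
        signal_signs = {gid: int(signal_signs[gid]) for gid in signal_genes}

    # Latent radiosensitivity: signed combination of standardized signal
    # expression plus an independent residual (its stream does not depend
    # on the signal-gene draw, so the no-signal SF2 is invariant to it).
    latent = rng["latent_residual"].normal(0.0, config.latent_noise_sd, size=n)
    if config.signal_effect != 0 and signal_genes:
        sub = expression.loc[signal_genes].to_numpy()
        mu = sub.mean(axis=1, keepdims=True)
        sdv = sub.std(axis=1, ddof=1, keepdims=True)
        sdv[sdv == 0] = 1.0
        z = (sub - mu) / sdv
        signs_arr = np.array([signal_signs[gid] for gid in signal_genes], float)
        latent = latent + config.signal_effect * (signs_arr @ z)
    if config.couple_tissue_to_sf2:
        tissue_latent = rng["tissue_effects"].normal(0.0, 1.0, size=config.n_tissues)
        latent = latent + tissue_latent[tissues]

    lat_sd = latent.std(ddof=1)
    z_lat = (latent - latent.mean()) / lat_sd if lat_sd > 1e-12 else np.zeros(n)
    sf2 = _match_sf2_moments(z_lat, config.sf2_target_mean, config.sf2_target_sd)

    denom = 2.0 + 4.0 * config.beta_alpha_ratio
    alpha = -np.log(sf2) / denom
    beta = config.beta_alpha_ratio * alpha
    true_sf2 = np.exp(-2.0 * alpha - 4.0 * beta)

    doses = np.asarray(config.dose_grid, float)
    log_sf_true = -np.outer(alpha, doses) - np.outer(beta, doses**2)
    noise = rng["survival_noise"].normal(
        0.0, config.survival_noise_sd, size=log_sf_true.shape
    )
    sf_obs = np.minimum(np.exp(log_sf_true + noise), 1.0)
    curves = [
        DoseResponseCurve(
            sample_id=sid, doses=tuple(doses), survival=tuple(sf_obs[i])
        )
        for i, sid in enumerate(sample_ids)
    ]

    truth = GroundTruth(
        sample_ids=sample_ids,
        signal_gene_ids=list(signal_genes),
        signal_signs=dict(signal_signs),
        alpha=alpha,
        beta=beta,
        true_sf2=true_sf2,
        tissues=[int(t) for t in tissues],
    )
    return Cohort(
        name=name, expression=expression, curves=curves, truth=truth, config=config
    )


def generate_paired_cohorts(
    discovery: CohortConfig,
    validation: CohortConfig,
    shared_gene_fraction: float = 1.0,
) -> tuple[Cohort, Cohort]:
    """Generate discovery/validation cohorts with a shared signal.

    The two gene universes overlap in ``ceil(shared_gene_fraction * min
    universe size)`` identifiers; all signal genes live in the overlap and
    carry the identical gene->effect mapping, so the planted signal
    transfers across cohorts.  Samples and random streams are independent.
    """
    if not 0 < shared_gene_fraction <= 1:
        raise ValueError("shared_gene_fraction must lie in (0, 1]")
    if discovery.n_signal_genes != validation.n_signal_genes:
        raise ValueError("cohorts must share n_signal_genes")
    if discovery.signal_effect != validation.signal_effect:
        raise ValueError("cohorts must share signal_effect")
    if discovery.seed == validation.seed:
        raise ValueError("discovery and validation seeds must differ")

    n_min = min(discovery.n_genes, validation.n_genes)
    n_shared = int(math.ceil(shared_gene_fraction * n_min))
    shared = [f"G{i + 1:05d}" for i in range(n_shared)]
    disc_ids = shared + [
        f"DG{i + 1:05d}" for i in range(discovery.n_genes - n_shared)
    ]
    valid_ids = shared + [
        f"VG{i + 1:05d}" for i in range(validation.n_genes - n_shared)
    ]

    sig_rng = np.random.default_rng(np.random.SeedSequence(discovery.seed).spawn(9)[-1])
    idx = sig_rng.choice(n_shared, size=discovery.n_signal_genes, replace=False)
    signal_genes = [shared[i] for i in sorted(idx)]
    signs = sig_rng.choice([-1, 1], size=discovery.n_signal_genes)
    signal_signs = {gid: int(s) for gid, s in zip(signal_genes, signs)}

    cohort_d = generate_cohort(
        discovery,
        gene_ids=disc_ids,
        signal_genes=signal_genes,
        signal_signs=signal_signs,
        sample_prefix="D",
        name="discovery",
    )
    cohort_v = generate_cohort(
        validation,
        gene_ids=valid_ids,
        signal_genes=signal_genes,
        signal_signs=signal_signs,
        sample_prefix="V",
        name="validation",
    )
    return cohort_d, cohort_v


def generate_gene_sets(
    universe: Sequence[str],
    signal_genes: Sequence[str],
    n_sets: int = 1498,
    n_planted: int = 0,
    size_range: tuple[int, int] = (15, 100),
    seed: int = 0,
    signal_signs: Mapping[str, int] | None = None,
    planted_fraction: float = 0.6,
) -> GeneSetCollection:
    """Build a gene-set collection with optionally planted enriched sets.

    Planted sets draw a majority (``planted_fraction``) of their members
    from the signal genes; when a sign map is given each planted set uses
    genes of a single effect sign so its enrichment direction is coherent
    (names carry a ``PLANTED_POS``/``PLANTED_NEG`` prefix and the
    description records the expected direction).  The remaining sets are
    uniform random draws from the universe.
    """
    universe = [str(u) for u in universe]
    signal_genes = [str(s) for s in signal_genes]
    if n_planted > n_sets:
        raise ValueError("n_planted must be <= n_sets")
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid size_range {size_range}")
    if hi > len(universe):
        raise ValueError(
            f"size_range upper bound {hi} exceeds universe size {len(universe)}"
        )
    if n_planted > 0 and not signal_genes:
        raise ValueError("cannot plant sets without signal genes")
    missing = set(signal_genes) - set(universe)
    if missing:
        raise ValueError(f"signal genes outside universe: {sorted(missing)}")
    if not 0.5 < planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in (0.5, 1]")

    rng = np.random.default_rng(seed)
    non_signal = [u for u in universe if u not in set(signal_genes)]
    if signal_signs:
        pools = {
            sgn: [g for g in signal_genes if signal_signs[g] == sgn] for sgn in (1, -1)
        }
        pools = {sgn: pool for sgn, pool in pools.items() if pool}
    else:
        pools = {1: signal_genes}
    pool_signs = sorted(pools)

    sets: list[GeneSet] = []
    for j in range(n_planted):
        sgn = pool_signs[j % len(pool_signs)]
        pool = pools[sgn]
        size = int(rng.integers(lo, hi + 1))
        n_sig = min(len(pool), int(math.ceil(planted_fraction * size)))
        # keep the signal majority even when the pool is small
        size = min(size, max(1, int(math.floor(n_sig / planted_fraction))))
        n_fill = max(0, size - n_sig)
        members = list(rng.choice(pool, size=n_sig, replace=False))
        if n_fill:
            members += list(rng.choice(non_signal, size=n_fill, replace=False))
        label = "POS" if sgn > 0 else "NEG"
        sets.append(
            GeneSet(
                name=f"PLANTED_{label}_{j + 1:03d}",
                description=f"planted direction={'+' if sgn > 0 else '-'}1",
                genes=tuple(members),
            )
        )
    for j in range(n_sets - n_planted):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"RANDOM_{j + 1:04d}",
                description="random draw",
                genes=tuple(members),
            )
        )
    return GeneSetCollection(sets=sets)
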