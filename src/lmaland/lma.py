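"""Local malignant adaptation scores: four models, weight grid search, diagnostics.

A sample's LMA score sums the contribution of each of its clonal drivers,
split into an *intrinsic* component (selective advantage and self-sufficiency,
properties of the driver alone) and an *interactive* component (the driver's
epistatic interactions with the other drivers present in the sample).  Four
models combine them:

====================  =========================================================
separate_mean         F = sum_i [SA_i*w_sa + SS_i*w_ss + mean_{j!=i} E_ij*w_epi]
separate_prod         as above with the product of E_ij instead of the mean
combined_mean         F = sum_i [SA_i*SS_i*w_int + mean_{j!=i} E_ij*w_epi]
combined_prod         F = sum_i [SA_i*SS_i*w_int + prod_{j!=i} E_ij*w_epi]
====================  =========================================================

where j runs over the *other drivers present in the same sample*; a driver
with no partner contributes a neutral epistasis aggregate of 1.  Weights are
drawn from a fixed grid of 37 empirical values spanning 0.01-100 and chosen
per cohort by exhaustive search minimising sd(F)/median(F) — the working
assumption being that tumour-initiating clones of one tumour type are all
similarly adapted, so the best weighting is the one that makes their scores
most homogeneous.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lmaland.core_data import AlterationMatrix
from lmaland.landscape import Landscape

#: The canonical 37-value weight grid (0.01 to 100, mirrored around 1).
WEIGHT_GRID: tuple[float, ...] = (
    0.010, 0.011, 0.012, 0.014, 0.017, 0.020, 0.025, 0.033, 0.05,
    0.10, 0.11, 0.12, 0.14, 0.17, 0.20, 0.25, 0.33, 0.5,
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
    20, 30, 40, 50, 60, 70, 80, 90, 100,
)

MODELS = ("separate_mean", "separate_prod", "combined_mean", "combined_prod")

_SEPARATE_KEYS = ("sa", "ss", "epi")
_COMBINED_KEYS = ("intrinsic", "interactive")


@dataclass(frozen=True)
class ModelConfig:
    """A model name plus its component weights."""

    model: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        keys = _COMBINED_KEYS if self.model.startswith("combined") else _SEPARATE_KEYS
        if set(self.weights) != set(keys):
            raise ValueError(f"{self.model} needs weights {keys}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")

    def to_json_dict(self) -> dict:
        return {"model": self.model, "weights": dict(self.weights)}

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelConfig":
        return cls(d["model"], dict(d["weights"]))


@dataclass(frozen=True)
class LmaScore:
    """Per-sample LMA score with its intrinsic/interactive decomposition."""

    sample_id: str
    f: float
    intrinsic_part: float
    interactive_part: float
    n_drivers: int

    @property
    def intrinsic_share(self) -> float:
        return self.intrinsic_part / self.f if self.f > 0 else float("nan")


def _components(driver_set: Sequence[str], landscape: Landscape):
    """Per-sample sums entering every model: (sum SA, sum SS, sum SA*SS,
    sum of per-driver mean-E aggregates, sum of per-driver prod-E aggregates)."""
    drivers = list(driver_set)
    unknown = [d for d in drivers if d not in landscape.sa]
    if unknown:
        raise KeyError(f"alterations not in landscape: {unknown}")
    if not drivers:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    sa = np.array([landscape.sa[d] for d in drivers])
    ss = np.array([landscape.ss[d] for d in drivers])
    if len(drivers) == 1:
        cmean = cprod = 1.0
    else:
        e = landscape.epistasis.loc[drivers, drivers].to_numpy(dtype=float)
        np.fill_diagonal(e, 1.0)
        cprod = float(np.prod(e, axis=1).sum())
        np.fill_diagonal(e, 0.0)
        cmean = float((e.sum(axis=1) / (len(drivers) - 1)).sum())
    return float(sa.sum()), float(ss.sum()), float((sa * ss).sum()), cmean, cprod


def _combine(comp, config: ModelConfig) -> tuple[float, float]:
    """(intrinsic_part, interactive_part) from precomputed components."""
    a, b, d, cmean, cprod = comp
    w = config.weights
    c = cmean if config.model.endswith("_mean") else cprod
    if config.model.startswith("separate"):
        return a * w["sa"] + b * w["ss"], c * w["epi"]
    return d * w["intrinsic"], c * w["interactive"]


def lma_score(
    driver_set: Iterable[str], landscape: Landscape, config: ModelConfig,
    sample_id: str = "",
) -> LmaScore:
    """LMA score of one sample's clonal driver set in a landscape.

    The set must be a subset of the landscape's retained drivers (foreign
    alterations are dropped upstream).  An empty set scores 0.
    """
    drivers = list(driver_set)
    comp = _components(drivers, landscape)
    intrinsic, interactive = _combine(comp, config)
    return LmaScore(
        sample_id=sample_id,
        f=intrinsic + interactive,
        intrinsic_part=intrinsic,
        interactive_part=interactive,
        n_drivers=len(drivers),
    )


def score_cohort(
    matrix: AlterationMatrix, landscape: Landscape, config: ModelConfig
) -> pd.DataFrame:
    """Score every sample of a retained-driver matrix; columns f,
    intrinsic_part, interactive_part, intrinsic_share, n_drivers."""
    rows = []
    for sample, alts in matrix.sample_sets().items():
        sc = lma_score(sorted(alts), landscape, config, sample_id=sample)
        rows.append(
            {
                "sample": sample,
                "f": sc.f,
                "intrinsic_part": sc.intrinsic_part,
                "interactive_part": sc.interactive_part,
                "intrinsic_share": sc.intrinsic_share,
                "n_drivers": sc.n_drivers,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def objective(scores: Sequence[float]) -> float:
    """Median-normalised dispersion sd(F)/median(F); +inf when median <= 0
    (such weight combinations are rejected)."""
    arr = np.asarray(scores, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least two scores")
    med = float(np.median(arr))
    if med <= 0:
        return math.inf
    # shift by the first score before the sd: a mathematical no-op that keeps
    # identical-score cohorts at exactly 0 despite floating-point round-off
    return float(np.std(arr - arr[0], ddof=1) / med)


@dataclass(frozen=True)
class OptimizationResult:
    config: ModelConfig
    objective: float
    n_combinations: int


def optimize_weights(
    matrix: AlterationMatrix,
    landscape: Landscape,
    model: str,
    grid: Sequence[float] = WEIGHT_GRID,
) -> OptimizationResult:
    """Exhaustive grid search for the weights minimising sd/median of LMA.

    Enumerates all len(grid)^2 (combined models) or len(grid)^3 (separate
    models) combinations in ascending lexicographic grid order; ties keep the
    first combination encountered.  Samples with zero retained drivers are
    excluded (the median-normalised objective is undefined for them).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    comps = []
    for sample, alts in matrix.sample_sets().items():
        if alts:
            comps.append(_components(sorted(alts), landscape))
    if len(comps) < 2:
        raise ValueError("need at least two samples with retained drivers")
    arr = np.array(comps)  # columns: A, B, D, Cmean, Cprod
    a, b, d = arr[:, 0], arr[:, 1], arr[:, 2]
    c = arr[:, 3] if model.endswith("_mean") else arr[:, 4]

    keys = _COMBINED_KEYS if model.startswith("combined") else _SEPARATE_KEYS
    best: tuple[float, ...] | None = None
    best_obj = math.inf
    n_comb = 0
    for combo in itertools.product(grid, repeat=len(keys)):
        n_comb += 1
        if model.startswith("combined"):
            f = d * combo[0] + c * combo[1]
        else:
            f = a * combo[0] + b * combo[1] + c * combo[2]
        med = np.median(f)
        obj = math.inf if med <= 0 else float(np.std(f - f[0], ddof=1) / med)
        if obj < best_obj:
            best_obj = obj
            best = combo
    if best is None or not math.isfinite(best_obj):
        raise ValueError("all weight combinations rejected")
    config = ModelConfig(model, dict(zip(keys, (float(v) for v in best))))
    return OptimizationResult(config, best_obj, n_comb)


def cohort_median_lma(
    matrix: AlterationMatrix, landscape: Landscape, config: ModelConfig
) -> float:
    """Median LMA of the cohort (used to normalise cross-landscape scores)."""
    return float(score_cohort(matrix, landscape, config)["f"].median())


def attach_cohort_median(
    landscape: Landscape, matrix: AlterationMatrix, config: ModelConfig
) -> Landscape:
    landscape.cohort_median_lma = cohort_median_lma(matrix, landscape, config)
    return landscape


def r_squared_vs_n_drivers(scores: pd.DataFrame) -> float:
    """R^2 of an ordinary least-squares fit of F on the number of drivers;
    NaN when either quantity is constant."""
    f = scores["f"].to_numpy(dtype=float)
    n = scores["n_drivers"].to_numpy(dtype=float)
    if np.ptp(f) == 0 or np.ptp(n) == 0:
        return float("nan")
    res = stats.linregress(n, f)
    return float(res.rvalue**2)


def model_comparison(matrix: AlterationMatrix, landscape: Landscape) -> pd.DataFrame:
    """Fit all four models and tabulate their diagnostics: optimal weights,
    objective value, R^2 of LMA vs driver count, and the mean intrinsic share."""
    rows = []
    for model in MODELS:
        res = optimize_weights(matrix, landscape, model)
        scores = score_cohort(matrix, landscape, res.config)
        nz = scores[scores["n_drivers"] > 0]
        rows.append(
            {
                "model": model,
                "weights": res.config.weights,
                "objective": res.objective,
                "r2_vs_n_drivers": r_squared_vs_n_drivers(nz),
                "mean_intrinsic_share": float(nz["intrinsic_share"].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("model")
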