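"""Scoring lesions across tumour-type landscapes: benign precursors, primaries, metastases.

A lesion's clonal alteration set can be scored in any landscape: alterations
that are not among that landscape's retained drivers are ignored, and the raw
LMA score is divided by the landscape's native cohort median so that values
are comparable across landscapes (a score of 1 means "as adapted as the
median native tumour").  Paired and unpaired Wilcoxon comparisons then ask,
e.g., whether benign precursors are less adapted than their matched
malignancies, or whether metastases are more adapted to their site of origin
than to the invaded site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lmaland.landscape import Landscape
from lmaland.lma import ModelConfig, lma_score

LESION_CLASSES = ("benign", "malignant", "primary", "metastasis")


@dataclass(frozen=True)
class LesionAnnotation:
    """Curated annotation of a lesion sample."""

    sample_id: str
    lesion_class: str
    native_type: str | None = None
    secondary_type: str | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {self.lesion_class!r}")


def read_annotations(path: str | Path) -> list[LesionAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        def opt(name):
            v = getattr(r, name, None)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else str(v)

        out.append(
            LesionAnnotation(
                sample_id=str(r.sample),
                lesion_class=str(r.lesion_class),
                native_type=opt("native_type"),
                secondary_type=opt("secondary_type"),
                pair_id=opt("pair_id"),
            )
        )
    return out


def write_annotations(annotations: Sequence[LesionAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": a.sample_id,
                "lesion_class": a.lesion_class,
                "native_type": a.native_type,
                "secondary_type": a.secondary_type,
                "pair_id": a.pair_id,
            }
            for a in annotations
        ]
    ).to_csv(path, sep="\t", index=False)


def score_in_landscape(
    alterations: Iterable[str],
    landscape: Landscape,
    config: ModelConfig,
    normalized: bool = True,
) -> float:
    """LMA of an alteration set in a (possibly foreign) landscape.

    Alterations outside the landscape's retained driver list are dropped; the
    raw score is divided by the landscape's native cohort median LMA unless
    `normalized=False`.
    """
    kept = sorted(set(alterations) & set(landscape.drivers))
    raw = lma_score(kept, landscape, config).f
    if not normalized:
        return raw
    if landscape.cohort_median_lma is None or landscape.cohort_median_lma <= 0:
        raise ValueError(
            f"landscape {landscape.tumour_type} has no positive cohort median LMA"
        )
    return raw / landscape.cohort_median_lma


def cross_score_table(
    sample_sets: Mapping[str, Iterable[str]],
    landscapes: Mapping[str, Landscape],
    configs: Mapping[str, ModelConfig],
) -> pd.DataFrame:
    """Raw and normalised LMA of every sample in every landscape."""
    rows = []
    for sample, alts in sample_sets.items():
        alts = set(alts)
        for ttype, land in landscapes.items():
            raw = score_in_landscape(alts, land, configs[ttype], normalized=False)
            norm = score_in_landscape(alts, land, configs[ttype], normalized=True)
            rows.append(
                {
                    "sample": sample,
                    "landscape": ttype,
                    "raw_f": raw,
                    "normalized_f": norm,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedComparison:
    statistic: float
    pvalue: float
    n_pairs: int
    median_difference: float

    @property
    def direction(self) -> str:
        if self.median_difference > 0:
            return "b_greater"
        if self.median_difference < 0:
            return "a_greater"
        return "none"


def compare_paired(
    scores_a: Mapping[str, float], scores_b: Mapping[str, float]
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on per-pair score differences.

    `scores_a` and `scores_b` map pair ids to scores; only complete pairs are
    used.  All-zero differences give p = 1 (no signal).
    """
    pairs = sorted(set(scores_a) & set(scores_b))
    if not pairs:
        raise ValueError("no complete pairs")
    a = np.array([scores_a[p] for p in pairs], dtype=float)
    b = np.array([scores_b[p] for p in pairs], dtype=float)
    diff = b - a
    if np.all(diff == 0):
        return PairedComparison(0.0, 1.0, len(pairs), 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return PairedComparison(
        float(res.statistic), float(res.pvalue), len(pairs), float(np.median(diff))
    )


def compare_unpaired(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test for unpaired lesion groups."""
    res = stats.mannwhitneyu(scores_a, scores_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def native_vs_other_landscapes(
    sample_sets: Mapping[str, Iterable[str]],
    native_type: str,
    landscapes: Mapping[str, Landscape],
    configs: Mapping[str, ModelConfig],
) -> tuple[pd.DataFrame, PairedComparison]:
    """Normalised LMA in the native landscape vs the mean over all others.

    Returns the per-sample table (native, other_mean) and a paired Wilcoxon
    comparison across samples.
    """
    if native_type not in landscapes:
        raise ValueError(f"native landscape {native_type!r} missing")
    others = [t for t in landscapes if t != native_type]
    if not others:
        raise ValueError("need at least two landscapes")
    rows = []
    for sample, alts in sample_sets.items():
        alts = set(alts)
        native = score_in_landscape(alts, landscapes[native_type], configs[native_type])
        other = float(
            np.mean(
                [score_in_landscape(alts, landscapes[t], configs[t]) for t in others]
            )
        )
        rows.append({"sample": sample, "native": native, "other_mean": other})
    table = pd.DataFrame(rows).set_index("sample")
    comp = compare_paired(
        table["other_mean"].to_dict(), table["native"].to_dict()
    )  # positive difference = native higher
    return table, comp
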