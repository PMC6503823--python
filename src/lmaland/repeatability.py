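"""Repeatability of somatic evolution: pairwise Jaccard indices vs load-preserving nulls.

Each sample's clonal alteration set is treated as the genotype of an
independently evolved clone; high pairwise Jaccard similarity across a cohort
indicates parallel evolution.  The null model reassigns each sample's
alterations uniformly at random over a gene universe while preserving the
per-sample mutational load exactly, so any excess similarity is attributable
to recurrent selection rather than to mutation burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from lmaland.core_data import AlterationMatrix


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index |A∩B| / |A∪B|; two empty sets give 0 by convention."""
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def pairwise_jaccard(matrix: AlterationMatrix) -> np.ndarray:
    """All C(n,2) pairwise Jaccard indices, in condensed (row-major) order."""
    x = matrix.values.to_numpy(dtype=np.int64)
    inter = x @ x.T
    loads = x.sum(axis=1)
    union = loads[:, None] + loads[None, :] - inter
    iu = np.triu_indices(len(loads), k=1)
    inter_u = inter[iu].astype(float)
    union_u = union[iu].astype(float)
    out = np.zeros_like(inter_u)
    nz = union_u > 0
    out[nz] = inter_u[nz] / union_u[nz]
    return out


def randomize_matrix(
    matrix: AlterationMatrix, universe_size: int, seed: int
) -> AlterationMatrix:
    """Load-preserving randomization.

    Every sample keeps its alteration count m_s but receives m_s distinct
    alterations drawn uniformly without replacement from a universe of
    `universe_size` anonymous labels.  Column identities of the input are
    discarded.
    """
    loads = matrix.sample_loads
    max_load = int(loads.max()) if len(loads) else 0
    if universe_size < max_load:
        raise ValueError(
            f"universe_size {universe_size} < maximum sample load {max_load}"
        )
    rng = np.random.default_rng(seed)
    width = len(str(universe_size - 1)) if universe_size > 0 else 1
    labels = [f"g{idx:0{width}d}" for idx in range(universe_size)]
    sets = {}
    for sample, m in loads.items():
        picks = rng.choice(universe_size, size=int(m), replace=False)
        sets[sample] = {labels[int(i)] for i in picks}
    used = sorted({a for s in sets.values() for a in s})
    return AlterationMatrix.from_sets(sets, alteration_ids=used)


@dataclass
class RepeatabilityReport:
    """Observed vs null pairwise similarity for one cohort.

    `normalized_indices` are the observed indices divided by the 95th
    percentile of the pooled null distribution; `pct_above_p95` is the
    percentage of observed indices strictly exceeding that percentile.
    """

    observed_indices: np.ndarray
    null_indices: np.ndarray
    p95_null: float
    normalized_indices: np.ndarray = field(init=False)
    pct_above_p95: float = field(init=False)

    def __post_init__(self) -> None:
        if self.p95_null > 0:
            self.normalized_indices = self.observed_indices / self.p95_null
        else:
            self.normalized_indices = np.where(
                self.observed_indices > 0, np.inf, 0.0
            )
        above = self.observed_indices > self.p95_null
        self.pct_above_p95 = float(100.0 * above.mean()) if len(above) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": self.observed_indices,
                "normalized": self.normalized_indices,
            }
        )


def repeatability_report(
    matrix: AlterationMatrix,
    universe_size: int,
    n_randomizations: int = 10,
    seed: int = 0,
) -> RepeatabilityReport:
    """Observed pairwise Jaccard indices against a pooled randomized null.

    `n_randomizations` load-preserving random matrices are generated (RNG
    streams seeded `seed + r`), their pairwise indices pooled, and the 95th
    percentile of the pooled null (linear-interpolation quantile) used to
    normalize the observed indices.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    observed = pairwise_jaccard(matrix)
    null_parts = []
    for r in range(n_randomizations):
        rand = randomize_matrix(matrix, universe_size, seed=seed + r)
        null_parts.append(pairwise_jaccard(rand))
    null = np.concatenate(null_parts)
    p95 = float(np.quantile(null, 0.95))  # type-7 linear interpolation
    return RepeatabilityReport(observed, null, p95)
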