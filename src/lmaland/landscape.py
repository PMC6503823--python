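"""Per-tumour-type evolutionary parameters: selective advantage, self-sufficiency, epistasis.

Three occurrence-based quantities summarise the role of each retained driver
alteration in a cohort:

* **selective advantage** SA_d — observed occurrences of the alteration over
  its expected occurrences.  For mutations the expectation distributes the
  cohort's clonal mutation total over mutated genes proportionally to gene
  length (median transcript length in bp); for copy-number gains and losses
  (scored separately) every gene is equally likely.  SA is centred around 1
  with a lower bound of 0.

* **self-sufficiency** SS_d — drivers that occur alongside few other drivers
  are deemed more able to push a clone towards malignancy on their own.
  mu_d is the mean number of *additional* retained drivers in samples
  harbouring d; SS_d = mu_overall / max(mu_d, floor), where mu_overall pools
  the additional-driver count over every (sample, driver) incidence.

* **malignant epistatic interactions** E_ij — ratio of observed to expected
  co-occurrence of drivers i and j.  The expectation is hypergeometric: given
  that sample s carries m_s of the cohort's T driver events and driver i
  accounts for k_i of them, presence probabilities follow from drawing m_s
  events without replacement.  E_ij > 1 marks cooperation, E_ij < 1
  antagonism; a pseudo-count keeps E finite and positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from lmaland.core_data import AlterationMatrix, DriverCatalog, alteration_id


# ---------------------------------------------------------------------------
# selective advantage
# ---------------------------------------------------------------------------

def selective_advantage_mut(
    clonal_mut_counts: Mapping[str, int], gene_lengths: Mapping[str, int]
) -> dict[str, float]:
    """SA for mutated genes: observed / length-weighted expected counts.

    expected_g = M_total * length_g / sum of lengths over mutated genes.
    """
    mutated = {g: c for g, c in clonal_mut_counts.items() if c > 0}
    if not mutated:
        raise ValueError("no mutated genes")
    missing = sorted(g for g in mutated if g not in gene_lengths)
    if missing:
        raise ValueError(f"mutated genes with unknown length: {missing}")
    m_total = float(sum(mutated.values()))
    length_sum = float(sum(gene_lengths[g] for g in mutated))
    return {
        g: c / (m_total * gene_lengths[g] / length_sum) for g, c in mutated.items()
    }


def selective_advantage_cna(
    event_counts: Mapping[str, int],
    n_genes: int | None = None,
) -> dict[str, float]:
    """SA for copy-number events of one class (gains or losses), all genes
    equally likely: expected = E_total / n_genes for every gene.

    `n_genes` defaults to the number of genes with at least one observed
    event of the class, mirroring the mutation definition.
    """
    total = float(sum(event_counts.values()))
    if total <= 0:
        raise ValueError("no copy-number events observed")
    if n_genes is None:
        n_genes = sum(1 for c in event_counts.values() if c > 0)
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    expected = total / n_genes
    return {g: c / expected for g, c in event_counts.items()}


# ---------------------------------------------------------------------------
# self-sufficiency
# ---------------------------------------------------------------------------

def self_sufficiency(
    matrix: AlterationMatrix,
    floor: float = 0.5,
    alpha: float = 0.05,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Self-sufficiency of each driver in a retained-driver matrix.

    Returns (ss mapping, per-driver table with mu_d, SS, Mann-Whitney p/q
    values and a direction flag).  The flag compares each driver's
    additional-driver counts to those pooled over all other incidences
    ('fewer'/'more' partners than typical, Benjamini-Hochberg at `alpha`);
    it is descriptive and not used in any score.
    """
    x = matrix.values.to_numpy(dtype=np.int64)
    loads = x.sum(axis=1)
    k = x.sum(axis=0)
    absent = [a for a, ki in zip(matrix.alteration_ids, k) if ki == 0]
    if absent:
        raise ValueError(f"drivers absent from cohort: {absent}")
    t_total = loads.sum()
    if t_total == 0:
        raise ValueError("empty matrix")
    mu_overall = float((loads * (loads - 1)).sum() / t_total)

    ss: dict[str, float] = {}
    rows = []
    partner_lists = {}
    for j, aid in enumerate(matrix.alteration_ids):
        partners = loads[x[:, j] == 1] - 1
        partner_lists[aid] = partners
        mu_d = float(partners.mean())
        ss[aid] = mu_overall / max(mu_d, floor)
        rows.append({"driver": aid, "mu": mu_d, "ss": ss[aid], "capped": mu_d < floor})

    # significance of each driver's partner-count distribution vs the rest
    all_partners = np.concatenate([partner_lists[a] for a in matrix.alteration_ids])
    pvals = []
    for row in rows:
        mine = partner_lists[row["driver"]]
        others = np.concatenate(
            [partner_lists[a] for a in matrix.alteration_ids if a != row["driver"]]
        )
        if len(others) == 0 or np.ptp(all_partners) == 0:
            pvals.append(1.0)
            continue
        try:
            p = stats.mannwhitneyu(mine, others, alternative="two-sided").pvalue
        except ValueError:  # identical constant inputs
            p = 1.0
        pvals.append(float(p))
    qvals = stats.false_discovery_control(pvals) if pvals else []
    table = pd.DataFrame(rows)
    table["pval"] = pvals
    table["qval"] = qvals
    overall_mean = float(all_partners.mean())
    table["flag"] = [
        ("fewer" if row["mu"] < overall_mean else "more") if q < alpha else "ns"
        for row, q in zip(rows, qvals)
    ]
    return ss, table.set_index("driver")


# ---------------------------------------------------------------------------
# hypergeometric co-occurrence expectations
# ---------------------------------------------------------------------------

def _log_comb(n, r):
    """log C(n, r) with -inf where r > n; vectorised."""
    n = np.asarray(n, dtype=float)
    r = np.asarray(r, dtype=float)
    out = np.where(
        r > n,
        -np.inf,
        gammaln(n + 1) - gammaln(r + 1) - gammaln(np.maximum(n - r, 0) + 1),
    )
    return out


def expected_presence_prob(k_i: int, m_s: int, t_total: int) -> float:
    """P(sample with load m_s carries alteration i at least once), drawing m_s
    of the cohort's T events without replacement, k_i of which are copies of i.

    P = 1 - C(T-k_i, m_s) / C(T, m_s); equals 1 when m_s > T - k_i.
    """
    if min(k_i, m_s, t_total) < 0 or k_i > t_total or m_s > t_total:
        raise ValueError("need 0 <= k_i, m_s <= T")
    if k_i == 0:
        return 0.0
    if m_s > t_total - k_i:
        return 1.0
    log_q = _log_comb(t_total - k_i, m_s) - _log_comb(t_total, m_s)
    return float(1.0 - np.exp(log_q))


def expected_copresence_prob(
    k_i: int, k_j: int, m_s: int, t_total: int, method: str = "joint"
) -> float:
    """P(both i and j present in a sample with load m_s).

    'joint' (default) is the exact inclusion-exclusion probability under the
    without-replacement draw and is unbiased for the load-preserving label
    permutation null; 'product' multiplies the two marginal presence
    probabilities (an independence approximation).
    """
    if method == "product":
        return expected_presence_prob(k_i, m_s, t_total) * expected_presence_prob(
            k_j, m_s, t_total
        )
    if method != "joint":
        raise ValueError("method must be 'joint' or 'product'")
    log_ct = _log_comb(t_total, m_s)
    q_i = float(np.exp(_log_comb(t_total - k_i, m_s) - log_ct))
    q_j = float(np.exp(_log_comb(t_total - k_j, m_s) - log_ct))
    q_ij = float(np.exp(_log_comb(t_total - k_i - k_j, m_s) - log_ct))
    return max(0.0, 1.0 - q_i - q_j + q_ij)


def expected_cooccurrence(
    matrix: AlterationMatrix, method: str = "joint"
) -> pd.DataFrame:
    """Expected pairwise co-occurrence counts exp_ij = sum over samples of the
    per-sample co-presence probability."""
    ids = matrix.alteration_ids
    x = matrix.values.to_numpy(dtype=np.int64)
    k = x.sum(axis=0)
    m = x.sum(axis=1)
    t_total = int(m.sum())
    nd = len(ids)
    log_ct = _log_comb(t_total, m)  # per sample
    # marginal absence prob per (sample, driver)
    q1 = np.exp(_log_comb(t_total - k[None, :], m[:, None]) - log_ct[:, None])
    p1 = 1.0 - q1
    if method == "product":
        exp = p1.T @ p1
    elif method == "joint":
        ksum = k[None, :] + k[:, None]  # (nd, nd)
        exp = np.zeros((nd, nd))
        for s in range(x.shape[0]):
            q2 = np.exp(_log_comb(t_total - ksum, m[s]) - log_ct[s])
            pboth = np.maximum(0.0, 1.0 - q1[s][None, :] - q1[s][:, None] + q2)
            exp += pboth
    else:
        raise ValueError("method must be 'joint' or 'product'")
    return pd.DataFrame(exp, index=ids, columns=ids)


def epistasis_matrix(
    matrix: AlterationMatrix,
    pseudo: float = 0.5,
    method: str = "joint",
) -> pd.DataFrame:
    """Symmetric malignant epistatic interaction matrix.

    E_ij = (obs_ij + pseudo) / (exp_ij + pseudo) with obs_ij the number of
    samples carrying both drivers and exp_ij the hypergeometric expectation.
    The diagonal is NaN (self-interaction undefined).  Drivers never observed
    in the cohort are excluded with a warning.
    """
    if len(matrix.alteration_ids) < 2:
        raise ValueError("need at least two drivers")
    k = matrix.alteration_counts
    dead = list(k.index[k == 0])
    if dead:
        warnings.warn(f"excluding drivers never observed: {dead}")
        matrix = matrix.restrict([a for a in matrix.alteration_ids if a not in dead])
    x = matrix.values.to_numpy(dtype=np.int64)
    obs = (x.T @ x).astype(float)
    exp = expected_cooccurrence(matrix, method=method).to_numpy()
    e = (obs + pseudo) / (exp + pseudo)
    np.fill_diagonal(e, np.nan)
    ids = matrix.alteration_ids
    return pd.DataFrame(e, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# the landscape container
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """Tumour-type-specific evolutionary landscape: retained drivers with
    their SA, SS and pairwise epistatic interactions."""

    tumour_type: str
    drivers: list[str]
    sa: dict[str, float]
    ss: dict[str, float]
    epistasis: pd.DataFrame
    frequencies: dict[str, float] = field(default_factory=dict)
    cohort_median_lma: float | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in self.drivers:
            if d not in self.sa or d not in self.ss:
                raise ValueError(f"driver {d} missing SA or SS")
            if self.sa[d] < 0 or self.ss[d] < 0:
                raise ValueError(f"driver {d}: SA and SS must be non-negative")
        e = self.epistasis.to_numpy()
        off = ~np.eye(len(e), dtype=bool)
        if len(e) and not np.allclose(e[off], e.T[off], equal_nan=True):
            raise ValueError("epistasis matrix must be symmetric")

    def e(self, i: str, j: str) -> float:
        return float(self.epistasis.loc[i, j])

    def top_drivers(self, k: int) -> list[str]:
        """The k most frequent drivers (ties broken lexicographically)."""
        ranked = sorted(self.drivers, key=lambda d: (-self.frequencies.get(d, 0.0), d))
        return ranked[:k]

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "tumour_type": self.tumour_type,
            "drivers": self.drivers,
            "sa": self.sa,
            "ss": self.ss,
            "epistasis": {
                i: {j: None if pd.isna(v) else float(v) for j, v in row.items()}
                for i, row in self.epistasis.to_dict(orient="index").items()
            },
            "frequencies": self.frequencies,
            "cohort_median_lma": self.cohort_median_lma,
            "settings": self.settings,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Landscape":
        payload = json.loads(Path(path).read_text())
        drivers = payload["drivers"]
        e = pd.DataFrame(payload["epistasis"]).reindex(index=drivers, columns=drivers)
        return cls(
            tumour_type=payload["tumour_type"],
            drivers=drivers,
            sa=payload["sa"],
            ss=payload["ss"],
            epistasis=e.astype(float),
            frequencies=payload.get("frequencies", {}),
            cohort_median_lma=payload.get("cohort_median_lma"),
            settings=payload.get("settings", {}),
        )


def build_landscape(
    matrix: AlterationMatrix,
    retained: DriverCatalog,
    gene_lengths: Mapping[str, int] | None = None,
    tumour_type: str | None = None,
    n_cna_genes: int | None = None,
    pseudo: float = 0.5,
    ss_floor: float = 0.5,
    method: str = "joint",
) -> Landscape:
    """Compute a full landscape from a cohort matrix.

    `matrix` should be the full cohort matrix (all clonal alterations,
    drivers and passengers alike): mutation SA uses every mutated gene to set
    the length-weighted expectation, while SS and epistasis are computed on
    the matrix restricted to the retained drivers.  `gene_lengths` is
    required when the retained catalogue contains mutation drivers.
    """
    retained_ids = retained.alteration_ids
    missing = [a for a in retained_ids if a not in matrix.alteration_ids]
    if missing:
        raise KeyError(f"retained drivers absent from matrix: {missing}")

    counts = matrix.alteration_counts
    by_class: dict[str, dict[str, int]] = {"mut": {}, "gain": {}, "loss": {}}
    for aid, c in counts.items():
        if "_" not in aid:
            continue
        gene, cls = aid.rsplit("_", 1)
        if cls in by_class and c > 0:
            by_class[cls][gene] = int(c)

    sa: dict[str, float] = {}
    sa_mut = (
        selective_advantage_mut(by_class["mut"], gene_lengths)
        if by_class["mut"] and gene_lengths is not None
        else {}
    )
    sa_cna = {
        cls: selective_advantage_cna(by_class[cls], n_genes=n_cna_genes)
        for cls in ("gain", "loss")
        if by_class[cls]
    }
    for gene, cls in retained.entries:
        aid = alteration_id(gene, cls)
        if cls == "mut":
            if gene not in sa_mut:
                raise ValueError(
                    f"cannot compute mutation SA for {gene}: counts or lengths missing"
                )
            sa[aid] = sa_mut[gene]
        else:
            sa[aid] = sa_cna[cls][gene]

    restricted = matrix.restrict(retained_ids)
    ss, _ = self_sufficiency(restricted, floor=ss_floor)
    e = epistasis_matrix(restricted, pseudo=pseudo, method=method)
    freqs = {a: float(f) for a, f in restricted.frequencies.items()}
    return Landscape(
        tumour_type=tumour_type or retained.tumour_type,
        drivers=retained_ids,
        sa=sa,
        ss=ss,
        epistasis=e,
        frequencies=freqs,
        settings={
            "pseudo": pseudo,
            "ss_floor": ss_floor,
            "epistasis_method": method,
            "n_samples": matrix.n_samples,
        },
    )
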