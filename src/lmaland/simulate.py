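"""Synthetic cohorts with the statistical structure the LMA framework assumes.

The generator emulates the *inputs* of the pipeline — per-mutation tables
with CCF confidence intervals, copy-number segment tables, gene annotation
and binary clonal alteration matrices — without attempting realistic
mutational signatures or chromosome geometry:

* driver presence/absence vectors are drawn from a pairwise (Ising-style)
  model whose fields are set from the requested marginal frequencies and
  whose couplings are user-specified log-odds, via Gibbs sampling;
* passenger mutations hit genes with probability proportional to gene length
  at a configurable per-Mb rate, a fraction of them clonal;
* clonal mutations receive CCF estimates near 1 whose 95% CI includes 1,
  subclonal decoys receive lower CCFs whose CI excludes 1;
* copy-number driver events are emitted as segments deviating from diploid
  ploidy by more than the calling threshold, next to a large neutral
  baseline segment, so the standard calling rules recover them exactly.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lmaland.core_data import (
    AlterationMatrix,
    CnSegment,
    DriverCatalog,
    GeneAnnotation,
    MutationRecord,
    alteration_id,
    matrix_from_calls,
)
from lmaland.cross_landscape import LesionAnnotation


@dataclass(frozen=True)
class DriverSpec:
    """One simulated driver: gene name, alteration class, marginal frequency."""

    gene: str
    cls: str
    freq: float

    def __post_init__(self) -> None:
        if not 0.0 < self.freq < 1.0:
            raise ValueError(f"{self.gene}: marginal frequency must be in (0,1)")
        if self.cls not in ("mut", "gain", "loss"):
            raise ValueError(f"{self.gene}: unknown class {self.cls!r}")

    @property
    def alteration_id(self) -> str:
        return alteration_id(self.gene, self.cls)


def default_gene_universe(n_genes: int = 100) -> list[tuple[str, int]]:
    """A deterministic passenger gene universe with lengths spanning roughly
    0.5-20 kb (log-spaced, the ballpark of median transcript lengths)."""
    lengths = np.logspace(np.log10(500), np.log10(20000), n_genes).astype(int)
    return [(f"PSG{i:04d}", int(l)) for i, l in enumerate(lengths)]


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_samples: int
    drivers: list[DriverSpec]
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    passenger_rate: float = 2.0  # clonal+subclonal mutations per Mb of gene territory
    gene_universe: list[tuple[str, int]] = field(default_factory=default_gene_universe)
    ccf_noise: float = 0.02  # sd of clonal CCF around 1
    seed: int = 0
    tumour_type: str = "SIM"
    passenger_clonal_fraction: float = 0.5
    driver_gene_length: int = 5000
    gibbs_burn_in: int = 100
    gibbs_thin: int = 10

    def driver_ids(self) -> list[str]:
        return [d.alteration_id for d in self.drivers]

    def gene_lengths(self) -> dict[str, int]:
        out = {g: l for g, l in self.gene_universe}
        for d in self.drivers:
            out.setdefault(d.gene, self.driver_gene_length)
        return out

    def catalog(self) -> DriverCatalog:
        return DriverCatalog(
            [(d.gene, d.cls) for d in self.drivers], tumour_type=self.tumour_type
        )

    def gene_annotation(self) -> list[GeneAnnotation]:
        """Deterministic layout: driver genes then passenger genes, laid end
        to end on chromosome 1 with 10 kb gaps."""
        out = []
        pos = 1
        for gene, length in [
            (d.gene, self.gene_lengths()[d.gene]) for d in self.drivers
        ] + list(self.gene_universe):
            if any(g.gene == gene for g in out):
                continue
            out.append(
                GeneAnnotation(
                    gene=gene, chrom="1", start=pos, end=pos + length - 1,
                    length_bp=length,
                )
            )
            pos += length + 10_000
        return out


def _coupling_matrix(config: SimConfig) -> np.ndarray:
    ids = config.driver_ids()
    idx = {a: i for i, a in enumerate(ids)}
    j = np.zeros((len(ids), len(ids)))
    for (a, b), v in config.interactions.items():
        if a not in idx or b not in idx:
            raise KeyError(f"interaction references unknown driver ({a}, {b})")
        j[idx[a], idx[b]] = v
        j[idx[b], idx[a]] = v
    return j


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gibbs_driver_states(
    config: SimConfig, rng: np.random.Generator, n_samples: int
) -> np.ndarray:
    """(n_samples, n_drivers) boolean states from the pairwise model.

    One chain: fields h_i = logit(freq_i), couplings J from the config;
    burn-in then thinned draws.  With nonzero couplings the achieved
    marginals shift away from the planted ones; a warning reports the
    achieved values when the shift is large.
    """
    freqs = np.array([d.freq for d in config.drivers])
    h = np.log(freqs / (1 - freqs))
    j = _coupling_matrix(config)
    k = len(freqs)
    x = (rng.random(k) < freqs).astype(float)

    def sweep() -> None:
        for i in range(k):
            p = _sigmoid(h[i] + j[i] @ x - j[i, i] * x[i])
            x[i] = 1.0 if rng.random() < p else 0.0

    for _ in range(config.gibbs_burn_in):
        sweep()
    states = np.empty((n_samples, k), dtype=bool)
    for s in range(n_samples):
        for _ in range(config.gibbs_thin):
            sweep()
        states[s] = x.astype(bool)

    if np.any(j):
        achieved = states.mean(axis=0)
        drift = np.abs(achieved - freqs)
        if drift.max() > 0.15:
            worst = int(np.argmax(drift))
            warnings.warn(
                "interactions shifted marginals; achieved frequencies: "
                + ", ".join(
                    f"{d.alteration_id}={a:.2f}" for d, a in zip(config.drivers, achieved)
                )
                + f" (largest drift at {config.drivers[worst].alteration_id})"
            )
    return states


def _clonal_ccf(rng: np.random.Generator, sd: float) -> tuple[float, float, float]:
    eps = min(abs(rng.normal(0.0, sd)), 1.95 * sd) if sd > 0 else 0.0
    ccf = max(0.0, 1.0 - eps)
    lo = max(0.0, ccf - 1.96 * sd)
    hi = min(1.0, ccf + 1.96 * sd)
    return ccf, lo, hi


def _subclonal_ccf(rng: np.random.Generator) -> tuple[float, float, float]:
    sd = 0.05
    ccf = rng.uniform(0.2, 0.7)
    return ccf, max(0.0, ccf - 1.96 * sd), ccf + 1.96 * sd


@dataclass
class CohortSim:
    """A simulated cohort: raw tables, the clonal alteration matrix, and the
    ground truth used to generate it."""

    config: SimConfig
    mutations: list[MutationRecord]
    segments: list[CnSegment]
    genes: list[GeneAnnotation]
    matrix: AlterationMatrix
    driver_states: pd.DataFrame  # samples x driver alteration ids, 0/1
    truth: dict

    def write_tables(self, outdir: str | Path) -> None:
        """Emit the TSV dialects the readers in `core_data` accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "sample": m.sample_id, "gene": m.gene, "ccf": m.ccf,
                    "ccf_low": m.ccf_ci_low, "ccf_high": m.ccf_ci_high, "maf": m.maf,
                }
                for m in self.mutations
            ]
        ).to_csv(outdir / "mutations.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "sample": s.sample_id, "chrom": s.chrom, "start": s.start,
                    "end": s.end, "cn": s.copy_number, "n_probes": s.n_probes,
                    "n_exons": s.n_exons,
                }
                for s in self.segments
            ]
        ).to_csv(outdir / "segments.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene": g.gene, "chrom": g.chrom, "start": g.start,
                    "end": g.end, "length_bp": g.length_bp,
                }
                for g in self.genes
            ]
        ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
        self.matrix.to_tsv(outdir / "matrix.tsv")
        pd.DataFrame(
            [{"gene": g, "class": c} for g, c in self.config.catalog().entries]
        ).to_csv(outdir / "catalog.tsv", sep="\t", index=False)


def simulate_cohort(config: SimConfig) -> CohortSim:
    """Draw a full cohort under the config's generative model."""
    rng = np.random.default_rng(config.seed)
    states = _gibbs_driver_states(config, rng, config.n_samples)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    ids = config.driver_ids()
    genes = config.gene_annotation()
    gene_by_name = {g.gene: g for g in genes}

    universe_genes = [g for g, _ in config.gene_universe]
    lengths = np.array([l for _, l in config.gene_universe], dtype=float)
    probs = lengths / lengths.sum()
    lam = config.passenger_rate * lengths.sum() / 1e6

    mutations: list[MutationRecord] = []
    segments: list[CnSegment] = []
    clonal_calls: list[tuple[str, str]] = []
    cna_calls: list[tuple[str, str, str]] = []
    cna_driver_genes = [(d.gene, d.cls) for d in config.drivers if d.cls != "mut"]

    baseline_start = max(g.end for g in genes) + 50_000

    for s_idx, sample in enumerate(sample_ids):
        present = {ids[j] for j in range(len(ids)) if states[s_idx, j]}
        # driver mutations
        for d in config.drivers:
            if d.cls == "mut" and d.alteration_id in present:
                ccf, lo, hi = _clonal_ccf(rng, config.ccf_noise)
                mutations.append(
                    MutationRecord(sample, d.gene, ccf=ccf, ccf_ci_low=lo, ccf_ci_high=hi)
                )
                clonal_calls.append((sample, d.gene))
        # passengers, length-proportional
        n_pass = rng.poisson(lam)
        hit = rng.choice(len(universe_genes), size=n_pass, p=probs)
        clonal_flags = rng.random(n_pass) < config.passenger_clonal_fraction
        seen: set[tuple[str, bool]] = set()
        for g_idx, is_clonal in zip(hit, clonal_flags):
            gene = universe_genes[int(g_idx)]
            if (gene, bool(is_clonal)) in seen:  # multiple hits collapse to one record
                continue
            seen.add((gene, bool(is_clonal)))
            if is_clonal:
                ccf, lo, hi = _clonal_ccf(rng, config.ccf_noise)
                clonal_calls.append((sample, gene))
            else:
                ccf, lo, hi = _subclonal_ccf(rng)
            mutations.append(
                MutationRecord(sample, gene, ccf=ccf, ccf_ci_low=lo, ccf_ci_high=hi)
            )
        # copy-number segments: one per CNA driver gene plus a neutral baseline
        for gene, cls in cna_driver_genes:
            ann = gene_by_name[gene]
            aid = alteration_id(gene, cls)
            if aid in present:
                cn = 2.0 + 1.2 if cls == "gain" else 2.0 - 1.2
                cna_calls.append((sample, gene, cls))
            else:
                cn = 2.0
            segments.append(
                CnSegment(
                    sample_id=sample, chrom=ann.chrom,
                    start=max(1, ann.start - 100), end=ann.end + 100,
                    copy_number=cn, n_probes=50, n_exons=10,
                )
            )
        segments.append(
            CnSegment(
                sample_id=sample, chrom="1",
                start=baseline_start, end=baseline_start + 10_000_000,
                copy_number=2.0, n_probes=500, n_exons=1000,
            )
        )

    matrix = matrix_from_calls(clonal_calls, cna_calls, sample_ids=sample_ids)
    truth = {
        "planted_frequencies": {d.alteration_id: d.freq for d in config.drivers},
        "achieved_frequencies": {
            aid: float(states[:, j].mean()) for j, aid in enumerate(ids)
        },
        "interactions": {f"{a}|{b}": v for (a, b), v in config.interactions.items()},
        "seed": config.seed,
    }
    driver_states = pd.DataFrame(
        states.astype(np.int8), index=sample_ids, columns=ids
    )
    return CohortSim(
        config=config, mutations=mutations, segments=segments, genes=genes,
        matrix=matrix, driver_states=driver_states, truth=truth,
    )


def simulate_progression_pairs(
    config: SimConfig, n_pairs: int, drivers_removed: int = 1
) -> tuple[dict[str, frozenset[str]], list[LesionAnnotation]]:
    """Paired benign/malignant lesion driver sets.

    The malignant lesion of each pair is drawn from the cohort model; its
    benign partner is the same set minus `drivers_removed` uniformly chosen
    drivers (0 is allowed as a control and makes the pair identical).
    Malignant draws with fewer drivers than `drivers_removed` are resampled.
    """
    if drivers_removed < 0:
        raise ValueError("drivers_removed must be >= 0")
    rng = np.random.default_rng(config.seed)
    states = _gibbs_driver_states(config, rng, n_pairs)
    ids = config.driver_ids()
    sets: dict[str, frozenset[str]] = {}
    annotations: list[LesionAnnotation] = []
    extra_budget = 200 * max(n_pairs, 1)
    for p in range(n_pairs):
        mal = [ids[j] for j in range(len(ids)) if states[p, j]]
        while len(mal) < max(drivers_removed, 1):
            if extra_budget == 0:
                raise RuntimeError(
                    "could not draw malignant sets large enough to remove drivers from"
                )
            extra_budget -= 1
            redraw = _gibbs_driver_states(
                replace(config, gibbs_burn_in=20, seed=int(rng.integers(2**31))), rng, 1
            )
            mal = [ids[j] for j in range(len(ids)) if redraw[0, j]]
        removed = rng.choice(len(mal), size=drivers_removed, replace=False)
        ben = [a for i, a in enumerate(mal) if i not in set(int(r) for r in removed)]
        pair_id = f"P{p:03d}"
        for cls, alts in (("malignant", mal), ("benign", ben)):
            sid = f"{pair_id}_{cls}"
            sets[sid] = frozenset(alts)
            annotations.append(
                LesionAnnotation(
                    sample_id=sid, lesion_class=cls,
                    native_type=config.tumour_type, pair_id=pair_id,
                )
            )
    return sets, annotations


def simulate_metastatic_panel(
    primary_config: SimConfig, foreign_config: SimConfig, n: int
) -> tuple[dict[str, frozenset[str]], list[LesionAnnotation]]:
    """Metastatic samples drawn from the primary site's generative model but
    annotated with a foreign metastatic site."""
    if primary_config.drivers == foreign_config.drivers and (
        primary_config.interactions == foreign_config.interactions
    ):
        warnings.warn("primary and foreign configs are identical; contrast undefined")
    rng = np.random.default_rng(primary_config.seed)
    states = _gibbs_driver_states(primary_config, rng, n)
    ids = primary_config.driver_ids()
    sets = {}
    annotations = []
    for i in range(n):
        sid = f"M{i:04d}"
        sets[sid] = frozenset(ids[j] for j in range(len(ids)) if states[i, j])
        annotations.append(
            LesionAnnotation(
                sample_id=sid, lesion_class="metastasis",
                native_type=primary_config.tumour_type,
                secondary_type=foreign_config.tumour_type,
            )
        )
    return sets, annotations
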