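"""Domain types and preprocessing: from mutation/copy-number calls to binary clonal driver matrices.

The central container is :class:`AlterationMatrix`, a binary samples x
alterations incidence matrix of *clonal* alterations.  Alteration identifiers
are ``<gene>_<class>`` with class one of ``mut``, ``gain``, ``loss`` so that a
mutation and a copy-number event of the same gene are distinct alterations.

Clonality rules implemented here:

* whole-exome cohorts: a mutation is clonal when the 95% confidence interval
  of its cancer cell fraction (CCF) includes 1;
* targeted panels without CCF estimates: clonal when the normalised mutant
  allele fraction (MAF) exceeds 0.8;
* multi-region lesions: clonal in the lesion when clonal in >= 75% of its
  regions;
* copy-number alterations are always treated as clonal (no clonality
  estimator exists for CNAs).

Gene-level copy-number calls are made against sample ploidy: a gene is
gained/lost when the copy number of the segment covering it deviates from
ploidy by at least 0.6, after discarding segments supported by fewer than 10
probes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALTERATION_CLASSES = ("mut", "gain", "loss")

_ID_RE = re.compile(r"^(?P<gene>.+)_(?P<cls>mut|gain|loss)$")


def alteration_id(gene: str, cls: str) -> str:
    if cls not in ALTERATION_CLASSES:
        raise ValueError(f"unknown alteration class {cls!r}")
    return f"{gene}_{cls}"


def parse_alteration_id(alt_id: str) -> tuple[str, str]:
    m = _ID_RE.match(alt_id)
    if m is None:
        raise ValueError(f"cannot parse alteration id {alt_id!r}")
    return m.group("gene"), m.group("cls")


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic point mutation in one sample.

    Either the CCF triple (point estimate plus 95% CI bounds) or a normalised
    MAF must be present, depending on the assay.
    """

    sample_id: str
    gene: str
    ccf: float | None = None
    ccf_ci_low: float | None = None
    ccf_ci_high: float | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        has_ccf = (
            self.ccf is not None
            and self.ccf_ci_low is not None
            and self.ccf_ci_high is not None
        )
        if not has_ccf and self.maf is None:
            raise ValueError(
                f"{self.sample_id}/{self.gene}: need a CCF triple or a MAF value"
            )
        if has_ccf and not (self.ccf_ci_low <= self.ccf <= self.ccf_ci_high):
            raise ValueError(
                f"{self.sample_id}/{self.gene}: CCF {self.ccf} outside its CI "
                f"[{self.ccf_ci_low}, {self.ccf_ci_high}]"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"{self.sample_id}/{self.gene}: MAF {self.maf} not in [0,1]")


@dataclass(frozen=True)
class CnSegment:
    """A copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: float
    n_probes: int
    n_exons: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.n_probes < 0:
            raise ValueError("n_probes must be non-negative")
        if self.copy_number < 0:
            raise ValueError("copy_number must be non-negative")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene locus plus median transcript length in base pairs."""

    gene: str
    chrom: str
    start: int
    end: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.gene}: length_bp must be positive")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class DriverCatalog:
    """Catalogue of candidate driver alterations for one tumour type."""

    entries: list[tuple[str, str]]
    tumour_type: str = "NA"

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate entries in driver catalogue")
        for gene, cls in self.entries:
            if cls not in ALTERATION_CLASSES:
                raise ValueError(f"unknown class {cls!r} for {gene}")

    @property
    def alteration_ids(self) -> list[str]:
        return [alteration_id(g, c) for g, c in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


class AlterationMatrix:
    """Binary samples x alterations incidence matrix.

    Rows are samples, columns are alteration ids; cells are 0/1 for absence/
    presence of a clonal alteration.  Multiple clonal mutations in one gene in
    one sample collapse to a single 1.
    """

    def __init__(self, values: pd.DataFrame):
        arr = values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("matrix values must be 0 or 1")
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("duplicate sample or alteration ids")
        self.values = values.astype(np.int8)

    # -- identity -----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def alteration_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    # -- derived counts -----------------------------------------------------
    @property
    def sample_loads(self) -> pd.Series:
        """Per-sample alteration count m_s (row sums)."""
        return self.values.sum(axis=1)

    @property
    def alteration_counts(self) -> pd.Series:
        """Per-alteration occurrence count k_i (column sums)."""
        return self.values.sum(axis=0)

    @property
    def total_events(self) -> int:
        """T = sum of all incidences."""
        return int(self.values.to_numpy().sum())

    @property
    def frequencies(self) -> pd.Series:
        """Cohort frequency of each alteration, k_i / n_samples."""
        return self.alteration_counts / self.n_samples

    # -- views --------------------------------------------------------------
    def restrict(self, alteration_ids: Sequence[str]) -> "AlterationMatrix":
        """Matrix restricted to the given columns, in the given order."""
        missing = [a for a in alteration_ids if a not in self.values.columns]
        if missing:
            raise KeyError(f"alterations not in matrix: {missing}")
        return AlterationMatrix(self.values.loc[:, list(alteration_ids)].copy())

    def sample_set(self, sample_id: str) -> frozenset[str]:
        row = self.values.loc[sample_id]
        return frozenset(row.index[row.to_numpy().astype(bool)])

    def sample_sets(self) -> dict[str, frozenset[str]]:
        return {s: self.sample_set(s) for s in self.sample_ids}

    def merge_columns(self, sources: Sequence[str], merged_id: str) -> "AlterationMatrix":
        """Replace `sources` by a single column equal to their logical OR."""
        present = [c for c in sources if c in self.values.columns]
        if not present:
            return self
        merged = (self.values[present].sum(axis=1) > 0).astype(np.int8)
        out = self.values.drop(columns=present)
        out[merged_id] = merged
        return AlterationMatrix(out)

    # -- IO -----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlterationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    @classmethod
    def from_sets(
        cls,
        sample_sets: Mapping[str, Iterable[str]],
        alteration_ids: Sequence[str] | None = None,
    ) -> "AlterationMatrix":
        """Build a matrix from per-sample alteration sets."""
        if alteration_ids is None:
            alteration_ids = sorted({a for alts in sample_sets.values() for a in alts})
        df = pd.DataFrame(
            0, index=list(sample_sets), columns=list(alteration_ids), dtype=np.int8
        )
        for s, alts in sample_sets.items():
            present = [a for a in alts if a in df.columns]
            df.loc[s, present] = 1
        return cls(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlterationMatrix):
            return NotImplemented
        return self.values.equals(other.values)

    def __repr__(self) -> str:
        return f"AlterationMatrix({self.n_samples} samples x {len(self.alteration_ids)} alterations)"


# ---------------------------------------------------------------------------
# clonality calls
# ---------------------------------------------------------------------------

def call_clonal_by_ccf(records: Sequence[MutationRecord]) -> list[bool]:
    """Clonal iff the 95% CCF confidence interval includes 1."""
    calls = []
    for r in records:
        if r.ccf_ci_low is None or r.ccf_ci_high is None:
            raise ValueError(f"{r.sample_id}/{r.gene}: CCF confidence interval missing")
        calls.append(r.ccf_ci_low <= 1.0 <= r.ccf_ci_high)
    return calls


def call_clonal_by_maf(records: Sequence[MutationRecord], threshold: float = 0.8) -> list[bool]:
    """Clonal iff normalised MAF strictly exceeds `threshold` (default 0.8)."""
    calls = []
    for r in records:
        if r.maf is None:
            raise ValueError(f"{r.sample_id}/{r.gene}: MAF missing")
        calls.append(r.maf > threshold)
    return calls


def multi_region_clonality(per_region_flags: Sequence[bool], fraction: float = 0.75) -> bool:
    """Clonal in a multi-region lesion iff clonal in >= `fraction` of regions."""
    if len(per_region_flags) == 0:
        raise ValueError("need at least one region")
    return sum(bool(f) for f in per_region_flags) / len(per_region_flags) >= fraction


# ---------------------------------------------------------------------------
# copy-number calls
# ---------------------------------------------------------------------------

def call_cna_vs_ploidy(
    segments: Sequence[CnSegment],
    sample_ploidy: float,
    genes: Sequence[GeneAnnotation],
    deviation: float = 0.6,
    min_probes: int = 10,
) -> dict[str, str]:
    """Per-gene gain/loss/none calls for one sample, relative to its ploidy.

    Segments with fewer than `min_probes` probes are discarded.  A gene is
    assigned the call of the surviving segment covering its midpoint (the
    deterministic rule when a gene spans a breakpoint); genes covered by no
    surviving segment are 'none'.
    """
    if sample_ploidy <= 0:
        raise ValueError("sample_ploidy must be positive")
    surviving = [s for s in segments if s.n_probes >= min_probes]
    calls: dict[str, str] = {}
    for g in genes:
        call = "none"
        mid = g.midpoint
        for seg in surviving:
            if seg.chrom == g.chrom and seg.start <= mid <= seg.end:
                dev = seg.copy_number - sample_ploidy
                if dev >= deviation:
                    call = "gain"
                elif dev <= -deviation:
                    call = "loss"
                break
        calls[g.gene] = call
    return calls


def call_cna_vs_normal(
    segment_mean: float,
    normal_means: Sequence[float],
    direction: str,
    alpha: float = 0.05,
) -> bool:
    """One-tailed normal test of a segment mean against normal-sample segment means.

    For panel data without ploidy estimates: the segment logR is compared to
    the normal distribution fitted to segment means of normal samples; a
    'gain' is significant in the upper tail, a 'loss' in the lower tail.
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    if len(normal_means) < 2:
        raise ValueError("need at least two normal segment means")
    mu = float(np.mean(normal_means))
    sd = float(np.std(normal_means, ddof=1))
    if sd == 0:
        raise ValueError("normal segment means have zero standard deviation")
    z = (segment_mean - mu) / sd
    p = stats.norm.sf(z) if direction == "gain" else stats.norm.cdf(z)
    return bool(p < alpha)


def weighted_ploidy(segments: Sequence[CnSegment]) -> float:
    """Sample ploidy as the exon-count-weighted mean copy number over segments."""
    if not segments:
        raise ValueError("no segments")
    weights = np.array([s.n_exons for s in segments], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("total exon count must be positive")
    cns = np.array([s.copy_number for s in segments], dtype=float)
    return float((cns * weights).sum() / weights.sum())


# ---------------------------------------------------------------------------
# driver selection
# ---------------------------------------------------------------------------

MERGED_CDKN_LOSS = "CDKN2A/B_loss"
_CDKN_PAIR = ("CDKN2A_loss", "CDKN2B_loss")


def select_drivers(
    matrix: AlterationMatrix,
    catalog: DriverCatalog,
    max_n: int = 50,
    min_freq: float = 0.005,
) -> tuple[DriverCatalog, AlterationMatrix]:
    """Retain the most frequent driver alterations of a cohort.

    CDKN2A and CDKN2B losses are first merged into a single event (they sit
    next to each other on 9p21, so separate columns would fake a perfect
    co-occurrence).  Candidate drivers with cohort frequency strictly above
    `min_freq` are then ranked by frequency (ties broken lexicographically by
    alteration id) and the top `max_n` kept.

    Returns the retained catalogue together with the (possibly merged) matrix.
    """
    if len(catalog) == 0:
        raise ValueError("empty driver catalogue")
    merged = matrix.merge_columns(_CDKN_PAIR, MERGED_CDKN_LOSS)
    cand_ids = []
    for gene, cls in catalog.entries:
        aid = alteration_id(gene, cls)
        if aid in _CDKN_PAIR:
            aid = MERGED_CDKN_LOSS
        if aid not in cand_ids:
            cand_ids.append(aid)
    freqs = merged.frequencies
    scored = [(aid, float(freqs.get(aid, 0.0))) for aid in cand_ids]
    kept = [(aid, f) for aid, f in scored if f > min_freq]
    kept.sort(key=lambda t: (-t[1], t[0]))
    kept = kept[:max_n]
    entries = []
    for aid, _ in kept:
        if aid == MERGED_CDKN_LOSS:
            entries.append(("CDKN2A/B", "loss"))
        else:
            entries.append(parse_alteration_id(aid))
    return DriverCatalog(entries, tumour_type=catalog.tumour_type), merged


# ---------------------------------------------------------------------------
# cohort matrix construction
# ---------------------------------------------------------------------------

def matrix_from_calls(
    clonal_mutations: Iterable[tuple[str, str]],
    cna_calls: Iterable[tuple[str, str, str]] = (),
    sample_ids: Sequence[str] | None = None,
) -> AlterationMatrix:
    """Assemble a binary matrix from (sample, gene) clonal mutations and
    (sample, gene, class) copy-number calls."""
    sets: dict[str, set[str]] = {}
    if sample_ids is not None:
        for s in sample_ids:
            sets[s] = set()
    for s, g in clonal_mutations:
        sets.setdefault(s, set()).add(alteration_id(g, "mut"))
    for s, g, cls in cna_calls:
        if cls in ("gain", "loss"):
            sets.setdefault(s, set()).add(alteration_id(g, cls))
    return AlterationMatrix.from_sets(sets)


def build_cohort_matrix(
    mutations: Sequence[MutationRecord],
    segments: Sequence[CnSegment] = (),
    genes: Sequence[GeneAnnotation] = (),
    ploidies: Mapping[str, float] | None = None,
    clonality: str = "ccf",
    maf_threshold: float = 0.8,
    deviation: float = 0.6,
    min_probes: int = 10,
) -> AlterationMatrix:
    """Full pipeline: clonality calls plus per-sample CNA calls -> matrix.

    `clonality` is 'ccf' (CI-includes-1 rule) or 'maf' (>0.8 rule).  Sample
    ploidies default to the exon-weighted mean copy number of each sample's
    segments; CNAs are treated as clonal throughout.
    """
    if clonality == "ccf":
        flags = call_clonal_by_ccf(mutations)
    elif clonality == "maf":
        flags = call_clonal_by_maf(mutations, threshold=maf_threshold)
    else:
        raise ValueError("clonality must be 'ccf' or 'maf'")
    clonal = [(r.sample_id, r.gene) for r, ok in zip(mutations, flags) if ok]

    by_sample: dict[str, list[CnSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    cna_calls: list[tuple[str, str, str]] = []
    for sample, segs in by_sample.items():
        if ploidies is not None and sample in ploidies:
            ploidy = ploidies[sample]
        else:
            ploidy = weighted_ploidy(segs)
        for gene, call in call_cna_vs_ploidy(
            segs, ploidy, genes, deviation=deviation, min_probes=min_probes
        ).items():
            if call != "none":
                cna_calls.append((sample, gene, call))

    all_samples = sorted(
        {r.sample_id for r in mutations} | set(by_sample),
    )
    return matrix_from_calls(clonal, cna_calls, sample_ids=all_samples)


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------

def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    """Mutation table: columns sample, gene, ccf, ccf_low, ccf_high, maf
    (missing values allowed in the numeric columns)."""
    df = pd.read_csv(path, sep="\t")
    recs = []
    for row in df.itertuples(index=False):
        def val(name: str) -> float | None:
            v = getattr(row, name, None)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        recs.append(
            MutationRecord(
                sample_id=str(row.sample),
                gene=str(row.gene),
                ccf=val("ccf"),
                ccf_ci_low=val("ccf_low"),
                ccf_ci_high=val("ccf_high"),
                maf=val("maf"),
            )
        )
    return recs


def read_segments_tsv(path: str | Path) -> list[CnSegment]:
    """Segment table: columns sample, chrom, start, end, cn, n_probes[, n_exons]."""
    df = pd.read_csv(path, sep="\t")
    if "n_exons" not in df.columns:
        df["n_exons"] = 0
    return [
        CnSegment(
            sample_id=str(r.sample),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            copy_number=float(r.cn),
            n_probes=int(r.n_probes),
            n_exons=int(r.n_exons),
        )
        for r in df.itertuples(index=False)
    ]


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Gene annotation from BED (0-based half-open; converted to 1-based
    inclusive on read) or a 4+-column TSV with header gene/chrom/start/end
    [/length_bp] in 1-based inclusive coordinates."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
        )
        return [
            GeneAnnotation(
                gene=str(r.gene), chrom=str(r.chrom),
                start=int(r.start) + 1, end=int(r.end),
                length_bp=int(r.end) - int(r.start),
            )
            for r in df.itertuples(index=False)
        ]
    df = pd.read_csv(path, sep="\t")
    has_len = "length_bp" in df.columns
    return [
        GeneAnnotation(
            gene=str(r.gene), chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            length_bp=int(r.length_bp) if has_len else int(r.end) - int(r.start) + 1,
        )
        for r in df.itertuples(index=False)
    ]


def read_driver_catalog(path: str | Path, tumour_type: str = "NA") -> DriverCatalog:
    """Driver catalogue TSV with columns gene, class."""
    df = pd.read_csv(path, sep="\t")
    entries = [(str(g), str(c)) for g, c in zip(df["gene"], df["class"])]
    return DriverCatalog(entries, tumour_type=tumour_type)
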