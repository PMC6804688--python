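"""Shared data model: genotype cohort, sample metadata, gene models, window tracks.

All coordinates are 0-based half-open internally.  VCF (1-based positions)
and GFF3 (1-based inclusive intervals) keep their native conventions at the
I/O boundary only; :mod:`popscan.io` performs the single conversion.

Genotypes are stored unphased as allele-index pairs in a dense
``(n_samples, n_sites, 2)`` int8 array with ``MISSING`` (= -1) for
uncalled alleles, alongside per-call read depth (DP) and genotype quality
(GQ) matrices.  This is the central container every statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alts", "is_snp", "is_indel"]


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    return len(ref) == 1 and all(len(a) == 1 for a in alts)


def make_sites_frame(records: Iterable[tuple]) -> pd.DataFrame:
    """Build a site table from (chrom, pos0, ref, alts) tuples.

    Sites are sorted by (chrom, pos); duplicate (chrom, pos, ref, alts)
    entries raise.  ``alts`` is stored as a tuple of upper-cased strings.
    """
    rows = []
    for chrom, pos, ref, alts in records:
        ref = ref.upper()
        alts = tuple(a.upper() for a in alts)
        if pos < 0:
            raise ValueError(f"negative position {pos} on {chrom}")
        if not ref:
            raise ValueError(f"empty REF at {chrom}:{pos}")
        rows.append((str(chrom), int(pos), ref, alts, _is_snp(ref, alts), not _is_snp(ref, alts)))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    key = list(zip(df.chrom, df.pos, df.ref, df.alts))
    if len(set(key)) != len(key):
        raise ValueError("duplicate (chrom, pos, ref, alts) site records")
    return df


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced accession: a pool of ``pool_size`` plants of one cultivar."""

    accession: str
    morphotype: str
    subspecies: str
    pool_size: int = 5

    def __post_init__(self):
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


@dataclass
class GeneModel:
    """One gene model (longest-CDS transcript), 0-based half-open intervals.

    ``exons`` are sorted and non-overlapping; ``cds`` is a subset of the
    exons.  ``utr5``/``utr3`` are the exonic remainder partitioned by
    strand.  A gene without CDS is non-coding and excluded from coding
    effect calls.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        self.cds = sorted(tuple(c) for c in self.cds)
        if not self.utr5 and not self.utr3:
            self.utr5, self.utr3 = derive_utrs(self.exons, self.cds, self.strand)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]


def derive_utrs(exons, cds, strand):
    """Exonic intervals outside the CDS, split into 5' and 3' by strand."""
    if not cds:
        return [], []
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    before, after = [], []
    for s, e in exons:
        if s < cds_start:
            before.append((s, min(e, cds_start)))
        if e > cds_end:
            after.append((max(s, cds_end), e))
    if strand == "+":
        return before, after
    return after, before


@dataclass
class CohortTable:
    """Filtered (or raw) genotype matrix: accessions x variant sites.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos (0-based), ref, alts (tuple),
        is_snp, is_indel; sorted by (chrom, pos).
    gt : int8 array (n_samples, n_sites, 2); MISSING (-1) for uncalled.
    dp, gq : int32 arrays (n_samples, n_sites).
    samples : list of SampleMeta, row order of gt.
    has_dp, has_gq : whether DP/GQ were present in the source (absent
        fields disable the depth/quality mask rather than failing).
    masked : set once depth/quality masking has been applied.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    samples: list[SampleMeta]
    has_dp: bool = True
    has_gq: bool = True
    masked: bool = False

    def __post_init__(self):
        n_samples, n_sites = len(self.samples), len(self.sites)
        if self.gt.shape != (n_samples, n_sites, 2):
            raise ValueError(f"gt shape {self.gt.shape} != {(n_samples, n_sites, 2)}")
        if self.dp.shape != (n_samples, n_sites) or self.gq.shape != (n_samples, n_sites):
            raise ValueError("dp/gq shape mismatch")
        both = (self.gt == MISSING).sum(axis=2)
        if np.any(both == 1):
            raise ValueError("half-missing genotype call (alleles must both be set or both MISSING)")

    # -- basic accessors ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_names(self) -> list[str]:
        return [s.accession for s in self.samples]

    @property
    def is_missing(self) -> np.ndarray:
        """(n_samples, n_sites) bool: call fully missing."""
        return self.gt[:, :, 0] == MISSING

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s.accession: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown accession {exc.args[0]!r}") from exc

    def group_indices(self, by: str = "subspecies") -> dict[str, np.ndarray]:
        """Sample row indices grouped by 'subspecies', 'morphotype' or 'accession'."""
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            groups.setdefault(getattr(s, by if by != "accession" else "accession"), []).append(i)
        return {k: np.array(v, dtype=int) for k, v in sorted(groups.items())}

    # -- derived matrices ----------------------------------------------
    def dosage(self, allele: int = 1) -> np.ndarray:
        """Copies of ``allele`` per call as float (NaN where missing)."""
        d = (self.gt == allele).sum(axis=2).astype(np.float64)
        d[self.is_missing] = np.nan
        return d

    def is_het(self) -> np.ndarray:
        called = ~self.is_missing
        return called & (self.gt[:, :, 0] != self.gt[:, :, 1])

    def is_hom_alt(self) -> np.ndarray:
        called = ~self.is_missing
        return called & (self.gt[:, :, 0] == self.gt[:, :, 1]) & (self.gt[:, :, 0] > 0)

    def is_hom_ref(self) -> np.ndarray:
        called = ~self.is_missing
        return called & (self.gt[:, :, 0] == 0) & (self.gt[:, :, 1] == 0)

    # -- subsetting -----------------------------------------------------
    def take_sites(self, idx) -> "CohortTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            gt=self.gt[:, idx, :].copy(),
            dp=self.dp[:, idx].copy(),
            gq=self.gq[:, idx].copy(),
        )

    def take_samples(self, idx) -> "CohortTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            gt=self.gt[idx].copy(),
            dp=self.dp[idx].copy(),
            gq=self.gq[idx].copy(),
        )

    def biallelic_snps(self) -> "CohortTable":
        """Sites that are SNPs with exactly one declared ALT."""
        mask = self.sites.is_snp.to_numpy() & (self.sites.alts.map(len) == 1).to_numpy()
        return self.take_sites(mask)

    def copy(self) -> "CohortTable":
        return replace(
            self,
            sites=self.sites.copy(),
            gt=self.gt.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
            samples=list(self.samples),
        )


def make_windows(chrom_lengths: dict[str, int], size: int) -> pd.DataFrame:
    """Non-overlapping windows tiling each chromosome (0-based half-open)."""
    if size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + size, length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_stat_frame(rows: Iterable[tuple]) -> pd.DataFrame:
    """(chrom, start, end, stat, value, n_sites) rows -> WindowStat table."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "stat", "value", "n_sites"])
    if len(df) and (df.end <= df.start).any():
        raise ValueError("window end must exceed start")
    return df
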