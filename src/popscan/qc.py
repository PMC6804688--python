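"""Genotype masking, site filtering, and per-accession / windowed summaries.

The filter chain is: (1) set genotype calls with depth < 10 reads or
quality < 20 to missing; (2) drop sites that are non-biallelic or have
more than 30% missing calls (computed after masking).  Thresholds are
strict inequalities, so calls at exactly DP=10 / GQ=20 and sites at
exactly 30% missing survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import MISSING, CohortTable, make_windows, window_stat_frame


@dataclass
class FilterConfig:
    min_depth: int = 10
    min_gq: int = 20
    max_missing_frac: float = 0.30
    biallelic_only: bool = True
    snps_only_for_stats: bool = True

    def __post_init__(self):
        if not 0 <= self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("min_depth and min_gq must be >= 0")


@dataclass
class FilterReport:
    input_sites: int
    removed_nonbiallelic: int
    removed_missing: int
    retained: int
    masked_calls: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def mask_genotypes(table: CohortTable, cfg: FilterConfig | None = None) -> CohortTable:
    """Set calls with depth < min_depth OR quality < min_gq to missing.

    Returns a new table (input untouched).  If the source VCF lacked DP or
    GQ the corresponding check is skipped with a warning.
    """
    cfg = cfg or FilterConfig()
    out = table.copy()
    bad = np.zeros((table.n_samples, table.n_sites), dtype=bool)
    if table.has_dp:
        bad |= out.dp < cfg.min_depth
    else:
        warnings.warn("DP absent; depth mask skipped")
    if table.has_gq:
        bad |= out.gq < cfg.min_gq
    else:
        warnings.warn("GQ absent; quality mask skipped")
    n_new = int((bad & ~out.is_missing).sum())
    out.gt[bad] = MISSING
    out.masked = True
    out._n_masked = n_new  # stashed for the filter report
    return out


def _n_observed_alleles(table: CohortTable) -> np.ndarray:
    """Distinct alleles per site: declared ALTs plus REF."""
    return 1 + table.sites.alts.map(len).to_numpy()


def filter_sites(table: CohortTable, cfg: FilterConfig | None = None):
    """Drop non-biallelic sites and sites with > max_missing_frac missing calls.

    Requires masking to have been applied first (or DP/GQ to be absent).
    Each removed site is attributed to the first rule that removes it,
    non-biallelic before missingness.  Idempotent.
    """
    cfg = cfg or FilterConfig()
    if not table.masked and (table.has_dp or table.has_gq):
        raise ValueError("apply mask_genotypes before filter_sites")
    n_alleles = _n_observed_alleles(table)
    nonbi = n_alleles > 2 if cfg.biallelic_only else np.zeros(table.n_sites, dtype=bool)
    miss_frac = table.is_missing.sum(axis=0) / table.n_samples
    too_missing = miss_frac > cfg.max_missing_frac
    keep = ~nonbi & ~too_missing
    report = FilterReport(
        input_sites=table.n_sites,
        removed_nonbiallelic=int(nonbi.sum()),
        removed_missing=int((too_missing & ~nonbi).sum()),
        retained=int(keep.sum()),
        masked_calls=int(getattr(table, "_n_masked", 0)),
    )
    out = table.take_sites(keep)
    out.masked = True
    return out, report


def accession_summary(table: CohortTable) -> pd.DataFrame:
    """Per-accession variable-site classification and observed heterozygosity.

    A called site is invariant (hom-ref), biallelic-variable (het: one
    allele matches the reference, one differs) or monoallelic-variable
    (hom-alt: both alleles differ from the reference).  Percentages of
    biallelic/monoallelic are over the accession's variable sites; percent
    missing and Ho are over all retained sites.
    """
    het = table.is_het()
    hom_alt = table.is_hom_alt()
    miss = table.is_missing
    n_sites = table.n_sites
    rows = []
    for i, s in enumerate(table.samples):
        n_het, n_hom_alt = int(het[i].sum()), int(hom_alt[i].sum())
        n_var = n_het + n_hom_alt
        rows.append(
            dict(
                accession=s.accession,
                morphotype=s.morphotype,
                subspecies=s.subspecies,
                n_variable=n_var,
                pct_biallelic=100.0 * n_het / n_var if n_var else 0.0,
                pct_monoallelic=100.0 * n_hom_alt / n_var if n_var else 0.0,
                pct_missing=100.0 * int(miss[i].sum()) / n_sites if n_sites else 0.0,
                ho=n_het / n_sites if n_sites else 0.0,
            )
        )
    return pd.DataFrame(rows)


def snp_density_windows(
    table: CohortTable, chrom_lengths: dict[str, int], window: int = 100_000
):
    """Retained-SNP counts per non-overlapping window, plus per-chromosome totals.

    Returns (WindowStat table with stat='snp_count', per-chromosome frame
    with columns chrom, n_snps, per_kb).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    snp = table.sites[table.sites.is_snp & (table.sites.alts.map(len) == 1)]
    wins = make_windows(chrom_lengths, window)
    rows = []
    for w in wins.itertuples():
        n = int(((snp.chrom == w.chrom) & (snp.pos >= w.start) & (snp.pos < w.end)).sum())
        rows.append((w.chrom, w.start, w.end, "snp_count", float(n), n))
    stats = window_stat_frame(rows)
    per_chrom = []
    for chrom, length in chrom_lengths.items():
        n = int((snp.chrom == chrom).sum())
        per_chrom.append((chrom, n, 1000.0 * n / length if length else np.nan))
    return stats, pd.DataFrame(per_chrom, columns=["chrom", "n_snps", "per_kb"])


def density_homogeneity_test(density: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome one-sample one-tailed t test of window SNP density.

    H1: the chromosome's mean window density exceeds the genome-wide mean
    window density.  A chromosome whose windows all equal the genome mean
    gives t = 0, p = 0.5; windows uniformly below the mean push p toward 1.
    """
    values = density[density.stat == "snp_count"]
    genome_mean = values.value.mean()
    rows = []
    for chrom, grp in values.groupby("chrom", sort=True):
        x = grp.value.to_numpy(dtype=float)
        if len(x) < 2:
            warnings.warn(f"{chrom}: fewer than 2 windows, t test undefined")
            rows.append((chrom, np.nan, np.nan))
            continue
        if np.ptp(x) == 0:  # zero variance: sign of the mean difference decides
            diff = x[0] - genome_mean
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 0.5 if diff == 0 else (0.0 if diff > 0 else 1.0)
        else:
            t, p = sps.ttest_1samp(x, genome_mean, alternative="greater")
        rows.append((chrom, float(t), float(p)))
    return pd.DataFrame(rows, columns=["chrom", "t", "p"])


def gene_snp_density_regression(snp_density: pd.DataFrame, gene_density: pd.DataFrame) -> dict:
    """OLS of per-window SNP count on per-window gene count.

    Windows are matched on (chrom, start).  Returns slope, r2 and the
    two-sided p-value for the slope.
    """
    a = snp_density[snp_density.stat == "snp_count"][["chrom", "start", "value"]]
    b = gene_density[["chrom", "start", "value"]]
    merged = a.merge(b, on=["chrom", "start"], suffixes=("_snp", "_gene"))
    if len(merged) < 3:
        raise ValueError("need at least 3 matched windows for regression")
    x = merged.value_gene.to_numpy(dtype=float)
    y = merged.value_snp.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("gene density has zero variance; regression undefined")
    res = sps.linregress(x, y)
    return {"slope": res.slope, "r2": res.rvalue**2, "p": res.pvalue, "n_windows": len(merged)}


def gene_density_windows(genes, chrom_lengths: dict[str, int], window: int = 100_000) -> pd.DataFrame:
    """Number of genes whose span midpoint falls in each window (stat='gene_count')."""
    wins = make_windows(chrom_lengths, window)
    mids = pd.DataFrame(
        [(g.chrom, (g.start + g.end) // 2) for g in genes], columns=["chrom", "mid"]
    )
    rows = []
    for w in wins.itertuples():
        n = int(((mids.chrom == w.chrom) & (mids.mid >= w.start) & (mids.mid < w.end)).sum())
        rows.append((w.chrom, w.start, w.end, "gene_count", float(n), n))
    return window_stat_frame(rows)
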