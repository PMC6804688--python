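"""Weir-Cockerham Fst, Tajima's D, and the per-gene selection scans.

The two-population Weir-Cockerham (1984) estimator partitions allele
frequency variance into among-population (a), among-individual-within-
population (b) and within-individual (c) components; theta = a/(a+b+c)
per site, and ratio-of-sums Sum(a)/Sum(a+b+c) over windows or genes.
Negative per-site components are retained in the aggregation (flooring
would bias the ratio upward).

Tajima's D for an interval uses only sites completely called within the
group, so the sample size n (2 x diploids) that the constants a1..e2
require stays fixed: D = (pi_sum - S/a1) / sqrt(e1*S + e2*S*(S-1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CohortTable, GeneModel
from .diversity import site_pi

FST_ONE_TOL = 1e-12


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _group_counts(table: CohortTable, group: np.ndarray):
    sub = table.take_samples(np.asarray(group))
    called = ~sub.is_missing
    n = called.sum(axis=0).astype(float)          # called diploids
    alt = (sub.gt == 1).sum(axis=2).astype(float)
    alt[~called] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt.sum(axis=0) / (2.0 * n)
        h = (sub.is_het().sum(axis=0)) / n
    return n, p, h


def wc_fst_site(table: CohortTable, group1: np.ndarray, group2: np.ndarray) -> pd.DataFrame:
    """Per-site variance components a, b, c and theta for two populations.

    A site is usable when each group has at least one called diploid (and
    n_bar > 1 so the within-population terms are defined).  Sites
    monomorphic across both groups get zero components and NaN theta.
    """
    g1, g2 = np.asarray(group1), np.asarray(group2)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    if set(g1.tolist()) & set(g2.tolist()):
        raise ValueError("groups overlap")
    n1, p1, h1 = _group_counts(table, g1)
    n2, p2, h2 = _group_counts(table, g2)
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0

    usable = (n1 >= 1) & (n2 >= 1) & (n_bar > 1)
    mono = usable & ((p_bar == 0) | (p_bar == 1)) & (h_bar == 0)
    for arr in (a, b, c):
        arr[~usable] = np.nan
        arr[mono] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / (a + b + c)
    theta[mono] = np.nan
    theta = np.clip(theta, -1.0, 1.0)
    return pd.DataFrame(
        {
            "chrom": table.sites.chrom,
            "pos": table.sites.pos,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
            "n_bar": n_bar,
            "n_c": n_c,
            "p_bar": p_bar,
            "s2": s2,
            "h_bar": h_bar,
            "usable": usable & ~np.isnan(a),
        }
    )


def fst_aggregate(components: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Ratio-of-sums theta per interval (frame with chrom, start, end[, id]).

    Adds sum_a, sum_bc and the fixed-difference flag is_one
    (|sum_b + sum_c| < 1e-12 with positive sum_a), which defines the
    "Fst = 1.00" class.
    """
    comp = components[components.usable]
    rows = []
    for iv in intervals.itertuples():
        sel = (comp.chrom == iv.chrom) & (comp.pos >= iv.start) & (comp.pos < iv.end)
        sub = comp[sel]
        sum_a = float(sub.a.sum())
        sum_abc = float((sub.a + sub.b + sub.c).sum())
        poly = sub[(sub.a != 0) | (sub.b != 0) | (sub.c != 0)]
        n_sites = int(len(poly))
        if n_sites == 0 or sum_abc <= 0:
            theta, is_one = np.nan, False
        else:
            theta = sum_a / sum_abc
            is_one = abs(sum_abc - sum_a) < FST_ONE_TOL and sum_a > 0
        rows.append(
            (
                iv.chrom,
                iv.start,
                iv.end,
                getattr(iv, "id", None),
                theta,
                sum_a,
                sum_abc - sum_a,
                n_sites,
                is_one,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "id", "theta", "sum_a", "sum_bc", "n_sites", "is_one"],
    )


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass
class TajimaInputs:
    n: int
    S: int
    pi_sum: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1..e2 constants for n sampled sequences."""
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d_from_counts(n: int, derived_counts: np.ndarray) -> TajimaInputs:
    """D from per-site derived-allele counts of n sequences (infinite sites)."""
    k = tajima_constants(n)
    counts = np.asarray(derived_counts, dtype=float)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    c = counts[seg]
    pi_sum = float(np.sum(2.0 * c * (n - c) / (n * (n - 1.0))))
    if S == 0:
        D = np.nan
    else:
        var = k["e1"] * S + k["e2"] * S * (S - 1.0)
        D = (pi_sum - S / k["a1"]) / np.sqrt(var)
    return TajimaInputs(n=n, S=S, pi_sum=pi_sum, D=float(D), **k)


def tajima_d(
    table: CohortTable,
    group: np.ndarray,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> TajimaInputs:
    """Tajima's D for an interval (whole table if no interval given).

    Uses only sites with complete calls in the group; any missing call
    drops the site so that n = 2 x group size stays constant.
    """
    group = np.asarray(group)
    n = 2 * len(group)
    if n < 4:
        warnings.warn("Tajima's D needs >= 4 sequences; returning NaN")
        k = tajima_constants(max(n, 2))
        return TajimaInputs(n=n, S=0, pi_sum=0.0, D=np.nan, **k)
    sub = table.take_samples(group)
    mask = np.ones(sub.n_sites, dtype=bool)
    if chrom is not None:
        pos = sub.sites.pos.to_numpy()
        mask = (sub.sites.chrom.to_numpy() == chrom) & (pos >= start) & (pos < end)
    complete = ~sub.is_missing.any(axis=0)
    use = mask & complete
    counts = (sub.gt[:, use, :] == 1).sum(axis=(0, 2))
    return tajima_d_from_counts(n, counts)


# ---------------------------------------------------------------------------
# per-gene statistics and scans
# ---------------------------------------------------------------------------

def gene_stats(
    table: CohortTable,
    genes: list[GeneModel],
    groups: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-gene pi and Tajima's D per group, plus multi-site Fst between the
    two groups.  ``groups`` must map exactly two labels (e.g. the two
    subspecies) to sample-row index arrays.  Per-gene pi uses the gene
    span length as denominator.  Genes with no SNPs get zero pi and NaN
    D / Fst.
    """
    if len(groups) != 2:
        raise ValueError("gene_stats needs exactly two groups")
    (name1, g1), (name2, g2) = sorted(groups.items())
    snps = table.biallelic_snps()
    comp = wc_fst_site(snps, g1, g2)
    intervals = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.gene_id) for g in genes],
        columns=["chrom", "start", "end", "id"],
    )
    fst = fst_aggregate(comp, intervals).set_index("id")

    pos = snps.sites.pos.to_numpy()
    chroms = snps.sites.chrom.to_numpy()
    pi_by_group = {name: site_pi(snps, g) for name, g in ((name1, g1), (name2, g2))}
    rows = []
    for g in genes:
        in_gene = (chroms == g.chrom) & (pos >= g.start) & (pos < g.end)
        span = g.end - g.start
        rec = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "n_sites": int(in_gene.sum()),
        }
        for name, grp in ((name1, g1), (name2, g2)):
            vals = pi_by_group[name][in_gene]
            rec[f"pi_{name}"] = float(np.nansum(vals)) / span
            td = tajima_d(snps.take_sites(in_gene), grp) if in_gene.any() else None
            rec[f"tajima_d_{name}"] = td.D if td is not None else np.nan
        frow = fst.loc[g.gene_id]
        rec["fst"] = frow.theta
        rec["fst_is_one"] = bool(frow.is_one)
        rec["sum_a"] = frow.sum_a
        rec["sum_bc"] = frow.sum_bc
        rows.append(rec)
    return pd.DataFrame(rows)


def candidate_fst_scan(stats: pd.DataFrame, threshold: float = 0.80) -> dict:
    """Genes with Fst strictly above ``threshold`` and genes fixed at Fst = 1.

    The equality class uses the |sum(b+c)| < 1e-12 flag from aggregation
    rather than float comparison of the ratio.
    """
    scanned = stats[~stats.fst.isna()]
    n_scanned = len(stats)
    above = scanned[scanned.fst > threshold]
    fixed = scanned[scanned.fst_is_one]
    return {
        "threshold": threshold,
        "n_genes_scanned": n_scanned,
        "genes_above": sorted(above.gene_id.tolist()),
        "n_above": len(above),
        "pct_above": 100.0 * len(above) / n_scanned if n_scanned else 0.0,
        "genes_fixed": sorted(fixed.gene_id.tolist()),
        "n_fixed": len(fixed),
        "pct_fixed": 100.0 * len(fixed) / n_scanned if n_scanned else 0.0,
    }


def high_diversity_scan(stats: pd.DataFrame, percentile: float = 99.0) -> dict:
    """Genes with pi strictly above the per-group diversity percentile.

    Returns flagged lists per group and the lists exclusive to exactly
    one group.
    """
    pi_cols = [c for c in stats.columns if c.startswith("pi_")]
    flagged = {}
    for col in pi_cols:
        name = col[3:]
        q = float(np.quantile(stats[col].to_numpy(), percentile / 100.0))
        flagged[name] = set(stats.gene_id[stats[col] > q])
    names = sorted(flagged)
    report = {"percentile": percentile, "flagged": {k: sorted(v) for k, v in flagged.items()}}
    if len(names) == 2:
        a, b = names
        report["exclusive"] = {
            a: sorted(flagged[a] - flagged[b]),
            b: sorted(flagged[b] - flagged[a]),
        }
        report["shared"] = sorted(flagged[a] & flagged[b])
    return report
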