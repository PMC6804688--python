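"""Nucleotide diversity, composite LD r², LD decay, and background LD.

Site diversity follows the unbiased pairwise-difference estimator
pi = 2 c (n - c) / (n (n - 1)) for a biallelic site with n called allele
copies of which c are the alternate.  Window pi divides the summed site
values by the full window length (monomorphic positions count as zero).

r² is the squared Pearson correlation of alternate-allele dosages
(0/1/2), i.e. the phase-free composite (Rogers-Huff style) estimator,
using pairwise-complete observations.

Background LD (BLD) bootstraps the r² level expected between unlinked
loci: per replicate, draw SNPs genome-wide and average r² over random
inter-chromosomal pairs; the BLD value is the upper bound of the 95%
interval (97.5th percentile) of the replicate means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CohortTable, make_windows, window_stat_frame

MIN_ALLELES_FOR_PI = 4


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(table: CohortTable, group: np.ndarray | None = None) -> np.ndarray:
    """Per-site pi over the given sample rows (all samples by default).

    Sites with fewer than 4 called allele copies return NaN.  Expects
    filtered biallelic SNPs; the alt-allele index is 1.
    """
    sub = table if group is None else table.take_samples(np.asarray(group))
    if sub.n_samples == 0:
        raise ValueError("empty sample group")
    called = ~sub.is_missing
    n = 2.0 * called.sum(axis=0)
    c = (sub.gt == 1).sum(axis=2).astype(float)
    c[~called] = 0.0
    c_alt = c.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * c_alt * (n - c_alt) / (n * (n - 1.0))
    pi[n < MIN_ALLELES_FOR_PI] = np.nan
    return pi


def window_pi(
    table: CohortTable,
    chrom_lengths: dict[str, int],
    group: np.ndarray | None = None,
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-bp pi in non-overlapping windows (denominator = full window bp)."""
    pi = site_pi(table, group)
    pos = table.sites.pos.to_numpy()
    chroms = table.sites.chrom.to_numpy()
    wins = make_windows(chrom_lengths, window)
    rows = []
    for w in wins.itertuples():
        in_w = (chroms == w.chrom) & (pos >= w.start) & (pos < w.end)
        vals = pi[in_w]
        n_used = int(np.sum(~np.isnan(vals)))
        total = float(np.nansum(vals)) if n_used else 0.0
        rows.append((w.chrom, w.start, w.end, "pi", total / (w.end - w.start), n_used))
    return window_stat_frame(rows)


def interval_pi(table: CohortTable, chrom: str, start: int, end: int,
                group: np.ndarray | None = None) -> tuple[float, int]:
    """Per-bp pi over one interval; shares the site_pi kernel with window_pi."""
    pos = table.sites.pos.to_numpy()
    in_iv = (table.sites.chrom.to_numpy() == chrom) & (pos >= start) & (pos < end)
    if not in_iv.any():
        return 0.0, 0
    vals = site_pi(table.take_sites(in_iv), group)
    n_used = int(np.sum(~np.isnan(vals)))
    return float(np.nansum(vals)) / (end - start), n_used


# ---------------------------------------------------------------------------
# pairwise r^2
# ---------------------------------------------------------------------------

def _r2_from_moments(n, sx, sy, sxy, sxx, syy):
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = (cov * cov) / (vx * vy)
    ok = (n > 0) & (vx > 1e-12) & (vy > 1e-12)
    return np.where(ok, r2, np.nan)


def pairwise_r2(
    table: CohortTable,
    group: np.ndarray | None = None,
    max_dist: int = 500_000,
    min_samples: int = 3,
    chunk: int = 1024,
) -> pd.DataFrame:
    """Composite r² for all same-chromosome site pairs within ``max_dist``.

    Returns a frame with site_a, site_b (global site indexes), chrom,
    midpoint, distance, r2, n_used.  Pairs with fewer than ``min_samples``
    complete observations or a monomorphic member are skipped.
    """
    sub = table if group is None else table.take_samples(np.asarray(group))
    D = sub.dosage()
    pos_all = table.sites.pos.to_numpy()
    chroms = table.sites.chrom.to_numpy()
    out = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        out.append(_banded_r2(D[:, idx], pos_all[idx], idx, chrom, max_dist, min_samples, chunk))
    if not out:
        return _empty_pairs()
    return pd.concat(out, ignore_index=True)


def _empty_pairs():
    return pd.DataFrame(
        {
            "site_a": pd.Series(dtype=np.int64),
            "site_b": pd.Series(dtype=np.int64),
            "chrom": pd.Series(dtype=object),
            "midpoint": pd.Series(dtype=np.float64),
            "distance": pd.Series(dtype=np.int64),
            "r2": pd.Series(dtype=np.float64),
            "n_used": pd.Series(dtype=np.int64),
        }
    )


def _banded_r2(D, pos, global_idx, chrom, max_dist, min_samples, chunk):
    S = D.shape[1]
    V = (~np.isnan(D)).astype(np.float64)
    X = np.nan_to_num(D)
    X2 = X * X
    frames = []
    for i0 in range(0, S, chunk):
        i1 = min(i0 + chunk, S)
        jmax = int(np.searchsorted(pos, pos[i1 - 1] + max_dist, side="right"))
        j0 = i0
        Xa, Va, X2a = X[:, i0:i1], V[:, i0:i1], X2[:, i0:i1]
        Xb, Vb, X2b = X[:, j0:jmax], V[:, j0:jmax], X2[:, j0:jmax]
        n = Va.T @ Vb
        r2 = _r2_from_moments(
            n, Xa.T @ Vb, Va.T @ Xb, Xa.T @ Xb, X2a.T @ Vb, Va.T @ X2b
        )
        ii = np.arange(i0, i1)[:, None]
        jj = np.arange(j0, jmax)[None, :]
        dist = np.abs(pos[jj] - pos[ii])
        keep = (jj > ii) & (dist <= max_dist) & (n >= min_samples) & ~np.isnan(r2)
        ai, bj = np.nonzero(keep)
        if len(ai):
            a = ii[ai, 0]
            b = jj[0, bj]
            frames.append(
                pd.DataFrame(
                    {
                        "site_a": global_idx[a],
                        "site_b": global_idx[b],
                        "chrom": chrom,
                        "midpoint": (pos[a] + pos[b]) / 2.0,
                        "distance": dist[ai, bj].astype(np.int64),
                        "r2": np.clip(r2[ai, bj], 0.0, 1.0),
                        "n_used": n[ai, bj].astype(np.int64),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True) if frames else _empty_pairs()


def window_ld(pairs: pd.DataFrame, chrom_lengths: dict[str, int], window: int = 50_000) -> pd.DataFrame:
    """Mean r² of pairs whose midpoint falls in each window (NaN when empty)."""
    wins = make_windows(chrom_lengths, window)
    rows = []
    for w in wins.itertuples():
        sel = (pairs.chrom == w.chrom) & (pairs.midpoint >= w.start) & (pairs.midpoint < w.end)
        vals = pairs.r2[sel]
        rows.append(
            (w.chrom, w.start, w.end, "ld_mean",
             float(vals.mean()) if len(vals) else np.nan, int(len(vals)))
        )
    return window_stat_frame(rows)


# ---------------------------------------------------------------------------
# LD decay: tricube-weighted local quadratic regression
# ---------------------------------------------------------------------------

@dataclass
class LdDecayFit:
    grid: np.ndarray
    fitted: np.ndarray
    crossings: dict[float, float | None]
    n_pairs: int
    span: float


def bin_pairs(distance, r2, grid_step):
    """Mean r² and pair count per distance bin of width ``grid_step``."""
    distance = np.asarray(distance, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    bins = (distance // grid_step).astype(np.int64)
    n = np.bincount(bins)
    s = np.bincount(bins, weights=r2)
    nz = n > 0
    centers = (np.arange(len(n))[nz] + 0.5) * grid_step
    return centers, s[nz] / n[nz], n[nz]


def ld_decay_fit(
    pairs: pd.DataFrame,
    span: float = 0.3,
    grid_step: int = 1000,
    thresholds: tuple[float, ...] = (0.6, 0.4, 0.3),
    min_pairs: int = 50,
) -> LdDecayFit:
    """Fit r² against distance with a tricube-weighted local quadratic.

    Pairs are first reduced to distance-bin means (bin width =
    ``grid_step``) weighted by pair counts, then a degree-2 local
    regression with tricube weights and nearest-neighbour span is
    evaluated on a regular grid.  For each threshold t the smallest grid
    distance with fitted r² < t is reported (None if never crossed).
    """
    if len(pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs to fit LD decay, got {len(pairs)}")
    d, m, w = bin_pairs(pairs.distance, pairs.r2, grid_step)
    grid = np.arange(0, int(pairs.distance.max()) + grid_step, grid_step, dtype=float)
    fitted = _local_quadratic(d, m, w, grid, span)
    crossings: dict[float, float | None] = {}
    for t in thresholds:
        below = np.flatnonzero(fitted < t)
        crossings[t] = float(grid[below[0]]) if len(below) else None
    return LdDecayFit(grid=grid, fitted=fitted, crossings=crossings, n_pairs=len(pairs), span=span)


def _local_quadratic(x, y, w, grid, span):
    """Weighted local polynomial (degree 2, tricube kernel, count weights)."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")  # ties broken by site order
    x, y, w = x[order], np.asarray(y, float)[order], np.asarray(w, float)[order]
    total_w = w.sum()
    fitted = np.empty(len(grid))
    for k, g in enumerate(grid):
        ad = np.abs(x - g)
        sort = np.argsort(ad, kind="stable")
        cum = np.cumsum(w[sort])
        take = int(np.searchsorted(cum, span * total_w)) + 1
        take = min(max(take, 3), len(x))
        h = ad[sort[take - 1]]
        if h == 0:
            h = 1.0
        u = np.clip(ad / h, 0, 1)
        tw = w * (1 - u**3) ** 3
        use = tw > 0
        deg = 2 if use.sum() >= 3 else (1 if use.sum() == 2 else 0)
        xc = (x[use] - g) / h  # scale to [-1, 1] to keep the solve well-conditioned
        W = tw[use]
        A = np.vander(xc, deg + 1, increasing=True)
        Aw = A * W[:, None]
        coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y[use], rcond=None)
        fitted[k] = coef[0]
    return fitted


# ---------------------------------------------------------------------------
# background LD
# ---------------------------------------------------------------------------

@dataclass
class BldResult:
    replicate_means: np.ndarray
    bld: float
    n_reps: int
    n_snps_per_rep: int
    pair_cap: int
    seed: int
    mode: str = "replicate-means"


def _pair_r2(D, i, j):
    """Vectorised composite r² for index-pair arrays i, j (columns of D)."""
    x, y = D[:, i], D[:, j]
    valid = ~np.isnan(x) & ~np.isnan(y)
    xv = np.where(valid, x, 0.0)
    yv = np.where(valid, y, 0.0)
    n = valid.sum(axis=0).astype(float)
    return _r2_from_moments(
        n,
        xv.sum(axis=0),
        yv.sum(axis=0),
        (xv * yv).sum(axis=0),
        (xv * xv).sum(axis=0),
        (yv * yv).sum(axis=0),
    ), n


def background_ld(
    table: CohortTable,
    group: np.ndarray | None = None,
    n_reps: int = 1000,
    n_snps: int = 1000,
    seed: int = 0,
    pair_cap: int = 50_000,
    mode: str = "replicate-means",
) -> BldResult:
    """Bootstrap background LD from inter-chromosomal SNP pairs.

    Per replicate, ``n_snps`` SNPs are drawn without replacement
    genome-wide (all SNPs, with a warning, if fewer exist); r² is computed
    for up to ``pair_cap`` random pairs on different chromosomes and the
    replicate mean recorded.  ``mode='replicate-means'`` (default) reports
    the 97.5th percentile of the replicate means; ``mode='pooled'``
    reports the 97.5th percentile of the pooled pair r² values.
    """
    snps = table.biallelic_snps()
    chroms = snps.sites.chrom.to_numpy()
    if len(pd.unique(chroms)) < 2:
        raise ValueError(
            "background LD needs >= 2 chromosomes for unlinked pairs; "
            "use an inter-window fallback on single-chromosome data"
        )
    sub = snps if group is None else snps.take_samples(np.asarray(group))
    D = sub.dosage()
    S = D.shape[1]
    if S < n_snps:
        warnings.warn(f"only {S} SNPs available (< {n_snps}); using all in each replicate")
    rng = np.random.default_rng(seed)
    means = np.empty(n_reps)
    pooled = [] if mode == "pooled" else None
    for rep in range(n_reps):
        take = rng.choice(S, size=min(n_snps, S), replace=False)
        i, j = _sample_inter_chrom_pairs(chroms[take], pair_cap, rng)
        r2, _ = _pair_r2(D, take[i], take[j])
        r2 = r2[~np.isnan(r2)]
        means[rep] = r2.mean() if len(r2) else np.nan
        if pooled is not None:
            pooled.append(r2)
    if mode == "pooled":
        bld = float(np.percentile(np.concatenate(pooled), 97.5))
    else:
        bld = float(np.nanpercentile(means, 97.5))
    return BldResult(
        replicate_means=means,
        bld=bld,
        n_reps=n_reps,
        n_snps_per_rep=min(n_snps, S),
        pair_cap=pair_cap,
        seed=seed,
        mode=mode,
    )


def _sample_inter_chrom_pairs(chroms, cap, rng):
    """Random unordered pairs with members on different chromosomes."""
    m = len(chroms)
    _, codes = np.unique(chroms, return_inverse=True)
    counts = np.bincount(codes)
    total_inter = (m * (m - 1) - int(np.sum(counts * (counts - 1)))) // 2
    if total_inter <= cap:
        ii, jj = np.triu_indices(m, k=1)
        keep = codes[ii] != codes[jj]
        return ii[keep], jj[keep]
    out_i, out_j = [], []
    got = 0
    while got < cap:
        need = cap - got
        i = rng.integers(0, m, size=int(need * 1.5) + 16)
        j = rng.integers(0, m, size=len(i))
        keep = codes[i] != codes[j]
        i, j = i[keep][:need], j[keep][:need]
        out_i.append(i)
        out_j.append(j)
        got += len(i)
    return np.concatenate(out_i), np.concatenate(out_j)


# ---------------------------------------------------------------------------
# heterozygosity tracks
# ---------------------------------------------------------------------------

def observed_heterozygosity(
    table: CohortTable,
    chrom_lengths: dict[str, int],
    group: np.ndarray | None = None,
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-window fraction of called genotypes that are het / hom-alt."""
    sub = table if group is None else table.take_samples(np.asarray(group))
    het = sub.is_het()
    hom_alt = sub.is_hom_alt()
    called = ~sub.is_missing
    pos = sub.sites.pos.to_numpy()
    chroms = sub.sites.chrom.to_numpy()
    wins = make_windows(chrom_lengths, window)
    rows = []
    for w in wins.itertuples():
        in_w = (chroms == w.chrom) & (pos >= w.start) & (pos < w.end)
        n_called = int(called[:, in_w].sum())
        n_sites = int(in_w.sum())
        if n_called == 0:
            rows.append((w.chrom, w.start, w.end, "het_freq", np.nan, n_sites))
            rows.append((w.chrom, w.start, w.end, "homalt_freq", np.nan, n_sites))
        else:
            rows.append((w.chrom, w.start, w.end, "het_freq",
                         het[:, in_w].sum() / n_called, n_sites))
            rows.append((w.chrom, w.start, w.end, "homalt_freq",
                         hom_alt[:, in_w].sum() / n_called, n_sites))
    return window_stat_frame(rows)
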