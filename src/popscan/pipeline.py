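"""End-to-end orchestration: filter -> summaries -> diversity/LD -> distance
-> scans -> annotation, with deterministic, config-hashed outputs.

Window conventions follow the analysis defaults: 100 kb windows for SNP
counts, heterozygosity, diversity and effect tracks, 50 kb for LD, 1 kb
diversity windows for the distribution summaries; pairwise r² within
0.5 Mb; background LD from 1000 replicates of 1000 SNPs; gene scans at
Fst > 0.80 / Fst = 1.00 and the 99th diversity percentile; 5 kb flanks
for upstream/downstream annotation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, distance, diversity, io, qc, selection
from .model import CohortTable, make_windows, window_stat_frame


@dataclass
class PipelineConfig:
    vcf: str = ""
    gff3: str = ""
    fasta: str = ""
    meta: str = ""
    outdir: str = "popscan_out"
    filter: qc.FilterConfig = field(default_factory=qc.FilterConfig)
    pi_window_small: int = 1_000
    pi_window: int = 100_000
    ld_window: int = 50_000
    track_window: int = 100_000
    ld_max_dist: int = 500_000
    bld_reps: int = 1000
    bld_snps: int = 1000
    fst_threshold: float = 0.80
    pi_percentile: float = 99.0
    flank: int = 5_000
    seed: int = 0
    group_by: str = "subspecies"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _dump_json(obj, path, cfg_hash):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return None if np.isnan(o) else float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump({"config_hash": cfg_hash, **obj}, fh, indent=1, sort_keys=True, default=default)


def _ld_stage(table: CohortTable, group, chrom_lengths, cfg: PipelineConfig):
    """Stream LD per chromosome; reduce to window means, decay bins, summary."""
    snps = table.biallelic_snps()
    grid_step = 1000
    n_bins = cfg.ld_max_dist // grid_step + 1
    bin_sum = np.zeros(n_bins)
    bin_n = np.zeros(n_bins, dtype=np.int64)
    win_rows = []
    short_sum, short_n = 0.0, 0
    total_pairs = 0
    for chrom in chrom_lengths:
        sel = snps.sites.chrom.to_numpy() == chrom
        if not sel.any():
            continue
        sub = snps.take_sites(sel)
        pairs = diversity.pairwise_r2(sub, group=group, max_dist=cfg.ld_max_dist)
        total_pairs += len(pairs)
        if len(pairs):
            b = (pairs.distance.to_numpy() // grid_step).astype(np.int64)
            bin_sum += np.bincount(b, weights=pairs.r2.to_numpy(), minlength=n_bins)[:n_bins]
            bin_n += np.bincount(b, minlength=n_bins)[:n_bins]
            near = pairs.distance.to_numpy() <= 1000
            short_sum += float(pairs.r2.to_numpy()[near].sum())
            short_n += int(near.sum())
        win_rows.append(
            diversity.window_ld(pairs, {chrom: chrom_lengths[chrom]}, window=cfg.ld_window)
        )
        del pairs
    windows = (
        pd.concat(win_rows, ignore_index=True)
        if win_rows
        else window_stat_frame([])
    )
    nz = bin_n > 0
    centers = (np.arange(n_bins)[nz] + 0.5) * grid_step
    means = bin_sum[nz] / bin_n[nz]
    decay = None
    if nz.sum() >= 10 and total_pairs >= 50:
        grid = np.arange(0, cfg.ld_max_dist + grid_step, grid_step, dtype=float)
        fitted = diversity._local_quadratic(centers, means, bin_n[nz].astype(float), grid, 0.3)
        crossings = {}
        for t in (0.6, 0.4, 0.3):
            below = np.flatnonzero(fitted < t)
            crossings[str(t)] = float(grid[below[0]]) if len(below) else None
        decay = {"crossings": crossings, "r2_at_1kb": (short_sum / short_n) if short_n else None}
    return windows, decay, total_pairs


def _group_window_features(table, group, chrom_lengths, window):
    """Per-window SNP count (segregating sites carried by the group) and
    mean alternate-allele frequency, for the subspecies difference tracks."""
    sub = table.take_samples(group)
    carries = (sub.gt > 0).any(axis=2).any(axis=0)
    dose = sub.dosage()
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dose, axis=0) / 2.0
    pos = sub.sites.pos.to_numpy()
    chroms = sub.sites.chrom.to_numpy()
    wins = make_windows(chrom_lengths, window)
    rows_n, rows_f = [], []
    for w in wins.itertuples():
        in_w = (chroms == w.chrom) & (pos >= w.start) & (pos < w.end)
        n = int(in_w.sum())
        rows_n.append((w.chrom, w.start, w.end, "snp_count", float(carries[in_w].sum()), n))
        with np.errstate(invalid="ignore"):
            mean_f = float(np.nanmean(freq[in_w])) if n else np.nan
        rows_f.append((w.chrom, w.start, w.end, "alt_freq", mean_f, n))
    return window_stat_frame(rows_n), window_stat_frame(rows_f)


def _difference_track(track_a: pd.DataFrame, track_b: pd.DataFrame, stat: str) -> pd.DataFrame:
    m = track_a.merge(track_b, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
    return window_stat_frame(
        [
            (r.chrom, r.start, r.end, f"diff_{stat}", r.value_a - r.value_b,
             int(r.n_sites_a + r.n_sites_b))
            for r in m.itertuples()
        ]
    )


def run_all(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of output paths and key results."""
    out = Path(cfg.outdir)
    tracks = out / "tracks"
    tracks.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    log: list[dict] = []

    def stage(name, **counts):
        log.append({"stage": name, **counts})

    # ---- inputs --------------------------------------------------------
    meta = io.read_sample_meta(cfg.meta)
    table = io.read_vcf(cfg.vcf, meta)
    ref = io.read_fasta(cfg.fasta)
    genes = io.read_gff3(cfg.gff3)
    chrom_lengths = ref.chrom_lengths
    stage("read", sites=table.n_sites, samples=table.n_samples, genes=len(genes))

    # ---- filtering -----------------------------------------------------
    masked = qc.mask_genotypes(table, cfg.filter)
    filtered, report = qc.filter_sites(masked, cfg.filter)
    _dump_json(report.as_dict(), out / "filter_report.json", h)
    io.write_vcf(filtered, out / "filtered.vcf")
    stage("filter", **report.as_dict())

    # ---- per-accession summary (Table-1 style) -------------------------
    summary = qc.accession_summary(filtered)
    summary.to_csv(out / "table1_summary.tsv", sep="\t", index=False, float_format="%.6g")

    # ---- density tracks and tests --------------------------------------
    snp_wins, per_chrom = qc.snp_density_windows(filtered, chrom_lengths, cfg.track_window)
    gene_wins = qc.gene_density_windows(genes, chrom_lengths, cfg.track_window)
    io.write_track_table(snp_wins, tracks / "snp_count.tsv", h)
    io.write_track_table(gene_wins, tracks / "gene_count.tsv", h)
    homogeneity = qc.density_homogeneity_test(snp_wins)
    try:
        regression = qc.gene_snp_density_regression(snp_wins, gene_wins)
    except ValueError:
        regression = None
    stage("density", windows=len(snp_wins))

    groups = filtered.group_indices(cfg.group_by)
    group_names = sorted(groups)

    # ---- diversity -----------------------------------------------------
    pi_tracks = {"all": diversity.window_pi(filtered, chrom_lengths, window=cfg.pi_window)}
    pi_small = {"all": diversity.window_pi(filtered, chrom_lengths, window=cfg.pi_window_small)}
    for name in group_names:
        pi_tracks[name] = diversity.window_pi(
            filtered, chrom_lengths, group=groups[name], window=cfg.pi_window
        )
        pi_small[name] = diversity.window_pi(
            filtered, chrom_lengths, group=groups[name], window=cfg.pi_window_small
        )
    for name, tr in pi_tracks.items():
        io.write_track_table(tr, tracks / f"pi_{name}.tsv", h)
    het_tracks = diversity.observed_heterozygosity(filtered, chrom_lengths, window=cfg.track_window)
    io.write_track_table(het_tracks, tracks / "het_homalt.tsv", h)
    pi_summary = {
        name: {
            "mean_pi_small_windows": float(t.value.mean()),
            "median_pi_small_windows": float(t.value.median()),
        }
        for name, t in pi_small.items()
    }
    stage("diversity", groups=len(pi_tracks))

    # ---- LD ------------------------------------------------------------
    ld_summary, ld_windows = {}, {}
    for name in ["all"] + group_names:
        grp = None if name == "all" else groups[name]
        wins, decay, n_pairs = _ld_stage(filtered, grp, chrom_lengths, cfg)
        ld_windows[name] = wins
        io.write_track_table(wins, tracks / f"ld_{name}.tsv", h)
        entry = {"n_pairs": n_pairs, "decay": decay}
        try:
            bld = diversity.background_ld(
                filtered, group=grp, n_reps=cfg.bld_reps, n_snps=cfg.bld_snps, seed=cfg.seed
            )
            entry["bld"] = bld.bld
        except ValueError as exc:
            entry["bld"] = None
            entry["bld_error"] = str(exc)
        ld_summary[name] = entry
    stage("ld", groups=len(ld_summary))

    # ---- distance and tree ---------------------------------------------
    dm = distance.distance_matrix(filtered)
    io.write_distance_nexus(dm.labels, dm.d, out / "dist.nexus")
    io.write_distance_phylip(dm.labels, dm.d, out / "dist.phy")
    newick = distance.nj_tree(dm) if len(dm.labels) >= 3 else None
    if newick:
        (out / "tree.nwk").write_text(newick + "\n")
    stage("distance", pairs=len(dm.labels) * (len(dm.labels) - 1) // 2)

    # ---- gene scans -----------------------------------------------------
    scan_report: dict = {}
    if len(groups) == 2:
        gstats = selection.gene_stats(filtered, genes, groups)
        gstats.to_csv(out / "gene_stats.tsv", sep="\t", index=False, float_format="%.6g", na_rep="NA")
        scan_report["fst_scan"] = selection.candidate_fst_scan(gstats, cfg.fst_threshold)
        scan_report["high_diversity_scan"] = selection.high_diversity_scan(gstats, cfg.pi_percentile)
        # windowed Fst track
        snps = filtered.biallelic_snps()
        (n1, g1), (n2, g2) = sorted(groups.items())
        comp = selection.wc_fst_site(snps, g1, g2)
        wins = make_windows(chrom_lengths, cfg.track_window)
        fst_win = selection.fst_aggregate(comp, wins)
        fst_track = window_stat_frame(
            [
                (r.chrom, r.start, r.end, "fst", r.theta, r.n_sites)
                for r in fst_win.itertuples()
            ]
        )
        io.write_track_table(fst_track, tracks / "fst_windows.tsv", h)
        stage("scan", genes=len(gstats))

    # ---- annotation -----------------------------------------------------
    effects, ann_summary = annotation.annotate_variants(
        filtered, genes, ref, flank=cfg.flank, group_by=cfg.group_by
    )
    effects.to_csv(out / "effects.tsv", sep="\t", index=False, na_rep="NA")
    gene_sets = annotation.gene_set_comparisons(filtered, effects, group_by=cfg.group_by)
    morpho_sets = annotation.gene_set_comparisons(filtered, effects, group_by="morphotype")
    _dump_json(
        {**ann_summary, "gene_sets": gene_sets, "gene_sets_morphotype": morpho_sets},
        out / "annotation_summary.json",
        h,
    )
    # HIGH / MODERATE impact tracks
    for tier in ("HIGH", "MODERATE"):
        sel_idx = set(effects.site_index[effects.impact == tier])
        in_tier = filtered.sites.index.isin(sel_idx)
        pos = filtered.sites.pos.to_numpy()
        chroms = filtered.sites.chrom.to_numpy()
        rows = []
        for w in make_windows(chrom_lengths, cfg.track_window).itertuples():
            sel = (chroms == w.chrom) & (pos >= w.start) & (pos < w.end) & in_tier
            rows.append((w.chrom, w.start, w.end, f"{tier.lower()}_ct", float(sel.sum()), int(sel.sum())))
        io.write_track_table(window_stat_frame(rows), tracks / f"impact_{tier.lower()}.tsv", h)
    stage("annotate", records=len(effects))

    # ---- subspecies difference tracks (pepo minus ovifera order: a - b
    # with groups sorted descending so 'pepo' - 'ovifera' when present) ---
    if len(groups) == 2:
        name_a, name_b = sorted(groups, reverse=True)
        snp_a, freq_a = _group_window_features(filtered, groups[name_a], chrom_lengths, cfg.track_window)
        snp_b, freq_b = _group_window_features(filtered, groups[name_b], chrom_lengths, cfg.track_window)
        io.write_track_table(_difference_track(snp_a, snp_b, "snp_count"), tracks / "diff_snp_count.tsv", h)
        io.write_track_table(_difference_track(freq_a, freq_b, "alt_freq"), tracks / "diff_alt_freq.tsv", h)
        io.write_track_table(
            _difference_track(pi_tracks[name_a], pi_tracks[name_b], "pi"), tracks / "diff_pi.tsv", h
        )
        if len(ld_windows.get(name_a, [])) and len(ld_windows.get(name_b, [])):
            io.write_track_table(
                _difference_track(ld_windows[name_a], ld_windows[name_b], "ld"),
                tracks / "diff_ld.tsv", h,
            )

    # ---- reports ---------------------------------------------------------
    _dump_json(
        {
            "seed": cfg.seed,
            "groups": group_names,
            "filter": report.as_dict(),
            "density_homogeneity": homogeneity.to_dict(orient="records"),
            "gene_snp_regression": regression,
            "pi": pi_summary,
            "ld": ld_summary,
            **scan_report,
        },
        out / "scan_report.json",
        h,
    )
    _dump_json(
        {"version": __version__, "stages": log, "config": asdict(cfg)},
        out / "run_log.json",
        h,
    )
    return {
        "outdir": str(out),
        "filter_report": report,
        "accession_summary": summary,
        "scan_report": scan_report,
        "ld_summary": ld_summary,
        "annotation_summary": ann_summary,
        "config_hash": h,
    }
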