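"""Readers and writers for the standard formats at the pipeline boundary.

VCF is read with cyvcf2 and written as plain text (gzip when the path ends
in ``.gz``); FASTA is read with pyfaidx; GFF3 with gffutils.  Distance
matrices are exported as a NEXUS DISTANCES block (SplitsTree input) and as
a square PHYLIP matrix.  Window statistics go out as BED-style TSV tracks.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import MISSING, CohortTable, GeneModel, SampleMeta, derive_utrs, make_sites_frame

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Malformed input file."""


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path) -> list[SampleMeta]:
    """TSV with columns accession, morphotype, subspecies[, pool_size]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"accession", "morphotype", "subspecies"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample metadata needs columns {sorted(required)}")
    pool = df["pool_size"] if "pool_size" in df.columns else [5] * len(df)
    return [
        SampleMeta(str(a), str(m), str(s), int(p))
        for a, m, s, p in zip(df.accession, df.morphotype, df.subspecies, pool)
    ]


def write_sample_meta(samples: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        [(s.accession, s.morphotype, s.subspecies, s.pool_size) for s in samples],
        columns=["accession", "morphotype", "subspecies", "pool_size"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, meta: Sequence[SampleMeta]) -> CohortTable:
    """Load a multi-sample VCF into a CohortTable for the accessions in ``meta``.

    Per-chromosome record order is restored by sorting on position.  Missing
    DP/GQ FORMAT fields are stored as 0 and flagged so the depth/quality
    mask can be disabled downstream.  Multi-allelic records are retained
    (site filtering happens later).
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    vcf_samples = list(vcf.samples)
    missing_samples = [s.accession for s in meta if s.accession not in vcf_samples]
    if missing_samples:
        raise ConfigurationError(f"samples in metadata absent from VCF: {missing_samples}")
    col = np.array([vcf_samples.index(s.accession) for s in meta])

    records, gts, dps, gqs = [], [], [], []
    has_dp = has_gq = True
    for var in vcf:
        records.append((var.CHROM, var.POS - 1, var.REF, tuple(var.ALT)))
        g = np.asarray(var.genotype.array())[:, :2]
        g = np.where(g < 0, MISSING, g)
        gts.append(g[col].astype(np.int8))
        dp = var.format("DP")
        if dp is None:
            has_dp = False
            dps.append(np.zeros(len(col), dtype=np.int32))
        else:
            dps.append(np.where(dp[col, 0] < 0, 0, dp[col, 0]).astype(np.int32))
        gq = var.format("GQ")
        if gq is None:
            has_gq = False
            gqs.append(np.zeros(len(col), dtype=np.int32))
        else:
            gqs.append(np.where(gq[col, 0] < 0, 0, gq[col, 0]).astype(np.int32))
    vcf.close()

    sites = make_sites_frame(records)
    gt = (
        np.stack(gts, axis=1) if gts else np.zeros((len(meta), 0, 2), dtype=np.int8)
    )
    dp = np.stack(dps, axis=1) if dps else np.zeros((len(meta), 0), dtype=np.int32)
    gq = np.stack(gqs, axis=1) if gqs else np.zeros((len(meta), 0), dtype=np.int32)
    # half-calls (one allele set) are demoted to fully missing
    half = (gt == MISSING).sum(axis=2) == 1
    gt[half] = MISSING

    order = np.lexsort((sites.pos.to_numpy(), sites.chrom.to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    if not has_dp:
        warnings.warn("DP absent from VCF; depth mask will be disabled")
    if not has_gq:
        warnings.warn("GQ absent from VCF; quality mask will be disabled")
    return CohortTable(
        sites=sites,
        gt=gt[:, order, :],
        dp=dp[:, order],
        gq=gq[:, order],
        samples=list(meta),
        has_dp=has_dp,
        has_gq=has_gq,
    )


def write_vcf(table: CohortTable, path) -> None:
    """Emit the cohort as VCF v4.2 with GT:DP:GQ (gzip if path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in table.sites.chrom.unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_names)
            + "\n"
        )
        gt, dp, gq = table.gt, table.dp, table.gq
        for j, row in enumerate(table.sites.itertuples()):
            calls = []
            for i in range(table.n_samples):
                a, b = gt[i, j]
                g = "./." if a == MISSING else f"{a}/{b}"
                calls.append(f"{g}:{dp[i, j]}:{gq[i, j]}")
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{','.join(row.alts) or '.'}"
                f"\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[GeneModel]:
    """One GeneModel per gene (longest-CDS mRNA when several), sorted by position."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    # orphan CDS check
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="mRNA"))
        if not parents:
            raise FormatError(f"CDS {cds.id} has no parent mRNA")

    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        best, best_len = None, -1
        for m in mrnas:
            clen = sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))
            if clen > best_len:
                best, best_len = m, clen
        if best is None:
            continue
        if len(mrnas) > 1:
            warnings.warn(f"gene {gene.id}: {len(mrnas)} mRNAs, keeping longest CDS")
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(best, featuretype="exon")
        )
        cds = sorted((c.start - 1, c.end) for c in db.children(best, featuretype="CDS"))
        if not exons and cds:
            exons = list(cds)
        gm = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,
            end=gene.end,
            exons=exons,
            cds=cds,
        )
        if gm.is_coding and gm.cds_len % 3 != 0:
            warnings.warn(f"gene {gene.id}: CDS length {gm.cds_len} not divisible by 3")
        genes.append(gm)
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3(genes: Sequence[GeneModel], path, chrom_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpopscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tpopscan\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tpopscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{k};Parent={mrna_id}\n"
                )
            for k, (s, e) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tpopscan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna_id}.cds{k};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class ReferenceGenome:
    """Upper-cased chromosome sequences with 0-based half-open fetch."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = {k: v.upper() for k, v in seqs.items()}

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"fetch {chrom}:{start}-{end} outside [0, {len(seq)})")
        return seq[start:end]

    def __contains__(self, chrom):
        return chrom in self.seqs


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> ReferenceGenome:
    from pyfaidx import Fasta

    try:
        fa = Fasta(str(path), duplicate_action="stop", rebuild=True)
    except Exception as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    return ReferenceGenome({name: str(fa[name][:]) for name in fa.keys()})


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def _check_square(labels, d, atol=1e-9):
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
    if np.max(np.abs(d - d.T)) > atol:
        raise ValueError("distance matrix asymmetric beyond 1e-9")
    return d


def _nexus_label(label: str) -> str:
    return f"'{label}'" if any(c.isspace() for c in label) else label


def write_distance_nexus(labels: Sequence[str], d, path) -> None:
    """NEXUS DISTANCES block (triangle=both, labels=left), SplitsTree-ready."""
    d = _check_square(labels, d)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={len(labels)};\nTAXLABELS\n")
        for i, lab in enumerate(labels, 1):
            fh.write(f"[{i}] {_nexus_label(lab)}\n")
        fh.write(";\nEND;\n\nBEGIN Distances;\n")
        fh.write(f"DIMENSIONS ntax={len(labels)};\n")
        fh.write("FORMAT labels=left diagonal triangle=both;\nMATRIX\n")
        for i, lab in enumerate(labels):
            row = " ".join(f"{x:.10g}" for x in d[i])
            fh.write(f"{_nexus_label(lab)} {row}\n")
        fh.write(";\nEND;\n")


def read_distance_nexus(path) -> tuple[list[str], np.ndarray]:
    """Read back the DISTANCES block written by :func:`write_distance_nexus`."""
    text = Path(path).read_text()
    lines = text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.strip() == "MATRIX")
    except StopIteration as exc:
        raise FormatError("no MATRIX line in NEXUS file") from exc
    labels, rows = [], []
    for line in lines[start + 1 :]:
        line = line.strip()
        if line == ";" or line.startswith("END"):
            break
        if line.startswith("'"):
            close = line.index("'", 1)
            labels.append(line[1:close])
            rest = line[close + 1 :]
        else:
            lab, _, rest = line.partition(" ")
            labels.append(lab)
        rows.append([float(x) for x in rest.split()])
    return labels, np.array(rows)


def write_distance_phylip(labels: Sequence[str], d, path) -> None:
    d = _check_square(labels, d)
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for i, lab in enumerate(labels):
            fh.write(f"{lab[:10]:<10} " + " ".join(f"{x:.10g}" for x in d[i]) + "\n")


# ---------------------------------------------------------------------------
# window-stat tracks
# ---------------------------------------------------------------------------

def write_track_table(stats: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """TSV track: chrom, start, end, stat, value, n_sites (NaN -> "NA")."""
    cols = ["chrom", "start", "end", "stat", "value", "n_sites"]
    df = stats[cols] if len(stats) else pd.DataFrame(columns=cols)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_track_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
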