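"""Synthetic two-subspecies cohort generator with machine-readable truth.

The generator emulates the statistical structure the analysis assumes:
eight pooled accessions (five subspecies *pepo*, three *ovifera*, each a
pool of five plants), Balding-Nichols differentiation between and within
subspecies, haplotype-block LD with tunable decay, per-call depth and
quality, missingness, and planted features with known truth (tri-allelic
sites, high-missingness sites, fixed-difference genes, high-diversity
genes, private HIGH/MODERATE effect variants).

A small Hudson coalescent sampler (neutral, no recombination, infinite
sites) provides null site-frequency spectra for Tajima's D.

All randomness flows from one root seed through labelled child streams,
so adding a component never perturbs another's stream, and a fixed seed
gives byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .annotation import GENETIC_CODE
from .model import MISSING, CohortTable, GeneModel, SampleMeta, make_sites_frame

STOP_CODONS = {"TAA", "TAG", "TGA"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream for one component, derived from (seed, label)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def default_samples() -> list[SampleMeta]:
    """The eight-accession cohort: 5 subspecies pepo + 3 subspecies ovifera."""
    spec = [
        ("Pumpkin", "Pumpkin", "pepo"),
        ("Marrow", "Vegetable_Marrow", "pepo"),
        ("Cocozelle", "Cocozelle", "pepo"),
        ("Zucchini_yellow", "Zucchini", "pepo"),
        ("Zucchini_green", "Zucchini", "pepo"),
        ("Acorn", "Acorn", "ovifera"),
        ("Crookneck", "Crookneck", "ovifera"),
        ("Scallop", "Scallop", "ovifera"),
    ]
    return [SampleMeta(a, m, s, 5) for a, m, s in spec]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 4
    chrom_len: int = 1_000_000
    n_sites: int = 20_000
    genes_per_chrom: int = 50  # 1 gene / 20 kb: flanked genes plus real intergenic space
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    F_subspecies: float = 0.3
    F_morphotype: float = 0.1
    block_len: int = 20_000
    recomb_between_blocks: float = 0.5
    indel_frac: float = 0.2
    ts_fraction: float = 0.62  # transition probability per SNP: Ts/Tv ~ 1.6
    genic_thinning: float = 0.6
    samples: list[SampleMeta] = field(default_factory=default_samples)
    depth_mean: float = 33.0
    depth_dispersion: float = 8.0
    gq_mean: float = 60.0
    gq_sd: float = 15.0
    missing_rate: float = 0.02
    pool_het_min: float = 0.15
    n_triallelic: int = 120
    n_high_missing: int = 300
    n_fixed_diff_genes: int = 40
    n_high_pi_genes: int = 10
    high_pi_subspecies: str = "pepo"
    sites_per_high_pi_gene: int = 40
    private_high_per_accession: int = 1
    private_moderate_per_accession: int = 2
    private_high_per_subspecies: int = 1  # planted as a frameshift deletion
    private_moderate_per_subspecies: int = 1

    def __post_init__(self):
        for f in (self.F_subspecies, self.F_morphotype):
            if not 0 < f < 1:
                raise ValueError("F parameters must lie strictly in (0, 1)")
        if self.n_chrom < 2:
            raise ValueError("need >= 2 chromosomes (background LD requires unlinked pairs)")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chrom)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_len for c in self.chrom_names}


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------

def balding_nichols_freqs(p_anc, F: float, rng: np.random.Generator, size=None):
    """Population allele frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    p_anc = np.asarray(p_anc, dtype=float)
    scale = (1.0 - F) / F
    inner = np.clip(p_anc, 1e-12, 1.0 - 1e-12)
    draw = rng.beta(inner * scale, (1.0 - inner) * scale, size=size)
    # alleles already fixed stay fixed (Beta is undefined at p in {0, 1})
    return np.where(p_anc <= 0.0, 0.0, np.where(p_anc >= 1.0, 1.0, draw))


def simulate_haplotypes(
    freqs: np.ndarray,
    block_of_site: np.ndarray,
    n_haplotypes: int,
    recomb_between_blocks: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Block-copying haplotypes: sites in a block share one latent uniform.

    Each haplotype carries one uniform u per block; the alternate allele is
    present at site s iff u_block(s) < freqs[s], so frequency-matched
    sites within a block are perfectly correlated.  At each block boundary
    the uniform is redrawn with probability ``recomb_between_blocks``,
    giving geometric LD decay at block scale.
    """
    n_blocks = int(block_of_site.max()) + 1 if len(block_of_site) else 0
    u = np.empty((n_haplotypes, n_blocks))
    if n_blocks:
        u[:, 0] = rng.random(n_haplotypes)
        for b in range(1, n_blocks):
            switch = rng.random(n_haplotypes) < recomb_between_blocks
            u[:, b] = np.where(switch, rng.random(n_haplotypes), u[:, b - 1])
    return (u[:, block_of_site] < freqs[None, :]).astype(np.int8)


def pool_plants_to_accession(plant_alleles: np.ndarray, pool_het_min: float = 0.15):
    """Collapse pooled plant haplotypes into one diploid call per site.

    ``plant_alleles`` has shape (2 * pool_size, n_sites) with 0/1 alleles.
    The pooled alternate fraction f maps to hom-ref (f < pool_het_min),
    hom-alt (f > 1 - pool_het_min) or het, emulating the excess apparent
    heterozygosity of pooled calling.  Returns (codes in {0,1,2}, f).
    """
    f = plant_alleles.mean(axis=0)
    code = np.ones(plant_alleles.shape[1], dtype=np.int8)  # het
    code[f < pool_het_min] = 0
    code[f > 1.0 - pool_het_min] = 2
    return code, f


def hudson_coalescent(n: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Neutral coalescent (no recombination), infinite-sites mutations.

    Returns the derived-allele count of each segregating site in a sample
    of ``n`` sequences; E[S] = theta * a1(n).
    """
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    sizes = [1] * n
    counts: list[int] = []
    k = n
    while k > 1:
        dt = rng.exponential(2.0 / (k * (k - 1)))
        n_mut = rng.poisson(theta / 2.0 * dt, size=k)
        for lineage, m in enumerate(n_mut):
            counts.extend([sizes[lineage]] * int(m))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = min(i, j), max(i, j)
        sizes[i] += sizes.pop(j)
        k -= 1
    return np.array(counts, dtype=np.int64)


def balding_nichols_cohort(
    n_diploids: int,
    n_sites: int,
    F: float,
    seed: int,
    n_pops: int = 2,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> CohortTable:
    """Two(+) HWE populations with Balding-Nichols differentiation.

    Individuals draw alleles independently from their population frequency
    (random mating); used to check Weir-Cockerham recovery of the true F.
    Sites are spread over two synthetic chromosomes.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(*freq_range, size=n_sites)
    samples, gts = [], []
    for p in range(n_pops):
        pf = balding_nichols_freqs(p_anc, F, rng) if F > 1e-9 else p_anc
        alleles = (rng.random((n_diploids, n_sites, 2)) < pf[None, :, None]).astype(np.int8)
        gts.append(alleles)
        samples.extend(
            SampleMeta(f"pop{p + 1}_{i:03d}", f"pop{p + 1}", f"pop{p + 1}")
            for i in range(n_diploids)
        )
    gt = np.concatenate(gts, axis=0)
    half = n_sites // 2
    recs = [("chr01" if j < half else "chr02", j * 10, "A", ("T",)) for j in range(n_sites)]
    sites = make_sites_frame(recs)
    shape = (len(samples), n_sites)
    return CohortTable(
        sites=sites,
        gt=gt,
        dp=np.full(shape, 30, dtype=np.int32),
        gq=np.full(shape, 99, dtype=np.int32),
        samples=samples,
        masked=True,
    )


# ---------------------------------------------------------------------------
# gene models and reference
# ---------------------------------------------------------------------------

# relative gene template (length 1400): UTR5 200 | CDS 100 | intron 200 |
# CDS 300 | intron 200 | CDS 200 | UTR3 200; CDS total 600 (divisible by 3)
_TEMPLATE_LEN = 1400
_TEMPLATE_EXONS = [(0, 300), (500, 800), (1000, 1400)]
_TEMPLATE_CDS_PLUS = [(200, 300), (500, 800), (1000, 1200)]
_TEMPLATE_CDS_MINUS = [(200, 400), (600, 900), (1100, 1200)]
_TEMPLATE_EXONS_MINUS = [(0, 400), (600, 900), (1100, 1400)]


def _tile_genes(cfg: SimulationConfig) -> list[GeneModel]:
    genes = []
    slot = cfg.chrom_len // cfg.genes_per_chrom
    if slot < _TEMPLATE_LEN + 200:
        raise ValueError("chromosome too short for the requested gene count")
    offset = (slot - _TEMPLATE_LEN) // 2
    for ci, chrom in enumerate(cfg.chrom_names):
        for k in range(cfg.genes_per_chrom):
            base = k * slot + offset
            strand = "+" if (k % 2 == 0) else "-"
            exons = _TEMPLATE_EXONS if strand == "+" else _TEMPLATE_EXONS_MINUS
            cds = _TEMPLATE_CDS_PLUS if strand == "+" else _TEMPLATE_CDS_MINUS
            genes.append(
                GeneModel(
                    gene_id=f"{chrom}_g{k:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=base,
                    end=base + _TEMPLATE_LEN,
                    exons=[(base + s, base + e) for s, e in exons],
                    cds=[(base + s, base + e) for s, e in cds],
                )
            )
    return genes


def _cds_layout(gene: GeneModel):
    ivs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    offsets = np.cumsum([0] + [e - s for s, e in ivs])
    return ivs, offsets


def _codon_genome_positions(gene: GeneModel, codon_idx: int) -> list[int]:
    """Genome positions of the three codon bases, in coding-strand order."""
    ivs, offsets = _cds_layout(gene)
    out = []
    for off in range(3 * codon_idx, 3 * codon_idx + 3):
        for (s, e), o0 in zip(ivs, offsets):
            if o0 <= off < o0 + (e - s):
                out.append(s + (off - o0) if gene.strand == "+" else e - 1 - (off - o0))
                break
    return out

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _write_codon(seq: np.ndarray, gene: GeneModel, codon_idx: int, codon: str) -> None:
    for pos, base in zip(_codon_genome_positions(gene, codon_idx), codon):
        seq[pos] = base if gene.strand == "+" else _COMP[base]


def _scrub_cds(seq_by_chrom: dict[str, np.ndarray], genes: list[GeneModel]) -> None:
    """Give every CDS an ATG start, a TAA stop, and no internal stops."""
    for g in genes:
        seq = seq_by_chrom[g.chrom]
        n_codons = g.cds_len // 3
        _write_codon(seq, g, 0, "ATG")
        _write_codon(seq, g, n_codons - 1, "TAA")
        for k in range(1, n_codons - 1):
            positions = _codon_genome_positions(g, k)
            codon = "".join(
                seq[p] if g.strand == "+" else _COMP[seq[p]] for p in positions
            )
            if codon in STOP_CODONS:
                _write_codon(seq, g, k, "CTG")


# ---------------------------------------------------------------------------
# the cohort generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SimulationConfig
    reference: "pio.ReferenceGenome"
    genes: list[GeneModel]
    table: CohortTable
    truth: dict


def _plan_effects(cfg: SimulationConfig, genes_pool: list[GeneModel], seq_by_chrom, rng):
    """Rewrite reference codons and plan private effect variants.

    Returns a list of planned variant dicts (position, ref/alt on the plus
    strand, effect, impact, carrier group).  Each effect lives in its own
    gene, codon 5 (stop/missense) or a mid-CDS 2-bp window (frameshift).
    """
    plans = []
    pool = iter(genes_pool)
    groups: list[tuple[str, str, str]] = []  # (group_by, group, kind)
    for s in cfg.samples:
        groups += [("accession", s.accession, "stop")] * cfg.private_high_per_accession
        groups += [("accession", s.accession, "missense")] * cfg.private_moderate_per_accession
    for sub in sorted({s.subspecies for s in cfg.samples}):
        groups += [("subspecies", sub, "frameshift")] * cfg.private_high_per_subspecies
        groups += [("subspecies", sub, "missense")] * cfg.private_moderate_per_subspecies

    for group_by, group, kind in groups:
        gene = next(pool, None)
        if gene is None:
            raise ValueError(
                "not enough unplanted genes for the requested private effects; "
                "increase genes_per_chrom or reduce planted gene counts"
            )
        seq = seq_by_chrom[gene.chrom]
        if kind == "frameshift":
            # 1-bp deletion anchored inside the middle CDS interval
            s, e = gene.cds[len(gene.cds) // 2]
            pos = (s + e) // 2
            ref = seq[pos] + seq[pos + 1]
            plans.append(
                dict(chrom=gene.chrom, pos=pos, ref=ref, alt=ref[0], gene_id=gene.gene_id,
                     effect="frameshift_variant", impact="HIGH",
                     group_by=group_by, group=group)
            )
            continue
        codon_idx = 5
        if kind == "stop":
            _write_codon(seq, gene, codon_idx, "TAC")
            coding_ref, coding_alt, base_k = "C", "G", 2   # TAC -> TAG (*)
            effect, impact = "stop_gained", "HIGH"
        else:
            _write_codon(seq, gene, codon_idx, "GAA")
            coding_ref, coding_alt, base_k = "A", "T", 1   # GAA (E) -> GTA (V)
            effect, impact = "missense_variant", "MODERATE"
        pos = _codon_genome_positions(gene, codon_idx)[base_k]
        if gene.strand == "-":
            coding_ref, coding_alt = _COMP[coding_ref], _COMP[coding_alt]
        plans.append(
            dict(chrom=gene.chrom, pos=pos, ref=coding_ref, alt=coding_alt,
                 gene_id=gene.gene_id, effect=effect, impact=impact,
                 group_by=group_by, group=group)
        )
    return plans


def _sample_positions(cfg, chrom, n, genic_mask, used, rng):
    """Distinct positions with genic thinning, avoiding ``used``."""
    weights = np.where(genic_mask, cfg.genic_thinning, 1.0)
    weights[list(used)] = 0.0
    weights[-2:] = 0.0  # leave room for indel REF anchors
    weights /= weights.sum()
    chosen: list[int] = []
    seen = set(used)
    while len(chosen) < n:
        cand = rng.choice(cfg.chrom_len, size=2 * (n - len(chosen)) + 16, p=weights)
        for p in cand:
            if p not in seen:
                seen.add(int(p))
                chosen.append(int(p))
                if len(chosen) == n:
                    break
    return sorted(chosen)


def generate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Build the synthetic cohort in memory (see :func:`emit_cohort` for files)."""
    samples = cfg.samples
    n_acc = len(samples)
    subspecies = sorted({s.subspecies for s in samples})
    if len(subspecies) != 2:
        raise ValueError("the generator expects exactly two subspecies")

    # --- reference and gene models ------------------------------------
    genes = _tile_genes(cfg)
    rng_ref = child_rng(cfg.seed, "reference")
    seq_by_chrom = {
        c: rng_ref.choice(np.array(list("ACGT")), size=cfg.chrom_len)
        for c in cfg.chrom_names
    }
    _scrub_cds(seq_by_chrom, genes)

    # --- planted gene classes -----------------------------------------
    rng_pick = child_rng(cfg.seed, "planted-genes")
    order = rng_pick.permutation(len(genes))
    fixed_ids = [genes[i].gene_id for i in order[: cfg.n_fixed_diff_genes]]
    hp_lo = cfg.n_fixed_diff_genes
    high_pi_ids = [genes[i].gene_id for i in order[hp_lo : hp_lo + cfg.n_high_pi_genes]]
    effect_pool = [genes[i] for i in order[hp_lo + cfg.n_high_pi_genes :]]
    gene_by_id = {g.gene_id: g for g in genes}

    effect_plans = _plan_effects(cfg, effect_pool, seq_by_chrom, rng_pick)

    # --- site positions ------------------------------------------------
    rng_pos = child_rng(cfg.seed, "positions")
    sites_by_chrom: dict[str, dict[int, dict]] = {c: {} for c in cfg.chrom_names}
    for plan in effect_plans:
        sites_by_chrom[plan["chrom"]][plan["pos"]] = dict(kind="effect", plan=plan)
    for gid in fixed_ids:
        g = gene_by_id[gid]
        for off in (350, 400, 450):  # intron 1 of the template
            sites_by_chrom[g.chrom].setdefault(g.start + off, dict(kind="fixed", gene=gid))
    for gid in high_pi_ids:
        g = gene_by_id[gid]
        offs = np.linspace(10, g.end - g.start - 10, cfg.sites_per_high_pi_gene).astype(int)
        for off in np.unique(offs):
            sites_by_chrom[g.chrom].setdefault(g.start + int(off), dict(kind="high_pi", gene=gid))

    n_placed = sum(len(v) for v in sites_by_chrom.values())
    n_random = max(cfg.n_sites - n_placed, 0)
    per_chrom = np.full(cfg.n_chrom, n_random // cfg.n_chrom)
    per_chrom[: n_random % cfg.n_chrom] += 1
    for chrom, n_c in zip(cfg.chrom_names, per_chrom):
        genic = np.zeros(cfg.chrom_len, dtype=bool)
        for g in genes:
            if g.chrom == chrom:
                genic[g.start : g.end] = True
        pos = _sample_positions(cfg, chrom, int(n_c), genic, set(sites_by_chrom[chrom]), rng_pos)
        for p in pos:
            sites_by_chrom[chrom][p] = dict(kind="random")

    # planted gene spans capture every random site that fell inside them
    for chrom in cfg.chrom_names:
        for p, info in sites_by_chrom[chrom].items():
            if info["kind"] != "random":
                continue
            for gid in fixed_ids + high_pi_ids:
                g = gene_by_id[gid]
                if g.chrom == chrom and g.start <= p < g.end:
                    info.update(kind="fixed" if gid in fixed_ids else "high_pi", gene=gid)
                    break

    # --- alleles --------------------------------------------------------
    rng_allele = child_rng(cfg.seed, "alleles")
    records = []  # (chrom, pos, ref, alts, kind, payload)
    for chrom in cfg.chrom_names:
        seq = seq_by_chrom[chrom]
        for p in sorted(sites_by_chrom[chrom]):
            info = sites_by_chrom[chrom][p]
            kind = info["kind"]
            if kind == "effect":
                plan = info["plan"]
                records.append((chrom, p, plan["ref"], (plan["alt"],), kind, plan))
                continue
            ref = seq[p]
            if kind == "random" and rng_allele.random() < cfg.indel_frac:
                if rng_allele.random() < 0.5:
                    records.append((chrom, p, ref + seq[p + 1], (ref,), "random", None))
                else:
                    ins = rng_allele.choice(list("ACGT"))
                    records.append((chrom, p, ref, (ref + ins,), "random", None))
            else:
                if rng_allele.random() < cfg.ts_fraction:
                    alt = _TRANSITION[ref]
                else:
                    tv = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
                    alt = tv[rng_allele.integers(0, 2)]
                records.append((chrom, p, ref, (alt,), kind, info.get("gene")))

    sites = make_sites_frame([(c, p, r, a) for c, p, r, a, _, _ in records])
    kinds = np.array([k for *_, k, _ in records])
    payloads = [pl for *_, pl in records]
    S = len(sites)
    is_snp_1alt = sites.is_snp.to_numpy() & (sites.alts.map(len) == 1).to_numpy()

    # tri-allelic planting: random SNP sites outside planted genes
    rng_tri = child_rng(cfg.seed, "triallelic")
    cand = np.flatnonzero((kinds == "random") & is_snp_1alt)
    tri_idx = np.sort(rng_tri.choice(cand, size=min(cfg.n_triallelic, len(cand)), replace=False))
    alts_col = sites.alts.tolist()
    for j in tri_idx:
        ref, (alt1,) = sites.ref.iat[j], alts_col[j]
        extra = next(b for b in "ACGT" if b not in (ref, alt1))
        alts_col[j] = (alt1, extra)
    sites = sites.assign(alts=alts_col, is_snp=[
        len(r) == 1 and all(len(a) == 1 for a in al) for r, al in zip(sites.ref, alts_col)
    ])
    sites = sites.assign(is_indel=~sites.is_snp)

    # --- frequencies and haplotypes ------------------------------------
    rng_freq = child_rng(cfg.seed, "frequencies")
    p_anc = rng_freq.uniform(*cfg.ancestral_freq_range, size=S)
    sub_freq = {s: balding_nichols_freqs(p_anc, cfg.F_subspecies, rng_freq) for s in subspecies}
    acc_freq = {
        s.accession: balding_nichols_freqs(sub_freq[s.subspecies], cfg.F_morphotype, rng_freq)
        for s in samples
    }

    chrom_arr = sites.chrom.to_numpy()
    pos_arr = sites.pos.to_numpy()
    block = (pos_arr // cfg.block_len).astype(np.int64)

    codes = np.zeros((n_acc, S), dtype=np.int8)  # 0 hom-ref, 1 het, 2 hom-alt
    rng_hap = child_rng(cfg.seed, "haplotypes")
    for i, s in enumerate(samples):
        for chrom in cfg.chrom_names:
            sel = chrom_arr == chrom
            hap = simulate_haplotypes(
                acc_freq[s.accession][sel], block[sel], 2 * s.pool_size,
                cfg.recomb_between_blocks, rng_hap,
            )
            codes[i, sel], _ = pool_plants_to_accession(hap, cfg.pool_het_min)

    # --- overwrite planted patterns ------------------------------------
    i_by_sub = {
        sub: np.array([i for i, s in enumerate(samples) if s.subspecies == sub])
        for sub in subspecies
    }
    sub_a, sub_b = subspecies  # fixed-difference: sub_a hom-ref, sub_b hom-alt
    fixed_mask = kinds == "fixed"
    codes[np.ix_(i_by_sub[sub_a], np.flatnonzero(fixed_mask))] = 0
    codes[np.ix_(i_by_sub[sub_b], np.flatnonzero(fixed_mask))] = 2
    sub_freq[sub_a][fixed_mask] = 0.0
    sub_freq[sub_b][fixed_mask] = 1.0

    hp_mask = kinds == "high_pi"
    hp_sub = cfg.high_pi_subspecies
    other_sub = sub_a if hp_sub == sub_b else sub_b
    codes[np.ix_(i_by_sub[hp_sub], np.flatnonzero(hp_mask))] = 1
    codes[np.ix_(i_by_sub[other_sub], np.flatnonzero(hp_mask))] = 0
    sub_freq[hp_sub][hp_mask] = 0.5
    sub_freq[other_sub][hp_mask] = 0.0

    effect_cols = np.flatnonzero(kinds == "effect")
    for j in effect_cols:
        plan = payloads[j]
        codes[:, j] = 0
        if plan["group_by"] == "accession":
            carriers = [i for i, s in enumerate(samples) if s.accession == plan["group"]]
        else:
            carriers = list(i_by_sub[plan["group"]])
        codes[carriers, j] = 1
        for sub in subspecies:
            rows = i_by_sub[sub]
            sub_freq[sub][j] = np.isin(rows, carriers).sum() / (2.0 * len(rows))

    # --- depth, quality, missingness -----------------------------------
    rng_depth = child_rng(cfg.seed, "depth")
    k = cfg.depth_dispersion
    dp = rng_depth.negative_binomial(k, k / (k + cfg.depth_mean), size=(n_acc, S)).astype(np.int32)
    gq = np.clip(np.rint(rng_depth.normal(cfg.gq_mean, cfg.gq_sd, size=(n_acc, S))), 0, 99).astype(np.int32)
    miss = child_rng(cfg.seed, "missing").random((n_acc, S)) < cfg.missing_rate

    planted_site = kinds != "random"
    miss[:, planted_site] = False
    dp[:, planted_site] = np.maximum(dp[:, planted_site], 10)
    gq[:, planted_site] = np.maximum(gq[:, planted_site], 20)

    # high-missingness planting: just over 30% of calls unusable after masking
    rng_hm = child_rng(cfg.seed, "high-missing")
    n_bad = int(np.floor(0.3 * n_acc)) + 1
    cand = np.flatnonzero((kinds == "random") & sites.is_snp.to_numpy()
                          & (sites.alts.map(len) == 1).to_numpy() & ~np.isin(np.arange(S), tri_idx))
    hm_idx = np.sort(rng_hm.choice(cand, size=min(cfg.n_high_missing, len(cand)), replace=False))
    for j in hm_idx:
        bad_rows = rng_hm.choice(n_acc, size=n_bad, replace=False)
        dp[bad_rows, j] = rng_hm.integers(0, 10, size=n_bad)
        good = np.setdiff1d(np.arange(n_acc), bad_rows)
        dp[good, j] = np.maximum(dp[good, j], 10)
        gq[good, j] = np.maximum(gq[good, j], 20)
        miss[good, j] = False

    # exactness repair: no unplanted site may exceed the missingness cutoff
    unusable = miss | (dp < 10) | (gq < 20)
    protect = np.isin(np.arange(S), hm_idx)
    max_missing = int(np.floor(0.3 * n_acc))
    over = np.flatnonzero((unusable.sum(axis=0) > max_missing) & ~protect)
    for j in over:
        rows = np.flatnonzero(unusable[:, j])
        for i in rows[max_missing:]:
            miss[i, j] = False
            dp[i, j] = max(dp[i, j], 10)
            gq[i, j] = max(gq[i, j], 20)

    # Break any unplanted gene that is, by chance, a perfect fixed
    # difference between the subspecies: the "Fst = 1.00" truth class must
    # contain exactly the planted genes.  One hom-alt call is downgraded
    # to het at the first clean fixed-difference site of such a gene.
    unusable = miss | (dp < 10) | (gq < 20)
    biallelic_snp = sites.is_snp.to_numpy() & (sites.alts.map(len) == 1).to_numpy()
    rows_a, rows_b = i_by_sub[sub_a], i_by_sub[sub_b]
    for g in genes:
        if g.gene_id in fixed_ids:
            continue
        cols = np.flatnonzero(
            (chrom_arr == g.chrom) & (pos_arr >= g.start) & (pos_arr < g.end)
            & biallelic_snp & ~np.isin(np.arange(S), hm_idx)
        )
        if not len(cols):
            continue
        fixed_site = None
        is_one = False
        for j in cols:
            ca = codes[rows_a, j][~unusable[rows_a, j]]
            cb = codes[rows_b, j][~unusable[rows_b, j]]
            both = np.concatenate([ca, cb])
            if len(ca) == 0 or len(cb) == 0 or both.min() == both.max():
                continue  # unusable or monomorphic: contributes nothing
            if (both == 1).any():
                is_one = False
                break
            clean = (ca.min() == ca.max()) and (cb.min() == cb.max()) and ca[0] != cb[0]
            if not clean:
                is_one = False
                break
            is_one, fixed_site = True, (fixed_site if fixed_site is not None else j)
        if is_one:
            usable_b = rows_b[~unusable[rows_b, fixed_site]]
            codes[usable_b[0], fixed_site] = 1

    gt = np.stack(
        [np.where(codes == 2, 1, 0), np.where(codes == 0, 0, 1)], axis=2
    ).astype(np.int8)
    gt[miss] = MISSING

    # --- truth record ---------------------------------------------------
    het_frac = ((gt[:, :, 0] != gt[:, :, 1]) & (gt[:, :, 0] != MISSING)).sum(axis=1) / S
    gene_class = {g.gene_id: "neutral" for g in genes}
    gene_class.update({gid: "fixed_difference" for gid in fixed_ids})
    gene_class.update({gid: f"high_pi_{hp_sub}" for gid in high_pi_ids})
    truth = {
        "seed": cfg.seed,
        "true_F": {"subspecies": cfg.F_subspecies, "morphotype": cfg.F_morphotype},
        "gene_class": gene_class,
        "fixed_diff_genes": sorted(fixed_ids),
        "high_pi_genes": sorted(high_pi_ids),
        "high_pi_subspecies": hp_sub,
        "planted_effects": [
            dict(chrom=p["chrom"], pos=int(p["pos"]), ref=p["ref"], alt=p["alt"],
                 gene_id=p["gene_id"], effect=p["effect"], impact=p["impact"],
                 group_by=p["group_by"], group=p["group"])
            for p in effect_plans
        ],
        "triallelic_sites": [
            [chrom_arr[j], int(pos_arr[j])] for j in tri_idx
        ],
        "high_missing_sites": [
            [chrom_arr[j], int(pos_arr[j])] for j in hm_idx
        ],
        "het_fraction": {s.accession: float(h) for s, h in zip(samples, het_frac)},
        "subspecies_freqs": {sub: np.round(f, 6).tolist() for sub, f in sub_freq.items()},
        "site_keys": [[c, int(p)] for c, p in zip(chrom_arr, pos_arr)],
    }

    table = CohortTable(
        sites=sites, gt=gt, dp=dp, gq=gq, samples=list(samples),
    )
    reference = pio.ReferenceGenome({c: "".join(seq_by_chrom[c]) for c in cfg.chrom_names})
    return SyntheticCohort(config=cfg, reference=reference, genes=genes, table=table, truth=truth)


def emit_cohort(cfg: SimulationConfig, outdir) -> dict:
    """Generate and write ref.fa, genes.gff3, cohort.vcf, meta.tsv, truth.json.

    A self-check re-reads the VCF through the package's own reader and
    verifies that genotypes, depth and quality round-trip exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)
    paths = {
        "fasta": outdir / "ref.fa",
        "gff3": outdir / "genes.gff3",
        "vcf": outdir / "cohort.vcf",
        "meta": outdir / "meta.tsv",
        "truth": outdir / "truth.json",
    }
    pio.write_fasta(cohort.reference.seqs, paths["fasta"])
    pio.write_gff3(cohort.genes, paths["gff3"], cfg.chrom_lengths)
    pio.write_vcf(cohort.table, paths["vcf"])
    pio.write_sample_meta(cfg.samples, paths["meta"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)

    reread = pio.read_vcf(paths["vcf"], cfg.samples)
    if not (
        np.array_equal(reread.gt, cohort.table.gt)
        and np.array_equal(reread.dp, cohort.table.dp)
        and np.array_equal(reread.gq, cohort.table.gq)
    ):
        raise RuntimeError("self-check failed: emitted VCF does not round-trip")
    return {"cohort": cohort, **{k: str(v) for k, v in paths.items()}}
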