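"""Variant region/effect classification with impact tiers, Ka/Ks and Ts/Tv.

Region classes follow the usual annotation-tool conventions: splice
donor/acceptor are the first/last two intronic bases (HIGH); the splice
region is intronic bases 3-8 from a junction or the three exonic bases
flanking it (LOW); "splice site region" tallies count the union.
Anything outside a gene span but within ``flank`` (default 5 kb) is
upstream/downstream by strand; beyond that, intergenic.

For each (variant, gene) one primary record is kept, carrying the
highest-impact candidate effect; the region field is made consistent
with that effect (a coding effect always reports region ``exon``).  The
standalone :func:`classify_region` applies the pure location precedence
(splice_site_region > exon > UTR > intron) for Table-style tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ReferenceGenome, reverse_complement
from .model import CohortTable, GeneModel

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

IMPACT_OF = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "frameshift_variant": "HIGH",
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "synonymous_variant": "LOW",
    "splice_region_variant": "LOW",
    "stop_retained_variant": "LOW",
    "utr_premature_start_gain": "LOW",
    "5_prime_UTR_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
    "non_coding_exon_variant": "MODIFIER",
}

_IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}

# deterministic tie-break among equal-impact candidate effects
_EFFECT_PRIORITY = [
    "stop_gained", "stop_lost", "start_lost", "frameshift_variant",
    "splice_acceptor_variant", "splice_donor_variant",
    "missense_variant", "inframe_deletion", "inframe_insertion",
    "synonymous_variant", "stop_retained_variant",
    "utr_premature_start_gain", "splice_region_variant",
    "5_prime_UTR_variant", "3_prime_UTR_variant",
    "intron_variant", "upstream_gene_variant", "downstream_gene_variant",
    "intergenic_variant", "non_coding_exon_variant",
]

_REGION_OF_EFFECT = {
    "stop_gained": "exon", "stop_lost": "exon", "start_lost": "exon",
    "frameshift_variant": "exon", "missense_variant": "exon",
    "inframe_insertion": "exon", "inframe_deletion": "exon",
    "synonymous_variant": "exon", "stop_retained_variant": "exon",
    "non_coding_exon_variant": "exon",
    "splice_acceptor_variant": "splice_site_region",
    "splice_donor_variant": "splice_site_region",
    "splice_region_variant": "splice_site_region",
    "utr_premature_start_gain": "utr5",
    "5_prime_UTR_variant": "utr5",
    "3_prime_UTR_variant": "utr3",
    "intron_variant": "intron",
    "upstream_gene_variant": "upstream",
    "downstream_gene_variant": "downstream",
    "intergenic_variant": "intergenic",
}

REGION_CLASSES = [
    "intergenic", "exon", "intron", "splice_site_region", "utr5", "utr3",
    "upstream", "downstream",
]


def impact_of(effect: str) -> str:
    return IMPACT_OF[effect]


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the reference genome."""


def _in(pos, ivs):
    return any(s <= pos < e for s, e in ivs)


def _splice_zones(gene: GeneModel):
    """(donor, acceptor, intronic_region, exonic_region) interval lists."""
    donor, acceptor, intr_region, exon_region = [], [], [], []
    for s, e in gene.introns:
        five, three = ((s, s + 2), (e - 2, e)) if gene.strand == "+" else ((e - 2, e), (s, s + 2))
        donor.append(five)
        acceptor.append(three)
        intr_region.append((s + 2, min(s + 8, e - 2) if e - s > 4 else s + 2))
        intr_region.append((max(e - 8, s + 2), e - 2))
        exon_region.append((s - 3, s))
        exon_region.append((e, e + 3))
    return donor, acceptor, intr_region, exon_region


# ---------------------------------------------------------------------------
# region classification (location precedence)
# ---------------------------------------------------------------------------

def classify_region(
    pos: int, chrom: str, genes: list[GeneModel], flank: int = 5000
) -> list[tuple[str, str | None]]:
    """Location class of a position against every gene it touches.

    Precedence within a gene: splice_site_region > exon (CDS) > UTR >
    intron.  Outside all spans but within ``flank`` of a gene: upstream
    or downstream by that gene's strand (one record per gene).  Otherwise
    a single ('intergenic', None) record.
    """
    records = []
    for g in genes:
        if g.chrom != chrom or not (g.start - flank <= pos < g.end + flank):
            continue
        if g.start <= pos < g.end:
            donor, acceptor, intr_reg, ex_reg = _splice_zones(g)
            if _in(pos, donor) or _in(pos, acceptor) or _in(pos, intr_reg) or _in(pos, ex_reg):
                records.append(("splice_site_region", g.gene_id))
            elif _in(pos, g.cds):
                records.append(("exon", g.gene_id))
            elif _in(pos, g.utr5):
                records.append(("utr5", g.gene_id))
            elif _in(pos, g.utr3):
                records.append(("utr3", g.gene_id))
            elif _in(pos, g.exons):
                records.append(("exon", g.gene_id))
            else:
                records.append(("intron", g.gene_id))
        elif pos < g.start:
            records.append(("upstream" if g.strand == "+" else "downstream", g.gene_id))
        else:
            records.append(("downstream" if g.strand == "+" else "upstream", g.gene_id))
    return records or [("intergenic", None)]


# ---------------------------------------------------------------------------
# coding effects
# ---------------------------------------------------------------------------

def _cds_layout(gene: GeneModel):
    """CDS intervals in transcription order with cumulative offsets."""
    ivs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    offsets = np.cumsum([0] + [e - s for s, e in ivs])
    return ivs, offsets


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    ivs, offsets = _cds_layout(gene)
    for (s, e), off in zip(ivs, offsets):
        if s <= pos < e:
            return int(off + (pos - s if gene.strand == "+" else e - 1 - pos))
    return None


def _cds_sequence(gene: GeneModel, ref: ReferenceGenome) -> str:
    seq = "".join(ref.fetch(gene.chrom, s, e) for s, e in gene.cds)
    return seq if gene.strand == "+" else reverse_complement(seq)


def classify_coding_effect(
    pos: int, ref_allele: str, alt_allele: str, gene: GeneModel, ref: ReferenceGenome
) -> str:
    """SNP: rebuild the affected codon on the coding strand and translate;
    indel: frameshift unless the length change is a multiple of 3."""
    genome_base = ref.fetch(gene.chrom, pos, pos + len(ref_allele))
    if genome_base != ref_allele:
        raise ReferenceMismatchError(
            f"{gene.chrom}:{pos + 1} REF {ref_allele!r} != genome {genome_base!r}"
        )
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        shift = abs(len(ref_allele) - len(alt_allele))
        if shift % 3 != 0:
            return "frameshift_variant"
        return "inframe_deletion" if len(ref_allele) > len(alt_allele) else "inframe_insertion"

    off = _cds_offset(gene, pos)
    if off is None:
        raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")
    cds_seq = _cds_sequence(gene, ref)
    codon_idx, within = divmod(off, 3)
    codon = cds_seq[3 * codon_idx : 3 * codon_idx + 3]
    if len(codon) < 3:
        warnings.warn(f"{gene.gene_id}: truncated terminal codon; variant left unclassified")
        return "synonymous_variant"
    new_base = alt_allele if gene.strand == "+" else reverse_complement(alt_allele)
    new_codon = codon[:within] + new_base + codon[within + 1 :]
    aa_old, aa_new = GENETIC_CODE[codon], GENETIC_CODE[new_codon]
    if aa_old == aa_new:
        return "stop_retained_variant" if aa_old == "*" else "synonymous_variant"
    if aa_new == "*":
        return "stop_gained"
    if aa_old == "*":
        return "stop_lost"
    if codon_idx == 0 and codon == "ATG":
        return "start_lost"
    return "missense_variant"


def _utr_start_gain(pos, ref_allele, alt_allele, gene, ref) -> bool:
    """Does the alt base create a new ATG on the mRNA strand of the 5' UTR?"""
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        return False
    for s, e in gene.utr5:
        if s <= pos < e:
            lo, hi = max(s, pos - 2), min(e, pos + 3)
            window = ref.fetch(gene.chrom, lo, hi)
            alt_window = window[: pos - lo] + alt_allele + window[pos - lo + 1 :]
            if gene.strand == "-":
                window, alt_window = reverse_complement(window), reverse_complement(alt_window)
            return "ATG" in alt_window and "ATG" not in window
    return False


# ---------------------------------------------------------------------------
# per-variant effects
# ---------------------------------------------------------------------------

def _candidate_effects(pos, ref_allele, alt_allele, gene, ref) -> list[str]:
    effects = []
    is_snp = len(ref_allele) == 1 and len(alt_allele) == 1
    # indel footprint: bases after the anchor for deletions, insertion point otherwise
    foot_lo, foot_hi = (pos, pos + 1) if is_snp else (pos + 1, pos + max(len(ref_allele), 2))
    donor, acceptor, intr_reg, ex_reg = _splice_zones(gene)
    if is_snp:
        if _in(pos, donor):
            effects.append("splice_donor_variant")
        elif _in(pos, acceptor):
            effects.append("splice_acceptor_variant")
        elif _in(pos, intr_reg) or _in(pos, ex_reg):
            effects.append("splice_region_variant")
    if is_snp:
        in_cds = gene.is_coding and _in(pos, gene.cds)
    else:
        in_cds = gene.is_coding and any(s < foot_hi and foot_lo < e for s, e in gene.cds)
    if in_cds:
        effects.append(classify_coding_effect(pos, ref_allele, alt_allele, gene, ref))
    elif _in(pos, gene.utr5):
        effects.append(
            "utr_premature_start_gain"
            if _utr_start_gain(pos, ref_allele, alt_allele, gene, ref)
            else "5_prime_UTR_variant"
        )
    elif _in(pos, gene.utr3):
        effects.append("3_prime_UTR_variant")
    elif _in(pos, gene.exons):
        effects.append("non_coding_exon_variant")
    elif gene.start <= pos < gene.end:
        effects.append("intron_variant")
    return effects


def variant_effects(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    genes: list[GeneModel],
    ref: ReferenceGenome,
    flank: int = 5000,
) -> list[dict]:
    """Primary EffectRecord per gene the variant touches (or one intergenic)."""
    records = []
    for g in genes:
        if g.chrom != chrom or not (g.start - flank <= pos < g.end + flank):
            continue
        if g.start <= pos < g.end:
            effects = _candidate_effects(pos, ref_allele, alt_allele, g, ref)
        elif pos < g.start:
            effects = ["upstream_gene_variant" if g.strand == "+" else "downstream_gene_variant"]
        else:
            effects = ["downstream_gene_variant" if g.strand == "+" else "upstream_gene_variant"]
        if not effects:
            continue
        primary = min(
            effects, key=lambda e: (-_IMPACT_RANK[IMPACT_OF[e]], _EFFECT_PRIORITY.index(e))
        )
        records.append(
            dict(
                chrom=chrom,
                pos=pos,
                ref=ref_allele,
                alt=alt_allele,
                gene_id=g.gene_id,
                region=_REGION_OF_EFFECT[primary],
                effect=primary,
                impact=IMPACT_OF[primary],
            )
        )
    if not records:
        records.append(
            dict(
                chrom=chrom, pos=pos, ref=ref_allele, alt=alt_allele, gene_id=None,
                region="intergenic", effect="intergenic_variant", impact="MODIFIER",
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort-level annotation
# ---------------------------------------------------------------------------

def annotate_variants(
    table: CohortTable,
    genes: list[GeneModel],
    ref: ReferenceGenome,
    flank: int = 5000,
    group_by: str = "subspecies",
) -> tuple[pd.DataFrame, dict]:
    """Annotate every retained variant and summarise.

    Returns (effects frame: one primary record per (variant, gene)),
    and a summary dict with region counts/percentages (one region per
    variant, from its highest-impact record), per-impact counts for the
    cohort and for each sample group (a variant counts for a group when
    at least one member carries a non-reference allele), Ka/Ks and Ts/Tv.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    all_records = []
    variant_primary = []
    for j, row in enumerate(table.sites.itertuples()):
        alt = row.alts[0] if row.alts else row.ref
        recs = variant_effects(
            row.chrom, row.pos, row.ref, alt, by_chrom.get(row.chrom, []), ref, flank
        )
        for r in recs:
            r["site_index"] = j
        all_records.append(recs)
        primary = min(
            recs,
            key=lambda r: (-_IMPACT_RANK[r["impact"]], _EFFECT_PRIORITY.index(r["effect"])),
        )
        variant_primary.append(primary)
    effects = pd.DataFrame([r for recs in all_records for r in recs])
    primary_df = pd.DataFrame(variant_primary)

    n_var = len(primary_df)
    region_counts = primary_df.region.value_counts().to_dict() if n_var else {}
    region_pct = {k: 100.0 * v / n_var for k, v in region_counts.items()}
    impact_counts = primary_df.impact.value_counts().to_dict() if n_var else {}
    impact_pct = {k: 100.0 * v / n_var for k, v in impact_counts.items()}

    carries = (table.gt > 0).any(axis=2)  # sample x site: >=1 non-ref allele
    group_impacts = {}
    for name, idx in table.group_indices(group_by).items():
        has = carries[idx].any(axis=0)
        sub = primary_df[has.astype(bool)[primary_df.site_index.to_numpy()]] if n_var else primary_df
        group_impacts[name] = sub.impact.value_counts().to_dict()

    summary = {
        "n_variants": n_var,
        "region_counts": region_counts,
        "region_pct": region_pct,
        "impact_counts": impact_counts,
        "impact_pct": impact_pct,
        "impact_counts_by_group": group_impacts,
        "ka_ks": ka_ks(primary_df),
        "ts_tv": ts_tv(table.sites),
    }
    return effects, summary


def ts_tv(sites: pd.DataFrame) -> float:
    """Transition/transversion count ratio over biallelic SNPs (NaN if no Tv)."""
    snps = sites[sites.is_snp & (sites.alts.map(len) == 1)]
    pairs = {frozenset(p) for p in (("A", "G"), ("C", "T"))}
    ts = sum(1 for r, a in zip(snps.ref, snps.alts) if frozenset((r, a[0])) in pairs)
    tv = len(snps) - ts
    if tv == 0:
        warnings.warn("no transversions; Ts/Tv undefined")
        return float("nan")
    return ts / tv


KA_EFFECTS = {"missense_variant", "stop_gained", "stop_lost", "start_lost"}


def ka_ks(effects: pd.DataFrame) -> float:
    """Raw count ratio of non-synonymous to synonymous changes (NaN if no Ks)."""
    if not len(effects):
        return float("nan")
    ka = int(effects.effect.isin(KA_EFFECTS).sum())
    ks = int((effects.effect == "synonymous_variant").sum())
    if ks == 0:
        warnings.warn("no synonymous variants; Ka/Ks undefined")
        return float("nan")
    return ka / ks


def gene_set_comparisons(
    table: CohortTable, effects: pd.DataFrame, group_by: str = "subspecies"
) -> dict:
    """Private HIGH/MODERATE gene sets per sample group.

    A variant is private to a group when at least one member carries a
    non-reference allele and no member of any other group does.  Reports
    each group's private gene set, plus pairwise shared counts.
    """
    carries = (table.gt > 0).any(axis=2)
    groups = table.group_indices(group_by)
    strong = effects[(effects.impact.isin(["HIGH", "MODERATE"])) & effects.gene_id.notna()]
    private_genes: dict[str, set] = {}
    private_sites: dict[str, set] = {}
    for name, idx in groups.items():
        others = np.concatenate([v for k, v in groups.items() if k != name]) if len(groups) > 1 else np.array([], dtype=int)
        site_in = carries[idx].any(axis=0)
        site_out = carries[others].any(axis=0) if len(others) else np.zeros(table.n_sites, dtype=bool)
        private = site_in & ~site_out
        sel = strong[private[strong.site_index.to_numpy()]] if len(strong) else strong
        private_genes[name] = set(sel.gene_id)
        private_sites[name] = set(sel.site_index)
    names = sorted(groups)
    pairwise = {
        f"{a}&{b}": len(private_genes[a] & private_genes[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return {
        "group_by": group_by,
        "private_genes": {k: sorted(v) for k, v in private_genes.items()},
        "private_gene_counts": {k: len(v) for k, v in private_genes.items()},
        "private_variant_counts": {k: len(v) for k, v in private_sites.items()},
        "pairwise_shared_private": pairwise,
    }
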