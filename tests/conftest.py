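"""Shared fixtures: tiny cohort builders, independent oracles, toy genome."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from popscan.io import ReferenceGenome
from popscan.model import MISSING, CohortTable, GeneModel, SampleMeta, make_sites_frame
from popscan.simulate import _scrub_cds, _codon_genome_positions, _write_codon, _COMP


# ---------------------------------------------------------------------------
# cohort builders
# ---------------------------------------------------------------------------

def build_table(
    gt_pairs,
    positions=None,
    chroms=None,
    samples=None,
    refs=None,
    alts=None,
    dp=30,
    gq=99,
    masked=True,
):
    """CohortTable from a nested list gt_pairs[sample][site] = (a, b).

    Defaults: biallelic A/T SNPs spaced 10 bp apart on one chromosome,
    full depth/quality, masking already applied.
    """
    gt = np.array(gt_pairs, dtype=np.int8)
    n_samples, n_sites = gt.shape[:2]
    positions = positions if positions is not None else [10 * j for j in range(n_sites)]
    chroms = chroms if chroms is not None else ["chr1"] * n_sites
    refs = refs if refs is not None else ["A"] * n_sites
    alts = alts if alts is not None else [("T",)] * n_sites
    samples = samples or [
        SampleMeta(f"s{i}", "m", "pepo" if i < (n_samples + 1) // 2 else "ovifera")
        for i in range(n_samples)
    ]
    sites = make_sites_frame(list(zip(chroms, positions, refs, alts)))
    dp_arr = np.full((n_samples, n_sites), dp, dtype=np.int32) if np.isscalar(dp) else np.asarray(dp, dtype=np.int32)
    gq_arr = np.full((n_samples, n_sites), gq, dtype=np.int32) if np.isscalar(gq) else np.asarray(gq, dtype=np.int32)
    return CohortTable(
        sites=sites, gt=gt, dp=dp_arr, gq=gq_arr, samples=samples, masked=masked
    )


def random_table(rng, n_samples=8, n_sites=50, missing_rate=0.1, n_chrom=2):
    """Random biallelic cohort with some missing calls."""
    gt = rng.integers(0, 2, size=(n_samples, n_sites, 2)).astype(np.int8)
    miss = rng.random((n_samples, n_sites)) < missing_rate
    gt[miss] = MISSING
    per = n_sites // n_chrom
    idx = [min(j // per, n_chrom - 1) for j in range(n_sites)]
    chroms = [f"chr{1 + c}" for c in idx]
    positions = [(j - c * per) * 10 for j, c in zip(range(n_sites), idx)]
    return build_table(gt, positions=positions, chroms=chroms)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_bruteforce(alleles):
    """Mean pairwise difference over all haplotype pairs at one site."""
    alleles = list(alleles)
    pairs = list(itertools.combinations(range(len(alleles)), 2))
    if not pairs:
        return float("nan")
    return sum(alleles[i] != alleles[j] for i, j in pairs) / len(pairs)


def kosman_leonard_bruteforce(gt_i, gt_j):
    """Multiset-intersection Kosman-Leonard distance for two genotype vectors."""
    sims = []
    for (a, b), (c, d) in zip(gt_i, gt_j):
        if MISSING in (a, b, c, d):
            continue
        inter = sum((Counter([a, b]) & Counter([c, d])).values())
        sims.append(inter / 2.0)
    if not sims:
        raise ValueError("no shared loci")
    return 1.0 - sum(sims) / len(sims), len(sims)


def wc_theta_oracle(n1, p1, h1, n2, p2, h2):
    """Direct transcription of the two-population variance-component algebra.

    Written independently of the vectorised implementation: scalar
    arithmetic, explicit intermediate quantities.
    """
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# hand-built toy genome for annotation golden tests
# ---------------------------------------------------------------------------

TOY_CHROM = "toy1"
TOY_LEN = 20_000


@pytest.fixture(scope="session")
def toy_genome():
    """Two genes (one per strand) on a 20 kb chromosome, plus 12 variants
    whose effects are known by construction (codons written by hand)."""
    rng = np.random.default_rng(20190811)
    seq = rng.choice(np.array(list("ACGT")), size=TOY_LEN)

    gene_a = GeneModel(
        gene_id="geneA", chrom=TOY_CHROM, strand="+", start=8000, end=9400,
        exons=[(8000, 8300), (8500, 8800), (9000, 9400)],
        cds=[(8200, 8300), (8500, 8800), (9000, 9200)],
    )
    gene_b = GeneModel(
        gene_id="geneB", chrom=TOY_CHROM, strand="-", start=12000, end=13400,
        exons=[(12000, 12400), (12600, 12900), (13100, 13400)],
        cds=[(12200, 12400), (12600, 12900), (13100, 13200)],
    )
    genes = [gene_a, gene_b]
    _scrub_cds({TOY_CHROM: seq}, genes)

    # plant specific codons (coding strand) so effects are known exactly
    _write_codon(seq, gene_a, 4, "GGA")  # -> GGT synonymous (Gly)
    _write_codon(seq, gene_a, 6, "GAA")  # -> GTA missense (Glu->Val)
    _write_codon(seq, gene_a, 8, "TAC")  # -> TAG stop_gained
    _write_codon(seq, gene_b, 5, "GAG")  # -> GTG missense (Glu->Val)
    _write_codon(seq, gene_b, 7, "TAC")  # -> TAA stop_gained
    seq[8098:8103] = list("CCCCC")  # 5' UTR window without ATG potential

    def codon_pos(gene, idx, k):
        return _codon_genome_positions(gene, idx)[k]

    variants = []  # (pos, ref, alt, expected gene_id, effect, impact)

    p = codon_pos(gene_a, 4, 2)
    variants.append((p, seq[p], "T", "geneA", "synonymous_variant", "LOW"))
    p = codon_pos(gene_a, 6, 1)
    variants.append((p, seq[p], "T", "geneA", "missense_variant", "MODERATE"))
    p = codon_pos(gene_a, 8, 2)
    variants.append((p, seq[p], "G", "geneA", "stop_gained", "HIGH"))
    # splice donor: first intronic base of intron 1 (plus strand)
    p = 8300
    alt = "A" if seq[p] != "A" else "G"
    variants.append((p, seq[p], alt, "geneA", "splice_donor_variant", "HIGH"))
    # frameshift: 1 bp deletion anchored at 8600 (footprint 8601 in CDS)
    variants.append((8600, seq[8600] + seq[8601], seq[8600], "geneA", "frameshift_variant", "HIGH"))
    # plain 5' UTR
    variants.append((8100, "C", "G", "geneA", "5_prime_UTR_variant", "MODIFIER"))
    # plain intron (intron 1 interior, outside all splice zones)
    p = 8450
    alt = "A" if seq[p] != "A" else "G"
    variants.append((p, seq[p], alt, "geneA", "intron_variant", "MODIFIER"))
    # upstream at 3 kb from gene A (plus strand; gene B is 7 kb away)
    p = 5000
    alt = "A" if seq[p] != "A" else "G"
    variants.append((p, seq[p], alt, "geneA", "upstream_gene_variant", "MODIFIER"))
    # intergenic at 6 kb from gene A, 10 kb from gene B
    p = 2000
    alt = "A" if seq[p] != "A" else "G"
    variants.append((p, seq[p], alt, None, "intergenic_variant", "MODIFIER"))
    # minus-strand gene: missense (coding GAG -> GTG)
    p = codon_pos(gene_b, 5, 1)
    variants.append((p, seq[p], _COMP["T"], "geneB", "missense_variant", "MODERATE"))
    # minus-strand stop gained (coding TAC -> TAA)
    p = codon_pos(gene_b, 7, 2)
    variants.append((p, seq[p], _COMP["A"], "geneB", "stop_gained", "HIGH"))
    # 3' UTR of the minus-strand gene lies at its low-coordinate end
    p = 12100
    alt = "A" if seq[p] != "A" else "G"
    variants.append((p, seq[p], alt, "geneB", "3_prime_UTR_variant", "MODIFIER"))

    ref = ReferenceGenome({TOY_CHROM: "".join(seq)})
    return ref, genes, sorted(variants, key=lambda v: v[0])


@pytest.fixture(scope="session")
def toy_cohort(toy_genome):
    """Two-sample cohort over the 12 toy variants (first sample het everywhere)."""
    ref, genes, variants = toy_genome
    n = len(variants)
    gt = np.zeros((2, n, 2), dtype=np.int8)
    gt[0, :, 1] = 1  # sample 0 het at every site
    table = build_table(
        gt,
        positions=[v[0] for v in variants],
        chroms=[TOY_CHROM] * n,
        refs=[v[1] for v in variants],
        alts=[(v[2],) for v in variants],
        samples=[SampleMeta("acc1", "m1", "pepo"), SampleMeta("acc2", "m2", "ovifera")],
    )
    return ref, genes, variants, table
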