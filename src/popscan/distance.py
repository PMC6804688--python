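"""Kosman-Leonard codominant genetic distance, distance matrix, and NJ tree.

The Kosman-Leonard similarity of two diploid genotypes at one locus is
half the size of the multiset intersection of their allele pairs (1 for
identical genotypes, 0.5 for AA/AB, 0 for disjoint pairs); the distance
between two accessions is 1 minus the mean similarity over the loci
called in both.  Pairwise deletion means each pair may use a different
locus set; ``n_loci_used`` is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import MISSING, CohortTable


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    n_loci_used: np.ndarray


def kosman_leonard_pair(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[float, int]:
    """Distance between two genotype vectors of shape (n_loci, 2).

    Only loci called (no MISSING allele) in both vectors contribute.
    Handles any allele coding (multiset intersection, not dosage).
    """
    calls_i = np.asarray(calls_i)
    calls_j = np.asarray(calls_j)
    if calls_i.shape != calls_j.shape:
        raise ValueError("genotype vectors differ in length")
    used = (calls_i != MISSING).all(axis=1) & (calls_j != MISSING).all(axis=1)
    n = int(used.sum())
    if n == 0:
        raise ValueError("no loci called in both members of the pair")
    gi, gj = calls_i[used], calls_j[used]
    alleles = np.unique(np.concatenate([gi.ravel(), gj.ravel()]))
    inter = np.zeros(n)
    for a in alleles:
        inter += np.minimum((gi == a).sum(axis=1), (gj == a).sum(axis=1))
    s = inter / 2.0
    return float(1.0 - s.mean()), n


def distance_matrix(table: CohortTable, snps_only: bool = True) -> DistanceMatrix:
    """All-pairs Kosman-Leonard distances between accessions."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 accessions")
    sub = table.biallelic_snps() if snps_only else table
    n = sub.n_samples
    d = np.zeros((n, n))
    loci = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        loci[i, i] = sub.n_sites
        for j in range(i + 1, n):
            try:
                dij, nij = kosman_leonard_pair(sub.gt[i], sub.gt[j])
            except ValueError as exc:
                raise ValueError(
                    f"pair ({sub.samples[i].accession}, {sub.samples[j].accession}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = dij
            loci[i, j] = loci[j, i] = nij
    return DistanceMatrix(labels=sub.sample_names, d=d, n_loci_used=loci)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (Newick) from the distance matrix.

    Negative branch lengths are clamped to zero with a warning; label
    order gives deterministic tie-breaking.
    """
    import skbio

    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.labels)
    try:
        tree = skbio.tree.nj(sk_dm, neg_as_zero=True)
    except TypeError:
        tree = skbio.tree.nj(sk_dm)
        clamped = False
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
                clamped = True
        if clamped:
            warnings.warn("negative NJ branch lengths clamped to 0")
    return str(tree).strip()
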