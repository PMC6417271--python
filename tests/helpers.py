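"""Independent oracles and toy-data builders shared across tests.

Everything here deliberately avoids the package's vectorised code
paths: statistics are recomputed with explicit per-site loops, trees
are generated by random agglomeration, VCFs are written as literal
text.
"""
from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np

from aedespop.genotypes import GenotypeMatrix
from aedespop.trees import Clade, Tree


def site_alleles(gm: GenotypeMatrix, site: int, sample_idx) -> list[int]:
    """Explicit 0/1 allele list at one site for a diploid sample group."""
    out = []
    for j in sample_idx:
        d = int(gm.dosage[site, j])
        if d < 0:
            continue
        out.extend([1] * d + [0] * (gm.ploidy - d))
    return out


def naive_hudson_sums(gm: GenotypeMatrix, g1, g2, sites=None):
    """Hudson numerator/denominator totals via a per-site double loop."""
    i1 = gm.sample_indices(g1)
    i2 = gm.sample_indices(g2)
    tot_n = tot_d = 0.0
    for s in sites if sites is not None else range(gm.n_sites):
        al1 = site_alleles(gm, s, i1)
        al2 = site_alleles(gm, s, i2)
        n1, n2 = len(al1), len(al2)
        if n1 < 2 or n2 < 2:
            continue
        p1 = sum(al1) / n1
        p2 = sum(al2) / n2
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        tot_n += num
        tot_d += den
    return tot_n, tot_d


def brute_pi_site(alleles) -> float:
    """Mean pairwise allele difference over all C(n, 2) allele pairs."""
    pairs = list(combinations(alleles, 2))
    if not pairs:
        return 0.0
    return sum(a != b for a, b in pairs) / len(pairs)


def random_additive_tree(rng: np.random.Generator, n_leaves: int) -> Tree:
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [
        Clade(name=f"t{i}", length=float(rng.uniform(0.1, 2.0)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = Clade(
            length=float(rng.uniform(0.1, 2.0)), children=[nodes[i], nodes[j]]
        )
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [joined]
    return Tree(root=Clade(children=nodes))


def normalized_splits(tree: Tree) -> set:
    """Bipartitions as unordered {side, complement} pairs."""
    leaves = frozenset(tree.leaf_names())
    return {frozenset([s, leaves - s]) for s, _ in tree.bipartitions()}


def partition_from_labels(label_of: dict) -> set:
    """Set-of-frozensets partition from a sample -> label mapping."""
    groups: dict = {}
    for s, lab in label_of.items():
        groups.setdefault(lab, set()).add(s)
    return {frozenset(g) for g in groups.values()}


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=SAF,Number=A,Type=Integer,Description="fwd">
##INFO=<ID=SAR,Number=A,Type=Integer,Description="rev">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
"""


def write_toy_vcf(path: Path, samples: list[str], records: list[str],
                  header: str = VCF_HEADER) -> Path:
    """records are pre-formatted data lines (CHROM..FORMAT + calls)."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    body = header + cols + ("\t" + "\t".join(samples) if samples else "") + "\n"
    body += "".join(r + "\n" for r in records)
    path.write_text(body)
    return path
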