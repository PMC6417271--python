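"""Mitogenome consensus extraction, gene concatenation and lineage calls.

Haploid variant calls are applied to a reference mitogenome to build a
per-sample consensus (missing calls are filled with the reference base
and recorded, the usual consensus-extraction convention).  Protein-
coding genes are then cut out, reverse-complemented where annotated on
the minus strand, and concatenated in annotation order; lineages are
assigned by building a neighbor-joining tree on Jukes-Cantor distances
of the concatenated alignment and cutting its longest internal
branches.

Indels are rejected in the consensus step (substitutions only), so all
consensus sequences keep the reference length and stay aligned without
a multiple-alignment step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from . import trees

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


@dataclass
class MitoConsensus:
    sample: str
    sequence: str
    variant_positions: list[int] = field(default_factory=list)  # 1-based, applied
    reference_filled: list[int] = field(default_factory=list)  # 1-based, missing GT


@dataclass
class GeneAnnotation:
    gene: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval for gene {self.gene!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-' for gene {self.gene!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConcatAlignment:
    samples: list[str]
    sequences: list[str]
    offsets: list[tuple[str, int, int]]  # gene, start offset, end offset (half-open)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def records(self) -> list[tuple[str, str]]:
        return list(zip(self.samples, self.sequences))

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.records():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def read_gene_table(path) -> list[GeneAnnotation]:
    """TSV with columns gene, start, end, strand (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneAnnotation(str(r.gene), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def consensus_from_vcf(vcf_path, reference_path) -> list[MitoConsensus]:
    """Per-sample consensus from a haploid VCF and reference FASTA.

    Substitutions only: indel records are skipped with a warning.
    A diploid GT anywhere raises (the mitogenome must be called at
    ploidy 1).
    """
    ref_record = next(SeqIO.parse(str(reference_path), "fasta"))
    reference = str(ref_record.seq).upper()
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    seqs = {s: list(reference) for s in samples}
    applied: dict[str, list[int]] = {s: [] for s in samples}
    filled: dict[str, list[int]] = {s: [] for s in samples}
    n_indels = 0
    for rec in vf:
        alts = tuple(rec.alts or ())
        if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
            n_indels += 1
            continue
        if rec.pos > len(reference):
            raise ValueError(
                f"variant at position {rec.pos} beyond reference length "
                f"{len(reference)}"
            )
        for s in samples:
            alleles = rec.samples[s].get("GT", None)
            if alleles is None:
                alleles = (None,)
            if len(alleles) != 1:
                raise ValueError(
                    f"diploid GT at {rec.chrom}:{rec.pos} sample {s}; "
                    "the mitochondrial VCF must be called at ploidy 1"
                )
            a = alleles[0]
            if a is None:
                filled[s].append(rec.pos)
            elif a > 0:
                seqs[s][rec.pos - 1] = alts[a - 1].upper()
                applied[s].append(rec.pos)
    if n_indels:
        warnings.warn(f"skipped {n_indels} indel records in mito VCF")
    return [
        MitoConsensus(
            sample=s,
            sequence="".join(seqs[s]),
            variant_positions=applied[s],
            reference_filled=filled[s],
        )
        for s in samples
    ]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_and_concatenate(
    consensuses: list[MitoConsensus], genes: list[GeneAnnotation]
) -> ConcatAlignment:
    """Cut gene intervals out of each consensus and concatenate them in
    annotation order (minus-strand genes reverse-complemented)."""
    if not consensuses:
        raise ValueError("no consensus sequences")
    ref_len = len(consensuses[0].sequence)
    for g in genes:
        if g.end > ref_len:
            raise ValueError(
                f"gene {g.gene!r} interval [{g.start}, {g.end}] exceeds "
                f"reference length {ref_len}"
            )
    offsets = []
    cursor = 0
    for g in genes:
        offsets.append((g.gene, cursor, cursor + g.length))
        cursor += g.length
    seqs = []
    for cons in consensuses:
        parts = []
        for g in genes:
            sub = cons.sequence[g.start - 1 : g.end]
            parts.append(reverse_complement(sub) if g.strand == "-" else sub)
        seqs.append("".join(parts))
    return ConcatAlignment(
        samples=[c.sample for c in consensuses], sequences=seqs, offsets=offsets
    )


def assign_lineages(
    concat: ConcatAlignment, n_lineages: int = 2
) -> tuple[dict[str, str], trees.Tree | None]:
    """Assign samples to mitochondrial lineages.

    Builds a JC69 + neighbor-joining tree on the concatenated genes and
    cuts its ``n_lineages - 1`` longest internal branches; groups are
    named L1, L2, ... largest first.  Returns (assignment, tree); the
    tree is None when fewer than 3 samples make NJ undefined.
    """
    n = len(concat.samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_lineages > n:
        raise ValueError(f"n_lineages={n_lineages} exceeds {n} samples")
    if n_lineages == 1:
        return {s: "L1" for s in concat.samples}, None
    if n == 2:
        # degenerate: each sample its own lineage
        return {s: f"L{i + 1}" for i, s in enumerate(concat.samples)}, None
    dm = trees.sequence_distance(concat.records())
    tree = trees.nj(dm)
    groups = trees.split_by_longest_edges(tree, n_lineages)
    assignment = {}
    for gi, group in enumerate(groups):
        for s in group:
            assignment[s] = f"L{gi + 1}"
    return assignment, tree


def write_consensus_fasta(consensuses: list[MitoConsensus], path) -> None:
    with open(path, "w") as fh:
        for cons in consensuses:
            fh.write(f">{cons.sample}\n")
            for i in range(0, len(cons.sequence), 70):
                fh.write(cons.sequence[i : i + 70] + "\n")


def write_lineage_table(assignment: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlineage\n")
        for s, l in assignment.items():
            fh.write(f"{s}\t{l}\n")
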