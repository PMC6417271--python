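"""Synthetic population-genomic datasets with known truth.

Nuclear genotypes are simulated under the Balding-Nichols model: each
site has an ancestral allele frequency p-bar, and population k draws its
own frequency from Beta(p-bar (1-F_k)/F_k, (1-p-bar)(1-F_k)/F_k).  The
model is chosen because expected divergence is analytic -- between two
populations with parameters F_a and F_b the genome-wide Hudson F_ST
converges to (F_a + F_b) / 2 -- so parameter recovery can be tested
exactly.  Sites are independent (no linkage disequilibrium); that is a
deliberate trade of realism for known truth.

The default configuration mirrors the scale of the study the package
is built around: four diverged populations of 18/9/7/3 diploids
(three invading clusters plus one out-of-range reference group), a
divergence parameter on the scale reported between those clusters,
three chromosomes with a masked centromeric interval each where SNP
density drops, read depths near 10x, one F1 hybrid between the two
central populations, and two deep mitochondrial lineages distributed
across the nuclear clusters.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import GenotypeMatrix

_BASES = np.array(["A", "C", "G", "T"])


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class DepthModel:
    """Negative-binomial per-genotype read depth.

    mean ~10 emulates low-coverage individual resequencing (median
    coverage near 10x); dispersion is the NB size parameter (variance =
    mean + mean^2/dispersion).
    """

    mean: float = 10.0
    dispersion: float = 5.0


@dataclass
class MitoConfig:
    """Design of the simulated mitogenome.

    Lineage 1 is the reference haplotype; every further lineage carries
    its own disjoint set of defining substitutions, so the pairwise
    lineage distance to the reference lineage equals that count.  All
    variant positions fall inside protein-coding genes so that the
    concatenated-gene alignment preserves every difference.
    ``assignment`` maps samples to lineages (0-based); ``None``
    alternates lineages within each nuclear population, which decouples
    the mitochondrial partition from the nuclear one.
    """

    n_lineages: int = 2
    defining_substitutions: int | list[int] = 30
    private_rate: float = 2.0
    length: int = 15_000
    n_genes: int = 13
    assignment: list[int] | None = None

    def substitution_counts(self) -> list[int]:
        if isinstance(self.defining_substitutions, int):
            return [0] + [self.defining_substitutions] * (self.n_lineages - 1)
        counts = list(self.defining_substitutions)
        if len(counts) != self.n_lineages:
            raise SimConfigError("defining_substitutions list length != n_lineages")
        return counts


def _default_layout():
    return [("chr1", 3_000_000), ("chr2", 5_000_000), ("chr3", 4_000_000)]


def _default_masks(layout):
    """One central 'centromeric' interval of 10% span per chromosome."""
    out = []
    for name, length in layout:
        half = length // 20
        mid = length // 2
        out.append((name, mid - half, mid + half))
    return out


@dataclass
class SimConfig:
    """Full description of a synthetic dataset."""

    n_populations: int = 4
    target_F: float | list[float] = 0.15
    samples_per_population: list[int] = field(default_factory=lambda: [18, 9, 7, 3])
    n_sites: int = 50_000
    genome_layout: list[tuple[str, int]] = field(default_factory=_default_layout)
    mask_intervals: list[tuple[str, int, int]] | None = None
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.05
    depth: DepthModel = field(default_factory=DepthModel)
    n_hybrids: list[tuple[str, str, int]] = field(default_factory=list)
    mask_snp_density: float = 0.1
    strand_fail_rate: float = 0.0
    years: list[int] | None = None
    mito: MitoConfig = field(default_factory=MitoConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mask_intervals is None:
            self.mask_intervals = _default_masks(self.genome_layout)
        self.validate()

    # -- derived views ------------------------------------------------
    @property
    def population_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def per_population_F(self) -> np.ndarray:
        if np.isscalar(self.target_F):
            return np.full(self.n_populations, float(self.target_F))
        F = np.asarray(self.target_F, dtype=float)
        if len(F) != self.n_populations:
            raise SimConfigError("target_F list length != n_populations")
        return F

    def validate(self) -> None:
        F = self.per_population_F()
        if np.any(F <= 0) or np.any(F >= 1):
            raise SimConfigError("target_F must lie strictly in (0, 1)")
        if len(self.samples_per_population) != self.n_populations:
            raise SimConfigError("samples_per_population length != n_populations")
        if any(n < 2 for n in self.samples_per_population):
            raise SimConfigError("need >= 2 samples per population")
        if self.n_sites <= 0:
            raise SimConfigError("n_sites must be positive")
        if any(length <= 0 for _, length in self.genome_layout):
            raise SimConfigError("chromosome lengths must be positive")
        lengths = dict(self.genome_layout)
        for chrom, start, end in self.mask_intervals:
            if chrom not in lengths:
                raise SimConfigError(f"mask interval on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise SimConfigError(f"mask interval {(chrom, start, end)} out of bounds")
        lo, hi = self.ancestral_freq_range
        if not (0 <= lo < hi <= 1):
            raise SimConfigError("invalid ancestral_freq_range")
        if not (0 <= self.missing_rate < 1):
            raise SimConfigError("missing_rate must be in [0, 1)")
        names = set(self.population_names)
        for a, b, count in self.n_hybrids:
            if a not in names or b not in names or a == b:
                raise SimConfigError(f"invalid hybrid parent pair ({a}, {b})")
            if count < 0:
                raise SimConfigError("hybrid count must be >= 0")
        if self.years is not None and len(self.years) != self.n_populations:
            raise SimConfigError("years length != n_populations")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "depth" in d and isinstance(d["depth"], dict):
            d["depth"] = DepthModel(**d["depth"])
        if "mito" in d and isinstance(d["mito"], dict):
            d["mito"] = MitoConfig(**d["mito"])
        if "genome_layout" in d:
            d["genome_layout"] = [tuple(x) for x in d["genome_layout"]]
        if d.get("mask_intervals") is not None:
            d["mask_intervals"] = [tuple(x) for x in d["mask_intervals"]]
        if "n_hybrids" in d:
            d["n_hybrids"] = [tuple(x) for x in d["n_hybrids"]]
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    ancestral_freq: np.ndarray
    population_freqs: np.ndarray  # (n_sites, K)
    population_of: dict[str, str]  # non-hybrid samples only
    hybrid_parents: dict[str, tuple[str, str]]
    mito_lineage: dict[str, int]
    year_of: dict[str, int]

    def label_of(self, sample: str) -> str:
        if sample in self.hybrid_parents:
            a, b = self.hybrid_parents[sample]
            return f"{a}x{b}"
        return self.population_of[sample]


@dataclass
class MitoSim:
    """Simulated mitogenome: reference, genes and haploid variants."""

    reference: str
    genes: list[tuple[str, int, int, str]]  # name, start, end (1-based incl), strand
    positions: np.ndarray  # 1-based variant positions
    ref_alleles: np.ndarray
    alt_alleles: np.ndarray
    genotypes: np.ndarray  # (n_variants, n_samples) in {0, 1}
    samples: list[str]
    lineage_of: dict[str, int]

    def consensus(self, sample: str) -> str:
        j = self.samples.index(sample)
        seq = list(self.reference)
        for i in np.flatnonzero(self.genotypes[:, j] == 1):
            seq[self.positions[i] - 1] = self.alt_alleles[i]
        return "".join(seq)


@dataclass
class SimBundle:
    """Everything one simulation run produced, pre-serialization."""

    config: SimConfig
    gm: GenotypeMatrix
    truth: TruthRecord
    depth: np.ndarray  # (n_sites, n_samples)
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    saf: np.ndarray
    sar: np.ndarray
    mito: MitoSim


# ---------------------------------------------------------------------
# frequency and genotype simulation
# ---------------------------------------------------------------------

def draw_population_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols per-population allele frequencies.

    Returns ``(ancestral, freqs)`` with ``freqs`` of shape
    (n_sites, n_populations).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    F = cfg.per_population_F()
    lo, hi = cfg.ancestral_freq_range
    pbar = rng.uniform(lo, hi, size=cfg.n_sites)
    freqs = np.empty((cfg.n_sites, cfg.n_populations))
    for k in range(cfg.n_populations):
        a = pbar * (1 - F[k]) / F[k]
        b = (1 - pbar) * (1 - F[k]) / F[k]
        freqs[:, k] = rng.beta(a, b)
    return pbar, freqs


def _in_mask(pos: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Membership of 1-based positions in 0-based half-open intervals."""
    if not intervals:
        return np.zeros(len(pos), dtype=bool)
    ivs = sorted(intervals)
    starts = np.array([s for s, _ in ivs])
    ends = np.array([e for _, e in ivs])
    p0 = pos - 1
    idx = np.searchsorted(starts, p0, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = p0[ok] < ends[idx[ok]]
    return out


def draw_site_positions(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unique sorted 1-based positions; density inside masks is reduced
    by ``mask_snp_density`` (emulating repeat-poor centromeres)."""
    masks: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in cfg.genome_layout}
    for chrom, s, e in cfg.mask_intervals:
        masks[chrom].append((s, e))
    weights = []
    for chrom, length in cfg.genome_layout:
        masked = sum(e - s for s, e in masks[chrom])
        weights.append((length - masked) + masked * cfg.mask_snp_density)
    weights = np.asarray(weights, dtype=float)
    counts = rng.multinomial(cfg.n_sites, weights / weights.sum())
    chroms, positions = [], []
    for (chrom, length), count in zip(cfg.genome_layout, counts):
        pos = np.empty(0, dtype=np.int64)
        while len(pos) < count:
            cand = rng.integers(1, length + 1, size=2 * (count - len(pos)) + 16)
            masked = _in_mask(cand, masks[chrom])
            keep = ~masked | (rng.random(len(cand)) < cfg.mask_snp_density)
            pos = np.unique(np.concatenate([pos, cand[keep]]))
        pos = np.sort(rng.choice(pos, size=count, replace=False))
        chroms.append(np.full(count, chrom, dtype=object))
        positions.append(pos)
    return np.concatenate(chroms), np.concatenate(positions)


def _sample_ids(cfg: SimConfig) -> tuple[list[str], list[str], dict, dict]:
    ids, pop_of, hyb_of = [], {}, {}
    for name, n in zip(cfg.population_names, cfg.samples_per_population):
        for j in range(n):
            sid = f"{name}_s{j + 1:02d}"
            ids.append(sid)
            pop_of[sid] = name
    h = 0
    for a, b, count in cfg.n_hybrids:
        for _ in range(count):
            h += 1
            sid = f"hyb{h:02d}_{a}x{b}"
            ids.append(sid)
            hyb_of[sid] = (a, b)
    return ids, cfg.population_names, pop_of, hyb_of


def simulate_genotypes(
    freqs: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    ancestral: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, TruthRecord, np.ndarray]:
    """Diploid genotypes, missingness and depths from population frequencies.

    Non-hybrids draw Binomial(2, p_pop) dosages; F1 hybrids draw one
    allele from each parent population.  Returns (matrix, truth, depth).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if np.any((freqs < 0) | (freqs > 1)):
        raise SimConfigError("frequencies must lie in [0, 1]")
    chrom, pos = draw_site_positions(cfg, rng)
    ids, pop_names, pop_of, hyb_of = _sample_ids(cfg)
    n_sites = cfg.n_sites
    cols = []
    for sid in ids:
        if sid in hyb_of:
            a, b = hyb_of[sid]
            pa = freqs[:, pop_names.index(a)]
            pb = freqs[:, pop_names.index(b)]
            g = rng.binomial(1, pa) + rng.binomial(1, pb)
        else:
            p = freqs[:, pop_names.index(pop_of[sid])]
            g = rng.binomial(2, p)
        cols.append(g.astype(np.int8))
    dosage = np.stack(cols, axis=1)
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = -1
    nb_n = cfg.depth.dispersion
    nb_p = nb_n / (nb_n + cfg.depth.mean)
    depth = rng.negative_binomial(nb_n, nb_p, size=dosage.shape).astype(np.int32)
    years = cfg.years or [2016] * cfg.n_populations
    year_of = {
        sid: years[pop_names.index(pop_of[sid])] if sid in pop_of else max(years)
        for sid in ids
    }
    truth = TruthRecord(
        ancestral_freq=ancestral if ancestral is not None else np.full(n_sites, np.nan),
        population_freqs=freqs,
        population_of=pop_of,
        hybrid_parents=hyb_of,
        mito_lineage={},
        year_of=year_of,
    )
    gm = GenotypeMatrix(samples=ids, chrom=chrom, pos=pos, dosage=dosage)
    return gm, truth, depth


# ---------------------------------------------------------------------
# mitogenome simulation
# ---------------------------------------------------------------------

def _gene_layout(length: int, n_genes: int) -> list[tuple[str, int, int, str]]:
    """Tile n_genes protein-coding genes over the reference with short
    intergenic gaps; a fixed subset sits on the minus strand."""
    gap = 60
    coding = length - gap * (n_genes + 1)
    if coding < n_genes * 30:
        raise SimConfigError("mito reference too short for gene layout")
    base = coding // n_genes
    minus = {i for i in (4, 7, 10, 12) if i < n_genes}
    genes = []
    cursor = gap
    for i in range(n_genes):
        size = base + (1 if i < coding % n_genes else 0)
        start = cursor + 1  # 1-based inclusive
        end = cursor + size
        genes.append((f"gene{i + 1:02d}", start, end, "-" if i in minus else "+"))
        cursor = end + gap
    return genes


def simulate_mito(
    cfg: SimConfig,
    sample_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
    population_of: dict[str, str] | None = None,
) -> MitoSim:
    """Reference mitogenome plus haploid lineage-structured variants.

    Each lineage beyond the reference lineage is defined by a disjoint
    substitution set; samples add Poisson-distributed private mutations
    at globally unique positions.  All variant positions fall inside
    gene intervals.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mc = cfg.mito
    if sample_ids is None:
        sample_ids, _, population_of, _ = _sample_ids(cfg)
    reference = "".join(rng.choice(_BASES, size=mc.length))
    genes = _gene_layout(mc.length, mc.n_genes)
    gene_positions = np.concatenate(
        [np.arange(start, end + 1) for _, start, end, _ in genes]
    )

    counts = mc.substitution_counts()
    n_private_each = rng.poisson(mc.private_rate, size=len(sample_ids))
    total_needed = sum(counts) + int(n_private_each.sum())
    if total_needed > len(gene_positions):
        raise SimConfigError("too many substitutions for gene span")
    chosen = rng.choice(gene_positions, size=total_needed, replace=False)
    cursor = 0
    lineage_sites: list[np.ndarray] = []
    for c in counts:
        lineage_sites.append(np.sort(chosen[cursor : cursor + c]))
        cursor += c
    private_sites: list[np.ndarray] = []
    for npriv in n_private_each:
        private_sites.append(np.sort(chosen[cursor : cursor + npriv]))
        cursor += npriv

    # lineage assignment: alternate within populations unless given
    if mc.assignment is not None:
        if len(mc.assignment) != len(sample_ids):
            raise SimConfigError("mito assignment length != number of samples")
        lineage_of = {s: int(l) for s, l in zip(sample_ids, mc.assignment)}
        if any(not 0 <= l < mc.n_lineages for l in lineage_of.values()):
            raise SimConfigError("mito assignment lineage out of range")
    else:
        lineage_of = {}
        per_pop_counter: dict[str, int] = {}
        for sid in sample_ids:
            pop = (population_of or {}).get(sid, "_")
            c = per_pop_counter.get(pop, 0)
            lineage_of[sid] = c % mc.n_lineages
            per_pop_counter[pop] = c + 1

    all_pos = np.unique(np.concatenate(lineage_sites + private_sites))
    pos_index = {int(p): i for i, p in enumerate(all_pos)}
    geno = np.zeros((len(all_pos), len(sample_ids)), dtype=np.int8)
    ref_alleles = np.array([reference[p - 1] for p in all_pos], dtype=object)
    alt_alleles = np.empty(len(all_pos), dtype=object)
    for i, p in enumerate(all_pos):
        alt_alleles[i] = rng.choice([b for b in _BASES if b != ref_alleles[i]])
    for j, sid in enumerate(sample_ids):
        carried = np.concatenate([lineage_sites[lineage_of[sid]], private_sites[j]])
        for p in carried:
            geno[pos_index[int(p)], j] = 1
    return MitoSim(
        reference=reference,
        genes=genes,
        positions=all_pos.astype(np.int64),
        ref_alleles=ref_alleles,
        alt_alleles=alt_alleles,
        genotypes=geno,
        samples=list(sample_ids),
        lineage_of=lineage_of,
    )


# ---------------------------------------------------------------------
# top-level simulation and serialization
# ---------------------------------------------------------------------

def simulate(cfg: SimConfig) -> SimBundle:
    """Run the full simulation (nuclear + mito) deterministically."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_freq, rng_geno, rng_mito, rng_vcf = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    pbar, freqs = draw_population_frequencies(cfg, rng_freq)
    gm, truth, depth = simulate_genotypes(freqs, cfg, rng_geno, ancestral=pbar)
    mito = simulate_mito(cfg, gm.samples, rng_mito, truth.population_of)
    truth.mito_lineage = dict(mito.lineage_of)

    n_sites = gm.n_sites
    ref_idx = rng_vcf.integers(0, 4, size=n_sites)
    alt_shift = rng_vcf.integers(1, 4, size=n_sites)
    ref_allele = _BASES[ref_idx]
    alt_allele = _BASES[(ref_idx + alt_shift) % 4]
    saf = rng_vcf.integers(2, 40, size=n_sites).astype(np.int64)
    sar = rng_vcf.integers(2, 40, size=n_sites).astype(np.int64)
    if cfg.strand_fail_rate > 0:
        fail = rng_vcf.random(n_sites) < cfg.strand_fail_rate
        which = rng_vcf.random(n_sites) < 0.5
        saf[fail & which] = 0
        sar[fail & ~which] = 0
    return SimBundle(
        config=cfg,
        gm=gm,
        truth=truth,
        depth=depth,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        saf=saf,
        sar=sar,
        mito=mito,
    )


_GT_DIPLOID = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_dataset(bundle: SimBundle, out_dir) -> dict[str, Path]:
    """Write the file bundle: nuclear VCF, mito VCF + reference FASTA,
    gene table, mask BED, sample TSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    gm = bundle.gm
    paths = {
        "nuclear_vcf": out / "nuclear.vcf",
        "mito_vcf": out / "mito.vcf",
        "mito_ref": out / "mito_ref.fasta",
        "genes": out / "genes.tsv",
        "mask_bed": out / "mask.bed",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }

    with open(paths["nuclear_vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=aedespop-simdata\n")
        for chrom, length in cfg.genome_layout:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=SAF,Number=A,Type=Integer,Description='
            '"Alt allele forward-strand supporting reads">\n'
            '##INFO=<ID=SAR,Number=A,Type=Integer,Description='
            '"Alt allele reverse-strand supporting reads">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            calls = [
                f"{_GT_DIPLOID[int(g)]}:{int(d)}"
                for g, d in zip(gm.dosage[i], bundle.depth[i])
            ]
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{bundle.ref_allele[i]}\t"
                f"{bundle.alt_allele[i]}\t.\tPASS\t"
                f"SAF={bundle.saf[i]};SAR={bundle.sar[i]}\tGT:DP\t"
                + "\t".join(calls)
                + "\n"
            )

    m = bundle.mito
    with open(paths["mito_vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=aedespop-simdata\n")
        fh.write(f"##contig=<ID=mito,length={len(m.reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        for i in range(len(m.positions)):
            calls = [str(int(g)) for g in m.genotypes[i]]
            fh.write(
                f"mito\t{m.positions[i]}\t.\t{m.ref_alleles[i]}\t"
                f"{m.alt_alleles[i]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )

    SeqIO.write(
        [SeqRecord(Seq(m.reference), id="mito", description="synthetic mitogenome")],
        str(paths["mito_ref"]),
        "fasta",
    )

    with open(paths["genes"], "w") as fh:
        fh.write("gene\tstart\tend\tstrand\n")
        for gene, start, end, strand in m.genes:
            fh.write(f"{gene}\t{start}\t{end}\t{strand}\n")

    with open(paths["mask_bed"], "w") as fh:
        for chrom, start, end in cfg.mask_intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")

    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tpopulation\tyear\n")
        for sid in gm.samples:
            fh.write(
                f"{sid}\t{bundle.truth.label_of(sid)}\t{bundle.truth.year_of[sid]}\n"
            )

    truth_dump = {
        "seed": cfg.seed,
        "target_F": (
            float(cfg.target_F)
            if np.isscalar(cfg.target_F)
            else [float(x) for x in cfg.target_F]
        ),
        "population_of": bundle.truth.population_of,
        "hybrid_parents": {k: list(v) for k, v in bundle.truth.hybrid_parents.items()},
        "mito_lineage": {k: int(v) for k, v in bundle.truth.mito_lineage.items()},
        "year_of": bundle.truth.year_of,
        "n_sites": int(cfg.n_sites),
        "genome_layout": [[c, int(l)] for c, l in cfg.genome_layout],
    }
    paths["truth"].write_text(json.dumps(truth_dump, indent=2, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------
# temporal founder-effect scenario
# ---------------------------------------------------------------------

def simulate_temporal_bottleneck(
    n_sites: int = 50_000,
    n_samples_before: int = 3,
    n_samples_after: int = 4,
    n_founders: int = 6,
    segment_mean_bp: int = 5_000_000,
    n_sweeps: int = 3,
    sweep_span_bp: int = 400_000,
    sweep_strength: float = 0.5,
    genome_layout: list[tuple[str, int]] | None = None,
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[str], list[str]]:
    """Two temporal samples of one population across a founder event.

    The 'before' individuals draw directly from the standing allele
    frequencies p.  The 'after' population is re-founded by
    ``n_founders`` diploids: the 2 x n_founders founder haplotypes are
    Bernoulli(p) draws, and each sampled gamete three years on is a
    recombinant mosaic of those haplotypes with exponentially
    distributed segment lengths (mean ``segment_mean_bp``).  Because
    nearby sites inherit the same founder haplotype, the founder drift
    pulse -- expected magnitude ~1/(2 n_founders) genome-wide -- is
    locally correlated, so individual windows scatter around it.

    ``n_sweeps`` genomic regions (one per chromosome by default) are
    additionally pushed toward fixation with strength
    ``sweep_strength``, emulating local adaptation during establishment;
    these produce the strongly differentiated, diversity-depleted
    windows that ride on top of the near-zero genome-wide divergence.
    Default sample sizes mirror a 3-vs-4 individual temporal comparison.

    Returns (matrix, before-sample ids, after-sample ids).
    """
    if genome_layout is None:
        genome_layout = _default_layout()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo, hi = ancestral_freq_range
    p = rng.uniform(lo, hi, size=n_sites)

    cfg = SimConfig(
        n_populations=2,
        samples_per_population=[max(n_samples_before, 2), max(n_samples_after, 2)],
        n_sites=n_sites,
        genome_layout=genome_layout,
        missing_rate=0.0,
        seed=seed,
    )
    chrom, pos = draw_site_positions(cfg, rng)

    # selection targets: after-population frequencies shifted toward 0/1
    p_after_base = p.copy()
    for s_i in range(n_sweeps):
        c_name, c_len = genome_layout[s_i % len(genome_layout)]
        center = int(rng.integers(sweep_span_bp, c_len - sweep_span_bp))
        lo_bp, hi_bp = center - sweep_span_bp // 2, center + sweep_span_bp // 2
        target = float(rng.integers(0, 2))
        in_region = (chrom == c_name) & (pos - 1 >= lo_bp) & (pos - 1 < hi_bp)
        p_after_base[in_region] = (
            (1 - sweep_strength) * p[in_region] + sweep_strength * target
        )

    founders = rng.binomial(1, p_after_base, size=(2 * n_founders, n_sites)).astype(
        np.int8
    )
    before_ids = [f"before_s{j + 1:02d}" for j in range(n_samples_before)]
    after_ids = [f"after_s{j + 1:02d}" for j in range(n_samples_after)]
    cols = [rng.binomial(2, p).astype(np.int8) for _ in before_ids]
    site_idx = np.arange(n_sites)
    for _ in after_ids:
        g = np.zeros(n_sites, dtype=np.int8)
        for _gamete in range(2):
            hap_idx = np.zeros(n_sites, dtype=np.intp)
            for c_name, c_len in genome_layout:
                on_c = np.flatnonzero(chrom == c_name)
                n_breaks = rng.poisson(c_len / segment_mean_bp)
                breaks = np.sort(rng.integers(1, c_len, size=n_breaks))
                seg = np.searchsorted(breaks, pos[on_c])
                choice = rng.integers(0, 2 * n_founders, size=n_breaks + 1)
                hap_idx[on_c] = choice[seg]
            g += founders[hap_idx, site_idx]
        cols.append(g)
    gm = GenotypeMatrix(
        samples=before_ids + after_ids,
        chrom=chrom,
        pos=pos,
        dosage=np.stack(cols, axis=1),
    )
    return gm, before_ids, after_ids
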