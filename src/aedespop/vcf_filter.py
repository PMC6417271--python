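"""Site filtering from VCF to an analysis-ready genotype matrix.

The filter chain reproduces a standard low-coverage resequencing
workflow: keep biallelic SNPs only, mask individual genotypes below a
per-sample depth floor (default 8x), require alternate-allele support
on both strands where the caller annotated it, drop sites inside
repeat/centromere mask intervals, and finally drop sites whose missing
fraction exceeds a threshold (default 20%, applied strictly: a site at
exactly the threshold is retained).  The order is fixed so that
depth-masked genotypes count toward site-level missingness.

Coordinates: VCF positions are 1-based; BED mask intervals are 0-based
half-open, so a VCF record at position P is masked when P-1 falls in
[start, end).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genotypes import GenotypeMatrix

DEFAULT_MIN_DEPTH = 8
DEFAULT_MAX_MISSING = 0.20


@dataclass
class VariantTable:
    """All records of a VCF, prior to filtering.

    ``gt`` holds allele indices per (site, sample, allele slot); -1
    marks a missing allele.  ``depth`` is per-sample DP (-1 where the
    annotation is absent).  ``saf``/``sar`` are site-level
    forward/reverse alt-supporting read counts (None when the VCF
    carries no strand annotation).
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alts: np.ndarray  # object array of tuples
    gt: np.ndarray  # (n_sites, n_samples, ploidy) int8
    depth: np.ndarray | None
    saf: np.ndarray | None
    sar: np.ndarray | None
    ploidy: int = 2

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take(self, keep) -> "VariantTable":
        return VariantTable(
            samples=list(self.samples),
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alts=self.alts[keep],
            gt=self.gt[keep],
            depth=None if self.depth is None else self.depth[keep],
            saf=None if self.saf is None else self.saf[keep],
            sar=None if self.sar is None else self.sar[keep],
            ploidy=self.ploidy,
        )


@dataclass
class FilterReport:
    """Per-stage site accounting; counts telescope by construction."""

    stages: list[dict] = field(default_factory=list)
    sample_missingness: dict[str, float] = field(default_factory=dict)
    genotypes_depth_masked: int = 0

    def add(self, name: str, sites_in: int, sites_removed: int, **extra) -> None:
        stage = {
            "filter": name,
            "sites_in": int(sites_in),
            "sites_removed": int(sites_removed),
            "sites_out": int(sites_in - sites_removed),
        }
        stage.update(extra)
        self.stages.append(stage)

    @property
    def sites_out(self) -> int:
        return self.stages[-1]["sites_out"] if self.stages else 0

    def to_json(self, path=None) -> str:
        payload = {
            "stages": self.stages,
            "genotypes_depth_masked": int(self.genotypes_depth_masked),
            "sample_missingness": self.sample_missingness,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def read_vcf(path, ploidy: int = 2) -> VariantTable:
    """Load every record of a VCF with genotypes, depths and strand info.

    Multi-allelic records and indels are preserved here; removing them
    is the biallelic filter's job.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as e:
        raise ValueError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vf.header.samples)
    chrom, pos, ref, alts = [], [], [], []
    gts, depths, safs, sars = [], [], [], []
    has_dp = False
    has_strand = False
    for rec in vf:
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alts.append(tuple(rec.alts or ()))
        row_gt = np.full((len(samples), ploidy), -1, dtype=np.int8)
        row_dp = np.full(len(samples), -1, dtype=np.int32)
        for j, s in enumerate(samples):
            call = rec.samples[s]
            alleles = call.get("GT", None)
            if alleles is None:
                alleles = (None,) * ploidy
            if len(alleles) != ploidy:
                raise ValueError(
                    f"ploidy mismatch at {rec.chrom}:{rec.pos} sample {s}: "
                    f"got {len(alleles)} alleles, expected {ploidy}"
                )
            for a_i, a in enumerate(alleles):
                row_gt[j, a_i] = -1 if a is None else a
            dp = call.get("DP", None)
            if dp is not None:
                row_dp[j] = dp
                has_dp = True
        gts.append(row_gt)
        depths.append(row_dp)
        def _info_get(key):
            # pysam raises on keys absent from the header definition
            try:
                return rec.info.get(key, None)
            except (KeyError, ValueError):
                return None

        saf = _info_get("SAF")
        sar = _info_get("SAR")
        if saf is not None or sar is not None:
            has_strand = True

        def _scalar(v):
            if v is None:
                return -1
            if isinstance(v, (tuple, list)):
                return int(sum(v))
            return int(v)

        safs.append(_scalar(saf))
        sars.append(_scalar(sar))
    n = len(pos)
    return VariantTable(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alts=np.array(alts, dtype=object),
        gt=(
            np.stack(gts) if n else np.empty((0, len(samples), ploidy), dtype=np.int8)
        ),
        depth=(
            (np.stack(depths) if n else np.empty((0, len(samples)), dtype=np.int32))
            if has_dp
            else None
        ),
        saf=np.array(safs, dtype=np.int64) if has_strand else None,
        sar=np.array(sars, dtype=np.int64) if has_strand else None,
        ploidy=ploidy,
    )


def filter_biallelic_snp(vt: VariantTable) -> VariantTable:
    """Keep records with exactly one single-base alternate allele and a
    single-base reference (no indels, no multi-allelics)."""
    keep = np.array(
        [
            len(alts) == 1 and len(r) == 1 and len(alts[0]) == 1
            for r, alts in zip(vt.ref, vt.alts)
        ],
        dtype=bool,
    )
    return vt.take(keep)


def apply_depth_mask(vt: VariantTable, min_depth: int = DEFAULT_MIN_DEPTH) -> VariantTable:
    """Set genotypes with per-sample depth below ``min_depth`` to missing.

    Sites are retained; site-level removal is the missingness filter's
    job.  Pass ``min_depth=None`` to disable explicitly.
    """
    if min_depth is None:
        return vt
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1 (or None to disable)")
    if vt.depth is None:
        raise ValueError(
            "VCF carries no per-sample DP annotation; pass min_depth=None "
            "to disable the depth filter explicitly"
        )
    out = vt.take(np.ones(vt.n_sites, dtype=bool))
    low = (out.depth >= 0) & (out.depth < min_depth)
    out.gt = out.gt.copy()
    out.gt[low] = -1
    return out


def filter_strand_support(vt: VariantTable) -> VariantTable:
    """Drop sites lacking >=1 forward or >=1 reverse alt-supporting read.

    Skipped (with a warning) when the VCF has no strand annotation,
    since that filter is then assumed to have run inside the caller.
    """
    if vt.saf is None or vt.sar is None:
        warnings.warn(
            "no strand-support annotation (SAF/SAR) found; strand filter skipped"
        )
        return vt
    keep = (vt.saf >= 1) & (vt.sar >= 1)
    return vt.take(keep)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED3 mask (0-based half-open)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]), int(f[2])))
    return out


def filter_mask_regions(
    vt: VariantTable, mask: list[tuple[str, int, int]]
) -> VariantTable:
    """Remove records whose 0-based position falls inside a mask interval."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    known = set(vt.chrom)
    for chrom, start, end in mask:
        if chrom not in known:
            warnings.warn(f"mask interval on unknown chromosome {chrom!r}; ignored")
            continue
        by_chrom.setdefault(chrom, []).append((start, end))
    if not by_chrom:
        return vt.take(np.ones(vt.n_sites, dtype=bool))
    remove = np.zeros(vt.n_sites, dtype=bool)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        on_c = vt.chrom == chrom
        p0 = vt.pos[on_c] - 1
        idx = np.searchsorted(starts, p0, side="right") - 1
        hit = (idx >= 0) & (p0 < ends[np.maximum(idx, 0)])
        remove[np.flatnonzero(on_c)[hit]] = True
    return vt.take(~remove)


def _to_matrix(vt: VariantTable) -> GenotypeMatrix:
    missing = (vt.gt < 0).any(axis=2)
    dosage = (vt.gt == 1).sum(axis=2).astype(np.int8)
    dosage[missing] = -1
    return GenotypeMatrix(
        samples=list(vt.samples),
        chrom=vt.chrom,
        pos=vt.pos,
        dosage=dosage,
        ploidy=vt.ploidy,
    )


def filter_missingness(
    vt: VariantTable, max_missing_fraction: float = DEFAULT_MAX_MISSING
) -> tuple[GenotypeMatrix, int]:
    """Drop sites with missing fraction strictly above the threshold and
    convert the survivors to a dosage matrix.

    Returns (matrix, n_sites_removed)."""
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    missing_frac = (vt.gt < 0).any(axis=2).mean(axis=1) if vt.n_sites else np.empty(0)
    keep = missing_frac <= max_missing_fraction
    return _to_matrix(vt.take(keep)), int((~keep).sum())


def run_filter_pipeline(
    vt: VariantTable,
    mask: list[tuple[str, int, int]] | None = None,
    min_depth: int | None = DEFAULT_MIN_DEPTH,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Full chain: biallelic -> depth mask -> strand -> region mask ->
    missingness, with per-stage accounting."""
    report = FilterReport()

    stage = filter_biallelic_snp(vt)
    report.add("biallelic_snp", vt.n_sites, vt.n_sites - stage.n_sites)

    if min_depth is not None and stage.depth is not None:
        before_masked = int((stage.gt < 0).any(axis=2).sum())
        stage = apply_depth_mask(stage, min_depth)
        after_masked = int((stage.gt < 0).any(axis=2).sum())
        report.genotypes_depth_masked = after_masked - before_masked
        report.add(
            "depth_mask",
            stage.n_sites,
            0,
            genotypes_masked=report.genotypes_depth_masked,
            min_depth=min_depth,
        )
    else:
        report.add("depth_mask", stage.n_sites, 0, skipped=True)

    n_in = stage.n_sites
    stage = filter_strand_support(stage)
    report.add("strand_support", n_in, n_in - stage.n_sites)

    n_in = stage.n_sites
    stage = filter_mask_regions(stage, mask or [])
    report.add("region_mask", n_in, n_in - stage.n_sites)

    n_in = stage.n_sites
    gm, removed = filter_missingness(stage, max_missing)
    report.add("missingness", n_in, removed, max_missing=max_missing)

    miss = (gm.dosage < 0).mean(axis=0) if gm.n_sites else np.zeros(gm.n_samples)
    report.sample_missingness = {
        s: float(f) for s, f in zip(gm.samples, miss)
    }
    return gm, report


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    """Site x sample dosage table (missing written as NA)."""
    df = pd.DataFrame(
        gm.dosage.astype(float), columns=gm.samples
    ).replace(-1.0, np.nan)
    df.insert(0, "pos", gm.pos)
    df.insert(0, "chrom", gm.chrom)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_samples_table(path) -> pd.DataFrame:
    """sample_id / population / year table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    required = {"sample_id", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"samples table must have columns {sorted(required)}")
    return df
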