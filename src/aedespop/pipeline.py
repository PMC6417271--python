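"""End-to-end orchestration: filter -> scans -> PCA/clusters -> trees -> mito.

A single :class:`RunConfig` (optionally loaded from a flat YAML file)
drives the whole analysis and produces a machine-readable run report
plus per-stage artifact files.  Re-running with an identical config and
seed reproduces identical outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cluster_pca, mito, popgen_stats, trees, vcf_filter
from .genotypes import GenotypeMatrix

log = logging.getLogger("aedespop")

DEFAULT_HIGHLIGHT_FST = 0.1


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    nuclear_vcf: str
    samples: str
    out_dir: str
    mask_bed: str | None = None
    mito_vcf: str | None = None
    mito_ref: str | None = None
    genes: str | None = None
    min_depth: int | None = 8
    max_missing: float = 0.20
    window_bp: int = 1_000_000
    step_bp: int = 500_000
    min_snps: int = 10
    block_bp: int = 1_000_000
    n_components: int = 10
    k_clusters: int = 4
    n_pcs: int | None = None
    hybrid_threshold: float = 0.5
    highlight_fst: float = DEFAULT_HIGHLIGHT_FST
    n_lineages: int = 2
    comparisons: list[tuple[str, str]] | None = None  # default: all pairs
    chrom_lengths: list[tuple[str, int]] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "comparisons" in data and data["comparisons"] is not None:
            data["comparisons"] = [tuple(c) for c in data["comparisons"]]
        if "chrom_lengths" in data and data["chrom_lengths"] is not None:
            data["chrom_lengths"] = [tuple(c) for c in data["chrom_lengths"]]
        return cls(**data)

    def echo(self) -> dict:
        d = asdict(self)
        return d


def _populations(samples_df: pd.DataFrame) -> dict[str, list[str]]:
    pops: dict[str, list[str]] = {}
    for r in samples_df.itertuples():
        pops.setdefault(str(r.population), []).append(str(r.sample_id))
    return pops


def run_all(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written
    to out_dir/report.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": cfg.echo(), "stages": {}}

    samples_df = vcf_filter.read_samples_table(cfg.samples)
    pops = _populations(samples_df)
    log.info("samples: %d in %d populations", len(samples_df), len(pops))

    # -- filtering ----------------------------------------------------
    vt = vcf_filter.read_vcf(cfg.nuclear_vcf, ploidy=2)
    log.info("read %d variant records from %s", vt.n_sites, cfg.nuclear_vcf)
    mask = vcf_filter.read_bed(cfg.mask_bed) if cfg.mask_bed else []
    gm, filt_report = vcf_filter.run_filter_pipeline(
        vt, mask=mask, min_depth=cfg.min_depth, max_missing=cfg.max_missing
    )
    filt_report.to_json(out / "filter_report.json")
    report["stages"]["filter"] = json.loads(filt_report.to_json())
    log.info("filtering: %d -> %d sites", vt.n_sites, gm.n_sites)

    unknown = [s for s in samples_df.sample_id if s not in set(gm.samples)]
    if unknown:
        raise ValueError(f"samples table names unknown samples: {unknown}")

    # -- per-comparison scans and genome F_ST -------------------------
    comparisons = cfg.comparisons
    if comparisons is None:
        labels = list(pops)
        comparisons = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    chrom_lengths = dict(cfg.chrom_lengths) if cfg.chrom_lengths else None
    scans = {}
    for a, b in comparisons:
        for lab in (a, b):
            if lab not in pops:
                raise ValueError(f"unknown population label {lab!r} in comparisons")
        scan = popgen_stats.windowed_scan(
            gm, pops[a], pops[b], cfg.window_bp, cfg.step_bp, cfg.min_snps,
            chrom_lengths,
        )
        gfst = popgen_stats.genome_fst(gm, pops[a], pops[b], cfg.block_bp)
        path = out / f"scan_{a}_vs_{b}.tsv"
        scan.to_csv(path, sep="\t", index=False)
        high = scan[scan["fst"] > cfg.highlight_fst]
        scans[f"{a}_vs_{b}"] = {
            "scan_tsv": str(path),
            "genome_fst": gfst.estimate,
            "genome_fst_se": gfst.se,
            "n_blocks": gfst.n_blocks,
            "n_windows": int(len(scan)),
            "n_windows_above_highlight": int(len(high)),
            "mean_delta_pi_per_chrom": {
                c: float(v)
                for c, v in scan.groupby("chrom")["delta_pi"].mean().items()
            },
        }
        log.info("%s vs %s: F_ST %.4f +/- %.4f", a, b, gfst.estimate, gfst.se)
    report["stages"]["scans"] = scans

    # -- PCA, clusters, hybrids ---------------------------------------
    pca = cluster_pca.run_pca(gm, n_components=min(cfg.n_components, gm.n_samples - 1))
    pca.coords_frame().to_csv(out / "pca_coords.tsv", sep="\t")
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(pca.variance_fraction))],
            "variance_fraction": pca.variance_fraction,
        }
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
    assignment = cluster_pca.assign_clusters(
        pca, cfg.k_clusters, n_pcs=cfg.n_pcs, seed=cfg.seed
    )
    assignment = cluster_pca.flag_hybrids(assignment, cfg.hybrid_threshold)
    assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
    cluster_sizes = pd.Series(assignment.labels).value_counts().to_dict()
    flagged = assignment.hybrid[assignment.hybrid.hybrid_flag]
    report["stages"]["clusters"] = {
        "k": cfg.k_clusters,
        "n_pcs_used": assignment.n_pcs_used,
        "variance_fraction": [float(v) for v in pca.variance_fraction],
        "cluster_sizes": {str(k): int(v) for k, v in cluster_sizes.items()},
        "hybrids_flagged": flagged.sample_id.tolist(),
    }
    log.info(
        "clusters: %s; %d hybrid(s) flagged", cluster_sizes, len(flagged)
    )

    # -- population F_ST matrix and NJ tree ---------------------------
    fst_df = popgen_stats.pairwise_fst_matrix(gm, pops, cfg.block_bp)
    fst_df.to_csv(out / "pairwise_fst.tsv", sep="\t")
    dm = trees.DistanceMatrix.from_frame(popgen_stats.fst_to_distance(fst_df))
    tree_path = None
    if len(pops) >= 3:
        nuc_tree = trees.nj(dm)
        tree_path = out / "nuclear_fst_nj.nwk"
        trees.write_newick(nuc_tree, tree_path)
    report["stages"]["nuclear_tree"] = {
        "pairwise_fst_tsv": str(out / "pairwise_fst.tsv"),
        "newick": str(tree_path) if tree_path else None,
    }

    # -- mitogenome ----------------------------------------------------
    if cfg.mito_vcf and cfg.mito_ref and cfg.genes:
        consensuses = mito.consensus_from_vcf(cfg.mito_vcf, cfg.mito_ref)
        mito.write_consensus_fasta(consensuses, out / "mito_consensus.fasta")
        genes = mito.read_gene_table(cfg.genes)
        concat = mito.extract_and_concatenate(consensuses, genes)
        concat.write_fasta(out / "mito_concat.fasta")
        lineages, mtree = mito.assign_lineages(concat, cfg.n_lineages)
        mito.write_lineage_table(lineages, out / "mito_lineages.tsv")
        mito_newick = None
        if mtree is not None:
            mito_newick = out / "mito_nj.nwk"
            trees.write_newick(mtree, mito_newick)
        counts = pd.Series(list(lineages.values())).value_counts().to_dict()
        report["stages"]["mito"] = {
            "n_samples": len(consensuses),
            "concat_length": concat.length,
            "lineage_sizes": {str(k): int(v) for k, v in counts.items()},
            "lineage_tsv": str(out / "mito_lineages.tsv"),
            "newick": str(mito_newick) if mito_newick else None,
        }
        log.info("mito lineages: %s", counts)
    else:
        report["stages"]["mito"] = None

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def temporal_compare(
    gm: GenotypeMatrix,
    samples_df: pd.DataFrame,
    population: str,
    year_a: int,
    year_b: int,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
    min_snps: int = 10,
    block_bp: int = 1_000_000,
    highlight_fst: float = DEFAULT_HIGHLIGHT_FST,
    chrom_lengths=None,
) -> tuple[pd.DataFrame, popgen_stats.GenomeFst, pd.DataFrame]:
    """Windowed + genome-wide comparison of two collection years of one
    population.  Same code path as any two-group scan; groups are
    (population, year).  Returns (scan, genome_fst, highlighted windows).
    """
    if "year" not in samples_df.columns:
        raise ValueError("samples table has no 'year' column")
    sel = samples_df[samples_df.population == population]
    ga = sel[sel.year == year_a].sample_id.tolist()
    gb = sel[sel.year == year_b].sample_id.tolist()
    for year, grp in ((year_a, ga), (year_b, gb)):
        if len(grp) < 2:
            raise ValueError(
                f"population {population!r} year {year} has {len(grp)} samples; "
                "need >= 2"
            )
    scan = popgen_stats.windowed_scan(
        gm, ga, gb, window_bp, step_bp, min_snps, chrom_lengths
    )
    gfst = popgen_stats.genome_fst(gm, ga, gb, block_bp)
    high = scan[scan["fst"] > highlight_fst].copy()
    return scan, gfst, high
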