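"""Hudson F_ST, nucleotide diversity and windowed genome scans.

The divergence statistic throughout is Hudson's F_ST in the
two-population parameterization

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)

per site, aggregated as a ratio of averages (sum the numerators and
denominators over sites before dividing), which has much lower bias than
averaging per-site ratios.  ``p`` is the sample alternate-allele
frequency and ``n`` the number of called alleles in each group; sites
with fewer than 2 called alleles in either group are excluded.

Nucleotide diversity within a group uses the unbiased per-site
heterozygosity n/(n-1) * 2p(1-p) and is normalised by window span in
base pairs, so monomorphic (and unobserved) positions contribute zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_STEP_BP = 500_000
DEFAULT_BLOCK_BP = 1_000_000
DEFAULT_MIN_SNPS = 10

SCAN_COLUMNS = ["chrom", "start", "end", "n_snps", "fst", "pi_1", "pi_2", "delta_pi"]


@dataclass
class GenomeFst:
    """Genome-wide Hudson F_ST with a block-jackknife standard error."""

    estimate: float
    se: float
    n_blocks: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.estimate:.4f} +/- {self.se:.4f} ({self.n_blocks} blocks)"


def allele_counts(gm: GenotypeMatrix, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt-allele count, called-allele count) for a sample group."""
    idx = gm.sample_indices(sample_ids)
    d = gm.dosage[:, idx].astype(np.int64)
    called = d >= 0
    n = gm.ploidy * called.sum(axis=1)
    a = np.where(called, d, 0).sum(axis=1)
    return a, n


def site_fst_components(
    a1: np.ndarray, n1: np.ndarray, a2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hudson numerator/denominator per site.

    Returns ``(num, den, valid)`` where ``valid`` marks sites with at
    least two called alleles in both groups; num/den are zero-filled on
    invalid sites so masked sums can be taken directly.
    """
    a1 = np.asarray(a1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(valid, a1 / np.where(n1 > 0, n1, 1), 0.0)
        p2 = np.where(valid, a2 / np.where(n2 > 0, n2, 1), 0.0)
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(valid, num, 0.0)
    den = np.where(valid, den, 0.0)
    return num, den, valid


def site_pi(a: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site heterozygosity n/(n-1) * 2p(1-p).

    Equals the mean pairwise allele difference over all C(n, 2) pairs of
    called alleles.  Returns ``(pi, valid)``; invalid (n < 2) sites are
    zero-filled.
    """
    a = np.asarray(a, dtype=float)
    n = np.asarray(n, dtype=float)
    valid = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(valid, a / np.where(n > 0, n, 1), 0.0)
        pi = n / np.maximum(n - 1, 1) * 2.0 * p * (1.0 - p)
    return np.where(valid, pi, 0.0), valid


def enumerate_windows(
    chrom_length: int, window_bp: int, step_bp: int | None = None
) -> list[tuple[int, int]]:
    """Sliding windows [start, end) from position 0 at step intervals.

    Full-length windows are laid down while they fit on the chromosome;
    a single trailing partial window is appended when the chromosome end
    is not already covered (and a short chromosome yields one window
    spanning it entirely).
    """
    if step_bp is None:
        step_bp = window_bp
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    windows: list[tuple[int, int]] = []
    s = 0
    while s + window_bp <= chrom_length:
        windows.append((s, s + window_bp))
        s += step_bp
    if not windows:
        windows.append((0, chrom_length))
    elif windows[-1][1] < chrom_length:
        windows.append((windows[-1][0] + step_bp, chrom_length))
    return windows


def _chrom_lengths(gm: GenotypeMatrix, chrom_lengths) -> dict[str, int]:
    if chrom_lengths is not None:
        return dict(chrom_lengths)
    out = {}
    for c in gm.chromosomes:
        out[c] = int(gm.pos[gm.chrom == c].max())
    return out


def _window_frame(gm, chrom_lengths, window_bp, step_bp):
    """One row per window with index ranges into the (sorted) site arrays."""
    lengths = _chrom_lengths(gm, chrom_lengths)
    rows = []
    for c in lengths:
        on_c = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[on_c]
        for start, end in enumerate_windows(lengths[c], window_bp, step_bp):
            # site pos is 1-based; window [start, end) is 0-based half-open
            lo = np.searchsorted(pos - 1, start, side="left")
            hi = np.searchsorted(pos - 1, end, side="left")
            rows.append((c, start, end, on_c[lo:hi]))
    return rows


def windowed_fst(
    gm: GenotypeMatrix,
    group1,
    group2,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    min_snps: int = DEFAULT_MIN_SNPS,
    chrom_lengths=None,
) -> pd.DataFrame:
    """Hudson F_ST per sliding window (ratio of averages within each window).

    Windows holding fewer than ``min_snps`` usable sites report NaN.
    """
    a1, n1 = allele_counts(gm, group1)
    a2, n2 = allele_counts(gm, group2)
    num, den, valid = site_fst_components(a1, n1, a2, n2)
    rows = []
    for c, start, end, idx in _window_frame(gm, chrom_lengths, window_bp, step_bp):
        v = valid[idx]
        nsnp = int(v.sum())
        if nsnp < min_snps or den[idx].sum() == 0:
            fst = np.nan
        else:
            fst = num[idx].sum() / den[idx].sum()
        rows.append((c, start, end, nsnp, fst))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])


def windowed_pi(
    gm: GenotypeMatrix,
    group,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    chrom_lengths=None,
) -> pd.DataFrame:
    """Nucleotide diversity per window, normalised by window span in bp."""
    a, n = allele_counts(gm, group)
    pi, valid = site_pi(a, n)
    rows = []
    for c, start, end, idx in _window_frame(gm, chrom_lengths, window_bp, step_bp):
        span = end - start
        rows.append((c, start, end, int(valid[idx].sum()), pi[idx].sum() / span))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi"])


def delta_pi(pi1: pd.DataFrame, pi2: pd.DataFrame) -> pd.Series:
    """Elementwise pi_1 - pi_2 over aligned window grids."""
    key = ["chrom", "start", "end"]
    if len(pi1) != len(pi2) or not (
        pi1[key].reset_index(drop=True).equals(pi2[key].reset_index(drop=True))
    ):
        raise ValueError("window grids do not match")
    return (pi1["pi"].to_numpy() - pi2["pi"].to_numpy())


def windowed_scan(
    gm: GenotypeMatrix,
    group1,
    group2,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    min_snps: int = DEFAULT_MIN_SNPS,
    chrom_lengths=None,
) -> pd.DataFrame:
    """Joint window table: F_ST, pi per group and delta-pi (pi_1 - pi_2)."""
    fst = windowed_fst(gm, group1, group2, window_bp, step_bp, min_snps, chrom_lengths)
    p1 = windowed_pi(gm, group1, window_bp, step_bp, chrom_lengths)
    p2 = windowed_pi(gm, group2, window_bp, step_bp, chrom_lengths)
    out = fst.copy()
    out["pi_1"] = p1["pi"]
    out["pi_2"] = p2["pi"]
    out["delta_pi"] = delta_pi(p1, p2)
    return out[SCAN_COLUMNS]


def genome_fst(
    gm: GenotypeMatrix,
    group1,
    group2,
    block_bp: int = DEFAULT_BLOCK_BP,
) -> GenomeFst:
    """Genome-wide Hudson F_ST with delete-one-block jackknife SE.

    Blocks are non-overlapping ``block_bp`` intervals per chromosome;
    only blocks containing usable sites enter the jackknife.  With a
    single block the SE is reported as NaN with a warning.
    """
    a1, n1 = allele_counts(gm, group1)
    a2, n2 = allele_counts(gm, group2)
    num, den, valid = site_fst_components(a1, n1, a2, n2)
    total_n = num[valid].sum()
    total_d = den[valid].sum()
    if total_d == 0:
        raise ValueError("no usable sites for F_ST (denominator is zero)")
    estimate = total_n / total_d

    # block sums keyed by (chrom, block index)
    codes = pd.factorize(gm.chrom)[0]
    block_key = codes.astype(np.int64) * (2**32) + (gm.pos - 1) // block_bp
    keys, inv = np.unique(block_key[valid], return_inverse=True)
    bn = np.bincount(inv, weights=num[valid], minlength=len(keys))
    bd = np.bincount(inv, weights=den[valid], minlength=len(keys))
    g = len(keys)
    if g < 2:
        warnings.warn("fewer than 2 blocks contain sites; jackknife SE undefined")
        return GenomeFst(estimate=float(estimate), se=float("nan"), n_blocks=g)
    loo = (total_n - bn) / (total_d - bd)
    se = np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
    return GenomeFst(estimate=float(estimate), se=float(se), n_blocks=g)


def pairwise_fst_matrix(
    gm: GenotypeMatrix,
    populations: dict[str, list[str]],
    block_bp: int = DEFAULT_BLOCK_BP,
) -> pd.DataFrame:
    """Symmetric genome-wide Hudson F_ST between every population pair.

    Negative estimates (common between near-identical groups) are
    retained here; clamp with :func:`fst_to_distance` before tree
    building.  Populations with fewer than 2 samples are computed but
    trigger a warning, as estimates are then very noisy.
    """
    labels = list(populations)
    if len(labels) < 2:
        raise ValueError("need at least 2 populations")
    for lab in labels:
        if len(populations[lab]) < 2:
            warnings.warn(f"population {lab!r} has <2 samples; F_ST will be noisy")
    k = len(labels)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            est = genome_fst(
                gm, populations[labels[i]], populations[labels[j]], block_bp
            ).estimate
            mat[i, j] = mat[j, i] = est
    return pd.DataFrame(mat, index=labels, columns=labels)


def fst_to_distance(fst_matrix: pd.DataFrame) -> pd.DataFrame:
    """Clamp negative F_ST estimates to 0 for use as tree distances."""
    return fst_matrix.clip(lower=0.0)
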