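"""PCA population structure, k-means cluster assignment and hybrid flagging.

Genotype dosages are mean-imputed per site, centered, and scaled by
1/sqrt(p(1-p)) with p the observed alternate-allele frequency
(drift-variance scaling, the standard choice for genotype PCA).
Clusters are assigned by k-means over the leading components, which
formalizes the visual cluster-calling step of a typical PCA figure.

A putative F1 hybrid lies near the midpoint of the segment joining its
parent clusters' centroids and far from both.  The admixture score for
a sample against a cluster pair (i, j) is

    score = 1 - 2 |t - d/2| / d,   t = projection onto the i->j axis,

clipped to [0, 1]: 0 at either centroid, 1 exactly at the midpoint.
A sample is flagged when the score against its two *nearest* centroids
reaches the threshold and its distance to the nearest centroid exceeds
the 95th percentile of within-cluster distances; restricting the
candidate pair to the two nearest centroids prevents members of a
third cluster (which project near the midpoint of any axis between two
other clusters) from being flagged spuriously.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genotypes import GenotypeMatrix


@dataclass
class PcaResult:
    samples: list[str]
    coords: np.ndarray  # (n_samples, n_components)
    variance_fraction: np.ndarray
    center: np.ndarray  # per retained site (2 * p-hat)
    scale: np.ndarray  # per retained site sqrt(p-hat (1 - p-hat))
    site_index: np.ndarray  # indices of retained sites in the input matrix

    def coords_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.samples, columns=cols)


@dataclass
class ClusterAssignment:
    samples: list[str]
    labels: list[str]  # GC1..GCk, ordered by descending cluster size
    centroids: np.ndarray  # (k, n_pcs_used), same label order
    n_pcs_used: int
    coords: np.ndarray  # the coordinates clustering ran on
    hybrid: pd.DataFrame | None = None  # filled by flag_hybrids

    @property
    def cluster_names(self) -> list[str]:
        return [f"GC{i + 1}" for i in range(len(self.centroids))]

    def label_index(self) -> np.ndarray:
        order = {name: i for i, name in enumerate(self.cluster_names)}
        return np.array([order[l] for l in self.labels])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.samples, "cluster": self.labels})
        if self.hybrid is not None:
            df = df.merge(self.hybrid, on="sample_id", how="left")
        return df


def prepare_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Imputed, centered, scaled samples x sites matrix.

    Missing dosages take the site mean; monomorphic and fully-missing
    sites are dropped.  Returns (X, center, scale, kept_site_index).
    """
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise ValueError("need at least 2 samples and 2 sites for PCA")
    d = gm.dosage.astype(float).T  # samples x sites
    missing = d < 0
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        warnings.warn(f"dropping {int(fully_missing.sum())} fully-missing sites")
    with np.errstate(invalid="ignore"):
        called = (~missing).sum(axis=0)
        mean = np.where(called > 0, np.where(missing, 0, d).sum(axis=0), 0) / np.maximum(
            called, 1
        )
    p_hat = mean / gm.ploidy
    poly = (~fully_missing) & (p_hat > 0) & (p_hat < 1)
    if not poly.any():
        raise ValueError("all sites are monomorphic; PCA undefined")
    keep = np.flatnonzero(poly)
    d = d[:, keep]
    missing = missing[:, keep]
    center = mean[keep]
    scale = np.sqrt(p_hat[keep] * (1 - p_hat[keep]))
    d = np.where(missing, center, d)
    X = (d - center) / scale
    return X, center, scale, keep


def run_pca(
    gm_or_matrix, n_components: int = 10, samples: list[str] | None = None
) -> PcaResult:
    """Principal components of the prepared genotype matrix via SVD.

    Accepts either a GenotypeMatrix (prepared internally) or an already
    prepared samples x sites array.  Variance fractions come from the
    squared singular values; each component's sign is fixed so that its
    largest-magnitude site loading is positive.
    """
    if isinstance(gm_or_matrix, GenotypeMatrix):
        X, center, scale, site_index = prepare_matrix(gm_or_matrix)
        samples = list(gm_or_matrix.samples)
    else:
        X = np.asarray(gm_or_matrix, dtype=float)
        center = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
        site_index = np.arange(X.shape[1])
        if samples is None:
            samples = [f"s{i}" for i in range(X.shape[0])]
    n_samples, n_sites = X.shape
    max_rank = min(n_samples - 1, n_sites)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds max rank {max_rank}"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"matrix rank {rank} < requested components; returning {k}")
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(k):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    coords = U[:, :k] * S[:k]
    total = (S**2).sum()
    var_frac = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaResult(
        samples=samples,
        coords=coords,
        variance_fraction=var_frac,
        center=center,
        scale=scale,
        site_index=site_index,
    )


def _default_n_pcs(pca: PcaResult, k: int, seed: int) -> int:
    """Leading components covering >=80% of the among-cluster variance.

    A pilot k-means over all returned components measures how much
    between-cluster sum of squares each component carries; trailing
    components that only hold within-cluster noise are then excluded
    from the final clustering and from the hybrid geometry (never fewer
    than 2 components).
    """
    n_comp = pca.coords.shape[1]
    if k < 2 or n_comp <= 2:
        return min(2, n_comp)
    pilot = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pca.coords)
    centers = pilot.cluster_centers_
    sizes = np.bincount(pilot.labels_, minlength=k).astype(float)
    grand = pca.coords.mean(axis=0)
    between = (sizes[:, None] * (centers - grand) ** 2).sum(axis=0)
    total = between.sum()
    if total <= 0:
        return min(2, n_comp)
    cum = np.cumsum(between) / total
    q = int(np.searchsorted(cum, 0.8) + 1)
    return max(2, min(q, n_comp))


def assign_clusters(
    pca: PcaResult,
    k: int,
    n_pcs: int | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """k-means over the leading components; labels GC1..GCk ordered by
    descending cluster size (ties by first member) for determinism."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(pca.samples):
        raise ValueError(f"k={k} exceeds {len(pca.samples)} samples")
    q = (
        _default_n_pcs(pca, k, seed)
        if n_pcs is None
        else min(n_pcs, pca.coords.shape[1])
    )
    coords = pca.coords[:, :q]
    if k == 1:
        raw = np.zeros(len(pca.samples), dtype=int)
        centers = coords.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=25, random_state=seed)
        raw = km.fit_predict(coords)
        centers = km.cluster_centers_
    sizes = np.bincount(raw, minlength=k)
    first_member = np.full(k, len(raw))
    for i, c in enumerate(raw):
        first_member[c] = min(first_member[c], i)
    order = sorted(range(k), key=lambda c: (-sizes[c], first_member[c]))
    relabel = {old: new for new, old in enumerate(order)}
    labels = [f"GC{relabel[c] + 1}" for c in raw]
    centroids = centers[order]
    return ClusterAssignment(
        samples=list(pca.samples),
        labels=labels,
        centroids=centroids,
        n_pcs_used=q,
        coords=coords,
    )


def admixture_scores(assignment: ClusterAssignment) -> pd.DataFrame:
    """Midpoint score of every sample against every cluster pair."""
    rows = []
    cent = assignment.centroids
    names = assignment.cluster_names
    for si, sample in enumerate(assignment.samples):
        x = assignment.coords[si]
        for i in range(len(cent)):
            for j in range(i + 1, len(cent)):
                d = np.linalg.norm(cent[j] - cent[i])
                if d == 0:
                    score = 0.0
                else:
                    t = float((x - cent[i]) @ (cent[j] - cent[i]) / d)
                    score = float(np.clip(1 - 2 * abs(t - d / 2) / d, 0, 1))
                rows.append((sample, names[i], names[j], score))
    return pd.DataFrame(rows, columns=["sample_id", "cluster_a", "cluster_b", "score"])


def flag_hybrids(
    assignment: ClusterAssignment, threshold: float = 0.5
) -> ClusterAssignment:
    """Flag putative F1 hybrids between the two nearest clusters.

    Conditions: midpoint score against the two nearest centroids >=
    ``threshold`` AND distance to the nearest centroid above the 95th
    percentile of within-cluster distances.
    """
    cent = assignment.centroids
    names = assignment.cluster_names
    k = len(cent)
    n = len(assignment.samples)
    own_idx = assignment.label_index()
    dists = np.linalg.norm(
        assignment.coords[:, None, :] - cent[None, :, :], axis=2
    )  # (n, k)
    intra = dists[np.arange(n), own_idx]
    cutoff = np.percentile(intra, 95) if n else 0.0
    flags, parents_a, parents_b, scores = [], [], [], []
    for si in range(n):
        if k < 2:
            flags.append(False)
            parents_a.append(None)
            parents_b.append(None)
            scores.append(0.0)
            continue
        order = np.argsort(dists[si], kind="stable")
        i, j = sorted(order[:2])
        d = np.linalg.norm(cent[j] - cent[i])
        if d == 0:
            score = 0.0
        else:
            t = float(
                (assignment.coords[si] - cent[i]) @ (cent[j] - cent[i]) / d
            )
            score = float(np.clip(1 - 2 * abs(t - d / 2) / d, 0, 1))
        flagged = bool(score >= threshold and dists[si].min() > cutoff)
        flags.append(flagged)
        parents_a.append(names[i] if flagged else None)
        parents_b.append(names[j] if flagged else None)
        scores.append(score)
    hybrid = pd.DataFrame(
        {
            "sample_id": assignment.samples,
            "hybrid_flag": flags,
            "parent_a": parents_a,
            "parent_b": parents_b,
            "score": scores,
        }
    )
    return ClusterAssignment(
        samples=assignment.samples,
        labels=assignment.labels,
        centroids=assignment.centroids,
        n_pcs_used=assignment.n_pcs_used,
        coords=assignment.coords,
        hybrid=hybrid,
    )
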