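"""Choosing a sequencing reference set from a genotyped population.

The strategy mirrors standard practice in livestock genomics: build the
genomic relationship matrix (GRM, VanRaden method 1) of the genotyped
cohort, cluster its spectral embedding with k-means into as many clusters
as animals to be sequenced, and within each cluster pick the sire with the
largest number of genotyped progeny, so the chosen animals jointly tag the
haplotype diversity of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Genomic relationship matrix over an ordered sample set."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square over sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if (np.diag(self.values) < -1e-12).any():
            raise ValueError("GRM diagonal must be non-negative")


@dataclass
class ClusterAssignment:
    k: int
    labels: dict[str, int]
    representatives: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(self.labels.values())
        if len(present) != self.k:
            raise ValueError(f"expected {self.k} non-empty clusters, found {len(present)}")
        for cluster, rep in self.representatives.items():
            if self.labels.get(rep) != cluster:
                raise ValueError(f"representative {rep!r} is not a member of cluster {cluster}")


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM: G = Z Z' / (2 * sum_j p_j (1 - p_j)).

    Z is the genotype matrix centred by twice the observed alt-allele
    frequency per site.  Missing genotypes are mean-imputed per site for
    this computation only; monomorphic sites carry zero weight.
    """
    codes = genotypes.codes.astype(float)
    miss = genotypes.codes == MISSING
    obs = ~miss
    counts = np.where(obs, codes, 0.0).sum(axis=0)
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("site with no observed genotypes; filter first")
    p = counts / (2.0 * n_obs)
    het = p * (1.0 - p)
    if het.sum() <= 0:
        raise ValueError("all sites monomorphic; GRM undefined")
    codes[miss] = np.broadcast_to(2.0 * p, codes.shape)[miss]
    z = codes - 2.0 * p
    g = (z @ z.T) / (2.0 * het.sum())
    g = (g + g.T) / 2.0  # exact symmetry against rounding
    return GRM(sample_ids=list(genotypes.sample_ids), values=g)


def spectral_embedding(grm: GRM, n_components: int) -> np.ndarray:
    """Leading eigenvectors of the GRM scaled by sqrt(eigenvalue).

    This is the principal-component representation of relationship
    structure; clustering it avoids conflating an animal's self-relationship
    (inbreeding) with its relationship pattern.
    """
    n = len(grm.sample_ids)
    if not 1 <= n_components <= n:
        raise ValueError("n_components must lie in [1, n_samples]")
    vals, vecs = eigh(grm.values, subset_by_index=(n - n_components, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def kmeans_reference_clusters(
    grm: GRM, k: int, n_components: int = 20, seed: int = 0
) -> ClusterAssignment:
    """k-means on the spectral embedding of the GRM.

    Uses k-means++ initialisation with 10 restarts and a fixed seed, so the
    assignment is deterministic.  scikit-learn relocates empty clusters
    internally, so every returned cluster is non-empty.
    """
    n = len(grm.sample_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    n_components = min(n_components, n)
    emb = spectral_embedding(grm, n_components)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(emb)
    if len(np.unique(labels)) < k:  # pragma: no cover - sklearn guards this
        logger.warning("k-means produced empty clusters; re-seeding once")
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed + 1)
        labels = km.fit_predict(emb)
    return ClusterAssignment(k=k, labels=dict(zip(grm.sample_ids, (int(l) for l in labels))))


def pick_representatives(
    assignment: ClusterAssignment, progeny_counts: dict[str, int] | pd.Series
) -> ClusterAssignment:
    """Per cluster, the sample with the most genotyped progeny.

    Samples without a recorded count default to 0; ties break toward the
    lexicographically smallest sample id (logged), so selection is
    deterministic.
    """
    counts = dict(progeny_counts) if not isinstance(progeny_counts, dict) else progeny_counts
    reps: dict[int, str] = {}
    by_cluster: dict[int, list[str]] = {}
    for sample, cluster in assignment.labels.items():
        by_cluster.setdefault(cluster, []).append(sample)
    for cluster, members in by_cluster.items():
        ranked = sorted(members, key=lambda s: (-counts.get(s, 0), s))
        reps[cluster] = ranked[0]
        if len(ranked) > 1 and counts.get(ranked[0], 0) == counts.get(ranked[1], 0):
            logger.info("cluster %d: tie on progeny count, picked %s lexicographically", cluster, ranked[0])
    return ClusterAssignment(k=assignment.k, labels=dict(assignment.labels), representatives=reps)
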