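"""Pan-/core-genome statistics, persistence, and presence/absence ordination.

Definitions used throughout (identical for DAB and SB cluster sets):

* **persistence** of a cluster — number of genomes containing at least one
  member, divided by the total number of genomes considered; in (0, 1].
* **pan genome** — the total number of clusters.
* **core genome** — clusters with persistence exactly 1.
* **singleton** — a cluster containing exactly one *protein* (not one genome:
  a one-genome cluster with several paralogs is not a singleton).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .annotation_io import ClusterSet
from .clustering import AbundanceMatrix

__all__ = [
    "PersistenceProfile",
    "PangenomeSummary",
    "persistence",
    "summarize",
    "singleton_ratio",
    "presence_pca",
    "flag_outliers",
    "round_ratio",
]


def round_ratio(x: float | None, ndigits: int = 2) -> float | None:
    """Round half-up to the printed precision (2 decimals by default)."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PersistenceProfile:
    """Per-cluster persistence values and their histogram.

    The histogram uses ``n_bins`` equal bins on (0, 1]; a cluster present in
    every genome (persistence 1) falls in the top bin. Bin counts sum to the
    number of clusters.
    """

    values: dict[str, float]
    n_genomes: int
    n_bins: int = 20
    bin_edges: np.ndarray = field(init=False)
    histogram: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        vals = np.fromiter(self.values.values(), dtype=float, count=len(self.values))
        if len(vals) and ((vals <= 0).any() or (vals > 1).any()):
            raise ValueError("persistence values must lie in (0, 1]")
        self.histogram, self.bin_edges = np.histogram(
            vals, bins=self.n_bins, range=(0.0, 1.0)
        )


@dataclass
class PangenomeSummary:
    """Pan/core/singleton counts and the two ratios reported alongside them.

    Ratios are plain quotients; ``*_rounded`` applies half-up rounding at two
    decimals, matching how such ratios are conventionally printed.
    ``core_singletons`` is ``None`` (an explicit undefined marker, never an
    infinity) when there are no singletons.
    """

    n_genomes: int
    pan_size: int
    core_size: int
    singleton_count: int

    def __post_init__(self) -> None:
        if self.core_size > self.pan_size:
            raise ValueError("core size cannot exceed the pan size")
        if self.singleton_count > self.pan_size:
            # impossible for computed summaries, but published count tables are
            # occasionally inconsistent as printed; keep them usable as inputs
            warnings.warn(
                f"singleton count {self.singleton_count} exceeds pan size "
                f"{self.pan_size}; counts are inconsistent"
            )

    @property
    def core_pan(self) -> float | None:
        return self.core_size / self.pan_size if self.pan_size else None

    @property
    def core_singletons(self) -> float | None:
        if self.singleton_count == 0:
            return None
        return self.core_size / self.singleton_count

    @property
    def core_pan_rounded(self) -> float | None:
        return round_ratio(self.core_pan)

    @property
    def core_singletons_rounded(self) -> float | None:
        return round_ratio(self.core_singletons)


def _genomes_of(
    clusters: ClusterSet, protein_to_genome: Mapping[str, str]
) -> dict[str, set[str]]:
    per_cluster: dict[str, set[str]] = {}
    for cid, members in clusters.clusters.items():
        gs = set()
        for p in members:
            try:
                gs.add(protein_to_genome[p])
            except KeyError:
                raise KeyError(
                    f"protein {p!r} (cluster {cid!r}) has no genome mapping"
                ) from None
        per_cluster[cid] = gs
    return per_cluster


def persistence(
    clusters: ClusterSet,
    protein_to_genome: Mapping[str, str],
    n_genomes: int | None = None,
    n_bins: int = 20,
) -> PersistenceProfile:
    """Per-cluster persistence over the genome set.

    ``n_genomes`` defaults to the number of distinct genomes in the mapping
    (pass it explicitly if some considered genomes contributed no proteins).
    """
    if n_genomes is None:
        n_genomes = len(set(protein_to_genome.values()))
    if n_genomes < 1:
        raise ValueError("need at least one genome")
    per_cluster = _genomes_of(clusters, protein_to_genome)
    values = {cid: len(gs) / n_genomes for cid, gs in per_cluster.items()}
    return PersistenceProfile(values=values, n_genomes=n_genomes, n_bins=n_bins)


def summarize(
    clusters: ClusterSet,
    protein_to_genome: Mapping[str, str],
    n_genomes: int | None = None,
) -> PangenomeSummary:
    """Pan, core and singleton counts for a cluster set."""
    prof = persistence(clusters, protein_to_genome, n_genomes=n_genomes)
    core = sum(1 for v in prof.values.values() if v == 1.0)
    singletons = sum(1 for m in clusters.clusters.values() if len(m) == 1)
    return PangenomeSummary(
        n_genomes=prof.n_genomes,
        pan_size=clusters.n_clusters,
        core_size=core,
        singleton_count=singletons,
    )


def singleton_ratio(
    summary_a: PangenomeSummary, summary_b: PangenomeSummary
) -> float | None:
    """Ratio of singleton counts between two analyses of the same genome set.

    ``None`` marks the undefined case (no singletons in the denominator).
    """
    if summary_b.singleton_count == 0:
        return None
    return summary_a.singleton_count / summary_b.singleton_count


def presence_pca(
    matrix: AbundanceMatrix, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the binarized presence/absence matrix.

    Columns are mean-centered, not unit-scaled (standard for presence/absence
    ordination). Returns ``(scores, explained_variance_ratio)`` with one score
    row per genome, in ``matrix.genome_ids`` order. Scores are deterministic
    up to component sign. A zero-variance matrix (identical genomes) yields
    all-zero scores with a warning.
    """
    if matrix.n_genomes < 2:
        raise ValueError("PCA needs at least two genomes")
    if n_components > min(matrix.n_genomes, matrix.pan_size):
        raise ValueError("n_components exceeds matrix rank bound")
    X = matrix.presence.astype(float)
    if not (X != X[0]).any():
        warnings.warn("presence matrix has no variance; all scores are zero")
        return (
            np.zeros((matrix.n_genomes, n_components)),
            np.zeros(n_components),
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def flag_outliers(
    matrix: AbundanceMatrix,
    multiple: float = 4.0,
    n_components: int = 2,
) -> list[str]:
    """Genomes far from the group centroid in presence/absence PCA space.

    A genome is flagged when its score-space distance to the centroid exceeds
    ``multiple`` times the median distance. Advisory only — exclusion is the
    user's decision.
    """
    if matrix.n_genomes < 3:
        raise ValueError("outlier flagging needs at least three genomes")
    n_components = min(n_components, matrix.n_genomes - 1, matrix.pan_size)
    scores, _ = presence_pca(matrix, n_components=n_components)
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    med = float(np.median(dist))
    cutoff = multiple * med
    return [
        g for g, d in zip(matrix.genome_ids, dist) if np.isfinite(cutoff) and d > cutoff
    ]
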