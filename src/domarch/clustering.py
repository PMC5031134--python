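"""Domain-architecture-based (DAB) clustering and abundance matrices.

DAB clusters are simply the equivalence classes of the architecture label:
every protein carrying the same canonical label string lands in the same
cluster, and the label string itself is the cluster id — which makes
independently computed analyses mergeable by construction.

The genome × architecture abundance matrix counts proteins per label per
genome; its binarized presence/absence view feeds persistence, Heaps and PCA
computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_io import ClusterSet
from .architecture import ArchitectureLabel

logger = logging.getLogger(__name__)

__all__ = ["AbundanceMatrix", "dab_cluster", "abundance_matrix"]

LabelMap = Mapping[str, "ArchitectureLabel | str"]


def _canon(label: "ArchitectureLabel | str") -> str:
    return label.canonical_string if isinstance(label, ArchitectureLabel) else label


@dataclass
class AbundanceMatrix:
    """Genomes × architectures count matrix with a presence/absence view.

    ``architecture_labels`` are in deterministic (lexicographic) order; no
    column may be all-zero — every architecture is present in at least one
    genome. All-zero *rows* (genomes without a single labeled protein) are
    permitted but logged.
    """

    genome_ids: list[str]
    architecture_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.genome_ids), len(self.architecture_labels)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genome_ids)} genomes × "
                f"{len(self.architecture_labels)} architectures"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.architecture_labels and not self.counts.any(axis=0).all():
            raise ValueError("all-zero architecture column(s) present")

    @property
    def presence(self) -> np.ndarray:
        """Binarized view: presence = count >= 1."""
        return (self.counts >= 1).astype(np.int8)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def pan_size(self) -> int:
        return len(self.architecture_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.genome_ids, columns=self.architecture_labels
        )

    def drop_genomes(self, excluded: set[str]) -> "AbundanceMatrix":
        """Row-filter, dropping architectures no longer present anywhere."""
        keep = [i for i, g in enumerate(self.genome_ids) if g not in excluded]
        sub = self.counts[keep, :]
        col_keep = sub.any(axis=0)
        return AbundanceMatrix(
            genome_ids=[self.genome_ids[i] for i in keep],
            architecture_labels=[
                a for a, k in zip(self.architecture_labels, col_keep) if k
            ],
            counts=sub[:, col_keep],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(
            genome_ids=[str(g) for g in df.index],
            architecture_labels=[str(c) for c in df.columns],
            counts=df.to_numpy(dtype=np.int64),
        )


def dab_cluster(label_maps: Mapping[str, LabelMap]) -> ClusterSet:
    """Group proteins by identical architecture label.

    ``label_maps`` maps genome_id → (protein_id → label). Protein ids must be
    globally unique. One cluster per distinct canonical label string; the
    cluster id *is* the label string.
    """
    clusters: dict[str, set[str]] = {}
    for labels in label_maps.values():
        for protein_id, label in labels.items():
            clusters.setdefault(_canon(label), set()).add(protein_id)
    n_proteins = sum(len(m) for m in label_maps.values())
    n_clustered = sum(len(v) for v in clusters.values())
    if n_clustered != n_proteins:
        raise ValueError(
            "protein ids are not globally unique across genomes "
            f"({n_proteins} labeled proteins, {n_clustered} distinct ids)"
        )
    return ClusterSet(
        label="DAB",
        clusters={cid: frozenset(v) for cid, v in clusters.items()},
    )


def abundance_matrix(label_maps: Mapping[str, LabelMap]) -> AbundanceMatrix:
    """Count proteins per architecture per genome.

    Column order is lexicographic on the canonical label string. A genome with
    no labeled proteins keeps its all-zero row (with a logged warning).
    """
    genome_ids = sorted(label_maps)
    all_labels = sorted(
        {_canon(lbl) for labels in label_maps.values() for lbl in labels.values()}
    )
    col = {a: j for j, a in enumerate(all_labels)}
    counts = np.zeros((len(genome_ids), len(all_labels)), dtype=np.int64)
    for i, g in enumerate(genome_ids):
        for label in label_maps[g].values():
            counts[i, col[_canon(label)]] += 1
        if not counts[i].any():
            logger.warning("genome %s has no labeled proteins (all-zero row)", g)
    return AbundanceMatrix(
        genome_ids=genome_ids, architecture_labels=all_labels, counts=counts
    )
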