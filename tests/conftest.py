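from __future__ import annotations

import numpy as np
import pytest

from domarch.annotation_io import ClusterSet, DomainHit, SourceDB


@pytest.fixture
def make_hit():
    def _make(
        domain_id: str,
        start: int,
        end: int,
        protein_id: str = "p1",
        genome_id: str = "g1",
        source_db: SourceDB = SourceDB.PFAM,
    ) -> DomainHit:
        return DomainHit(
            protein_id=protein_id,
            genome_id=genome_id,
            domain_id=domain_id,
            source_db=source_db,
            start=start,
            end=end,
        )

    return _make


def random_hits(rng: np.random.Generator, n: int, protein_id: str = "p1"):
    """Random hit lists drawn so positional ties and overlaps actually occur."""
    alphabet = [f"PF{c}" for c in "ABCDEFGHIJ"]
    hits = []
    for _ in range(n):
        start = int(rng.integers(1, 120))
        length = int(rng.integers(5, 80))
        hits.append(
            DomainHit(
                protein_id=protein_id,
                genome_id="g1",
                domain_id=str(rng.choice(alphabet)),
                source_db=SourceDB.PFAM,
                start=start,
                end=start + length,
            )
        )
    return hits


def random_partition_pair(
    rng: np.random.Generator, n_proteins: int, n_clusters: int
) -> tuple[ClusterSet, ClusterSet]:
    """A correlated pair of random partitions of the same universe."""
    proteins = [f"p{i}" for i in range(n_proteins)]
    a_assign = rng.integers(0, n_clusters, size=n_proteins)
    # perturb ~30% of memberships so identical, subset and split cases all occur
    b_assign = a_assign.copy()
    flip = rng.random(n_proteins) < 0.3
    b_assign[flip] = rng.integers(0, n_clusters, size=int(flip.sum()))

    def build(assign, label):
        clusters: dict[str, set[str]] = {}
        for p, c in zip(proteins, assign):
            clusters.setdefault(f"{label}{c}", set()).add(p)
        return ClusterSet(
            label=label, clusters={k: frozenset(v) for k, v in clusters.items()}
        )

    return build(a_assign, "A"), build(b_assign, "B")
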