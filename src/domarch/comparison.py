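"""Directional comparison of DAB and SB cluster sets over a shared universe.

Two partitions of the same proteins are compared in both directions. Taking
one partition as the reference, each of its clusters touches some number N of
clusters of the other partition:

* a cluster with an *identical* counterpart (exact protein-set equality) is a
  one-to-one agreement;
* a non-identical cluster with N = 1 is a strict subset of a single
  counterpart cluster (a ``1d→1s`` or ``1s→1d`` mismatch);
* N >= 2 means the cluster's members are scattered across several
  counterpart clusters.

Counts of N are binned as {1, 2, 3, 4, 5, 6+}; one-to-one clusters are kept
out of the histogram and reported separately (raw N values are also emitted so
either rendering can be reproduced).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .annotation_io import ClusterSet
from .architecture import ArchitectureLabel, domain_count

__all__ = [
    "MismatchProfile",
    "counterpart_counts",
    "classify",
    "identical_cluster_count",
    "one_to_one_composition",
    "HISTOGRAM_BINS",
]

HISTOGRAM_BINS: tuple[str, ...] = ("1", "2", "3", "4", "5", "6+")


def _bin_of(n: int) -> str:
    return str(n) if n <= 5 else "6+"


@dataclass
class MismatchProfile:
    """Counterpart histogram for one comparison direction.

    ``histogram`` counts only clusters *without* an identical counterpart;
    ``one_to_one`` (identical in both directions) is reported separately.
    ``subset_count`` is the N = 1 bin: reference clusters that are strict
    subsets of one counterpart cluster. ``raw_counts`` keeps every reference
    cluster's N for re-binning.
    """

    direction: str  # "D->S" or "S->D"
    n_reference_clusters: int
    one_to_one: int
    histogram: dict[str, int]
    raw_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.one_to_one + sum(self.histogram.values()) != self.n_reference_clusters:
            raise ValueError(
                "one_to_one plus non-identical histogram mass must equal the "
                "number of reference clusters"
            )

    @property
    def subset_count(self) -> int:
        return self.histogram.get("1", 0)


def _check_universe(reference: ClusterSet, other: ClusterSet) -> None:
    if reference.universe != other.universe:
        only_ref = sorted(reference.universe - other.universe)[:10]
        only_other = sorted(other.universe - reference.universe)[:10]
        raise ValueError(
            "cluster sets do not share a universe; restrict both to the same "
            f"protein set first (examples only in reference: {only_ref}; "
            f"only in other: {only_other})"
        )


def counterpart_counts(reference: ClusterSet, other: ClusterSet) -> dict[str, int]:
    """For each reference cluster, the number of distinct clusters of ``other``
    its members fall into (N >= 1)."""
    _check_universe(reference, other)
    where = other.membership()
    return {
        cid: len({where[p] for p in members})
        for cid, members in reference.clusters.items()
    }


def _profile(
    reference: ClusterSet, other: ClusterSet, direction: str, identical: set[frozenset[str]]
) -> MismatchProfile:
    raw = counterpart_counts(reference, other)
    hist: Counter[str] = Counter({b: 0 for b in HISTOGRAM_BINS})
    one_to_one = 0
    for cid, members in reference.clusters.items():
        if members in identical:
            one_to_one += 1
        else:
            hist[_bin_of(raw[cid])] += 1
    return MismatchProfile(
        direction=direction,
        n_reference_clusters=reference.n_clusters,
        one_to_one=one_to_one,
        histogram=dict(hist),
        raw_counts=raw,
    )


def _identical_sets(a: ClusterSet, b: ClusterSet) -> set[frozenset[str]]:
    return set(a.clusters.values()) & set(b.clusters.values())


def classify(
    dab: ClusterSet, sb: ClusterSet
) -> tuple[MismatchProfile, MismatchProfile]:
    """Both directional profiles, D→S and S→D.

    One-to-one clusters (identical protein sets in both partitions) are counted
    once and appear in both profiles with the same count.
    """
    _check_universe(dab, sb)
    identical = _identical_sets(dab, sb)
    return (
        _profile(dab, sb, "D->S", identical),
        _profile(sb, dab, "S->D", identical),
    )


def identical_cluster_count(dab: ClusterSet, sb: ClusterSet) -> int:
    """Number of protein sets that are a cluster in both partitions (symmetric)."""
    _check_universe(dab, sb)
    return len(_identical_sets(dab, sb))


def one_to_one_composition(
    dab: ClusterSet,
    sb: ClusterSet,
    labels: Mapping[str, "ArchitectureLabel | str"],
) -> dict[int, int]:
    """Domain-count table of the architectures inside one-to-one clusters.

    Every member of a one-to-one DAB cluster carries the same label by
    construction; the table counts identical clusters by the domain count of
    that shared label.
    """
    table: Counter[int] = Counter()
    for members in _identical_sets(dab, sb):
        member_labels = {
            lbl.canonical_string if isinstance(lbl, ArchitectureLabel) else lbl
            for lbl in (labels[p] for p in members)
        }
        if len(member_labels) != 1:
            raise ValueError(
                f"one-to-one cluster {sorted(members)[:5]}... carries "
                f"{len(member_labels)} distinct labels; expected one"
            )
        table[domain_count(next(iter(member_labels)))] += 1
    return dict(table)
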