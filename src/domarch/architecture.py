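"""Canonical, order-aware domain-architecture labels.

A protein's architecture is the N→C ordered sequence of its domain signature
accessions. Order is determined by start position; two tie rules apply when
positions are ambiguous:

* hits with the *same* start position are ordered alphabetically by accession,
  whether or not they overlap;
* *overlapping* hits whose start positions differ by strictly less than 3
  amino acids are also ordered alphabetically.

Everything else is plain start-position order. Content, order and recurrence
all matter: ``A;B`` ≠ ``B;A`` and ``A;A`` ≠ ``A``.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import DomainHit, GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureLabel",
    "order_domains",
    "architecture_label",
    "assign_labels",
    "domain_count",
    "TIE_DISTANCE",
]

#: Overlapping hits whose starts differ by strictly less than this many amino
#: acids are ordered alphabetically instead of by position.
TIE_DISTANCE = 3

SEPARATOR = ";"


@dataclass(frozen=True)
class ArchitectureLabel:
    """An ordered sequence of domain accessions; the functional-equivalence key.

    Equality is ordered-sequence equality — content, order and recurrence all
    distinguish labels.
    """

    domains: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("an architecture label cannot be empty")
        for d in self.domains:
            if not d:
                raise ValueError("empty domain id in label")
            if SEPARATOR in d:
                raise ValueError(f"domain id {d!r} contains the separator {SEPARATOR!r}")

    @property
    def canonical_string(self) -> str:
        return SEPARATOR.join(self.domains)

    @classmethod
    def from_string(cls, s: str) -> "ArchitectureLabel":
        return cls(tuple(s.split(SEPARATOR)))

    def __len__(self) -> int:
        return len(self.domains)

    def __str__(self) -> str:
        return self.canonical_string


def _tie_applies(a: DomainHit, b: DomainHit) -> bool:
    """Whether the alphabetic rule governs the pair (a, b)."""
    if a.start == b.start:
        return True
    return a.overlaps(b) and abs(a.start - b.start) < TIE_DISTANCE


def _compare(a: DomainHit, b: DomainHit) -> int:
    if _tie_applies(a, b):
        key_a = (a.domain_id, a.start, a.end)
        key_b = (b.domain_id, b.start, b.end)
    else:
        key_a = (a.start, a.domain_id, a.end)  # type: ignore[assignment]
        key_b = (b.start, b.domain_id, b.end)  # type: ignore[assignment]
    return -1 if key_a < key_b else (1 if key_a > key_b else 0)


def _pathological_groups(hits: Sequence[DomainHit]) -> list[list[DomainHit]]:
    """Chains where transitively-linked tie pairs include a non-tie pair.

    On such groups the pairwise rule can be intransitive; the sort result is
    still deterministic but the published ordering rule does not fully define
    it, so the group is logged.
    """
    n = len(hits)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _tie_applies(hits[i], hits[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    bad = []
    for members in groups.values():
        if len(members) < 3:
            continue
        if any(
            not _tie_applies(hits[i], hits[j])
            for k, i in enumerate(members)
            for j in members[k + 1 :]
        ):
            bad.append([hits[i] for i in members])
    return bad


def order_domains(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Sort one protein's hits into their N→C architecture order.

    Deterministic and invariant to the input order of ``hits``. Raises on an
    empty list — unannotated proteins carry no architecture and must be
    skipped by the caller.
    """
    if not hits:
        raise ValueError("cannot order an empty hit list")
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(proteins)}")
    for group in _pathological_groups(hits):
        logger.warning(
            "protein %s: tie-rule chain spans hits without a pairwise tie "
            "(%s); ordering is deterministic but the positional rule alone "
            "does not define it",
            hits[0].protein_id,
            ", ".join(f"{h.domain_id}@{h.start}-{h.end}" for h in group),
        )
    # canonical pre-sort makes the comparison sort permutation-invariant even
    # on pathological (intransitive) instances
    canonical = sorted(hits, key=lambda h: (h.start, h.end, h.domain_id))
    return sorted(canonical, key=functools.cmp_to_key(_compare))


def architecture_label(ordered_hits: Sequence[DomainHit]) -> ArchitectureLabel:
    """Build the label from hits already ordered by :func:`order_domains`."""
    return ArchitectureLabel(tuple(h.domain_id for h in ordered_hits))


def assign_labels(
    annotation: GenomeAnnotation,
) -> dict[str, ArchitectureLabel]:
    """Label every annotated protein of a genome.

    Proteins with zero hits are absent from the result; the mapping is
    invariant to the order in which hits were recorded.
    """
    labels: dict[str, ArchitectureLabel] = {}
    for protein_id, hits in annotation.hits.items():
        if not hits:
            continue
        labels[protein_id] = architecture_label(order_domains(hits))
    return labels


def domain_count(label: ArchitectureLabel | str) -> int:
    """Number of domains in a label, counting repeats."""
    if isinstance(label, str):
        label = ArchitectureLabel.from_string(label)
    return len(label)
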