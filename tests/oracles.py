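"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive expected results from first principles (explicit
pairwise rules, double loops over membership sets) and share no code with the
implementation paths they check.
"""

from __future__ import annotations

from domarch.annotation_io import ClusterSet, DomainHit


# --- domain ordering rule, literally ----------------------------------------


def literal_precedes(a: DomainHit, b: DomainHit) -> bool | None:
    """Whether hit ``a`` comes before ``b`` under the published rule.

    The rule, pair by pair: same start → alphabetic; overlapping with starts
    closer than 3 aa → alphabetic; otherwise → start position. Returns ``None``
    for indistinguishable hits (same accession and coordinates).
    """
    overlap = a.start <= b.end and b.start <= a.end
    if a.start == b.start or (overlap and abs(a.start - b.start) < 3):
        if a.domain_id != b.domain_id:
            return a.domain_id < b.domain_id
        if (a.start, a.end) != (b.start, b.end):
            return (a.start, a.end) < (b.start, b.end)
        return None
    return a.start < b.start


def oracle_order(hits: list[DomainHit]) -> list[str] | None:
    """Topologically sort hits by the literal pairwise rule.

    In a transitive tournament the unique topological order sorts nodes by
    their number of pairwise wins; the result is verified pairwise afterwards.
    Returns the ordered accession sequence, or ``None`` when the pairwise
    rule is intransitive (pathological chain) and no consistent order exists.
    """
    n = len(hits)
    wins = [0] * n
    for i in range(n):
        for j in range(n):
            if i != j and literal_precedes(hits[i], hits[j]):
                wins[i] += 1
    order = sorted(range(n), key=lambda i: -wins[i])
    for a, b in zip(order, order[1:]):
        if literal_precedes(hits[b], hits[a]):
            return None
    return [hits[i].domain_id for i in order]


# --- bipartite partition comparison, literally -------------------------------


def oracle_counterpart_counts(reference: ClusterSet, other: ClusterSet) -> dict[str, int]:
    """N per reference cluster via an explicit double loop over cluster pairs."""
    out: dict[str, int] = {}
    for cid, members in reference.clusters.items():
        n = 0
        for other_members in other.clusters.values():
            if members & other_members:
                n += 1
        out[cid] = n
    return out


def oracle_identical_count(a: ClusterSet, b: ClusterSet) -> int:
    n = 0
    for ma in a.clusters.values():
        for mb in b.clusters.values():
            if ma == mb:
                n += 1
    return n


def oracle_profile(
    reference: ClusterSet, other: ClusterSet
) -> tuple[int, dict[str, int]]:
    """(one_to_one, histogram-over-non-identical) by explicit enumeration."""
    other_sets = list(other.clusters.values())
    hist = {b: 0 for b in ("1", "2", "3", "4", "5", "6+")}
    one_to_one = 0
    for members in reference.clusters.values():
        if any(members == o for o in other_sets):
            one_to_one += 1
            continue
        n = sum(1 for o in other_sets if members & o)
        hist[str(n) if n <= 5 else "6+"] += 1
    return one_to_one, hist
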