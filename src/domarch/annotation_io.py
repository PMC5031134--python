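"""Readers for per-genome domain-annotation tables and external cluster files.

Two text dialects are consumed:

* InterProScan 5 tab-separated output (the 15-column dialect). Only a handful of
  columns are required: protein accession (1), analysis / signature database (4),
  signature accession (5), start (7) and stop (8). The optional score column (9)
  is kept for provenance. Coordinates are 1-based inclusive amino-acid positions
  and are never converted anywhere else in the package.

* The MCL cluster dialect: one cluster per line, protein ids separated by
  whitespace. This is how externally computed sequence-similarity (SB)
  clusterings arrive, and how domain-architecture (DAB) clusterings are written
  back out, so the two are interchangeable downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "SourceDB",
    "DomainHit",
    "GenomeAnnotation",
    "ClusterSet",
    "read_interproscan_tsv",
    "read_cluster_file",
    "write_cluster_file",
    "restrict_to_annotated",
    "DEFAULT_ALLOWED_DBS",
]


class SourceDB(str, Enum):
    """Controlled vocabulary for the signature database a hit came from."""

    PFAM = "Pfam"
    TIGRFAM = "TIGRFAM"
    INTERPRO = "InterPro"
    OTHER = "other"

    @classmethod
    def from_string(cls, raw: str) -> "SourceDB":
        """Map an analysis-column string onto the vocabulary, case-insensitively.

        Unknown databases map to ``OTHER`` (and are excluded by the default
        ``allowed_dbs``).
        """
        norm = raw.strip().lower()
        if norm == "pfam":
            return cls.PFAM
        if norm in ("tigrfam", "tigrfams"):
            return cls.TIGRFAM
        if norm == "interpro":
            return cls.INTERPRO
        return cls.OTHER


#: Default database selection. The main analyses use Pfam signatures; InterPro
#: aggregation is supported but has to be requested explicitly.
DEFAULT_ALLOWED_DBS: frozenset[SourceDB] = frozenset({SourceDB.PFAM})


@dataclass(frozen=True)
class DomainHit:
    """One signature match on one protein.

    ``start``/``end`` are 1-based inclusive amino-acid positions. Duplicate hits
    (same protein, domain, coordinates) are retained throughout — no pruning for
    redundancy is ever performed.
    """

    protein_id: str
    genome_id: str
    domain_id: str
    source_db: SourceDB
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be non-empty")
        if ";" in self.domain_id:
            raise ValueError(
                f"domain_id {self.domain_id!r} contains the reserved separator ';'"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates for {self.protein_id}/{self.domain_id}: "
                f"start={self.start}, end={self.end} (need 1 <= start <= end)"
            )

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class GenomeAnnotation:
    """All domain hits of one genome, grouped per protein."""

    genome_id: str
    hits: dict[str, list[DomainHit]] = field(default_factory=dict)
    protein_count_total: int | None = None

    def __post_init__(self) -> None:
        for protein_id, protein_hits in self.hits.items():
            for hit in protein_hits:
                if hit.genome_id != self.genome_id:
                    raise ValueError(
                        f"hit on {protein_id} carries genome_id {hit.genome_id!r}, "
                        f"container is {self.genome_id!r}"
                    )

    @property
    def n_hits(self) -> int:
        return sum(len(v) for v in self.hits.values())

    @property
    def annotated_proteins(self) -> set[str]:
        """Proteins with at least one hit."""
        return {p for p, h in self.hits.items() if h}


@dataclass
class ClusterSet:
    """A partition of a protein universe into named clusters (DAB or SB).

    Clusters must be pairwise disjoint, non-empty, and cover the universe.
    """

    label: str
    clusters: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {cid!r} is empty")
            for p in members:
                if p in seen:
                    raise ValueError(
                        f"protein {p!r} appears in clusters {seen[p]!r} and {cid!r}"
                    )
                seen[p] = cid
        union = frozenset(seen)
        if self.universe is None:
            self.universe = union
        elif frozenset(self.universe) != union:
            raise ValueError("universe does not equal the union of the clusters")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_proteins(self) -> int:
        return len(self.universe)

    def membership(self) -> dict[str, str]:
        """protein_id -> cluster_id lookup."""
        return {p: cid for cid, members in self.clusters.items() for p in members}

    def __eq__(self, other: object) -> bool:
        """Partition equality: same universe, same cluster contents (ids ignored)."""
        if not isinstance(other, ClusterSet):
            return NotImplemented
        return self.universe == other.universe and set(
            self.clusters.values()
        ) == set(other.clusters.values())


# --- InterProScan TSV ------------------------------------------------------

# 1-based positions of the required columns in the 15-column dialect.
_COL_PROTEIN = 0
_COL_ANALYSIS = 3
_COL_SIGNATURE = 4
_COL_START = 6
_COL_STOP = 7
_COL_SCORE = 8
_COL_INTERPRO = 11


def _parse_row(
    fields: list[str], genome_id: str, lineno: int
) -> tuple[DomainHit, DomainHit | None]:
    """Parse one TSV row into its primary hit plus the InterPro-integrated view.

    The second element is a hit keyed by the InterPro accession of column 12
    (when present), so that InterPro-level analyses can be run from the same
    file; ``None`` when the row is not integrated into an InterPro entry.
    """
    if len(fields) <= _COL_STOP:
        raise ValueError(
            f"line {lineno}: expected at least {_COL_STOP + 1} tab-separated "
            f"columns, got {len(fields)}"
        )
    try:
        start = int(fields[_COL_START])
        end = int(fields[_COL_STOP])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates: {exc}") from None
    score: float | None = None
    if len(fields) > _COL_SCORE:
        raw_score = fields[_COL_SCORE].strip()
        if raw_score and raw_score != "-":
            try:
                score = float(raw_score)
            except ValueError:
                score = None  # informational only
    try:
        primary = DomainHit(
            protein_id=fields[_COL_PROTEIN],
            genome_id=genome_id,
            domain_id=fields[_COL_SIGNATURE],
            source_db=SourceDB.from_string(fields[_COL_ANALYSIS]),
            start=start,
            end=end,
            score=score,
        )
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from None
    interpro: DomainHit | None = None
    if len(fields) > _COL_INTERPRO:
        ipr = fields[_COL_INTERPRO].strip()
        if ipr and ipr != "-":
            interpro = DomainHit(
                protein_id=primary.protein_id,
                genome_id=genome_id,
                domain_id=ipr,
                source_db=SourceDB.INTERPRO,
                start=start,
                end=end,
                score=score,
            )
    return primary, interpro


def read_interproscan_tsv(
    path: str | Path,
    allowed_dbs: Iterable[SourceDB | str] = DEFAULT_ALLOWED_DBS,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Read an InterProScan TSV file into a :class:`GenomeAnnotation`.

    Only hits whose source database is in ``allowed_dbs`` are kept. Selecting
    :attr:`SourceDB.INTERPRO` keeps one hit per row that is integrated into an
    InterPro entry (column 12), keyed by the InterPro accession; member-database
    rows lacking that column are still usable when their own database is
    selected directly. Row order never affects the result beyond hit
    multiplicity; duplicates are retained.

    Raises ``ValueError`` naming the line number for unparseable rows
    (non-integer coordinates, start > end, too few columns). An empty file
    yields an empty annotation with a warning.
    """
    path = Path(path)
    allowed = frozenset(
        db if isinstance(db, SourceDB) else SourceDB.from_string(db)
        for db in allowed_dbs
    )
    if genome_id is None:
        genome_id = path.stem
    hits: dict[str, list[DomainHit]] = {}
    proteins_seen: set[str] = set()
    n_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            n_rows += 1
            fields = line.split("\t")
            primary, interpro = _parse_row(fields, genome_id, lineno)
            proteins_seen.add(primary.protein_id)
            if primary.source_db in allowed:
                hits.setdefault(primary.protein_id, []).append(primary)
            if interpro is not None and SourceDB.INTERPRO in allowed:
                hits.setdefault(interpro.protein_id, []).append(interpro)
    if n_rows == 0:
        warnings.warn(f"{path}: no annotation rows found", stacklevel=2)
    # keep hit lists in a canonical order so permuting file rows is a no-op
    for protein_hits in hits.values():
        protein_hits.sort(key=lambda h: (h.start, h.end, h.domain_id, h.source_db))
    return GenomeAnnotation(
        genome_id=genome_id, hits=hits, protein_count_total=len(proteins_seen)
    )


# --- MCL cluster dialect ----------------------------------------------------


def read_cluster_file(path: str | Path, label: str = "SB") -> ClusterSet:
    """Read a one-cluster-per-line, whitespace-separated cluster file.

    Cluster ids are assigned deterministically from the (1-based) file line
    number. Blank lines are ignored. A protein id appearing on two lines is a
    hard error — the file must describe a partition.
    """
    path = Path(path)
    clusters: dict[str, frozenset[str]] = {}
    seen: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            ids = line.split()
            if not ids:
                continue
            for p in ids:
                if p in seen:
                    raise ValueError(
                        f"{path}: protein {p!r} appears on lines {seen[p]} and "
                        f"{lineno}; clusters must partition the universe"
                    )
                seen[p] = lineno
            clusters[f"{label}_{lineno}"] = frozenset(ids)
    return ClusterSet(label=label, clusters=clusters)


def write_cluster_file(clusters: ClusterSet, path: str | Path) -> None:
    """Write a :class:`ClusterSet` in the MCL dialect (sorted for determinism)."""
    path = Path(path)
    with path.open("w") as fh:
        for cid in sorted(clusters.clusters):
            fh.write("\t".join(sorted(clusters.clusters[cid])) + "\n")


def restrict_to_annotated(
    clusters: ClusterSet, annotated: Iterable[str]
) -> ClusterSet:
    """Drop proteins without a domain annotation from a cluster set.

    Clusters left empty are removed; the result partitions
    ``universe ∩ annotated``. Idempotent.
    """
    annotated = frozenset(annotated)
    kept = {
        cid: members & annotated
        for cid, members in clusters.clusters.items()
        if members & annotated
    }
    return ClusterSet(label=clusters.label, clusters=kept)


def ensure_unique_protein_ids(
    annotations: Mapping[str, GenomeAnnotation]
) -> dict[str, GenomeAnnotation]:
    """Guarantee globally unique protein ids across genomes.

    Protein ids are treated as globally unique; when a collision between
    genomes is detected, every protein id in the colliding set is prefixed
    ``"<genome_id>|<protein_id>"`` and the decision is logged.
    """
    owner: dict[str, str] = {}
    collisions: set[str] = set()
    for gid, ann in annotations.items():
        for pid in ann.hits:
            if pid in owner and owner[pid] != gid:
                collisions.add(pid)
            owner.setdefault(pid, gid)
    if not collisions:
        return dict(annotations)
    logger.warning(
        "protein id collision across genomes for %d ids (e.g. %r); "
        "applying 'genome|protein' prefixes",
        len(collisions),
        next(iter(sorted(collisions))),
    )
    out: dict[str, GenomeAnnotation] = {}
    for gid, ann in annotations.items():
        new_hits: dict[str, list[DomainHit]] = {}
        for pid, hs in ann.hits.items():
            new_pid = f"{gid}|{pid}" if pid in collisions else pid
            new_hits[new_pid] = [
                DomainHit(
                    protein_id=new_pid,
                    genome_id=h.genome_id,
                    domain_id=h.domain_id,
                    source_db=h.source_db,
                    start=h.start,
                    end=h.end,
                    score=h.score,
                )
                for h in hs
            ]
        out[gid] = GenomeAnnotation(
            genome_id=gid, hits=new_hits, protein_count_total=ann.protein_count_total
        )
    return out
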