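"""Synthetic pan-genome fixtures with known ground truth.

The generator emulates the inputs the analysis modules consume — genomes of
architecture labels, InterProScan-style annotation files, and paired DAB/SB
clusterings with controlled mismatch composition — so every statistic the
package computes can be checked against generator bookkeeping without any
external data.

The occurrence model is deliberately simple: each accessory architecture is
carried by each genome independently with a stratum-specific probability
(no phylogeny), core architectures are carried by every genome, and singleton
architectures are private to one genome with exactly one protein. Ground truth
(pan/core/singleton counts, per-architecture persistence) is recorded from the
*realized* sample, so an accessory architecture that happens to land in every
genome counts as core, exactly as the analyzers will see it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import ClusterSet

__all__ = [
    "SyntheticPanGenomeConfig",
    "GroundTruth",
    "generate_pangenome",
    "emit_interproscan_tsv",
    "PairedTruth",
    "generate_paired_clusterings",
    "power_law_strata",
    "inject_divergent_genome",
    "DEFAULT_LENGTH_DISTRIBUTION",
]

#: Architecture length (domain count) distribution: a steep decay dominated by
#: single-domain architectures, as observed in real one-to-one cluster tables.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    1: 0.70,
    2: 0.17,
    3: 0.07,
    4: 0.03,
    5: 0.02,
    6: 0.01,
}


@dataclass
class SyntheticPanGenomeConfig:
    """Parameters of the synthetic pan-genome model.

    ``accessory_strata`` is a list of ``(probability, count)`` pairs: ``count``
    architectures each carried by each genome independently with
    ``probability``. ``singleton_rate`` is the expected number of private
    single-protein architectures per genome (Poisson). ``paralog_rate`` is the
    probability that a genome carrying an architecture carries two proteins of
    it instead of one (never applied to singletons).
    """

    n_genomes: int = 10
    n_core_architectures: int = 50
    accessory_strata: list[tuple[float, int]] = field(default_factory=list)
    singleton_rate: float = 0.0
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    paralog_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        if self.n_core_architectures < 0 or self.singleton_rate < 0:
            raise ValueError("counts and rates must be non-negative")
        for p, count in self.accessory_strata:
            if not (0.0 <= p <= 1.0) or count < 0:
                raise ValueError(f"invalid accessory stratum ({p}, {count})")
        if not (0.0 <= self.paralog_rate <= 1.0):
            raise ValueError("paralog_rate must be a probability")
        total = sum(self.length_distribution.values())
        if total <= 0:
            raise ValueError("length distribution must have positive mass")
        self.length_distribution = {
            k: v / total for k, v in self.length_distribution.items()
        }


@dataclass
class GroundTruth:
    """Realized truth of a generated sample, from generator bookkeeping."""

    n_genomes: int
    pan_size: int
    core_size: int
    singleton_count: int
    persistence: dict[str, float]
    counts: dict[str, dict[str, int]]  # label -> genome -> copy number

    @property
    def architecture_frequencies(self) -> dict[str, int]:
        """label -> number of genomes carrying it."""
        return {a: len(g) for a, g in self.counts.items()}


def _draw_lengths(
    rng: np.random.Generator, dist: Mapping[int, float], size: int
) -> np.ndarray:
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks], dtype=float)
    return rng.choice(ks, size=size, p=ps)


def _unique_labels(
    rng: np.random.Generator,
    n: int,
    dist: Mapping[int, float],
    pool_size: int,
    taken: set[str],
) -> list[str]:
    """Draw ``n`` distinct multi-domain labels from a synthetic domain pool."""
    labels: list[str] = []
    lengths = _draw_lengths(rng, dist, n)
    for k in lengths:
        for _ in range(1000):
            idx = rng.integers(0, pool_size, size=int(k))
            label = ";".join(f"PF{i:05d}" for i in idx)
            if label not in taken:
                break
        else:  # pragma: no cover - pool far exceeds demand in practice
            raise RuntimeError("could not draw a fresh architecture label")
        taken.add(label)
        labels.append(label)
    return labels


def generate_pangenome(
    config: SyntheticPanGenomeConfig,
) -> tuple[dict[str, dict[str, str]], GroundTruth]:
    """Sample a pan-genome: per-genome protein → label maps plus ground truth.

    Deterministic per seed. Genome ids are ``g000, g001, ...``; protein ids
    ``<genome>|p<k>`` are globally unique.
    """
    rng = np.random.default_rng(config.seed)
    genomes = [f"g{i:03d}" for i in range(config.n_genomes)]
    taken: set[str] = set()
    n_accessory = sum(c for _, c in config.accessory_strata)
    pool_size = max(64, 8 * (config.n_core_architectures + n_accessory))
    core = _unique_labels(
        rng, config.n_core_architectures, config.length_distribution, pool_size, taken
    )
    accessory: list[tuple[str, float]] = []
    for p, count in config.accessory_strata:
        for label in _unique_labels(
            rng, count, config.length_distribution, pool_size, taken
        ):
            accessory.append((label, p))

    counts: dict[str, dict[str, int]] = {}

    def carry(label: str, genome: str, copies: int) -> None:
        counts.setdefault(label, {})[genome] = copies

    n = config.n_genomes
    if core:
        paralogs = rng.random((len(core), n)) < config.paralog_rate
        for i, label in enumerate(core):
            for gi, g in enumerate(genomes):
                carry(label, g, 2 if paralogs[i, gi] else 1)
    if accessory:
        probs = np.array([p for _, p in accessory])
        present = rng.random((len(accessory), n)) < probs[:, None]
        paralogs = rng.random((len(accessory), n)) < config.paralog_rate
        for i, (label, _) in enumerate(accessory):
            for gi in np.flatnonzero(present[i]):
                carry(label, genomes[gi], 2 if paralogs[i, gi] else 1)
    # private singletons: a unique leading domain guarantees a fresh label
    singleton_counter = itertools.count()
    for g in genomes:
        k = rng.poisson(config.singleton_rate)
        lengths = _draw_lengths(rng, config.length_distribution, int(k))
        for length in lengths:
            head = f"SG{next(singleton_counter):06d}"
            tail = [
                f"PF{i:05d}" for i in rng.integers(0, pool_size, size=int(length) - 1)
            ]
            carry(";".join([head, *tail]), g, 1)

    label_maps: dict[str, dict[str, str]] = {g: {} for g in genomes}
    protein_counter = {g: itertools.count() for g in genomes}
    for label in sorted(counts):
        for g, copies in sorted(counts[label].items()):
            for _ in range(copies):
                pid = f"{g}|p{next(protein_counter[g]):05d}"
                label_maps[g][pid] = label

    persistence = {a: len(gs) / n for a, gs in counts.items()}
    truth = GroundTruth(
        n_genomes=n,
        pan_size=len(counts),
        core_size=sum(1 for gs in counts.values() if len(gs) == n),
        singleton_count=sum(
            1 for gs in counts.values() if sum(gs.values()) == 1
        ),
        persistence=persistence,
        counts={a: dict(gs) for a, gs in counts.items()},
    )
    return label_maps, truth


# --- annotation-file emission ----------------------------------------------

_DOMAIN_LENGTH = 100
_DOMAIN_SPACING = 120  # starts strictly increasing, far beyond the tie window


def emit_interproscan_tsv(
    label_maps: Mapping[str, Mapping[str, str]],
    out_dir: str | Path,
    analysis: str = "Pfam",
) -> dict[str, Path]:
    """Write one InterProScan-style TSV per genome.

    Each domain of a protein's label becomes one row with fabricated
    non-overlapping coordinates whose starts increase in label order, so
    re-parsing and re-labeling reproduces the generating labels exactly.
    Returns genome_id → file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for genome_id in sorted(label_maps):
        path = out_dir / f"{genome_id}.tsv"
        with path.open("w") as fh:
            for protein_id in sorted(label_maps[genome_id]):
                domains = label_maps[genome_id][protein_id].split(";")
                protein_length = 10 + _DOMAIN_SPACING * len(domains)
                for k, domain in enumerate(domains):
                    start = 10 + _DOMAIN_SPACING * k
                    end = start + _DOMAIN_LENGTH
                    fh.write(
                        "\t".join(
                            [
                                protein_id,
                                "-",
                                str(protein_length),
                                analysis,
                                domain,
                                "-",
                                str(start),
                                str(end),
                                "1.0E-10",
                                "T",
                                "-",
                                "-",
                                "-",
                            ]
                        )
                        + "\n"
                    )
        paths[genome_id] = path
    return paths


# --- paired clusterings ------------------------------------------------------


@dataclass
class PairedTruth:
    """Expected comparison outcome for a constructed DAB/SB pair."""

    one_to_one: int
    d_to_s_histogram: dict[str, int]
    s_to_d_histogram: dict[str, int]
    identical_clusters: int


def _empty_hist() -> dict[str, int]:
    return {b: 0 for b in ("1", "2", "3", "4", "5", "6+")}


def _bin(n: int) -> str:
    return str(n) if n <= 5 else "6+"


def generate_paired_clusterings(
    n_one_to_one: int,
    n_split: int,
    n_merge: int,
    seed: int = 0,
    split_k: int = 2,
    merge_m: int = 2,
    one_to_one_size: int = 2,
) -> tuple[ClusterSet, ClusterSet, PairedTruth]:
    """Build a DAB/SB pair with a configured mismatch taxonomy.

    * ``n_one_to_one`` clusters are identical in both partitions;
    * ``n_split`` DAB clusters are each split across ``split_k`` single-protein
      SB clusters (D→S count ``split_k``; each SB part a strict subset);
    * ``n_merge`` SB clusters each merge ``merge_m`` single-protein DAB
      clusters (S→D count ``merge_m``; each DAB part a strict subset).
    """
    if min(n_one_to_one, n_split, n_merge) < 0:
        raise ValueError("counts must be non-negative")
    if split_k < 2 or merge_m < 2 or one_to_one_size < 1:
        raise ValueError("split_k and merge_m must be >= 2")
    rng = np.random.default_rng(seed)
    counter = itertools.count()

    def new_proteins(k: int) -> list[str]:
        return [f"p{next(counter):06d}" for _ in range(k)]

    dab: dict[str, frozenset[str]] = {}
    sb: dict[str, frozenset[str]] = {}
    cid = itertools.count()
    for _ in range(n_one_to_one):
        members = frozenset(new_proteins(one_to_one_size))
        dab[f"D{next(cid):05d}"] = members
        sb[f"S{next(cid):05d}"] = members
    for _ in range(n_split):
        parts = new_proteins(split_k)
        dab[f"D{next(cid):05d}"] = frozenset(parts)
        for p in parts:
            sb[f"S{next(cid):05d}"] = frozenset([p])
    for _ in range(n_merge):
        parts = new_proteins(merge_m)
        sb[f"S{next(cid):05d}"] = frozenset(parts)
        for p in parts:
            dab[f"D{next(cid):05d}"] = frozenset([p])

    # cosmetic shuffle of cluster insertion order; contents are what matter
    dab = {k: dab[k] for k in rng.permutation(sorted(dab))}
    sb = {k: sb[k] for k in rng.permutation(sorted(sb))}

    d_hist = _empty_hist()
    d_hist[_bin(split_k)] += n_split
    d_hist["1"] += n_merge * merge_m
    s_hist = _empty_hist()
    s_hist["1"] += n_split * split_k
    s_hist[_bin(merge_m)] += n_merge
    truth = PairedTruth(
        one_to_one=n_one_to_one,
        d_to_s_histogram=d_hist,
        s_to_d_histogram=s_hist,
        identical_clusters=n_one_to_one,
    )
    return (
        ClusterSet(label="DAB", clusters=dab),
        ClusterSet(label="SB", clusters=sb),
        truth,
    )


# --- special-purpose fixtures ------------------------------------------------


def power_law_strata(
    kappa: float,
    alpha: float,
    n_genomes: int,
    p_grid: np.ndarray | None = None,
) -> list[tuple[float, int]]:
    """Accessory strata whose expected accumulation curve is ``kappa·j**(-alpha)``.

    For architectures carried i.i.d. across genomes with probability p, the
    expected number first discovered at the j-th genome of a random ordering
    is ``Σ_i p_i (1 - p_i)**(j-1)``. A non-negative least-squares mixture over
    a probability grid is solved so that this expectation matches the target
    power law at every j = 1..n_genomes (stratum counts are then rounded to
    integers; the rounding error on the expected curve is well below one
    architecture per rank).
    """
    from scipy.optimize import nnls

    if p_grid is None:
        p_grid = np.geomspace(1e-4, 1.0, 400)
    j = np.arange(1, n_genomes + 1)
    design = p_grid[None, :] * (1.0 - p_grid[None, :]) ** (j[:, None] - 1)
    target = kappa * j ** (-float(alpha))
    weights, _ = nnls(design, target)
    counts = np.round(weights).astype(int)
    return [
        (float(p), int(c)) for p, c in zip(p_grid, counts) if c > 0
    ]


def inject_divergent_genome(
    label_maps: dict[str, dict[str, str]],
    genome_id: str,
    n_private: int,
    carry_fraction: float = 1.0,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Add a genome carrying private architectures on top of a shared backbone.

    The new genome copies a ``carry_fraction`` random subset of the label set
    of the first existing genome, then adds ``n_private`` architectures seen
    nowhere else — the classic signature of a divergent strain that distorts
    openness estimates.
    """
    if genome_id in label_maps:
        raise ValueError(f"genome {genome_id!r} already present")
    rng = np.random.default_rng(seed)
    first = label_maps[sorted(label_maps)[0]]
    backbone = sorted(set(first.values()))
    k = int(round(carry_fraction * len(backbone)))
    chosen = list(rng.choice(backbone, size=min(k, len(backbone)), replace=False))
    new_map: dict[str, str] = {}
    counter = itertools.count()
    for label in chosen:
        new_map[f"{genome_id}|p{next(counter):05d}"] = label
    for i in range(n_private):
        new_map[f"{genome_id}|p{next(counter):05d}"] = f"PRIV{genome_id}_{i:05d}"
    out = {g: dict(m) for g, m in label_maps.items()}
    out[genome_id] = new_map
    return out
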