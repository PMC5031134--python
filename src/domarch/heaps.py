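"""Heaps'-law openness estimation from new-cluster accumulation curves.

As genomes are added in random order, the number of previously unseen
architectures discovered at the j-th genome decays. The decay is modeled as

    y_new(j) = kappa * j**(-alpha),        j = 2, 3, ..., n

fitted by nonlinear least squares on the natural scale to the points (j, y)
pooled over many random genome orderings. ``alpha < 1`` indicates an open
pan-genome (new architectures keep arriving), ``alpha > 1`` a closed one;
the ``alpha = 1`` boundary is reported as open with a note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .clustering import AbundanceMatrix

__all__ = [
    "HeapsFit",
    "accumulation_curve",
    "fit_power_law",
    "heaps_fit",
    "heaps_fit_excluding",
]


@dataclass
class HeapsFit:
    """Fitted power-law parameters with diagnostics and the openness call."""

    kappa: float | None
    alpha: float | None
    n_permutations: int
    j: np.ndarray
    y: np.ndarray
    rss: float | None
    converged: bool
    openness: str  # {"open", "closed", "degenerate"}
    note: str = ""

    def __post_init__(self) -> None:
        if self.converged and (self.kappa is None or self.kappa <= 0):
            raise ValueError("a converged fit must have kappa > 0")


def accumulation_curve(
    presence: AbundanceMatrix | np.ndarray, order: Sequence[int] | Sequence[str]
) -> np.ndarray:
    """New-architecture counts along one genome ordering.

    ``y[0]`` is the number of architectures in the first genome; ``y[j-1]`` the
    number present in genome ``j`` but absent from all earlier ones. The counts
    sum to the pan size.
    """
    if isinstance(presence, AbundanceMatrix):
        P = presence.presence.astype(bool)
        if len(order) and isinstance(order[0], str):
            idx = {g: i for i, g in enumerate(presence.genome_ids)}
            order = [idx[g] for g in order]
    else:
        P = np.asarray(presence).astype(bool)
    order = np.asarray(order, dtype=int)
    if sorted(order.tolist()) != list(range(P.shape[0])):
        raise ValueError("order must be a permutation of all genomes")
    seen = np.zeros(P.shape[1], dtype=bool)
    y = np.empty(len(order), dtype=np.int64)
    for k, g in enumerate(order):
        new = P[g] & ~seen
        y[k] = int(new.sum())
        seen |= P[g]
    return y


def _power_law(j: np.ndarray, kappa: float, alpha: float) -> np.ndarray:
    return kappa * np.power(j, -alpha)


def fit_power_law(
    j: np.ndarray, y: np.ndarray, log_scale: bool = False
) -> tuple[float | None, float | None, float | None, bool, str]:
    """Least-squares fit of ``y = kappa * j**(-alpha)``.

    Initialization: ``kappa0`` = mean of y at the smallest j, ``alpha0 = 1``.
    The default objective is natural-scale least squares (zero counts are
    common, so no log transform); ``log_scale=True`` switches to a linear
    regression of ``log y`` on ``log j`` over the positive points, for
    sensitivity analysis.

    Returns ``(kappa, alpha, rss, converged, message)``.
    """
    j = np.asarray(j, dtype=float)
    y = np.asarray(y, dtype=float)
    if j.size == 0:
        return None, None, None, False, "no data points"
    if log_scale:
        pos = y > 0
        if pos.sum() < 2:
            return None, None, None, False, "not enough positive points for log fit"
        slope, intercept = np.polyfit(np.log(j[pos]), np.log(y[pos]), 1)
        kappa, alpha = float(np.exp(intercept)), float(-slope)
        rss = float(np.sum((y - _power_law(j, kappa, alpha)) ** 2))
        return kappa, alpha, rss, True, ""
    jmin = j.min()
    kappa0 = float(y[j == jmin].mean())
    if kappa0 <= 0:
        kappa0 = max(float(y.mean()), 1e-6)
    try:
        popt, _ = curve_fit(
            _power_law,
            j,
            y,
            p0=(kappa0, 1.0),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return None, None, None, False, f"fit did not converge: {exc}"
    kappa, alpha = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - _power_law(j, kappa, alpha)) ** 2))
    return kappa, alpha, rss, True, ""


def _openness(alpha: float) -> tuple[str, str]:
    if alpha < 1:
        return "open", ""
    if alpha > 1:
        return "closed", ""
    return "open", "alpha exactly at the open/closed boundary (alpha = 1)"


def heaps_fit(
    presence: AbundanceMatrix,
    n_permutations: int = 5000,
    seed: int = 0,
    use_means: bool = False,
    log_scale: bool = False,
) -> HeapsFit:
    """Fit the accumulation decay over random genome orderings.

    Points (j, y[j]) for j >= 2 are pooled across ``n_permutations`` random
    orderings (sampled with replacement from the n! space, single seeded
    generator) and fitted by :func:`fit_power_law`. ``use_means=True`` fits
    the per-j mean instead of the pooled points — the two coincide in
    expectation. Fully closed samples (every pooled y = 0) are reported as
    ``degenerate`` with no fit attempted.
    """
    if presence.n_genomes < 3:
        raise ValueError("Heaps fitting needs at least three genomes")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    n = presence.n_genomes
    P = presence.presence.astype(bool)
    js: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    jj = np.arange(2, n + 1)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        y = accumulation_curve(P, order)
        js.append(jj)
        ys.append(y[1:])
    j = np.concatenate(js).astype(float)
    y = np.concatenate(ys).astype(float)
    if use_means:
        means = np.array([y[j == v].mean() for v in jj], dtype=float)
        j_fit, y_fit = jj.astype(float), means
    else:
        j_fit, y_fit = j, y
    if not y.any():
        return HeapsFit(
            kappa=None,
            alpha=None,
            n_permutations=n_permutations,
            j=j,
            y=y,
            rss=None,
            converged=False,
            openness="degenerate",
            note="no new architectures beyond the first genome in any ordering",
        )
    kappa, alpha, rss, converged, msg = fit_power_law(j_fit, y_fit, log_scale=log_scale)
    if not converged:
        return HeapsFit(
            kappa=None,
            alpha=None,
            n_permutations=n_permutations,
            j=j,
            y=y,
            rss=None,
            converged=False,
            openness="degenerate",
            note=msg,
        )
    openness, note = _openness(alpha)
    return HeapsFit(
        kappa=kappa,
        alpha=alpha,
        n_permutations=n_permutations,
        j=j,
        y=y,
        rss=rss,
        converged=True,
        openness=openness,
        note=note,
    )


def heaps_fit_excluding(
    presence: AbundanceMatrix,
    excluded: Iterable[str],
    n_permutations: int = 5000,
    seed: int = 0,
    **kwargs,
) -> HeapsFit:
    """:func:`heaps_fit` on the matrix with ``excluded`` genome rows removed.

    Architectures carried only by excluded genomes drop out of the matrix. At
    least three genomes must remain.
    """
    excluded = set(excluded)
    sub = presence.drop_genomes(excluded)
    if sub.n_genomes < 3:
        raise ValueError(
            f"only {sub.n_genomes} genomes remain after exclusion; need >= 3"
        )
    return heaps_fit(sub, n_permutations=n_permutations, seed=seed, **kwargs)
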