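"""Ripley's K-function, CSR Monte Carlo envelopes, per-radius classification.

The estimator is

    K̂(r) = |A| / (n (n - 1)) · Σ_{i≠j} e_ij · 1{d_ij ≤ r}

with e_ij = 1 (no correction) or the translation edge correction
e_ij = |A| / |A ∩ A_{shift(i,j)}|, i.e. the reciprocal fraction of the
window that still overlaps itself after shifting by the pair's
displacement vector.  Translation correction is exact on arbitrary
simple polygons; an axis-aligned rectangle gets a closed-form fast path
so envelope simulation stays cheap.

Classification against a Monte Carlo envelope under complete spatial
randomness (CSR, with the observed count held fixed) is pointwise per
radius: K̂ above the envelope means clumped, below means regular,
inside means indistinguishable from random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .errors import (
    GridAlignmentError,
    InsufficientDataError,
    InvalidParameterError,
)
from .geometry import MarkedPointPattern, PlotWindow
from .simulate import simulate_csr

log = logging.getLogger(__name__)

CLUMPED, RANDOM, REGULAR = "clumped", "random", "regular"


@dataclass(frozen=True)
class KFunctionResult:
    r: np.ndarray            # radii, metres, strictly increasing
    k_hat: np.ndarray        # estimated K(r), m²
    edge_correction: str
    n_used: int
    window_area: float

    @property
    def k_theo(self) -> np.ndarray:
        """πr², the CSR expectation."""
        return np.pi * self.r**2


@dataclass(frozen=True)
class EnvelopeResult:
    r: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_sim: int
    rank: int
    k_obs: KFunctionResult
    classification: np.ndarray  # per-r label in {clumped, random, regular}


def default_r_grid(window: PlotWindow, n_steps: int = 512) -> np.ndarray:
    """512 equal steps from 0 to a quarter of the shorter bbox side."""
    xmin, ymin, xmax, ymax = window.bounds
    r_max = min(xmax - xmin, ymax - ymin) / 4.0
    return np.linspace(0.0, r_max, n_steps)


def _check_r_grid(
    r: np.ndarray, window: PlotWindow, edge_correction: str = "translation"
) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size < 2 or np.any(np.diff(r) <= 0) or r[0] < 0:
        raise InvalidParameterError("r grid must be 1-D, strictly increasing, >= 0")
    xmin, ymin, xmax, ymax = window.bounds
    w, h = xmax - xmin, ymax - ymin
    if edge_correction == "translation":
        # beyond half the shorter side the correction weights grow
        # without bound and the estimator variance explodes
        admissible = min(w, h) / 2.0
        what = "half the shorter bounding-box side"
    else:
        admissible = float(np.hypot(w, h))
        what = "the bounding-box diagonal"
    if r[-1] > admissible + 1e-9:
        raise InvalidParameterError(
            f"max radius {r[-1]:.3g} m exceeds the admissible limit "
            f"{admissible:.3g} m ({what})"
        )
    return r


def _translation_weights(coords: np.ndarray, window: PlotWindow) -> np.ndarray:
    """e_ij (condensed pdist order) for the translation correction."""
    area = window.polygon.area
    # |Δx|, |Δy| per unordered pair, in condensed (pdist) order
    dx = pdist(coords[:, :1], metric="cityblock")
    dy = pdist(coords[:, 1:], metric="cityblock")
    rect = window.as_rectangle()
    if rect is not None:
        w, h = rect
        overlap = (w - dx) * (h - dy)
    else:
        from shapely.affinity import translate

        poly = window.polygon
        overlap = np.empty(dx.size)
        for k in range(dx.size):
            overlap[k] = poly.intersection(translate(poly, dx[k], dy[k])).area
    if np.any(overlap <= 0):
        raise InvalidParameterError(
            "translation correction undefined: a pair's displacement "
            "exceeds the window extent"
        )
    return area / overlap


def k_function(
    pattern: MarkedPointPattern,
    r_grid: np.ndarray | None = None,
    edge_correction: str = "translation",
    mark: str | None = None,
) -> KFunctionResult:
    """Estimate K(r) for the points of one mark (or all points).

    ``pattern`` should already be restricted to a single taxon; pass
    ``mark`` to restrict here instead.  Requires at least two points.
    """
    window = pattern.window
    coords = pattern.coords(mark)
    n = coords.shape[0]
    if n < 2:
        raise InsufficientDataError(f"K-function needs >= 2 points, got {n}")
    r = (
        default_r_grid(window)
        if r_grid is None
        else _check_r_grid(r_grid, window, edge_correction)
    )
    d = pdist(coords)
    if edge_correction == "none":
        w = np.ones_like(d)
    elif edge_correction == "translation":
        w = _translation_weights(coords, window)
    else:
        raise InvalidParameterError(
            f"unknown edge correction {edge_correction!r}; "
            "use 'none' or 'translation'"
        )
    # pair with distance d contributes to every r >= d: bin the weights
    # by the first grid radius >= d, then take the running sum over bins
    bins = np.searchsorted(r, d, side="left")
    keep = bins < r.size
    cum = np.cumsum(np.bincount(bins[keep], weights=w[keep], minlength=r.size))
    # each unordered pair counts twice in the i != j double sum
    area = window.polygon.area
    k_hat = 2.0 * area / (n * (n - 1)) * cum
    return KFunctionResult(
        r=r, k_hat=k_hat, edge_correction=edge_correction,
        n_used=n, window_area=area,
    )


def classify_pattern(
    k: KFunctionResult, env: "EnvelopeResult | tuple[np.ndarray, np.ndarray, np.ndarray]"
) -> tuple[np.ndarray, dict[str, list[tuple[float, float]]]]:
    """Per-radius labels and the r-intervals occupied by each label.

    ``clumped`` where K̂ exceeds the upper envelope bound, ``regular``
    where it falls below the lower bound, ``random`` in between.
    """
    if isinstance(env, EnvelopeResult):
        r_env, lo, hi = env.r, env.lo, env.hi
    else:
        r_env, lo, hi = env
    if k.r.shape != r_env.shape or not np.allclose(k.r, r_env):
        raise GridAlignmentError("K result and envelope use different r grids")
    labels = np.where(k.k_hat > hi, CLUMPED, np.where(k.k_hat < lo, REGULAR, RANDOM))
    intervals: dict[str, list[tuple[float, float]]] = {
        CLUMPED: [], RANDOM: [], REGULAR: []
    }
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            intervals[str(labels[start])].append((float(k.r[start]), float(k.r[i - 1])))
            start = i
    return labels, intervals


def csr_envelope(
    pattern: MarkedPointPattern,
    r_grid: np.ndarray | None = None,
    n_sim: int = 300,
    rank: int = 1,
    seed: int | None = None,
    edge_correction: str = "translation",
    mark: str | None = None,
) -> EnvelopeResult:
    """Monte Carlo CSR envelope for the observed pattern.

    Simulates ``n_sim`` CSR patterns with the observed count in the
    observed window, estimates K̂ for each, and takes the pointwise
    ``rank``-th smallest/largest simulated values as lower/upper bounds
    (rank 1 = pointwise min/max).  The observed curve is classified per
    radius against these bounds.
    """
    if rank < 1 or n_sim < 2 * rank:
        raise InvalidParameterError(
            f"need n_sim >= 2*rank and rank >= 1, got n_sim={n_sim}, rank={rank}"
        )
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        log.info("csr_envelope: no seed supplied, drew seed=%d", seed)
    window = pattern.window
    coords = pattern.coords(mark)
    n = coords.shape[0]
    if n < 2:
        raise InsufficientDataError(f"envelope needs >= 2 points, got {n}")
    r = (
        default_r_grid(window)
        if r_grid is None
        else _check_r_grid(r_grid, window, edge_correction)
    )
    restricted = pattern if mark is None else pattern.subset(mark)
    k_obs = k_function(restricted, r, edge_correction)
    child_seeds = np.random.SeedSequence(seed).spawn(n_sim)
    sims = np.empty((n_sim, r.size))
    for s in range(n_sim):
        sim_seed = int(child_seeds[s].generate_state(1)[0] % (2**31))
        sim = simulate_csr(window, n, sim_seed, mark="2x")
        sims[s] = k_function(sim, r, edge_correction).k_hat
    part = np.partition(sims, [rank - 1, n_sim - rank], axis=0)
    lo = part[rank - 1]
    hi = part[n_sim - rank]
    labels, _ = classify_pattern(k_obs, (r, lo, hi))
    return EnvelopeResult(
        r=r, lo=lo, hi=hi, n_sim=n_sim, rank=rank,
        k_obs=k_obs, classification=labels,
    )
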