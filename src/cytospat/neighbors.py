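"""Nearest cross-taxon distances and distance-band density profiles.

For every triploid the Euclidean distance to its nearest diploid (and,
separately, nearest tetraploid) is recorded.  The profile then reports
triploid density (individuals/m²) as a function of that distance: the
window is partitioned into distance bands around the reference taxon —
the set of locations whose nearest-reference distance falls in
[a, a + Δ) — and the triploid count per band is divided by the band's
area.  Band areas come from a discrete distance transform: a fine
lattice of window points, each assigned its nearest-reference distance.
Without this normalisation the raw histogram mostly reflects how much
area lies at each distance, not any affinity between the taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InsufficientDataError, InvalidParameterError, ResolutionError
from .geometry import MarkedPointPattern, PlotWindow


@dataclass(frozen=True)
class CrossDistanceSet:
    source_mark: str
    reference_mark: str
    distances: np.ndarray  # metres, one per source individual

    @property
    def n(self) -> int:
        return int(self.distances.size)


@dataclass(frozen=True)
class NeighborProfile:
    bin_edges: np.ndarray   # metres, len = n_bins + 1
    counts: np.ndarray      # source individuals per band
    band_areas: np.ndarray  # m² of window at each nearest-reference distance band
    density: np.ndarray     # individuals / m²; 0 where the band is empty
    mean: float             # mean nearest distance, metres
    se: float               # standard error of the mean, metres

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def nearest_cross_distances(
    source: MarkedPointPattern,
    reference: MarkedPointPattern,
    source_mark: str | None = None,
    reference_mark: str | None = None,
) -> CrossDistanceSet:
    """Distance from each source individual to its nearest reference one."""
    src = source.coords(source_mark)
    ref = reference.coords(reference_mark)
    if src.shape[0] == 0:
        raise InsufficientDataError("source pattern is empty")
    if ref.shape[0] == 0:
        raise InsufficientDataError("reference pattern is empty")
    d, _ = cKDTree(ref).query(src)
    return CrossDistanceSet(
        source_mark=source_mark or "source",
        reference_mark=reference_mark or "reference",
        distances=np.asarray(d, dtype=float),
    )


def summarize_distances(d: CrossDistanceSet) -> tuple[float, float]:
    """(mean, standard error); SE uses the n−1 sample standard deviation."""
    if d.n < 2:
        raise InsufficientDataError("standard error needs >= 2 distances")
    mean = float(np.mean(d.distances))
    se = float(np.std(d.distances, ddof=1) / np.sqrt(d.n))
    return mean, se


def band_areas(
    window: PlotWindow,
    reference: np.ndarray,
    bin_edges: np.ndarray,
    grid_res: float,
) -> np.ndarray:
    """Area (m²) of the window region whose nearest-reference distance
    falls in each [a, b) band, by counting grid_res-spaced lattice points."""
    if grid_res <= 0:
        raise InvalidParameterError(f"grid_res must be > 0, got {grid_res}")
    xmin, ymin, xmax, ymax = window.bounds
    gx = np.arange(xmin + grid_res / 2, xmax, grid_res)
    gy = np.arange(ymin + grid_res / 2, ymax, grid_res)
    mx, my = np.meshgrid(gx, gy)
    mx, my = mx.ravel(), my.ravel()
    inside = window.contains(mx, my)
    pts = np.column_stack([mx[inside], my[inside]])
    d, _ = cKDTree(reference).query(pts)
    counts, _ = np.histogram(d, bins=bin_edges)
    return counts * grid_res**2


def distance_band_profile(
    d: CrossDistanceSet,
    window: PlotWindow,
    reference: MarkedPointPattern | np.ndarray,
    bin_width: float = 0.5,
    grid_res: float = 0.25,
    reference_mark: str | None = None,
) -> NeighborProfile:
    """Source density per m² as a function of nearest-reference distance.

    Bands of ``bin_width`` metres cover both the observed source
    distances and the window's full distance transform, so density ×
    band area sums back to the source count.
    """
    if bin_width <= 0:
        raise InvalidParameterError(f"bin_width must be > 0, got {bin_width}")
    ref = (
        reference.coords(reference_mark)
        if isinstance(reference, MarkedPointPattern)
        else np.asarray(reference, dtype=float)
    )
    if ref.shape[0] == 0:
        raise InsufficientDataError("reference pattern is empty")
    d_max = float(np.max(d.distances)) if d.n else 0.0
    n_bins = max(int(np.ceil((d_max + 1e-12) / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    areas = band_areas(window, ref, edges, grid_res)
    counts, _ = np.histogram(d.distances, bins=edges)
    # include source points sitting exactly on the last edge
    counts[-1] += int(np.sum(d.distances == edges[-1]))
    bad = (areas <= 0) & (counts > 0)
    if np.any(bad):
        raise ResolutionError(
            f"{int(bad.sum())} band(s) hold source individuals but no grid "
            f"area; re-run with grid_res finer than {grid_res} m"
        )
    density = np.zeros_like(areas, dtype=float)
    nz = areas > 0
    density[nz] = counts[nz] / areas[nz]
    mean, se = summarize_distances(d) if d.n >= 2 else (float(np.mean(d.distances)), float("nan"))
    return NeighborProfile(
        bin_edges=edges, counts=counts, band_areas=areas,
        density=density, mean=mean, se=se,
    )


def profile_peaks(
    profile: NeighborProfile, min_separation: float = 0.0
) -> np.ndarray:
    """Local maxima of the binned density, at bin midpoints.

    A peak is strictly greater than both neighbours (plateaus take the
    left edge; the first/last bin only needs to beat its single
    neighbour).  Peaks closer than ``min_separation`` to a taller peak
    are dropped.  Returned in descending height order.
    """
    y = profile.density
    if y.size == 0:
        return np.empty(0)
    mids = profile.bin_midpoints
    if y.size == 1:
        return mids[:1] if y[0] > 0 else np.empty(0)
    candidates = []
    i = 0
    while i < y.size:
        j = i
        while j + 1 < y.size and y[j + 1] == y[i]:
            j += 1  # plateau [i, j]
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == y.size - 1 or y[j + 1] < y[i]
        interior = not (i == 0 and j == y.size - 1)  # flat profile: no peak
        if left_ok and right_ok and interior:
            candidates.append(i)  # plateau takes its left edge
        i = j + 1
    candidates = [c for c in candidates if y[c] > 0]
    candidates.sort(key=lambda c: (-y[c], mids[c]))
    kept: list[int] = []
    for c in candidates:
        if all(abs(mids[c] - mids[k]) >= min_separation for k in kept):
            kept.append(c)
    return mids[kept]
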