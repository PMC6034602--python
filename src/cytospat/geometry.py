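"""Plot windows, marked point patterns, and their file I/O.

Coordinates are planar Cartesian metres.  Field plots are georeferenced
with projected (UTM) coordinates and span well under a kilometre, so no
geodetic computation is performed anywhere in the package: the projected
easting/northing pairs are used as-is.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import (
    DegenerateGeometryError,
    InvalidGeometryError,
    PointOutsideWindowError,
    PointTableParseError,
)

#: Ploidy marks used throughout the package: diploid, triploid hybrid,
#: tetraploid.  The label set of a pattern is extensible, this is only
#: the default.
DEFAULT_TAXA: tuple[str, ...] = ("2x", "3x", "4x")

M2_PER_HECTARE = 10_000.0


def polygon_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Planar polygon area via the shoelace formula, in m².

    Orientation-independent (the absolute value is taken).  Raises
    :class:`InvalidGeometryError` for fewer than three vertices or a
    self-intersecting ring, and :class:`DegenerateGeometryError` for a
    (numerically) zero-area polygon.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise InvalidGeometryError(
            f"a polygon needs >=3 (x, y) vertices, got shape {v.shape}"
        )
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0.0:
        raise DegenerateGeometryError("polygon has zero area")
    if not Polygon(v).is_simple:
        raise InvalidGeometryError("polygon is self-intersecting")
    return float(area)


@dataclass(frozen=True)
class PlotWindow:
    """A polygonal sampling plot in planar metres.

    Parameters
    ----------
    plot_id
        Free-text plot label (e.g. ``"El Saler North"``).
    vertices
        Ordered ring of (x, y) corners in metres; not closed (the last
        vertex differs from the first).
    printed_area_m2
        Optional published/override area.  When supplied and it differs
        from the shoelace value by more than 0.5 % a warning is issued;
        reporting code then uses the printed value so published tables
        can be reproduced exactly.
    """

    plot_id: str
    vertices: tuple[tuple[float, float], ...]
    printed_area_m2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )
        shoelace = polygon_area(self.vertices)  # validates the ring
        if self.printed_area_m2 is not None:
            rel = abs(self.printed_area_m2 - shoelace) / shoelace
            if rel > 0.005:
                warnings.warn(
                    f"plot {self.plot_id!r}: supplied area "
                    f"{self.printed_area_m2} m² disagrees with the shoelace "
                    f"value {shoelace:.1f} m² by {100 * rel:.2f} %",
                    stacklevel=3,
                )

    @property
    def shoelace_area_m2(self) -> float:
        return polygon_area(self.vertices)

    @property
    def area_m2(self) -> float:
        """Reporting area: the printed override if given, else shoelace."""
        if self.printed_area_m2 is not None:
            return float(self.printed_area_m2)
        return self.shoelace_area_m2

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the bounding box."""
        v = np.asarray(self.vertices)
        return (
            float(v[:, 0].min()),
            float(v[:, 1].min()),
            float(v[:, 0].max()),
            float(v[:, 1].max()),
        )

    def contains(self, x, y) -> np.ndarray | bool:
        """Boundary-inclusive containment test, vectorised over x/y."""
        scalar = np.isscalar(x) and np.isscalar(y)
        inside = shapely.intersects_xy(
            self.polygon, np.atleast_1d(x), np.atleast_1d(y)
        )
        return bool(inside[0]) if scalar else inside

    def as_rectangle(self) -> tuple[float, float] | None:
        """(width, height) if the window is an axis-aligned rectangle.

        Used by fast paths (translation edge correction); ``None``
        otherwise.
        """
        if len(self.vertices) != 4:
            return None
        xmin, ymin, xmax, ymax = self.bounds
        corners = {(xmin, ymin), (xmin, ymax), (xmax, ymin), (xmax, ymax)}
        if set(self.vertices) == corners:
            return (xmax - xmin, ymax - ymin)
        return None


def point_in_window(window: PlotWindow, p: tuple[float, float]) -> bool:
    """True iff ``p`` lies inside or on the boundary of the window."""
    return bool(window.contains(p[0], p[1]))


@dataclass
class MarkedPointPattern:
    """Plant coordinates with ploidy marks inside a plot window."""

    window: PlotWindow
    x: np.ndarray
    y: np.ndarray
    marks: np.ndarray
    labels: tuple[str, ...] = DEFAULT_TAXA

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.marks = np.asarray(self.marks, dtype=object)
        if not (self.x.shape == self.y.shape == self.marks.shape):
            raise ValueError("x, y and marks must have equal length")
        unknown = set(self.marks) - set(self.labels)
        if unknown:
            raise PointTableParseError(f"unknown taxon codes: {sorted(unknown)}")
        if self.n > 0:
            inside = self.window.contains(self.x, self.y)
            if not np.all(inside):
                bad = int(np.flatnonzero(~inside)[0])
                raise PointOutsideWindowError(
                    f"point {bad} at ({self.x[bad]}, {self.y[bad]}) lies "
                    f"outside window {self.window.plot_id!r}"
                )

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def n_by_mark(self) -> dict[str, int]:
        counts = Counter(self.marks.tolist())
        return {lab: counts.get(lab, 0) for lab in self.labels}

    def coords(self, mark: str | None = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally restricted to one mark."""
        if mark is None:
            return np.column_stack([self.x, self.y])
        sel = self.marks == mark
        return np.column_stack([self.x[sel], self.y[sel]])

    def subset(self, mark: str) -> "MarkedPointPattern":
        sel = self.marks == mark
        return MarkedPointPattern(
            self.window, self.x[sel], self.y[sel], self.marks[sel], self.labels
        )


def read_point_table(
    path: str | Path,
    window: PlotWindow,
    *,
    labels: Iterable[str] = DEFAULT_TAXA,
    outside_policy: str = "fail",
) -> MarkedPointPattern:
    """Read a delimited point table (header ``plot_id,taxon,x,y``).

    Comma- or tab-delimited; the delimiter is sniffed from the header.
    ``outside_policy`` is ``"fail"`` (default: any point outside the
    window raises, naming the offending row) or ``"drop"`` (points
    outside are dropped with a warning).
    """
    path = Path(path)
    labels = tuple(labels)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise PointTableParseError(f"{path}: {exc}") from exc
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise PointTableParseError(f"{path}: {exc}") from exc
    required = {"plot_id", "taxon", "x", "y"}
    if not required.issubset(df.columns):
        raise PointTableParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise PointTableParseError(
                f"{path}: malformed {col!r} value in data row {row + 1}"
            )
        df[col] = pd.to_numeric(df[col])
    if df[["x", "y"]].isna().any().any():
        row = int(np.flatnonzero(df[["x", "y"]].isna().any(axis=1))[0])
        raise PointTableParseError(f"{path}: missing coordinate in data row {row + 1}")
    unknown = set(df["taxon"]) - set(labels)
    if unknown:
        raise PointTableParseError(f"{path}: unknown taxon codes {sorted(unknown)}")

    inside = window.contains(df["x"].to_numpy(), df["y"].to_numpy())
    if not np.all(inside):
        rows = np.flatnonzero(~inside)
        if outside_policy == "fail":
            r = int(rows[0])
            raise PointOutsideWindowError(
                f"{path}: data row {r + 1} at "
                f"({df['x'].iat[r]}, {df['y'].iat[r]}) is outside window "
                f"{window.plot_id!r}"
            )
        if outside_policy == "drop":
            warnings.warn(
                f"{path}: dropping {rows.size} point(s) outside window "
                f"{window.plot_id!r}",
                stacklevel=2,
            )
            df = df.loc[inside].reset_index(drop=True)
        else:
            raise ValueError(f"unknown outside_policy {outside_policy!r}")

    return MarkedPointPattern(
        window,
        df["x"].to_numpy(),
        df["y"].to_numpy(),
        df["taxon"].to_numpy(dtype=object),
        labels,
    )


def write_point_table(pattern: MarkedPointPattern, path: str | Path) -> None:
    """Write a pattern back to the delimited format ``read_point_table`` reads."""
    df = pd.DataFrame(
        {
            "plot_id": pattern.window.plot_id,
            "taxon": pattern.marks,
            "x": pattern.x,
            "y": pattern.y,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_window_geojson(path: str | Path, plot_id: str | None = None) -> PlotWindow:
    """Read a GeoJSON Polygon (first/exterior ring only) as a PlotWindow.

    Coordinates must already be projected to planar metres.
    """
    import json

    with open(path) as fh:
        gj = json.load(fh)
    geom = gj.get("geometry", gj)
    if geom.get("type") != "Polygon":
        raise InvalidGeometryError(f"{path}: expected a GeoJSON Polygon")
    ring = geom["coordinates"][0]
    if len(ring) > 1 and tuple(ring[0]) == tuple(ring[-1]):
        ring = ring[:-1]
    props = gj.get("properties") or {}
    return PlotWindow(
        plot_id=plot_id or str(props.get("plot_id", Path(path).stem)),
        vertices=tuple((float(x), float(y)) for x, y in ring),
    )


def density_per_hectare(n: int, area_m2: float) -> float:
    """Individuals per hectare: 10,000 · n / area."""
    if area_m2 <= 0:
        raise InvalidGeometryError(f"area must be positive, got {area_m2}")
    if n < 0:
        raise ValueError(f"count must be >= 0, got {n}")
    return M2_PER_HECTARE * n / area_m2
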