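"""Exception hierarchy shared by all cytospat modules."""


class CytospatError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(CytospatError):
    """Polygon or window fails a geometric validity requirement."""


class DegenerateGeometryError(InvalidGeometryError):
    """Polygon has (numerically) zero area."""


class PointTableParseError(CytospatError):
    """A delimited point/quadrat table could not be parsed."""


class PointOutsideWindowError(CytospatError):
    """A point falls outside its declared plot window."""


class InvalidParameterError(CytospatError):
    """A numeric parameter violates its admissible range."""


class InsufficientDataError(CytospatError):
    """Too few observations for the requested statistic."""


class GridAlignmentError(CytospatError):
    """Two per-radius results are defined on different radius grids."""


class ResolutionError(CytospatError):
    """The evaluation grid is too coarse for the requested quantity."""


class LayoutError(CytospatError):
    """Sampling-design blocks do not tile the survey grid."""
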