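"""Quadrat-scale comparisons between occupied and unoccupied quadrats.

Continuous covariates (cover fractions, path distance, slope, richness)
are compared between quadrats with and without a cytotype by a
two-sample Wilcoxon rank-sum (Mann–Whitney) test; species
presence/absence against cytotype presence/absence by a Yates
continuity-corrected 2×2 chi-square.  Both families are Bonferroni
corrected.  Bray–Curtis dissimilarities between quadrat species
profiles are exposed as the input for any off-the-shelf ordination.
Soil samples carry the grain-size stack, pH, conductivity, organic
matter, Munsell colour, and the redness index RI = R²/(B·G³), a proxy
for free iron in dune sands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .errors import InsufficientDataError, InvalidParameterError

#: Continuous covariates compared in the presence/absence family.
DEFAULT_COVARIATES = (
    "total_cover",
    "nanophanerophyte_cover",
    "hemicryptophyte_cover",
    "chamaephyte_cover",
    "geophyte_cover",
    "therophyte_cover",
    "path_cover",
    "distance_to_path",
    "slope",
    "species_richness",
)


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    n_absent: int
    n_present: int
    mean_absent: float
    mean_present: float
    se_absent: float
    se_present: float
    statistic: float
    p_raw: float
    p_adjusted: float
    test: str = "wilcoxon-rank-sum"


@dataclass(frozen=True)
class OccurrenceTestResult:
    species: str
    #: 2×2 counts: (taxon present & sp present, taxon present & sp absent,
    #: taxon absent & sp present, taxon absent & sp absent)
    counts: tuple[int, int, int, int]
    chi2: float
    p_raw: float
    p_adjusted: float
    test: str = "chi2-yates"


@dataclass(frozen=True)
class SoilSample:
    """One soil core: grain-size fractions (%), chemistry, and colour."""

    sample_id: str
    grain_fractions: tuple[float, ...]  # coarse->fine, must close to 100 %
    pH: float
    EC: float
    SOM: float
    munsell_hue: str
    munsell_value: float
    munsell_chroma: float
    rgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        fr = np.asarray(self.grain_fractions, dtype=float)
        if np.any(fr < 0):
            raise InvalidParameterError(
                f"{self.sample_id}: negative grain fraction"
            )
        if abs(fr.sum() - 100.0) > 0.5:
            raise InvalidParameterError(
                f"{self.sample_id}: grain fractions sum to {fr.sum():.2f}, "
                "must close to 100 ± 0.5 %"
            )
        if not 0.0 <= self.pH <= 14.0:
            raise InvalidParameterError(f"{self.sample_id}: pH {self.pH} out of range")

    @property
    def redness_index(self) -> float:
        r, g, b = self.rgb
        return redness_index(r, g, b)


def redness_index(R: float, G: float, B: float) -> float:
    """RI = R² / (B · G³) from calibrated mean channel values."""
    if G <= 0 or B <= 0:
        raise InvalidParameterError("G and B channels must be positive")
    return float(R**2 / (B * G**3))


def ranksum_test(
    values: Sequence[float], groups: Sequence[bool]
) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon rank-sum (Mann–Whitney U).

    Mid-ranks for ties.  The exact null distribution is enumerated when
    both groups have at most 10 observations and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections is used.  Returns (U statistic of the True group, p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    x = values[groups]
    y = values[~groups]
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if np.all(values == values[0]):
        warnings.warn("all values identical; rank-sum p set to 1", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(values).size < values.size
    method = "exact" if (max(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(
    raw_p: Sequence[float] | float, m: int
) -> np.ndarray | float:
    """min(1, p·m) elementwise; m is the family size."""
    if m < 1:
        raise InvalidParameterError(f"m must be >= 1, got {m}")
    p = np.asarray(raw_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    adj = np.minimum(1.0, p * m)
    return float(adj) if np.isscalar(raw_p) else adj


def occurrence_chi2(
    a: int, b: int, c: int, d: int, *, yates: bool = True,
    zero_marginal: str = "warn",
) -> tuple[float, float]:
    """Chi-square on the 2×2 table [[a, b], [c, d]], df = 1.

    Yates continuity correction is on by default.  A zero row/column
    marginal leaves the test undefined: with ``zero_marginal="warn"``
    (default) this returns (0, 1) with a warning, with ``"raise"`` it
    raises.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise InvalidParameterError("counts must be >= 0 with a positive total")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        if zero_marginal == "raise":
            raise InsufficientDataError("a zero marginal leaves the test undefined")
        warnings.warn(
            "zero marginal in 2x2 table; reporting chi2=0, p=1", stacklevel=2
        )
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=yates)
    return float(chi2), float(p)


def bray_curtis_matrix(abundances: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarities d(u,v) = Σ|u−v| / Σ(u+v).

    Rows are quadrats/samples, columns species.  A pair of all-zero rows
    has an undefined dissimilarity; it is reported as 0 with a warning.
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidParameterError("need a 2-D matrix with >= 2 rows")
    if np.any(x < 0):
        raise InvalidParameterError("abundances must be non-negative")
    zero_rows = ~np.any(x > 0, axis=1)
    with np.errstate(invalid="ignore"):
        dm = squareform(pdist(x, metric="braycurtis"))
    if zero_rows.sum() >= 2:
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero rows: their pairwise "
            "dissimilarities are undefined and reported as 0",
            stacklevel=2,
        )
    dm = np.nan_to_num(dm, nan=0.0)
    np.fill_diagonal(dm, 0.0)
    return dm


def species_columns(table: pd.DataFrame) -> list[str]:
    """Occurrence-flag columns, marked by the ``sp: `` prefix."""
    return [c for c in table.columns if c.startswith("sp: ")]


def compare_presence_absence(
    table: pd.DataFrame,
    taxon: str,
    variables: Sequence[str] | None = None,
    species: Sequence[str] | None = None,
    m_variables: int | None = None,
    m_species: int | None = None,
    yates: bool = True,
) -> tuple[list[ComparisonResult], list[OccurrenceTestResult]]:
    """Full presence/absence comparison for one cytotype.

    ``table`` needs a boolean ``present_<taxon>`` column, the continuous
    covariates, and ``sp: <name>`` occurrence flags.  Bonferroni family
    sizes default to the number of variables and species actually
    tested; pass ``m_variables`` / ``m_species`` to override (e.g. to
    correct across taxa as well).
    """
    flag_col = f"present_{taxon}"
    if flag_col not in table.columns:
        raise InvalidParameterError(f"table has no column {flag_col!r}")
    flags = table[flag_col].astype(bool).to_numpy()
    if variables is None:
        variables = [v for v in DEFAULT_COVARIATES if v in table.columns]
    if species is None:
        species = [c[len("sp: "):] for c in species_columns(table)]
    m_v = m_variables if m_variables is not None else max(len(variables), 1)
    m_s = m_species if m_species is not None else max(len(species), 1)
    if m_v < len(variables) or m_s < len(species):
        raise InvalidParameterError(
            "Bonferroni family size cannot be smaller than the number of tests"
        )

    comparisons: list[ComparisonResult] = []
    for var in variables:
        vals = table[var].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            warnings.warn(f"{var!r} has < 2 distinct values; skipped", stacklevel=2)
            continue
        stat, p = ranksum_test(vals, flags)
        pres, absn = vals[flags], vals[~flags]
        comparisons.append(
            ComparisonResult(
                variable=var,
                n_absent=absn.size, n_present=pres.size,
                mean_absent=float(np.mean(absn)),
                mean_present=float(np.mean(pres)),
                se_absent=float(np.std(absn, ddof=1) / np.sqrt(absn.size))
                if absn.size > 1 else float("nan"),
                se_present=float(np.std(pres, ddof=1) / np.sqrt(pres.size))
                if pres.size > 1 else float("nan"),
                statistic=stat, p_raw=p,
                p_adjusted=float(bonferroni_adjust(p, m_v)),
            )
        )

    occurrences: list[OccurrenceTestResult] = []
    for name in species:
        col = f"sp: {name}" if f"sp: {name}" in table.columns else name
        sp = table[col].astype(bool).to_numpy()
        a = int(np.sum(flags & sp))
        b = int(np.sum(flags & ~sp))
        c = int(np.sum(~flags & sp))
        dd = int(np.sum(~flags & ~sp))
        chi2, p = occurrence_chi2(a, b, c, dd, yates=yates)
        occurrences.append(
            OccurrenceTestResult(
                species=name, counts=(a, b, c, dd), chi2=chi2, p_raw=p,
                p_adjusted=float(bonferroni_adjust(p, m_s)),
            )
        )
    return comparisons, occurrences


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def occurrences_to_frame(results: Sequence[OccurrenceTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
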