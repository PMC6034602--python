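"""End-to-end orchestration, configuration, and summary reporting."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .density import association_chi2, equal_area_partition, kernel_density_grid
from .ecology import compare_presence_absence, comparisons_to_frame, occurrences_to_frame
from .errors import InvalidParameterError, LayoutError
from .geometry import (
    DEFAULT_TAXA,
    MarkedPointPattern,
    PlotWindow,
    density_per_hectare,
    read_point_table,
)
from .neighbors import distance_band_profile, nearest_cross_distances, profile_peaks
from .ripley import csr_envelope

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def build_summary_table(
    patterns: Mapping[str, MarkedPointPattern],
    areas: Mapping[str, float] | None = None,
    taxa: Sequence[str] = DEFAULT_TAXA,
) -> pd.DataFrame:
    """Per-plot counts, densities (individuals/ha) and cytotype ratios.

    Densities are rounded half-up to 1 decimal place and ratios to 2,
    the convention of the published per-plot summary.  ``areas`` can
    override the shoelace plot areas with published values.  Ratios with
    a zero denominator are reported as NA.
    """
    rows = []
    for plot_id, pat in patterns.items():
        area = (
            float(areas[plot_id])
            if areas and plot_id in areas
            else pat.window.area_m2
        )
        if area <= 0:
            raise InvalidParameterError(f"plot {plot_id!r}: non-positive area")
        counts = pat.n_by_mark
        row: dict[str, object] = {"plot": plot_id, "area_m2": area, "n_total": pat.n}
        row["density_total"] = round_half_up(density_per_hectare(pat.n, area), 1)
        for t in taxa:
            row[f"n_{t}"] = counts.get(t, 0)
            row[f"density_{t}"] = round_half_up(
                density_per_hectare(counts.get(t, 0), area), 1
            )
        for num, den in (("4x", "2x"), ("3x", "2x"), ("3x", "4x")):
            if counts.get(den, 0) == 0:
                row[f"ratio_{num}_{den}"] = np.nan
            else:
                row[f"ratio_{num}_{den}"] = round_half_up(
                    counts.get(num, 0) / counts[den], 2
                )
        rows.append(row)
    return pd.DataFrame(rows)


def grid_sampling_counts(
    grid_w: float, grid_h: float, quadrat: float, eco_block: float, soil_block: float
) -> tuple[int, int, int]:
    """Sampling-design counts for a rectangular survey grid.

    A ``grid_w × grid_h`` m grid is tiled by ``quadrat × quadrat`` m
    quadrats; ecology is scored in one quadrat per ``eco_block²`` block
    and soil cored once per ``soil_block²`` block.  All block sizes must
    evenly divide both grid dimensions.
    """
    for name, block in (("quadrat", quadrat), ("eco_block", eco_block),
                        ("soil_block", soil_block)):
        if block <= 0:
            raise InvalidParameterError(f"{name} must be > 0")
        for dim in (grid_w, grid_h):
            if abs(dim / block - round(dim / block)) > 1e-9:
                raise LayoutError(
                    f"{name} = {block} m does not evenly divide the "
                    f"{grid_w} × {grid_h} m grid"
                )
    n_quadrats = round(grid_w / quadrat) * round(grid_h / quadrat)
    n_eco = round(grid_w / eco_block) * round(grid_h / eco_block)
    n_soil = round(grid_w / soil_block) * round(grid_h / soil_block)
    return n_quadrats, n_eco, n_soil


# ---------------------------------------------------------------------------
# Configuration and the full pipeline


@dataclass
class AnalysisConfig:
    """Flat run configuration; every key maps to one config-file entry."""

    points: str                      # path to the marked point table
    window_vertices: list            # [[x, y], ...] plot corners
    plot_id: str = "plot"
    printed_area_m2: float | None = None
    quadrats: str | None = None      # optional quadrat ecology table
    taxa: tuple[str, ...] = DEFAULT_TAXA
    n_sim: int = 300
    rank: int = 1
    r_max: float | None = None
    edge_correction: str = "translation"
    bandwidth: float | None = None
    cell_size: float = 1.0
    bin_width: float = 0.5
    grid_res: float = 0.25
    m_variables: int | None = None
    m_species: int | None = None
    yates: bool = True
    seed: int = 0
    out_dir: str = "cytospat_out"

    def __post_init__(self) -> None:
        if self.n_sim < 2 * self.rank or self.rank < 1:
            raise InvalidParameterError(
                f"need n_sim >= 2*rank, got n_sim={self.n_sim}, rank={self.rank}"
            )
        for name in ("cell_size", "bin_width", "grid_res"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


#: Ordered association comparisons: (density taxon A, counted taxon B).
ASSOCIATION_PAIRS = (("2x", "4x"), ("4x", "2x"), ("2x", "3x"), ("4x", "3x"))
NEIGHBOR_PAIRS = (("3x", "2x"), ("3x", "4x"))


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write delimited-text reports to ``out_dir``.

    Stages: plot summary → per-taxon Ripley K envelopes → cross-taxon
    density associations → triploid neighbour profiles → quadrat
    ecology (when a quadrat table is configured).  Every output carries
    the config hash and seed in the run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = PlotWindow(
        config.plot_id,
        tuple(tuple(v) for v in config.window_vertices),
        printed_area_m2=config.printed_area_m2,
    )
    pattern = read_point_table(config.points, window, labels=config.taxa)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    log.info("stage summary: %d individuals in %r", pattern.n, config.plot_id)
    summary = build_summary_table({config.plot_id: pattern})
    summary.to_csv(out / "summary.csv", index=False)
    report["summary"] = summary.to_dict("records")

    r_grid = None
    if config.r_max is not None:
        r_grid = np.linspace(0.0, config.r_max, 512)
    counts = pattern.n_by_mark
    ripley_rows = []
    for i, taxon in enumerate(config.taxa):
        if counts.get(taxon, 0) < 2:
            log.warning("stage ripley: skipping %s (<2 individuals)", taxon)
            continue
        log.info("stage ripley: %s, n=%d, n_sim=%d", taxon, counts[taxon], config.n_sim)
        env = csr_envelope(
            pattern, r_grid=r_grid, n_sim=config.n_sim, rank=config.rank,
            seed=config.seed + i, edge_correction=config.edge_correction,
            mark=taxon,
        )
        df = pd.DataFrame(
            {
                "taxon": taxon, "r": env.r, "k_hat": env.k_obs.k_hat,
                "k_theo": env.k_obs.k_theo, "lo": env.lo, "hi": env.hi,
                "label": env.classification,
            }
        )
        ripley_rows.append(df)
    if ripley_rows:
        pd.concat(ripley_rows).to_csv(out / "ripley.csv", index=False)
        report["ripley"] = {
            str(df["taxon"].iat[0]): df["label"].value_counts().to_dict()
            for df in ripley_rows
        }

    assoc_rows = []
    for taxon_a, taxon_b in ASSOCIATION_PAIRS:
        if counts.get(taxon_a, 0) == 0 or counts.get(taxon_b, 0) == 0:
            continue
        log.info("stage associate: %s density vs %s counts", taxon_a, taxon_b)
        grid = kernel_density_grid(
            pattern, bandwidth=config.bandwidth, cell_size=config.cell_size,
            mark=taxon_a,
        )
        res = association_chi2(equal_area_partition(grid), pattern, mark=taxon_b)
        assoc_rows.append(
            {
                "taxon_a": taxon_a, "taxon_b": taxon_b,
                "o_low": res.observed["low"], "o_mid": res.observed["mid"],
                "o_high": res.observed["high"], "expected": res.expected,
                "chi2": res.chi2, "df": res.df, "p": res.p_value,
            }
        )
    if assoc_rows:
        pd.DataFrame(assoc_rows).to_csv(out / "association.csv", index=False)
        report["association"] = assoc_rows

    neigh_rows = []
    for src, ref in NEIGHBOR_PAIRS:
        if counts.get(src, 0) < 2 or counts.get(ref, 0) == 0:
            continue
        log.info("stage neighbors: %s -> nearest %s", src, ref)
        dset = nearest_cross_distances(pattern, pattern, src, ref)
        prof = distance_band_profile(
            dset, window, pattern, bin_width=config.bin_width,
            grid_res=config.grid_res, reference_mark=ref,
        )
        peaks = profile_peaks(prof, min_separation=2 * config.bin_width)
        pd.DataFrame(
            {
                "bin_lo": prof.bin_edges[:-1], "bin_hi": prof.bin_edges[1:],
                "count": prof.counts, "band_area_m2": prof.band_areas,
                "density_per_m2": prof.density,
            }
        ).to_csv(out / f"profile_{src}_to_{ref}.csv", index=False)
        neigh_rows.append(
            {
                "source": src, "reference": ref, "n": dset.n,
                "mean_m": prof.mean, "se_m": prof.se,
                "peaks_m": ";".join(f"{p:.2f}" for p in peaks),
            }
        )
    if neigh_rows:
        pd.DataFrame(neigh_rows).to_csv(out / "neighbors.csv", index=False)
        report["neighbors"] = neigh_rows

    if config.quadrats:
        log.info("stage ecology: %s", config.quadrats)
        table = pd.read_csv(config.quadrats)
        for taxon in config.taxa:
            if f"present_{taxon}" not in table.columns:
                continue
            comp, occ = compare_presence_absence(
                table, taxon, m_variables=config.m_variables,
                m_species=config.m_species, yates=config.yates,
            )
            comparisons_to_frame(comp).to_csv(
                out / f"ecology_covariates_{taxon}.csv", index=False
            )
            occurrences_to_frame(occ).to_csv(
                out / f"ecology_species_{taxon}.csv", index=False
            )
        report["ecology"] = "written"

    manifest = {
        "package": "cytospat", "version": __version__,
        "config": asdict(config), "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
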