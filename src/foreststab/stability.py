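"""Relative density, the forest stability index, and size-class partitions.

A population's relative density within a stand is the sum over its trees of
the density each tree represents divided by the maximum density a stand of
that forest type could hold were its mean tree size equal to that tree's
size:

    RD = Σ_h N_h / N_max(s_h).

Summing tree-level ratios (rather than dividing aggregate TPH by
N_max(S̄)) removes the class-aggregation bias that inflates relative density
in stands with skewed size distributions, and makes RD exactly additive over
any partition of the tree list — in particular over size-class deciles.

The forest stability index (FSI) is the average annual change in RD between
successive censuses, FSI = ΔRD/Δt; %FSI standardises by baseline relative
density, %FSI = 100·FSI/RD_t1, so that e.g. a %FSI of −5.56 %/yr sustained
over an 18-year study equals complete loss of the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .frontier import SizeDensityModel, predict_nmax
from .inventory import PlotCensus, TreeRecord

N_SIZE_CLASSES = 10


@dataclass(frozen=True)
class PopulationChangeRecord:
    """Relative density of one population on one plot at both censuses."""

    plot_id: str
    population_key: tuple  # (species,) or (species, size_class)
    rd_t1: float
    rd_t2: float
    delta_t: float
    fsi: float

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")


def relative_density(
    trees: Iterable[TreeRecord],
    model: SizeDensityModel,
    forest_type: int | None,
) -> float:
    """Tree-level relative density of a population (sum of N_h / N_max(s_h)).

    Empty tree lists give RD = 0. RD is not capped at 1: the frontier is a
    99th percentile, so a small fraction of stands legitimately exceed it.
    """
    rd = 0.0
    for t in trees:
        if not t.qualifies:
            continue
        rd += t.density_factor / predict_nmax(model, forest_type, t.basal_area)
    return rd


def aggregate_relative_density(
    trees: Sequence[TreeRecord],
    model: SizeDensityModel,
    forest_type: int | None,
) -> float:
    """Aggregate-index relative density TPH / N_max(S̄) (for bias comparison).

    Biased upward relative to :func:`relative_density` whenever tree sizes
    are unequal and |r| < 1 (Jensen's inequality on the concave s^{|r|}).
    """
    live = [t for t in trees if t.qualifies]
    tph = sum(t.density_factor for t in live)
    if tph == 0:
        return 0.0
    s_bar = sum(t.density_factor * t.basal_area for t in live) / tph
    return tph / predict_nmax(model, forest_type, s_bar)


def fsi(rd_t1: float, rd_t2: float, delta_t: float) -> float:
    """Average annual change in relative density, (RD_t2 − RD_t1)/Δt.

    Positive values are expansion, negative decline. Range expansion from
    absence (RD_t1 = 0) is an ordinary positive change.
    """
    if delta_t <= 0:
        raise ValueError(f"delta_t must be > 0, got {delta_t}")
    return (rd_t2 - rd_t1) / delta_t


def percent_fsi(mean_fsi: float, mean_rd_t1: float) -> float:
    """Population-level %FSI: 100 · mean FSI / mean baseline RD (% per year).

    Computed as a ratio of population means, never per plot (plot-level
    baselines of zero occur by design under range expansion). Total change
    over a study period is linear: %FSI × years.
    """
    if mean_rd_t1 <= 0:
        raise ValueError("mean baseline relative density must be > 0 "
                         "(population absent at baseline everywhere)")
    return 100.0 * mean_fsi / mean_rd_t1


# ---------------------------------------------------------------------------
# Size classes
# ---------------------------------------------------------------------------


@dataclass
class SizeClassTable:
    """Decile boundaries of baseline DBH per (species, site productivity class).

    ``boundaries[key]`` holds the nine inner decile boundaries q_1 … q_9;
    classes are the half-open intervals [q_{k−1}, q_k) with class 1 open
    below and class 10 closed above. A species-level fallback (pooled over
    site classes) covers combinations absent from the table.
    """

    boundaries: dict[tuple[int, int], np.ndarray]
    species_fallback: dict[int, np.ndarray]

    @classmethod
    def from_baseline(
        cls, diameters: Mapping[tuple[int, int], Sequence[float]]
    ) -> "SizeClassTable":
        """Build from initial-census diameters keyed by (species, site class)."""
        qs = np.linspace(0.1, 0.9, 9)
        bounds: dict[tuple[int, int], np.ndarray] = {}
        pooled: dict[int, list[float]] = {}
        for (sp, site), dbhs in diameters.items():
            arr = np.asarray(list(dbhs), dtype=float)
            if arr.size:
                bounds[(sp, site)] = np.quantile(arr, qs)
                pooled.setdefault(sp, []).extend(arr.tolist())
        fallback = {
            sp: np.quantile(np.asarray(v), qs) for sp, v in pooled.items() if v
        }
        return cls(boundaries=bounds, species_fallback=fallback)

    def assign(self, species: int, site_class: int, dbh: float) -> tuple[int, bool]:
        """Class 1–10 for one stem; second element flags species-level fallback."""
        key = (species, site_class)
        fell_back = key not in self.boundaries
        edges = self.species_fallback[species] if fell_back else self.boundaries[key]
        return int(np.searchsorted(edges, dbh, side="right")) + 1, fell_back


def assign_size_classes(
    trees: Sequence[TreeRecord], table: SizeClassTable, site_class: int
) -> list[int]:
    """Decile class (1–10) for each tree, by its species' baseline diameters."""
    return [table.assign(t.species_code, site_class, t.dbh)[0] for t in trees]


def build_size_class_table(censuses: Sequence[PlotCensus]) -> SizeClassTable:
    """Decile table from the initial censuses of a set of paired plots."""
    diameters: dict[tuple[int, int], list[float]] = {}
    for c in censuses:
        base = c.previous_census if c.paired else c
        for t in base.live_trees():
            diameters.setdefault(
                (t.species_code, base.site_productivity_class), []
            ).append(t.dbh)
    return SizeClassTable.from_baseline(diameters)


# ---------------------------------------------------------------------------
# Change records
# ---------------------------------------------------------------------------


def change_records(
    pairs: Sequence[PlotCensus],
    model: SizeDensityModel,
    *,
    by_size_class: bool = False,
    size_table: SizeClassTable | None = None,
    populations: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-plot, per-population relative density change table.

    One row per (plot, species[, size class]) for every species in
    ``populations`` (default: all species seen in either census of any
    pair), including absent populations (RD 0 → 0, FSI 0) so that
    population means are taken over the full plot set. Columns carry the
    plot context needed for estimation (stratum, panel year, areal units).
    """
    if by_size_class and size_table is None:
        size_table = build_size_class_table(pairs)
    if populations is None:
        seen: set[int] = set()
        for c in pairs:
            for cc in (c, c.previous_census):
                if cc is not None:
                    seen.update(t.species_code for t in cc.live_trees())
        populations = sorted(seen)

    rows = []
    for c in pairs:
        if not c.paired:
            raise ValueError(f"plot {c.plot_id} is unpaired")
        prev = c.previous_census
        rd1 = _population_rd(prev, model, by_size_class, size_table)
        rd2 = _population_rd(c, model, by_size_class, size_table,
                             site_class=prev.site_productivity_class)
        keys = set(rd1) | set(rd2)
        if not by_size_class:
            keys |= {(sp,) for sp in populations}
        else:
            keys |= {(sp, k) for sp in populations for k in range(1, N_SIZE_CLASSES + 1)}
        for key in sorted(keys):
            a, b = rd1.get(key, 0.0), rd2.get(key, 0.0)
            rows.append({
                "plot_id": c.plot_id,
                "species": key[0],
                "size_class": key[1] if by_size_class else 0,
                "rd_t1": a,
                "rd_t2": b,
                "delta_t": float(c.delta_t),
                "fsi": fsi(a, b, float(c.delta_t)),
                "panel_year": c.census_year,
                "stratum_id": c.stratum_id,
                "ecoregion_division": c.ecoregion_division,
                "ecoregion_subsection": c.ecoregion_subsection,
                "fire": c.disturbance_flags.get("fire", 0),
                "insect": c.disturbance_flags.get("insect", 0),
                "disease": c.disturbance_flags.get("disease", 0),
            })
    return pd.DataFrame(rows)


def _population_rd(
    census: PlotCensus,
    model: SizeDensityModel,
    by_size_class: bool,
    size_table: SizeClassTable | None,
    site_class: int | None = None,
) -> dict[tuple, float]:
    """RD keyed by (species,) or (species, size class) for one census."""
    site = census.site_productivity_class if site_class is None else site_class
    out: dict[tuple, float] = {}
    for t in census.live_trees():
        if by_size_class:
            k, _ = size_table.assign(t.species_code, site, t.dbh)
            key: tuple = (t.species_code, k)
        else:
            key = (t.species_code,)
        nmax = predict_nmax(model, census.forest_type, t.basal_area)
        out[key] = out.get(key, 0.0) + t.density_factor / nmax
    return out
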