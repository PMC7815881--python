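"""Domain types, FIA-dialect CSV I/O, census pairing, and eligibility filters.

The in-memory model mirrors the plot/tree structure of national forest
inventories: a :class:`PlotCensus` is one visit to one permanent plot and
carries a list of :class:`TreeRecord` (one live or dead stem each, with the
per-hectare density it represents under the plot design). Successive visits
are linked through the previous-plot key, exactly as the inventory datamart
links them, never by (plot number, year) heuristics.

Units are normalised on read: DBH to centimetres, represented density to
stems per hectare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

ACRES_PER_HECTARE = 2.4710538
CM_PER_INCH = 2.54
MIN_DBH_CM = 2.54
DISTURBANCE_TYPES = ("fire", "insect", "disease")

# Condition-level disturbance code ranges -> modelled disturbance type.
# Codes outside these ranges (weather, animals, ...) are carried but unmodelled.
_DISTURBANCE_CODE_MAP = {
    range(10, 20): "insect",
    range(20, 30): "disease",
    range(30, 40): "fire",
}


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """A record violates an invariant (e.g. non-positive remeasurement interval)."""


def classify_disturbance_code(code: int) -> str | None:
    """Map a condition-level disturbance code to {fire, insect, disease} or None."""
    for rng, name in _DISTURBANCE_CODE_MAP.items():
        if code in rng:
            return name
    return None


@dataclass
class TreeRecord:
    """One stem at one census.

    ``density_factor`` is the number of stems per hectare this record
    represents after plot-design expansion (microplot stems carry large
    factors, subplot stems small ones).
    """

    tree_id: str
    species_code: int
    dbh: float  # cm
    status: str  # "live" | "dead"
    density_factor: float  # stems / ha

    def __post_init__(self) -> None:
        if not math.isfinite(self.density_factor) or self.density_factor < 0:
            raise ValidationError(
                f"tree {self.tree_id}: density_factor must be finite and >= 0"
            )
        if self.status not in ("live", "dead"):
            raise ValidationError(f"tree {self.tree_id}: bad status {self.status!r}")

    @property
    def basal_area(self) -> float:
        """Stem basal area in m², π·DBH²/40000 with DBH in cm."""
        return math.pi * self.dbh**2 / 40000.0

    @property
    def qualifies(self) -> bool:
        """True for live stems at or above the 2.54 cm DBH threshold."""
        return self.status == "live" and self.dbh >= MIN_DBH_CM


@dataclass
class PlotCensus:
    """One plot × one measurement occasion, with stand context and tree list."""

    plot_id: str
    census_year: int
    forest_type: int
    site_productivity_class: int = 4
    ecoregion_division: str = ""
    ecoregion_subsection: str = ""
    stratum_id: str = ""
    prev_plot_id: str | None = None
    previous_census: "PlotCensus | None" = None
    delta_t: float | None = None  # years since previous census, > 0 when paired
    disturbance_flags: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in DISTURBANCE_TYPES}
    )
    other_disturbance_codes: tuple[int, ...] = ()
    treatment_flag: int = 0
    treatment_year: int | None = None
    trees: list[TreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in DISTURBANCE_TYPES:
            self.disturbance_flags.setdefault(t, 0)
            if self.disturbance_flags[t] not in (0, 1):
                raise ValidationError(
                    f"plot {self.plot_id}: disturbance flag {t} must be 0/1"
                )
        if self.previous_census is not None:
            if self.delta_t is None:
                self.delta_t = float(self.census_year - self.previous_census.census_year)
            if self.delta_t <= 0:
                raise ValidationError(
                    f"plot {self.plot_id}: paired census has delta_t {self.delta_t} <= 0"
                )

    @property
    def paired(self) -> bool:
        return self.previous_census is not None

    @property
    def disturbed(self) -> bool:
        return any(self.disturbance_flags[t] for t in DISTURBANCE_TYPES) or bool(
            self.other_disturbance_codes
        )

    def live_trees(self) -> list[TreeRecord]:
        return [t for t in self.trees if t.qualifies]


@dataclass(frozen=True)
class StandSummary:
    """Stand-level indices: absolute density, basal area, mean tree size, shape."""

    tph: float  # stems / ha
    ba_per_ha: float  # m² / ha
    mean_tree_ba: float | None  # m²; None when the stand is empty
    diameter_skewness: float | None  # None for < 3 stems or zero spread
    n_stems: int


def summarize_stand(census: PlotCensus) -> StandSummary:
    """Compute TPH, basal area per ha, mean tree basal area, and DBH skewness.

    Only live stems with DBH ≥ 2.54 cm contribute. Skewness is the
    population-moment coefficient g1 = m3 / m2^{3/2} on the unweighted DBH
    list (the measured sample, not the expanded population), undefined for
    fewer than three stems or a degenerate spread.
    """
    live = census.live_trees()
    tph = float(sum(t.density_factor for t in live))
    ba = float(sum(t.density_factor * t.basal_area for t in live))
    mean_ba = ba / tph if tph > 0 else None
    dbhs = np.array([t.dbh for t in live], dtype=float)
    skew: float | None = None
    if dbhs.size >= 3 and np.ptp(dbhs) > 0:
        skew = float(stats.skew(dbhs, bias=True))
    return StandSummary(tph=tph, ba_per_ha=ba, mean_tree_ba=mean_ba,
                        diameter_skewness=skew, n_stems=int(dbhs.size))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_DEFAULT_PLOT_COLUMNS = {
    "plot_id": "CN",
    "prev_plot_id": "PREV_PLT_CN",
    "census_year": "MEASYEAR",
    "forest_type": "FORTYPCD",
    "site_class": "SITECLCD",
    "division": "ECODIV",
    "subsection": "ECOSUBCD",
    "stratum": "STRATUM_CN",
    "disturbance_codes": ["DSTRBCD1", "DSTRBCD2", "DSTRBCD3"],
    "treatment_codes": ["TRTCD1", "TRTCD2", "TRTCD3"],
    "treatment_years": ["TRTYR1", "TRTYR2", "TRTYR3"],
}
_DEFAULT_TREE_COLUMNS = {
    "plot_id": "PLT_CN",
    "tree_id": "CN",
    "species": "SPCD",
    "dbh": "DIA",
    "status": "STATUSCD",
    "density_factor": "TPA_UNADJ",
}


@dataclass
class Dialect:
    """Column names and units of an inventory CSV pair (plot table + tree table).

    Defaults mimic the public FIA datamart: diameters in inches
    (``dbh_unit="in"``), expansion factors in trees per acre
    (``density_unit="per_acre"``), live status code 1. The canonical dialect
    used for writing is metric (cm, stems/ha).
    """

    plot_columns: dict = field(default_factory=lambda: dict(_DEFAULT_PLOT_COLUMNS))
    tree_columns: dict = field(default_factory=lambda: dict(_DEFAULT_TREE_COLUMNS))
    dbh_unit: str = "in"  # "in" | "cm"
    density_unit: str = "per_acre"  # "per_acre" | "per_ha"
    live_status_code: int = 1

    @classmethod
    def canonical(cls) -> "Dialect":
        return cls(dbh_unit="cm", density_unit="per_ha")

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        d = cls()
        for key in ("dbh_unit", "density_unit", "live_status_code"):
            if key in raw:
                setattr(d, key, raw[key])
        d.plot_columns.update(raw.get("plot_columns", {}))
        d.tree_columns.update(raw.get("tree_columns", {}))
        return d

    def dbh_to_cm(self, x: float) -> float:
        return x * CM_PER_INCH if self.dbh_unit == "in" else x

    def density_to_per_ha(self, x: float) -> float:
        return x * ACRES_PER_HECTARE if self.density_unit == "per_acre" else x


def _require(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{table} table is missing required column {c!r}")


def read_inventory(
    plot_path, tree_path, dialect: Dialect | None = None
) -> list[PlotCensus]:
    """Read a plot table and a tree table; return censuses paired via the
    previous-plot key.

    Censuses whose previous-plot key matches no record are retained but
    unpaired (``paired`` is False) and excluded from change analysis
    downstream. A claimed pair with a non-positive interval raises
    :class:`ValidationError`.
    """
    dialect = dialect or Dialect()
    pc, tc = dialect.plot_columns, dialect.tree_columns

    plots = pd.read_csv(plot_path, dtype={pc["plot_id"]: str, pc["prev_plot_id"]: str,
                                          pc["stratum"]: str})
    trees = pd.read_csv(tree_path, dtype={tc["plot_id"]: str, tc["tree_id"]: str})

    scalar_plot_cols = [pc[k] for k in ("plot_id", "prev_plot_id", "census_year",
                                        "forest_type", "site_class", "division",
                                        "subsection", "stratum")]
    _require(plots, scalar_plot_cols, "plot")
    _require(trees, [tc[k] for k in tc], "tree")

    trees_by_plot: dict[str, list[TreeRecord]] = {}
    for row in trees.itertuples(index=False):
        rec = TreeRecord(
            tree_id=str(getattr(row, tc["tree_id"])),
            species_code=int(getattr(row, tc["species"])),
            dbh=dialect.dbh_to_cm(float(getattr(row, tc["dbh"]))),
            status="live"
            if int(getattr(row, tc["status"])) == dialect.live_status_code
            else "dead",
            density_factor=dialect.density_to_per_ha(
                float(getattr(row, tc["density_factor"]))
            ),
        )
        trees_by_plot.setdefault(str(getattr(row, tc["plot_id"])), []).append(rec)

    censuses: dict[str, PlotCensus] = {}
    for row in plots.itertuples(index=False):
        get = lambda k: getattr(row, pc[k])  # noqa: E731
        flags = {t: 0 for t in DISTURBANCE_TYPES}
        other: list[int] = []
        for col in pc["disturbance_codes"]:
            if col in plots.columns and not pd.isna(getattr(row, col)):
                code = int(getattr(row, col))
                if code == 0:
                    continue
                kind = classify_disturbance_code(code)
                if kind is None:
                    other.append(code)
                else:
                    flags[kind] = 1
        trt_flag, trt_year = 0, None
        for ccol, ycol in zip(pc["treatment_codes"], pc["treatment_years"]):
            if ccol in plots.columns and not pd.isna(getattr(row, ccol)):
                if int(getattr(row, ccol)) != 0:
                    trt_flag = 1
                    if ycol in plots.columns and not pd.isna(getattr(row, ycol)):
                        y = int(getattr(row, ycol))
                        trt_year = y if trt_year is None else max(trt_year, y)
        prev_raw = get("prev_plot_id")
        prev_id = None if pd.isna(prev_raw) or str(prev_raw) in ("", "nan") else str(prev_raw)
        pid = str(get("plot_id"))
        censuses[pid] = PlotCensus(
            plot_id=pid,
            prev_plot_id=prev_id,
            census_year=int(get("census_year")),
            forest_type=int(get("forest_type")),
            site_productivity_class=int(get("site_class")),
            ecoregion_division=str(get("division")),
            ecoregion_subsection=str(get("subsection")),
            stratum_id=str(get("stratum")),
            disturbance_flags=flags,
            other_disturbance_codes=tuple(other),
            treatment_flag=trt_flag,
            treatment_year=trt_year,
            trees=trees_by_plot.get(pid, []),
        )

    for census in censuses.values():
        if census.prev_plot_id and census.prev_plot_id in censuses:
            prev = censuses[census.prev_plot_id]
            dt = float(census.census_year - prev.census_year)
            if dt <= 0:
                raise ValidationError(
                    f"plot {census.plot_id}: claimed pair with previous census "
                    f"{prev.plot_id} has non-positive interval {dt}"
                )
            census.previous_census = prev
            census.delta_t = dt
    return list(censuses.values())


def write_inventory(censuses: Sequence[PlotCensus], plot_path, tree_path) -> None:
    """Write censuses in the canonical metric dialect (cm, stems/ha)."""
    pc, tc = _DEFAULT_PLOT_COLUMNS, _DEFAULT_TREE_COLUMNS
    prow, trow = [], []
    for c in censuses:
        rec = {
            pc["plot_id"]: c.plot_id,
            pc["prev_plot_id"]: c.prev_plot_id or "",
            pc["census_year"]: c.census_year,
            pc["forest_type"]: c.forest_type,
            pc["site_class"]: c.site_productivity_class,
            pc["division"]: c.ecoregion_division,
            pc["subsection"]: c.ecoregion_subsection,
            pc["stratum"]: c.stratum_id,
        }
        dist_codes = []
        if c.disturbance_flags.get("insect"):
            dist_codes.append(10)
        if c.disturbance_flags.get("disease"):
            dist_codes.append(20)
        if c.disturbance_flags.get("fire"):
            dist_codes.append(30)
        dist_codes.extend(c.other_disturbance_codes)
        for i, col in enumerate(pc["disturbance_codes"]):
            rec[col] = dist_codes[i] if i < len(dist_codes) else 0
        for i, (ccol, ycol) in enumerate(zip(pc["treatment_codes"], pc["treatment_years"])):
            rec[ccol] = c.treatment_flag if i == 0 else 0
            rec[ycol] = (c.treatment_year if (i == 0 and c.treatment_year) else 0)
        prow.append(rec)
        for t in c.trees:
            trow.append({
                tc["plot_id"]: c.plot_id,
                tc["tree_id"]: t.tree_id,
                tc["species"]: t.species_code,
                tc["dbh"]: t.dbh,
                tc["status"]: 1 if t.status == "live" else 2,
                tc["density_factor"]: t.density_factor,
            })
    pd.DataFrame(prow).to_csv(plot_path, index=False)
    pd.DataFrame(trow).to_csv(tree_path, index=False)


# ---------------------------------------------------------------------------
# Eligibility filters
# ---------------------------------------------------------------------------

TREATMENT_LOOKBACK_YEARS = 5
SKEWNESS_BOUNDS = (-1.0, 1.0)


def _interval_start(census: PlotCensus) -> float:
    if census.paired:
        return census.census_year - float(census.delta_t)
    return float(census.census_year)


def _recent_treatment(census: PlotCensus) -> bool:
    """Treatment in the interval, or within 5 years before its start."""
    t1 = _interval_start(census)
    if census.treatment_flag:
        if census.treatment_year is None:
            return True
        return census.treatment_year >= t1 - TREATMENT_LOOKBACK_YEARS
    prev = census.previous_census
    if prev is not None and prev.treatment_flag:
        if prev.treatment_year is None:
            return False
        return prev.treatment_year >= t1 - TREATMENT_LOOKBACK_YEARS
    return False


def filter_frontier_training(
    censuses: Sequence[PlotCensus],
) -> tuple[list[PlotCensus], dict[str, str]]:
    """Select stands eligible for fitting the maximum size-density frontier.

    Keeps the most recent census of each plot with (1) no disturbance and no
    silvicultural treatment in the interval or the preceding 5 years and
    (2) DBH skewness within the closed interval [−1, 1]. Plots with fewer
    than three live stems cannot be screened for shape and are excluded.
    Returns the kept set and a plot_id → exclusion-reason map.
    """
    latest: dict[str, PlotCensus] = {}
    for c in censuses:
        key = _root_plot_id(c)
        if key not in latest or c.census_year > latest[key].census_year:
            latest[key] = c
    kept: list[PlotCensus] = []
    excluded: dict[str, str] = {}
    lo, hi = SKEWNESS_BOUNDS
    for c in latest.values():
        if c.disturbed or (c.previous_census is not None and c.previous_census.disturbed):
            excluded[c.plot_id] = "disturbed"
            continue
        if _recent_treatment(c):
            excluded[c.plot_id] = "treated"
            continue
        summary = summarize_stand(c)
        if summary.diameter_skewness is None:
            excluded[c.plot_id] = "too_few_trees"
            continue
        if not (lo <= summary.diameter_skewness <= hi):
            excluded[c.plot_id] = "skewness"
            continue
        kept.append(c)
    return kept, excluded


def _root_plot_id(census: PlotCensus) -> str:
    """Identity of the physical plot: walk back through previous censuses."""
    c = census
    seen = {c.plot_id}
    while c.previous_census is not None and c.previous_census.plot_id not in seen:
        c = c.previous_census
        seen.add(c.plot_id)
    return c.plot_id


def filter_change_analysis(
    censuses: Sequence[PlotCensus],
) -> tuple[list[PlotCensus], dict[str, str]]:
    """Select paired censuses for change (FSI) analysis.

    Pairs with silvicultural treatment during the interval or within 5 years
    of the initial measurement are removed. Disturbance does NOT exclude a
    pair here — it is a modelled covariate downstream.
    """
    kept: list[PlotCensus] = []
    excluded: dict[str, str] = {}
    for c in censuses:
        if not c.paired:
            excluded[c.plot_id] = "unpaired"
            continue
        if _recent_treatment(c):
            excluded[c.plot_id] = "treated"
            continue
        kept.append(c)
    return kept, excluded


def stand_table(censuses: Sequence[PlotCensus]) -> pd.DataFrame:
    """Stand summaries as a DataFrame (one row per census), for model fitting."""
    rows = []
    for c in censuses:
        s = summarize_stand(c)
        rows.append({
            "plot_id": c.plot_id,
            "census_year": c.census_year,
            "forest_type": c.forest_type,
            "tph": s.tph,
            "ba_per_ha": s.ba_per_ha,
            "mean_tree_ba": s.mean_tree_ba,
            "diameter_skewness": s.diameter_skewness,
            "n_stems": s.n_stems,
        })
    return pd.DataFrame(rows)
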