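"""Synthetic paired-census forest landscapes with known ground truth.

The generator emulates the structure of a remeasured national-inventory
panel: plots carry a forest community type, stratum and areal labels, two
censuses roughly a decade apart within a 2001–2018 window (remeasurements
in the 2011–2018 annual panels), per-interval binary fire/insect/disease
flags, occasional silvicultural treatment, and tree lists whose summaries
match sampled stand states exactly.

Statistical structure, all recorded in the returned ground truth:

* stand states (TPH, S̄) are placed under a per-type power-law frontier
  N_max = a_i · S̄^{r_i}, with a configurable fraction of stands above it
  (the frontier is a 99th percentile, not a hard wall);
* per-species relative density evolves as RD_t2 = RD_t1 + Δt · FSI with
  FSI = drift + Σ_l β_jl x_l + noise, i.e. exactly the severity model the
  attribution stage fits;
* interval disturbance flags arise from annual Bernoulli(ψ) events — the
  flag is set if at least one event occurs in Δt years, so the binary datum
  censors multi-event intervals exactly as in the field protocol.

Tree diameters are drawn from a lognormal family (moment-matched to the
target mean basal area) whose log-scale spread controls the diameter
skewness: "normal" stands pass the |g1| ≤ 1 screen, "skewed" stands fail it.
Second-census tree lists keep first-census diameters and rescale the
represented densities to hit the target relative density exactly (an
optional diameter growth rate re-solves the density scaling under the true
frontier).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .inventory import DISTURBANCE_TYPES, MIN_DBH_CM, PlotCensus, TreeRecord

DEFAULT_SPECIES = (202, 108, 93)  # Douglas-fir, lodgepole pine, Engelmann spruce


def _default_frontier() -> list[tuple[float, float]]:
    return [(math.exp(7.0), -0.8), (math.exp(7.2), -0.85), (math.exp(6.8), -0.75)]


def _default_mixing() -> list[list[float]]:
    return [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]


class ConfigError(ValueError):
    """A landscape configuration violates an invariant."""


@dataclass
class LandscapeConfig:
    """Generating parameters of a synthetic landscape.

    Defaults describe a quiet but realistic western-US-like panel: mean
    remeasurement interval 9.78 years inside a 2001–2018 window, 1% of
    stands above their type's frontier, annual disturbance probabilities of
    ~1%, disturbance severities of −0.004…−0.015 RD/yr, a small positive
    undisturbed drift (stands grow toward maximum density between
    disturbances), and plot-level FSI noise of 0.005/yr.
    """

    seed: int
    n_plots: int = 2000
    n_forest_types: int = 3
    true_frontier: list[tuple[float, float]] = field(default_factory=_default_frontier)
    exceedance: float = 0.01
    rd_log_sd: float = 0.35  # spread of log relative density across stands
    species_pool: tuple[int, ...] = DEFAULT_SPECIES
    mixing_weights: list[list[float]] = field(default_factory=_default_mixing)
    species_ranges: dict[int, tuple[str, ...]] | None = None  # subsection labels
    delta_t_mean: float = 9.78
    delta_t_sd: float = 1.0
    study_window: tuple[int, int] = (2001, 2018)
    panel_years: tuple[int, ...] = tuple(range(2011, 2019))
    disturbance_probs: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            sp: {"fire": 0.010, "insect": 0.015, "disease": 0.008}
            for sp in DEFAULT_SPECIES
        }
    )
    disturbance_severities: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            sp: {"fire": -0.015, "insect": -0.010, "disease": -0.004}
            for sp in DEFAULT_SPECIES
        }
    )
    # RD / yr on undisturbed plots; a dict gives per-species drifts
    baseline_drift: float | dict[int, float] = 0.002
    noise_sd: float = 0.005  # plot-level FSI noise ς
    diameter_growth_rate: float = 0.0  # relative DBH growth / yr
    mean_tree_ba_log_mean: float = math.log(0.02)
    mean_tree_ba_log_sd: float = 0.5
    trees_per_plot_mean: float = 22.0
    skewed_fraction: float = 0.0
    normal_log_sd: float = 0.2  # lognormal DBH spread, |g1| well inside [-1, 1]
    skewed_log_sd: float = 0.9  # heavy right tail, g1 > 1
    treated_fraction: float = 0.0
    n_strata: int = 4
    stratum_weights: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    n_subsections: int = 10
    n_divisions: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.exceedance < 1):
            raise ConfigError("exceedance must lie in (0, 1)")
        if len(self.true_frontier) != self.n_forest_types:
            raise ConfigError("one (a, r) pair per forest type is required")
        for a, r in self.true_frontier:
            if a <= 0 or r >= 0:
                raise ConfigError("frontier needs a > 0 and r < 0")
        for sp in self.species_pool:
            for l, p in self.disturbance_probs.get(sp, {}).items():
                if not (0 <= p <= 1):
                    raise ConfigError(f"psi[{sp}][{l}] must lie in [0, 1]")
        if len(self.mixing_weights) != self.n_forest_types:
            raise ConfigError("one mixing-weight row per forest type is required")
        if abs(sum(self.stratum_weights) - 1.0) > 1e-9:
            raise ConfigError("stratum weights must sum to 1")
        if self.noise_sd < 0 or self.delta_t_sd < 0:
            raise ConfigError("scale parameters must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "LandscapeConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "true_frontier" in raw:
            raw["true_frontier"] = [tuple(p) for p in raw["true_frontier"]]
        for key in ("disturbance_probs", "disturbance_severities"):
            if key in raw:
                raw[key] = {int(k): dict(v) for k, v in raw[key].items()}
        for key in ("species_pool", "stratum_weights", "panel_years", "study_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Everything the generator knows: parameters and realised plot states."""

    config: LandscapeConfig
    frontier: list[tuple[float, float]]
    psi: dict[int, dict[str, float]]
    beta: dict[int, dict[str, float]]
    drift: float
    noise_sd: float
    stratum_weights: dict[str, float]
    species_ranges: dict[int, tuple[str, ...]]
    plot_table: pd.DataFrame  # per plot: type, flags, event counts, exceedance
    population_table: pd.DataFrame  # per plot × species: rd_t1, rd_t2, realised fsi

    def true_mean_fsi(self, species: int) -> float:
        sub = self.population_table[self.population_table["species"] == species]
        return float(sub["fsi"].mean())

    def to_json(self, path) -> None:
        payload = {
            "config": _config_dict(self.config),
            "frontier": self.frontier,
            "psi": {str(k): v for k, v in self.psi.items()},
            "beta": {str(k): v for k, v in self.beta.items()},
            "drift": self.drift,
            "noise_sd": self.noise_sd,
            "stratum_weights": self.stratum_weights,
            "species_ranges": {str(k): list(v) for k, v in self.species_ranges.items()},
            "plot_table": self.plot_table.to_dict(orient="list"),
            "population_table": self.population_table.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _config_dict(config: LandscapeConfig) -> dict:
    d = dataclasses.asdict(config)
    d["disturbance_probs"] = {str(k): v for k, v in d["disturbance_probs"].items()}
    d["disturbance_severities"] = {
        str(k): v for k, v in d["disturbance_severities"].items()
    }
    if d.get("species_ranges"):
        d["species_ranges"] = {str(k): list(v) for k, v in d["species_ranges"].items()}
    return d


def simulate_self_thinning_track(
    a: float, r: float, start_s: float, end_s: float, steps: int
) -> list[tuple[float, float]]:
    """Points (S̄, TPH) exactly on N = a·S̄^r at geometrically spaced sizes.

    A stand moving along such a track thins as it grows while its relative
    density stays exactly 1: its stability index is zero by construction.
    """
    if a <= 0:
        raise ConfigError("a must be > 0")
    if r >= 0:
        raise ConfigError("r must be < 0")
    if not (0 < start_s < end_s):
        raise ConfigError("need 0 < start_s < end_s")
    s = np.geomspace(start_s, end_s, steps)
    return [(float(si), float(a * si**r)) for si in s]


def _draw_diameters(rng, m: int, target_mean_ba: float, log_sd: float) -> np.ndarray:
    """m DBHs (cm) with sample mean basal area exactly ``target_mean_ba``."""
    dbh = rng.lognormal(mean=math.log(15.0), sigma=log_sd, size=m)
    for _ in range(6):
        scale = math.sqrt(target_mean_ba / (math.pi * np.mean(dbh**2) / 40000.0))
        dbh = dbh * scale
        low = dbh < MIN_DBH_CM + 0.1
        if not low.any():
            break
        dbh[low] = MIN_DBH_CM + 0.1
    return dbh


def _tree_rd(dbh: np.ndarray, df: np.ndarray, a: float, r: float) -> np.ndarray:
    """Per-tree relative density contributions under the true frontier."""
    ba = math.pi * dbh**2 / 40000.0
    return df / (a * ba**r)


def generate_landscape(
    config: LandscapeConfig,
) -> tuple[list[PlotCensus], GroundTruth]:
    """Generate paired censuses plus the generating truth.

    Identical config and seed give identical output; every plot uses its own
    seeded substream so subsetting plots does not reshuffle the rest.
    """
    z = float(stats.norm.ppf(1 - config.exceedance))
    subsections = [f"S{i:02d}" for i in range(config.n_subsections)]
    div_of = {
        s: f"D{(i * config.n_divisions) // config.n_subsections}"
        for i, s in enumerate(subsections)
    }
    strata = {f"ST{i}": w for i, w in enumerate(config.stratum_weights)}
    stratum_ids = list(strata)
    stratum_p = np.array(config.stratum_weights)
    species = list(config.species_pool)
    ranges = config.species_ranges or {sp: tuple(subsections) for sp in species}
    lo_year, hi_year = config.study_window

    censuses: list[PlotCensus] = []
    plot_rows, pop_rows = [], []
    for i in range(config.n_plots):
        rng = np.random.default_rng([config.seed, i])
        ft = int(rng.integers(config.n_forest_types))
        a, r = config.true_frontier[ft]
        stratum = stratum_ids[int(rng.choice(len(stratum_ids), p=stratum_p))]
        subsection = subsections[int(rng.integers(config.n_subsections))]
        division = div_of[subsection]
        site_class = int(rng.integers(1, 8))

        t2_year = int(rng.choice(config.panel_years))
        dt = int(np.clip(np.rint(rng.normal(config.delta_t_mean, config.delta_t_sd)),
                         5, t2_year - lo_year))
        t1_year = t2_year - dt

        s_bar = float(rng.lognormal(config.mean_tree_ba_log_mean,
                                    config.mean_tree_ba_log_sd))
        rd_agg = float(np.exp(rng.normal(-z * config.rd_log_sd, config.rd_log_sd)))
        tph = rd_agg * a * s_bar**r

        skewed = bool(rng.random() < config.skewed_fraction)
        log_sd = config.skewed_log_sd if skewed else config.normal_log_sd
        m = int(rng.poisson(config.trees_per_plot_mean)) + 3
        dbh1 = _draw_diameters(rng, m, s_bar, log_sd)
        df1 = np.full(m, tph / m)

        allowed = [sp for sp in species if subsection in ranges.get(sp, ())]
        if not allowed:
            allowed = species
        w = np.array([config.mixing_weights[ft][species.index(sp)] for sp in allowed])
        w = w / w.sum()
        sp_of_tree = rng.choice(allowed, size=m, p=w)

        rd1_tree = _tree_rd(dbh1, df1, a, r)
        rd1 = {sp: float(rd1_tree[sp_of_tree == sp].sum()) for sp in allowed}
        dominant = max(rd1, key=rd1.get)

        flags, events = {}, {}
        for l in DISTURBANCE_TYPES:
            psi = config.disturbance_probs.get(dominant, {}).get(l, 0.0)
            k = int(rng.binomial(dt, psi)) if psi > 0 else 0
            events[l] = k
            flags[l] = int(k > 0)

        treated = bool(rng.random() < config.treated_fraction)
        trt_year = int(t1_year - rng.integers(0, 6)) if treated else None

        growth = (1.0 + config.diameter_growth_rate) ** dt
        dbh2 = dbh1 * growth
        scale_by_sp = {}
        for sp in allowed:
            if rd1[sp] <= 0:
                continue
            drift = (config.baseline_drift.get(sp, 0.0)
                     if isinstance(config.baseline_drift, dict)
                     else config.baseline_drift)
            fsi_sp = drift + sum(
                config.disturbance_severities.get(sp, {}).get(l, 0.0) * flags[l]
                for l in DISTURBANCE_TYPES
            )
            if config.noise_sd > 0:
                fsi_sp += float(rng.normal(0.0, config.noise_sd))
            rd2 = max(rd1[sp] + dt * fsi_sp, 0.0)
            mask = sp_of_tree == sp
            rd2_raw = float(_tree_rd(dbh2[mask], df1[mask], a, r).sum())
            scale_by_sp[sp] = rd2 / rd2_raw if rd2_raw > 0 else 0.0
            pop_rows.append({
                "plot_id": f"P{i:05d}_2", "species": int(sp),
                "rd_t1": rd1[sp], "rd_t2": rd2, "delta_t": float(dt),
                "fsi": (rd2 - rd1[sp]) / dt,
            })

        trees1 = [
            TreeRecord(tree_id=f"T{i:05d}_{h}", species_code=int(sp_of_tree[h]),
                       dbh=float(dbh1[h]), status="live", density_factor=float(df1[h]))
            for h in range(m)
        ]
        df2 = df1 * np.array([scale_by_sp.get(sp, 0.0) for sp in sp_of_tree])
        trees2 = [
            TreeRecord(tree_id=f"T{i:05d}_{h}", species_code=int(sp_of_tree[h]),
                       dbh=float(dbh2[h]), status="live", density_factor=float(df2[h]))
            for h in range(m) if df2[h] > 0
        ]

        common = dict(
            forest_type=ft, site_productivity_class=site_class,
            ecoregion_division=division, ecoregion_subsection=subsection,
            stratum_id=stratum,
        )
        t1 = PlotCensus(plot_id=f"P{i:05d}_1", census_year=t1_year,
                        trees=trees1, **common)
        t2 = PlotCensus(
            plot_id=f"P{i:05d}_2", census_year=t2_year,
            prev_plot_id=t1.plot_id, previous_census=t1, delta_t=float(dt),
            disturbance_flags=dict(flags),
            treatment_flag=int(treated), treatment_year=trt_year,
            trees=trees2, **common,
        )
        censuses.extend([t1, t2])
        plot_rows.append({
            "plot_id": t2.plot_id, "forest_type": ft, "stratum_id": stratum,
            "subsection": subsection, "division": division,
            "delta_t": dt, "panel_year": t2_year, "skewed": skewed,
            "treated": treated, "dominant_species": int(dominant),
            "rd_aggregate_t1": rd_agg, "above_frontier": rd_agg > 1.0,
            **{f"{l}_flag": flags[l] for l in DISTURBANCE_TYPES},
            **{f"{l}_events": events[l] for l in DISTURBANCE_TYPES},
        })

    truth = GroundTruth(
        config=config,
        frontier=list(config.true_frontier),
        psi={sp: dict(config.disturbance_probs.get(sp, {})) for sp in species},
        beta={sp: dict(config.disturbance_severities.get(sp, {})) for sp in species},
        drift=config.baseline_drift,
        noise_sd=config.noise_sd,
        stratum_weights=strata,
        species_ranges={sp: tuple(ranges[sp]) for sp in species},
        plot_table=pd.DataFrame(plot_rows),
        population_table=pd.DataFrame(pop_rows),
    )
    return censuses, truth
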