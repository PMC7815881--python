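"""Post-stratified, annual-panel moving-average estimation of FSI change.

Plot-level FSI records are averaged with known stratum area weights
(post-stratification), separately within each annual remeasurement panel,
and panels are then combined with equal weight (the simple moving-average
estimator). Populations are classified from the 95% confidence interval of
the range-averaged mean FSI: stable if it covers zero, expanding if it lies
entirely above, declining if entirely below.

%FSI is a ratio of two correlated means (mean FSI over mean baseline RD);
its variance uses the first-order delta method with plot-level covariance
carried through both estimation stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

Z95 = 1.959963984540054


@dataclass
class StratificationScheme:
    """Stratum area weights W_s (summing to 1) and plot counts."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"stratum weights must sum to 1, got {total}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("stratum weights must be positive")

    @classmethod
    def single(cls) -> "StratificationScheme":
        return cls(weights={"__all__": 1.0})


@dataclass
class PopulationEstimate:
    """Mean FSI of one population group with uncertainty and classification."""

    group: dict
    mean_fsi: float
    variance: float
    ci95: tuple[float, float]
    mean_rd_t1: float
    percent_fsi: float | None
    percent_fsi_se: float | None
    classification: str  # expanding | declining | stable
    n_plots: int
    panels_used: int
    flags: list[str] = field(default_factory=list)


def classify(ci95: tuple[float, float]) -> str:
    lo, hi = ci95
    if hi < 0:
        return "declining"
    if lo > 0:
        return "expanding"
    return "stable"


def _collapse_singletons(
    df: pd.DataFrame, scheme: StratificationScheme
) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """Merge strata observed with a single plot into the heaviest other stratum.

    The sample variance is undefined at n_s = 1; inventory practice collapses
    such strata before variance estimation. Weights of merged strata are
    pooled. Strata in the scheme with no plots at all simply drop out (their
    weight is re-normalised away), flagged.
    """
    counts = df.groupby("stratum_id")["plot_id"].nunique()
    unknown = set(counts.index) - set(scheme.weights)
    if unknown:
        raise ValueError(f"plots reference unknown strata: {sorted(unknown)}")
    flags: list[str] = []
    weights = {s: w for s, w in scheme.weights.items() if counts.get(s, 0) > 0}
    missing = set(scheme.weights) - set(weights)
    if missing:
        flags.append(f"empty strata dropped: {sorted(missing)}")
    singles = [s for s in weights if counts[s] == 1]
    if singles and len(weights) > len(singles):
        hosts = {s: w for s, w in weights.items() if s not in singles}
        host = max(hosts, key=hosts.get)
        df = df.copy()
        df.loc[df["stratum_id"].isin(singles), "stratum_id"] = host
        for s in singles:
            weights[host] = weights[host] + weights.pop(s)
        flags.append(f"singleton strata collapsed into {host}: {sorted(singles)}")
    elif singles:
        flags.append("all strata are singletons; variance undefined")
    total = sum(weights.values())
    weights = {s: w / total for s, w in weights.items()}
    return df, weights, flags


def poststratified_estimate(
    records: pd.DataFrame,
    scheme: StratificationScheme,
    value_col: str = "fsi",
    aux_col: str | None = None,
) -> dict:
    """Post-stratified mean and variance of a plot-level variable.

    mean = Σ_s W_s ȳ_s, variance = Σ_s W_s² s_s²/n_s. With ``aux_col`` the
    same estimator is applied to the auxiliary variable and the plot-level
    covariance between the two is carried (Σ_s W_s² s_{xy,s}/n_s), as needed
    for the delta-method %FSI variance. One observation per plot is required.
    """
    if records.empty:
        raise ValueError("no records to estimate from")
    df, weights, flags = _collapse_singletons(records, scheme)
    out = {"mean": 0.0, "variance": 0.0, "n_plots": int(df["plot_id"].nunique()),
           "flags": flags}
    if aux_col:
        out["aux_mean"] = 0.0
        out["aux_variance"] = 0.0
        out["covariance"] = 0.0
    for s, w in weights.items():
        sub = df[df["stratum_id"] == s]
        y = sub[value_col].to_numpy(dtype=float)
        n = y.size
        out["mean"] += w * y.mean()
        if n > 1:
            out["variance"] += w**2 * y.var(ddof=1) / n
        if aux_col:
            xv = sub[aux_col].to_numpy(dtype=float)
            out["aux_mean"] += w * xv.mean()
            if n > 1:
                out["aux_variance"] += w**2 * xv.var(ddof=1) / n
                cov = float(np.cov(y, xv, ddof=1)[0, 1])
                out["covariance"] += w**2 * cov / n
    return out


def moving_average_panels(panel_estimates: Sequence[Mapping]) -> dict:
    """Combine annual panel estimates with equal weight.

    mean = (1/P) Σ_p mean_p; variance = (1/P²) Σ_p var_p (panels are
    independent plot subsets). Auxiliary means/covariances combine the same
    way when present.
    """
    P = len(panel_estimates)
    if P == 0:
        raise ValueError("at least one panel is required")
    keys = ["mean", "variance"]
    if all("aux_mean" in p for p in panel_estimates):
        keys += ["aux_mean", "aux_variance", "covariance"]
    out = {}
    for k in keys:
        vals = [p[k] for p in panel_estimates]
        out[k] = sum(vals) / P if k in ("mean", "aux_mean") else sum(vals) / P**2
    out["n_plots"] = int(sum(p.get("n_plots", 0) for p in panel_estimates))
    out["panels_used"] = P
    out["flags"] = [f for p in panel_estimates for f in p.get("flags", [])]
    return out


def define_range(records: pd.DataFrame) -> dict[int, set[str]]:
    """Species range = areal subsections with at least one detection.

    Detection means positive relative density at either census on any plot
    in the subsection.
    """
    present = records[(records["rd_t1"] > 0) | (records["rd_t2"] > 0)]
    out: dict[int, set[str]] = {}
    for sp, sub in present.groupby("species"):
        out[int(sp)] = set(sub["ecoregion_subsection"].astype(str))
    return out


def _delta_method_percent(est: Mapping) -> tuple[float | None, float | None]:
    """%FSI point value and SE from a combined mean/variance/covariance dict."""
    x = est.get("aux_mean", 0.0)
    if x is None or x <= 0:
        return None, None
    ratio = est["mean"] / x
    var = (est["variance"] + ratio**2 * est["aux_variance"]
           - 2 * ratio * est["covariance"]) / x**2
    return 100.0 * ratio, 100.0 * math.sqrt(max(var, 0.0))


def grouped_estimates(
    records: pd.DataFrame,
    scheme: StratificationScheme,
    groupers: Sequence[str] = ("species",),
    *,
    restrict_to_range: bool = True,
) -> list[PopulationEstimate]:
    """One PopulationEstimate per group (species × optional size class/areal unit).

    Valid groupers: ``species``, ``size_class``, ``ecoregion_division``,
    ``ecoregion_subsection``. Estimates are computed per annual panel
    (remeasurement year) and combined by the moving-average estimator.
    Species-level estimates are restricted to plots inside the species range
    (subsections with a detection); a species never detected raises.
    Groups with zero plots are omitted. Deterministic ordering by group key.
    """
    valid = {"species", "size_class", "ecoregion_division", "ecoregion_subsection"}
    bad = set(groupers) - valid
    if bad:
        raise ValueError(f"unknown groupers: {sorted(bad)}")
    if "species" not in groupers:
        raise ValueError("groupers must include 'species'")
    ranges = define_range(records) if restrict_to_range else None
    estimates: list[PopulationEstimate] = []
    for key, sub in sorted(records.groupby(list(groupers)), key=lambda kv: kv[0]):
        key = key if isinstance(key, tuple) else (key,)
        group = dict(zip(groupers, (k.item() if hasattr(k, "item") else k for k in key)))
        sp = int(group["species"])
        if ranges is not None:
            if sp not in ranges:
                raise ValueError(f"species {sp} was never detected; no range")
            sub = sub[sub["ecoregion_subsection"].astype(str).isin(ranges[sp])]
        if sub.empty:
            continue
        panels = []
        for _, psub in sorted(sub.groupby("panel_year")):
            panels.append(
                poststratified_estimate(psub, scheme, "fsi", aux_col="rd_t1")
            )
        combined = moving_average_panels(panels)
        mean, var = combined["mean"], combined["variance"]
        half = Z95 * math.sqrt(var)
        ci = (mean - half, mean + half)
        pfsi, pfsi_se = _delta_method_percent(combined)
        estimates.append(PopulationEstimate(
            group=group,
            mean_fsi=mean,
            variance=var,
            ci95=ci,
            mean_rd_t1=combined.get("aux_mean", float("nan")),
            percent_fsi=pfsi,
            percent_fsi_se=pfsi_se,
            classification=classify(ci),
            n_plots=combined["n_plots"],
            panels_used=combined["panels_used"],
            flags=combined["flags"],
        ))
    return estimates


def estimates_table(estimates: Sequence[PopulationEstimate]) -> pd.DataFrame:
    """Flatten PopulationEstimates to a DataFrame with fixed columns."""
    rows = []
    for e in estimates:
        row = dict(e.group)
        row.update({
            "mean_fsi": e.mean_fsi,
            "variance": e.variance,
            "ci95_lo": e.ci95[0],
            "ci95_hi": e.ci95[1],
            "mean_rd_t1": e.mean_rd_t1,
            "percent_fsi": e.percent_fsi,
            "percent_fsi_se": e.percent_fsi_se,
            "classification": e.classification,
            "n_plots": e.n_plots,
            "panels_used": e.panels_used,
        })
        rows.append(row)
    return pd.DataFrame(rows)
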