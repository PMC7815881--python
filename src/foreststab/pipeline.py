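"""End-to-end orchestration: data → filters → frontier → FSI → estimates → attribution.

A single :class:`RunConfig` (YAML-loadable) drives the whole chain and a
run manifest records seeds, per-stage record counts, and content hashes of
every artifact, so an identical config and seed reproduce byte-identical
deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .attribution import (AttributionSettings, build_observations,
                          fit_probability, fit_severity, standardized_effect)
from .estimation import StratificationScheme, estimates_table, grouped_estimates
from .frontier import FrontierSettings, fit_frontier
from .inventory import (Dialect, filter_change_analysis,
                        filter_frontier_training, read_inventory, stand_table,
                        write_inventory)
from .stability import change_records
from .synth import LandscapeConfig, generate_landscape

log = logging.getLogger("foreststab")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``synth`` (landscape generator parameters; its seed is derived
    from the run seed) or ``plot_csv``/``tree_csv`` input paths must be
    given. ``stratum_weights`` is required for real inputs; synthetic runs
    take it from the generator truth.
    """

    seed: int
    out_dir: str
    synth: dict | None = None
    plot_csv: str | None = None
    tree_csv: str | None = None
    dialect_yaml: str | None = None
    stratum_weights: dict[str, float] | None = None
    groupers: tuple[str, ...] = ("species",)
    by_size_class: bool = False
    frontier: dict = field(default_factory=dict)
    attribution: dict = field(default_factory=dict)
    run_attribution: bool = True

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.plot_csv is None):
            raise ValueError("exactly one of synth config or input paths is required")
        if self.plot_csv is not None:
            for p in (self.plot_csv, self.tree_csv):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
            if self.stratum_weights is None:
                raise ValueError("stratum_weights are required for CSV inputs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "groupers" in raw:
            raw["groupers"] = tuple(raw["groupers"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the run manifest (also written to
    ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }

    # --- stage: data -------------------------------------------------------
    truth = None
    if config.synth is not None:
        synth_cfg = LandscapeConfig(**{"seed": config.seed, **config.synth})
        censuses, truth = generate_landscape(synth_cfg)
        scheme = StratificationScheme(weights=truth.stratum_weights)
        write_inventory(censuses, out / "plots.csv", out / "trees.csv")
        truth.to_json(out / "ground_truth.json")
    else:
        dialect = (Dialect.from_yaml(config.dialect_yaml)
                   if config.dialect_yaml else Dialect())
        censuses = read_inventory(config.plot_csv, config.tree_csv, dialect)
        scheme = StratificationScheme(weights=dict(config.stratum_weights))
    manifest["stages"]["data"] = {"censuses": len(censuses)}
    log.info("data: %d censuses", len(censuses))

    # --- stage: filters ----------------------------------------------------
    training, train_excl = filter_frontier_training(censuses)
    pairs, pair_excl = filter_change_analysis(censuses)
    manifest["stages"]["filters"] = {
        "frontier_training_kept": len(training),
        "frontier_training_excluded": _reason_counts(train_excl),
        "change_pairs_kept": len(pairs),
        "change_pairs_excluded": _reason_counts(pair_excl),
    }
    if not training:
        raise StageError("filters", "no stands eligible for frontier training")
    if not pairs:
        raise StageError("filters", "no paired censuses for change analysis")

    # --- stage: frontier ---------------------------------------------------
    settings = FrontierSettings(**{"seed": config.seed + 1, **config.frontier})
    stands = stand_table(training)
    try:
        model = fit_frontier(stands, settings)
    except Exception as exc:  # surface stage context
        raise StageError("frontier", str(exc)) from exc
    model.summary().to_csv(out / "frontier.csv", index=False)
    manifest["stages"]["frontier"] = {
        "training_stands": len(stands),
        "types": model.types,
        "converged": model.converged,
        "warnings": model.warnings,
    }

    # --- stage: stability --------------------------------------------------
    records = change_records(pairs, model, by_size_class=config.by_size_class)
    records.to_csv(out / "records.csv", index=False)
    manifest["stages"]["stability"] = {"records": len(records)}

    # --- stage: estimation -------------------------------------------------
    whole = records[records["size_class"] == 0] if config.by_size_class else records
    estimates = grouped_estimates(whole, scheme, config.groupers)
    est_df = estimates_table(estimates)
    est_df.to_csv(out / "estimates.csv", index=False)
    manifest["stages"]["estimation"] = {
        "groups": len(estimates),
        "classifications": est_df["classification"].value_counts().to_dict(),
    }

    # --- stage: attribution ------------------------------------------------
    if config.run_attribution:
        att = AttributionSettings(**{"seed": config.seed + 2, **config.attribution})
        obs = build_observations(records)
        try:
            severity = fit_severity(obs, att)
            probability = fit_probability(obs, att)
        except Exception as exc:
            raise StageError("attribution", str(exc)) from exc
        mean_rd = obs.groupby("species")["rd_t1"].mean().to_dict()
        effects = standardized_effect(severity, probability, mean_rd)
        effects.summary().to_csv(out / "disturbance_effects.csv", index=False)
        manifest["stages"]["attribution"] = {
            "observations": len(obs),
            "species": severity.species,
            "flags": {str(k): v for k, v in severity.flags.items() if v},
        }

    for p in sorted(out.glob("*.csv")):
        manifest["artifacts"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _reason_counts(excl: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for reason in excl.values():
        counts[reason] = counts.get(reason, 0) + 1
    return counts
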