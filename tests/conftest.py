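import math

import numpy as np
import pytest

from foreststab import LandscapeConfig, SizeDensityModel, TreeRecord

NO_DISTURBANCE = {sp: {"fire": 0.0, "insect": 0.0, "disease": 0.0}
                  for sp in (202, 108, 93)}


def quiet_config(seed: int, n_plots: int, **overrides) -> LandscapeConfig:
    """A landscape with no change mechanism: no disturbance, drift, or noise."""
    base = dict(
        seed=seed,
        n_plots=n_plots,
        disturbance_probs={sp: dict(v) for sp, v in NO_DISTURBANCE.items()},
        disturbance_severities={sp: dict(v) for sp, v in NO_DISTURBANCE.items()},
        baseline_drift=0.0,
        noise_sd=0.0,
        skewed_fraction=0.0,
        treated_fraction=0.0,
    )
    base.update(overrides)
    return LandscapeConfig(**base)


@pytest.fixture
def identity_model() -> SizeDensityModel:
    """Frontier with a=1000, r=-1: N_max(1 m²) = 1000 stems/ha."""
    return SizeDensityModel.from_parameters(1000.0, -1.0)


def make_tree(dbh: float, density: float, species: int = 202,
              status: str = "live", tree_id: str = "t") -> TreeRecord:
    return TreeRecord(tree_id=tree_id, species_code=species, dbh=dbh,
                      status=status, density_factor=density)


def dbh_for_ba(ba_m2: float) -> float:
    """Diameter (cm) whose stem basal area is ``ba_m2``."""
    return math.sqrt(40000.0 * ba_m2 / math.pi)


def random_stand(rng: np.random.Generator, n: int = 12,
                 species: int = 202) -> list[TreeRecord]:
    dbhs = rng.lognormal(math.log(18.0), 0.5, n)
    dens = rng.uniform(5.0, 60.0, n)
    return [make_tree(float(d), float(w), species, tree_id=f"t{i}")
            for i, (d, w) in enumerate(zip(dbhs, dens))]
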