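"""Synthetic spoor-survey generator.

Spoor encounters are simulated as a Poisson process along each transect
pass: for species *s* with true density ``D`` (animals/100 km2) on a pass
of length ``L`` km, the number of genuine spoor is Poisson with mean

    (slope_s * D + intercept_s) * L / 100

so that expected spoor density (spoor/100 km) equals ``slope_s * D +
intercept_s`` — exactly the linear relation the calibration stage inverts.
Positions are uniform on the pass. Optional contamination spawns old
(>24 h) or duplicate records for the filtering stage to remove; an
optional negative-binomial switch adds overdispersion.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .calibration import CalibrationModel, default_model
from .survey_data import (
    ConfigError,
    SpoorRecord,
    Stratum,
    SurveyDataset,
    Transect,
)

_BASE_DATE = dt.date(2008, 10, 1)


@dataclass(frozen=True)
class TransectPlan:
    """One planned transect: where it is, how long, how often driven."""

    lut: str
    length_km: float
    passes: int = 1
    transect_id: str | None = None


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic survey.

    ``true_density`` maps (species, lut) to animals/100 km2; pairs not
    listed default to zero. ``group_size_dist`` maps species to a
    categorical distribution over positive integers (default: always 1).
    ``contamination`` is the probability that a genuine record spawns one
    extra contaminant (old or duplicate) record. ``dispersion`` switches
    the count law to negative binomial with that shape parameter
    (Poisson when ``None``).
    """

    true_density: Mapping[tuple[str, str], float]
    transect_plan: Sequence[TransectPlan]
    areas: Mapping[str, float]
    calibration: CalibrationModel = field(default_factory=default_model)
    group_size_dist: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    contamination: float = 0.0
    dispersion: float | None = None
    seed: int = 0

    def validated(self) -> "SimulationConfig":
        for key, d in self.true_density.items():
            if d < 0:
                raise ConfigError(f"negative true density for {key}: {d}")
        if not (0.0 <= self.contamination < 1.0):
            raise ConfigError(f"contamination must be in [0, 1), got {self.contamination}")
        for sp, dist in self.group_size_dist.items():
            if any(k < 1 for k in dist):
                raise ConfigError(f"group sizes must be >= 1 for {sp}")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"group-size probabilities for {sp} must sum to 1")
        for plan in self.transect_plan:
            if plan.length_km <= 0 or plan.passes < 1:
                raise ConfigError(f"bad transect plan entry {plan}")
            if plan.lut not in self.areas:
                raise ConfigError(f"transect plan lut {plan.lut!r} has no area")
        return self


def _expected_count(config: SimulationConfig, species: str, lut: str, length_km: float) -> float:
    density = config.true_density.get((species, lut), 0.0)
    mean = (
        config.calibration.slope(species) * density + config.calibration.intercept(species)
    ) * length_km / 100.0
    if mean < 0:
        raise ConfigError(
            f"negative expected spoor count for {species}/{lut} "
            f"(pathological intercept {config.calibration.intercept(species)})"
        )
    return mean


def simulate_survey(config: SimulationConfig, seed: int | None = None) -> SurveyDataset:
    """Generate one survey; bitwise-reproducible for a fixed seed.

    Contaminant records carry ``age_hours`` > 24 or ``duplicate_of`` set,
    so :func:`~spoorstats.spoor_metrics.filter_spoor` recovers exactly the
    genuine records.
    """
    config.validated()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    species_list = sorted({sp for sp, _lut in config.true_density})
    transects: list[Transect] = []
    for i, plan in enumerate(config.transect_plan):
        tid = plan.transect_id or f"T{i + 1:03d}"
        transects.append(Transect(tid, plan.lut, plan.length_km, plan.passes))
    luts_used = {t.lut for t in transects}
    strata = [Stratum(lut, config.areas[lut]) for lut in config.areas if lut in luts_used or True]

    records: list[SpoorRecord] = []
    counter = 0
    for transect in transects:
        for p in range(transect.passes):
            day = _BASE_DATE + dt.timedelta(days=p)
            for species in species_list:
                mean = _expected_count(config, species, transect.lut, transect.length_km)
                if mean == 0.0:
                    continue
                if config.dispersion is None:
                    n = int(rng.poisson(mean))
                else:
                    k = config.dispersion
                    n = int(rng.negative_binomial(k, k / (k + mean)))
                if n == 0:
                    continue
                positions = np.sort(rng.uniform(0.0, transect.length_km, size=n))
                sizes = _draw_group_sizes(rng, config, species, n)
                for pos, gs in zip(positions, sizes):
                    counter += 1
                    rid = f"r{counter:06d}"
                    records.append(
                        SpoorRecord(
                            species=species,
                            transect_id=transect.transect_id,
                            position_km=float(pos),
                            group_size=int(gs),
                            recorded_on=day,
                            lut=transect.lut,
                            age_hours=float(rng.uniform(0.0, 24.0)),
                            record_id=rid,
                        )
                    )
                    if config.contamination > 0 and rng.random() < config.contamination:
                        counter += 1
                        records.append(
                            _contaminant(rng, records[-1], f"r{counter:06d}", transect.length_km)
                        )
    return SurveyDataset(records=records, transects=transects, strata=strata)


def _draw_group_sizes(rng, config: SimulationConfig, species: str, n: int) -> np.ndarray:
    dist = config.group_size_dist.get(species)
    if not dist:
        return np.ones(n, dtype=int)
    sizes = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[int(s)] for s in sizes], dtype=float)
    return rng.choice(sizes, size=n, p=probs)


def _contaminant(rng, parent: SpoorRecord, rid: str, length_km: float) -> SpoorRecord:
    """An old-spoor or same-individual repeat record derived from a genuine one."""
    if rng.random() < 0.5:
        return SpoorRecord(
            species=parent.species,
            transect_id=parent.transect_id,
            position_km=float(rng.uniform(0.0, length_km)),
            group_size=parent.group_size,
            recorded_on=parent.recorded_on,
            lut=parent.lut,
            age_hours=float(24.0 + rng.exponential(24.0)),
            record_id=rid,
        )
    return SpoorRecord(
        species=parent.species,
        transect_id=parent.transect_id,
        position_km=float(min(length_km, parent.position_km + rng.exponential(0.5))),
        group_size=parent.group_size,
        recorded_on=parent.recorded_on,
        lut=parent.lut,
        age_hours=parent.age_hours,
        duplicate_of=parent.record_id,
        record_id=rid,
    )


# ---------------------------------------------------------------------------
# the packaged worked-example scenario
# ---------------------------------------------------------------------------

#: Point population densities (animals/100 km2) of the 2008 worked example,
#: used as simulation truth. Pairs not listed are zero (communal is empty).
SVC_TRUE_DENSITY: Mapping[tuple[str, str], float] = {
    ("lion", "private"): 2.85,
    ("leopard", "private"): 7.64,
    ("cheetah", "private"): 0.44,
    ("wild_dog", "private"): 5.65,
    ("spotted_hyaena", "private"): 4.51,
    ("brown_hyaena", "private"): 0.53,
    ("spotted_hyaena", "resettlement"): 0.61,
    ("lion", "communal"): 0.0,
}


def make_svc_scenario(n_private_transects: int = 20, seed: int = 2008) -> SimulationConfig:
    """Scenario matching the worked example's truth and effort.

    Effort: 348 km of private transects driven twice (696 km total, the
    published surveyed figure), 149 km resettlement and 110 km communal
    driven once. The private kilometres are split across
    ``n_private_transects`` equal transects so the transect bootstrap has
    resampling units to work with; the split does not change any expected
    count.
    """
    plan = [
        TransectPlan("private", 348.0 / n_private_transects, 2, f"P{i + 1:02d}")
        for i in range(n_private_transects)
    ]
    plan += [TransectPlan("resettlement", 149.0, 1, "R01"), TransectPlan("communal", 110.0, 1, "C01")]
    return SimulationConfig(
        true_density=dict(SVC_TRUE_DENSITY),
        transect_plan=plan,
        areas={"private": 2530.0, "resettlement": 960.0, "communal": 984.0},
        calibration=default_model(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML round trip for CLI use
# ---------------------------------------------------------------------------


def config_from_yaml(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    calibration = (
        CalibrationModel.from_mapping(raw["calibration"]) if "calibration" in raw else default_model()
    )
    true_density = {
        (sp, lut): float(v) for sp, by_lut in raw["true_density"].items() for lut, v in by_lut.items()
    }
    plan = [
        TransectPlan(p["lut"], float(p["length_km"]), int(p.get("passes", 1)), p.get("transect_id"))
        for p in raw["transect_plan"]
    ]
    group = {
        sp: {int(k): float(v) for k, v in dist.items()}
        for sp, dist in raw.get("group_size_dist", {}).items()
    }
    return SimulationConfig(
        true_density=true_density,
        transect_plan=plan,
        areas={k: float(v) for k, v in raw["areas"].items()},
        calibration=calibration,
        group_size_dist=group,
        contamination=float(raw.get("contamination", 0.0)),
        dispersion=raw.get("dispersion"),
        seed=int(raw.get("seed", 0)),
    ).validated()


def config_to_yaml(config: SimulationConfig, path: str | Path) -> Path:
    by_species: dict[str, dict[str, float]] = {}
    for (sp, lut), v in config.true_density.items():
        by_species.setdefault(sp, {})[lut] = float(v)
    raw = {
        "true_density": by_species,
        "transect_plan": [
            {"lut": p.lut, "length_km": p.length_km, "passes": p.passes, "transect_id": p.transect_id}
            for p in config.transect_plan
        ],
        "areas": dict(config.areas),
        "calibration": config.calibration.to_mapping(),
        "group_size_dist": {sp: dict(d) for sp, d in config.group_size_dist.items()},
        "contamination": config.contamination,
        "dispersion": config.dispersion,
        "seed": config.seed,
    }
    out = Path(path)
    out.write_text(yaml.safe_dump(raw, sort_keys=False))
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
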