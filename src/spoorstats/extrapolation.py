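"""National-scale land accounting and carnivore-decline scenarios.

A :class:`LandLedger` records per-category national land areas (million
ha) at two epochs, before and after the land-reform programme. The
decline model is deliberately simple and scenario-driven: a species loses
the fraction of its national population that sat on large-scale private
land, times the fraction of that land converted to resettlement, times
one minus the fraction surviving the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .survey_data import ConfigError

#: km2 per million hectares.
MILLION_HA_TO_KM2 = 10_000.0

LAND_CATEGORIES = (
    "large_scale_private",
    "small_scale_private",
    "old_resettlement",
    "new_resettlement",
    "communal",
    "parks_and_forest",
    "other",
)

EPOCHS = ("2000", "2010")


@dataclass(frozen=True)
class LandLedger:
    """Per-category national land areas (million ha) for the two epochs."""

    areas: Mapping[str, Mapping[str, float]]  # epoch -> category -> million ha
    national_total_mha: float = 39.1

    def validated(self) -> "LandLedger":
        for epoch in EPOCHS:
            if epoch not in self.areas:
                raise ConfigError(f"ledger missing epoch {epoch}")
            total = sum(self.areas[epoch].values())
            if abs(total - self.national_total_mha) > 0.05:
                raise ConfigError(
                    f"epoch {epoch} areas sum to {total}, expected {self.national_total_mha}"
                )
        return self

    def area(self, category: str, epoch: str) -> float:
        return self.areas[epoch][category]


def load_ledger(path: str | Path | None = None) -> LandLedger:
    """Load a land ledger from YAML; defaults to the packaged national table."""
    if path is None:
        text = resources.files("spoorstats").joinpath("data/table1.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    areas = {
        str(epoch): {cat: float(v) for cat, v in cats.items()}
        for epoch, cats in raw["areas"].items()
    }
    return LandLedger(areas=areas, national_total_mha=float(raw.get("total_mha", 39.1))).validated()


def land_shares(ledger: LandLedger, epoch: str) -> dict[str, float]:
    """Each category's percentage of the national total, at 1 dp."""
    total = sum(ledger.areas[epoch].values())
    return {cat: round(100.0 * a / total, 1) for cat, a in ledger.areas[epoch].items()}


def fraction_private_resettled(ledger: LandLedger) -> float:
    """Fraction of large-scale private land lost between the two epochs."""
    before = ledger.area("large_scale_private", "2000")
    after = ledger.area("large_scale_private", "2010")
    if before <= 0:
        raise ConfigError("pre-reform private area must be positive")
    return (before - after) / before


def area_share(part_km2: float, total_mha: float) -> float:
    """A reserve's km2 as a percentage of a national area in million ha, 1 dp."""
    if total_mha <= 0:
        raise ValueError("total area must be positive")
    return round(100.0 * part_km2 / (total_mha * MILLION_HA_TO_KM2), 1)


@dataclass(frozen=True)
class DeclineScenario:
    """Inputs to the proportional-loss decline model.

    ``share_private`` maps species to the fraction of its national
    population that was on large-scale private land pre-reform.
    ``fraction_resettled`` is the fraction of that land converted;
    ``retention`` the fraction of carnivores surviving on converted land.
    """

    share_private: Mapping[str, float]
    fraction_resettled: float
    retention: float = 0.0

    def validated(self) -> "DeclineScenario":
        for sp, v in self.share_private.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"share_private[{sp}] = {v} outside [0, 1]")
        for name, v in (("fraction_resettled", self.fraction_resettled), ("retention", self.retention)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        return self


@dataclass(frozen=True)
class DeclineResult:
    per_species: dict[str, float]  # percent decline
    mean: float
    max: float


def national_decline(scenario: DeclineScenario) -> DeclineResult:
    """Percent national decline per species, with mean and max across species.

    decline_s = 100 * share_private_s * fraction_resettled * (1 - retention)
    """
    scenario.validated()
    per = {
        sp: 100.0 * share * scenario.fraction_resettled * (1.0 - scenario.retention)
        for sp, share in scenario.share_private.items()
    }
    if not per:
        raise ConfigError("scenario lists no species")
    values = list(per.values())
    return DeclineResult(per_species=per, mean=sum(values) / len(values), max=max(values))


def scenario_from_yaml(path: str | Path) -> DeclineScenario:
    raw = yaml.safe_load(Path(path).read_text())
    return DeclineScenario(
        share_private={sp: float(v) for sp, v in raw["share_private"].items()},
        fraction_resettled=float(raw["fraction_resettled"]),
        retention=float(raw.get("retention", 0.0)),
    ).validated()
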