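"""Record filtering and descriptive survey statistics.

Spoor density is spoor per 100 km driven; spoor frequency is km driven per
spoor (their product is 100 whenever both are defined). Inter-spoor
intervals are gaps between consecutive spoor after concatenating transect
passes into one linear axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey_data import (
    LAND_USE_TYPES,
    SpoorRecord,
    SurveyDataset,
    SurveyReferenceError,
    InsufficientDataError,
)

#: A transect pass: (transect_id, 1-based pass index).
PassKey = tuple[str, int]


@dataclass(frozen=True)
class EffortSummary:
    """Survey effort for one land-use stratum.

    ``sample_penetration`` is stratum area (km2) per single-pass transect
    km — a coverage heuristic with a recommended value near 7. It is kept
    at full precision here; report it at 1 decimal.
    """

    lut: str
    area_km2: float
    transect_sum_km: float
    sample_penetration: float
    surveyed_km: float


def filter_spoor(records: list[SpoorRecord]) -> list[SpoorRecord]:
    """Drop records over 24 h old and records flagged as duplicates.

    Records with unknown age are kept. Order is otherwise preserved.
    """
    return [r for r in records if not r.is_old and not r.is_duplicate]


def spoor_density(n_spoor: int, surveyed_km: float) -> float:
    """Spoor per 100 km of transect driven."""
    if surveyed_km <= 0:
        raise ValueError(f"surveyed_km must be positive, got {surveyed_km}")
    return 100.0 * n_spoor / surveyed_km


def spoor_frequency(surveyed_km: float, n_spoor: int) -> float:
    """Kilometres of transect driven per spoor record.

    Raises
    ------
    InsufficientDataError
        when ``n_spoor`` is zero (frequency undefined; report "no spoor").
    """
    if n_spoor < 1:
        raise InsufficientDataError("spoor frequency undefined when no spoor were recorded")
    return surveyed_km / n_spoor


# ---------------------------------------------------------------------------
# transect passes and the combined linear axis
# ---------------------------------------------------------------------------


def assign_passes(dataset: SurveyDataset) -> dict[str, PassKey]:
    """Map record_id -> (transect_id, pass index).

    Repeat passes of a transect are distinguished by survey date: the
    distinct dates seen on a transect, sorted, become passes 1, 2, ...
    """
    dates: dict[str, list] = {}
    for r in dataset.records:
        dates.setdefault(r.transect_id, [])
        if r.recorded_on not in dates[r.transect_id]:
            dates[r.transect_id].append(r.recorded_on)
    order = {tid: {d: i + 1 for i, d in enumerate(sorted(ds))} for tid, ds in dates.items()}
    tmap = dataset.transect_map
    out: dict[str, PassKey] = {}
    for i, r in enumerate(dataset.records):
        idx = order[r.transect_id][r.recorded_on]
        transect = tmap.get(r.transect_id)
        if transect is not None and idx > transect.passes:
            raise SurveyReferenceError(
                f"transect {r.transect_id!r} has records on more distinct dates "
                f"than its {transect.passes} pass(es)"
            )
        out[r.record_id or str(i + 1)] = (r.transect_id, idx)
    return out


def default_ordering(dataset: SurveyDataset, lut: str | None = None) -> list[PassKey]:
    """Chronological combined-axis ordering of every transect pass.

    Passes are sorted by (earliest record date on the pass, transect id,
    pass index); passes that carry no records sort last among their
    transect. This is one systematic way of combining transects; any
    explicit ordering can be passed to :func:`inter_spoor_intervals`.
    """
    first_date: dict[PassKey, object] = {}
    passes_of = assign_passes(dataset)
    for i, r in enumerate(dataset.records):
        key = passes_of[r.record_id or str(i + 1)]
        if key not in first_date or r.recorded_on < first_date[key]:
            first_date[key] = r.recorded_on
    keys: list[PassKey] = []
    for t in dataset.transects:
        if lut is not None and t.lut != lut:
            continue
        for p in range(1, t.passes + 1):
            keys.append((t.transect_id, p))
    sentinel = pd.Timestamp.max.date()
    keys.sort(key=lambda k: (first_date.get(k, sentinel), k[0], k[1]))
    return keys


def inter_spoor_intervals(
    dataset: SurveyDataset,
    species: str,
    lut: str | None = None,
    ordering: list[PassKey] | None = None,
) -> np.ndarray:
    """Gaps (km) between consecutive spoor on the combined transect axis.

    Transect passes are concatenated, in ``ordering``, into a single
    linear axis; each record sits at (offset of its pass) + position_km.
    Returns the successive differences of the sorted combined positions:
    ``n_spoor - 1`` values, empty when fewer than two spoor exist.

    Raises
    ------
    SurveyReferenceError
        if a matching record sits on a pass absent from ``ordering``.
    """
    if ordering is None:
        ordering = default_ordering(dataset, lut=lut)
    tmap = dataset.transect_map
    offsets: dict[PassKey, float] = {}
    total = 0.0
    for key in ordering:
        offsets[key] = total
        total += tmap[key[0]].length_km

    passes_of = assign_passes(dataset)
    positions = []
    for i, r in enumerate(dataset.records):
        if r.species != species or (lut is not None and r.lut != lut):
            continue
        key = passes_of[r.record_id or str(i + 1)]
        if key not in offsets:
            raise SurveyReferenceError(f"ordering omits transect pass {key!r} carrying records")
        positions.append(offsets[key] + r.position_km)
    positions.sort()
    return np.diff(np.asarray(positions, dtype=float))


# ---------------------------------------------------------------------------
# tabular summaries
# ---------------------------------------------------------------------------


def effort_summary(dataset: SurveyDataset) -> list[EffortSummary]:
    """Per-stratum effort accounting: area, transect sum, penetration, km driven."""
    out = []
    for stratum in dataset.strata:
        transects = [t for t in dataset.transects if t.lut == stratum.lut]
        single = sum(t.length_km for t in transects)
        surveyed = sum(t.surveyed_km for t in transects)
        penetration = stratum.area_km2 / single if single > 0 else float("nan")
        out.append(
            EffortSummary(
                lut=stratum.lut,
                area_km2=stratum.area_km2,
                transect_sum_km=single,
                sample_penetration=penetration,
                surveyed_km=surveyed,
            )
        )
    return out


def effort_frame(dataset: SurveyDataset, round_for_report: bool = True) -> pd.DataFrame:
    """Effort table as a DataFrame (penetration at 1 dp when rounding)."""
    rows = [
        {
            "lut": e.lut,
            "area_km2": e.area_km2,
            "transect_sum_km": e.transect_sum_km,
            "sample_penetration": round(e.sample_penetration, 1) if round_for_report else e.sample_penetration,
            "surveyed_km": e.surveyed_km,
        }
        for e in effort_summary(dataset)
    ]
    return pd.DataFrame(rows)


def density_matrix(dataset: SurveyDataset) -> pd.DataFrame:
    """Species x land-use table of spoor densities (spoor/100 km).

    Expects an already-filtered dataset. Cells for species/LUT
    combinations with no records are 0. Columns follow stratum order;
    LUTs without transects get NaN (density undefined without effort).
    """
    efforts = {e.lut: e.surveyed_km for e in effort_summary(dataset)}
    luts = [s.lut for s in dataset.strata]
    species = dataset.species_present() or list(dataset.species_present())
    if not species:
        from .survey_data import SPECIES

        species = list(SPECIES)
    counts: dict[tuple[str, str], int] = {}
    for r in dataset.records:
        counts[(r.species, r.lut)] = counts.get((r.species, r.lut), 0) + 1
    table = pd.DataFrame(index=species, columns=luts, dtype=float)
    for sp in species:
        for lut in luts:
            km = efforts.get(lut, 0.0)
            if km > 0:
                table.loc[sp, lut] = spoor_density(counts.get((sp, lut), 0), km)
            else:
                table.loc[sp, lut] = float("nan")
    table.index.name = "species"
    return table
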