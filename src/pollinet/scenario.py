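"""Current-vs-future comparison: range changes and network rewiring.

Two quantities capture the climate-change signal. At the species level, the
percentage change in high-suitability range,

    pct_change = 100 * (n_future - n_current) / n_current,

is undefined when a species has no current range (colonization from zero is
reported separately rather than as an infinite percentage). At the network
level, per-cell diffs list the species and links lost and gained between
scenarios; gained links are the rewiring — pollinators meeting plants that
migrated into the cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import CellNetwork, CellNetworkSet
from .raster import BinaryMap, SpeciesStack


@dataclass(frozen=True)
class RangeChangeRecord:
    species_id: str
    guild: str
    n_current: int
    n_future: int
    pct_change: float | None  # None = undefined (n_current == 0)

    def __post_init__(self) -> None:
        if self.n_current < 0 or self.n_future < 0:
            raise ValueError("cell counts must be non-negative")
        if (self.pct_change is None) != (self.n_current == 0):
            raise ValueError("pct_change must be undefined exactly when n_current == 0")


@dataclass(frozen=True)
class GuildSummary:
    """Counts and moments of range change within one guild.

    Species are split by the sign of their percentage change; means and
    population standard deviations are per sign group. Zero-change species
    and species with undefined change (no current range) are counted
    separately and enter neither group.
    """

    guild: str
    n_increase: int
    mean_increase: float | None
    sd_increase: float | None
    n_decrease: int
    mean_decrease: float | None
    sd_decrease: float | None
    n_zero: int
    n_new_range: int  # n_current == 0 but n_future > 0
    n_lost_entirely: int  # pct_change == -100


@dataclass(frozen=True)
class NetworkDiff:
    lat: float
    lon: float
    plants_lost: frozenset[str]
    plants_gained: frozenset[str]
    pollinators_lost: frozenset[str]
    pollinators_gained: frozenset[str]
    links_lost: frozenset[tuple[str, str]]
    links_gained: frozenset[tuple[str, str]]

    @property
    def is_empty(self) -> bool:
        return not (
            self.plants_lost or self.plants_gained
            or self.pollinators_lost or self.pollinators_gained
            or self.links_lost or self.links_gained
        )


def range_change(cur: BinaryMap, fut: BinaryMap, guild: str = "unknown") -> RangeChangeRecord:
    """Percentage change in presence cells between two aligned maps."""
    if cur.species_id != fut.species_id:
        raise ValueError(f"species mismatch: {cur.species_id!r} vs {fut.species_id!r}")
    if not cur.grid.aligned_with(fut.grid):
        raise ValueError(f"{cur.species_id}: current and future grids are not aligned")
    n_cur, n_fut = cur.n_presence, fut.n_presence
    pct = None if n_cur == 0 else 100.0 * (n_fut - n_cur) / n_cur
    return RangeChangeRecord(
        species_id=cur.species_id, guild=guild, n_current=n_cur, n_future=n_fut, pct_change=pct
    )


def range_changes(cur: SpeciesStack, fut: SpeciesStack) -> list[RangeChangeRecord]:
    """Per-species range change for a whole guild (matched by species id)."""
    fut_by_id = {lyr.species_id: lyr for lyr in fut.layers}
    missing = [lyr.species_id for lyr in cur.layers if lyr.species_id not in fut_by_id]
    if missing:
        raise ValueError(f"species absent from future stack: {', '.join(sorted(missing))}")
    return [
        range_change(lyr, fut_by_id[lyr.species_id], guild=cur.guild)
        for lyr in sorted(cur.layers, key=lambda l: l.species_id)
    ]


def _group_stats(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std())  # population SD


def summarize_guild(records: list[RangeChangeRecord], guild: str | None = None) -> GuildSummary:
    """Split a guild's records by sign of change and summarize each group."""
    if not records:
        raise ValueError("no records to summarize")
    guild = guild or records[0].guild
    inc = [r.pct_change for r in records if r.pct_change is not None and r.pct_change > 0]
    dec = [r.pct_change for r in records if r.pct_change is not None and r.pct_change < 0]
    n_zero = sum(1 for r in records if r.pct_change == 0)
    n_new = sum(1 for r in records if r.pct_change is None and r.n_future > 0)
    n_gone = sum(1 for r in records if r.pct_change is not None and r.pct_change == -100.0)
    mi, si = _group_stats(inc)
    md, sd = _group_stats(dec)
    return GuildSummary(
        guild=guild,
        n_increase=len(inc), mean_increase=mi, sd_increase=si,
        n_decrease=len(dec), mean_decrease=md, sd_decrease=sd,
        n_zero=n_zero, n_new_range=n_new, n_lost_entirely=n_gone,
    )


def diff_networks(cur: CellNetwork, fut: CellNetwork) -> NetworkDiff:
    """Species and link turnover between two scenarios of one cell.

    Species presence comes from the extraction-time presence vectors when
    available, falling back to row/column activity; a species whose every
    partner was disallowed still counts as present. Links compare the 0/1
    matrices elementwise.
    """
    if cur.plant_ids != fut.plant_ids or cur.pollinator_ids != fut.pollinator_ids:
        raise ValueError("networks have different species axes")
    if (cur.lat, cur.lon) != (fut.lat, fut.lon):
        raise ValueError("networks describe different cells")

    p_cur, p_fut = cur.plants_present(), fut.plants_present()
    a_cur, a_fut = cur.pollinators_present(), fut.pollinators_present()
    plants = np.asarray(cur.plant_ids)
    pols = np.asarray(cur.pollinator_ids)

    lost = (cur.links == 1) & (fut.links == 0)
    gained = (cur.links == 0) & (fut.links == 1)
    return NetworkDiff(
        lat=cur.lat,
        lon=cur.lon,
        plants_lost=frozenset(plants[p_cur & ~p_fut]),
        plants_gained=frozenset(plants[~p_cur & p_fut]),
        pollinators_lost=frozenset(pols[a_cur & ~a_fut]),
        pollinators_gained=frozenset(pols[~a_cur & a_fut]),
        links_lost=frozenset((str(plants[i]), str(pols[j])) for i, j in zip(*np.nonzero(lost))),
        links_gained=frozenset((str(plants[i]), str(pols[j])) for i, j in zip(*np.nonzero(gained))),
    )


@dataclass(frozen=True)
class ScenarioComparison:
    n_cells_current: int
    n_cells_future: int
    cells_lost: tuple[tuple[int, int], ...]  # had a network, loses it
    cells_gained: tuple[tuple[int, int], ...]
    diffs: dict[tuple[int, int], NetworkDiff]  # cells with a network in both


def compare_scenarios(cur_set: CellNetworkSet, fut_set: CellNetworkSet) -> ScenarioComparison:
    """Cell-level bookkeeping of where networks persist, vanish or appear."""
    if not cur_set.grid.aligned_with(fut_set.grid):
        raise ValueError("scenario network sets live on different grids")
    cur_keys = set(cur_set.networks)
    fut_keys = set(fut_set.networks)
    diffs = {
        key: diff_networks(cur_set.networks[key], fut_set.networks[key])
        for key in sorted(cur_keys & fut_keys)
    }
    return ScenarioComparison(
        n_cells_current=len(cur_keys),
        n_cells_future=len(fut_keys),
        cells_lost=tuple(sorted(cur_keys - fut_keys)),
        cells_gained=tuple(sorted(fut_keys - cur_keys)),
        diffs=diffs,
    )


def range_change_table(records: list[RangeChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species_id,
                "guild": r.guild,
                "n_current": r.n_current,
                "n_future": r.n_future,
                "pct_change": np.nan if r.pct_change is None else r.pct_change,
            }
            for r in records
        ]
    )


def comparison_summary(comp: ScenarioComparison) -> dict:
    """JSON-ready summary of a scenario comparison."""
    return {
        "n_cells_current": comp.n_cells_current,
        "n_cells_future": comp.n_cells_future,
        "n_cells_lost": len(comp.cells_lost),
        "n_cells_gained": len(comp.cells_gained),
        "n_cells_in_both": len(comp.diffs),
        "n_cells_rewired": sum(1 for d in comp.diffs.values() if d.links_gained),
        "n_cells_unchanged": sum(1 for d in comp.diffs.values() if d.is_empty),
        "total_links_lost": sum(len(d.links_lost) for d in comp.diffs.values()),
        "total_links_gained": sum(len(d.links_gained) for d in comp.diffs.values()),
    }


def diff_table(comp: ScenarioComparison) -> pd.DataFrame:
    """Per-cell diff counts for cells with a network in both scenarios."""
    rows = []
    for (r, c), d in sorted(comp.diffs.items()):
        rows.append(
            {
                "row": r, "col": c, "lat": d.lat, "lon": d.lon,
                "plants_lost": len(d.plants_lost),
                "plants_gained": len(d.plants_gained),
                "pollinators_lost": len(d.pollinators_lost),
                "pollinators_gained": len(d.pollinators_gained),
                "links_lost": len(d.links_lost),
                "links_gained": len(d.links_gained),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["row", "col", "lat", "lon", "plants_lost", "plants_gained",
                 "pollinators_lost", "pollinators_gained", "links_lost", "links_gained"],
    )
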