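"""Suitability and presence layers, guild stacks, and richness maps.

A habitat-suitability model scores every grid cell in [0, 1]; thresholding
the score turns the continuous surface into a 0/1 presence map. Presence
maps for one guild (plants or pollinators) are stacked on a shared grid,
which is where all downstream network extraction happens.

Missing data convention: NaN marks a missing cell everywhere in memory; on
disk it is the raster's NoData value. A cell is *usable* for network
extraction only when it is non-missing in every layer of both guild stacks
(see :func:`usable_mask`) — this prevents "absent" and "unknown" from being
conflated when links are inferred from co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from . import geotiff
from .grid import GridSpec

Guild = Literal["plant", "pollinator"]

RASTER_SUFFIXES = (".tif", ".tiff")


@dataclass(frozen=True)
class SuitabilityMap:
    """Continuous per-cell habitat suitability in [0, 1] for one species."""

    species_id: str
    grid: GridSpec
    values: np.ndarray  # float64, NaN = missing

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError(f"{self.species_id}: suitability values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BinaryMap:
    """0/1 presence map for one species; NaN = missing."""

    species_id: str
    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        finite = v[~np.isnan(v)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError(f"{self.species_id}: binary map holds values outside {{0, 1, missing}}")
        object.__setattr__(self, "values", v)

    @property
    def n_presence(self) -> int:
        """Number of presence (value 1) cells — the species' range size."""
        return int(np.nansum(self.values))


@dataclass(frozen=True)
class SpeciesStack:
    """Aligned presence layers for one guild, unique species ids."""

    guild: Guild
    layers: tuple[BinaryMap, ...]
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.guild not in ("plant", "pollinator"):
            raise ValueError(f"guild must be 'plant' or 'pollinator', got {self.guild!r}")
        misaligned = [lyr.species_id for lyr in self.layers if not lyr.grid.aligned_with(self.grid)]
        if misaligned:
            raise ValueError(f"layers not aligned with stack grid: {', '.join(misaligned)}")
        ids = [lyr.species_id for lyr in self.layers]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate species ids in {self.guild} stack: {', '.join(sorted(dupes))}")

    @property
    def species_ids(self) -> list[str]:
        return [lyr.species_id for lyr in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def as_array(self) -> np.ndarray:
        """(n_species, n_rows, n_cols) float array; NaN = missing."""
        if not self.layers:
            return np.empty((0,) + self.grid.shape)
        return np.stack([lyr.values for lyr in self.layers])


def read_suitability(path: str | Path) -> SuitabilityMap:
    """Read one species' suitability raster; species id = file stem."""
    path = Path(path)
    values, grid = geotiff.read_geotiff(path)
    return SuitabilityMap(species_id=path.stem, grid=grid, values=values)


def read_binary(path: str | Path) -> BinaryMap:
    """Read a presence/absence raster already holding only {0, 1, NoData}."""
    path = Path(path)
    values, grid = geotiff.read_geotiff(path)
    return BinaryMap(species_id=path.stem, grid=grid, values=values)


def write_map(map_: SuitabilityMap | BinaryMap, path: str | Path) -> Path:
    """Write a layer as a float32 GeoTIFF with NaN NoData."""
    return geotiff.write_geotiff(path, map_.values, map_.grid, dtype="float32", nodata=float("nan"))


def binarize(map_: SuitabilityMap, threshold: float, *, inclusive: bool = False) -> BinaryMap:
    """Threshold a suitability surface into a presence map.

    A cell becomes presence when its value strictly exceeds ``threshold``
    (the high-suitability convention); pass ``inclusive=True`` for >=.
    Missing cells stay missing.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    v = map_.values
    with np.errstate(invalid="ignore"):
        hits = v >= threshold if inclusive else v > threshold
    out = np.where(np.isnan(v), np.nan, hits.astype(np.float64))
    return BinaryMap(species_id=map_.species_id, grid=map_.grid, values=out)


def load_stack(
    directory: str | Path,
    guild: Guild,
    *,
    threshold: float | None = None,
    inclusive: bool = False,
) -> SpeciesStack:
    """Load every raster in a folder as one guild's presence stack.

    Files are taken in sorted name order so the stack's species axis is
    stable across platforms. When ``threshold`` is given, continuous rasters
    are binarized on the fly; otherwise layers must already be binary.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{guild} folder not found: {directory}")
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in RASTER_SUFFIXES)
    if not paths:
        raise ValueError(f"no rasters (*.tif) found in {directory}")

    stems = [p.stem for p in paths]
    dupes = {s for s in stems if stems.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate species ids in {directory}: {', '.join(sorted(dupes))}")

    layers = []
    for p in paths:
        if threshold is not None:
            layers.append(binarize(read_suitability(p), threshold, inclusive=inclusive))
        else:
            layers.append(read_binary(p))

    grid = layers[0].grid
    misaligned = [p.name for p, lyr in zip(paths, layers) if not lyr.grid.aligned_with(grid)]
    if misaligned:
        raise ValueError(
            f"layers in {directory} are not aligned with {paths[0].name}: {', '.join(misaligned)}"
        )
    return SpeciesStack(guild=guild, layers=tuple(layers), grid=grid)


def richness_map(stack: SpeciesStack) -> np.ndarray:
    """Per-cell species richness: the sum of presences over all layers.

    Missing-in-some-layers contributes 0 to the count; a cell is missing in
    the output only when it is missing in every layer. Richness maps are
    descriptive — network extraction instead requires cells valid in all
    layers (see :func:`usable_mask`).
    """
    arr = stack.as_array()
    if arr.shape[0] == 0:
        return np.full(stack.grid.shape, np.nan)
    counts = np.nansum(arr, axis=0)
    all_missing = np.isnan(arr).all(axis=0)
    return np.where(all_missing, np.nan, counts)


def write_richness(stack: SpeciesStack, path: str | Path) -> Path:
    """Write the richness map as an integer-band GeoTIFF (NoData -1)."""
    return geotiff.write_geotiff(path, richness_map(stack), stack.grid, dtype="int32", nodata=-1)


def usable_mask(*stacks: SpeciesStack) -> np.ndarray:
    """Boolean mask of cells non-missing in every layer of every stack.

    Only these cells can yield a network: a missing suitability value says
    nothing about absence, so co-occurrence is undefined there.
    """
    if not stacks:
        raise ValueError("at least one stack required")
    grid = stacks[0].grid
    mask = np.ones(grid.shape, dtype=bool)
    for stack in stacks:
        if not stack.grid.aligned_with(grid):
            raise ValueError("stacks are not aligned")
        arr = stack.as_array()
        if arr.shape[0]:
            mask &= ~np.isnan(arr).any(axis=0)
    return mask
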