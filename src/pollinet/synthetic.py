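"""Synthetic landscapes, guild stacks, catalogs and future scenarios.

Everything the pipeline consumes can be generated here with known ground
truth: smooth suitability surfaces standing in for distribution-model
output, binary guild stacks with controlled co-occurrence (identical,
disjoint or independent ranges), random interaction catalogs, canonical
test matrices for the metric layer, and "future" stacks produced by
shifting ranges with edge clipping and random contraction — whose expected
range changes follow directly from the construction.

Reproducibility: one global seed fans out to per-species sub-seeds through
a stable hash of the species id (CRC-32), so adding a species to a run
never perturbs any other species' range.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .extraction import Metaweb, write_metaweb
from .grid import GridSpec
from .raster import BinaryMap, SpeciesStack, SuitabilityMap, write_map

#: Demo landscape: a coarse Chile-like bounding box (lat -56..-17, lon
#: -76..-66). Purely evocative; any WGS84 grid works.
DEMO_GRID = GridSpec(n_rows=50, n_cols=50, origin_lat=-17.0, origin_lon=-76.0, cell_size=0.2)


def species_seed(global_seed: int, species_id: str) -> int:
    """Stable per-species sub-seed (< 2^31) derived from the global seed."""
    return (zlib.crc32(species_id.encode("utf-8")) ^ (global_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


@dataclass(frozen=True)
class SurfaceSpec:
    """Recipe for a smooth suitability surface: Gaussian bumps plus noise."""

    grid: GridSpec
    centers: tuple[tuple[float, float], ...] = ()
    spread: float = 1.0  # degrees; Gaussian sigma of each bump
    peak: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if not 0 < self.peak <= 1:
            raise ValueError("peak must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class ShiftSpec:
    """Future-scenario recipe: translate ranges, then thin them randomly.

    ``d_lat``/``d_lon`` are signed whole-cell offsets (positive d_lat moves
    ranges north, positive d_lon east); cells shifted off-grid are clipped.
    ``contraction`` is the fraction of surviving presence cells removed at
    random — the expected future range of an interior (unclipped) species
    is (1 - contraction) times its current range.
    """

    d_lat: int = 0
    d_lon: int = 0
    contraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contraction <= 1.0:
            raise ValueError("contraction must lie in [0, 1]")


def make_surface(spec: SurfaceSpec, species_id: str = "synthetic") -> SuitabilityMap:
    """Sum-of-Gaussian-bumps suitability surface, clamped to [0, 1]."""
    grid = spec.grid
    lats = grid.origin_lat - (np.arange(grid.n_rows) + 0.5) * grid.cell_size
    lons = grid.origin_lon + (np.arange(grid.n_cols) + 0.5) * grid.cell_size
    lat_grid, lon_grid = np.meshgrid(lats, lons, indexing="ij")

    values = np.zeros(grid.shape)
    for c_lat, c_lon in spec.centers:
        d2 = (lat_grid - c_lat) ** 2 + (lon_grid - c_lon) ** 2
        values += spec.peak * np.exp(-d2 / (2.0 * spec.spread**2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values += rng.normal(0.0, spec.noise_sd, size=grid.shape)
    return SuitabilityMap(species_id=species_id, grid=grid, values=np.clip(values, 0.0, 1.0))


def _random_range(grid: GridSpec, rng: np.random.Generator, fill: float) -> np.ndarray:
    """A contiguous-ish random range: a random rectangular block thinned to
    roughly ``fill`` of the grid.
    """
    h = max(1, int(round(grid.n_rows * np.sqrt(fill))))
    w = max(1, int(round(grid.n_cols * np.sqrt(fill))))
    r0 = int(rng.integers(0, grid.n_rows - h + 1))
    c0 = int(rng.integers(0, grid.n_cols - w + 1))
    values = np.zeros(grid.shape)
    values[r0 : r0 + h, c0 : c0 + w] = 1.0
    return values


def make_guild_stacks(
    n_plants: int,
    n_pollinators: int,
    grid: GridSpec | None = None,
    overlap: str = "random",
    seed: int = 0,
    fill: float = 0.25,
) -> tuple[SpeciesStack, SpeciesStack]:
    """Binary guild stacks with controlled co-occurrence structure.

    overlap='identical': every species of both guilds shares one range, so
    every presence cell yields a complete network. 'disjoint': plant and
    pollinator ranges never share a cell, so extraction finds no network.
    'random': independent per-species ranges (block ranges covering about
    ``fill`` of the grid).
    """
    if n_plants < 1 or n_pollinators < 1:
        raise ValueError("need at least one species per guild")
    if overlap not in ("identical", "disjoint", "random"):
        raise ValueError(f"unknown overlap mode {overlap!r}")
    grid = grid or DEMO_GRID

    plant_ids = [f"plant_{i:03d}" for i in range(n_plants)]
    pol_ids = [f"pollinator_{i:03d}" for i in range(n_pollinators)]

    if overlap == "identical":
        shared = _random_range(grid, np.random.default_rng(seed), fill)
        plant_maps = {sid: shared for sid in plant_ids}
        pol_maps = {sid: shared for sid in pol_ids}
    elif overlap == "disjoint":
        half = grid.n_rows // 2
        north = np.zeros(grid.shape)
        north[:half, :] = 1.0
        south = np.zeros(grid.shape)
        south[half:, :] = 1.0
        plant_maps = {sid: north for sid in plant_ids}
        pol_maps = {sid: south for sid in pol_ids}
    else:
        plant_maps = {
            sid: _random_range(grid, np.random.default_rng(species_seed(seed, sid)), fill)
            for sid in plant_ids
        }
        pol_maps = {
            sid: _random_range(grid, np.random.default_rng(species_seed(seed, sid)), fill)
            for sid in pol_ids
        }

    plants = SpeciesStack(
        guild="plant",
        layers=tuple(BinaryMap(sid, grid, vals) for sid, vals in plant_maps.items()),
        grid=grid,
    )
    pollinators = SpeciesStack(
        guild="pollinator",
        layers=tuple(BinaryMap(sid, grid, vals) for sid, vals in pol_maps.items()),
        grid=grid,
    )
    return plants, pollinators


def make_metaweb(P: int, A: int, target_connectance: float, seed: int = 0) -> Metaweb:
    """Random reference catalog with expected fill ``target_connectance``.

    For any positive target, every species is guaranteed at least one
    allowed link (a resampling step fixes empty rows/columns); at target 0
    the guarantee is waived and the catalog is empty.
    """
    if not 0.0 <= target_connectance <= 1.0:
        raise ValueError("target_connectance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    allowed = (rng.random((P, A)) < target_connectance).astype(np.int8)
    if target_connectance > 0:
        for i in np.nonzero(~allowed.any(axis=1))[0]:
            allowed[i, rng.integers(0, A)] = 1
        for j in np.nonzero(~allowed.any(axis=0))[0]:
            allowed[rng.integers(0, P), j] = 1
    return Metaweb(
        plant_ids=tuple(f"plant_{i:03d}" for i in range(P)),
        pollinator_ids=tuple(f"pollinator_{i:03d}" for i in range(A)),
        allowed=allowed,
    )


def canonical_matrix(kind: str, P: int = 3, A: int = 3) -> np.ndarray:
    """Golden structures for the metric layer.

    stair: rows of decreasing prefix fill (perfectly nested);
    identity: ones on the diagonal; complete: all ones; block2: two
    disjoint complete 2x2 blocks (requires 4x4); antidiagonal: ones on the
    reversed diagonal.
    """
    if kind == "stair":
        if P != A:
            raise ValueError("stair requires a square matrix")
        return _stair(P)
    if kind == "identity":
        if P != A:
            raise ValueError("identity requires a square matrix")
        return np.eye(P, dtype=np.int8)
    if kind == "complete":
        return np.ones((P, A), dtype=np.int8)
    if kind == "block2":
        if (P, A) != (4, 4):
            raise ValueError("block2 is defined as 4x4")
        m = np.zeros((4, 4), dtype=np.int8)
        m[:2, :2] = 1
        m[2:, 2:] = 1
        return m
    if kind == "antidiagonal":
        if P != A:
            raise ValueError("antidiagonal requires a square matrix")
        return np.eye(P, dtype=np.int8)[:, ::-1].copy()
    raise ValueError(f"unknown canonical matrix kind {kind!r}")


def _stair(n: int) -> np.ndarray:
    """n x n stair: row i has ones in the first n - i columns."""
    m = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        m[i, : n - i] = 1
    return m


def apply_shift(stack: SpeciesStack, spec: ShiftSpec) -> SpeciesStack:
    """Future scenario: translate every layer, clip at the grid edge, then
    remove a random ``contraction`` fraction of surviving presence cells.
    """
    layers = []
    for lyr in stack.layers:
        values = np.zeros(stack.grid.shape)
        # positive d_lat moves presence toward lower row indices (north)
        src = lyr.values
        dr, dc = -spec.d_lat, spec.d_lon
        r_src = slice(max(0, -dr), min(stack.grid.n_rows, stack.grid.n_rows - dr))
        r_dst = slice(max(0, dr), min(stack.grid.n_rows, stack.grid.n_rows + dr))
        c_src = slice(max(0, -dc), min(stack.grid.n_cols, stack.grid.n_cols - dc))
        c_dst = slice(max(0, dc), min(stack.grid.n_cols, stack.grid.n_cols + dc))
        if r_src.stop > r_src.start and c_src.stop > c_src.start:
            values[r_dst, c_dst] = np.nan_to_num(src[r_src, c_src], nan=0.0)
        if spec.contraction > 0:
            rng = np.random.default_rng(species_seed(spec.seed, lyr.species_id))
            rows, cols = np.nonzero(values == 1.0)
            drop = rng.random(rows.size) < spec.contraction
            values[rows[drop], cols[drop]] = 0.0
        values[np.isnan(src)] = np.nan  # missing cells stay missing
        layers.append(BinaryMap(lyr.species_id, stack.grid, values))
    return SpeciesStack(guild=stack.guild, layers=tuple(layers), grid=stack.grid)


def write_stack(stack: SpeciesStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_map(lyr, directory / f"{lyr.species_id}.tif") for lyr in stack.layers]


def write_demo_inputs(
    out_dir: str | Path,
    n_plants: int = 20,
    n_pollinators: int = 20,
    seed: int = 42,
    shift: ShiftSpec | None = None,
    metaweb_connectance: float = 0.3,
    grid: GridSpec | None = None,
) -> dict[str, Path]:
    """Write a complete demo input tree: current/ and future/ raster folders
    per guild plus a metaweb edge list. Returns the created paths.
    """
    out_dir = Path(out_dir)
    grid = grid or DEMO_GRID
    shift = shift or ShiftSpec(d_lat=-3, d_lon=0, contraction=0.2, seed=seed)

    plants, pollinators = make_guild_stacks(n_plants, n_pollinators, grid, "random", seed)
    fut_plants = apply_shift(plants, shift)
    fut_pollinators = apply_shift(pollinators, shift)
    web = make_metaweb(n_plants, n_pollinators, metaweb_connectance, seed)

    paths = {
        "current_plants": out_dir / "current" / "plants",
        "current_pollinators": out_dir / "current" / "pollinators",
        "future_plants": out_dir / "future" / "plants",
        "future_pollinators": out_dir / "future" / "pollinators",
    }
    write_stack(plants, paths["current_plants"])
    write_stack(pollinators, paths["current_pollinators"])
    write_stack(fut_plants, paths["future_plants"])
    write_stack(fut_pollinators, paths["future_pollinators"])
    paths["metaweb"] = write_metaweb(web, out_dir / "metaweb.csv")
    return paths
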