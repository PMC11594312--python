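"""Per-cell bipartite network extraction from overlaid presence maps.

The core inference step: in each grid cell, every plant present is assumed
to potentially interact with every pollinator present — the cell's
incidence matrix is the outer product of the two presence vectors. Links
never observed in a reference interaction catalog (the *metaweb*) can then
be deleted, so that inferred networks contain only plausible interactions.
One CSV per cell is written, named by the cell-center coordinates.

Plants are always rows and pollinators columns; species axes are sorted
lexicographically so outputs are byte-stable across runs.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec
from .raster import SpeciesStack, usable_mask

logger = logging.getLogger(__name__)

COORD_DECIMALS = 6


class UnusableCellError(ValueError):
    """Raised when extraction is asked for a cell with missing data."""


@dataclass(frozen=True)
class Metaweb:
    """Reference catalog of allowed plant x pollinator interactions."""

    plant_ids: tuple[str, ...]
    pollinator_ids: tuple[str, ...]
    allowed: np.ndarray  # (P, A) in {0, 1}

    def __post_init__(self) -> None:
        a = np.asarray(self.allowed, dtype=np.int8)
        if a.shape != (len(self.plant_ids), len(self.pollinator_ids)):
            raise ValueError(f"allowed matrix shape {a.shape} does not match id lists")
        if len(set(self.plant_ids)) != len(self.plant_ids):
            raise ValueError("duplicate plant ids in metaweb")
        if len(set(self.pollinator_ids)) != len(self.pollinator_ids):
            raise ValueError("duplicate pollinator ids in metaweb")
        if a.size and not np.isin(a, (0, 1)).all():
            raise ValueError("metaweb entries must be 0/1")
        object.__setattr__(self, "allowed", a)


@dataclass(frozen=True)
class CellNetwork:
    """One cell's plants x pollinators incidence matrix.

    ``plant_presence`` / ``pollinator_presence`` record which species were
    present in the cell at extraction time. A species can be present yet
    have no links (all its co-occurring partners disallowed by the
    metaweb); keeping the presence vectors separate lets scenario diffs
    distinguish species loss from link loss. They are excluded from
    equality so that a CSV round-trip — which stores only the links —
    reproduces an equal network.
    """

    lat: float
    lon: float
    plant_ids: tuple[str, ...]
    pollinator_ids: tuple[str, ...]
    links: np.ndarray  # (P, A) in {0, 1}
    plant_presence: np.ndarray | None = field(default=None, compare=False)
    pollinator_presence: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.links, dtype=np.int8)
        if m.shape != (len(self.plant_ids), len(self.pollinator_ids)):
            raise ValueError(f"links shape {m.shape} does not match id lists")
        if m.size and not np.isin(m, (0, 1)).all():
            raise ValueError("link entries must be 0/1")
        object.__setattr__(self, "links", m)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellNetwork):
            return NotImplemented
        return (
            self.lat == other.lat
            and self.lon == other.lon
            and self.plant_ids == other.plant_ids
            and self.pollinator_ids == other.pollinator_ids
            and np.array_equal(self.links, other.links)
        )

    @property
    def n_links(self) -> int:
        return int(self.links.sum())

    def plants_present(self) -> np.ndarray:
        if self.plant_presence is not None:
            return np.asarray(self.plant_presence, dtype=bool)
        return self.links.any(axis=1)

    def pollinators_present(self) -> np.ndarray:
        if self.pollinator_presence is not None:
            return np.asarray(self.pollinator_presence, dtype=bool)
        return self.links.any(axis=0)


@dataclass
class CellNetworkSet:
    """Extracted networks keyed by (row, col); shared grid and species axes."""

    grid: GridSpec
    networks: dict[tuple[int, int], CellNetwork]

    def __post_init__(self) -> None:
        for (r, c) in self.networks:
            if not (0 <= r < self.grid.n_rows and 0 <= c < self.grid.n_cols):
                raise ValueError(f"cell ({r}, {c}) outside grid {self.grid.shape}")
        axes = {(n.plant_ids, n.pollinator_ids) for n in self.networks.values()}
        if len(axes) > 1:
            raise ValueError("all networks in a set must share the same species axes")

    def __len__(self) -> int:
        return len(self.networks)


def _sorted_stack_axes(stack: SpeciesStack) -> tuple[tuple[str, ...], np.ndarray]:
    """Species ids sorted lexicographically with the matching layer order."""
    order = sorted(range(len(stack)), key=lambda i: stack.layers[i].species_id)
    ids = tuple(stack.layers[i].species_id for i in order)
    arr = stack.as_array()[order] if len(stack) else np.empty((0,) + stack.grid.shape)
    return ids, arr


def extract_cell(plants: SpeciesStack, pollinators: SpeciesStack, row: int, col: int) -> CellNetwork:
    """Build one cell's incidence matrix from co-occurrence.

    links[i, j] = 1 iff plant i and pollinator j are both present in the
    cell — the outer product of the presence vectors.
    """
    if not plants.grid.aligned_with(pollinators.grid):
        raise ValueError("plant and pollinator stacks are not aligned")
    p_ids, p_arr = _sorted_stack_axes(plants)
    a_ids, a_arr = _sorted_stack_axes(pollinators)
    p_vec = p_arr[:, row, col]
    a_vec = a_arr[:, row, col]
    if np.isnan(p_vec).any() or np.isnan(a_vec).any():
        raise UnusableCellError(f"cell ({row}, {col}) skipped: missing data in at least one layer")
    lat, lon = plants.grid.cell_center(row, col)
    return CellNetwork(
        lat=lat,
        lon=lon,
        plant_ids=p_ids,
        pollinator_ids=a_ids,
        links=np.outer(p_vec, a_vec).astype(np.int8),
        plant_presence=p_vec.astype(bool),
        pollinator_presence=a_vec.astype(bool),
    )


def apply_metaweb(net: CellNetwork, web: Metaweb, *, strict: bool = True) -> CellNetwork:
    """Delete links absent from the reference catalog (elementwise AND).

    Species in the network but not in the catalog are an error in strict
    mode; in permissive mode all their links are disallowed (zero row or
    column) and the species are logged. Link count never increases.
    """
    p_index = {s: i for i, s in enumerate(web.plant_ids)}
    a_index = {s: j for j, s in enumerate(web.pollinator_ids)}
    unknown = [s for s in net.plant_ids if s not in p_index]
    unknown += [s for s in net.pollinator_ids if s not in a_index]
    if unknown and strict:
        raise KeyError(f"species missing from metaweb (strict mode): {', '.join(sorted(unknown))}")
    if unknown:
        logger.warning("metaweb lacks %d species; their links are disallowed: %s",
                       len(unknown), ", ".join(sorted(unknown)))

    allowed = np.zeros(net.links.shape, dtype=np.int8)
    for i, p in enumerate(net.plant_ids):
        if p not in p_index:
            continue
        for j, a in enumerate(net.pollinator_ids):
            if a in a_index:
                allowed[i, j] = web.allowed[p_index[p], a_index[a]]
    return CellNetwork(
        lat=net.lat,
        lon=net.lon,
        plant_ids=net.plant_ids,
        pollinator_ids=net.pollinator_ids,
        links=net.links & allowed,
        plant_presence=net.plant_presence,
        pollinator_presence=net.pollinator_presence,
    )


def extract_all(
    plants: SpeciesStack,
    pollinators: SpeciesStack,
    web: Metaweb | None = None,
    *,
    drop_empty: bool = True,
    strict_metaweb: bool = True,
) -> CellNetworkSet:
    """Extract a network for every usable cell.

    With ``drop_empty`` (default) cells whose matrix holds no link are
    omitted, automating the manual pruning of interaction-free files.
    """
    mask = usable_mask(plants, pollinators)
    networks: dict[tuple[int, int], CellNetwork] = {}
    for row, col in zip(*np.nonzero(mask)):
        net = extract_cell(plants, pollinators, int(row), int(col))
        if web is not None:
            net = apply_metaweb(net, web, strict=strict_metaweb)
        if drop_empty and net.n_links == 0:
            continue
        networks[(int(row), int(col))] = net
    if not mask.any():
        warnings.warn("no usable cells: every cell is missing in at least one layer", stacklevel=2)
    return CellNetworkSet(grid=plants.grid, networks=networks)


def _coord_token(x: float) -> str:
    return f"{x:.{COORD_DECIMALS}f}"


def cell_csv_name(net: CellNetwork) -> str:
    """'<lat>_<lon>.csv' with 6-decimal fixed-point coordinates."""
    return f"{_coord_token(net.lat)}_{_coord_token(net.lon)}.csv"


def write_cell_csv(net: CellNetwork, out_dir: str | Path) -> Path:
    """Write one cell's matrix: corner label 'plant', pollinator columns,
    one row per plant with 0/1 entries. Fails on a coordinate name collision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / cell_csv_name(net)
    if path.exists():
        raise FileExistsError(f"cell file name collision: {path.name} already written")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plant", *net.pollinator_ids])
        for plant, row in zip(net.plant_ids, net.links):
            writer.writerow([plant, *(int(v) for v in row)])
    return path


def write_all_csv(nets: CellNetworkSet, out_dir: str | Path) -> list[Path]:
    return [write_cell_csv(net, out_dir) for _, net in sorted(nets.networks.items())]


def read_cell_csv(path: str | Path) -> CellNetwork:
    """Read a per-cell matrix CSV; coordinates come from the file name."""
    path = Path(path)
    try:
        lat_str, lon_str = path.stem.split("_")
        lat, lon = float(lat_str), float(lon_str)
    except ValueError as exc:
        raise ValueError(f"{path.name}: file name is not '<lat>_<lon>.csv'") from exc
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or not rows[0] or rows[0][0] != "plant":
        raise ValueError(f"{path.name}: missing 'plant' header row")
    pollinator_ids = tuple(rows[0][1:])
    plant_ids, links = [], []
    for line_no, row in enumerate(rows[1:], start=2):
        if len(row) != len(pollinator_ids) + 1:
            raise ValueError(f"{path.name}:{line_no}: expected {len(pollinator_ids) + 1} fields")
        plant_ids.append(row[0])
        try:
            values = [int(v) for v in row[1:]]
        except ValueError as exc:
            raise ValueError(f"{path.name}:{line_no}: non-integer matrix entry") from exc
        if any(v not in (0, 1) for v in values):
            raise ValueError(f"{path.name}:{line_no}: matrix entries must be 0 or 1")
        links.append(values)
    return CellNetwork(
        lat=lat,
        lon=lon,
        plant_ids=tuple(plant_ids),
        pollinator_ids=pollinator_ids,
        links=np.asarray(links, dtype=np.int8).reshape(len(plant_ids), len(pollinator_ids)),
    )


def read_network_dir(directory: str | Path, grid: GridSpec) -> CellNetworkSet:
    """Load every per-cell CSV in a folder back into a network set."""
    directory = Path(directory)
    networks = {}
    for path in sorted(directory.glob("*.csv")):
        net = read_cell_csv(path)
        networks[grid.nearest_cell(net.lat, net.lon)] = net
    return CellNetworkSet(grid=grid, networks=networks)


def network_presence_map(nets: CellNetworkSet) -> np.ndarray:
    """0/1 raster marking cells that host a network with at least one link."""
    out = np.zeros(nets.grid.shape, dtype=np.int32)
    for (row, col), net in nets.networks.items():
        if net.n_links > 0:
            out[row, col] = 1
    return out


def read_metaweb(path: str | Path) -> Metaweb:
    """Read a reference catalog.

    Accepts either an edge list (columns ``plant``, ``pollinator``; one
    interaction per row) or a full matrix in the per-cell CSV dialect
    (corner label 'plant'). The format is sniffed from the header.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    if header[:2] == ["plant", "pollinator"] and len(header) == 2:
        df = pd.read_csv(path)
        plant_ids = tuple(sorted(df["plant"].astype(str).unique()))
        pollinator_ids = tuple(sorted(df["pollinator"].astype(str).unique()))
        allowed = np.zeros((len(plant_ids), len(pollinator_ids)), dtype=np.int8)
        p_index = {s: i for i, s in enumerate(plant_ids)}
        a_index = {s: j for j, s in enumerate(pollinator_ids)}
        for plant, pol in zip(df["plant"].astype(str), df["pollinator"].astype(str)):
            allowed[p_index[plant], a_index[pol]] = 1
        return Metaweb(plant_ids=plant_ids, pollinator_ids=pollinator_ids, allowed=allowed)
    if header and header[0] == "plant":
        df = pd.read_csv(path, index_col=0)
        return Metaweb(
            plant_ids=tuple(str(s) for s in df.index),
            pollinator_ids=tuple(str(s) for s in df.columns),
            allowed=df.to_numpy(dtype=np.int8),
        )
    raise ValueError(f"{path.name}: not an edge list (plant,pollinator) nor a matrix CSV")


def write_metaweb(web: Metaweb, path: str | Path) -> Path:
    """Write a catalog as an edge list CSV."""
    rows = [
        {"plant": web.plant_ids[i], "pollinator": web.pollinator_ids[j]}
        for i, j in zip(*np.nonzero(web.allowed))
    ]
    pd.DataFrame(rows, columns=["plant", "pollinator"]).to_csv(path, index=False)
    return Path(path)
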