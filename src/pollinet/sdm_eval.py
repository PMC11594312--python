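"""Occurrence handling and distribution-model evaluation statistics.

These operations support the SDM side of the workflow: spatial thinning of
occurrence records, pseudo-absence generation on the analysis grid, k-fold
splits, and three threshold-independent evaluation statistics — rank AUC,
IMAE (1 minus mean absolute error) and the continuous Boyce index. Model
fitting itself (e.g. MaxEnt) is out of scope; these functions evaluate
prediction scores produced elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridSpec

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class OccurrenceSet:
    """Presence points for one species, (lat, lon) in decimal degrees."""

    species_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for lat, lon in self.points:
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValueError(f"{self.species_id}: point ({lat}, {lon}) outside lat/lon bounds")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class EvalScores:
    """Model predictions at presence sites and at background/absence sites."""

    presence_scores: tuple[float, ...]
    background_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, scores in (("presence", self.presence_scores), ("background", self.background_scores)):
            arr = np.asarray(scores, dtype=float)
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError(f"{name} scores must lie in [0, 1]")


@dataclass(frozen=True)
class BoyceConfig:
    """Moving-window setup for the continuous Boyce index.

    ``window_width`` defaults to a tenth of the observed score range and
    ``n_windows`` to 101 equally spaced overlapping windows — the usual
    continuous-Boyce configuration. Correlation is always Spearman rank.
    """

    window_width: float | None = None  # None -> (max - min) / 10
    n_windows: int = 101

    def __post_init__(self) -> None:
        if self.window_width is not None and self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if self.n_windows < 3:
            raise ValueError("need at least 3 windows")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (spherical Earth, R = 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def thin_occurrences(occ: OccurrenceSet, min_dist_km: float = 10.0) -> OccurrenceSet:
    """Greedy spatial thinning: keep a point iff it is at least
    ``min_dist_km`` from every already-kept point, scanning in input order.

    Deterministic (no RNG) and idempotent. The default 10 km radius removes
    duplicate records and reduces spatial clustering of presences.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    kept: list[tuple[float, float]] = []
    for lat, lon in occ.points:
        if all(haversine_km(lat, lon, klat, klon) >= min_dist_km for klat, klon in kept):
            kept.append((lat, lon))
    return OccurrenceSet(species_id=occ.species_id, points=tuple(kept))


def pseudo_absences(
    grid: GridSpec,
    usable: np.ndarray,
    n: int,
    exclude: OccurrenceSet | None = None,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Draw ``n`` distinct cell centers uniformly, without replacement, from
    usable cells that contain no excluded presence point.
    """
    usable = np.asarray(usable, dtype=bool)
    if usable.shape != grid.shape:
        raise ValueError(f"mask shape {usable.shape} != grid shape {grid.shape}")
    eligible = usable.copy()
    if exclude is not None:
        for lat, lon in exclude.points:
            try:
                r, c = grid.nearest_cell(lat, lon)
            except IndexError:
                continue  # presence outside the grid cannot veto a cell
            eligible[r, c] = False
    rows, cols = np.nonzero(eligible)
    if n > rows.size:
        raise ValueError(f"requested {n} pseudo-absences but only {rows.size} eligible cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False)
    return [grid.cell_center(int(rows[i]), int(cols[i])) for i in pick]


def kfold_split(items: list, k: int, seed: int = 0) -> list[list]:
    """Shuffle then partition into k folds whose sizes differ by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(items):
        raise ValueError(f"k={k} exceeds number of items ({len(items)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    return [[items[i] for i in chunk] for chunk in np.array_split(order, k)]


def auc(scores: EvalScores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank handling of ties.

    Equals the probability that a random presence outscores a random
    background point, counting ties as half.
    """
    pres = np.asarray(scores.presence_scores, dtype=float)
    back = np.asarray(scores.background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("AUC needs non-empty presence and background scores")
    ranks = stats.rankdata(np.concatenate([pres, back]))
    n_p, n_a = pres.size, back.size
    return float((ranks[:n_p].sum() - n_p * (n_p + 1) / 2.0) / (n_p * n_a))


def imae(predictions: list[float] | np.ndarray, labels: list[int] | np.ndarray) -> float:
    """Inverse mean absolute error: 1 - mean(|prediction - label|).

    Labels are 1 for presence and 0 for (pseudo-)absence; higher is better.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} predictions vs {y.shape} labels")
    return float(1.0 - np.abs(p - y).mean())


def boyce(scores: EvalScores, cfg: BoyceConfig | None = None) -> float | None:
    """Continuous Boyce index.

    Overlapping windows span the combined score range; each window's
    predicted-to-expected ratio P/E compares the share of presence scores it
    captures against the share of background scores. The index is the
    Spearman rank correlation of P/E against the window midpoint: +1 when
    presences concentrate monotonically in high-suitability windows, values
    near 0 for a model no better than chance, negative when worse. Returns
    ``None`` ("not computable") when fewer than 3 windows keep E > 0.
    """
    cfg = cfg or BoyceConfig()
    pres = np.asarray(scores.presence_scores, dtype=float)
    back = np.asarray(scores.background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("Boyce needs non-empty presence and background scores")

    combined = np.concatenate([pres, back])
    lo, hi = float(combined.min()), float(combined.max())
    width = cfg.window_width if cfg.window_width is not None else (hi - lo) / 10.0
    if width <= 0:  # all scores identical — no gradient to correlate against
        return None

    starts = np.linspace(lo, hi - width, cfg.n_windows)
    mids, ratios = [], []
    for s in starts:
        e = s + width
        p_share = np.mean((pres >= s) & (pres <= e))
        e_share = np.mean((back >= s) & (back <= e))
        if e_share == 0:
            continue
        mids.append(s + width / 2.0)
        ratios.append(p_share / e_share)
    if len(ratios) < 3:
        return None
    rho = stats.spearmanr(mids, ratios).statistic
    return None if np.isnan(rho) else float(rho)


def read_occurrences(path: str | Path) -> dict[str, OccurrenceSet]:
    """Read a CSV with columns species, lat, lon into per-species sets."""
    df = pd.read_csv(path)
    required = {"species", "lat", "lon"}
    if not required.issubset(df.columns):
        raise ValueError(f"occurrence table must have columns {sorted(required)}, got {list(df.columns)}")
    out = {}
    for species, sub in df.groupby("species", sort=True):
        out[str(species)] = OccurrenceSet(
            species_id=str(species),
            points=tuple(zip(sub["lat"].astype(float), sub["lon"].astype(float))),
        )
    return out


def write_occurrences(sets: dict[str, OccurrenceSet], path: str | Path) -> Path:
    rows = [
        {"species": sid, "lat": lat, "lon": lon}
        for sid, occ in sorted(sets.items())
        for lat, lon in occ.points
    ]
    pd.DataFrame(rows, columns=["species", "lat", "lon"]).to_csv(path, index=False)
    return Path(path)
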