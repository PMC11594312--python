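"""Network-level bipartite metrics.

Twelve indices summarize each extracted plants x pollinators incidence
matrix: connectance, web asymmetry, links per species, Barber bipartite
modularity Q, matrix (nestedness) temperature, NODF, a weighted-NODF
variant, quantitative linkage density, the two active species counts, and
secondary-extinction robustness for each level. All are computed from
scratch on the *active* matrix — the incidence matrix with all-zero rows
and columns removed, standard practice before bipartite indices — while
the dropped-species counts are kept for reporting.

"HL" (higher level) is the pollinator side, "LL" (lower level) the plant
side. A metric that is undefined for a degenerate matrix (for example
nestedness of a single-link network) is reported as ``None`` — "not
computable" — and batch averages skip it rather than coercing it to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .extraction import CellNetwork, CellNetworkSet

#: Atmar-Patterson scaling constant for matrix temperature: the mean squared
#: normalized distance of a maximally disordered matrix is 0.04145, so T is
#: mean unexpectedness times 100/0.04145, clamped to [0, 100].
TEMPERATURE_K = 100.0 / 0.04145

Level = Literal["HL", "LL"]
RemovalOrder = Literal["random", "degree_asc", "degree_desc"]


@dataclass(frozen=True)
class ActiveMatrix:
    """Incidence matrix restricted to species with at least one link."""

    matrix: np.ndarray  # (P, A) in {0, 1}, no all-zero row or column
    n_dropped_plants: int = 0
    n_dropped_pollinators: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if m.size and not np.isin(m, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        if m.size and (not m.any(axis=1).all() or not m.any(axis=0).all()):
            raise ValueError("active matrix may not contain all-zero rows or columns")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_links(cls, links: np.ndarray) -> "ActiveMatrix":
        links = np.asarray(links, dtype=np.int8)
        keep_rows = links.any(axis=1)
        keep_cols = links.any(axis=0)
        return cls(
            matrix=links[np.ix_(keep_rows, keep_cols)],
            n_dropped_plants=int((~keep_rows).sum()),
            n_dropped_pollinators=int((~keep_cols).sum()),
        )

    @classmethod
    def from_network(cls, net: CellNetwork) -> "ActiveMatrix":
        return cls.from_links(net.links)

    @property
    def n_plants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pollinators(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_links(self) -> int:
        return int(self.matrix.sum())


def _as_active(M: ActiveMatrix | np.ndarray) -> ActiveMatrix:
    return M if isinstance(M, ActiveMatrix) else ActiveMatrix.from_links(np.asarray(M))


def connectance(M: ActiveMatrix | np.ndarray) -> float | None:
    """Realized fraction of possible links, L / (P * A)."""
    M = _as_active(M)
    if M.n_links == 0:
        return None
    return M.n_links / (M.n_plants * M.n_pollinators)


def web_asymmetry(M: ActiveMatrix | np.ndarray) -> float | None:
    """(A - P) / (A + P): positive = more pollinators, negative = more plants."""
    M = _as_active(M)
    total = M.n_plants + M.n_pollinators
    if total == 0:
        return None
    return (M.n_pollinators - M.n_plants) / total


def links_per_species(M: ActiveMatrix | np.ndarray) -> float | None:
    """Qualitative mean links per species, L / (P + A)."""
    M = _as_active(M)
    total = M.n_plants + M.n_pollinators
    if total == 0:
        return None
    return M.n_links / total


def linkage_density(M: ActiveMatrix | np.ndarray) -> float | None:
    """Quantitative (diversity-weighted) linkage density.

    Each species contributes its effective number of partners 2^H (H the
    Shannon entropy of its interaction weights), weighted by its marginal
    total. For a 0/1 matrix 2^H equals the degree, so the index reduces to
    (sum of squared row degrees + sum of squared column degrees) / (2 L).
    """
    M = _as_active(M)
    L = M.n_links
    if L == 0:
        return None
    row_deg = M.matrix.sum(axis=1).astype(float)
    col_deg = M.matrix.sum(axis=0).astype(float)
    return float((np.sum(row_deg**2) + np.sum(col_deg**2)) / (2.0 * L))


def _nodf_axis_sum(mat: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap terms over all row pairs, and the pair count."""
    n = mat.shape[0]
    fills = mat.sum(axis=1)
    total = 0.0
    for u in range(n):
        for v in range(u + 1, n):
            hi, lo = (u, v) if fills[u] > fills[v] else (v, u)
            if fills[hi] > fills[lo] > 0:
                shared = int(np.minimum(mat[hi], mat[lo]).sum())
                total += 100.0 * shared / fills[lo]
    return total, n * (n - 1) // 2


def nodf(M: ActiveMatrix | np.ndarray) -> float | None:
    """NODF nestedness (0-100): mean paired overlap with decreasing fill.

    For every ordered pair of rows whose fills strictly decrease, the term
    is 100 times the fraction of the poorer row's links shared with the
    richer row; likewise for columns. Pairs with equal fill contribute 0.
    """
    M = _as_active(M)
    P, A = M.matrix.shape
    if P < 2 and A < 2:
        return None
    row_sum, row_pairs = _nodf_axis_sum(M.matrix)
    col_sum, col_pairs = _nodf_axis_sum(M.matrix.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


def weighted_nestedness(M: ActiveMatrix | np.ndarray) -> float | None:
    """Weighted-NODF variant on the interaction weights.

    A pair contributes only when its marginal totals strictly decrease, and
    counts cells where the poorer species interacts with weight no larger
    than the richer species' weight there (0 < w_poor <= w_rich). On 0/1
    matrices this tie rule makes the index coincide with NODF; it is an
    approximation of count-weighted nestedness indices, which degenerate on
    purely binary data.
    """
    M = _as_active(M)
    P, A = M.matrix.shape
    if P < 2 and A < 2:
        return None

    def axis_sum(mat: np.ndarray) -> tuple[float, int]:
        n = mat.shape[0]
        totals = mat.sum(axis=1)
        acc = 0.0
        for u in range(n):
            for v in range(u + 1, n):
                hi, lo = (u, v) if totals[u] > totals[v] else (v, u)
                if totals[hi] > totals[lo] > 0:
                    lo_fill = int((mat[lo] > 0).sum())
                    hits = int(((mat[lo] > 0) & (mat[lo] <= mat[hi])).sum())
                    acc += 100.0 * hits / lo_fill
        return acc, n * (n - 1) // 2

    row_sum, row_pairs = axis_sum(M.matrix)
    col_sum, col_pairs = axis_sum(M.matrix.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


def _pack(mat: np.ndarray) -> np.ndarray:
    """Canonical packing: rows and columns by descending marginal totals,
    marginal ties broken by descending content.

    Because a content tie-break on one axis depends on the ordering of the
    other, the two sorts are alternated until the arrangement stops changing
    (with a cycle guard); the fixed point is independent of the input
    row/column order, which makes the temperature permutation-invariant.
    """
    packed = mat
    seen: set[bytes] = set()
    for _ in range(100):
        key = packed.tobytes()
        if key in seen:
            break
        seen.add(key)
        row_key = sorted(range(packed.shape[0]), key=lambda i: (-packed[i].sum(), tuple(-packed[i])))
        packed = packed[row_key]
        col_key = sorted(range(packed.shape[1]), key=lambda j: (-packed[:, j].sum(), tuple(-packed[:, j])))
        packed = packed[:, col_key]
    return packed


#: Packing searches every arrangement consistent with the marginal sort as
#: long as the number of tie permutations stays below this; beyond it the
#: alternating-sort heuristic packs instead.
_PACK_SEARCH_CAP = 50_000


def _unexpectedness_grid(P: int, A: int, L: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Cell scores, perfect-nestedness membership and isocline boundary for
    a P x A matrix of fill L. Depends only on the shape and fill.
    """
    i = np.arange(P)[:, None]
    j = np.arange(A)[None, :]
    score = (i + 0.5) / P + (j + 0.5) / A  # in (0, 2)
    flat = score.ravel()
    order = np.argsort(flat, kind="stable")
    perfect = np.zeros(P * A, dtype=bool)
    perfect[order[:L]] = True
    if L == 0:
        boundary = 0.0
    elif L == P * A:
        boundary = 2.0
    else:
        boundary = (flat[order[L - 1]] + flat[order[L]]) / 2.0
    return score, perfect.reshape(P, A), boundary


def _mean_unexpectedness(arranged: np.ndarray, score: np.ndarray,
                         perfect: np.ndarray, boundary: float) -> float:
    mismatch = (arranged == 1) != perfect
    u = np.where(mismatch, ((score - boundary) / 2.0) ** 2, 0.0)
    return float(u.mean())


def _tie_groups(marginals: np.ndarray) -> list[list[int]]:
    """Index groups of equal marginal total, in descending-total order."""
    groups: dict[int, list[int]] = {}
    for idx, total in enumerate(marginals):
        groups.setdefault(int(total), []).append(idx)
    return [groups[t] for t in sorted(groups, reverse=True)]


def nestedness_temperature(M: ActiveMatrix | np.ndarray) -> float | None:
    """Matrix temperature: 0 = perfectly nested ("cold"), 100 = disorder.

    Rows and columns are packed by descending marginal totals; every cell is
    scored by its normalized anti-diagonal position s = (i+1/2)/P + (j+1/2)/A
    and the perfectly nested matrix of the observed fill is the set of the L
    lowest-scoring cells, whose score boundary plays the role of the
    isocline. Each presence outside that set and absence inside it
    contributes the squared normalized distance of its score from the
    boundary; T is the mean contribution scaled by the Atmar-Patterson
    constant 100/0.04145 and clamped to [0, 100].

    Packing minimizes the disorder, so arrangements that differ only within
    marginal ties are searched exhaustively for the coldest one — making T
    invariant to row/column permutations of the input. When the tie space
    is too large to enumerate the alternating marginal/content sort packs
    heuristically instead. This is a simplified published-family variant;
    agreement with any particular legacy implementation is not claimed.
    """
    import itertools
    import math as _math

    M = _as_active(M)
    P, A = M.matrix.shape
    if P < 2 or A < 2:
        return None
    mat = M.matrix
    L = int(mat.sum())
    score, perfect, boundary = _unexpectedness_grid(P, A, L)

    row_groups = _tie_groups(mat.sum(axis=1))
    col_groups = _tie_groups(mat.sum(axis=0))
    n_arrangements = 1
    for g in row_groups + col_groups:
        n_arrangements *= _math.factorial(len(g))

    if n_arrangements > _PACK_SEARCH_CAP:
        u = _mean_unexpectedness(_pack(mat), score, perfect, boundary)
        return float(min(100.0, TEMPERATURE_K * u))

    best = np.inf
    for row_perms in itertools.product(*(itertools.permutations(g) for g in row_groups)):
        row_order = [i for perm in row_perms for i in perm]
        by_rows = mat[row_order]
        for col_perms in itertools.product(*(itertools.permutations(g) for g in col_groups)):
            col_order = [j for perm in col_perms for j in perm]
            u = _mean_unexpectedness(by_rows[:, col_order], score, perfect, boundary)
            if u < best:
                best = u
                if best == 0.0:
                    return 0.0
    return float(min(100.0, TEMPERATURE_K * best))


# ---------------------------------------------------------------------------
# Barber bipartite modularity


def barber_q(mat: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber's bipartite modularity for a given module assignment:
    Q = (1/L) * sum_ij (B_ij - k_i d_j / L) [g_i == g_j].
    """
    mat = np.asarray(mat, dtype=float)
    L = mat.sum()
    if L == 0:
        raise ValueError("modularity undefined for an empty matrix")
    btilde = mat - np.outer(mat.sum(axis=1), mat.sum(axis=0)) / L
    q = 0.0
    for lab in np.unique(np.concatenate([row_labels, col_labels])):
        q += btilde[np.ix_(row_labels == lab, col_labels == lab)].sum()
    return float(q / L)


def _propagate(btilde: np.ndarray, row_lab: np.ndarray, col_lab: np.ndarray) -> None:
    """One sweep of label propagation: columns adopt the best row label,
    then rows the best column label; ties go to the smallest label index.
    Operates in place.
    """
    row_labels = np.unique(row_lab)
    for j in range(btilde.shape[1]):
        gains = np.array([btilde[row_lab == lab, j].sum() for lab in row_labels])
        col_lab[j] = row_labels[int(np.argmax(gains))]  # argmax keeps first (smallest) on ties
    col_labels = np.unique(col_lab)
    for i in range(btilde.shape[0]):
        gains = np.array([btilde[i, col_lab == lab].sum() for lab in col_labels])
        row_lab[i] = col_labels[int(np.argmax(gains))]


def _merge_best(btilde: np.ndarray, L: float, row_lab: np.ndarray, col_lab: np.ndarray) -> bool:
    """Greedily merge the module pair with the largest positive Q gain.
    Returns True if a merge happened.
    """
    labels = np.unique(np.concatenate([row_lab, col_lab]))
    best_gain, best_pair = 0.0, None
    for x in range(len(labels)):
        for y in range(x + 1, len(labels)):
            l1, l2 = labels[x], labels[y]
            gain = (
                btilde[np.ix_(row_lab == l1, col_lab == l2)].sum()
                + btilde[np.ix_(row_lab == l2, col_lab == l1)].sum()
            ) / L
            if gain > best_gain + 1e-12:
                best_gain, best_pair = gain, (l1, l2)
    if best_pair is None:
        return False
    l1, l2 = best_pair
    row_lab[row_lab == l2] = l1
    col_lab[col_lab == l2] = l1
    return True


def modularity(
    M: ActiveMatrix | np.ndarray,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[float, tuple[np.ndarray, np.ndarray]] | None:
    """Maximize Barber bipartite modularity by seeded label propagation.

    Each restart initializes rows with their own labels (first restart) or
    a random labelling, alternates row/column label propagation to
    convergence, then greedily merges modules while Q improves. The best
    (Q, (row_labels, col_labels)) over all restarts is returned;
    deterministic for a fixed seed. Returns ``None`` for an empty matrix.
    """
    M = _as_active(M)
    mat = M.matrix.astype(float)
    L = mat.sum()
    if L == 0:
        return None
    P, A = mat.shape
    btilde = mat - np.outer(mat.sum(axis=1), mat.sum(axis=0)) / L

    best_q, best_parts = -np.inf, None
    rng = np.random.default_rng(seed)
    for r in range(max(1, restarts)):
        if r == 0:
            row_lab = np.arange(P)
        else:
            row_lab = rng.integers(0, P, size=P)
        col_lab = np.zeros(A, dtype=int)
        q = -np.inf
        while True:
            _propagate(btilde, row_lab, col_lab)  # monotone coordinate ascent
            while _merge_best(btilde, L, row_lab, col_lab):
                pass
            new_q = barber_q(mat, row_lab, col_lab)
            if new_q <= q + 1e-12:
                q = max(q, new_q)
                break
            q = new_q
        if q > best_q:
            best_q, best_parts = q, (row_lab.copy(), col_lab.copy())
    return best_q, best_parts


# ---------------------------------------------------------------------------
# Secondary-extinction robustness


def _extinction_curve(mat: np.ndarray, removal_order: Iterable[int]) -> float:
    """Trapezoidal area under the survival curve for one removal sequence.

    ``mat`` is oriented so columns are removed; rows survive while they keep
    at least one remaining partner. The curve runs from (0, 1) to (1, y_S).
    """
    remaining = mat.copy().astype(bool)
    n_rows = mat.shape[0]
    S = mat.shape[1]
    ys = [1.0]
    for col in removal_order:
        remaining[:, col] = False
        ys.append(remaining.any(axis=1).sum() / n_rows)
    xs = np.arange(S + 1) / S
    return float(np.trapezoid(ys, xs))


def robustness(
    M: ActiveMatrix | np.ndarray,
    level: Level = "HL",
    order: RemovalOrder = "random",
    reps: int = 100,
    seed: int = 0,
) -> float | None:
    """Area under the secondary-extinction curve.

    Species of ``level`` are removed one at a time; after each removal,
    species at the other level left with no partner are secondarily
    extinct. With ``order='random'`` the result is the mean area over
    ``reps`` seeded uniform removal sequences; ``degree_asc`` /
    ``degree_desc`` remove least- / most-connected species first
    (ties by position). R = 1 means survival until the very end; R = 0.5 is
    the single-link worst case.
    """
    M = _as_active(M)
    if M.n_links == 0:
        return None
    mat = M.matrix if level == "HL" else M.matrix.T  # columns = removal level
    S = mat.shape[1]
    if S == 0:
        return None
    if order == "random":
        rng = np.random.default_rng(seed)
        areas = [_extinction_curve(mat, rng.permutation(S)) for _ in range(reps)]
        return float(np.mean(areas))
    degrees = mat.sum(axis=0)
    sequence = np.argsort(degrees, kind="stable")
    if order == "degree_desc":
        sequence = np.argsort(-degrees, kind="stable")
    return _extinction_curve(mat, sequence)


# ---------------------------------------------------------------------------
# Per-network record and batch averaging


@dataclass(frozen=True)
class MetricsRecord:
    """The 12 network-level metrics; ``None`` marks "not computable"."""

    connectance: float | None
    web_asymmetry: float | None
    links_per_species: float | None
    modularity_q: float | None
    nestedness_temperature: float | None
    nodf: float | None
    weighted_nestedness: float | None
    linkage_density: float | None
    n_species_hl: float | None
    n_species_ll: float | None
    robustness_hl: float | None
    robustness_ll: float | None


METRIC_NAMES = tuple(f.name for f in dataclass_fields(MetricsRecord))


@dataclass(frozen=True)
class MetricsConfig:
    seed: int = 0
    robustness_reps: int = 100
    robustness_order: RemovalOrder = "random"
    modularity_restarts: int = 10


def network_level(net: CellNetwork | np.ndarray, config: MetricsConfig | None = None) -> MetricsRecord:
    """All 12 metrics for one network, with degeneracy rules applied.

    Nestedness indices (temperature, NODF, weighted nestedness) need an
    active matrix of at least 2 x 2; modularity needs at least two species
    and one link; robustness needs at least one removable species. Very
    small networks — e.g. a single plant-pollinator connection — therefore
    yield "not computable" for several fields, and batch averages skip them.
    """
    config = config or MetricsConfig()
    links = net.links if isinstance(net, CellNetwork) else np.asarray(net)
    M = ActiveMatrix.from_links(links)
    P, A = M.n_plants, M.n_pollinators

    nest_ok = P >= 2 and A >= 2
    mod_ok = (P + A) >= 2 and M.n_links >= 1
    mod = modularity(M, seed=config.seed, restarts=config.modularity_restarts) if mod_ok else None

    return MetricsRecord(
        connectance=connectance(M),
        web_asymmetry=web_asymmetry(M) if (P + A) else None,
        links_per_species=links_per_species(M) if (P + A) else None,
        modularity_q=mod[0] if mod is not None else None,
        nestedness_temperature=nestedness_temperature(M) if nest_ok else None,
        nodf=nodf(M) if nest_ok else None,
        weighted_nestedness=weighted_nestedness(M) if nest_ok else None,
        linkage_density=linkage_density(M),
        n_species_hl=float(A) if M.n_links else None,
        n_species_ll=float(P) if M.n_links else None,
        robustness_hl=robustness(M, "HL", config.robustness_order, config.robustness_reps, config.seed),
        robustness_ll=robustness(M, "LL", config.robustness_order, config.robustness_reps, config.seed),
    )


def batch_means(records: list[MetricsRecord]) -> dict[str, dict[str, float | int | None]]:
    """Per-metric mean over the records where the metric was computable.

    Returns {metric: {"mean": value-or-None, "n": count}}; a metric no
    record could compute has mean None and n 0.
    """
    if not records:
        raise ValueError("no records to average")
    out: dict[str, dict[str, float | int | None]] = {}
    for name in METRIC_NAMES:
        values = [getattr(r, name) for r in records if getattr(r, name) is not None]
        out[name] = {"mean": float(np.mean(values)) if values else None, "n": len(values)}
    return out


def metrics_table(nets: CellNetworkSet, config: MetricsConfig | None = None) -> pd.DataFrame:
    """One row of metrics per cell network plus a final 'mean' row.

    The mean row averages each metric over the networks where it was
    computable (its per-metric n is in the 'n_networks' column block of
    :func:`batch_means`); cells are weighted equally.
    """
    from .extraction import cell_csv_name  # local import to avoid cycle at module load

    rows, index, records = [], [], []
    for key in sorted(nets.networks):
        net = nets.networks[key]
        rec = network_level(net, config)
        records.append(rec)
        rows.append({name: getattr(rec, name) for name in METRIC_NAMES})
        index.append(cell_csv_name(net))
    df = pd.DataFrame(rows, index=index, columns=list(METRIC_NAMES))
    if records:
        means = batch_means(records)
        df.loc["mean"] = {name: means[name]["mean"] for name in METRIC_NAMES}
    return df
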