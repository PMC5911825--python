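"""Structure of free-energy surfaces: basins, paths, barriers; TI quadrature.

The "minimum free-energy path" between two basins is implemented as the
minimax (lowest-saddle) path on the grid graph (8-connected in 2D): the path
minimizing the maximum free energy along it. Its arg-max cell is the
transition state, so ΔA_act = A(TS) − A(reactant minimum) is exactly the
lowest saddle height — the quantity an activation free energy needs. Among
equally low-saddle paths the one with the smallest total free energy is
chosen, with lexicographic cell order as the final tie-break, making the
path deterministic.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .fes import FreeEnergySurface

__all__ = [
    "Basin",
    "ReactionPath",
    "LambdaSchedule",
    "ReplicateAggregate",
    "WATERSWAP_LAMBDAS",
    "find_minima",
    "nearest_basin",
    "minimax_path",
    "activation_reaction_energies",
    "profile_delta",
    "ti_integrate",
    "aggregate_replicates",
]


@dataclass
class Basin:
    """A local minimum and its steepest-descent catchment."""

    label: str
    min_cell: tuple[int, ...]
    a_min: float
    cells: list[tuple[int, ...]]
    degenerate: bool = False


def _neighbors(cell, shape):
    if len(shape) == 1:
        (i,) = cell
        for di in (-1, 1):
            j = i + di
            if 0 <= j < shape[0]:
                yield (j,)
    else:
        i, j = cell
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < shape[0] and 0 <= b < shape[1]:
                    yield (a, b)


def find_minima(fes: FreeEnergySurface) -> list[Basin]:
    """Locate local minima and assign every unmasked cell by steepest descent.

    A cell descends to its lowest unmasked neighbour whenever that neighbour
    improves on (value, cell index) lexicographically; plateau cells thus
    merge into the lexicographically smallest cell of the plateau. A fully
    flat surface yields a single basin flagged degenerate.
    """
    values = fes.values
    mask = fes.mask
    shape = values.shape
    unmasked = [tuple(int(i) for i in c) for c in np.argwhere(~mask)]
    if not unmasked:
        raise ValueError("surface has no unmasked cells")

    sink: dict[tuple, tuple] = {}

    def descend(cell):
        trail = []
        while cell not in sink:
            trail.append(cell)
            best = (values[cell], cell)
            for nb in _neighbors(cell, shape):
                if mask[nb]:
                    continue
                cand = (values[nb], nb)
                if cand < best:
                    best = cand
            if best[1] == cell:  # local minimum
                sink[cell] = cell
                break
            cell = best[1]
        root = sink[cell]
        for c in trail:
            sink[c] = root
        return root

    for cell in unmasked:
        descend(cell)

    groups: dict[tuple, list] = {}
    for cell in unmasked:
        groups.setdefault(sink[cell], []).append(cell)

    vals = values[~mask]
    degenerate = bool(np.ptp(vals) == 0) and len(groups) == 1
    basins = []
    for k, (mc, cells) in enumerate(
        sorted(groups.items(), key=lambda kv: (values[kv[0]], kv[0]))
    ):
        basins.append(Basin(f"min{k}", mc, float(values[mc]), sorted(cells), degenerate))
    return basins


def nearest_basin(basins: list[Basin], fes: FreeEnergySurface, point) -> Basin:
    """Basin whose minimum lies nearest (in coordinate space) to ``point``."""
    point = np.atleast_1d(np.asarray(point, dtype=float))

    def coords(cell):
        return np.array([fes.centers[ax][cell[ax]] for ax in range(fes.ndim)])

    return min(basins, key=lambda b: float(np.linalg.norm(coords(b.min_cell) - point)))


@dataclass
class ReactionPath:
    """Ordered adjacent grid cells from reactant to product basin."""

    cells: list[tuple[int, ...]]
    energies: np.ndarray

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)

    @property
    def ts_index(self) -> int:
        return int(np.argmax(self.energies))

    @property
    def ts_cell(self) -> tuple[int, ...]:
        return self.cells[self.ts_index]

    @property
    def max_energy(self) -> float:
        return float(self.energies.max())


def _cell_of(basin_or_cell):
    return basin_or_cell.min_cell if isinstance(basin_or_cell, Basin) else tuple(basin_or_cell)


def minimax_path(fes: FreeEnergySurface, start, end) -> ReactionPath:
    """Lowest-saddle path between two basins (or explicit cells).

    Phase 1 finds the minimax level L by Dijkstra on the bottleneck
    objective; phase 2 finds, within the sublevel set {A ≤ L}, the path of
    minimal total energy (lexicographic cell order breaking residual ties).
    Raises if the basins are separated by masked cells.
    """
    start = _cell_of(start)
    end = _cell_of(end)
    values = fes.values
    mask = fes.mask
    shape = values.shape
    if mask[start] or mask[end]:
        raise ValueError("start/end cell is masked")
    if start == end:
        return ReactionPath([start], np.array([values[start]]))

    # phase 1: bottleneck Dijkstra
    best = {start: values[start]}
    heap = [(values[start], start)]
    level = None
    while heap:
        b, cell = heapq.heappop(heap)
        if cell == end:
            level = b
            break
        if b > best.get(cell, np.inf):
            continue
        for nb in _neighbors(cell, shape):
            if mask[nb]:
                continue
            nb_b = max(b, values[nb])
            if nb_b < best.get(nb, np.inf):
                best[nb] = nb_b
                heapq.heappush(heap, (nb_b, nb))
    if level is None:
        raise ValueError("basins are disconnected through unmasked cells")

    # phase 2: min-total-energy path within the sublevel set; the cell
    # index in the heap key makes tie-breaking deterministic (smaller cells
    # settle first and are never re-parented)
    allowed = (~mask) & (values <= level + 1e-12)
    dist = {start: values[start]}
    prev: dict[tuple, tuple] = {}
    settled: set[tuple] = set()
    heap = [(values[start], start)]
    while heap:
        d, cell = heapq.heappop(heap)
        if cell in settled:
            continue
        settled.add(cell)
        if cell == end:
            break
        for nb in _neighbors(cell, shape):
            if not allowed[nb] or nb in settled:
                continue
            nd = d + values[nb]
            if nd < dist.get(nb, np.inf):
                dist[nb] = nd
                prev[nb] = cell
                heapq.heappush(heap, (nd, nb))

    cells = [end]
    while cells[-1] != start:
        cells.append(prev[cells[-1]])
    cells.reverse()
    return ReactionPath(cells, values[tuple(np.array(cells).T)])


def activation_reaction_energies(fes: FreeEnergySurface, path: ReactionPath) -> dict:
    """ΔA_act = A(TS) − A(start), ΔA_reac = A(end) − A(start), kcal/mol."""
    a_start = float(path.energies[0])
    a_end = float(path.energies[-1])
    return {
        "delta_a_act": path.max_energy - a_start,
        "delta_a_reac": a_end - a_start,
        "ts_cell": path.ts_cell,
        "a_ts": path.max_energy,
    }


def profile_delta(fes: FreeEnergySurface, interval_a, interval_b) -> float:
    """Free-energy difference A(min in B) − A(min in A) of a 1D profile.

    ``interval_a``/``interval_b`` are coordinate intervals (lo, hi) that must
    each contain a local minimum of the profile.
    """
    if fes.ndim != 1:
        raise ValueError("profile_delta expects a 1D surface")
    basins = find_minima(fes)
    x = fes.centers[0]

    def pick(interval, name):
        lo, hi = sorted(interval)
        found = [b for b in basins if lo <= x[b.min_cell[0]] <= hi and not b.degenerate]
        if not found:
            raise ValueError(f"no free-energy minimum inside interval {name}={interval}")
        return min(found, key=lambda b: b.a_min)

    return pick(interval_b, "B").a_min - pick(interval_a, "A").a_min


# ---------------------------------------------------------------------------
# Thermodynamic integration & replicate statistics
# ---------------------------------------------------------------------------

#: The 16-point λ schedule used for water-swap thermodynamic integration.
WATERSWAP_LAMBDAS = (
    0.005, 0.071, 0.137, 0.203, 0.269, 0.335, 0.401, 0.467,
    0.533, 0.599, 0.665, 0.731, 0.797, 0.863, 0.929, 0.995,
)


@dataclass(frozen=True)
class LambdaSchedule:
    """Strictly increasing coupling-parameter values in the open (0, 1)."""

    values: tuple[float, ...]

    def __post_init__(self):
        v = tuple(float(x) for x in self.values)
        if len(v) < 2:
            raise ValueError("schedule needs at least two lambda values")
        if not all(0.0 < a < 1.0 for a in v) or any(
            b <= a for a, b in zip(v, v[1:])
        ):
            raise ValueError("lambdas must be strictly increasing within (0, 1)")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)

    @classmethod
    def from_text(cls, text: str) -> "LambdaSchedule":
        """Parse a printed λ list such as ``"0.005, 0.071, 0.137"``."""
        toks = text.replace("(", " ").replace(")", " ").replace(",", " ").split()
        return cls(tuple(float(t) for t in toks))


def ti_integrate(
    schedule: LambdaSchedule,
    gradients,
    burn_in_fraction: float = 1.0 / 3.0,
    extrapolate: bool = False,
) -> float:
    """Trapezoidal TI estimate ΔA = ∫⟨dU/dλ⟩ dλ over the sampled λ range.

    ``gradients`` holds one gradient series (or a scalar mean) per λ; the
    first ``burn_in_fraction`` of each series is discarded before averaging
    (default 1/3, i.e. the first 10M of 30M MC moves). With
    ``extrapolate=True`` the end gradients are constantly extended to λ=0
    and λ=1; default integrates only [λ₁, λₙ].
    """
    lam = np.asarray(schedule.values)
    if len(gradients) != len(lam):
        raise ValueError(
            f"schedule has {len(lam)} lambdas but {len(gradients)} gradient series"
        )
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    means = np.empty(len(lam))
    for i, g in enumerate(gradients):
        g = np.atleast_1d(np.asarray(g, dtype=float))
        start = int(np.floor(burn_in_fraction * len(g)))
        means[i] = g[start:].mean()
    val = float(np.trapezoid(means, lam))
    if extrapolate:
        val += float(means[0] * lam[0] + means[-1] * (1.0 - lam[-1]))
    return val


@dataclass
class ReplicateAggregate:
    """Mean ± spread over independent replicate estimates."""

    values: np.ndarray
    mean: float
    sd: float
    sem: float
    n: int
    single: bool = field(default=False)

    @property
    def spread(self) -> float:
        return self.sd  # SD and SEM both retained; pick via mode upstream


def aggregate_replicates(values, mode: str = "SEM") -> ReplicateAggregate:
    """Mean with SD (n−1 denominator) and SEM = SD/√n of replicate values.

    ``mode`` selects which spread a caller reports; both are stored. A single
    value yields SD = SEM = 0 with the ``single`` flag set.
    """
    if mode not in ("SD", "SEM"):
        raise ValueError("mode must be 'SD' or 'SEM'")
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty list of replicates")
    n = values.size
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return ReplicateAggregate(
        values, float(values.mean()), sd, sd / np.sqrt(n), n, single=(n == 1)
    )
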