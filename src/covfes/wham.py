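"""Weighted histogram analysis method (WHAM) for 1D/2D umbrella sampling.

One solver covers both dimensionalities: biased window samples are
histogrammed on a shared grid (left-closed, right-open bins) and the
standard self-consistent WHAM equations are solved for the unbiased bin
probabilities p_j and per-window free-energy offsets f_i:

    p_j ∝ M_j / Σ_i N_i exp[(f_i − c_ij)/k_BT]
    exp(−f_i/k_BT) = Σ_j p_j exp(−c_ij/k_BT)

with M_j the pooled counts, N_i the window sample counts and c_ij the bias
energy of window i at bin center j. For speed the equivalent convex
objective (Zhu & Hummer, J. Comput. Chem. 2012) is minimized first with
L-BFGS, then the fixed-point iteration is applied until the maximum offset
change falls below the requested tolerance, which is what the converged
flag reports. The free-energy surface is A_j = −k_BT ln p_j referenced to
its minimum; bins that received no samples are masked, never padded with
pseudo-counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import kt
from .fes import FreeEnergySurface
from .windows import GridSpec, HarmonicBias, UmbrellaWindow

__all__ = [
    "BinGrid",
    "HistogramGrid",
    "WhamResult",
    "default_bins_from_grid",
    "histogram",
    "wham",
    "wham_bootstrap",
    "window_overlap",
    "normality_report",
    "convergence_blocks",
]


@dataclass(frozen=True)
class BinGrid:
    """Per-axis strictly increasing bin edges; bins are [left, right)."""

    edges: tuple[np.ndarray, ...]

    def __post_init__(self):
        edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        for e in edges:
            if len(e) < 2 or np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing, >= 2 edges")
        object.__setattr__(self, "edges", edges)

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)


def default_bins_from_grid(spec_x: GridSpec, spec_y: GridSpec | None = None, refine: int = 3) -> BinGrid:
    """Histogram grid from the window ladder, refined ``refine``× per axis,
    extended half a window step beyond the extreme centers.

    The 3× default keeps the harmonic-bias energy variation across a bin
    well below k_BT for the canonical k = 100 kcal/mol/A^2 ladders; coarser
    bins noticeably bias the bin-center bias-energy approximation.
    """

    def axis_edges(spec: GridSpec) -> np.ndarray:
        step = abs(spec.step)
        lo = min(spec.start, spec.stop) - step / 2
        n_bins = (spec.count) * refine
        return lo + (step / refine) * np.arange(n_bins + 1)

    if spec_y is None:
        return BinGrid((axis_edges(spec_x),))
    return BinGrid((axis_edges(spec_x), axis_edges(spec_y)))


@dataclass
class HistogramGrid:
    """Counts on a :class:`BinGrid` plus out-of-range bookkeeping."""

    bins: BinGrid
    counts: np.ndarray  # float to allow weighted counts
    total_in_range: float
    out_of_range: float


def _bin_indices(samples: np.ndarray, bins: BinGrid):
    """Flat bin index per sample, −1 for out-of-range (left-closed rule)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float).T).T
    idx = np.zeros(samples.shape[0], dtype=np.int64)
    in_range = np.ones(samples.shape[0], dtype=bool)
    for axis, edges in enumerate(bins.edges):
        k = np.searchsorted(edges, samples[:, axis], side="right") - 1
        in_range &= (k >= 0) & (k < len(edges) - 1)
        idx = idx * (len(edges) - 1) + np.clip(k, 0, len(edges) - 2)
    idx[~in_range] = -1
    return idx, in_range


def histogram(samples, bins: BinGrid, weights=None) -> HistogramGrid:
    """Histogram samples (array (n,) / (n, d) or an :class:`UmbrellaWindow`).

    Counts conserve: sum(counts) + out_of_range == total weight supplied.
    """
    if isinstance(samples, UmbrellaWindow):
        weights = samples.weights if weights is None else weights
        samples = samples.samples
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot histogram an empty series")
    idx, in_range = _bin_indices(samples, bins)
    n_flat = int(np.prod(bins.shape))
    if weights is None:
        counts = np.bincount(idx[in_range], minlength=n_flat).astype(float)
        out = float(np.count_nonzero(~in_range))
    else:
        weights = np.asarray(weights, dtype=float)
        counts = np.bincount(idx[in_range], weights=weights[in_range], minlength=n_flat)
        out = float(weights[~in_range].sum())
    return HistogramGrid(bins, counts.reshape(bins.shape), float(counts.sum()), out)


@dataclass
class WhamResult:
    """Solved WHAM problem: surface, window offsets and iteration record."""

    fes: FreeEnergySurface
    offsets: np.ndarray  # f_i, kcal/mol, gauge f_0 = 0
    iterations: int
    converged: bool
    tolerance: float
    out_of_range: float = 0.0


def _log_bias_weights(windows, bins: BinGrid, beta: float) -> np.ndarray:
    """log Boltzmann weight of each window's bias at every bin center.

    The bias energy is evaluated at bin centers, which is accurate when the
    bias varies by well under k_BT across a bin — the reason the default
    binning refines the window ladder 3× per axis (see
    :func:`default_bins_from_grid`).
    """
    centers = bins.centers()
    if bins.ndim == 1:
        pts = centers[0]
    else:
        gx, gy = np.meshgrid(centers[0], centers[1], indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
    return np.stack([-beta * w.bias.energy(pts).ravel() for w in windows])


def wham(
    windows: list[UmbrellaWindow],
    bins: BinGrid | None = None,
    temperature: float | None = None,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
    use_lbfgs_start: bool = True,
) -> WhamResult:
    """Solve the WHAM equations for a set of umbrella windows.

    ``tolerance`` is on the max per-iteration change of any offset f_i in
    kcal/mol. Exceeding ``max_iter`` returns a result flagged unconverged.
    """
    if len(windows) == 0:
        raise ValueError("wham requires at least one window")
    if temperature is None:
        temperature = windows[0].temperature
    if bins is None:
        raise ValueError("a BinGrid is required (see default_bins_from_grid)")
    beta = 1.0 / kt(temperature)

    n_flat = int(np.prod(bins.shape))
    m = np.zeros(n_flat)
    n_i = np.zeros(len(windows))
    out_of_range = 0.0
    for i, w in enumerate(windows):
        h = histogram(w, bins)
        if h.total_in_range == 0:
            raise ValueError(
                f"window {i} (center {w.bias.center}) has no samples on the grid"
            )
        m += h.counts.ravel()
        n_i[i] = h.total_in_range
        out_of_range += h.out_of_range

    populated = m > 0
    mp = m[populated]
    log_b = _log_bias_weights(windows, bins, beta)[:, populated]
    b = np.exp(log_b)  # (nwin, npop); underflow to 0 is harmless

    g = np.zeros(len(windows))  # g_i = beta * f_i

    def p_hat(g):
        denom = (n_i * np.exp(g)) @ b
        return mp / denom

    iterations = 0
    if use_lbfgs_start and len(windows) > 1:
        # convex WHAM objective in the offsets, gauge g_0 = 0
        def objective(gfree):
            gg = np.concatenate([[0.0], gfree])
            w_i = n_i * np.exp(gg)
            denom = w_i @ b
            val = -np.dot(n_i, gg) + np.dot(mp, np.log(denom))
            grad_full = -n_i + w_i * (b @ (mp / denom))
            return val, grad_full[1:]

        res = optimize.minimize(
            objective,
            np.zeros(len(windows) - 1),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
        )
        g = np.concatenate([[0.0], res.x])
        iterations += int(res.nit)

    converged = False
    for _ in range(max_iter):
        iterations += 1
        p = p_hat(g)
        z = b @ (p / p.sum())
        g_new = -np.log(z)
        g_new -= g_new[0]
        delta = np.max(np.abs(g_new - g)) / beta
        g = g_new
        if delta <= tolerance:
            converged = True
            break

    p = p_hat(g)
    p /= p.sum()
    values = np.full(n_flat, np.nan)
    values[populated] = -np.log(p) / beta
    mask = ~populated
    fes = FreeEnergySurface(
        bins.centers(), values.reshape(bins.shape), mask.reshape(bins.shape), temperature
    ).min_referenced()
    offsets = g / beta
    return WhamResult(fes, offsets, iterations, converged, tolerance, out_of_range)


def wham_bootstrap(
    windows,
    bins,
    n_boot: int = 50,
    seed: int = 0,
    temperature: float | None = None,
    **wham_kwargs,
):
    """Bayesian bootstrap over per-window sample weights.

    Each resample draws Dirichlet(1,…,1) weights for every window's samples
    and re-solves WHAM. Returns (mean_A, sd_A) arrays over resamples, with
    NaN where a bin was masked in any resample.
    """
    rng = np.random.default_rng(seed)
    stack = []
    for _ in range(n_boot):
        resampled = []
        for w in windows:
            weights = rng.dirichlet(np.ones(w.n_samples)) * w.n_samples
            resampled.append(
                UmbrellaWindow(w.bias, w.samples, w.temperature, weights=weights)
            )
        r = wham(resampled, bins, temperature=temperature, **wham_kwargs)
        a = np.where(r.fes.mask, np.nan, r.fes.values)
        stack.append(a)
    stack = np.stack(stack)
    return np.nanmean(stack, axis=0), np.nanstd(stack, axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def window_overlap(windows, bins: BinGrid, threshold: float = 0.03):
    """Pairwise histogram overlap coefficients.

    The overlap of two windows is Σ_j min(ĥ_i, ĥ_j) of their normalized
    histograms, in [0, 1]. The report lists nearest-neighbour window pairs
    (by bias-center distance) whose overlap falls below ``threshold``.
    """
    if len(windows) < 2:
        raise ValueError("overlap needs at least two windows")
    hists = []
    for w in windows:
        h = histogram(w, bins)
        hists.append(h.counts.ravel() / h.total_in_range)
    hists = np.stack(hists)
    nwin = len(windows)
    overlap = np.zeros((nwin, nwin))
    for i in range(nwin):
        overlap[i, i:] = np.minimum(hists[i], hists[i:]).sum(axis=1)
        overlap[i:, i] = overlap[i, i:]

    centers = np.array([w.bias.center for w in windows])
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    adj_dist = d.min() * 1.001
    flagged = [
        (i, j, float(overlap[i, j]))
        for i in range(nwin)
        for j in range(i + 1, nwin)
        if d[i, j] <= adj_dist and overlap[i, j] < threshold
    ]
    return overlap, {
        "threshold": threshold,
        "n_adjacent_pairs": int((np.triu(d <= adj_dist, 1)).sum()),
        "flagged_pairs": flagged,
    }


def normality_report(windows, alpha: float = 0.05, max_points: int = 4096) -> pd.DataFrame:
    """Shapiro–Wilk normality check of each window's sampled coordinate(s).

    Series longer than ``max_points`` are thinned evenly before testing (the
    W statistic loses meaning for very large n). Returns one row per window
    per biased coordinate with the statistic, p-value and pass flag at
    ``alpha``; the frame carries the overall pass fraction in ``.attrs``.
    """
    rows = []
    for i, w in enumerate(windows):
        samples = np.atleast_2d(w.samples.T).T
        if samples.shape[0] < 8:
            raise ValueError(
                f"window {i} (center {w.bias.center}) has only "
                f"{samples.shape[0]} samples; need >= 8 for a normality test"
            )
        for axis, name in enumerate(w.bias.coordinate):
            x = samples[:, axis]
            if len(x) > max_points:
                x = x[:: int(np.ceil(len(x) / max_points))]
            stat, p = stats.shapiro(x)
            rows.append(
                {
                    "window": i,
                    "coordinate": name,
                    "center": w.bias.center[axis],
                    "statistic": float(stat),
                    "p_value": float(p),
                    "passed": bool(p >= alpha),
                }
            )
    frame = pd.DataFrame(rows)
    frame.attrs["alpha"] = alpha
    frame.attrs["pass_fraction"] = float(frame["passed"].mean())
    return frame


def convergence_blocks(
    windows,
    block_ends,
    extractor,
    bins: BinGrid | None = None,
    temperature: float | None = None,
    **wham_kwargs,
):
    """Re-run WHAM on windows truncated at each block end-point.

    ``block_ends`` are increasing sample counts; ``extractor`` maps a
    :class:`WhamResult` to a scalar (e.g. the activation free energy). The
    summary mirrors time-block convergence reporting: the final value is the
    mean ± SD (n−1) of the per-block estimates.
    """
    block_ends = [int(b) for b in block_ends]
    if any(b <= 0 for b in block_ends):
        raise ValueError("block end-points must be positive")
    if sorted(block_ends) != block_ends or len(set(block_ends)) != len(block_ends):
        raise ValueError("block end-points must be strictly increasing")
    n_min = min(w.n_samples for w in windows)
    if block_ends[-1] > n_min:
        raise ValueError(
            f"block end {block_ends[-1]} exceeds shortest window ({n_min} samples)"
        )
    values = []
    for end in block_ends:
        truncated = [w.truncated(end) for w in windows]
        result = wham(truncated, bins, temperature=temperature, **wham_kwargs)
        values.append(float(extractor(result)))
    values = np.asarray(values)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return {
        "block_ends": block_ends,
        "values": values,
        "mean": float(values.mean()),
        "sd": sd,
    }
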