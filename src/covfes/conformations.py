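"""Conformational statistics from unbiased-trajectory feature tables.

Implements the Boltzmann-inversion free-energy surface over the (S–Cβ
distance, C1–C2–N1–C3 dihedral) plane, A(r) = −k_BT ln P(r), built from
pooled replica snapshots, plus reactive-conformation fractions (distance
strictly below the van-der-Waals contact cutoff, 3.9 Å by default),
state-occupancy bookkeeping, basin free-energy gaps, distance–dihedral
coupling and H-bond occupancy.

Dihedral binning: the nominal −160°…+160° span is not an integer multiple
of the 15° class width. The default keeps the class width exact — 21 bins
of 15° centered on multiples of 15°, spanning [−157.5°, +157.5°) — and
counts anything outside as out-of-range; ``BinSpec2D(dihedral_mode="exact")``
instead spans −160…+160 exactly with 21 slightly wider (≈15.24°) classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_TEMPERATURE, kt
from .fes import FreeEnergySurface
from .wham import BinGrid, histogram

__all__ = [
    "BinSpec2D",
    "StateDefinition",
    "ReactiveStats",
    "pool_features",
    "boltzmann_fes",
    "reactive_fraction",
    "assign_states",
    "basin_delta",
    "coupling_report",
    "hbond_occupancy",
    "STATE_A",
    "STATE_B",
]

DISTANCE_COL = "s_cb_distance"
DIHEDRAL_COL = "dihedral"
HBOND_COL = "hbond_distance"


@dataclass(frozen=True)
class BinSpec2D:
    """Histogram classes for the (distance, dihedral) plane."""

    distance_start: float = 2.5
    distance_stop: float = 9.5
    distance_width: float = 0.1
    dihedral_start: float = -160.0
    dihedral_stop: float = 160.0
    dihedral_width: float = 15.0
    dihedral_mode: str = "centered"  # or "exact"

    def __post_init__(self):
        if self.distance_width <= 0 or self.dihedral_width <= 0:
            raise ValueError("class widths must be positive")
        if self.distance_stop <= self.distance_start or self.dihedral_stop <= self.dihedral_start:
            raise ValueError("stop must exceed start")
        if self.dihedral_mode not in ("centered", "exact"):
            raise ValueError("dihedral_mode must be 'centered' or 'exact'")

    def grid(self) -> BinGrid:
        n_d = int(round((self.distance_stop - self.distance_start) / self.distance_width))
        d_edges = self.distance_start + self.distance_width * np.arange(n_d + 1)
        span = self.dihedral_stop - self.dihedral_start
        n_a = int(round(span / self.dihedral_width))
        if self.dihedral_mode == "centered":
            # exact 15-degree classes centered on multiples of the width
            lo = (
                np.floor(self.dihedral_start / self.dihedral_width) * self.dihedral_width
                + self.dihedral_width / 2
            )
            n_a = int(round((self.dihedral_stop - self.dihedral_width / 2 - lo) / self.dihedral_width))
            a_edges = lo + self.dihedral_width * np.arange(n_a + 1)
        else:
            a_edges = np.linspace(self.dihedral_start, self.dihedral_stop, n_a + 1)
        return BinGrid((d_edges, a_edges))


#: Reactive-conformation state: dihedral −55° ± 20°, short S–Cβ distance.
STATE_A = None  # assigned after StateDefinition is defined
STATE_B = None


@dataclass(frozen=True)
class StateDefinition:
    """A labelled region of (dihedral, optional distance) space."""

    label: str
    dihedral_interval: tuple[float, float]
    distance_interval: tuple[float, float] | None = None

    def __post_init__(self):
        lo, hi = self.dihedral_interval
        if hi <= lo:
            raise ValueError(f"empty dihedral interval for state {self.label!r}")
        if self.distance_interval is not None:
            dlo, dhi = self.distance_interval
            if dhi <= dlo:
                raise ValueError(f"empty distance interval for state {self.label!r}")

    def contains(self, dihedral, distance) -> np.ndarray:
        lo, hi = self.dihedral_interval
        ok = (np.asarray(dihedral) >= lo) & (np.asarray(dihedral) <= hi)
        if self.distance_interval is not None:
            dlo, dhi = self.distance_interval
            ok &= (np.asarray(distance) >= dlo) & (np.asarray(distance) <= dhi)
        return ok

    def overlaps(self, other: "StateDefinition") -> bool:
        a0, a1 = self.dihedral_interval
        b0, b1 = other.dihedral_interval
        if a1 <= b0 or b1 <= a0:
            return False
        if self.distance_interval is None or other.distance_interval is None:
            return True
        c0, c1 = self.distance_interval
        d0, d1 = other.distance_interval
        return not (c1 <= d0 or d1 <= c0)


STATE_A = StateDefinition("a", (-75.0, -35.0), (2.5, 4.5))
STATE_B = StateDefinition("b", (90.0, 130.0), (4.5, 7.5))


def pool_features(series_list) -> pd.DataFrame:
    """Concatenate replica feature tables, preserving replica ids."""
    if not series_list:
        raise ValueError("nothing to pool")
    cols = list(series_list[0].columns)
    for i, s in enumerate(series_list[1:], start=1):
        if list(s.columns) != cols:
            raise ValueError(
                f"series {i} columns {list(s.columns)} differ from {cols}"
            )
    return pd.concat(series_list, ignore_index=True)


def boltzmann_fes(
    features: pd.DataFrame,
    bins: BinSpec2D | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    distance_col: str = DISTANCE_COL,
    dihedral_col: str = DIHEDRAL_COL,
) -> FreeEnergySurface:
    """Boltzmann inversion A = −k_BT ln P of the 2D conformational histogram.

    P is normalized over in-range counts; empty classes are masked; the
    out-of-range tally is recorded in ``fes.meta``.
    """
    bins = bins or BinSpec2D()
    grid = bins.grid()
    samples = features[[distance_col, dihedral_col]].to_numpy(dtype=float)
    h = histogram(samples, grid)
    if h.total_in_range == 0:
        raise ValueError("all samples fall outside the histogram range")
    p = h.counts / h.total_in_range
    with np.errstate(divide="ignore"):
        a = -kt(temperature) * np.log(p)
    mask = h.counts == 0
    fes = FreeEnergySurface(grid.centers(), np.where(mask, np.nan, a), mask, temperature)
    fes = fes.min_referenced()
    fes.meta["out_of_range"] = h.out_of_range
    fes.meta["n_in_range"] = h.total_in_range
    return fes


@dataclass
class ReactiveStats:
    """Reactive-conformation counts below the contact cutoff."""

    cutoff: float
    per_replica: pd.DataFrame  # columns: replica, n_reactive, n_total, fraction
    pooled_count: int
    pooled_total: int

    @property
    def pooled_fraction(self) -> float:
        return self.pooled_count / self.pooled_total


def reactive_fraction(
    features: pd.DataFrame,
    cutoff: float = 3.9,
    distance_col: str = DISTANCE_COL,
) -> ReactiveStats:
    """Fraction of snapshots with distance strictly below ``cutoff`` (Å).

    Exact integer counts are kept per replica and pooled; the pooled count
    equals the sum of per-replica counts by construction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if features.empty:
        raise ValueError("empty feature table")
    d = features[distance_col].to_numpy(dtype=float)
    reactive = d < cutoff  # strict: "smaller than" the vdW contact distance
    per = (
        pd.DataFrame({"replica": features["replica"].to_numpy(), "reactive": reactive})
        .groupby("replica")
        .agg(n_reactive=("reactive", "sum"), n_total=("reactive", "size"))
        .reset_index()
    )
    per["fraction"] = per["n_reactive"] / per["n_total"]
    return ReactiveStats(
        cutoff, per, int(reactive.sum()), int(len(reactive))
    )


def assign_states(
    features: pd.DataFrame,
    definitions=(STATE_A, STATE_B),
    distance_col: str = DISTANCE_COL,
    dihedral_col: str = DIHEDRAL_COL,
):
    """Label every record by the first matching state definition.

    Definitions must be pairwise non-overlapping; unmatched records get
    ``"other"``. Returns (labels Series, occupancy table per replica with a
    pooled row).
    """
    definitions = list(definitions)
    labels_set = [d.label for d in definitions]
    if len(set(labels_set)) != len(labels_set):
        raise ValueError("state labels must be unique")
    for i, a in enumerate(definitions):
        for b in definitions[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"state definitions {a.label!r} and {b.label!r} overlap")
    dihe = features[dihedral_col].to_numpy(dtype=float)
    dist = features[distance_col].to_numpy(dtype=float)
    labels = np.full(len(features), "other", dtype=object)
    for d in definitions:
        hit = d.contains(dihe, dist) & (labels == "other")
        labels[hit] = d.label
    labels = pd.Series(labels, index=features.index, name="state_label")

    occ_rows = []
    all_labels = labels_set + ["other"]
    for rep, grp in labels.groupby(features["replica"].to_numpy()):
        counts = grp.value_counts()
        row = {"replica": rep, "n": len(grp)}
        for lab in all_labels:
            row[lab] = counts.get(lab, 0) / len(grp)
        occ_rows.append(row)
    pooled = {"replica": "pooled", "n": len(labels)}
    counts = labels.value_counts()
    for lab in all_labels:
        pooled[lab] = counts.get(lab, 0) / len(labels)
    occ_rows.append(pooled)
    return labels, pd.DataFrame(occ_rows)


def basin_delta(p_a: float, p_b: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Free-energy gap ΔA(a→b) = −k_BT ln(P_b/P_a), kcal/mol.

    Negative means b is more stable. Antisymmetric under swapping a and b.
    """
    if p_a <= 0 or p_b <= 0:
        raise ValueError(
            "both states need nonzero population; sample longer trajectories"
        )
    return float(-kt(temperature) * np.log(p_b / p_a))


def coupling_report(
    features: pd.DataFrame,
    definitions=(STATE_A, STATE_B),
    distance_col: str = DISTANCE_COL,
    dihedral_col: str = DIHEDRAL_COL,
    midline: float = 4.5,
    lag: int = 5,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Quantify distance–dihedral coupling.

    Returns the point-biserial correlation between the distance and the
    binary dihedral-state label (records labelled by ``definitions``; the
    unmatched remainder is dropped), a permutation p-value for it, and the
    fraction of state switches at which the distance series crosses the
    ``midline`` within ±``lag`` snapshots of the switch (per replica, using
    time order).
    """
    if len(features) < 2:
        raise ValueError("need at least two records")
    # the binary label must reflect the dihedral state alone: distance
    # constraints in the definitions would correlate with the distance
    # mechanically and inflate r
    dihedral_only = tuple(
        StateDefinition(d.label, d.dihedral_interval) for d in definitions
    )
    labels, _ = assign_states(features, dihedral_only, distance_col, dihedral_col)
    lab_a, lab_b = definitions[0].label, definitions[1].label
    use = labels.isin([lab_a, lab_b]).to_numpy()
    if labels[use].nunique() < 2:
        raise ValueError("correlation undefined: only one state populated")
    binary = (labels[use] == lab_b).to_numpy(dtype=float)
    dist = features.loc[use, distance_col].to_numpy(dtype=float)
    r, p_param = stats.pointbiserialr(binary, dist)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(binary)
        r_perm, _ = stats.pointbiserialr(perm, dist)
        if abs(r_perm) >= abs(r):
            exceed += 1
    p_perm = (exceed + 1) / (n_permutations + 1)

    state_col = "state" if "state" in features.columns else None
    switches = 0
    co_occur = 0
    for _, grp in features.groupby("replica"):
        if state_col is not None:
            seq = grp[state_col].to_numpy()
        else:
            seq = labels.loc[grp.index].to_numpy()
        d = grp[distance_col].to_numpy(dtype=float)
        above = d > midline
        switch_idx = np.flatnonzero(seq[1:] != seq[:-1]) + 1
        for t in switch_idx:
            lo = max(t - lag, 0)
            hi = min(t + lag + 1, len(d))
            if above[lo:hi].min() != above[lo:hi].max():  # crosses the midline
                co_occur += 1
        switches += len(switch_idx)
    return {
        "point_biserial_r": float(r),
        "permutation_p": float(p_perm),
        "n_records_used": int(use.sum()),
        "n_switches": int(switches),
        "switch_crossing_fraction": co_occur / switches if switches else float("nan"),
        "midline": midline,
        "lag": lag,
    }


def hbond_occupancy(
    features: pd.DataFrame,
    hbond_col: str = HBOND_COL,
    cutoff: float = 3.5,
) -> dict:
    """Fraction of records with H-bond distance ≤ cutoff (heavy-atom, Å)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if features.empty:
        raise ValueError("empty feature table")
    bonded = features[hbond_col].to_numpy(dtype=float) <= cutoff
    per = {}
    for rep, grp in features.groupby("replica"):
        b = grp[hbond_col].to_numpy(dtype=float) <= cutoff
        per[rep] = float(b.mean())
    return {"per_replica": per, "pooled": float(bonded.mean()), "cutoff": cutoff}
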