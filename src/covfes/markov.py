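"""Two-state Markov trajectories with Gaussian emissions.

Emulates the two conformational states seen in unbiased simulations of the
non-covalent kinase–inhibitor complex: a reactive state *a* (warhead Cβ
close to the cysteine sulfur, acrylamide dihedral near −55°) and an
unreactive state *b* (long S–Cβ distance, dihedral rotated to +100…+120°,
and — in the L718Q-like preset — a short Gln718 H-bond that stabilizes it).
The hidden state is advanced as a first-order Markov chain per snapshot;
per-state Gaussian emissions produce the S–Cβ distance, the C1–C2–N1–C3
dihedral (wrapped into (−180°, 180°]) and an H-bond distance. The hidden
state label is kept in the output so estimators can be checked against
exact count oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kt

__all__ = [
    "TwoStateModel",
    "make_two_state_trajectory",
    "make_two_state_ensemble",
    "t790m_like_model",
    "l718q_like_model",
]

#: Column names emitted for each per-state (mean, sd) pair.
EMISSION_COLUMNS = ("s_cb_distance", "dihedral", "hbond_distance")


@dataclass(frozen=True)
class TwoStateModel:
    """Hidden two-state chain with per-state Gaussian emissions.

    ``p_ab``/``p_ba`` are per-step switch probabilities a→b and b→a;
    ``emissions_a``/``emissions_b`` map column name → (mean, sd). The
    stationary occupancy of state a is p_ba/(p_ab+p_ba) (NaN when both
    switch probabilities vanish — the chain then never leaves its start
    state).
    """

    p_ab: float
    p_ba: float
    emissions_a: dict = field(
        default_factory=lambda: {
            "s_cb_distance": (3.5, 0.4),
            "dihedral": (-55.0, 15.0),
            "hbond_distance": (5.5, 0.8),
        }
    )
    emissions_b: dict = field(
        default_factory=lambda: {
            "s_cb_distance": (5.5, 0.6),
            "dihedral": (110.0, 10.0),
            "hbond_distance": (6.0, 1.0),
        }
    )
    n_replicas: int = 4
    n_samples: int = 30_000
    dt_ps: float = 10.0  # 300 ns / 30 000 snapshots
    start_state: str = "stationary"  # "a", "b", or "stationary"

    def __post_init__(self):
        for p, name in ((self.p_ab, "p_ab"), (self.p_ba, "p_ba")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for emis in (self.emissions_a, self.emissions_b):
            if set(emis) != set(EMISSION_COLUMNS):
                raise ValueError(f"emissions must define exactly {EMISSION_COLUMNS}")
            for col, (_, sd) in emis.items():
                if sd <= 0:
                    raise ValueError(f"emission SD for {col!r} must be > 0")
        if self.start_state not in ("a", "b", "stationary"):
            raise ValueError("start_state must be 'a', 'b' or 'stationary'")
        if self.n_replicas < 1 or self.n_samples < 1:
            raise ValueError("n_replicas and n_samples must be >= 1")

    @property
    def stationary_a(self) -> float:
        tot = self.p_ab + self.p_ba
        return self.p_ba / tot if tot > 0 else float("nan")


def _wrap_degrees(x: np.ndarray) -> np.ndarray:
    """Map angles into (−180, 180], boundary to +180."""
    y = np.mod(-x + 180.0, 360.0)
    return -(y - 180.0) + 0.0  # -180 maps back to +180


def make_two_state_trajectory(
    model: TwoStateModel, replica: int = 0, seed: int = 0
) -> pd.DataFrame:
    """One replica's feature table with the hidden state retained.

    Columns: time (ps), replica, state ('a'/'b'), then the emission columns.
    """
    rng = np.random.default_rng(seed)
    n = model.n_samples
    states = np.empty(n, dtype=np.int8)  # 0 = a, 1 = b
    if model.start_state == "stationary":
        pa = model.stationary_a
        if np.isnan(pa):
            raise ValueError(
                "stationary start undefined when both switch probabilities are 0; "
                "set start_state to 'a' or 'b'"
            )
        cur = 0 if rng.random() < pa else 1
    else:
        cur = 0 if model.start_state == "a" else 1
    u = rng.random(n)
    for t in range(n):
        states[t] = cur
        if cur == 0:
            if u[t] < model.p_ab:
                cur = 1
        elif u[t] < model.p_ba:
            cur = 0

    frame = pd.DataFrame(
        {
            "time": np.arange(n) * model.dt_ps,
            "replica": np.full(n, replica, dtype=int),
            "state": np.where(states == 0, "a", "b"),
        }
    )
    is_b = states == 1
    for col in EMISSION_COLUMNS:
        ma, sa = model.emissions_a[col]
        mb, sb = model.emissions_b[col]
        vals = np.where(
            is_b,
            mb + sb * rng.standard_normal(n),
            ma + sa * rng.standard_normal(n),
        )
        if col == "dihedral":
            vals = _wrap_degrees(vals)
        frame[col] = vals
    return frame


def make_two_state_ensemble(model: TwoStateModel, seed: int = 0) -> list[pd.DataFrame]:
    """Independent replicas with seeds spawned from ``seed``."""
    out = []
    for r in range(model.n_replicas):
        child = np.random.SeedSequence(entropy=int(seed), spawn_key=(r,))
        out.append(
            make_two_state_trajectory(
                model, replica=r, seed=int(child.generate_state(1, np.uint64)[0] >> 1)
            )
        )
    return out


def t790m_like_model(**overrides) -> TwoStateModel:
    """Gatekeeper-mutant-like conditions: reactive state a (S–Cβ ≈ 3.5 Å,
    dihedral ≈ −55°) and unreactive state b about equally populated."""
    kwargs = dict(p_ab=0.01, p_ba=0.01)
    kwargs.update(overrides)
    return TwoStateModel(**kwargs)


def l718q_like_model(temperature: float = DEFAULT_TEMPERATURE, **overrides) -> TwoStateModel:
    """P-loop-mutant-like conditions: state a shifted to S–Cβ ≈ 4.5 Å (no
    longer reactive), state b at longer distances with a short Gln718-style
    H-bond, stabilized by ~1 kcal/mol relative to a."""
    ratio = np.exp(1.0 / kt(temperature))  # P_b / P_a for a 1 kcal/mol gap
    p_ab = 0.02
    kwargs = dict(
        p_ab=p_ab,
        p_ba=p_ab / ratio,
        emissions_a={
            "s_cb_distance": (4.5, 0.35),
            "dihedral": (-55.0, 15.0),
            "hbond_distance": (5.5, 0.8),
        },
        emissions_b={
            "s_cb_distance": (6.2, 0.45),
            "dihedral": (100.0, 10.0),
            "hbond_distance": (2.9, 0.3),
        },
    )
    kwargs.update(overrides)
    return TwoStateModel(**kwargs)
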