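"""Metropolis Monte Carlo sampling of biased windows.

The sampler targets the canonical density ∝ exp(−[U(ξ) + U_bias(ξ)]/k_BT)
by alternating two Metropolis kernels, each of which satisfies detailed
balance with respect to that density:

* a Gaussian random-walk proposal whose step is auto-tuned to a 30–60%
  acceptance rate during burn-in and frozen afterwards;
* an independence proposal drawn from the harmonic-bias Gaussian
  N(ξ0, k_BT/2k); its Hastings ratio reduces to exp(−ΔU/k_BT) in the bare
  potential alone, and every accepted move decorrelates the chain fully.

The alternation keeps the integrated autocorrelation time of a stiffly
biased window at a few steps, which is what makes window-to-window WHAM
offsets usable at moderate sample counts. Windows with a zero spring
constant on any axis use the random-walk kernel throughout. Detailed
balance makes the correctness contract simple: for a quadratic total
potential the sample mean and variance have closed forms, which the tests
check.

Per-window seeds are derived from the master seed and the window index via
``numpy.random.SeedSequence(master, spawn_key=(index,))`` and recorded in the
window metadata, so any single window can be replayed in isolation:
regenerating a window on its own is bit-identical to generating it as part
of the full grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt
from .windows import (
    GridSpec,
    HarmonicBias,
    UmbrellaWindow,
    build_window_grid,
    write_manifest,
    write_window_file,
)

__all__ = [
    "sample_biased_window",
    "generate_us_dataset",
    "UmbrellaDataset",
    "derive_window_seed",
]

#: Per-window simulated length the window files notionally represent (ps);
#: used only for bookkeeping totals, matching 50 ps of MD per window.
WINDOW_LENGTH_PS = 50.0


def derive_window_seed(master_seed: int, index: int) -> int:
    """Deterministic per-window seed = hash(master seed, window index)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, np.uint64)[0] >> 1)  # keep it positive


def _potential_energy(potential, state):
    """Energy of batch ``state`` (nwin, d) under ``potential`` (nwin,)."""
    if getattr(potential, "ndim", state.shape[1]) == 1:
        return np.asarray(potential.energy(state[:, 0]), dtype=float).reshape(-1)
    return np.asarray(potential.energy(state), dtype=float).reshape(-1)


def _metropolis(
    potential,
    biases: list[HarmonicBias],
    n_samples: int,
    seeds: list[int],
    temperature: float,
    burn_in: int,
    step_size: float | None,
):
    """Advance all windows simultaneously; returns (samples, step, acc_rate).

    samples: (nwin, n_samples, d); per-window randomness comes from each
    window's own RNG stream, so results are independent of batch composition.
    """
    nwin = len(biases)
    d = biases[0].ndim
    if any(b.ndim != d for b in biases):
        raise ValueError("all windows must share the coordinate dimension")
    beta = 1.0 / kt(temperature)
    n_total = burn_in + n_samples

    centers = np.array([b.center for b in biases], dtype=float)  # (nwin, d)
    ks = np.array([b.k for b in biases], dtype=float)
    pref = np.array([0.5 if b.half_convention else 1.0 for b in biases])[:, None]

    normals = np.empty((nwin, n_total, d))
    uniforms = np.empty((nwin, n_total))
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        normals[i] = rng.standard_normal((n_total, d))
        uniforms[i] = rng.random(n_total)

    state = centers.copy()

    def energies(x):
        u_pot = _potential_energy(potential, x)
        u_bias = np.sum(pref * ks * (x - centers) ** 2, axis=1)
        return u_pot, u_bias

    u_pot_cur, u_bias_cur = energies(state)
    if not np.all(np.isfinite(u_pot_cur + u_bias_cur)):
        bad = int(np.flatnonzero(~np.isfinite(u_pot_cur + u_bias_cur))[0])
        raise ValueError(f"non-finite potential at start point of window {bad}")

    if step_size is None:
        # harmonic guess from the stiffest restraint, clipped to sane range
        kmax = max(ks.max(), 1.0)
        step_size = float(np.clip(np.sqrt(kt(temperature) / kmax), 1e-4, 0.3))
    step = np.full(nwin, float(step_size))

    # independence-kernel parameters: Gaussian of the bias alone
    indep_ok = np.all(ks > 0, axis=1)
    sigma_ind = np.zeros_like(ks)
    sigma_ind[indep_ok] = np.sqrt(
        kt(temperature) / (2.0 * pref[indep_ok] * ks[indep_ok])
    )

    out = np.empty((nwin, n_samples, d))
    acc_count = np.zeros(nwin, dtype=np.int64)
    tune_acc = np.zeros(nwin, dtype=np.int64)
    tune_rw_steps = 0
    tune_block = 25  # random-walk steps per tuning adjustment

    for t in range(n_total):
        indep_step = (t % 2 == 1) & indep_ok
        prop = np.where(
            indep_step[:, None],
            centers + sigma_ind * normals[:, t, :],
            state + step[:, None] * normals[:, t, :],
        )
        u_pot_new, u_bias_new = energies(prop)
        # random walk: full energy change; independence: bias part cancels
        # against the proposal density, leaving the bare potential change
        de = np.where(
            indep_step,
            u_pot_new - u_pot_cur,
            (u_pot_new + u_bias_new) - (u_pot_cur + u_bias_cur),
        )
        accept = (de <= 0.0) | (
            uniforms[:, t] < np.exp(-beta * np.minimum(de, 700.0 / beta))
        )
        state[accept] = prop[accept]
        u_pot_cur[accept] = u_pot_new[accept]
        u_bias_cur[accept] = u_bias_new[accept]
        if t < burn_in:
            if t % 2 == 0:  # tune on random-walk moves only
                tune_acc += accept & ~indep_step
                tune_rw_steps += 1
                if tune_rw_steps % tune_block == 0:
                    rate = tune_acc / tune_block
                    step *= np.where(rate > 0.6, 1.25, np.where(rate < 0.3, 0.8, 1.0))
                    tune_acc[:] = 0
        else:
            out[:, t - burn_in, :] = state
            acc_count += accept

    acc_rate = acc_count / max(n_samples, 1)
    return out, step, acc_rate


def sample_biased_window(
    potential,
    bias: HarmonicBias,
    n_samples: int,
    seed: int,
    burn_in: int | None = None,
    step_size: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> UmbrellaWindow:
    """Sample one harmonic-bias window with Metropolis Monte Carlo.

    ``burn_in`` defaults to 10% of ``n_samples`` (discarded, used for step
    tuning). Identical arguments produce byte-identical samples.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if burn_in is None:
        burn_in = max(n_samples // 10, 50)
    samples, step, acc = _metropolis(
        potential, [bias], n_samples, [int(seed)], temperature, burn_in, step_size
    )
    s = samples[0]
    return UmbrellaWindow(
        bias,
        s[:, 0] if bias.ndim == 1 else s,
        temperature=temperature,
        seed=int(seed),
        burn_in=burn_in,
        step_size=float(step[0]),
        acceptance_rate=float(acc[0]),
    )


@dataclass
class UmbrellaDataset:
    """A full set of umbrella windows over a grid, plus bookkeeping."""

    windows: list[UmbrellaWindow]
    spec_x: GridSpec
    spec_y: GridSpec | None
    spring_constant: float
    temperature: float
    master_seed: int
    window_length_ps: float = WINDOW_LENGTH_PS
    manifest_path: str | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def total_sampling_time_ns(self) -> float:
        """Total notional simulation time: windows × window length."""
        return self.n_windows * self.window_length_ps / 1000.0


def generate_us_dataset(
    potential,
    spec_x: GridSpec,
    spec_y: GridSpec | None = None,
    spring_constant: float = 100.0,
    n_per_window: int = 2000,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    burn_in: int | None = None,
    coordinates: tuple[str, ...] | None = None,
    out_dir=None,
) -> UmbrellaDataset:
    """Generate one biased window per grid point (x-major order).

    With ``out_dir`` set, windows are written as plain-text time-series files
    plus a YAML manifest. Per-window seeds derive deterministically from
    ``seed``; rerunning with the same arguments reproduces every file.
    """
    centers = build_window_grid(spec_x, spec_y)
    ndim = 1 if spec_y is None else 2
    if coordinates is None:
        coordinates = ("r",) if ndim == 1 else ("x", "y")
    if burn_in is None:
        burn_in = max(n_per_window // 10, 50)

    biases = []
    seeds = []
    for i, c in enumerate(centers):
        center = (c,) if ndim == 1 else c
        biases.append(HarmonicBias(coordinates, center, (spring_constant,) * ndim))
        seeds.append(derive_window_seed(seed, i))

    samples, steps, accs = _metropolis(
        potential, biases, n_per_window, seeds, temperature, burn_in, None
    )
    windows = []
    for i, b in enumerate(biases):
        s = samples[i]
        windows.append(
            UmbrellaWindow(
                b,
                s[:, 0] if ndim == 1 else s,
                temperature=temperature,
                seed=seeds[i],
                burn_in=burn_in,
                step_size=float(steps[i]),
                acceptance_rate=float(accs[i]),
            )
        )

    dataset = UmbrellaDataset(
        windows, spec_x, spec_y, spring_constant, temperature, int(seed)
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            paths = []
            for i, w in enumerate(windows):
                p = out_dir / f"window_{i:04d}.dat"
                write_window_file(w, p)
                paths.append(p.name)
            manifest = out_dir / "manifest.yaml"
            write_manifest(windows, paths, manifest, temperature)
        except OSError as exc:
            raise OSError(f"failed writing umbrella dataset under {out_dir}: {exc}") from exc
        dataset.manifest_path = str(manifest)
    return dataset
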