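"""End-to-end orchestration: simulate → wham → analyze → conffes → report.

A single declarative YAML/dict config drives the whole protocol:

1. *simulate* — calibrate the 2D reaction surface and the 1D proton-transfer
   profile, sample their umbrella-window grids, and generate unbiased
   two-state trajectories;
2. *wham* — unbias both window sets into free-energy surfaces;
3. *analyze* — basins, minimax path, ΔA_act/ΔA_reac, 1D state difference;
4. *conffes* — Boltzmann-inversion conformational surface, reactive
   fractions, state occupancies, basin gap, H-bond occupancy, coupling;
5. *ti* — trapezoidal thermodynamic integration when gradient data are
   supplied;
6. *report* — one JSON report whose content fully determines re-execution.

Every stochastic stage draws its seed deterministically from the master
seed (``SeedSequence(master, spawn_key=(stage,))``), so rerunning the same
config reproduces every artifact byte for byte.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .analysis import (
    LambdaSchedule,
    WATERSWAP_LAMBDAS,
    activation_reaction_energies,
    find_minima,
    minimax_path,
    nearest_basin,
    profile_delta,
    ti_integrate,
)
from .conformations import (
    BinSpec2D,
    STATE_A,
    STATE_B,
    StateDefinition,
    assign_states,
    basin_delta,
    boltzmann_fes,
    coupling_report,
    hbond_occupancy,
    pool_features,
    reactive_fraction,
)
from .markov import l718q_like_model, make_two_state_ensemble, t790m_like_model
from .sampling import generate_us_dataset
from .surfaces import make_proton_transfer_profile, make_reaction_surface
from .wham import default_bins_from_grid, wham
from .windows import GridSpec

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "temperature": 300.0,
    "seed": 0,
    "out_dir": "covfes_run",
    "surface": {"barrier": 7.8, "reaction_free_energy": -10.3},
    "us_2d": {
        "grid_x": [3.6, 1.8, -0.1],
        "grid_y": [2.8, -2.2, -0.2],
        "spring_constant": 100.0,
        "n_per_window": 500,
        "write_windows": False,
    },
    "us_1d": {
        "delta_a": 0.5,
        "grid": [1.0, -1.0, -0.1],
        "spring_constant": 100.0,
        "n_per_window": 2000,
    },
    "trajectories": {"preset": "t790m_like", "n_replicas": 4, "n_samples": 30000},
    "conformations": {
        "reactive_cutoff": 3.9,
        "hbond_cutoff": 3.5,
        "n_permutations": 200,
        "states": None,  # optional list of {label, dihedral, distance}
    },
    "ti": {
        "lambdas": list(WATERSWAP_LAMBDAS),
        "gradients_path": None,
        "burn_in_fraction": 1.0 / 3.0,
    },
    "wham": {"tolerance": 1e-7, "max_iter": 100000, "refine": 3},
}

_POSITIVE = {
    "temperature": ("temperature",),
    "surface.barrier": ("surface", "barrier"),
    "us_2d.n_per_window": ("us_2d", "n_per_window"),
    "us_1d.n_per_window": ("us_1d", "n_per_window"),
    "trajectories.n_replicas": ("trajectories", "n_replicas"),
    "trajectories.n_samples": ("trajectories", "n_samples"),
    "conformations.reactive_cutoff": ("conformations", "reactive_cutoff"),
    "wham.tolerance": ("wham", "tolerance"),
}
_NON_NEGATIVE = {
    "us_2d.spring_constant": ("us_2d", "spring_constant"),
    "us_1d.spring_constant": ("us_1d", "spring_constant"),
}


def _deep_merge(base: dict, override: dict, errors: list, prefix: str = "") -> dict:
    merged = copy.deepcopy(base)
    for key, val in (override or {}).items():
        path = f"{prefix}{key}"
        if key not in merged:
            errors.append(f"{path}: unknown configuration field")
            continue
        if isinstance(merged[key], dict) and isinstance(val, dict):
            merged[key] = _deep_merge(merged[key], val, errors, prefix=f"{path}.")
        else:
            merged[key] = val
    return merged


def validate_config(config) -> tuple[dict, list[str]]:
    """Fill defaults and check a run configuration.

    ``config`` is a dict, YAML text, or a path to a YAML file. Returns the
    fully-expanded config (defaults echoed) and an aggregated error list;
    an empty list means the config is valid.
    """
    if isinstance(config, (str, Path)) and "\n" not in str(config):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    elif isinstance(config, str):
        config = yaml.safe_load(config) or {}
    errors: list[str] = []
    cfg = _deep_merge(DEFAULT_CONFIG, config, errors)

    def get(path):
        node = cfg
        for k in path:
            node = node[k]
        return node

    for name, path in _POSITIVE.items():
        v = get(path)
        if v is None or not isinstance(v, (int, float)) or v <= 0:
            errors.append(f"{name}: must be a positive number, got {v!r}")
    for name, path in _NON_NEGATIVE.items():
        v = get(path)
        if v is None or not isinstance(v, (int, float)) or v < 0:
            errors.append(f"{name}: must be a non-negative number, got {v!r}")
    for axis in ("grid_x", "grid_y"):
        try:
            GridSpec(*cfg["us_2d"][axis])
        except (TypeError, ValueError) as exc:
            errors.append(f"us_2d.{axis}: {exc}")
    try:
        GridSpec(*cfg["us_1d"]["grid"])
    except (TypeError, ValueError) as exc:
        errors.append(f"us_1d.grid: {exc}")
    if cfg["trajectories"]["preset"] not in ("t790m_like", "l718q_like"):
        errors.append(
            f"trajectories.preset: unknown preset {cfg['trajectories']['preset']!r}"
        )
    try:
        LambdaSchedule(tuple(cfg["ti"]["lambdas"]))
    except (TypeError, ValueError) as exc:
        errors.append(f"ti.lambdas: {exc}")
    gp = cfg["ti"]["gradients_path"]
    if gp is not None and not Path(gp).exists():
        errors.append(f"ti.gradients_path: file not found: {gp}")
    if not isinstance(cfg["seed"], int):
        errors.append(f"seed: must be an integer, got {cfg['seed']!r}")
    return cfg, errors


def _stage_seed(master: int, stage: int) -> int:
    return int(
        np.random.SeedSequence(entropy=int(master), spawn_key=(stage,)).generate_state(
            1, np.uint64
        )[0]
        >> 1
    )


def run_pipeline(config, out_dir=None) -> dict:
    """Execute all stages; returns the report dict (also written as JSON).

    Identical config + seed reproduces identical artifacts. A stage failure
    raises with the stage name; artifacts of completed stages remain on
    disk.
    """
    cfg, errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    temperature = float(cfg["temperature"])
    master = int(cfg["seed"])
    report: dict = {
        "version": _version,
        "config": cfg,
        "seeds": {},
        "warnings": [],
        "stages": {},
    }

    def fail(stage, exc):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- simulate -------------------------------------------------------
    try:
        surface = make_reaction_surface(
            float(cfg["surface"]["barrier"]),
            float(cfg["surface"]["reaction_free_energy"]),
            temperature=temperature,
        )
        profile = make_proton_transfer_profile(
            float(cfg["us_1d"]["delta_a"]), temperature=temperature
        )
        sx = GridSpec(*cfg["us_2d"]["grid_x"])
        sy = GridSpec(*cfg["us_2d"]["grid_y"])
        s1 = GridSpec(*cfg["us_1d"]["grid"])
        seed_2d = _stage_seed(master, 0)
        seed_1d = _stage_seed(master, 1)
        seed_tr = _stage_seed(master, 2)
        report["seeds"] = {"us_2d": seed_2d, "us_1d": seed_1d, "trajectories": seed_tr}
        ds2 = generate_us_dataset(
            surface,
            sx,
            sy,
            spring_constant=float(cfg["us_2d"]["spring_constant"]),
            n_per_window=int(cfg["us_2d"]["n_per_window"]),
            seed=seed_2d,
            temperature=temperature,
            out_dir=(out / "windows_2d") if cfg["us_2d"]["write_windows"] else None,
        )
        ds1 = generate_us_dataset(
            profile,
            s1,
            spring_constant=float(cfg["us_1d"]["spring_constant"]),
            n_per_window=int(cfg["us_1d"]["n_per_window"]),
            seed=seed_1d,
            temperature=temperature,
        )
        preset = (
            t790m_like_model if cfg["trajectories"]["preset"] == "t790m_like" else l718q_like_model
        )
        model = preset(
            n_replicas=int(cfg["trajectories"]["n_replicas"]),
            n_samples=int(cfg["trajectories"]["n_samples"]),
        )
        replicas = make_two_state_ensemble(model, seed=seed_tr)
        report["stages"]["simulate"] = {
            "n_windows_2d": ds2.n_windows,
            "n_windows_1d": ds1.n_windows,
            "total_sampling_time_ns_2d": ds2.total_sampling_time_ns,
            "n_trajectory_snapshots": int(sum(len(r) for r in replicas)),
        }
    except Exception as exc:  # noqa: BLE001 - stage context added
        fail("simulate", exc)

    # ---- wham -----------------------------------------------------------
    try:
        refine = int(cfg["wham"]["refine"])
        tol = float(cfg["wham"]["tolerance"])
        max_iter = int(cfg["wham"]["max_iter"])
        r2 = wham(
            ds2.windows,
            default_bins_from_grid(sx, sy, refine),
            temperature=temperature,
            tolerance=tol,
            max_iter=max_iter,
        )
        r1 = wham(
            ds1.windows,
            default_bins_from_grid(s1, refine=refine),
            temperature=temperature,
            tolerance=tol,
            max_iter=max_iter,
        )
        for tag, res in (("2d", r2), ("1d", r1)):
            res.fes.write_tsv(out / f"fes_{tag}.tsv")
            if not res.converged:
                report["warnings"].append(f"wham_{tag}_unconverged")
        report["stages"]["wham"] = {
            "iterations_2d": r2.iterations,
            "converged_2d": r2.converged,
            "iterations_1d": r1.iterations,
            "converged_1d": r1.converged,
            "out_of_range_2d": r2.out_of_range,
        }
    except Exception as exc:
        fail("wham", exc)

    # ---- analyze --------------------------------------------------------
    try:
        basins = find_minima(r2.fes)
        b_r = nearest_basin(basins, r2.fes, surface.wells[0].center)
        b_p = nearest_basin(basins, r2.fes, surface.wells[1].center)
        path = minimax_path(r2.fes, b_r, b_p)
        energies = activation_reaction_energies(r2.fes, path)
        well_a = profile.wells[0].center
        well_b = profile.wells[1].center
        half = abs(well_a - well_b) / 2.5
        d1 = profile_delta(
            r1.fes, (well_a - half, well_a + half), (well_b - half, well_b + half)
        )
        pd.DataFrame(
            {
                "cell": [list(c) for c in path.cells],
                "A": path.energies,
            }
        ).to_csv(out / "reaction_path.tsv", sep="\t", index=False)
        report["stages"]["analyze"] = {
            "delta_a_act": energies["delta_a_act"],
            "delta_a_reac": energies["delta_a_reac"],
            "ts_cell": list(energies["ts_cell"]),
            "proton_transfer_delta_a": d1,
            "n_basins_2d": len(basins),
        }
    except Exception as exc:
        fail("analyze", exc)

    # ---- conffes --------------------------------------------------------
    try:
        pooled = pool_features(replicas)
        conf_fes = boltzmann_fes(pooled, BinSpec2D(), temperature)
        conf_fes.write_tsv(out / "conformational_fes.tsv")
        states_cfg = cfg["conformations"]["states"]
        if states_cfg:
            defs = [
                StateDefinition(
                    s["label"], tuple(s["dihedral"]),
                    tuple(s["distance"]) if s.get("distance") else None,
                )
                for s in states_cfg
            ]
        else:
            defs = (STATE_A, STATE_B)
        labels, occupancy = assign_states(pooled, defs)
        pooled_row = occupancy[occupancy["replica"] == "pooled"].iloc[0]
        gap = (
            basin_delta(pooled_row[defs[0].label], pooled_row[defs[1].label], temperature)
            if pooled_row[defs[0].label] > 0 and pooled_row[defs[1].label] > 0
            else None
        )
        rs = reactive_fraction(pooled, float(cfg["conformations"]["reactive_cutoff"]))
        hb = hbond_occupancy(pooled, cutoff=float(cfg["conformations"]["hbond_cutoff"]))
        coup = coupling_report(
            pooled, defs, n_permutations=int(cfg["conformations"]["n_permutations"])
        )
        occupancy.to_csv(out / "state_occupancy.tsv", sep="\t", index=False)
        report["stages"]["conffes"] = {
            "reactive_fraction_pooled": rs.pooled_fraction,
            "reactive_fraction_per_replica": rs.per_replica["fraction"].tolist(),
            "basin_gap_a_to_b": gap,
            "hbond_occupancy_pooled": hb["pooled"],
            "point_biserial_r": coup["point_biserial_r"],
            "coupling_permutation_p": coup["permutation_p"],
            "out_of_range": conf_fes.meta["out_of_range"],
        }
    except Exception as exc:
        fail("conffes", exc)

    # ---- ti -------------------------------------------------------------
    if cfg["ti"]["gradients_path"]:
        try:
            table = pd.read_csv(cfg["ti"]["gradients_path"], sep="\t", comment="#")
            schedule = LambdaSchedule(tuple(cfg["ti"]["lambdas"]))
            grads = [
                table.loc[np.isclose(table["lambda"], lam), "gradient"].to_numpy()
                for lam in schedule.values
            ]
            delta_a_bind = ti_integrate(
                schedule, grads, float(cfg["ti"]["burn_in_fraction"])
            )
            report["stages"]["ti"] = {
                "delta_a": delta_a_bind,
                "n_lambdas": len(schedule),
            }
        except Exception as exc:
            fail("ti", exc)
    else:
        report["stages"]["ti"] = {"skipped": "no gradients_path configured"}

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    report["report_path"] = str(report_path)
    return report
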