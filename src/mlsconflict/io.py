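"""Config loading and structured output writing."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .games import classify_game, payoffs_from_coefficients
from .solver_fv import SimulationConfig, Trajectory, config_from_dict

__all__ = ["load_config", "write_outputs", "config_to_dict"]


def load_config(path) -> SimulationConfig:
    """Parse and validate a YAML (or JSON) config file.

    Either a ``preset: NAME`` key (optionally overridden by other keys) or
    a full config with ``game`` and ``kernel`` sections.  Unknown keys are
    errors; defaults (N=256, renormalize off, ...) fill the rest.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    preset_name = raw.pop("preset", None)
    if preset_name is not None:
        from .presets import get_preset

        config = get_preset(preset_name).config
        allowed = {"lambda", "lam", "dt", "n_steps", "N", "initial", "renormalize", "snapshot_every"}
        extra = set(raw) - allowed
        if extra:
            raise ValueError(f"unknown config key(s) with preset: {sorted(extra)}")
        if raw:
            from dataclasses import replace

            if "lambda" in raw:
                raw["lam"] = raw.pop("lambda")
            config = replace(config, **{k: raw[k] for k in raw})
        return config
    return config_from_dict(raw)


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable echo of a configuration."""
    m = payoffs_from_coefficients(config.game)
    return {
        "game": {
            "alpha": config.game.alpha,
            "beta": config.game.beta,
            "gamma": config.game.gamma,
            "P": config.game.P,
            "payoffs": {"R": m.R, "S": m.S, "T": m.T, "P": m.P},
            "class": classify_game(m),
        },
        "kernel": {"family": config.kernel.family, **config.kernel.params},
        "lambda": config.lam,
        "dt": config.dt,
        "n_steps": config.n_steps,
        "N": config.N,
        "initial": config.initial,
        "renormalize": config.renormalize,
        "snapshot_every": config.snapshot_every,
    }


def write_outputs(traj: Trajectory, out_dir) -> None:
    """Write snapshots.csv, diagnostics.csv and metadata.json.

    Deterministic solver plus fixed float formatting makes reruns of the
    same config byte-identical.
    """
    if not traj.states:
        raise ValueError("trajectory has no snapshots; nothing to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    frames = []
    for state in traj.states:
        frames.append(
            pd.DataFrame(
                {
                    "time": np.full(state.grid.N, state.time),
                    "cell_center": state.grid.centers,
                    "density": state.values,
                }
            )
        )
    snapshots = pd.concat(frames, ignore_index=True)
    snapshots.to_csv(out / "snapshots.csv", index=False, float_format="%.12g")

    diagnostics = pd.DataFrame(traj.diagnostics)
    diagnostics.to_csv(out / "diagnostics.csv", index=False, float_format="%.12g")

    mass = np.asarray(traj.diagnostics["mass"])
    metadata = {
        "config": config_to_dict(traj.config),
        "package_version": __version__,
        "n_snapshots": len(traj.states),
        "final_time": float(traj.times[-1]),
        "max_mass_drift": float(np.max(np.abs(mass - 1.0))),
    }
    (out / "metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
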