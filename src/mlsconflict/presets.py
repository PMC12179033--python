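"""Scenario presets encoding the published simulation set-ups.

Each preset records a complete, CFL-valid configuration together with a
provenance note saying which figure it encodes.  Step counts follow the
captions; the long 9,600-step runs can be shortened via ``n_steps``.

Known caption inconsistencies, preserved here deliberately:

- the bistable (stag-hunt) scenario lists beta = 0, which would put the
  interior equilibrium at 0 instead of the stated 0.5; the preset uses
  beta = -1, which reproduces x_eq = 0.5 and the SH payoff ordering;
- the lambda-sweep figures quote step-size 0.01 in prose while most
  captions use 0.003; each preset follows its own caption.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .games import GameCoefficients
from .solver_fv import SimulationConfig
from .victory import fermi_kernel

__all__ = ["ScenarioPreset", "PRESETS", "get_preset", "preset_names"]


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    config: SimulationConfig
    provenance: str

    def with_steps(self, n_steps: int | None) -> SimulationConfig:
        if n_steps is None:
            return self.config
        return replace(self.config, n_steps=n_steps)


_PD_GAME = GameCoefficients(alpha=-1.0, beta=-1.0, gamma=1.5, P=1.0)
_PD_GAME_FULLC = GameCoefficients(alpha=-1.0, beta=-1.0, gamma=2.0, P=1.0)
_HD_GAME = GameCoefficients(alpha=-2.0, beta=1.0, gamma=3.5, P=1.0)
_HD_GAME_FULLC = GameCoefficients(alpha=-2.0, beta=1.0, gamma=4.0, P=1.0)
_SH_GAME = GameCoefficients(alpha=2.0, beta=-1.0, gamma=0.0, P=2.0)


def _cfg(game, lam, dt, n_steps, **kw) -> SimulationConfig:
    return SimulationConfig(
        game=game,
        kernel=fermi_kernel(game, s=1.0),
        lam=lam,
        dt=dt,
        n_steps=n_steps,
        **kw,
    )


def _build_presets() -> dict[str, ScenarioPreset]:
    presets = [
        ScenarioPreset(
            "fig1-left",
            _cfg(_PD_GAME, lam=0.01, dt=0.003, n_steps=1000),
            "dominance game, weak conflict: gamma=1.5, alpha=beta=-1, P=1, "
            "fermi s=1, lambda=0.01, 1000 steps of dt=0.003; all groups "
            "concentrate on the all-defector composition",
        ),
        ScenarioPreset(
            "fig1-right",
            _cfg(_PD_GAME, lam=14.0, dt=0.003, n_steps=1400),
            "dominance game, strong conflict: lambda=14, 1400 steps of "
            "dt=0.003; tends to a steady-state density",
        ),
        ScenarioPreset(
            "fig2-left",
            _cfg(_PD_GAME_FULLC, lam=14.0, dt=0.003, n_steps=9600),
            "dominance game with G maximized at full cooperation (gamma=2); "
            "caption compares several lambda values, lambda=14 here",
        ),
        ScenarioPreset(
            "fig2-right",
            _cfg(_PD_GAME, lam=14.0, dt=0.003, n_steps=9600),
            "dominance game with G maximized at 75% cooperation (gamma=1.5); "
            "caption compares several lambda values, lambda=14 here",
        ),
        ScenarioPreset(
            "fig3",
            _cfg(_PD_GAME, lam=14.0, dt=0.003, n_steps=9600),
            "base config for the dominance-game lambda sweep of success vs "
            "the all-cooperator group (9600 steps, dt=0.003)",
        ),
        ScenarioPreset(
            "fig4",
            _cfg(_PD_GAME, lam=8.0, dt=0.01, n_steps=9600),
            "base config for the dominance-game lambda sweep of mean "
            "cooperation; prose gives dt=0.01 (vs 0.003 elsewhere)",
        ),
        ScenarioPreset(
            "fig5-left",
            _cfg(_HD_GAME, lam=0.1, dt=0.003, n_steps=1600),
            "coexistence game, weak conflict: gamma=3.5, alpha=-2, beta=1, "
            "P=1, lambda=0.1, 1600 steps of dt=0.003; concentrates near "
            "x_eq=0.5",
        ),
        ScenarioPreset(
            "fig5-right",
            _cfg(_HD_GAME, lam=15.0, dt=0.003, n_steps=1200),
            "coexistence game, strong conflict: lambda=15, 1200 steps of "
            "dt=0.003; steady state supports cooperation above x_eq",
        ),
        ScenarioPreset(
            "fig6-left",
            _cfg(_HD_GAME_FULLC, lam=16.0, dt=0.003, n_steps=9600),
            "coexistence game with G maximized at full cooperation "
            "(gamma=4); lambda=16, 9600 steps of dt=0.003",
        ),
        ScenarioPreset(
            "fig6-right",
            _cfg(_HD_GAME, lam=192.0, dt=0.003, n_steps=9600),
            "coexistence game with G maximized at 87.5% cooperation "
            "(gamma=3.5); lambda=192, 9600 steps of dt=0.003",
        ),
        ScenarioPreset(
            "fig7",
            _cfg(_HD_GAME, lam=15.0, dt=0.003, n_steps=9600),
            "base config for the coexistence-game lambda sweep of success "
            "vs the all-cooperator group (9600 steps, dt=0.003)",
        ),
        ScenarioPreset(
            "fig8",
            _cfg(_HD_GAME, lam=15.0, dt=0.01, n_steps=9600),
            "base config for the coexistence-game lambda sweep of mean "
            "cooperation; prose gives dt=0.01",
        ),
        ScenarioPreset(
            "fig9-left",
            _cfg(_SH_GAME, lam=0.0, dt=0.01, n_steps=250),
            "bistable game, no conflict: gamma=0, alpha=2, P=2, lambda=0, "
            "250 steps of dt=0.01; caption lists beta=0 but states "
            "x_eq=0.5, which requires beta=-1 (used here)",
        ),
        ScenarioPreset(
            "fig9-right",
            _cfg(_SH_GAME, lam=1.0, dt=0.01, n_steps=250),
            "bistable game with conflict: lambda=1; population concentrates "
            "on the all-cooperator composition; beta corrected to -1 as in "
            "the lambda=0 panel",
        ),
    ]
    return {p.name: p for p in presets}


PRESETS: dict[str, ScenarioPreset] = _build_presets()


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}") from None
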