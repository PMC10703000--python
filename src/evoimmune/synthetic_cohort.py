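"""Synthetic six-arm murine cohorts with the noise structure the calibration assumes.

The experimental protocol emulated here: tumors inoculated at day 0 and
grown to ~100 mm^3, caliper volume measurements every 2-3 days from day 6
through day 39, hypoxia imaging (vascularized fraction) at days 12 and
17, evofosfamide daily on days 13-17, and checkpoint-blockade
immunotherapy on configurable days (default 7, 10, 13).  Six arms:

    I    control
    II   hypoxic, immunotherapy
    III  normoxic, immunotherapy
    IV   evofosfamide alone
    V    hypoxic, immunotherapy + evofosfamide
    VI   normoxic, immunotherapy + evofosfamide

Hypoxic arms start with a lower well-vascularized fraction than normoxic
ones.  The generator emits one group-mean series per arm (optionally the
mean of per-mouse replicates) with additive i.i.d. Gaussian noise,
truncated to the physical domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tumor_model import ModelParameters, TreatmentSchedule, simulate

__all__ = [
    "SCENARIO_IDS",
    "ScenarioSpec",
    "ObservationSet",
    "NoiseSpec",
    "default_protocol",
    "default_measurement_days",
    "generate_cohort",
]

SCENARIO_IDS = ("I", "II", "III", "IV", "V", "VI")

_LABELS = {
    "I": "control",
    "II": "hypoxic + immunotherapy",
    "III": "normoxic + immunotherapy",
    "IV": "evofosfamide",
    "V": "hypoxic + immunotherapy + evofosfamide",
    "VI": "normoxic + immunotherapy + evofosfamide",
}

#: Default initial well-vascularized fractions.  Hypoxic arms (I, II, IV, V)
#: start 80% hypoxic; normoxic arms (III, VI) 40%.  Not printed by the
#: source study; see docs/methods.md for the rationale.
DEFAULT_V0 = {"I": 0.2, "II": 0.2, "III": 0.6, "IV": 0.2, "V": 0.2, "VI": 0.6}

DEFAULT_IMMUNO_DAYS = (7.0, 10.0, 13.0)
DEFAULT_EVO_DAYS = (13.0, 14.0, 15.0, 16.0, 17.0)
DEFAULT_T0 = 100.0
DEFAULT_WINDOW = (6.0, 39.0)
VASCULAR_IMAGING_DAYS = (12.0, 17.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """One experimental arm: flags, initial conditions and dose schedule."""

    id: str
    label: str
    receives_immuno: bool
    receives_evo: bool
    V0: float
    T0: float
    schedule: TreatmentSchedule
    tumor_days: tuple = ()
    vascular_days: tuple = VASCULAR_IMAGING_DAYS

    def __post_init__(self):
        if not (0.0 <= self.V0 <= 1.0):
            raise ValueError(f"V0 must be in [0,1], got {self.V0}")
        if self.T0 <= 0:
            raise ValueError(f"T0 must be > 0, got {self.T0}")
        if self.receives_immuno != bool(self.schedule.immuno_days):
            raise ValueError(
                f"scenario {self.id}: receives_immuno={self.receives_immuno} "
                f"inconsistent with immuno_days={self.schedule.immuno_days}"
            )
        if self.receives_evo != bool(self.schedule.evo_days):
            raise ValueError(
                f"scenario {self.id}: receives_evo={self.receives_evo} "
                f"inconsistent with evo_days={self.schedule.evo_days}"
            )


@dataclass(frozen=True)
class ObservationSet:
    """Noisy group-mean measurements for one arm."""

    scenario_id: str
    tumor_obs: tuple    # ((day, volume_mm3), ...)
    vascular_obs: tuple  # ((day, fraction), ...)

    def __post_init__(self):
        for day, v in self.tumor_obs:
            if v < 0:
                raise ValueError(f"tumor volume < 0 at day {day}")
        for day, v in self.vascular_obs:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"vascular fraction outside [0,1] at day {day}")

    @property
    def N_t(self) -> int:
        return len(self.tumor_obs)

    @property
    def N_v(self) -> int:
        return len(self.vascular_obs)

    @property
    def tumor_days(self) -> np.ndarray:
        return np.array([d for d, _ in self.tumor_obs])

    @property
    def tumor_values(self) -> np.ndarray:
        return np.array([v for _, v in self.tumor_obs])

    @property
    def vascular_days(self) -> np.ndarray:
        return np.array([d for d, _ in self.vascular_obs])

    @property
    def vascular_values(self) -> np.ndarray:
        return np.array([v for _, v in self.vascular_obs])


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise, reproducible from the seed."""

    sigma_T: float = 25.0   # mm^3, per-mouse measurement scale
    sigma_V: float = 0.05   # fraction, per-mouse
    seed: int = 0
    n_replicates: int = 8   # mice per arm, averaged into the group-mean series

    def __post_init__(self):
        if self.sigma_T < 0 or self.sigma_V < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def default_measurement_days(t_span=DEFAULT_WINDOW) -> tuple:
    """Caliper measurement days: every 2-3 days from day 6 through day 39."""
    days, step = [], (3.0, 2.0)
    t, i = float(t_span[0]), 0
    while t <= t_span[1] + 1e-9:
        days.append(round(t, 6))
        t += step[i % 2]
        i += 1
    if t_span[1] - days[-1] >= 2.0:
        days.append(float(t_span[1]))
    return tuple(days)


def default_protocol(
    immuno_days=DEFAULT_IMMUNO_DAYS,
    evo_days=DEFAULT_EVO_DAYS,
    V0=None,
    T0=DEFAULT_T0,
    t_span=DEFAULT_WINDOW,
) -> list:
    """The six default :class:`ScenarioSpec` arms."""
    v0 = dict(DEFAULT_V0)
    if V0:
        v0.update(V0)
    tumor_days = default_measurement_days(t_span)
    receives = {
        "I": (False, False), "II": (True, False), "III": (True, False),
        "IV": (False, True), "V": (True, True), "VI": (True, True),
    }
    specs = []
    for sid in SCENARIO_IDS:
        imm, evo = receives[sid]
        specs.append(
            ScenarioSpec(
                id=sid,
                label=_LABELS[sid],
                receives_immuno=imm,
                receives_evo=evo,
                V0=v0[sid],
                T0=T0,
                schedule=TreatmentSchedule(
                    immuno_days=tuple(immuno_days) if imm else (),
                    evo_days=tuple(evo_days) if evo else (),
                ),
                tumor_days=tumor_days,
                vascular_days=VASCULAR_IMAGING_DAYS,
            )
        )
    return specs


def generate_cohort(
    true_params: ModelParameters,
    specs,
    noise: NoiseSpec,
    t_span=DEFAULT_WINDOW,
    dt: float = 0.01,
    param_overrides=None,
) -> dict:
    """Simulate every arm and add measurement noise.

    ``param_overrides`` maps scenario id -> {rate name: value} and exists
    for designed-failure experiments (e.g. generating the normoxic
    combination arm with an inflated gamma_i).

    Returns
    -------
    dict of scenario id -> :class:`ObservationSet`.
    """
    rng = np.random.default_rng(noise.seed)
    out = {}
    for spec in specs:
        params = true_params
        if param_overrides and spec.id in param_overrides:
            params = params.replace(**param_overrides[spec.id])
        meas_days = np.unique(np.concatenate([spec.tumor_days, spec.vascular_days]))
        traj = simulate(
            params, spec.schedule, spec.T0, spec.V0,
            t_span=t_span, dt=dt, extra_days=meas_days,
        )
        t_true = traj.at(spec.tumor_days, "T")
        v_true = traj.at(spec.vascular_days, "V")
        # group mean of n_replicates i.i.d. noisy mice
        nrep = noise.n_replicates
        t_noisy = t_true + rng.normal(0, noise.sigma_T, (nrep, t_true.size)).mean(axis=0)
        v_noisy = v_true + rng.normal(0, noise.sigma_V, (nrep, v_true.size)).mean(axis=0)
        t_noisy = np.clip(t_noisy, 0.0, None)
        v_noisy = np.clip(v_noisy, 0.0, 1.0)
        out[spec.id] = ObservationSet(
            scenario_id=spec.id,
            tumor_obs=tuple(zip(spec.tumor_days, t_noisy)),
            vascular_obs=tuple(zip(spec.vascular_days, v_noisy)),
        )
    return out
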