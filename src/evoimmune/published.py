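"""Published calibrated parameter values and prior boxes.

The study this package models reports a single shared posterior (mean and
16th/84th percentiles) for the eight kinetic rates, calibrated in stages
to five treatment arms, plus a separate gamma_i re-calibrated to the
sixth (normoxic combination-therapy) arm.  Those printed values serve as
ground truth for synthetic cohorts and as the default parameter set for
forward simulation; the uniform prior boxes are the calibration defaults.
"""

from __future__ import annotations

from .tumor_model import ModelParameters, PARAM_NAMES

__all__ = [
    "POSTERIOR_SHARED",
    "POSTERIOR_VI_GAMMA_I",
    "PRIOR_BOUNDS",
    "posterior_mean_parameters",
    "published_summary",
    "gamma_i_fold_change",
]

#: Shared calibrated posterior (scenarios I-V): mean, 16th and 84th percentiles.
POSTERIOR_SHARED = {
    "k_T": {"mean": 0.33, "p16": 0.31, "p84": 0.34},
    "k_V": {"mean": 0.094, "p16": 0.087, "p84": 0.10},
    "mu_V": {"mean": 0.082, "p16": 0.071, "p84": 0.094},
    "mu_T": {"mean": 0.36, "p16": 0.34, "p84": 0.39},
    "gamma_i": {"mean": 0.022, "p16": 0.016, "p84": 0.029},
    "r_i": {"mean": 0.17, "p16": 0.14, "p84": 0.19},
    "gamma_e": {"mean": 0.0091, "p16": 0.0052, "p84": 0.014},
    "r_e": {"mean": 0.14, "p16": 0.072, "p84": 0.18},
}

#: gamma_i re-calibrated to the normoxic combination-therapy arm (scenario VI).
POSTERIOR_VI_GAMMA_I = {"mean": 0.41, "p16": 0.37, "p84": 0.45}

#: Default uniform prior boxes for the eight rates (per day).
PRIOR_BOUNDS = {
    "k_T": (0.0, 0.4),
    "k_V": (0.0, 0.5),
    "mu_V": (0.0, 0.5),
    "mu_T": (0.0, 0.5),
    "gamma_i": (0.0, 3.5),
    "r_i": (0.0, 0.2),
    "gamma_e": (0.0, 3.5),
    "r_e": (0.0, 0.2),
}


def posterior_mean_parameters() -> ModelParameters:
    """The shared posterior means as a :class:`ModelParameters`."""
    return ModelParameters(**{n: POSTERIOR_SHARED[n]["mean"] for n in PARAM_NAMES})


def posterior_sd(name: str) -> float:
    """Half the 16th-84th percentile span (the sd of a normal)."""
    entry = POSTERIOR_VI_GAMMA_I if name == "gamma_i_VI" else POSTERIOR_SHARED[name]
    return (entry["p84"] - entry["p16"]) / 2.0


def published_summary() -> dict:
    """The published calibrated values in the summary-JSON layout
    (scenario block -> parameter -> {mean, p16, p84}) that the report
    command consumes."""
    return {
        "shared": {k: dict(v) for k, v in POSTERIOR_SHARED.items()},
        "scenario_VI": {"gamma_i": dict(POSTERIOR_VI_GAMMA_I)},
    }


def gamma_i_fold_change(summary: dict | None = None) -> float:
    """Ratio of the scenario-VI gamma_i to the shared-arm value.

    This is the headline quantity: how much stronger the immunotherapy
    kill term must be in normoxic tumors receiving evofosfamide than the
    value calibrated to all other arms.
    """
    if summary is None:
        summary = published_summary()
    return summary["scenario_VI"]["gamma_i"]["mean"] / summary["shared"]["gamma_i"]["mean"]
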