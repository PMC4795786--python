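"""Synthetic scenarios, randomized parameter ensembles, and noisy time
courses.

Everything the pipeline consumes can be generated here without any
download: the frozen calibrated default scenario (control and oxidative
stress), log-uniform parameter ensembles around the defaults for
robustness checks, and Gaussian-noise-corrupted cGMP time courses that
stand in for assay readouts when exercising estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model import (
    DEFAULT_INITIAL_STATE,
    DEFAULT_PARAMETERS,
    InitialState,
    ParameterSet,
    ValidationError,
    apply_oxidative_stress,
    simulate,
)

__all__ = [
    "H2O2_DOSE",
    "ScenarioSpec",
    "NoisyTimecourse",
    "default_scenario",
    "sample_parameters",
    "noisy_timecourse",
]

#: Oxidant dose (μM H2O2) defining the stressed condition.
H2O2_DOSE = 500.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified simulation condition.

    ``control`` is the H2O2-free initial state and ``stressed`` the same
    state with the oxidant dose applied. ``seed`` records the RNG seed when
    the parameters were sampled rather than taken from the defaults.
    """

    label: str
    params: ParameterSet
    control: InitialState
    stressed: InitialState
    h2o2: float = H2O2_DOSE
    t_end: float = 200.0
    n_points: int = 201
    seed: int | None = None

    def initial_state(self, stressed: bool = True) -> InitialState:
        return self.stressed if stressed else self.control


def default_scenario(h2o2: float = H2O2_DOSE) -> ScenarioSpec:
    """The frozen calibrated defaults with control and oxidant variants."""
    control = apply_oxidative_stress(DEFAULT_INITIAL_STATE, 0.0)
    return ScenarioSpec(
        label="calibrated-default",
        params=DEFAULT_PARAMETERS,
        control=control,
        stressed=apply_oxidative_stress(control, h2o2),
        h2o2=h2o2,
    )


def sample_parameters(
    seed: int | np.random.Generator,
    spread: float = 0.5,
    base: ParameterSet = DEFAULT_PARAMETERS,
) -> ParameterSet:
    """Draw each rate constant log-uniformly within ±``spread`` decades.

    The activated/basal catalysis ratio is preserved by construction:
    k8 is drawn and k9 is set to 200·k8 rather than sampled.

    ``seed`` may be an integer or an existing Generator (consumed in
    place, so successive calls with one Generator give distinct sets).
    """
    if not spread > 0:
        raise ValidationError(f"spread must be > 0, got {spread}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = {}
    for i in range(1, 14):
        if i == 9:
            continue
        lo = math.log10(getattr(base, f"k{i}")) - spread
        values[f"k{i}"] = 10.0 ** rng.uniform(lo, lo + 2 * spread)
    values["k9"] = 200.0 * values["k8"]
    return ParameterSet(**values)


@dataclass(frozen=True)
class NoisyTimecourse:
    """A cGMP trajectory with additive zero-mean Gaussian noise.

    ``sigma`` is the noise standard deviation as a fraction of the
    noiseless peak. Values are not clamped, so small negatives can occur.
    """

    t: np.ndarray
    cgmp: np.ndarray
    sigma: float
    seed: int

    def peak_time(self) -> float:
        """Grid time of the (noisy) cGMP maximum."""
        return float(self.t[int(np.argmax(self.cgmp))])


def noisy_timecourse(
    scenario: ScenarioSpec,
    sigma: float,
    seed: int,
    *,
    stressed: bool = False,
) -> NoisyTimecourse:
    """Simulate the scenario and add Gaussian noise to the cGMP readout."""
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    res = simulate(
        scenario.params,
        scenario.initial_state(stressed),
        scenario.t_end,
        scenario.n_points,
    )
    cg = res.cgmp.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        cg = cg + rng.normal(0.0, sigma * float(cg.max()), size=cg.shape)
    return NoisyTimecourse(t=res.t, cgmp=cg, sigma=float(sigma), seed=int(seed))
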