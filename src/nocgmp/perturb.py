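"""Combinatorial rate-constant perturbation screening.

A perturbation multiplies one or more rate constants by a fractional ratio
ρ ∈ (0, 1], emulating concentration-dependent inhibition of the targeted
reactions. The screen enumerates every single, paired, and triple target
set among the 13 rate constants (377 sets for the defaults), simulates each
under oxidative stress, and ranks the results by the time-integrated cGMP
response cGMP_T = ∫₀ᵀ [cGMP](t) dt with T = 200 s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    InitialState,
    IntegrationError,
    ParameterSet,
    SimulationResult,
    ValidationError,
    N_RATE_CONSTANTS,
    simulate,
)

__all__ = [
    "PerturbationSpec",
    "IntegratedResponse",
    "enumerate_perturbations",
    "apply_perturbation",
    "integrate_cgmp",
    "screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationSpec:
    """A set of (rate-constant index, fractional ratio) pairs.

    ``targets`` are 1-based, distinct, sorted indices into k1..k13;
    ``ratios`` are per-target multipliers in (0, 1].
    """

    targets: tuple[int, ...]
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        targets = tuple(int(t) for t in self.targets)
        ratios = tuple(float(r) for r in self.ratios)
        if len(targets) != len(ratios):
            raise ValidationError(
                f"{len(targets)} targets but {len(ratios)} ratios"
            )
        if not 1 <= len(targets):
            raise ValidationError("at least one target required")
        if len(set(targets)) != len(targets):
            raise ValidationError(f"duplicate targets in {targets}")
        for t in targets:
            if not 1 <= t <= N_RATE_CONSTANTS:
                raise ValidationError(f"target index out of range 1..13: {t}")
        for r in ratios:
            if not (math.isfinite(r) and 0 < r <= 1):
                raise ValidationError(f"ratio must be in (0, 1], got {r}")
        order = np.argsort(targets)
        object.__setattr__(self, "targets", tuple(targets[i] for i in order))
        object.__setattr__(self, "ratios", tuple(ratios[i] for i in order))

    @classmethod
    def uniform(cls, targets: Iterable[int], rho: float) -> "PerturbationSpec":
        """Spec applying the same ratio to every target."""
        targets = tuple(targets)
        return cls(targets=targets, ratios=(rho,) * len(targets))

    def label(self) -> str:
        return "+".join(f"k{t}" for t in self.targets)


@dataclass(frozen=True)
class IntegratedResponse:
    """Time-integrated cGMP for one perturbation (μM·s over [0, T])."""

    spec: PerturbationSpec | None
    cgmp_T: float
    T: float
    relative_cgmp_T: float | None = None
    peak_cgmp: float | None = None
    peak_time: float | None = None

    def __post_init__(self) -> None:
        if self.cgmp_T < 0:
            raise ValidationError(f"cGMP_T must be >= 0, got {self.cgmp_T}")
        if self.T <= 0:
            raise ValidationError(f"T must be > 0, got {self.T}")


def enumerate_perturbations(q: int = N_RATE_CONSTANTS, max_order: int = 3):
    """All target subsets of {1..q} of size 1..max_order, lexicographic.

    The count is Σᵢ C(q, i) for i = 1..max_order; for q=13, max_order=3
    that is 13 + 78 + 286 = 377.
    """
    if not (isinstance(q, int) and q >= 1):
        raise ValidationError(f"q must be a positive int, got {q!r}")
    if not (isinstance(max_order, int) and 1 <= max_order <= q):
        raise ValidationError(
            f"max_order must be in 1..q={q}, got {max_order!r}"
        )
    out: list[tuple[int, ...]] = []
    for size in range(1, max_order + 1):
        out.extend(combinations(range(1, q + 1), size))
    return out


def apply_perturbation(params: ParameterSet, spec: PerturbationSpec) -> ParameterSet:
    """New ParameterSet with k_i ← ρ_i·k_i for each target; input untouched."""
    return params.scaled(dict(zip(spec.targets, spec.ratios)))


def integrate_cgmp(result: SimulationResult, T: float = 200.0) -> IntegratedResponse:
    """cGMP_T = ∫₀ᵀ [cGMP](t) dt by composite trapezoidal quadrature.

    The result's time grid must cover [0, T]; integration runs over the
    grid points with t <= T (the dense output grid is uniform, so T is
    expected to fall on a grid point).
    """
    if T <= 0:
        raise ValidationError(f"T must be > 0, got {T}")
    t = result.t
    if t[-1] < T - 1e-9:
        raise ValidationError(
            f"time grid ends at {t[-1]:g} s but T={T:g} s was requested"
        )
    mask = t <= T + 1e-9
    cg = result.cgmp
    value = float(np.trapezoid(cg[mask], t[mask]))
    peak, peak_t = result.peak_cgmp()
    return IntegratedResponse(
        spec=None, cgmp_T=value, T=float(T), peak_cgmp=peak, peak_time=peak_t
    )


def screen(
    params: ParameterSet,
    init: InitialState,
    max_order: int = 3,
    rho: float = 0.1,
    *,
    q: int = N_RATE_CONSTANTS,
    t_end: float = 200.0,
    n_points: int = 201,
    control_init: InitialState | None = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """Rank all perturbations up to ``max_order`` by time-integrated cGMP.

    One simulation per enumerated target set, each with the uniform ratio
    ``rho`` applied to every target, under the supplied (typically
    H2O2-containing) initial state. Results are sorted by descending
    cGMP_T with ties broken lexicographically by target tuple.

    Returns a DataFrame with columns: targets, order, rho, cgmp_T,
    relative_cgmp_T (vs. the unperturbed condition of ``init``),
    relative_to_control (if ``control_init`` is given, e.g. the H2O2-free
    state), peak_cgmp, peak_time, status. Failed solves carry an error
    message in ``status``, NaN responses, and sort to the bottom.
    """
    if not (0 < rho <= 1):
        raise ValidationError(f"rho must be in (0, 1], got {rho}")
    base = integrate_cgmp(
        simulate(params, init, t_end, n_points, **sim_kwargs), T=t_end
    )
    ctrl_value = None
    if control_init is not None:
        ctrl_value = integrate_cgmp(
            simulate(params, control_init, t_end, n_points, **sim_kwargs), T=t_end
        ).cgmp_T
    rows = []
    n_failed = 0
    for targets in enumerate_perturbations(q, max_order):
        spec = PerturbationSpec.uniform(targets, rho)
        row = {
            "targets": spec.label(),
            "order": len(targets),
            "rho": rho,
            "_targets": targets,
        }
        try:
            res = simulate(
                apply_perturbation(params, spec), init, t_end, n_points, **sim_kwargs
            )
            resp = integrate_cgmp(res, T=t_end)
        except IntegrationError as exc:
            n_failed += 1
            logger.warning("perturbation %s failed: %s", spec.label(), exc)
            row.update(
                cgmp_T=np.nan,
                relative_cgmp_T=np.nan,
                peak_cgmp=np.nan,
                peak_time=np.nan,
                status=f"error: {exc}",
            )
        else:
            row.update(
                cgmp_T=resp.cgmp_T,
                relative_cgmp_T=resp.cgmp_T / base.cgmp_T if base.cgmp_T > 0 else np.nan,
                peak_cgmp=resp.peak_cgmp,
                peak_time=resp.peak_time,
                status="ok",
            )
        if ctrl_value is not None:
            row["relative_to_control"] = (
                row["cgmp_T"] / ctrl_value if ctrl_value > 0 else np.nan
            )
        rows.append(row)
    if n_failed:
        logger.warning(
            "%d of %d perturbations failed and are excluded from the ranking",
            n_failed,
            len(rows),
        )
    df = pd.DataFrame(rows)
    ok = df["status"] == "ok"
    ranked = df[ok].sort_values(
        ["cgmp_T", "_targets"], ascending=[False, True], kind="mergesort"
    )
    failed = df[~ok].sort_values("_targets", kind="mergesort")
    df = pd.concat([ranked, failed]).drop(columns="_targets").reset_index(drop=True)
    return df
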