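"""Dose-combination analysis: dose vectors, response surfaces, Bliss
independence, and isobologram additivity classification.

Perturbation strength is expressed as the fractional ratio ρ left on a rate
constant (ρ = 1 is untreated). Two equivalent inhibitor-dose coordinates
are used when classifying isoboles:

* the residual-fraction dose d = 1 - ρ (the axes the dose matrices are
  plotted on, up to orientation), and
* the equivalent-occupancy dose x = 1/ρ - 1, the inhibitor concentration
  in units of its binding constant that reduces an effective rate constant
  to ρ·k under simple competitive inhibition (ρ = 1 / (1 + [I]/K_i)).

A combination's interaction call (synergistic / antagonistic) is reported
only when the iso-effect contour bows the same way beyond threshold in both
coordinates; a call that inverts under a monotone reparameterization of
dose is not robust evidence of interaction, and the combination is then
classified additive. See docs/methods.md for the rationale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from contourpy import contour_generator
from scipy.integrate import solve_ivp

from .model import (
    InitialState,
    ParameterSet,
    ValidationError,
    apply_oxidative_stress,
    simulate,
)
from .perturb import PerturbationSpec, apply_perturbation, integrate_cgmp

__all__ = [
    "DoseVector",
    "CombinationSurface",
    "BlissPrediction",
    "IsoboleClassification",
    "make_dose_vector",
    "dose_response",
    "bliss_predict",
    "compare_to_bliss",
    "build_surface",
    "classify_isoboles",
    "overall_call",
    "independent_channels_response",
    "RHO_MIN_CONVENTION",
    "N_DOSES",
]

logger = logging.getLogger(__name__)

#: Published convention: the dose-vector minimum is 0.1 for single, 0.3 for
#: paired, and 0.5 for triple perturbations (weaker individual inhibition as
#: more targets are combined).
RHO_MIN_CONVENTION = {1: 0.1, 2: 0.3, 3: 0.5}

#: Dose vectors carry eleven linearly spaced ratios.
N_DOSES = 11


@dataclass(frozen=True)
class DoseVector:
    """Fractional multipliers for one rate constant, 1.0 down to ρ_min.

    The published convention uses eleven linearly spaced values
    (:data:`N_DOSES`); denser grids are permitted for refinement checks.
    """

    target: int
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if r.size < 2:
            raise ValidationError(f"dose vector needs at least 2 values, got {r.size}")
        if r[0] != 1.0:
            raise ValidationError("dose vector must start at 1.0")
        if not (np.diff(r) < 0).all():
            raise ValidationError("dose vector must be strictly decreasing")
        if r[-1] <= 0:
            raise ValidationError("dose vector minimum must be > 0")
        object.__setattr__(self, "ratios", tuple(float(v) for v in r))

    @property
    def rho_min(self) -> float:
        return self.ratios[-1]

    def doses(self) -> np.ndarray:
        """Residual-fraction doses d = 1 - ρ (ascending from 0)."""
        return 1.0 - np.asarray(self.ratios)


def make_dose_vector(target: int, rho_min: float, n: int = N_DOSES) -> DoseVector:
    """Linearly spaced dose vector from 1.0 down to ``rho_min`` inclusive."""
    if not (0 < rho_min < 1):
        raise ValidationError(f"rho_min must be in (0, 1), got {rho_min}")
    ratios = np.linspace(1.0, rho_min, n)
    return DoseVector(target=int(target), ratios=tuple(ratios))


def dose_response(
    params: ParameterSet,
    init: InitialState,
    vector: DoseVector,
    *,
    t_end: float = 200.0,
    n_points: int = 201,
    **sim_kwargs,
) -> pd.DataFrame:
    """Simulate cGMP_T at every multiplier of a single-target dose vector.

    Returns a DataFrame with columns rho, cgmp_T, relative_cgmp_T (vs. the
    ρ=1 entry), peak_cgmp, peak_time.
    """
    rows = []
    for rho in vector.ratios:
        p = params.scaled({vector.target: rho})
        resp = integrate_cgmp(simulate(p, init, t_end, n_points, **sim_kwargs), T=t_end)
        rows.append(
            {
                "rho": rho,
                "cgmp_T": resp.cgmp_T,
                "peak_cgmp": resp.peak_cgmp,
                "peak_time": resp.peak_time,
            }
        )
    df = pd.DataFrame(rows)
    base = df["cgmp_T"].iloc[0]
    df["relative_cgmp_T"] = df["cgmp_T"] / base if base > 0 else np.nan
    return df


# ---------------------------------------------------------------------------
# Bliss independence
# ---------------------------------------------------------------------------

def bliss_predict(effect_i: float, effect_j: float, mode: str = "response-product") -> float:
    """Combined-effect prediction for two independent inhibitions.

    ``response-product`` is standard Bliss independence on fractional
    effects in [0, 1]: E_ij = E_i + E_j - E_i·E_j. ``literal-eq15``
    multiplies the two arguments as printed (the combined perturbation
    ratio as the product of the individual ratios); arguments may then be
    any non-negative ratios.
    """
    if mode == "response-product":
        for e in (effect_i, effect_j):
            if not (math.isfinite(e) and 0 <= e <= 1):
                raise ValidationError(
                    f"fractional effects must be in [0, 1] for mode "
                    f"'response-product', got {e!r}"
                )
        return effect_i + effect_j - effect_i * effect_j
    if mode == "literal-eq15":
        for e in (effect_i, effect_j):
            if not (math.isfinite(e) and e >= 0):
                raise ValidationError(f"ratios must be >= 0, got {e!r}")
        return effect_i * effect_j
    raise ValidationError(f"unknown Bliss mode {mode!r}")


@dataclass(frozen=True)
class BlissPrediction:
    """Observed vs. Bliss-predicted combined response for one pair."""

    spec: PerturbationSpec
    mode: str
    single_i: float  # cGMP_T with only the first target perturbed
    single_j: float
    observed: float  # cGMP_T with both targets perturbed
    predicted: float
    baseline: float  # unperturbed (H2O2) cGMP_T
    control: float  # H2O2-free cGMP_T used for the effect scale
    t: np.ndarray | None = None
    observed_timecourse: np.ndarray | None = None
    predicted_timecourse: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.predicted < 0 or self.observed < 0:
            raise ValidationError("responses must be >= 0")

    @property
    def excess(self) -> float:
        """Observed minus predicted combined cGMP_T (μM·s)."""
        return self.observed - self.predicted


def compare_to_bliss(
    pair: Sequence[int],
    rho: float,
    params: ParameterSet,
    init: InitialState,
    *,
    control_init: InitialState | None = None,
    mode: str = "response-product",
    t_end: float = 200.0,
    n_points: int = 201,
    **sim_kwargs,
) -> BlissPrediction:
    """Simulate a pair and its two singles; compare to the Bliss prediction.

    With the default mode, the fractional effect of a perturbation s is
    E(s) = (cGMP_T(s) - cGMP_T(baseline)) / (cGMP_T(control) -
    cGMP_T(baseline)), where baseline is the unperturbed H2O2 condition and
    control is the H2O2-free condition; effects are clipped into [0, 1]
    before combination, and the predicted pair response is mapped back to
    the cGMP_T scale. Time courses are combined pointwise wherever the
    control-baseline span is resolvable.
    """
    pair = tuple(int(i) for i in pair)
    if len(pair) != 2 or pair[0] == pair[1]:
        raise ValidationError(f"pair must be two distinct targets, got {pair}")
    spec = PerturbationSpec.uniform(pair, rho)
    if control_init is None:
        control_init = apply_oxidative_stress(init, 0.0)

    def run(p):
        return simulate(p, init, t_end, n_points, **sim_kwargs)

    base_res = run(params)
    ctrl_res = simulate(params, control_init, t_end, n_points, **sim_kwargs)
    res_i = run(params.scaled({pair[0]: rho}))
    res_j = run(params.scaled({pair[1]: rho}))
    res_ij = run(apply_perturbation(params, spec))

    T = t_end
    base = integrate_cgmp(base_res, T).cgmp_T
    ctrl = integrate_cgmp(ctrl_res, T).cgmp_T
    si = integrate_cgmp(res_i, T).cgmp_T
    sj = integrate_cgmp(res_j, T).cgmp_T
    obs = integrate_cgmp(res_ij, T).cgmp_T

    if mode == "response-product":
        span = ctrl - base
        if span <= 0:
            raise ValidationError(
                "control response does not exceed the baseline; the "
                "fractional-effect scale is undefined"
            )
        ei = min(max((si - base) / span, 0.0), 1.0)
        ej = min(max((sj - base) / span, 0.0), 1.0)
        predicted = base + bliss_predict(ei, ej, mode) * span
        # pointwise prediction where the span is resolvable
        span_t = ctrl_res.cgmp - base_res.cgmp
        tiny = 1e-6 * max(float(span_t.max()), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            ei_t = np.clip((res_i.cgmp - base_res.cgmp) / span_t, 0.0, 1.0)
            ej_t = np.clip((res_j.cgmp - base_res.cgmp) / span_t, 0.0, 1.0)
            pred_t = base_res.cgmp + (ei_t + ej_t - ei_t * ej_t) * span_t
        pred_t[np.abs(span_t) <= tiny] = np.nan
    elif mode == "literal-eq15":
        # multiplicative null on the response scale: the combined fold-change
        # is the product of the single fold-changes
        if base <= 0:
            raise ValidationError("baseline response is zero; fold-changes undefined")
        predicted = base * bliss_predict(si / base, sj / base, mode)
        with np.errstate(divide="ignore", invalid="ignore"):
            pred_t = np.where(
                base_res.cgmp > 0,
                base_res.cgmp * (res_i.cgmp / base_res.cgmp) * (res_j.cgmp / base_res.cgmp),
                np.nan,
            )
    else:
        raise ValidationError(f"unknown Bliss mode {mode!r}")

    return BlissPrediction(
        spec=spec,
        mode=mode,
        single_i=si,
        single_j=sj,
        observed=obs,
        predicted=float(max(predicted, 0.0)),
        baseline=base,
        control=ctrl,
        t=base_res.t,
        observed_timecourse=res_ij.cgmp,
        predicted_timecourse=pred_t,
    )


# ---------------------------------------------------------------------------
# Combination surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationSurface:
    """cGMP_T on a full-factorial dose grid over 2 or 3 rate constants.

    ``values`` has one axis per target, each of length 11 (or the requested
    grid size), ordered along the corresponding dose vector (ρ descending
    from 1.0). ``values[0, 0(, 0)]`` is the unperturbed reference.
    """

    targets: tuple[int, ...]
    vectors: tuple[DoseVector, ...]
    values: np.ndarray
    reference: float  # unperturbed cGMP_T (equals the all-ones corner)

    def __post_init__(self) -> None:
        if len(self.targets) not in (2, 3):
            raise ValidationError("surface must have 2 or 3 targets")
        if self.values.ndim != len(self.targets):
            raise ValidationError("grid dimensionality must match target count")
        if (np.asarray(self.values) < 0).any():
            raise ValidationError("cGMP_T values must be >= 0")

    def normalized(self) -> np.ndarray:
        """Surface as relative cGMP_T (unperturbed corner = 1)."""
        return self.values / self.reference

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per grid cell."""
        axes = [np.asarray(v.ratios) for v in self.vectors]
        mesh = np.meshgrid(*axes, indexing="ij")
        data = {f"rho_{t}": m.ravel() for t, m in zip(self.targets, mesh)}
        data["cgmp_T"] = self.values.ravel()
        data["relative_cgmp_T"] = self.normalized().ravel()
        return pd.DataFrame(data)


def build_surface(
    targets: Sequence[int],
    params: ParameterSet,
    init: InitialState,
    *,
    rho_min: float | None = None,
    n: int = N_DOSES,
    t_end: float = 200.0,
    n_points: int = 201,
    **sim_kwargs,
) -> CombinationSurface:
    """Full-factorial cGMP_T surface over 2 or 3 dose vectors.

    ``rho_min`` defaults to the published convention for the combination
    order (0.3 for pairs, 0.5 for triples). ``n`` points per axis (11 by
    default; 121 or 1331 simulations).
    """
    targets = tuple(int(t) for t in targets)
    if len(targets) not in (2, 3):
        raise ValidationError(f"2 or 3 targets required, got {targets}")
    if len(set(targets)) != len(targets):
        raise ValidationError(f"duplicate targets: {targets}")
    if rho_min is None:
        rho_min = RHO_MIN_CONVENTION[len(targets)]
    if not (0 < rho_min < 1):
        raise ValidationError(f"rho_min must be in (0, 1), got {rho_min}")
    ratios = np.linspace(1.0, rho_min, n)
    vectors = tuple(DoseVector(t, tuple(ratios)) for t in targets)
    shape = (n,) * len(targets)
    values = np.empty(shape)
    for idx in np.ndindex(shape):
        scale = {t: ratios[i] for t, i in zip(targets, idx)}
        resp = integrate_cgmp(
            simulate(params.scaled(scale), init, t_end, n_points, **sim_kwargs),
            T=t_end,
        )
        values[idx] = resp.cgmp_T
    return CombinationSurface(
        targets=targets,
        vectors=vectors,
        values=values,
        reference=float(values[(0,) * len(targets)]),
    )


# ---------------------------------------------------------------------------
# Isobole classification
# ---------------------------------------------------------------------------

def _contour_index(x_axis: np.ndarray, y_axis: np.ndarray, E: np.ndarray,
                   level: float) -> float | None:
    """Normalized signed area between an iso-effect contour and its chord.

    The contour is extracted by bilinear interpolation on the effect grid.
    It must run from an intercept on the y axis to an intercept on the
    x axis; otherwise None is returned. Positive values mean the contour
    bows toward the origin (less combined dose needed than the linear
    isobole: synergy); negative values mean it bows away.
    """
    cg = contour_generator(x=x_axis, y=y_axis, z=E)
    lines = cg.lines(level)
    eps_x = 1e-9 * max(abs(x_axis[-1]), 1.0)
    eps_y = 1e-9 * max(abs(y_axis[-1]), 1.0)
    for line in sorted(lines, key=len, reverse=True):
        p0, p1 = line[0], line[-1]
        a, b = sorted([p0, p1], key=lambda p: p[0])
        if abs(a[0]) > eps_x or abs(b[1]) > eps_y:
            continue  # does not span both axes
        D2 = float(a[1])  # y-axis intercept
        D1 = float(b[0])  # x-axis intercept
        if D1 <= 0 or D2 <= 0:
            continue
        poly = line if np.allclose(line[0], a) else line[::-1]
        xs = np.append(poly[:, 0], poly[0, 0])
        ys = np.append(poly[:, 1], poly[0, 1])
        area = 0.5 * float(np.sum(xs[:-1] * ys[1:] - xs[1:] * ys[:-1]))
        return area / (0.5 * D1 * D2)
    return None


def _classify_section(
    rhos_y: np.ndarray,
    rhos_x: np.ndarray,
    Z: np.ndarray,
    effect_levels: Sequence[float],
    threshold: float,
) -> list[dict]:
    """Classify one 2-D cGMP_T section in both dose coordinates."""
    E = Z - Z[0, 0]
    m = float(E.max())
    if m <= 0:
        raise ValidationError("section shows no positive effect; nothing to classify")
    E = E / m
    # iso-effect levels must be achievable by each agent alone for the
    # isobole to intersect both axes; scale to the weaker single-agent arm
    arm_max = min(float(E[1:, 0].max()), float(E[0, 1:].max()))
    d_y, d_x = 1.0 - rhos_y, 1.0 - rhos_x
    x_y, x_x = 1.0 / rhos_y - 1.0, 1.0 / rhos_x - 1.0
    rows = []
    for f in effect_levels:
        if not 0 < f < 1:
            raise ValidationError(f"effect levels must be in (0, 1), got {f}")
        level = f * arm_max
        ci_frac = _contour_index(d_x, d_y, E, level)
        ci_occ = _contour_index(x_x, x_y, E, level)
        if ci_frac is None or ci_occ is None:
            logger.warning(
                "iso-effect contour at level %.3g does not intersect both axes; skipped",
                level,
            )
            rows.append(
                {"level_fraction": f, "level": level, "index_fraction_plane": np.nan,
                 "index_occupancy_plane": np.nan, "classification": "skipped"}
            )
            continue
        if ci_frac > threshold and ci_occ > threshold:
            call = "synergistic"
        elif ci_frac < -threshold and ci_occ < -threshold:
            call = "antagonistic"
        else:
            call = "additive"
        rows.append(
            {"level_fraction": f, "level": level, "index_fraction_plane": ci_frac,
             "index_occupancy_plane": ci_occ, "classification": call}
        )
    return rows


@dataclass(frozen=True)
class IsoboleClassification:
    """Per-level (and, for 3-D surfaces, per-section) interaction calls."""

    table: pd.DataFrame

    @property
    def overall(self) -> str:
        return overall_call(self.table)


def overall_call(table: pd.DataFrame) -> str:
    """Majority interaction call over all classified levels (ties: additive)."""
    calls = table.loc[table["classification"] != "skipped", "classification"]
    if calls.empty:
        return "unclassified"
    counts = calls.value_counts()
    top = counts[counts == counts.max()].index.tolist()
    return top[0] if len(top) == 1 else "additive"


def classify_isoboles(
    surface: CombinationSurface,
    effect_levels: Sequence[float] = (0.25, 0.5, 0.75),
    *,
    threshold: float = 0.05,
) -> IsoboleClassification:
    """Classify a combination surface as additive/synergistic/antagonistic.

    Iso-effect contours are extracted at ``effect_levels`` (fractions of the
    largest effect the weaker single-agent arm achieves, so every contour
    has two axis intercepts). Each contour's curvature index is the signed
    area between the contour and the straight line joining its axis
    intercepts, normalized by the intercept-triangle area, computed in both
    dose coordinates (see the module docstring); |index| <= ``threshold``
    in either coordinate, or disagreement in sign, yields "additive".

    3-D surfaces are classified on their three axis-aligned sections
    through the ρ=1 faces plus the main-diagonal section in which the
    second and third doses move together.
    """
    rows: list[dict] = []
    if len(surface.targets) == 2:
        ry = np.asarray(surface.vectors[0].ratios)
        rx = np.asarray(surface.vectors[1].ratios)
        for row in _classify_section(ry, rx, surface.values, effect_levels, threshold):
            row["section"] = f"k{surface.targets[0]}-k{surface.targets[1]}"
            rows.append(row)
    else:
        t1, t2, t3 = surface.targets
        r = [np.asarray(v.ratios) for v in surface.vectors]
        Z = surface.values
        sections = [
            (f"k{t1}-k{t2}", r[0], r[1], Z[:, :, 0]),
            (f"k{t1}-k{t3}", r[0], r[2], Z[:, 0, :]),
            (f"k{t2}-k{t3}", r[1], r[2], Z[0, :, :]),
            (f"k{t1}-diag(k{t2},k{t3})", r[0], r[1],
             Z[:, np.arange(Z.shape[1]), np.arange(Z.shape[2])]),
        ]
        for name, ry, rx, section in sections:
            for row in _classify_section(ry, rx, section, effect_levels, threshold):
                row["section"] = name
                rows.append(row)
    cols = ["section", "level_fraction", "level", "index_fraction_plane",
            "index_occupancy_plane", "classification"]
    return IsoboleClassification(table=pd.DataFrame(rows)[cols])


# ---------------------------------------------------------------------------
# Independence oracle
# ---------------------------------------------------------------------------

def independent_channels_response(
    dose_i: float,
    dose_j: float,
    *,
    transmit: tuple[float, float] = (0.5, 0.4),
    loss: tuple[float, float] = (0.25, 0.2),
    t_end: float = 400.0,
    analytic: bool = False,
) -> float:
    """Response of a two-stage toy cascade with independent losses.

    Signal flows A -> B -> C through two sequential transmission steps with
    rate constants ``transmit``; each stage also loses signal at rate
    ``loss[i] * (1 + dose_i)``, i.e. inhibitor i accelerates only its own
    stage's loss. The response is the final amount of C. Because each
    inhibitor scales the survival of its own stage only, the fractional
    inhibition of the combination obeys Bliss independence exactly:
    1 - E_ij = (1 - E_i)(1 - E_j).

    With ``analytic=True`` the closed-form branching product is returned;
    otherwise the three-species linear ODE system is integrated
    numerically (the default, so the check is independent of the algebra).
    """
    for d in (dose_i, dose_j):
        if d < 0:
            raise ValidationError(f"doses must be >= 0, got {d}")
    t1, t2 = transmit
    l1 = loss[0] * (1.0 + dose_i)
    l2 = loss[1] * (1.0 + dose_j)
    if analytic:
        return (t1 / (t1 + l1)) * (t2 / (t2 + l2))

    def deriv(t, y):
        a, b, c = y
        return [-(t1 + l1) * a, t1 * a - (t2 + l2) * b, t2 * b]

    sol = solve_ivp(deriv, (0.0, t_end), [1.0, 0.0, 0.0], method="LSODA",
                    rtol=1e-10, atol=1e-12)
    return float(sol.y[2, -1])
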