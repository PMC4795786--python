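"""Unit and property tests for the 12-species kinetic model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nocgmp import (
    DEFAULT_INITIAL_STATE,
    DEFAULT_PARAMETERS,
    InitialState,
    NegativityError,
    ParameterSet,
    SPECIES,
    ValidationError,
    apply_oxidative_stress,
    conservation_drift,
    jacobian,
    rhs,
    simulate,
)

ZERO_PARAMS = ParameterSet(*([0.0] * 13))
ZERO_STATE = InitialState()


def test_rhs_no_species_no_flux():
    assert np.array_equal(rhs(ZERO_STATE, DEFAULT_PARAMETERS), np.zeros(12))


def test_rhs_no_rates_no_flux():
    state = InitialState(h2o2=3.0, sgc=1.0, no=0.5, gtp=10.0, pde=1.0, cgmp=2.0)
    assert np.array_equal(rhs(state, ZERO_PARAMS), np.zeros(12))


def test_rhs_oxidation_only_hand_derived():
    # only the H2O2 + sGC -> sGC_H2O2 reaction is active
    state = InitialState(h2o2=1.0, sgc=1.0)
    params = ParameterSet(0.01, *([0.0] * 12))
    dy = rhs(state, params)
    expected = np.zeros(12)
    expected[SPECIES.index("H2O2")] = -0.01
    expected[SPECIES.index("sGC")] = -0.01
    expected[SPECIES.index("sGC_H2O2")] = +0.01
    np.testing.assert_allclose(dy, expected, atol=0)


def test_rhs_strict_rejects_negative():
    y = np.zeros(12)
    y[0] = -1e-3
    rhs(y, DEFAULT_PARAMETERS)  # permissive by default
    with pytest.raises(ValidationError, match="H2O2"):
        rhs(y, DEFAULT_PARAMETERS, strict=True)


def test_rhs_dimension_mismatch():
    with pytest.raises(ValidationError):
        rhs(np.zeros(11), DEFAULT_PARAMETERS)


def test_jacobian_matches_finite_differences():
    rng = np.random.default_rng(0)
    y = rng.uniform(0.0, 2.0, size=12)
    J = jacobian(y, DEFAULT_PARAMETERS)
    eps = 1e-7
    for j in range(12):
        yp, ym = y.copy(), y.copy()
        yp[j] += eps
        ym[j] -= eps
        col = (rhs(yp, DEFAULT_PARAMETERS) - rhs(ym, DEFAULT_PARAMETERS)) / (2 * eps)
        np.testing.assert_allclose(J[:, j], col, rtol=1e-5, atol=1e-7)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    y=st.lists(st.floats(0.0, 100.0), min_size=12, max_size=12),
    k=st.lists(st.floats(0.0, 10.0), min_size=13, max_size=13),
)
def test_vector_field_conservation(y, k):
    """The rate law conserves the sGC, guanine, and PDE moieties and drains
    the NO· pool only through the k13 sink, for any state and parameters."""
    y = np.array(y)
    params = ParameterSet(*k)
    dy = rhs(y, params)
    idx = {s: i for i, s in enumerate(SPECIES)}
    scale = max(float(np.max(np.abs(dy))), 1.0)
    sgc = sum(dy[idx[s]] for s in ("sGC", "sGC_H2O2", "NO_sGC", "sGC_GTP", "NO_sGC_GTP"))
    gua = sum(dy[idx[s]] for s in ("GTP", "sGC_GTP", "NO_sGC_GTP", "cGMP", "cGMP_PDE", "GMP"))
    pde = dy[idx["PDE"]] + dy[idx["cGMP_PDE"]]
    no = sum(dy[idx[s]] for s in ("NO", "NO_sGC", "NO_sGC_GTP"))
    assert abs(sgc) <= 1e-12 * scale
    assert abs(gua) <= 1e-12 * scale
    assert abs(pde) <= 1e-12 * scale
    assert abs(no + params.k13 * y[idx["NO"]]) <= 1e-12 * scale


def test_simulate_no_substrate_gives_zero_cgmp():
    init = InitialState(sgc=0.1, pde=0.1)  # no NO, no H2O2, no GTP
    res = simulate(DEFAULT_PARAMETERS, init, t_end=50.0, n_points=51)
    assert np.all(res.cgmp == 0.0)


def test_simulate_bimolecular_closed_form():
    """With only k1 active the H2O2 trajectory follows the analytic solution
    of the irreversible bimolecular reaction A + B -> C."""
    a0, b0, k = 2.0, 1.0, 0.05
    params = ParameterSet(k, *([0.0] * 12))
    init = InitialState(h2o2=a0, sgc=b0)
    res = simulate(params, init, t_end=100.0, n_points=101)
    t = res.t
    # A(t) for A0 != B0: A = A0 (A0-B0) / (A0 - B0 exp(-(A0-B0) k t))
    d = a0 - b0
    expected = a0 * d / (a0 - b0 * np.exp(-d * k * t))
    np.testing.assert_allclose(res.species("H2O2"), expected, rtol=1e-6)


def test_first_row_equals_init(control_result, scenario):
    np.testing.assert_array_equal(control_result.y[0], scenario.control.as_array())


def test_trajectory_row_count(control_result):
    assert control_result.y.shape == (control_result.t.size, 12)


def test_apply_oxidative_stress_contract():
    init = DEFAULT_INITIAL_STATE
    stressed = apply_oxidative_stress(init, 500.0)
    assert stressed.h2o2 == 500.0
    assert stressed.sgc == init.sgc and stressed.no == init.no
    # identity at zero dose
    assert apply_oxidative_stress(init, 0.0) == init
    # replacement, not accumulation
    once = apply_oxidative_stress(init, 100.0)
    assert apply_oxidative_stress(once, 500.0).h2o2 == 500.0
    with pytest.raises(ValidationError):
        apply_oxidative_stress(init, -1.0)


def test_oxidant_and_substrate_pool_nonincreasing(stressed_result):
    """H2O2 has no source term, so it never increases. Free GTP can rise
    transiently (the enzyme-substrate complexes release it at k5 and k7),
    but the unconverted substrate pool GTP + sGC_GTP + NO_sGC_GTP only
    drains, through catalysis."""
    h2o2 = stressed_result.species("H2O2")
    assert np.all(np.diff(h2o2) <= 1e-12)
    pool = (stressed_result.species("GTP")
            + stressed_result.species("sGC_GTP")
            + stressed_result.species("NO_sGC_GTP"))
    assert np.all(np.diff(pool) <= 1e-10)


def test_peak_cgmp_monotone_in_oxidant(scenario):
    peaks = []
    for dose in (0.0, 100.0, 250.0, 500.0, 1000.0):
        init = apply_oxidative_stress(scenario.control, dose)
        res = simulate(scenario.params, init)
        peaks.append(res.peak_cgmp()[0])
    assert np.all(np.diff(peaks) <= 0)


def test_conservation_on_default_trajectories(control_result, stressed_result):
    for res in (control_result, stressed_result):
        for name, drift in conservation_drift(res).items():
            assert drift < 1e-6, name


def _rk4(f, y0, t_end, dt):
    y = y0.copy()
    t = 0.0
    while t < t_end - 1e-12:
        h = min(dt, t_end - t)
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y


def test_adaptive_solver_matches_fixed_step_reference(scenario):
    """On a short horizon the stiff solver agrees with a fixed-step 4th-order
    integrator at dt = 1e-4 s to relative error < 1e-4."""
    params, init = scenario.params, scenario.stressed
    f = lambda y: rhs(y, params)
    ref = _rk4(f, init.as_array(), 1.0, 1e-4)
    res = simulate(params, init, t_end=1.0, n_points=11)
    scale = max(float(np.max(np.abs(ref))), 1.0)
    np.testing.assert_allclose(res.y[-1], ref, rtol=1e-4, atol=1e-4 * scale * 1e-4)


def test_simulate_validation():
    with pytest.raises(ValidationError):
        simulate(DEFAULT_PARAMETERS, DEFAULT_INITIAL_STATE, t_end=0.0)
    with pytest.raises(ValidationError):
        simulate(DEFAULT_PARAMETERS, DEFAULT_INITIAL_STATE, n_points=1)


def test_parameter_set_validation():
    with pytest.raises(ValidationError):
        ParameterSet(*([-1.0] + [0.0] * 12))
    with pytest.raises(ValidationError):
        ParameterSet(*([float("nan")] + [0.0] * 12))
    with pytest.raises(ValidationError, match="k13"):
        ParameterSet.from_dict({f"k{i}": 1.0 for i in range(1, 13)})


def test_parameter_scaling_out_of_range():
    with pytest.raises(ValidationError):
        DEFAULT_PARAMETERS.scaled({14: 0.5})
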