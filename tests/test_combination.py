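"""Tests for dose vectors, response surfaces, Bliss comparison, and the
isobole classifier."""

import numpy as np
import pytest

from nocgmp import (
    CombinationSurface,
    DoseVector,
    ValidationError,
    bliss_predict,
    build_surface,
    classify_isoboles,
    compare_to_bliss,
    dose_response,
    independent_channels_response,
    integrate_cgmp,
    make_dose_vector,
    simulate,
)


# ---------------------------------------------------------------------------
# dose vectors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rho_min,step", [(0.1, 0.09), (0.3, 0.07), (0.5, 0.05)]
)
def test_dose_vector_spacing(rho_min, step):
    vec = make_dose_vector(3, rho_min)
    r = np.asarray(vec.ratios)
    assert r.size == 11
    assert r[0] == 1.0 and r[-1] == pytest.approx(rho_min)
    np.testing.assert_allclose(-np.diff(r), step, rtol=1e-12)


def test_dose_vector_degenerate_narrow_range():
    vec = make_dose_vector(1, 0.999)
    assert np.all(np.diff(vec.ratios) < 0)


def test_dose_vector_validation():
    with pytest.raises(ValidationError):
        make_dose_vector(1, 1.0)
    with pytest.raises(ValidationError):
        make_dose_vector(1, 0.0)
    with pytest.raises(ValidationError):
        DoseVector(1, (0.9,) * 11)  # does not start at 1.0


def test_dose_response_matches_manual_pipeline(scenario):
    """The dose-response endpoint equals apply + simulate + integrate done
    by hand, and the ρ=1 entry equals the unperturbed response."""
    vec = make_dose_vector(10, 0.1)
    df = dose_response(scenario.params, scenario.stressed, vec)
    manual = integrate_cgmp(
        simulate(scenario.params.scaled({10: 0.1}), scenario.stressed)
    ).cgmp_T
    assert df["cgmp_T"].iloc[-1] == manual
    unperturbed = integrate_cgmp(simulate(scenario.params, scenario.stressed)).cgmp_T
    assert df["cgmp_T"].iloc[0] == unperturbed
    assert df["relative_cgmp_T"].iloc[0] == 1.0


# ---------------------------------------------------------------------------
# Bliss independence
# ---------------------------------------------------------------------------

def test_bliss_predict_closed_forms():
    assert bliss_predict(0.0, 0.6) == pytest.approx(0.6)  # null inhibitor
    assert bliss_predict(0.5, 0.5) == pytest.approx(0.75)
    assert bliss_predict(1.0, 0.2) == pytest.approx(1.0)
    assert bliss_predict(0.1, 0.1, mode="literal-eq15") == pytest.approx(0.01)
    with pytest.raises(ValidationError):
        bliss_predict(1.2, 0.1)  # fractional mode needs [0, 1]
    with pytest.raises(ValidationError):
        bliss_predict(0.1, 0.1, mode="nope")


def test_compare_to_bliss_identity_at_rho_one(scenario):
    bp = compare_to_bliss((1, 3), 1.0, scenario.params, scenario.stressed)
    assert bp.observed == pytest.approx(bp.baseline, rel=1e-9)
    assert bp.predicted == pytest.approx(bp.baseline, rel=1e-9)
    assert bp.excess == pytest.approx(0.0, abs=1e-6 * bp.baseline)


def test_compare_to_bliss_literal_mode(scenario):
    bp = compare_to_bliss(
        (1, 3), 0.3, scenario.params, scenario.stressed, mode="literal-eq15"
    )
    # multiplicative null: predicted fold-change = product of single folds
    assert bp.predicted == pytest.approx(
        bp.baseline * (bp.single_i / bp.baseline) * (bp.single_j / bp.baseline)
    )


def test_independence_oracle_is_bliss_null():
    """On the two-channel cascade with independent losses, observed combined
    inhibition matches the Bliss prediction to < 1% at every grid point."""
    doses = np.linspace(0.0, 2.0, 5)
    r00 = independent_channels_response(0.0, 0.0)
    for di in doses:
        ei = 1.0 - independent_channels_response(di, 0.0) / r00
        for dj in doses:
            ej = 1.0 - independent_channels_response(0.0, dj) / r00
            observed = 1.0 - independent_channels_response(di, dj) / r00
            predicted = bliss_predict(ei, ej)
            assert observed == pytest.approx(predicted, abs=0.01)


def test_independence_oracle_ode_matches_analytic():
    for di, dj in [(0.0, 0.0), (1.0, 0.5), (2.0, 2.0)]:
        ode = independent_channels_response(di, dj)
        closed = independent_channels_response(di, dj, analytic=True)
        assert ode == pytest.approx(closed, rel=1e-6)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_pair_surface(scenario):
    return build_surface((1, 3), scenario.params, scenario.stressed,
                         rho_min=0.5, n=6)


def test_surface_corner_is_unperturbed(scenario, small_pair_surface):
    base = integrate_cgmp(simulate(scenario.params, scenario.stressed)).cgmp_T
    assert small_pair_surface.values[0, 0] == base
    assert small_pair_surface.reference == base


def test_surface_edges_reproduce_dose_response(scenario, small_pair_surface):
    ratios = small_pair_surface.vectors[0].ratios
    vec1 = DoseVector(1, ratios)
    df = dose_response(scenario.params, scenario.stressed, vec1)
    np.testing.assert_array_equal(small_pair_surface.values[:, 0],
                                  df["cgmp_T"].to_numpy())
    vec3 = DoseVector(3, ratios)
    df = dose_response(scenario.params, scenario.stressed, vec3)
    np.testing.assert_array_equal(small_pair_surface.values[0, :],
                                  df["cgmp_T"].to_numpy())


def test_surface_symmetry_under_target_swap(scenario, small_pair_surface):
    swapped = build_surface((3, 1), scenario.params, scenario.stressed,
                            rho_min=0.5, n=6)
    np.testing.assert_array_equal(swapped.values.T, small_pair_surface.values)


def test_surface_validation(scenario):
    with pytest.raises(ValidationError):
        build_surface((1,), scenario.params, scenario.stressed)
    with pytest.raises(ValidationError):
        build_surface((1, 1), scenario.params, scenario.stressed)


# ---------------------------------------------------------------------------
# isobole classification on constructed surfaces
# ---------------------------------------------------------------------------

def _synthetic_surface(fn, rho_min=0.3, n=11):
    ratios = np.linspace(1.0, rho_min, n)
    d = 1.0 - ratios
    Z = np.array([[fn(d1, d2) for d2 in d] for d1 in d])
    vectors = (DoseVector(1, tuple(ratios)), DoseVector(2, tuple(ratios)))
    return CombinationSurface(targets=(1, 2), vectors=vectors, values=Z,
                              reference=float(Z[0, 0]))


D1, D2 = 1.0, 1.4


def _additive(d1, d2):
    s = d1 / D1 + d2 / D2  # single effective dose
    return 10.0 * (1.0 + 2.0 * s / (1.0 + s))


def _potentiation(d1, d2):
    s = d1 / D1 + d2 / D2 + 1.5 * (d1 / D1) * (d2 / D2)
    return 10.0 * (1.0 + 2.0 * s / (1.0 + s))


def _no_cooperation(d1, d2):
    # effect driven solely by the stronger agent: classic antagonism with
    # L-shaped isoboles bowing away from the origin in any dose coordinate
    s = max(d1 / D1, d2 / D2)
    return 10.0 * (1.0 + 2.0 * s / (1.0 + s))


def test_exact_dose_additive_surface_classifies_additive():
    cls = classify_isoboles(_synthetic_surface(_additive))
    assert (cls.table["classification"] == "additive").all()
    assert cls.overall == "additive"


def test_potentiation_surface_classifies_synergistic():
    cls = classify_isoboles(_synthetic_surface(_potentiation))
    assert cls.overall == "synergistic"


def test_max_only_surface_classifies_antagonistic():
    cls = classify_isoboles(_synthetic_surface(_no_cooperation))
    assert cls.overall == "antagonistic"


def test_classification_reports_both_dose_planes():
    cls = classify_isoboles(_synthetic_surface(_additive))
    assert {"index_fraction_plane", "index_occupancy_plane"} <= set(cls.table.columns)
    assert cls.table["index_fraction_plane"].abs().max() <= 0.05


def test_flat_surface_rejected(scenario):
    flat = _synthetic_surface(lambda d1, d2: 5.0)
    with pytest.raises(ValidationError):
        classify_isoboles(flat)
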