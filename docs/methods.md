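# Methods

## Model

The pathway is modeled as a closed, well-mixed, deterministic mass-action
system of 12 species and 13 irreversible elementary steps (see the reaction
map in `nocgmp/model.py`). Key structural assumptions:

* NO· enters as an initial bolus rather than a sustained source; its only
  sinks are sGC binding (reversible) and a first-order oxidative loss
  (k13). There is no spatial transport — delivery from a generator cell is
  summarized by the initial NO· concentration.
* Oxidative inactivation of sGC by H2O2 (k1) is irreversible and acts only
  on free sGC; NO·-bound and substrate-bound forms are protected.
* Both free sGC and the NO·–sGC complex are catalytically competent
  through Michaelis-type binary complexes with GTP; the activated turnover
  exceeds the basal one 200-fold by construction (k9 = 200·k8).
* cGMP degradation is enzymatic (binding k10, release k11, hydrolysis
  k12), so the degradative limb saturates at high cGMP.

The rate law implies four exact balances used throughout the tests: the
sGC moiety, the guanine nucleotide pool, the PDE moiety, and the NO· pool
plus its cumulative k13 loss. The cumulative loss ∫k13·[NO]dt is
co-integrated as a 13th state so that the NO balance can be verified at
solver accuracy instead of output-grid quadrature accuracy.

## Default parameters and calibration

Units are μM and seconds everywhere; parameter files in other units are
converted on load. No measured reference parameter table is distributed
with this package, so the shipped defaults are **calibrated surrogates**:
they reproduce reported qualitative and semi-quantitative signatures of
the system, and no parameter-level fidelity to any experimental dataset is
claimed. They were produced by `scripts/calibrate.py`:
round values at literature-style magnitudes (fast NO·–sGC association,
sub-μM enzyme concentrations, tens-of-μM GTP), then a log-uniform random
search over the 13 rate constants (k9 tied to 200·k8) and the NO, GTP, and
PDE initial concentrations, accepting only candidates that satisfy every
published, desk-checkable signature of the system:

1. control cGMP peaks at ≤ 40 s;
2. control cGMP returns to ≤ 10% of its peak by 200 s (the operational
   definition of "return to baseline": at or below that level through the
   last 10% of the window);
3. 500 μM H2O2 suppresses peak cGMP 5–7-fold (target ~6);
4. k9/k8 = 200;
5. the four strongest single perturbations at ρ = 0.1 are k1, k3, k10, k12;
6. among matched k1/k3/k10 dose vectors, k3 moves cGMP_T the most;
7. cGMP_T({k1,k3}) < cGMP_T({k3,k10}) < cGMP_T({k1,k3,k10}), and the
   triple beats each of its constituent pairs;
8. each headline pair beats its Bliss prediction;
9. the headline pairwise dose matrices classify additive.

One passing candidate was rounded to the clean values frozen in
`nocgmp.model.DEFAULT_PARAMETERS` / `DEFAULT_INITIAL_STATE` and re-verified
(`python scripts/calibrate.py` re-runs all nine checks). The regime is
interpretable: oxidation of free sGC (k1·[H2O2] = 5 s⁻¹ at 500 μM) is
faster than NO· binding (k2·[NO·] = 1.4 s⁻¹), so stress diverts most sGC
to the oxidized pool; the active complex drains through dissociation (k3)
because freed sGC is quickly oxidized and freed NO· is quickly lost
(k13); and the 20 μM GTP pool is small enough that strong
production-boosting combinations begin to exhaust substrate, which is what
caps {k1,k3} below {k3,k10}.

Note one behavior of this regime: the global best triple in the ρ = 0.1
screen is {k1,k3,k12}, marginally above {k1,k3,k10}. k10 and k12 are both
constants of the PDE limb (binding vs. hydrolysis) and are inhibited by
the same pharmacological agent, so both triples express the same
three-target strategy (antioxidant + NO· stabilizer + PDE inhibitor).
When strong production boosts raise cGMP far above the PDE binding scale,
the degradative flux approaches its Vmax = k12·[PDE]_total and the
hydrolysis constant becomes the more sensitive handle.

## Numerics

* Solver: LSODA with the analytic Jacobian, rtol 1e-8, atol 1e-10 μM
  (stiffness: the oxidation step is fast relative to catalysis and the
  concentrations span several orders of magnitude). BDF and Radau are
  accepted alternatives through the `method` argument.
* Output: 201 uniform points on [0, 200] s (1-s resolution) by default;
  peak times are reported on this grid.
* Negativity: values in [−100·atol, 0) are clamped to zero after the
  solve; anything lower raises an error rather than being silently
  repaired. The first output row is set to the exact initial state.
* cGMP_T uses composite trapezoidal quadrature on the dense output grid;
  against closed-form integrands on the default grid the relative error is
  below 1e-4 (asserted in the tests).
* Screen determinism: ranking sorts by descending cGMP_T with ties broken
  lexicographically by target tuple; failed solves are reported with their
  solver diagnostics, excluded from the ranking, and never interpolated.

## Combination analysis

**Dose conventions.** Dose vectors hold 11 linearly spaced ratios from 1.0
down to ρ_min, with ρ_min = 0.1, 0.3, 0.5 for single, paired, and triple
perturbations (weaker per-target inhibition as more targets are
combined). Pairwise surfaces are 11×11, triples 11×11×11; every surface
edge re-runs exactly the single-target simulations, and the all-ones
corner is the unperturbed reference.

**Bliss.** Two modes are exposed because the source material states the
null two ways. The default (`response-product`) is standard Bliss
independence: fractional effects E = (R − R_stress)/(R_control −
R_stress) on the cGMP_T scale, clipped into [0, 1], combined as
E_i + E_j − E_i·E_j, and mapped back to cGMP_T. The `literal-eq15` mode is
the multiplicative null — the predicted combined fold-change is the
product of the single fold-changes. The clipping matters only when a
single perturbation overshoots the control level (E > 1), where the Bliss
formula loses meaning. The null calibration uses a two-stage transmission
cascade with independent per-stage losses, integrated numerically; its
combined inhibition obeys Bliss exactly, and the observed-minus-predicted
excess stays below 1% across the tested dose grid.

**Isobologram classification.** Iso-effect contours of the cGMP_T surface
are extracted by bilinear interpolation (contourpy) at effect levels of
25/50/75% of the *weaker single-agent arm's* maximum effect. Levels are
arm-limited because an isobole has axis intercepts only for effects each
agent can reach alone; on these surfaces the full-combination corner far
exceeds either arm, so levels tied to the surface maximum would have no
intercepts at all. For each contour the curvature index is the signed area
between the contour and the straight line joining its axis intercepts,
normalized by the intercept-triangle area (positive = bowed toward the
origin).

The index is computed in two dose coordinates: the residual-fraction dose
d = 1 − ρ (an affine relabeling of the rate-constant axes the matrices are
plotted on) and the equivalent-occupancy dose x = 1/ρ − 1 (the competitive
inhibitor concentration, in units of its binding constant, that scales a
rate constant to ρ·k). Straightness of an isobole is not invariant under
monotone reparameterization of the dose axes, and on this system the two
coordinates disagree systematically: responses are near-hyperbolic in ρ,
so contours bow away from the origin in d (index ≈ −0.1 to −0.3) and
toward it in x (≈ +0.1 to +0.3) across the entire admissible calibration
range. A synergy or antagonism call that flips sign under such a
relabeling is not robust evidence of interaction, so the classifier issues
it only when both coordinates agree beyond the |index| ≤ 0.05 threshold
and otherwise reports additive. Exactly dose-additive surfaces (index ≈ 0
in d, weakly positive in x) and strong interactions (same sign in both
coordinates, e.g. product-boosted potentiation, or effect-by-the-stronger-
agent-only antagonism with L-shaped isoboles) are classified correctly
under this rule, and classifications are stable when the dose grid is
refined from 11 to 21 points per axis.

3-D surfaces are classified on four planar sections: the three axis-
aligned faces through ρ = 1 and the section in which the second and third
doses move together (through the main diagonal); the overall call is the
majority over classified levels.

## Synthetic data

The scenario generator exposes the frozen defaults (control and 500 μM
H2O2 variants), log-uniform parameter ensembles within ±spread decades of
the defaults (k9/k8 preserved; used for the conservation property suite),
and noisy time courses with additive zero-mean Gaussian noise scaled to
the trajectory peak. The noise model is a minimal stand-in for assay
variability used to exercise estimators (e.g. peak-time recovery); it does
not model immunoassay calibration, sampling times, or biological
replicate structure. Passing tests therefore demonstrate correctness of
the pipeline on this idealized generator, not fidelity to any particular
cell system.

## Known limitations

* The defaults are calibrated surrogates: they reproduce the reported
  qualitative and semi-quantitative signatures of the system, not any
  measured parameter values.
* The Bliss effect scale degenerates if a perturbation drives responses
  far above control (effects clipped at 1).
* Interaction classification is intrinsically metameter-relative; the
  package's additive calls mean "no metameter-robust interaction", which
  is deliberately conservative.
* Deterministic ODEs only — no stochastic kinetics, no spatial gradients,
  no parameter fitting to experimental time courses.
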