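"""Condition bounds, the phi map, bi-level regularized FBA and FVA."""

import numpy as np
import pytest

from omicflux import fixtures as fx
from omicflux.fba import (
    ConditionSpec,
    ExpressionMapConfig,
    PhotonParams,
    apply_condition_bounds,
    apply_expression_bounds,
    expression_coefficient,
    photon_uptake_rate,
    postprocess_fluxes,
    run_all_conditions,
    solve_fva,
    solve_regularized_bilevel_fba,
)
from omicflux.gpr import compile_reaction_expressions
from omicflux.model import ObjectivePair, to_cobra


# --- photon uptake and the phi map -----------------------------------------


def test_photon_uptake_rate_arithmetic_and_linearity():
    assert photon_uptake_rate(PhotonParams(2, 0.5, 10)) == pytest.approx(0.1)
    assert photon_uptake_rate(PhotonParams(4, 0.5, 10)) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        PhotonParams(2, 0.5, 0)


def test_phi_identity_and_derived_values():
    cfg = ExpressionMapConfig(gamma=1.0)
    assert expression_coefficient(1.0, cfg) == 1.0
    assert expression_coefficient(np.e, cfg) == pytest.approx(2.0)
    assert expression_coefficient(1 / np.e, cfg) == pytest.approx(0.5)
    assert expression_coefficient(0.0, cfg) == 0.0
    with pytest.raises(ValueError):
        expression_coefficient(-0.1, cfg)


@pytest.mark.parametrize("gamma", [0.5, 1.0, 2.0])
@pytest.mark.parametrize("theta", [0.1, 0.5, 2.0, 10.0])
def test_phi_reciprocal_symmetry(gamma, theta):
    cfg = ExpressionMapConfig(gamma=gamma)
    prod = expression_coefficient(theta, cfg) * expression_coefficient(1 / theta, cfg)
    assert prod == pytest.approx(1.0)


# --- condition bounds ------------------------------------------------------


def test_apply_condition_bounds_overrides_only_listed(curated_model, condition_specs):
    by_name = {s.name: s for s in condition_specs}
    m = apply_condition_bounds(curated_model, by_name["Nitrate"])
    assert m.lb[m.rxns.index("EX_NO3")] == -12
    # untouched reaction keeps baseline bounds
    assert m.ub[m.rxns.index("BIOMASS")] == curated_model.ub[m.rxns.index("BIOMASS")]
    m = apply_condition_bounds(curated_model, by_name["Darkanoxic"])
    assert m.ub[m.rxns.index("EX_O2")] == -0.01
    assert m.lb[m.rxns.index("EX_O2")] == -0.01
    assert m.lb[m.rxns.index("EX_PHOTON")] == -0.003


def test_photon_params_set_photon_lower_bound(curated_model):
    spec = ConditionSpec(name="custom", photon=PhotonParams(2, 0.5, 10))
    m = apply_condition_bounds(curated_model, spec)
    assert m.lb[m.rxns.index("EX_PHOTON")] == pytest.approx(-0.1)


def test_condition_bounds_lb_above_ub_rejected(curated_model):
    spec = ConditionSpec(name="bad", lb_overrides={"EX_CO2": 5.0}, ub_overrides={"EX_CO2": -5.0})
    with pytest.raises(ValueError, match="bad"):
        apply_condition_bounds(curated_model, spec)


# --- expression bounds -----------------------------------------------------


def test_all_ones_expression_leaves_bounds_unchanged(curated_model):
    x = np.ones(curated_model.n_genes)
    m = apply_expression_bounds(curated_model, x)
    np.testing.assert_allclose(m.lb, curated_model.lb)
    np.testing.assert_allclose(m.ub, curated_model.ub)


def test_upshift_scales_bounds_by_phi(curated_model):
    # GLYCD is governed by the single gene glpK.1; theta = e doubles its bounds
    x = np.ones(curated_model.n_genes)
    x[curated_model.genes.index("glpK.1")] = np.e
    m = apply_expression_bounds(curated_model, x)
    j = curated_model.rxns.index("GLYCD")
    assert m.ub[j] == pytest.approx(2 * curated_model.ub[j])
    # negative lower bounds scale multiplicatively, preserving sign
    m2 = curated_model.copy()
    m2.lb[j] = -10.0
    m2 = apply_expression_bounds(m2, x)
    assert m2.lb[j] == pytest.approx(-20.0)


def test_silenced_gene_disables_reaction(curated_model):
    x = np.ones(curated_model.n_genes)
    x[curated_model.genes.index("glpK.1")] = 0.0
    m = apply_expression_bounds(curated_model, x)
    j = curated_model.rxns.index("GLYCD")
    assert m.lb[j] == 0.0 and m.ub[j] == 0.0


# --- bi-level solve --------------------------------------------------------


@pytest.fixture(scope="module")
def control_model(curated_model, condition_specs):
    return apply_condition_bounds(curated_model, condition_specs[-1])


def test_bilevel_primary_matches_cobra_lp_oracle(control_model):
    """Level-1 optimum must agree with an independent LP (COBRApy/GLPK)."""
    res = solve_regularized_bilevel_fba(control_model)
    assert res.status == "optimal"
    cm = to_cobra(control_model)
    cm.objective = "BIOMASS"
    sol = cm.optimize()
    assert sol.status == "optimal"
    assert res.f_out == pytest.approx(sol.objective_value, abs=1e-5)


def test_level3_matches_independent_qp_oracle(control_model):
    """The minimal-norm vector must match a trust-region QP on the
    optimum-fixed polytope, entrywise to 1e-5."""
    from scipy.optimize import LinearConstraint, minimize

    res = solve_regularized_bilevel_fba(control_model)
    pair = ObjectivePair.from_model(control_model)
    m = control_model.copy()
    eps = 1e-9 * max(1.0, abs(res.f_out))
    m.lb[pair.primary_index] = res.f_out - eps
    m.ub[pair.primary_index] = res.f_out + eps
    eps_g = 1e-9 * max(1.0, abs(res.g_out))
    m.lb[pair.secondary_index] = res.g_out - eps_g
    m.ub[pair.secondary_index] = min(m.ub[pair.secondary_index], res.g_out + eps_g)
    n = m.n_reactions
    oracle = minimize(
        lambda v: v @ v,
        np.clip(res.v + 0.01, m.lb, m.ub),  # start away from our solution
        jac=lambda v: 2 * v,
        method="trust-constr",
        constraints=[LinearConstraint(m.stoich, 0.0, 0.0)],
        bounds=list(zip(m.lb, m.ub)),
        options={"gtol": 1e-12, "xtol": 1e-14},
    )
    np.testing.assert_allclose(res.v, oracle.x, atol=1e-5)


def test_l2_splits_flux_equally_across_parallel_pathways(control_model):
    res = solve_regularized_bilevel_fba(control_model)
    v1 = res.v[control_model.rxns.index("PAR1")]
    v2 = res.v[control_model.rxns.index("PAR2")]
    assert v1 > 1e-4  # the pathway carries flux
    assert v1 == pytest.approx(v2, abs=1e-6)


def test_bilevel_solution_is_deterministic(control_model):
    a = solve_regularized_bilevel_fba(control_model)
    b = solve_regularized_bilevel_fba(control_model)
    np.testing.assert_allclose(a.v, b.v, atol=1e-6)


def test_bilevel_respects_steady_state_and_bounds(control_model):
    res = solve_regularized_bilevel_fba(control_model)
    assert np.abs(control_model.stoich @ res.v).max() < 1e-6
    assert (res.v >= control_model.lb - 1e-6).all()
    assert (res.v <= control_model.ub + 1e-6).all()


def test_infeasible_bounds_reported(control_model):
    m = control_model.copy()
    m.lb[m.rxns.index("ATPM")] = 5.0
    m.ub[m.rxns.index("ATPM")] = 4.0
    res = solve_regularized_bilevel_fba(m)
    assert res.status == "infeasible" and res.v is None


def test_unbounded_primary_reported(control_model):
    m = control_model.copy()
    j = m.rxns.index("ATPM")
    # decouple ATPM from the network: a free reaction with no stoichiometry
    m.stoich[:, j] = 0.0
    m.ub[j] = np.inf
    m.f = np.zeros(m.n_reactions, dtype=int)
    m.f[j] = 1
    m.g = np.zeros(m.n_reactions, dtype=int)
    m.g[m.rxns.index("BIOMASS")] = 1
    res = solve_regularized_bilevel_fba(m)
    assert res.status == "unbounded"


# --- FVA -------------------------------------------------------------------


def test_fva_sandwich_and_fixed_reaction(control_model):
    res = solve_regularized_bilevel_fba(control_model)
    fva = solve_fva(control_model, opt_fraction=1.0)
    assert (fva.min_flux <= fva.max_flux + 1e-9).all()
    assert (fva.min_flux - 1e-5 <= res.v).all()
    assert (res.v <= fva.max_flux + 1e-5).all()
    np.testing.assert_allclose(fva.mean_flux, (fva.min_flux + fva.max_flux) / 2)
    # a pinned reaction collapses to a point
    m = control_model.copy()
    j = m.rxns.index("EX_PHOTON")
    m.lb[j] = m.ub[j] = -0.05
    fva2 = solve_fva(m)
    assert fva2.min_flux[j] == pytest.approx(-0.05)
    assert fva2.max_flux[j] == pytest.approx(-0.05)
    assert fva2.mean_flux[j] == pytest.approx(-0.05)


# --- post-processing and the sweep -----------------------------------------


def test_postprocess_absolute_value_and_threshold():
    out = postprocess_fluxes(np.array([-0.5, 1e-5, 1e-4, 0.2]))
    np.testing.assert_allclose(out, [0.5, 0.0, 0.0, 0.2])
    with pytest.raises(ValueError):
        postprocess_fluxes(np.array([1.0]), threshold=-1)


def test_run_all_conditions_shapes_and_control(curated_model, condition_specs, transcript_fc):
    flux = run_all_conditions(curated_model, transcript_fc.T, condition_specs)
    assert flux.shape == (24, curated_model.n_reactions)
    assert list(flux.index) == fx.CONDITIONS + [fx.CONTROL_NAME]
    assert (flux.to_numpy() >= 0).all()  # post-processed
    # dark conditions fix less carbon than the standard control
    assert flux.loc["Darkoxic", "BIOMASS"] < flux.loc[fx.CONTROL_NAME, "BIOMASS"]
    # mixotrophic glycerol uptake is actually used
    assert flux.loc["Mixotrophic", "GLYCD"] > 0


def test_condition_bounds_do_not_leak(curated_model, condition_specs, transcript_fc):
    """Solving dark-anoxic first must not alter the control solution."""
    by_name = {s.name: s for s in condition_specs}
    sub = transcript_fc.loc[["Darkanoxic"]]
    flux_pairwise = run_all_conditions(
        curated_model, sub.T, [by_name["Darkanoxic"], by_name[fx.CONTROL_NAME]]
    )
    flux_control_only = run_all_conditions(
        curated_model, sub.T.iloc[:, :0], [by_name[fx.CONTROL_NAME]]
    )
    np.testing.assert_allclose(
        flux_pairwise.loc[fx.CONTROL_NAME], flux_control_only.loc[fx.CONTROL_NAME],
        atol=1e-8,
    )


def test_silencing_theta_zeroes_flux(curated_model, condition_specs):
    """Planted silencing of glpK drives glycerol catabolism to exactly 0
    even when glycerol is available (mixotrophic bounds)."""
    by_name = {s.name: s for s in condition_specs}
    m = apply_condition_bounds(curated_model, by_name["Mixotrophic"])
    x = np.ones(m.n_genes)
    x[m.genes.index("glpK.1")] = 0.0
    m = apply_expression_bounds(m, x, compile_reaction_expressions(m))
    res = solve_regularized_bilevel_fba(m)
    assert res.status == "optimal"
    assert res.v[m.rxns.index("GLYCD")] == 0.0
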