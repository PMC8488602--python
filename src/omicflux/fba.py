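"""Condition-specific constraint construction and regularized bi-level FBA.

For each growth condition the model receives two layers of constraints:

1. *Environmental bounds*: per-condition overrides of exchange-reaction
   lower/upper bounds (medium composition, light, O2/CO2 availability).
   Photon uptake may be derived from culture parameters as
   ``PU = LC * SA / DCW`` (light consumption x illuminated surface area
   / dry cell weight), applied as a negative lower bound on the photon
   exchange reaction.
2. *Expression bounds*: each reaction's expression level theta (from its
   GPR rule evaluated over gene fold changes) is mapped to a bound
   multiplier ``phi(theta) = (1 + gamma*|ln(theta)|) ** sgn(theta - 1)``,
   so theta = 1 leaves bounds unchanged, up-regulation widens them and
   down-regulation shrinks them symmetrically (phi(t) * phi(1/t) = 1).

The solve is lexicographic: maximize the primary objective, then the
secondary objective with the primary fixed at its optimum, then minimize
the squared 2-norm of the flux vector with both objectives fixed. The
final quadratic step is strictly convex, so the returned flux vector is
unique - essential when fluxes feed downstream statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .gpr import (
    ReactionExpressionMap,
    compile_reaction_expressions,
    evaluate_reaction_expression,
    map_profile_to_model,
)
from .model import MetabolicModel, ObjectivePair

__all__ = [
    "PhotonParams",
    "ConditionSpec",
    "ExpressionMapConfig",
    "FluxResult",
    "FvaResult",
    "photon_uptake_rate",
    "expression_coefficient",
    "apply_condition_bounds",
    "apply_expression_bounds",
    "solve_regularized_bilevel_fba",
    "solve_fva",
    "postprocess_fluxes",
    "run_all_conditions",
]

logger = logging.getLogger(__name__)

#: default solver feasibility/optimality tolerance (mmol/gDW/h)
SOLVER_TOL = 1e-6


@dataclass(frozen=True)
class PhotonParams:
    """Culture parameters determining photon uptake.

    LC: light consumption (mmol photons); SA: illuminated surface area
    (m^2); DCW: dry cell weight (g per volume). All strictly positive.
    """

    LC: float
    SA: float
    DCW: float

    def __post_init__(self) -> None:
        if self.LC <= 0 or self.SA <= 0 or self.DCW <= 0:
            raise ValueError("photon parameters must be strictly positive")


@dataclass
class ConditionSpec:
    """Per-condition exchange-bound overrides (one growth condition)."""

    name: str
    lb_overrides: dict[str, float] = field(default_factory=dict)
    ub_overrides: dict[str, float] = field(default_factory=dict)
    photon: PhotonParams | None = None
    photon_exchange_id: str = "EX_PHOTON"


@dataclass(frozen=True)
class ExpressionMapConfig:
    """Parameters of the logarithmic expression-to-bounds map.

    gamma: mapping strength (> 0); larger values amplify the effect of
    up/down-regulation on reaction bounds. theta_floor: expression
    levels below this are treated as complete silencing (phi = 0); the
    map itself diverges at theta = 0.
    """

    gamma: float = 1.0
    theta_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.theta_floor < 0:
            raise ValueError("theta_floor must be >= 0")


@dataclass
class FluxResult:
    v: np.ndarray | None
    f_out: float | None
    g_out: float | None
    status: str


@dataclass
class FvaResult:
    min_flux: np.ndarray
    max_flux: np.ndarray
    mean_flux: np.ndarray


def photon_uptake_rate(p: PhotonParams) -> float:
    """Photon uptake magnitude PU = LC * SA / DCW (mmol photons/gDW/h).

    The applied lower bound on the photon exchange is the negation,
    since uptake is negative by exchange convention.
    """
    if p.DCW == 0:
        raise ZeroDivisionError("dry cell weight must be nonzero")
    return p.LC * p.SA / p.DCW


def expression_coefficient(theta: float, config: ExpressionMapConfig) -> float:
    """Bound multiplier phi(theta) = (1 + gamma*|ln theta|)^sgn(theta-1)."""
    if theta < 0:
        raise ValueError("reaction expression level theta must be >= 0")
    if theta < config.theta_floor:
        return 0.0
    if theta == 1.0:
        return 1.0
    base = 1.0 + config.gamma * abs(math.log(theta))
    return base if theta > 1.0 else 1.0 / base


def apply_condition_bounds(model: MetabolicModel, spec: ConditionSpec) -> MetabolicModel:
    """Return a copy of the model with the condition's bounds applied."""
    out = model.copy()
    for rid, val in spec.lb_overrides.items():
        out.lb[out.reaction_index(rid)] = val
    for rid, val in spec.ub_overrides.items():
        out.ub[out.reaction_index(rid)] = val
    if spec.photon is not None:
        out.lb[out.reaction_index(spec.photon_exchange_id)] = -photon_uptake_rate(
            spec.photon
        )
    bad = np.nonzero(out.lb > out.ub)[0]
    if bad.size:
        names = [out.rxns[i] for i in bad]
        raise ValueError(f"condition {spec.name!r} leaves lb > ub for {names}")
    return out


def apply_expression_bounds(
    model: MetabolicModel,
    x: np.ndarray,
    rmap: ReactionExpressionMap | None = None,
    config: ExpressionMapConfig = ExpressionMapConfig(),
) -> MetabolicModel:
    """Scale every reaction's bounds by phi(theta) of its expression level."""
    if len(x) != model.n_genes:
        raise ValueError(
            f"expression vector length {len(x)} != gene count {model.n_genes}"
        )
    if rmap is None:
        rmap = compile_reaction_expressions(model)
    out = model.copy()
    for j, expr in enumerate(rmap.expressions):
        theta = evaluate_reaction_expression(expr, x)
        phi = expression_coefficient(theta, config)
        out.lb[j] *= phi
        out.ub[j] *= phi
    return out


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------


def _lp_max(model: MetabolicModel, objective_index: int):
    """Maximize v[objective_index] on the steady-state polytope."""
    n = model.n_reactions
    c = np.zeros(n)
    c[objective_index] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=model.stoich,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(model.lb, model.ub)),
        method="highs",
    )
    return res


def _min_norm(model: MetabolicModel, x0: np.ndarray) -> np.ndarray:
    """Minimize sum(v^2) subject to S v = 0 and the model bounds."""
    S = model.stoich
    cons = [{"type": "eq", "fun": lambda v: S @ v, "jac": lambda v: S}]
    res = minimize(
        lambda v: float(v @ v),
        x0,
        jac=lambda v: 2.0 * v,
        bounds=list(zip(model.lb, model.ub)),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    if not res.success:  # pragma: no cover - defensive
        logger.warning("norm-2 minimization did not fully converge: %s", res.message)
    return res.x


def solve_regularized_bilevel_fba(
    model: MetabolicModel,
    pair: ObjectivePair | None = None,
    fix_tol: float = 1e-9,
) -> FluxResult:
    """Lexicographic solve: primary LP, secondary LP, then minimal 2-norm.

    The primary objective is maximized first; its optimum is then fixed
    (within a relative tolerance ``fix_tol``) while the secondary
    objective is maximized; finally the squared 2-norm of the flux
    vector is minimized over the doubly-fixed polytope, whose strict
    convexity makes the returned vector unique.
    """
    if pair is None:
        pair = ObjectivePair.from_model(model)
    if np.any(model.lb > model.ub):
        return FluxResult(None, None, None, "infeasible")

    res1 = _lp_max(model, pair.primary_index)
    if res1.status == 3:
        return FluxResult(None, None, None, "unbounded")
    if res1.status != 0:
        return FluxResult(None, None, None, "infeasible")
    f_out = -res1.fun

    m2 = model.copy()
    eps = fix_tol * max(1.0, abs(f_out))
    m2.lb[pair.primary_index] = f_out - eps
    m2.ub[pair.primary_index] = min(m2.ub[pair.primary_index], f_out + eps)

    res2 = _lp_max(m2, pair.secondary_index)
    if res2.status == 3:
        return FluxResult(None, f_out, None, "unbounded")
    if res2.status != 0:  # pragma: no cover - fixed polytope is nonempty
        return FluxResult(None, f_out, None, "infeasible")
    g_out = -res2.fun

    eps_g = fix_tol * max(1.0, abs(g_out))
    m2.lb[pair.secondary_index] = g_out - eps_g
    m2.ub[pair.secondary_index] = min(m2.ub[pair.secondary_index], g_out + eps_g)

    v = _min_norm(m2, res2.x)
    return FluxResult(v=v, f_out=float(f_out), g_out=float(g_out), status="optimal")


def solve_fva(
    model: MetabolicModel,
    pair: ObjectivePair | None = None,
    opt_fraction: float = 1.0,
) -> FvaResult:
    """Flux variability analysis constrained to near-optimal primary flux.

    For each reaction the minimum and maximum flux are computed subject
    to steady state, the bounds, and primary flux >= opt_fraction times
    its optimum (only the primary objective enters the constraint set).
    ``mean_flux`` is the midpoint (min + max)/2.
    """
    if pair is None:
        pair = ObjectivePair.from_model(model)
    if not (0.0 <= opt_fraction <= 1.0):
        raise ValueError("opt_fraction must lie in [0, 1]")

    res1 = _lp_max(model, pair.primary_index)
    if res1.status != 0:
        raise RuntimeError(f"FVA primary objective LP failed (status {res1.status})")
    opt = -res1.fun

    m2 = model.copy()
    slack = (1.0 - opt_fraction) * abs(opt) + SOLVER_TOL
    m2.lb[pair.primary_index] = max(m2.lb[pair.primary_index], opt - slack)

    n = m2.n_reactions
    vmin = np.zeros(n)
    vmax = np.zeros(n)
    bounds = list(zip(m2.lb, m2.ub))
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        lo = linprog(c, A_eq=m2.stoich, b_eq=np.zeros(m2.n_metabolites), bounds=bounds, method="highs")
        hi = linprog(-c, A_eq=m2.stoich, b_eq=np.zeros(m2.n_metabolites), bounds=bounds, method="highs")
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem failed for reaction {m2.rxns[j]!r}")
        vmin[j] = lo.fun
        vmax[j] = -hi.fun
    return FvaResult(min_flux=vmin, max_flux=vmax, mean_flux=(vmin + vmax) / 2.0)


def postprocess_fluxes(flux, threshold: float = 1e-4):
    """Absolute values with sub-threshold entries zeroed (solver noise).

    Entries <= threshold after taking absolute values are set to 0; the
    default 1e-4 is two orders of magnitude above the solver tolerance.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if isinstance(flux, pd.DataFrame):
        out = flux.abs()
        return out.where(out > threshold, 0.0)
    out = np.abs(np.asarray(flux, dtype=float))
    out[out <= threshold] = 0.0
    return out


def run_all_conditions(
    model: MetabolicModel,
    profiles: pd.DataFrame,
    specs: Sequence[ConditionSpec],
    pair: ObjectivePair | None = None,
    config: ExpressionMapConfig = ExpressionMapConfig(),
    control_name: str = "Standardcontrol",
    flux_threshold: float = 1e-4,
    postprocess: bool = True,
) -> pd.DataFrame:
    """Solve the full condition sweep; one flux row per condition spec.

    ``profiles`` is a genes x conditions table of transcript fold
    changes (truncated gene ids). Each condition starts from the curated
    baseline model - bounds never leak between conditions. The control
    condition uses the all-ones expression configuration. Rows follow
    the order of ``specs`` (conventionally the 23 experimental
    conditions followed by the standard control). Post-processing
    (absolute value + thresholding) is applied once at the end.
    """
    if pair is None:
        pair = ObjectivePair.from_model(model)
    spec_names = [s.name for s in specs]
    missing = [c for c in profiles.columns if c not in spec_names]
    if missing:
        raise ValueError(f"no condition spec for profile conditions {missing}")
    if control_name not in spec_names:
        raise ValueError(f"condition specs must include the control {control_name!r}")

    rmap = compile_reaction_expressions(model)
    rows = []
    for spec in specs:
        m = apply_condition_bounds(model, spec)
        if spec.name == control_name:
            x = np.ones(model.n_genes)
        else:
            if spec.name not in profiles.columns:
                raise ValueError(f"no expression profile for condition {spec.name!r}")
            x = map_profile_to_model(model, profiles[spec.name])
        m = apply_expression_bounds(m, x, rmap, config)
        result = solve_regularized_bilevel_fba(m, pair)
        if result.status != "optimal":
            raise RuntimeError(
                f"FBA failed for condition {spec.name!r}: status {result.status}"
            )
        logger.info(
            "condition %s: primary=%.6g secondary=%.6g",
            spec.name,
            result.f_out,
            result.g_out,
        )
        rows.append(result.v)

    flux = pd.DataFrame(np.vstack(rows), index=spec_names, columns=model.rxns)
    if postprocess:
        flux = postprocess_fluxes(flux, flux_threshold)
    return flux
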