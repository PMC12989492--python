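"""Expression-constrained flux simulation.

Per-sample enzyme expression is mapped onto reaction activities through GPR
rules (AND -> min: a complex is limited by its scarcest subunit; OR -> sum:
isozymes add capacity), activities are normalized per sample by a high
percentile so bounds are unit-free, and a two-stage LP is solved per sample:

1. maximize total flux through the energy-associated subsystems
   (S.v = 0, expression-scaled bounds);
2. at the stage-1 optimum, minimize total flux (parsimonious step) so
   alternate optima collapse to one comparable vector per sample.

Reversible reactions are split into non-negative forward/backward halves in
both stages; reported flux is forward minus backward.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model_io import GprRule, MetabolicModel

__all__ = [
    "ENERGY_SUBSYSTEMS",
    "FluxSolverError",
    "reaction_activity",
    "cohort_activities",
    "energy_objective",
    "FluxProblem",
    "set_expression_bounds",
    "FluxSolution",
    "solve_sample_flux",
    "CohortFluxes",
    "simulate_cohort",
]

#: The nine energy-associated subsystems whose throughput is maximized.
ENERGY_SUBSYSTEMS: tuple[str, ...] = (
    "Citric Acid Cycle",
    "Oxidative Phosphorylation",
    "CoA Synthesis",
    "CoA Catabolism",
    "Glycolysis and Gluconeogenesis",
    "NAD Metabolism",
    "Fatty Acid Synthesis",
    "Fatty Acid Oxidation",
    "Biomass and Maintenance Functions",
)


class FluxSolverError(RuntimeError):
    """The per-sample LP was infeasible, unbounded or failed to converge."""


def _canon_subsystem(name: str) -> str:
    s = name.strip().lower().replace("/", " and ")
    return re.sub(r"\s+", " ", s)


_ENERGY_CANON = frozenset(_canon_subsystem(s) for s in ENERGY_SUBSYSTEMS)


# ---------------------------------------------------------------------------
# GPR -> activity
# ---------------------------------------------------------------------------


def reaction_activity(gpr: GprRule, expr: Mapping[str, float]) -> float | None:
    """Evaluate a GPR rule against per-gene expression.

    AND nodes take the minimum of their present children, OR nodes the sum;
    genes absent from ``expr`` are skipped.  Returns ``None`` when the rule
    is empty or no referenced gene is present (the reaction is then left
    unconstrained).
    """
    if gpr.kind == "empty":
        return None
    if gpr.kind == "gene":
        val = expr.get(gpr.gene)  # type: ignore[arg-type]
        if val is None:
            return None
        val = float(val)
        if val < 0:
            raise ValueError(f"negative expression for gene {gpr.gene!r}")
        return val
    parts = [reaction_activity(c, expr) for c in gpr.children]
    present = [v for v in parts if v is not None]
    if not present:
        return None
    return min(present) if gpr.kind == "all" else float(sum(present))


def cohort_activities(model: MetabolicModel, expression: pd.DataFrame) -> pd.DataFrame:
    """Per-reaction activity scores for every sample (NaN = unconstrained)."""
    out = np.full((len(model.reactions), expression.shape[1]), np.nan)
    for s, sample in enumerate(expression.columns):
        expr = expression[sample].to_dict()
        for j, rxn in enumerate(model.reactions):
            a = reaction_activity(rxn.gpr, expr)
            if a is not None:
                out[j, s] = a
    return pd.DataFrame(out, index=model.reaction_ids, columns=expression.columns)


# ---------------------------------------------------------------------------
# Objective and bounds
# ---------------------------------------------------------------------------


def energy_objective(
    model: MetabolicModel,
    synonyms: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Coefficient vector (+1 per energy-subsystem reaction, 0 elsewhere).

    Subsystem labels are matched case-insensitively after canonicalization
    ("/" is read as "and"); ``synonyms`` maps additional model labels onto
    canonical subsystem names.
    """
    syn = {
        _canon_subsystem(k): _canon_subsystem(v) for k, v in (synonyms or {}).items()
    }
    c = np.zeros(len(model.reactions))
    for j, rxn in enumerate(model.reactions):
        label = _canon_subsystem(rxn.subsystem) if rxn.subsystem else ""
        label = syn.get(label, label)
        if label in _ENERGY_CANON:
            c[j] = 1.0
    if not c.any():
        raise ValueError("no reaction matches any energy-associated subsystem")
    return c


@dataclass
class FluxProblem:
    """A per-sample LP: model, effective bounds and objective coefficients."""

    model: MetabolicModel
    lb_eff: np.ndarray
    ub_eff: np.ndarray
    c: np.ndarray
    sample_id: str | None = None
    feasibility_tol: float = 1e-9

    @classmethod
    def from_default_bounds(
        cls,
        model: MetabolicModel,
        objective: np.ndarray | None = None,
        sample_id: str | None = None,
    ) -> "FluxProblem":
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        c = objective if objective is not None else energy_objective(model)
        return cls(model, lb, ub, np.asarray(c, dtype=float), sample_id)


def set_expression_bounds(
    model: MetabolicModel,
    activity: Mapping[str, float] | pd.Series,
    *,
    percentile: float = 95.0,
    objective: np.ndarray | None = None,
    sample_id: str | None = None,
) -> FluxProblem:
    """Scale default bounds by percentile-normalized reaction activity.

    Each constrained reaction's activity is divided by the ``percentile``-th
    percentile of the sample's constrained activities and clipped to [0, 1];
    upper bounds (and negative lower bounds of reversible reactions) are
    multiplied by the normalized score.  Reactions with no activity score
    (NaN or missing) keep their default bounds.
    """
    n = len(model.reactions)
    acts = np.full(n, np.nan)
    for j, rid in enumerate(model.reaction_ids):
        val = activity.get(rid)
        acts[j] = np.nan if val is None else float(val)
    constrained = ~np.isnan(acts)

    scale = np.ones(n)
    if constrained.any():
        norm = float(np.percentile(acts[constrained], percentile))
        if norm <= 0:
            raise ValueError(
                f"all enzyme activities are zero in sample {sample_id!r}; "
                "cannot normalize expression bounds"
            )
        scale[constrained] = np.clip(acts[constrained] / norm, 0.0, 1.0)

    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    ub_eff = ub * scale
    lb_eff = np.where(lb < 0, lb * scale, np.minimum(lb, ub_eff))
    c = objective if objective is not None else energy_objective(model)
    return FluxProblem(model, lb_eff, ub_eff, np.asarray(c, dtype=float), sample_id)


# ---------------------------------------------------------------------------
# Two-stage LP
# ---------------------------------------------------------------------------


@dataclass
class FluxSolution:
    """Steady-state flux vector for one sample."""

    sample_id: str | None
    fluxes: pd.Series
    objective_value: float
    status: str = "optimal"


def solve_sample_flux(problem: FluxProblem) -> FluxSolution:
    """Maximize the energy objective, then minimize total flux at the optimum."""
    model = problem.model
    n = len(model.reactions)
    S = model.stoichiometric_matrix()
    m = S.shape[0]

    lb, ub = problem.lb_eff, problem.ub_eff
    # Forward/backward split: v = x_f - x_b with x_f, x_b >= 0.
    fwd_bounds = list(zip(np.maximum(lb, 0.0), np.maximum(ub, 0.0)))
    bwd_bounds = list(zip(np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)))
    bounds = fwd_bounds + bwd_bounds
    A_eq = sparse.hstack([S, -S], format="csr")
    b_eq = np.zeros(m)
    c_split = np.concatenate([problem.c, problem.c])

    sid = problem.sample_id
    res1 = linprog(-c_split, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res1.status != 0:
        raise FluxSolverError(f"sample {sid!r}: stage-1 LP failed ({res1.message})")
    z_star = float(c_split @ res1.x)

    # Parsimonious stage: hold the objective at its optimum (equality, the
    # pFBA convention) and minimize total flux; fall back to an inequality
    # with a small relative slack if the equality is reported infeasible.
    A_eq2 = sparse.vstack([A_eq, sparse.csr_matrix(c_split.reshape(1, -1))])
    res2 = linprog(
        np.ones(2 * n),
        A_eq=A_eq2,
        b_eq=np.concatenate([b_eq, [z_star]]),
        bounds=bounds,
        method="highs",
    )
    if res2.status != 0:
        tol = problem.feasibility_tol * max(1.0, abs(z_star))
        res2 = linprog(
            np.ones(2 * n),
            A_ub=sparse.csr_matrix(-c_split.reshape(1, -1)),
            b_ub=np.array([-(z_star - tol)]),
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=bounds,
            method="highs",
        )
    if res2.status != 0:
        raise FluxSolverError(f"sample {sid!r}: stage-2 LP failed ({res2.message})")

    v = res2.x[:n] - res2.x[n:]
    return FluxSolution(
        sample_id=sid,
        fluxes=pd.Series(v, index=model.reaction_ids, name=sid),
        objective_value=z_star,
    )


@dataclass
class CohortFluxes:
    """Per-sample flux solutions assembled into a reactions x samples table."""

    flux_table: pd.DataFrame
    objectives: pd.Series
    statuses: pd.Series
    failures: dict[str, str] = field(default_factory=dict)


def simulate_cohort(
    model: MetabolicModel,
    tpm: pd.DataFrame,
    *,
    percentile: float = 95.0,
    objective: np.ndarray | None = None,
    synonyms: Mapping[str, str] | None = None,
    on_error: str = "raise",
) -> CohortFluxes:
    """Solve the expression-constrained two-stage LP for every sample.

    ``tpm`` is a gene x sample expression table (TPM scale).  With
    ``on_error="collect"`` failed samples are flagged in ``statuses`` and
    recorded in ``failures`` instead of aborting the cohort.
    """
    if on_error not in ("raise", "collect"):
        raise ValueError("on_error must be 'raise' or 'collect'")
    c = objective if objective is not None else energy_objective(model, synonyms)
    columns: dict[str, pd.Series] = {}
    objectives: dict[str, float] = {}
    statuses: dict[str, str] = {}
    failures: dict[str, str] = {}
    for sample in tpm.columns:
        expr = tpm[sample].to_dict()
        acts = {
            rxn.id: reaction_activity(rxn.gpr, expr) for rxn in model.reactions
        }
        try:
            problem = set_expression_bounds(
                model, acts, percentile=percentile, objective=c, sample_id=sample
            )
            sol = solve_sample_flux(problem)
        except (ValueError, FluxSolverError) as exc:
            if on_error == "raise":
                raise
            failures[sample] = str(exc)
            statuses[sample] = "failed"
            columns[sample] = pd.Series(np.nan, index=model.reaction_ids, name=sample)
            objectives[sample] = np.nan
            continue
        columns[sample] = sol.fluxes
        objectives[sample] = sol.objective_value
        statuses[sample] = sol.status
    flux_table = pd.DataFrame(columns)[list(tpm.columns)]
    return CohortFluxes(
        flux_table=flux_table,
        objectives=pd.Series(objectives, name="objective")[list(tpm.columns)],
        statuses=pd.Series(statuses, name="status")[list(tpm.columns)],
        failures=failures,
    )
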