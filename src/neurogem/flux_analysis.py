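"""FBA, loopless flux correction, FVA, and physiological constraining.

All linear programs run through one interface (:func:`_solve_lp`, HiGHS via
``scipy.optimize.linprog``) with feasibility tolerance 1e-9 and optimality
tolerance 1e-8.  Fluxes are in µmol/(g tissue · min) throughout; the
:func:`csf_to_flux` converter is the only place concentration units enter.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import linprog

from .model_core import MetabolicModel, is_exchange, stoichiometric_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PhysiologicalConstraints",
    "FluxSolution",
    "FVAResult",
    "SolverError",
    "InfeasibleError",
    "csf_to_flux",
    "apply_physiological_constraints",
    "fba",
    "loopless_correct",
    "fva",
    "atp_production_by_reaction",
]

FEAS_TOL = 1e-9
OPT_TOL = 1e-8


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


class InfeasibleError(RuntimeError):
    """The optimization problem has no feasible point."""


@dataclass
class PhysiologicalConstraints:
    """Tissue-level constraints translated into exchange/reaction bounds.

    Units: fluxes in µmol/(g·min), CSF concentrations in µmol/L, CSF flow in
    L/min, tissue mass in g.  ``cmr_glu`` is the cerebral metabolic rate of
    glucose (the fixed glucose uptake); oxygen uptake magnitude is bracketed
    by ``o2_min`` and ``o2_glu_ratio * cmr_glu`` (the CMRO2/CMRglu ratio
    rule); ``atp_maintenance`` bounds the non-growth-associated ATP demand;
    ``vmax`` caps named enzyme reactions (glutaminase, glutamine synthetase,
    glutamate decarboxylase); CSF concentrations become maximum uptake rates
    for the corresponding exchange reactions.
    """

    cmr_glu: float
    o2_glu_ratio: float
    o2_min: float = 0.0
    atp_maintenance: tuple[float, float] = (10.0, 40.0)
    vmax: dict[str, float] = field(default_factory=dict)
    csf: dict[str, float] = field(default_factory=dict)
    csf_flow: float = 0.0
    tissue_mass: float = 1.0
    reaction_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        lb, ub = self.atp_maintenance
        if lb > ub:
            raise ValueError(f"atp_maintenance lb {lb} > ub {ub}")
        for name in ("cmr_glu", "o2_glu_ratio", "o2_min", "csf_flow", "tissue_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.o2_min > self.o2_glu_ratio * self.cmr_glu + 1e-12:
            raise ValueError("o2_min exceeds o2_glu_ratio * cmr_glu")

    @classmethod
    def from_yaml(cls, path, group: str | None = None) -> "PhysiologicalConstraints":
        """Load from a YAML file; per-group blocks (``asd:`` / ``control:``)
        are selected with *group*, shared keys (e.g. ``reaction_map``) merged."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        shared = {k: v for k, v in raw.items()
                  if k not in ("asd", "control") or group is None}
        if group is not None:
            shared = {k: v for k, v in raw.items() if not isinstance(v, dict)
                      or k in ("vmax", "csf", "reaction_map", "atp_maintenance")}
            shared.update(raw.get(group.lower(), {}))
        if "atp_maintenance" in shared:
            shared["atp_maintenance"] = tuple(shared["atp_maintenance"])
        return cls(**shared)


@dataclass
class FluxSolution:
    """One steady-state flux vector with solver status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FVAResult:
    """Per-reaction attainable [min, max] flux under an objective constraint."""

    ranges: dict[str, tuple[float, float]]
    objective_fraction: float
    loopless: bool


def csf_to_flux(conc: float, flow: float, mass: float) -> float:
    """Convert a CSF concentration (µmol/L) into an uptake-flux bound
    (µmol/(g·min)) given CSF flow (L/min) and tissue mass (g)."""
    if mass <= 0:
        raise ValueError("tissue mass must be positive")
    if conc < 0 or flow < 0:
        raise ValueError("concentration and flow must be nonnegative")
    return conc * flow / mass


_DEFAULT_ROLES = {
    "glucose_exchange": "EX_glc",
    "oxygen_exchange": "EX_o2",
    "atp_maintenance": "ATPM",
}


def apply_physiological_constraints(
    model: MetabolicModel, pc: PhysiologicalConstraints
) -> MetabolicModel:
    """Return a copy of *model* with tissue-level bounds applied.

    Exchange sign convention: uptake is negative flux, so fixing glucose
    uptake to ``cmr_glu`` sets the glucose exchange bounds to
    ``[-cmr_glu, -cmr_glu]`` and the oxygen uptake window to
    ``[-o2_glu_ratio*cmr_glu, -o2_min]``.  CSF metabolites absent from the
    model are skipped with a warning; missing *mapped* reactions (glucose,
    oxygen, ATP maintenance, vmax targets) are errors.
    """
    roles = dict(_DEFAULT_ROLES)
    roles.update(pc.reaction_map)
    out = model.copy()
    rxns = out.reactions_by_id

    def mapped(role: str):
        rid = roles[role]
        if rid not in rxns:
            raise KeyError(f"constraint role {role!r} maps to missing reaction {rid!r}")
        return rxns[rid]

    glc = mapped("glucose_exchange")
    glc.lb = -pc.cmr_glu
    glc.ub = -pc.cmr_glu
    glc.reversible = glc.lb < 0

    o2 = mapped("oxygen_exchange")
    o2.lb = -pc.o2_glu_ratio * pc.cmr_glu
    o2.ub = -pc.o2_min
    o2.reversible = o2.lb < 0

    atpm = mapped("atp_maintenance")
    atpm.lb, atpm.ub = pc.atp_maintenance
    atpm.reversible = atpm.lb < 0

    for rid, vmax in pc.vmax.items():
        if rid not in rxns:
            raise KeyError(f"vmax names missing reaction {rid!r}")
        rxns[rid].ub = min(rxns[rid].ub, float(vmax))

    exch_by_met = {}
    for r in out.reactions:
        if is_exchange(r, out):
            (met_id,) = r.stoich
            exch_by_met[met_id] = r
    for met_id, conc in pc.csf.items():
        r = exch_by_met.get(met_id)
        if r is None:
            logger.warning("CSF metabolite %s has no exchange reaction; skipped", met_id)
            continue
        bound = csf_to_flux(conc, pc.csf_flow, pc.tissue_mass)
        r.lb = -bound
        r.reversible = r.lb < 0
    return out


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------


def _objective_vector(model: MetabolicModel, objective: dict[str, float]) -> np.ndarray:
    idx = {r.id: i for i, r in enumerate(model.reactions)}
    c = np.zeros(len(model.reactions))
    for rid, w in objective.items():
        if rid not in idx:
            raise KeyError(f"objective names missing reaction {rid!r}")
        c[idx[rid]] = float(w)
    return c


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEAS_TOL,
                 "dual_feasibility_tolerance": OPT_TOL},
    )
    return res


def fba(
    model: MetabolicModel,
    objective: dict[str, float],
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize a weighted flux objective subject to
    S·v = 0 and the model bounds."""
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    S = stoichiometric_matrix(model).to_numpy()
    c = _objective_vector(model, objective)
    sign = -1.0 if sense == "max" else 1.0
    bounds = [(r.lb, r.ub) for r in model.reactions]
    res = _solve_lp(sign * c, S, np.zeros(S.shape[0]), bounds)
    if res.status == 2:
        return FluxSolution(fluxes={}, objective_value=float("nan"), status="infeasible")
    if res.status == 3:
        return FluxSolution(fluxes={}, objective_value=float("inf"), status="unbounded")
    if res.status != 0:
        raise SolverError(f"LP solver failure: {res.message}")
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution(fluxes=fluxes, objective_value=float(c @ res.x), status="optimal")


def loopless_correct(
    model: MetabolicModel,
    solution: FluxSolution,
    objective: dict[str, float] | None = None,
) -> FluxSolution:
    """Remove internal-cycle circulation from an optimal flux solution.

    Exchange fluxes (and, when given, the objective reactions' fluxes) are
    held fixed at their solved values; the remaining internal flux is
    re-chosen to minimize Σ|v| (flux-splitting LP).  Any flux component
    circulating around a closed internal loop has zero net exchange
    involvement and is stripped by the ℓ1 minimization, while the objective
    value is preserved to 1e-6.
    """
    if solution.status != "optimal":
        raise ValueError("loopless correction requires an optimal solution")
    S = stoichiometric_matrix(model).to_numpy()
    n = len(model.reactions)
    fixed = np.zeros(n, dtype=bool)
    v0 = np.array([solution.fluxes[r.id] for r in model.reactions])
    for i, r in enumerate(model.reactions):
        if is_exchange(r, model):
            fixed[i] = True
    if objective:
        idx = {r.id: i for i, r in enumerate(model.reactions)}
        for rid in objective:
            fixed[idx[rid]] = True

    # v = p - q with p, q >= 0; minimize sum(p + q) over free reactions.
    free = ~fixed
    nf = int(free.sum())
    # variables: [p (nf), q (nf)]
    A_eq = np.hstack([S[:, free], -S[:, free]])
    b_eq = -S[:, fixed] @ v0[fixed]
    c = np.ones(2 * nf)
    bounds = [(0.0, None)] * (2 * nf)
    # keep p - q inside the original [lb, ub] box
    eye = np.eye(nf)
    lb_free = np.array([model.reactions[i].lb for i in np.where(free)[0]])
    ub_free = np.array([model.reactions[i].ub for i in np.where(free)[0]])
    A_box = np.vstack([np.hstack([eye, -eye]), np.hstack([-eye, eye])])
    b_box = np.concatenate([ub_free, -lb_free])
    res = _solve_lp(c, A_eq, b_eq, bounds, A_ub=A_box, b_ub=b_box)
    if res.status != 0:
        raise SolverError(f"loopless correction LP failed: {res.message}")
    v = v0.copy()
    v[free] = res.x[:nf] - res.x[nf:]
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    obj = solution.objective_value
    if objective:
        obj = float(sum(w * fluxes[rid] for rid, w in objective.items()))
    return FluxSolution(fluxes=fluxes, objective_value=obj, status="optimal")


def fva(
    model: MetabolicModel,
    objective: dict[str, float],
    gamma: float = 1.0,
    loopless: bool = False,
) -> FVAResult:
    """Flux variability analysis at objective fraction *gamma*.

    For each reaction, minimize and maximize its flux subject to S·v = 0,
    bounds, and (max-sense) objective ≥ γ·z*.  With ``loopless=True`` each
    extreme solution is passed through :func:`loopless_correct` (exchanges
    and objective reactions fixed) and the corrected flux of the target
    reaction is reported, so no internal cycle inflates a range.  When the
    γ = 1 constraint is numerically infeasible for some reaction the
    analysis falls back to unconstrained-objective FVA for that model, with
    a logged downgrade.
    """
    base = fba(model, objective, sense="max")
    if base.status != "optimal":
        raise InfeasibleError(f"FVA requires an optimal FBA base (got {base.status})")
    z_star = base.objective_value
    S = stoichiometric_matrix(model).to_numpy()
    c_obj = _objective_vector(model, objective)
    bounds = [(r.lb, r.ub) for r in model.reactions]
    slack = 1e-9 * max(1.0, abs(z_star))
    A_ub = -c_obj.reshape(1, -1)
    b_ub = np.array([-(gamma * z_star - slack)])

    ranges: dict[str, tuple[float, float]] = {}
    n = len(model.reactions)
    constrained = True
    for j in range(n):
        lo_hi = []
        for sense in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sense
            res = _solve_lp(c, S, np.zeros(S.shape[0]), bounds,
                            A_ub=A_ub if constrained else None,
                            b_ub=b_ub if constrained else None)
            if res.status == 2 and constrained:
                logger.warning(
                    "FVA objective constraint infeasible at gamma=%g; "
                    "falling back to unconstrained-objective FVA", gamma)
                constrained = False
                res = _solve_lp(c, S, np.zeros(S.shape[0]), bounds)
            if res.status != 0:
                raise SolverError(f"FVA LP failed on {model.reactions[j].id}: {res.message}")
            val = float(res.x[j])
            if loopless and not is_exchange(model.reactions[j], model):
                sol = FluxSolution(
                    fluxes={r.id: float(x) for r, x in zip(model.reactions, res.x)},
                    objective_value=float(c_obj @ res.x), status="optimal")
                corrected = loopless_correct(model, sol, objective)
                val = corrected.fluxes[model.reactions[j].id]
            lo_hi.append(val)
        lo, hi = min(lo_hi), max(lo_hi)
        ranges[model.reactions[j].id] = (lo, hi)
    return FVAResult(ranges=ranges, objective_fraction=gamma, loopless=loopless)


def atp_production_by_reaction(
    model: MetabolicModel, solution: FluxSolution, atp_ids: tuple[str, ...] = ("atp_c", "atp_m")
) -> dict[str, float]:
    """Per-reaction ATP production rate (positive contributions only) at a
    flux solution — used to decompose the ATP yield into substrate-level
    and oxidative-phosphorylation shares."""
    out: dict[str, float] = {}
    for r in model.reactions:
        v = solution.fluxes.get(r.id, 0.0)
        made = sum(coef * v for met, coef in r.stoich.items() if met in atp_ids)
        if made > 1e-9:
            out[r.id] = made
    return out


def bounds_hash(model: MetabolicModel) -> str:
    """Stable hash of the model's reaction ids and bounds (provenance)."""
    h = hashlib.sha256()
    for r in model.reactions:
        h.update(f"{r.id}:{r.lb:.12g}:{r.ub:.12g};".encode())
    return h.hexdigest()[:16]
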