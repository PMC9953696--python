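"""Turn expression + a reference network into a context-specific model.

Steps: quantile normalization → per-group median aggregation over an age
window → bimodal threshold selection on the pooled values (kernel density,
Silverman bandwidth) → GPR reaction scoring (AND→min, OR→max) → MILP
extraction that keeps well-evidenced reactions while preserving protected
reactions and a minimum flux through the objective task → gap-filling of
protected reactions and their boundary support from the reference.

The extraction is a task-constrained selection MILP in the spirit of
expression-driven model extraction algorithms: binary y_r per reaction,
maximize Σ (score_r − θ)·y_r (no-evidence reactions pay a small penalty ε),
subject to S·v = 0, big-M flux coupling lb·y ≤ v ≤ ub·y, forced inclusion
of protected reactions, and objective reactions carrying flux ≥ δ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.stats import gaussian_kde, rankdata

from .model_core import MetabolicModel, assert_valid, is_exchange, is_transport, stoichiometric_matrix
from .synthetic_data import ExpressionProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionScoreSet",
    "ProtectedSet",
    "UnimodalError",
    "ExtractionError",
    "quantile_normalize",
    "aggregate_by_group",
    "select_threshold",
    "score_reactions",
    "extract_submodel",
    "gapfill_protected",
]


class UnimodalError(ValueError):
    """Pooled expression shows no interior density minimum between modes."""


class ExtractionError(RuntimeError):
    """The extraction MILP failed (infeasible task or timeout)."""


@dataclass
class ReactionScoreSet:
    """Expression evidence per reaction plus the inclusion threshold θ.

    Reactions with an empty (or fully unresolvable) gene rule are listed in
    ``no_evidence`` rather than carrying a numeric score.
    """

    scores: dict[str, float]
    threshold: float
    no_evidence: set[str] = field(default_factory=set)


@dataclass
class ProtectedSet:
    """Reactions that extraction must keep regardless of evidence."""

    reaction_ids: set[str]

    def check(self, model: MetabolicModel) -> None:
        missing = self.reaction_ids - set(model.reactions_by_id)
        if missing:
            raise KeyError(f"protected reactions not in model: {sorted(missing)}")


def quantile_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Map every sample (column) onto the cross-sample mean of order
    statistics, preserving within-column ranks.

    Ties within a column receive the mean of the reference values their
    positions span.
    """
    if raw.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if raw.isna().any().any():
        raise ValueError("missing values are not supported")
    arr = raw.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks - 1, np.arange(len(reference)), reference)
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def aggregate_by_group(
    profile: ExpressionProfile, age_range: tuple[float, float] = (2.0, 14.0)
) -> dict[str, pd.Series]:
    """Per-group, per-gene median over samples whose age lies in the closed
    *age_range* (default 2–14 y: the childhood window where expression is
    age-stable enough to pool)."""
    lo, hi = age_range
    keep = profile.age[(profile.age >= lo) & (profile.age <= hi)].index
    out: dict[str, pd.Series] = {}
    for group in sorted(profile.group.unique()):
        cols = [s for s in keep if profile.group[s] == group]
        if not cols:
            raise ValueError(
                f"group {group!r} has no samples with age in [{lo}, {hi}]")
        out[group] = profile.values[cols].median(axis=1)
    return out


def select_threshold(values, n_grid: int = 1024) -> float:
    """Abscissa of the lowest interior density minimum between the two
    highest modes of a kernel density estimate (Gaussian kernel, Silverman
    bandwidth) over the pooled values.

    Ties between equal-depth minima break toward the lower abscissa.
    Raises :class:`UnimodalError` when fewer than two modes are found.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 100:
        raise ValueError(f"need at least 100 values, got {x.size}")
    kde = gaussian_kde(x, bw_method="silverman")
    pad = 0.05 * (x.max() - x.min())
    grid = np.linspace(x.min() - pad, x.max() + pad, n_grid)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    if len(maxima) < 2:
        raise UnimodalError(
            f"unimodal distribution: found {len(maxima)} mode(s); "
            f"bandwidth={kde.factor * x.std():.4g}")
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo_m, hi_m = sorted(top2)
    interior = np.arange(lo_m + 1, hi_m)
    minima = interior[(dens[interior] <= dens[interior - 1])
                      & (dens[interior] <= dens[interior + 1])]
    if len(minima) == 0:
        raise UnimodalError("no interior density minimum between the two modes")
    best = minima[np.argmin(dens[minima])]  # argmin takes the first = lowest abscissa
    # refine on a fine local grid between the neighbouring coarse points
    fine = np.linspace(grid[best - 1], grid[best + 1], 201)
    return float(fine[np.argmin(kde(fine))])


def score_reactions(
    model: MetabolicModel, expr: dict[str, float] | pd.Series, threshold: float = 0.0
) -> ReactionScoreSet:
    """Evaluate each reaction's gene rule against per-gene expression
    (AND→min, OR→max; unresolvable leaves ignored)."""
    if isinstance(expr, pd.Series):
        expr = expr.to_dict()
    scores: dict[str, float] = {}
    no_evidence: set[str] = set()
    for r in model.reactions:
        val = r.gene_rule.evaluate(expr)
        if val is None:
            no_evidence.add(r.id)
        else:
            scores[r.id] = float(val)
    return ReactionScoreSet(scores=scores, threshold=float(threshold),
                            no_evidence=no_evidence)


def extract_submodel(
    ref: MetabolicModel,
    scores: ReactionScoreSet,
    protected: ProtectedSet,
    objective: list[str],
    delta: float = 1e-3,
    epsilon: float = 0.1,
    time_limit: float = 120.0,
    gapfill: bool = True,
) -> MetabolicModel:
    """Context-specific submodel via task-constrained MILP selection.

    Maximizes Σ w_r y_r with w_r = score_r − θ (w_r = −ε for no-evidence
    reactions) over binary inclusion variables y_r, subject to S·v = 0,
    per-reaction big-M coupling −M·y ≤ v ≤ M·y with M = max(|lb|, |ub|),
    y = 1 for protected and objective reactions, and each objective
    reaction carrying flux ≥ δ.  The returned model contains exactly the
    selected reactions, gap-filled from the reference (protected reactions
    plus boundary reactions supporting them) and re-validated.
    """
    protected.check(ref)
    rxn_ids = [r.id for r in ref.reactions]
    idx = {rid: i for i, rid in enumerate(rxn_ids)}
    for rid in objective:
        if rid not in idx:
            raise KeyError(f"objective reaction {rid!r} not in reference model")
    n = len(rxn_ids)
    S = stoichiometric_matrix(ref).to_numpy()
    m = S.shape[0]
    theta = scores.threshold

    w = np.empty(n)
    for i, r in enumerate(ref.reactions):
        if r.id in scores.no_evidence:
            w[i] = -epsilon
        elif r.id in scores.scores:
            # tiny bonus keeps score == θ reactions deterministically included
            w[i] = scores.scores[r.id] - theta + 1e-9
        else:
            w[i] = -epsilon

    forced = set(protected.reaction_ids) | set(objective)

    # variables: [v (n), y (n)]
    c = np.concatenate([np.zeros(n), -w])  # milp minimizes
    integrality = np.concatenate([np.zeros(n), np.ones(n)])
    lb_v = np.array([r.lb for r in ref.reactions], dtype=float)
    ub_v = np.array([r.ub for r in ref.reactions], dtype=float)
    for rid in objective:
        lb_v[idx[rid]] = max(lb_v[idx[rid]], delta)
    lb_y = np.zeros(n)
    ub_y = np.ones(n)
    for rid in forced:
        lb_y[idx[rid]] = 1.0
    var_lb = np.concatenate([lb_v, lb_y])
    var_ub = np.concatenate([ub_v, ub_y])

    bigM = np.maximum(np.abs(lb_v), np.abs(ub_v))
    bigM = np.maximum(bigM, delta)

    cons = [LinearConstraint(np.hstack([S, np.zeros((m, n))]), 0.0, 0.0)]
    # v - M y <= 0 and v + M y >= 0
    eye = np.eye(n)
    cons.append(LinearConstraint(np.hstack([eye, -np.diag(bigM)]), -np.inf, 0.0))
    cons.append(LinearConstraint(np.hstack([eye, np.diag(bigM)]), 0.0, np.inf))

    from scipy.optimize import Bounds

    res = milp(
        c, constraints=cons, integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"time_limit": time_limit, "mip_rel_gap": 1e-6},
    )
    if res.status == 2:
        raise ExtractionError(
            "extraction MILP infeasible: the protected/objective task cannot "
            f"carry flux >= {delta} in the reference model")
    if res.status == 1:
        gap = getattr(res, "mip_gap", float("nan"))
        raise ExtractionError(f"extraction MILP hit the time limit (gap={gap})")
    if res.status != 0:
        raise ExtractionError(f"extraction MILP failed: {res.message}")

    y = res.x[n:]
    kept = [rid for rid, i in idx.items() if y[i] > 0.5]
    sub = ref.subset(kept, id=f"{ref.id}_ctx")
    if gapfill:
        sub = gapfill_protected(sub, ref, protected)
    return assert_valid(sub)


def gapfill_protected(
    pruned: MetabolicModel, ref: MetabolicModel, protected: ProtectedSet
) -> MetabolicModel:
    """Copy from the reference any protected reaction missing from the
    pruned model, plus any exchange or transport reaction of the reference
    that touches a metabolite of a protected reaction and is absent from
    the pruned model.  Idempotent."""
    protected.check(ref)
    have = set(pruned.reactions_by_id)
    add: list[str] = []
    prot_mets: set[str] = set()
    for rid in protected.reaction_ids:
        prot_mets |= set(ref.reaction(rid).stoich)
        if rid not in have:
            add.append(rid)
    for r in ref.reactions:
        if r.id in have or r.id in add:
            continue
        if (is_exchange(r, ref) or is_transport(r, ref)) and (set(r.stoich) & prot_mets):
            add.append(r.id)
    if not add:
        return pruned
    out = pruned.copy()
    met_ids = set(out.metabolites_by_id)
    for rid in add:
        r = ref.reaction(rid).copy()
        for met_id in r.stoich:
            if met_id not in met_ids:
                out.metabolites.append(ref.metabolite(met_id))
                met_ids.add(met_id)
        out.reactions.append(r)
    return assert_valid(out)
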