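"""Uniform sampling of the FVA-bounded steady-state flux polytope.

The sampler is artificial centering hit-and-run (ACHR): directions are
drawn as (random stored point − running center), projected onto the null
space of S and normalized; the step length is uniform on the exact feasible
segment through the current point.  Warmup points are the FVA extreme
solutions.  Chains are fully reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .model_core import MetabolicModel, stoichiometric_matrix
from .flux_analysis import FVAResult, SolverError, _solve_lp, bounds_hash

__all__ = [
    "FluxSampleSet",
    "clamp_to_fva",
    "warmup_points",
    "achr_sample",
    "marker_flux",
    "MarkerValues",
]

SV_TOL = 1e-6
BOUND_TOL = 1e-8
NULLSPACE_TOL = 1e-10


@dataclass
class FluxSampleSet:
    """Steady-state flux vectors (samples × reactions) from one chain."""

    samples: pd.DataFrame
    n_samples: int
    seed: int
    provenance: str

    def to_tsv(self, path, sidecar: str | None = None) -> None:
        self.samples.to_csv(path, sep="\t", index_label="sample")
        if sidecar:
            import json

            with open(sidecar, "w") as fh:
                json.dump({"n_samples": self.n_samples, "seed": self.seed,
                           "provenance": self.provenance}, fh, indent=1)


def clamp_to_fva(model: MetabolicModel, fva: FVAResult, tol: float = 1e-6) -> MetabolicModel:
    """Replace each reaction's bounds by its FVA range (intersected with the
    original bounds).  An FVA range outside the original bounds beyond *tol*
    means the result was computed on a different model (stale) and raises."""
    out = model.copy()
    for r in out.reactions:
        if r.id not in fva.ranges:
            raise KeyError(f"FVA result missing reaction {r.id!r}")
        lo, hi = fva.ranges[r.id]
        if lo < r.lb - tol or hi > r.ub + tol:
            raise ValueError(
                f"stale FVA: range [{lo}, {hi}] for {r.id!r} outside bounds "
                f"[{r.lb}, {r.ub}]")
        r.lb = max(r.lb, lo)
        r.ub = min(r.ub, hi)
        if r.lb > r.ub:  # numerical crossing after intersection
            mid = 0.5 * (r.lb + r.ub)
            r.lb = r.ub = mid
        r.reversible = r.lb < 0
    return out


def warmup_points(model: MetabolicModel) -> np.ndarray:
    """FVA-extreme warmup points (≤ 2R, deduplicated), all satisfying
    S·v = 0 and the model bounds."""
    S = stoichiometric_matrix(model).to_numpy()
    n = len(model.reactions)
    bounds = [(r.lb, r.ub) for r in model.reactions]
    pts = []
    for j in range(n):
        for sense in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sense
            res = _solve_lp(c, S, np.zeros(S.shape[0]), bounds)
            if res.status == 2:
                raise ValueError("clamped model is infeasible; no warmup points")
            if res.status != 0:
                raise SolverError(f"warmup LP failed: {res.message}")
            pts.append(res.x)
    arr = np.unique(np.round(np.array(pts), 9), axis=0)
    return arr


def achr_sample(
    model: MetabolicModel,
    n_samples: int,
    thinning: int = 100,
    seed: int = 0,
    warmup: np.ndarray | None = None,
) -> FluxSampleSet:
    """Artificial centering hit-and-run over the model's flux polytope.

    Every ``thinning``-th chain point is stored until *n_samples* rows are
    collected.  The running center is the mean of warmup plus accepted
    points; directions come from stored points (classic ACHR), projected
    onto null(S).  The current point is re-projected onto the null space
    after every step to control numerical drift, and stored samples
    are clamped to the bounds (tolerance 1e-8).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    S = stoichiometric_matrix(model).to_numpy()
    N = null_space(S, rcond=NULLSPACE_TOL)  # orthonormal basis of null(S)
    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    if warmup is None:
        warmup = warmup_points(model)
    stored = [w for w in warmup]
    center = np.mean(warmup, axis=0)
    x = center.copy()
    # the centroid of feasible points is feasible (convexity)

    out = np.empty((n_samples, len(lb)))
    collected = 0
    it = 0
    degenerate = 0

    def bail():
        nonlocal degenerate
        degenerate += 1
        if degenerate > 1000:
            raise RuntimeError(
                "ACHR: >1000 consecutive degenerate directions "
                "(polytope may be a single point)")

    while collected < n_samples:
        it += 1
        pick = stored[rng.integers(len(stored))]
        d = pick - center
        d = N @ (N.T @ d)
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            bail()
            continue
        d /= nrm
        # exact feasible segment along x + alpha d; every coordinate that
        # moves appreciably constrains the step, so the chain state never
        # needs clipping back into the box (which would break S·v = 0)
        act = np.abs(d) > 1e-12
        if not act.any():
            bail()
            continue
        # tiny slack keeps the segment nonempty when rounding parks the
        # chain marginally outside a face; stored samples are clipped back
        with np.errstate(divide="ignore", invalid="ignore"):
            lo_a = (lb - 1e-9 - x) / d
            hi_a = (ub + 1e-9 - x) / d
        alphas_lo = np.where(d[act] > 0, lo_a[act], hi_a[act])
        alphas_hi = np.where(d[act] > 0, hi_a[act], lo_a[act])
        a_min = alphas_lo.max()
        a_max = alphas_hi.min()
        if not np.isfinite(a_min):
            a_min = -1e6
        if not np.isfinite(a_max):
            a_max = 1e6
        if a_max - a_min < 1e-12:
            bail()
            continue
        degenerate = 0
        alpha = rng.uniform(a_min, a_max)
        x = x + alpha * d
        # null(S) is a linear subspace: orthogonal projection of the point
        # itself strips accumulated rounding drift off S·x = 0
        x = N @ (N.T @ x)
        if it % thinning == 0:
            out[collected] = np.clip(x, lb, ub)
            collected += 1
            stored.append(x.copy())
            center = center + (x - center) / len(stored)
    rxn_ids = [r.id for r in model.reactions]
    df = pd.DataFrame(out, columns=rxn_ids)
    return FluxSampleSet(samples=df, n_samples=n_samples, seed=seed,
                         provenance=f"{model.id}:{bounds_hash(model)}")


@dataclass
class MarkerValues:
    """Per-sample marker readout plus the count of dropped (undefined)
    ratio samples."""

    values: np.ndarray
    n_dropped: int = 0


def marker_flux(samples: FluxSampleSet, panel_entry: dict,
                missing: str = "error") -> MarkerValues:
    """Per-sample marker value for one panel entry.

    ``secretion``: flux of the metabolite's exchange reaction (positive =
    secretion).  ``enzyme_sum``: summed net flux of the enzyme's reactions
    across compartments.  ``ratio``: per-sample numerator secretion over
    denominator uptake magnitude; samples with uptake below 1e-9 are
    dropped and counted.  Reactions absent from the sample set raise by
    default; ``missing="zero"`` treats them as structurally blocked
    (pruned from the model) and contributes zero flux.
    """
    df = samples.samples

    def col(rid: str) -> np.ndarray:
        if rid in df.columns:
            return df[rid].to_numpy()
        if missing == "zero":
            return np.zeros(len(df))
        raise KeyError(f"reaction {rid!r} not present in sample set")

    kind = panel_entry["type"]
    if kind in ("secretion", "enzyme_sum"):
        total = np.zeros(len(df))
        for rid in panel_entry["reactions"]:
            total = total + col(rid)
        return MarkerValues(values=total)
    if kind == "ratio":
        num = col(panel_entry["numerator"])
        den = np.abs(col(panel_entry["denominator"]))
        ok = den > 1e-9
        return MarkerValues(values=num[ok] / den[ok], n_dropped=int((~ok).sum()))
    raise ValueError(f"unknown marker type {kind!r}")
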