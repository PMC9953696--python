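"""Marker-wise comparison of two flux sample sets and pipeline orchestration.

Effect sizes are Cliff's d — the dominance statistic
d = P(x > y) − P(x < y) estimated over all pairs — with a 95% confidence
interval from Cliff's unbiased variance estimator (dominance-matrix row and
column variances, normal quantile).  Effect sizes are reported *instead of*
p-values and no multiplicity correction is applied: with thousands of
sampled flux vectors per group any difference is "significant", so the
magnitude of the dominance is the meaningful summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .contextualize import (
    ProtectedSet,
    aggregate_by_group,
    extract_submodel,
    quantile_normalize,
    score_reactions,
    select_threshold,
)
from .flux_analysis import PhysiologicalConstraints, apply_physiological_constraints, fva
from .model_core import MetabolicModel
from .sampling import FluxSampleSet, achr_sample, clamp_to_fva, marker_flux
from .synthetic_data import (
    GLN_GLU_GABA_REACTIONS,
    default_marker_panel,
    make_two_group_scenario,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EffectEntry",
    "EffectReport",
    "cliffs_delta",
    "magnitude",
    "flux_ratio",
    "build_report",
    "run_pipeline",
    "PipelineConfig",
]

#: |d| cutoffs for negligible / small / medium / large (Romano et al.),
#: the convention used by the common effect-size tooling; lower-inclusive.
MAGNITUDE_CUTOFFS = (0.147, 0.33, 0.474)

#: Sentinel for a flux ratio whose denominator mean is ~0.
UNDEFINED_RATIO = float("nan")


def cliffs_delta(x, y) -> tuple[float, tuple[float, float]]:
    """Cliff's d with a 95% CI from the unbiased variance estimator.

    d = (#{x_i > y_j} − #{x_i < y_j}) / (n·m); ties contribute zero.  The
    variance uses the dominance-matrix row/column means (Cliff 1993/1996);
    the CI is d ± 1.96·s truncated to [−1, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("cliffs_delta needs at least 2 values per sample")
    D = np.sign(x[:, None] - y[None, :])
    d = float(D.mean())
    di = D.mean(axis=1)
    dj = D.mean(axis=0)
    s2 = (m**2 * np.sum((di - d) ** 2) + n**2 * np.sum((dj - d) ** 2)
          - np.sum((D - d) ** 2)) / (n * m * (n - 1) * (m - 1))
    s = float(np.sqrt(max(s2, 0.0)))
    lo = max(-1.0, d - 1.96 * s)
    hi = min(1.0, d + 1.96 * s)
    return d, (lo, hi)


def magnitude(d: float) -> str:
    """Label |d|: negligible < 0.147 ≤ small < 0.33 ≤ medium < 0.474 ≤ large."""
    if not -1.0 <= d <= 1.0:
        raise ValueError(f"Cliff's d must lie in [-1, 1], got {d}")
    a = abs(d)
    if a < MAGNITUDE_CUTOFFS[0]:
        return "negligible"
    if a < MAGNITUDE_CUTOFFS[1]:
        return "small"
    if a < MAGNITUDE_CUTOFFS[2]:
        return "medium"
    return "large"


def flux_ratio(a, b, tol: float = 1e-9) -> float:
    """mean(a)/mean(b); the undefined-ratio sentinel (NaN) when |mean(b)|
    is below *tol* — never ±inf."""
    ma, mb = float(np.mean(a)), float(np.mean(b))
    if abs(mb) < tol:
        return UNDEFINED_RATIO
    return ma / mb


@dataclass
class EffectEntry:
    """Per-marker effect: Cliff's d, CI, magnitude, ASD/control flux ratio."""

    marker: str
    category: str
    cliffs_d: float
    ci95: tuple[float, float]
    magnitude: str
    ratio: float
    direction: str  # up | down | none
    n_dropped: int = 0


@dataclass
class EffectReport:
    """All marker effects grouped by pathway category, plus run metadata."""

    entries: list[EffectEntry]
    metadata: dict = field(default_factory=dict)

    def by_category(self) -> dict[str, list[EffectEntry]]:
        out: dict[str, list[EffectEntry]] = {}
        for e in self.entries:
            out.setdefault(e.category, []).append(e)
        return out

    def entry(self, marker: str) -> EffectEntry:
        for e in self.entries:
            if e.marker == marker:
                return e
        raise KeyError(f"no marker {marker!r} in report")

    def to_records(self) -> list[dict]:
        return [
            {"marker": e.marker, "category": e.category,
             "cliffs_d": e.cliffs_d, "ci_lo": e.ci95[0], "ci_hi": e.ci95[1],
             "magnitude": e.magnitude, "ratio": e.ratio,
             "direction": e.direction, "n_dropped": e.n_dropped}
            for e in self.entries
        ]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_records()).to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"entries": self.to_records(), "metadata": self.metadata},
                      fh, indent=1, default=str)


def build_report(
    asd: FluxSampleSet,
    control: FluxSampleSet,
    panels: list[dict] | None = None,
    missing: str = "error",
    metadata: dict | None = None,
) -> EffectReport:
    """Compare two sample sets marker-by-marker.

    Direction is the sign of Cliff's d when the magnitude is at least
    small, and "none" for negligible effects; the ASD/control ratio of mean
    fluxes is reported alongside.  ``missing="zero"`` treats reactions
    pruned from one model as structurally blocked (zero flux).
    """
    panels = panels if panels is not None else default_marker_panel()
    entries = []
    for entry in panels:
        try:
            va = marker_flux(asd, entry, missing=missing)
            vc = marker_flux(control, entry, missing=missing)
        except KeyError as exc:
            raise KeyError(f"marker {entry['id']!r}: {exc}") from exc
        d, ci = cliffs_delta(va.values, vc.values)
        mag = magnitude(d)
        direction = "none" if mag == "negligible" else ("up" if d > 0 else "down")
        entries.append(EffectEntry(
            marker=entry["id"], category=entry.get("category", ""),
            cliffs_d=d, ci95=ci, magnitude=mag,
            ratio=flux_ratio(va.values, vc.values), direction=direction,
            n_dropped=va.n_dropped + vc.n_dropped,
        ))
    return EffectReport(entries=entries, metadata=metadata or {})


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything one two-group run needs.

    Constraint defaults are deliberately round placeholder values
    (NOT-FROM-PAPER) suitable for the toy networks; any real-tissue use
    must override them from measured cerebral metabolic rates.
    """

    seed: int = 0
    n_samples: int = 10_000
    thinning: int = 100
    threshold: float | str = "auto"
    age_range: tuple[float, float] = (2.0, 14.0)
    objective: tuple[str, ...] = GLN_GLU_GABA_REACTIONS
    gamma: float = 1.0
    delta: float = 1e-3
    quantile_normalize: bool = False
    panels: list[dict] | None = None
    constraints: dict[str, PhysiologicalConstraints] | None = None
    n_per_group: int = 12
    implant_shift: float = 2.0

    @staticmethod
    def default_constraints() -> dict[str, PhysiologicalConstraints]:
        # Placeholder magnitudes (NOT-FROM-PAPER): glucose uptake 1, oxygen
        # up to 5.6x glucose, maintenance ATP in [0.1, 0.4] -- scaled to the
        # toy network's unit-glucose convention so the Gln cycle task and
        # the sampler have headroom.
        def one() -> PhysiologicalConstraints:
            return PhysiologicalConstraints(
                cmr_glu=1.0, o2_glu_ratio=5.6, o2_min=0.0,
                atp_maintenance=(0.1, 0.4),
                vmax={"GLS": 5.0, "GLNS": 5.0, "GAD": 5.0},
            )

        return {"ASD": one(), "control": one()}


def run_pipeline(
    config: PipelineConfig | dict | None = None,
    model: MetabolicModel | None = None,
    profile=None,
    out_dir=None,
) -> EffectReport:
    """Run contextualize → constrain → loopless FVA clamp → ACHR sample →
    compare for both groups and return the effect report.

    With no *model*/*profile* given, the packaged two-group synthetic
    scenario is generated from ``config.seed``.  When *out_dir* is set the
    contextualized models (JSON), flux samples (TSV) and the report
    (TSV + JSON) are written there.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig(**config)
    truth = None
    if model is None or profile is None:
        model, profile, truth = make_two_group_scenario(
            config.seed, n_per_group=config.n_per_group,
            implant_shift=config.implant_shift)

    values = profile.values
    if config.quantile_normalize:
        values = quantile_normalize(values)
        profile = type(profile)(values=values, group=profile.group, age=profile.age)

    medians = aggregate_by_group(profile, config.age_range)
    if config.threshold == "auto":
        theta = select_threshold(values.to_numpy().ravel())
    else:
        theta = float(config.threshold)
    logger.info("expression threshold theta = %.4f", theta)

    # default protected core: the objective cycle, every boundary exchange,
    # and the ATP maintenance reaction (gene-less but physiologically
    # mandatory)
    protected = ProtectedSet(
        set(config.objective)
        | {r.id for r in model.exchange_reactions()}
        | ({"ATPM"} & set(model.reactions_by_id))
    )
    constraints = config.constraints or PipelineConfig.default_constraints()
    objective = {rid: 1.0 for rid in config.objective}
    panels = config.panels if config.panels is not None else default_marker_panel()

    sample_sets: dict[str, FluxSampleSet] = {}
    group_seeds = {g: (config.seed * 1000 + k + 1) % (2**31)
                   for k, g in enumerate(sorted(medians))}
    ctx_models: dict[str, MetabolicModel] = {}
    for group, med in medians.items():
        scores = score_reactions(model, med, threshold=theta)
        ctx = extract_submodel(model, scores, protected,
                               objective=list(config.objective),
                               delta=config.delta)
        pc = constraints.get(group)
        if pc is not None:
            ctx = apply_physiological_constraints(ctx, pc)
        ranges = fva(ctx, objective, gamma=config.gamma, loopless=True)
        clamped = clamp_to_fva(ctx, ranges)
        sample_sets[group] = achr_sample(
            clamped, n_samples=config.n_samples, thinning=config.thinning,
            seed=group_seeds[group])
        ctx_models[group] = ctx
        logger.info("group %s: %d reactions kept, %d samples",
                    group, len(ctx.reactions), config.n_samples)

    report = build_report(
        sample_sets["ASD"], sample_sets["control"], panels=panels,
        missing="zero",
        metadata={
            "seed": config.seed, "group_seeds": group_seeds,
            "n_samples": config.n_samples, "thinning": config.thinning,
            "threshold": theta, "gamma": config.gamma,
            "objective": list(config.objective),
            "synthetic": True,
            "ground_truth": None if truth is None else truth.marker_effects,
        },
    )
    if out_dir is not None:
        from pathlib import Path

        from .model_io import write_model

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for group, ctx in ctx_models.items():
            write_model(ctx, out / f"model_{group}.json")
            sample_sets[group].to_tsv(out / f"samples_{group}.tsv",
                                      sidecar=str(out / f"samples_{group}.json"))
        report.to_tsv(out / "report.tsv")
        report.to_json(out / "report.json")
    return report


def load_panels(path) -> list[dict]:
    """Read a marker panel YAML (a list of panel entries)."""
    with open(path) as fh:
        panels = yaml.safe_load(fh)
    if not isinstance(panels, list):
        raise ValueError("panel YAML must contain a list of marker entries")
    return panels
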