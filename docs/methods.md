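# Methods

## Model containers and conventions

A `MetabolicModel` holds metabolites (id, compartment token, optional
formula/charge) and reactions (signed stoichiometry, bounds, subsystem,
gene rule). Flux units are µmol/(g tissue · min) everywhere; the only unit
conversion in the package is `csf_to_flux(conc, flow, mass) = conc·flow/mass`,
turning a CSF concentration (µmol/L) and flow (L/min) into an uptake bound.

Exchange reactions have exactly one metabolite, in compartment `"e"`, with
**positive flux = secretion** and negative flux = uptake. This makes "the
secretion rate of metabolite X" a direct nonnegative readout and fixes the
sign of every constraint setter (fixing glucose uptake to CMRglu sets the
glucose exchange to [−CMRglu, −CMRglu]). Compartment tokens are free
strings, not an enum, so any FBC-compliant SBML (including Human1 exports)
loads without translation. The native JSON dialect mirrors the in-memory
types 1:1 and round-trips byte-stably modulo key order; SBML support
covers Level 3 + FBC v2 bounds and gene-product associations only.

## Synthetic fixtures: what they emulate, and what they do not

**Respiration fixture.** A lumped network whose stoichiometry encodes the
classical yield bookkeeping: glycolysis (2 ATP + 2 cytosolic NADH per
glucose), a shuttle feeding cytosolic NADH into the chain at the
2-ATP-equivalent (FADH₂) level, pyruvate dehydrogenase, a lumped
per-acetyl-CoA TCA (1 ATP-equivalent, 3 NADH, 1 FADH₂, 2 CO₂), and chain
oxidations at 3 ATP/NADH and 2 ATP/FADH₂. Maximal ATP demand per unit
glucose is therefore exactly 36 = 2 + 2 + 32 with 6 CO₂; blocking oxygen
leaves glycolysis + lactate export (2 ATP, 0 CO₂). Lactate and CO₂
exchanges are secretion-only by default so no alternative substrate can
inflate the yield.

**Brain toy network** (126 reactions, 116 metabolites, 107 synthetic
genes). Extends the fixture with: the TCA cycle as individual reactions;
ETC complexes I–V coupled through a proton-motive pseudo-metabolite (4
charges pumped by complexes I and III, 2 by IV, 4 consumed per ATP by
complex V — i.e. P/O ≈ 2.5/1.5, the modern consensus values rather than
the textbook 3/2 used in the lumped fixture, whose yield arithmetic is the
point there); the glutamine–glutamate–GABA cycle with glutamate
dehydrogenase and pyruvate-carboxylase anaplerosis; ALT/AST transaminases
fed by an ATP-citrate-lyase route to cytosolic oxaloacetate; superoxide
generation, SOD, catalase and a two-compartment GSH/GSSG cycle (GPx + GSR,
NADPH from lumped transhydrogenases); choline uptake, choline kinase and
choline acetyltransferase; inositol synthesis from glucose; a PLA2-style
cleavage releasing arachidonate/DHA/EPA in fixed proportions
(0.6/0.2/0.2), with COX and LOX reactions to PGE2/PGE1/leukotriene; and
the de-novo sphingolipid chain serine + palmitoyl-CoA → ketosphinganine →
sphinganine → dihydroceramide → ceramide → {sphingomyelin,
glucosylceramide, sphingosine → S1P}. Every marker in the packaged panel
resolves to an exchange (metabolites) or reaction set (enzymes).

Where the pathway biochemistry leaves cofactor stoichiometry open
(sphingolipid chain, eicosanoid oxygen counts, NADPH supply), coefficients
are chosen minimal and mass-consistent per reaction. The quantitative
surface of this network is yields and flux *directions*, not kinetics:
none of its flux magnitudes should be read as physiological rates. Every
enzymatic and transport reaction carries a synthetic gene (AND-pairs for
multi-subunit complexes, OR-pairs for isozymes) so GPR scoring is
exercised on both connectives; exchanges are gene-less.

**Expression generator.** Each gene is assigned to the low or high
component of a two-Gaussian log2 mixture (defaults N(6, 0.8²) and
N(11, 0.8²), equal weight — modes > 4 sd apart, mimicking the bimodal
shape of quantile-normalized microarray values); its per-sample values are
i.i.d. draws from that component, so the pooled distribution is exactly
the stated mixture and the analytic inter-mode density minimum (1-D root
finding on the mixture density derivative) is the ground-truth threshold.
Genes named in `effects` are shifted in the ASD group only. Ages are 75%
children (uniform 2–14 y) and 25% adults (15–56 y) per group, so the
age-window filter always has material to discard. The generator does not
emulate probe-level noise, batch effects, gene–gene correlation, or
missingness — threshold-recovery and direction-recovery results on it
bound what the algorithms can do under clean conditions, not what real
microarray data will give.

**Two-group scenario** (the end-to-end test bed; default 12 samples per
group). Core-machinery genes (energy metabolism, neurotransmitter cycle,
transporters, redox, eicosanoid enzymes) are pinned to the high mode — a
cortex transcriptome always expresses these — while the sphingolipid-chain
genes (enzymes plus their dedicated exporters) start 1 log2 unit below the
inter-mode minimum and are shifted up by +2 in the ASD group. The shift
straddles the threshold with ≈1 log2 unit of margin on each side, so
extraction keeps the chain in the ASD model and prunes it from the
control model. 300 unmapped filler genes pad the pooled distribution for
the kernel density estimate. `implant_shift=0` gives the matched null
scenario: identical model structure in both groups, differing only by
sampling randomness.

## Contextualization

* Quantile normalization maps every sample onto the cross-sample mean of
  order statistics (ties averaged). The synthetic generator already emits
  normalized-scale values, so the pipeline applies this step only when
  asked (`quantile_normalize: true`) — real microarray matrices need it,
  the generator's output does not.
* Group aggregation takes per-gene medians over samples with age in a
  closed window, default [2, 14] years (children's expression, age-stable
  enough to pool).
* Threshold selection runs a Gaussian KDE with Silverman bandwidth on the
  pooled values, requires ≥ 100 points, takes the two highest modes, and
  returns the lowest interior minimum between them (ties break toward the
  lower abscissa; a final refinement minimizes the KDE on a 201-point
  local grid). Unimodal input is an explicit error, with the bandwidth in
  the message for diagnosis.
* Extraction MILP: binaries y_r, weights w_r = score_r − θ (+1e−9 so
  score = θ is deterministically kept), w_r = −ε with ε = 0.1 for
  reactions without gene evidence; big-M coupling with
  M_r = max(|lb_r|, |ub_r|, δ); protected and objective reactions forced
  y = 1; each objective reaction's flux lower bound raised to
  δ = 1e−3 µmol/(g·min). Solved with HiGHS branch-and-bound at relative
  gap 1e−6 (deterministic); a 120 s time limit raises with the incumbent
  gap rather than returning a silent suboptimum. Gap-filling copies absent
  protected reactions plus any reference exchange/transport touching a
  protected reaction's metabolites; it is idempotent.

The default protected core in the pipeline is the Gln–Glu–GABA cycle, all
boundary exchanges, and the ATP maintenance reaction. Protecting every
exchange keeps the boundary complete so that pruning decisions are made by
gene evidence on interior reactions, not by accidental loss of a sink.

## Flux analysis

FBA/FVA run through one HiGHS interface (feasibility 1e−9, optimality
1e−8). The model objective is the unweighted sum of the three
neurotransmitter-cycle fluxes (weights configurable). Loopless correction
is post-hoc ℓ1 minimization (CycleFreeFlux-style): exchanges and objective
reactions are fixed at their solved values and internal flux re-chosen to
minimize Σ|v| within the original box — an LP, sufficient at toy scale,
documented as an approximation to MILP loopless-FVA. FVA at objective
fraction γ (default 1.0) adds c·v ≥ γz* − 1e−9·max(1, |z*|); if that
constraint is ever numerically infeasible the analysis downgrades to
unconstrained-objective FVA with a logged warning, honoring "at the cycle
optimum, if possible". ATP maintenance default bounds are [10, 40]
µmol/(g·min) — 10 for non-signaling activity and 10 + 30 with
signaling — with the bare 30-reading available via configuration.

The shipped pipeline constraint defaults (CMRglu = 1, CMRO₂/CMRglu = 5.6,
ATP maintenance [0.1, 0.4], V_max = 5 for the three cycle enzymes) are
round placeholders on the toy network's unit-glucose scale, marked
NOT-FROM-PAPER in the config: real-tissue use must override them with
measured cerebral metabolic rates, enzyme V_max values and CSF
concentrations in the stated units.

## Sampling

ACHR: warmup points are the deduplicated per-reaction FVA extreme
solutions; the center is the running mean of warmup + accepted points;
directions are (random stored point − center) projected onto an
orthonormal null-space basis of S (rank tolerance 1e−10) and normalized;
the step is uniform on the exact feasible segment. Every `thinning`-th
point is stored (default 100; unreported by the method this follows, so a
package choice). Numerical drift: the chain point is re-projected onto
null(S) after every step — null(S) is a linear subspace, so orthogonal
projection restores S·v = 0 exactly — and the chain state is never
clipped into the bound box (clipping after projection feeds an
amplification loop through large stoichiometric coefficients; only the
*stored copy* of each sample is clipped, and a 1e−9 slack in the segment
computation keeps steps well-defined when rounding parks the chain on a
face). Degenerate directions (norm < 1e−12 or empty segment) are
resampled; more than 1000 consecutive failures abort — the polytope is a
single point. Samples satisfy S·v = 0 to 1e−6 and bounds to 1e−8, and
chains are bit-reproducible under a seed.

## Effect-size report

Cliff's d is computed from the full sign matrix (ties contribute 0); the
95% CI uses the unbiased variance estimator from the dominance-matrix row
and column means,

    s² = [m²Σᵢ(dᵢ. − d)² + n²Σⱼ(d.ⱼ − d)² − Σᵢⱼ(Dᵢⱼ − d)²] / [nm(n−1)(m−1)],

with a symmetric normal-quantile interval d ± 1.96·s truncated to [−1, 1]
(no bootstrap, for determinism; Monte Carlo agreement of the estimator
with the empirical variance and ≈95% coverage is part of the development
checks). Magnitude labels use the Romano cutoffs 0.147/0.33/0.474,
lower-inclusive. The reported direction is the sign of d when |d| is at
least "small" — the dominance statistic is robust to the sampler's heavy
tails — while the ASD/control ratio of arithmetic mean fluxes is shown
alongside (median behind a flag); a control mean below 1e−9 yields a NaN
sentinel, never ±inf. No multiplicity correction is applied, by design:
the report is effect-size-based screening, not hypothesis testing, and is
labelled synthetic whenever it came from the toy scenario.

## Problem sizes and determinism

Default pipeline runs use 10,000 samples per group. The repeated-replicate
null check (20 seeds) runs at 1,000 samples with thinning 50, and the
packaged CLI demo configs are smaller still — replicate counts matter more
than per-run depth for a calibration check, and the null comparison's d is
already stable at that depth. All randomness flows from explicit seeds
(expression generation, ACHR chains; group chains get distinct
seed-derived streams), so every report is reproducible bit-for-bit given
its config.

## Known limitations

* The extraction MILP is a desk-scale variant of task-constrained
  extraction: one metabolic task (the neurotransmitter cycle), linear
  weights score − θ, no ordered gene levels, no task list. It reproduces
  the selection behavior, not any specific published implementation.
* Loopless correction removes representable internal circulations by ℓ1
  minimization; it does not enforce thermodynamic (ΔG) consistency and can
  shrink a reaction's FVA extreme that is attainable loopless by a
  different ℓ1-suboptimal flux pattern.
* ACHR provides split-half mean agreement as its only convergence
  diagnostic; no parallel-chain (OptGP-style) sampling.
* Toy-network results demonstrate machinery. Real-data use requires an
  FBC-compliant reference model, measured physiological constraints, and a
  gene-id mapping done upstream by the user.
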