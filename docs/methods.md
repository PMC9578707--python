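# Methods

This note documents the models implemented in `crispra-screen`, the
reasoning behind their defaults, and what the synthetic benchmarks do and do
not establish about real screens.

## The screen generative model

A pooled CRISPRa enrichment screen is modeled as a sequence of three
stochastic operations on a vector of per-guide cell counts.

**Library build.** The naive library holds `coverage` cells per guide on
average (default 1000, matching the ≥1000× coverage such protocols
maintain). Per-guide initial abundances are log-normal with coefficient of
variation `abundance_cv` (default 0.5): lentiviral pools are right-skewed,
and the log-normal is the standard single-parameter choice. Each
gene-targeting guide receives an activation efficacy `e ∈ [0, 1]` drawn from
Beta(κ/2, κ/2) with κ = `efficacy_dispersion` (default 4, i.e. Beta(2, 2),
mean 0.5): guides activate their targets to varying degrees, and a symmetric
Beta captures that heterogeneity with one tunable parameter. κ = 0 is the
degenerate "ideal guides" setting in which every gene-targeting guide has
efficacy exactly 1. Control guides always have efficacy 0.

**Selection.** Each cell is captured on the bead column independently with
probability

    p = capture_base + (capture_max − capture_base) · e(guide) · s(gene),

where `s ∈ [0, 1]` is the gene's ground-truth binding strength (0 for
non-receptors and controls). Cells sharing a guide share `p`, so per-guide
capture is drawn as a single binomial. Captured cells are expanded back to
the pre-selection population size by multinomial resampling: growth-rate
differences between clones are not modeled, because between-round expansion
is short and fitness effects are not part of the phenomenon of interest.
Bead avidity, column physics and washing are all folded into the two capture
parameters. Defaults `capture_base = 0.005`, `capture_max = 0.5` were fixed
once by requiring the deterministic one-step frequency map
`f' = f·p_hit / (f·p_hit + (1−f)·p_bg)` to reproduce the qualitative
benchmark behavior of such screens — a sub-percent positive population after
transduction, tens of percent after one round, near-saturation after two —
starting from a ~0.5% guide share. No per-round capture efficiencies are
published for the platform, so these are calibration constants of the
simulator, not measurements.

**Sequencing.** Each sampled population (the naive library and every round)
is read as one multinomial draw of `sequencing_depth` reads (default 10⁶)
over guide frequencies. PCR bias, UMI structure and index hopping are not
modeled.

What the simulator therefore does *not* emulate: multiple integrations per
cell (MOI > 1), clone-specific growth, guide-level off-target activation,
and overdispersed sequencing noise. Passing benchmarks on this generator
shows that the statistical pipeline recovers planted signal under idealized
but realistically parameterized sampling; it does not certify performance
against correlated biological artifacts, which is what the membrane/secreted
annotation filter, blacklist and trajectory screens address downstream.

## Gene-level enrichment statistics

Per-guide enrichment is `x_i = log2(f_sel,i / f_ref,i)` with a pseudocount
α = 0.5 added to every count before frequency normalization (keeps dropout
guides finite; each selection round is always compared to the naive library,
not the previous round).

The null density f0 of guide enrichments is a Gaussian kernel density
estimate over the control-guide statistics (Scott's rule bandwidth). The
log-density is tabulated on a fine grid spanning [min − 5·bw, max + 5·bw]
and floored at −30 everywhere, so outlier guides cannot produce infinite
log-likelihoods.

A gene's effect θ is the *maximum* effect a guide can experience; a guide
realizes a uniform fraction of it, modeling variable guide efficacy. The
per-guide density under effect θ is

    f(x | θ) = (1/|θ|) ∫₀^{|θ|} f0(x − sgn(θ) t) dt,

which equals a difference of the null CDF: `(F0(x) − F0(x − θ)) / θ`. The
implementation tabulates F0 by cumulative trapezoid on the density grid and
evaluates the integral as that CDF difference — the same trapezoid
quadrature as a fixed-node rule, at much finer resolution and vectorizable
across the whole permutation workload. For |θ| < 10⁻⁴ the mixture is
evaluated as f0 itself (the continuity limit).

The effect is the argmax of `L(θ) = Σ_i log f(x_i | θ)` over a grid
θ ∈ [−15, +15] in steps of 0.1 log2 units (spanning any realistic
enrichment); ties break to the smallest |θ|, then the negative one, so a
flat profile yields effect 0. The score is the likelihood ratio
`2·[L(θ̂) − L(0)]`, clipped at 0. The effect interval is
`{θ : L(θ) ≥ L(θ̂) − 2}` — the standard ≈95% profile-likelihood region.

The p-value is a permutation test: `N_perm` pseudo-genes of the same guide
count are drawn with replacement from the pool of *all* gene-targeting
enrichments (conservative in real screens, where most genes are null), their
scores recomputed identically, and
`p = (1 + #{S_perm ≥ S_obs}) / (N_perm + 1)`, bounded below by
1/(N_perm + 1). Within one analysis round, pseudo-gene draws are shared
among genes with the same guide count — the draws are i.i.d. from the same
pool, so per-gene independent draws would be statistically identical and
G-fold slower. Default N_perm = 10,000; simulation-heavy benchmarks scale it
to 500, which leaves a p floor of 1/501 ≪ the 0.05 filter threshold.

### Numerical notes

- Null-density grid: 4001 points; CDF clamped to [0, 1] outside the grid;
  densities below e⁻³⁰ floored before taking logs.
- Degenerate (zero-variance) control sets are nudged by ±10⁻⁹ so the KDE is
  proper; the resulting null is a spike at the common value.
- Permutation scores are computed in chunks of 1000 pseudo-genes to bound
  memory at a few tens of MB regardless of N_perm.

## Hit calling

ESP = (effect + score) / max(p, p_floor) with p_floor = 1/(N_perm + 1): the
permutation p cannot be smaller, and the floor keeps ESP finite. The
first-pass filter retains genes with effect > 2 AND score > 2 AND p < 0.05
(strict inequalities, as published), an annotation class in the
membrane/secreted proteome, and no blacklist membership. The default
blacklist ships empty with a documented slot, since no canonical contaminant
list exists for arbitrary cell backgrounds.

Trajectories are classified on per-round ESP with a noise band τ = 0.1:
round-to-round dips of ≤ 10% of the previous magnitude are treated as
sampling noise. A constant trajectory is *flat*; a trajectory whose steps
all stay within the band and whose final value has not fallen more than the
band below its first value is *positive*; a final value below the first is
otherwise *negative*; deep transient dips with recovery are *flat*. The
terminal comparison honors the same band as the steps deliberately: once a
hit saturates (all guides far beyond the null support, p at the permutation
floor), `L(θ̂) ≈ −n·log θ̂` makes the score *decrease* slightly as
enrichment keeps growing, so a strict final-greater-than-first rule would
mislabel the strongest true positives as negative on a 1–2% wobble. A called
hit must pass the first-pass filter on the final round *and* have a positive
trajectory; called hits are ranked by final-round ESP (ties: higher score,
then gene id).

## Interactome analyses

Network summaries are exact set arithmetic over unordered, uppercased
ligand–receptor pairs (duplicate pairs are rejected; self-interactions are
permitted, as homodimeric ligands do occur). Phylogenetic homology analysis
uses pairwise global alignment (BLOSUM62, gap open 10, extend 1) rather than
a full multiple sequence alignment: for subfamily grouping the pairwise
distances d = 1 − identity are adequate, deterministic and dependency-free.
Identity is identical aligned positions over alignment length. Family trees
are neighbor-joining on these distances (negative branch lengths clamped to
zero); on additive matrices NJ reproduces all path lengths exactly, which
the tests verify to 10⁻⁹. PHA candidates around a validated receptor are all
family members within distance δ (default 0.6 — separating within- from
between-subfamily distances in typical receptor families; exposed because
the boundary is family-dependent).

Expression clustering is hierarchical with Ward linkage on correlation
distances (1 − Pearson r across tissues), applied through the
Lance–Williams update directly on the correlation distances, as the common
desktop statistics tools do; constant rows get the maximal distance 2 with
a warning. Database overlap is exact intersection over normalized pairs,
with the full Venn partition reported.

## SPR kinetics

The 1:1 Langmuir model is solved in closed form (association
`R(t) = Req(1 − e^{−(kon·C + koff)t})`, `Req = Rmax·C/(C + KD)`;
dissociation `R(t_a)·e^{−koff(t−t_a)}`) rather than by ODE integration —
exact and fast for this model class. Kinetic fitting is global nonlinear
least squares over all concentration series simultaneously, parameterized
in (log kon, log koff, log Rmax) so positivity is structural, with 8
starting points whose KD guesses are log-spaced two decades beyond the
concentration range (the loss surface has local minima for short
associations) and a koff initial guess from the log-linear dissociation
tail. Traces containing only dissociation data yield koff but flag kon, KD
and Rmax as unidentifiable. Steady-state analysis fits the binding
hyperbola; the fit is flagged underdetermined when the concentration series
never approaches KD or when the Rmax–KD ridge leaves the KD standard error
at or above the estimate. Reference subtraction and bulk-shift terms are
assumed handled upstream (traces pre-referenced); mass-transport limitation
and heterogeneous-ligand models are out of scope.

## Benchmark problem sizes

The packaged benchmarks use a 200-gene / 10-guides-per-gene / 200-control
screen with two selection rounds and N_perm = 500 for recovery and a
1000-gene null screen for calibration, at sequencing depth 10⁶ — sizes at
which the permutation machinery and KDE are exercised end-to-end while a
full 100-seed replicate sweep completes in about half a minute. The null
calibration checks both that p-values are approximately uniform (fraction
below 0.05 within [0.03, 0.07]) and that the composed filter plus
trajectory requirement calls zero hits in ≥95% of null screens.

## Known limitations

- The gene-level statistics are a normative reconstruction of the cited
  casTLE framework's published description, not a numerical re-implementation
  of its internals; score units are likelihood-ratio units under this
  package's null model.
- The score saturates (and slowly declines) once every guide of a gene lies
  beyond the control support; rankings among saturated hits then hinge on
  the effect term of ESP. This regime only occurs for extremely strong
  enrichment, where calling is unambiguous anyway.
- The uniform-efficacy mixture assumes guide effects are uniform on
  [0, θ]; bimodal guide behavior (dead guides plus perfect guides) is
  absorbed but not explicitly modeled.
- PHA distances come from pairwise alignments; families whose homology is
  only detectable through an MSA profile may cluster differently.
- No FDR machinery beyond the published fixed cut-offs is provided, by
  design.
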