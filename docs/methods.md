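# Methods

## Model and constraints

A metabolic network is the polytope P = {v : S v = 0, lb ≤ v ≤ ub} over
reaction fluxes v (mmol h⁻¹ g-DW⁻¹). Reactions with no declared bounds get
±1000 (0 lower if irreversible) — the conventional "effectively unbounded"
magnitude. Exchange reactions are auto-detected as stoichiometric columns
touching a single metabolite; uptake is negative flux on such a reaction.

Measured exchange fluxes are applied per condition as equality constraints
(lb = ub = v_exp) by default. A relative band mode
[v(1−ε), v(1+ε)] exists because strict equality can be infeasible under
measurement noise; exact mode is the default because the method's semantics
are "fix the measured fluxes". A measured value outside the model's bounds
is applied anyway with a warning — the LP then reports the infeasibility
rather than the loader silently repairing data.

Gene associations are flattened to (gene, reaction) pairs; isoenzymes are
separate rows and AND/OR enzyme-complex logic is deliberately not
evaluated, since the downstream classification is per enzyme, not per
complex.

## Corner sampling

Sampling extreme points uses the fact that a simplex optimum of a linear
objective over P is a vertex. Each draw picks 2 distinct eligible reactions
uniformly without replacement and assigns weight w = u / m, u ~ U(0,1),
m = max(|FVA min|, |FVA max|); the normalization makes reactions of very
different flux scales comparably likely to dominate the objective. The
sense is always maximization with positive weights, so corners that
*minimize* a given flux are only reached through other reactions'
objectives — a known directional bias of the approach that we keep, since
correcting it would change the sampled distribution. `m` uses the larger
FVA magnitude rather than the literal maximum so reversible reactions whose
maximum is 0 (but minimum negative) remain usable; reactions with both
magnitudes below 10⁻⁹ are ineligible. Duplicate corners are retained: the
statistics are over n solutions, not over unique vertices.

All LPs are solved with HiGHS dual simplex (via `scipy.optimize.linprog`,
method `highs-ds`), which returns basic feasible solutions, i.e. vertices;
interior-point methods are not used anywhere. Degenerate alternate optima
are resolved by whatever vertex the simplex lands on — in particular, an
objective that is constant over the polytope (both drawn reactions pinned
by measurements) returns a deterministic solver-chosen vertex. On small
fixtures this shifts corner means slightly away from the symmetric value
(e.g. branch means of 5/12 and 7/12 on a symmetric two-branch split);
tests account for it. Tolerances: steady-state residual ≤ 10⁻⁹ relative,
bound violation ≤ 10⁻⁶, FVA bound-hit detection 10⁻⁶ × default bound.

n = 500 samples per condition: the flux-change score Z (below) is estimated
with standard deviation ≈ 1/√n, and keeping the estimation error under
0.15 with probability 0.999 — roughly one mis-scored reaction per
genome-scale model — requires n ≥ (Φ⁻¹(0.9995)/0.15)² = 482
(`required_sample_size`); 500 is the round default. The 1/√n error model
counts only the sampling noise of the means and is exact at the no-change
null; a nonzero true Z contributes a further ≈ z²/4n of variance through
the variance estimator, so coverage at strongly changed reactions is
slightly below nominal (measured 0.998 at z ≈ 0.9). Significance calls
hinge on behavior near the null, where the guarantee holds.

## Loops

Internal stoichiometrically balanced cycles admit unbounded circulation
that would wreck means and variances. Loop-capable reactions are exactly
those whose FVA minimum or maximum reaches the ±1000 default bound (an
exchange-limited reaction cannot get there). They are excluded from
objective draws, and all of them are clamped to a single per-condition
bound [−B, B] (irreversible members keep lower bound 0), with B the
smallest multiple of 0.1 mmol h⁻¹ g-DW⁻¹ that keeps the measured fluxes
feasible. Feasibility is monotone in B, so B is found by bisection over
the multiples; the result equals the linear scan from 0.1 upward. One
global B per condition (not per reaction) keeps the calibration
one-dimensional and matches how a single per-condition value behaves in
practice. Thermodynamic loop-law elimination is out of scope by design —
bound-shrinking is the chosen mechanism.

## Hit-and-Run baseline

The comparison sampler runs hit-and-run in the null-space parameterization
v = v₀ + N y (measurement-pinned reactions are folded into the equality
system), started at the Chebyshev center, with warmup 10 × d and thinning d
for d degrees of freedom — conventional settings, configurable. It targets
the uniform distribution on P, so its per-reaction variances are those of
interior mass (e.g. 1/12 × width² on a segment) while corner sampling
concentrates on extreme points (e.g. ¼ × width² for an even two-point
split). That ordering — corner variance ≥ uniform variance on interval and
simplex geometries — is the package's testable version of the claim that
corner statistics are more conservative.

## Z-scores, probabilities, classification

Flux change: Z = (mean_A − mean_B)/√(var_A + var_B), orientation A minus B
with A listed first in a comparison. When var_A + var_B = 0 (fully
determined fluxes) Z is 0 for equal means, otherwise a ±38 sentinel
(erf saturates in double precision) flagged `z_capped`.

`deviation_z` = |measured − mean|/√variance scores how far a directly
measured flux sits from a sampler's distribution — the accuracy metric for
comparing samplers against ¹³C flux measurements.

Both Z's convert to change probabilities through the same two-sided
Gaussian form p(z) = erf(|z|/√2) = 2Φ(|z|) − 1. Using one function
everywhere reconciles the two phrasings of the transformation ("cumulative
normal" vs "error function"): the two coincide exactly under this form,
and p(0) = 0 as a change probability must. This is a reconstruction
decision — the alternatives (one-sided Φ variants) break either p(0) = 0
or the decision table below.

Classification per (gene, reaction):

    p_same = p(Z_expr) if same direction and not sign-inverted, else 0
    p_tr   = p_same · p(Z_flux)
    p_ptr  = p(Z_expr) · (1 − p(Z_flux))
    p_mr   = p(Z_flux) · (1 − p_same)

"Same direction" compares sign(Z_expr) with the sign of the flux
*magnitude* change (|mean_A| − |mean_B|): a negative flux becoming more
negative is an increase. A flux whose sign inverts between conditions
(both means clear of the noise floor 2σ, opposite signs) sets p_same = 0
outright: a transcript cannot flip a flux direction, metabolite levels
can. Writing p_mr with (1 − p_same) rather than (1 − p(Z_expr)) is what
makes a discordant expression change metabolic rather than unclassifiable;
when directions agree the two forms coincide. The label is the class whose
probability exceeds the 0.95 cutoff (classes are mutually exclusive above
any cutoff ≥ 0.5); otherwise `none`. The grid this produces, at saturating
|Z| = 8, is exactly the table in the README.

No multiple-testing correction is applied across reactions — the
probabilities are reported as-is, mirroring how such per-enzyme scores are
read; the enrichment step optionally applies Benjamini–Hochberg.

## TF enrichment

For each transcription factor, a 2×2 table over TR ∪ PR genes
(target/non-target × TR/PR) is tested for over-representation of targets
among TR genes with the one-sided exact hypergeometric tail
(`scipy.stats.hypergeom.sf`). The background is the TR ∪ PR union, a
direct two-group comparison — not a genome-wide background, which would
answer a different question. TFs with no target in the union are skipped.

## Synthetic fixtures — what they do and don't show

Fixtures are ≤ 30-reaction networks with hand-checkable geometry, flux
magnitudes in the 0.1–15 mmol h⁻¹ g-DW⁻¹ range of chemostat measurements:

- `chain`: fixed-throughput pathway, 0 degrees of freedom;
- `diamond` / `interval` / `simplex`: parallel-branch splits whose
  constrained polytopes are segments and simplices with known vertices.
  The "interval" is a two-branch split rather than a literal in/out pipe:
  a pipe's two fluxes are perfectly correlated, so positive-weight
  maximization could never reach the 0 endpoint — the split is the
  1-degree-of-freedom geometry on which both endpoints are samplable;
- `cycle`: a driven chain plus an isolated reversible 3-cycle (loop
  detection must flag exactly the cycle), or with `through > 0` a
  forward/backward 2-cycle carrying mandatory throughput (loop-bound
  calibration must land on the smallest step multiple ≥ the throughput);
- `planted_regulation`: independent 3-reaction units with known TR / PR /
  MR / none labels realized by construction: flux changes are imposed
  through uptake shifts (2 → 1), signal expression |Z| = 5, noise
  |Z| = 0.3. MR noise is oriented *against* the flux change — any
  same-direction expression noise leaves probability mass on the
  transcriptional explanation and dilutes p_mr below a 0.95 cutoff, so an
  MR label is only realizable with discordant (or negligible,
  |Z| < 0.063) expression noise.

`enumerate_vertices` is the independent oracle: it enumerates basic
feasible solutions by activating every d-subset of bound constraints in
the null-space parameterization (guarded at d ≤ 6), deduplicating at
10⁻⁸ — no LP involved.

What passing these fixtures does **not** show: behavior on genome-scale
models (thousands of reactions, degenerate optima everywhere, loop sets of
hundreds), robustness to inconsistent measurements beyond the band mode,
or the biological validity of expression Z-scores, which this package
consumes but never estimates. The published genome-scale comparisons
additionally require the iFF708 yeast reconstruction and external
chemostat flux / microarray datasets, which are optional inputs here, not
test dependencies.

## Problem sizes in the shipped checks

Unit and acceptance tests sample 30–500 corners and 1 500–4 000
hit-and-run points per fixture, and the sample-size study uses 10⁵
replicates of paired 500-sample estimates — sizes chosen so the whole
suite exercises every pipeline stage at Monte-Carlo tolerances a few times
tighter than the assertions.
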