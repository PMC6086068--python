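# Methods

## The model

`protrax` simulates and analyses **protracted speciation**: speciation
treated as a duration rather than an instant.  The unit of simulation is
the *population lineage*.  A lineage is either **good** (it has
completed speciation and founded a species) or **incipient** (a
divergent population not yet reproductively isolated).  Three
exponential hazards act continuously on every extant lineage, all in
units of events per lineage per million years (Myr):

| parameter | meaning | applies to |
|---|---|---|
| `splitting_rate` (λ′) | initiate a new divergent population | good and incipient (separately configurable) |
| `conversion_rate` (χ) | complete speciation; found a new species | incipient only |
| `extirpation_rate` (μ′) | lineage loss: death or merging back into the parental gene pool | good and incipient (separately configurable) |

1/χ is the expected speciation duration.  A good lineage has zero
conversion hazard: a species founder has nothing left to convert.

**Species identity** follows the *nearest completed ancestor* rule: a
lineage belongs to the species founded by the genealogically closest
ancestor (itself included) that has converted, the crown founder
counting as converted at time 0.  Equivalently, a conversion claims the
converting lineage's entire not-yet-converted descendant subtree —
including daughters born before the conversion — for the new species.
This is the species definition used throughout the protracted
birth-death literature.  We initially implemented the alternative
(birth-time inheritance only, no retroactive claim) and found it
depresses species richness noticeably when conversion is slow relative
to splitting; the retroactive rule is both the standard one and the one
consistent with published richness levels for these parameter ranges,
so it is the implemented semantics.

**Start and conditioning.**  Simulations start at the crown: one good
founder plus one incipient daughter at time 0, sharing the root species
until the daughter converts.  Time runs forward to `duration` (the
present).  By default an attempt is rejected and re-run (on the next
RNG substream; counted in `n_restarts`) unless *both* crown lineages
leave extant descendants, so the genealogy's crown age equals the
nominal duration — the natural convention when trees of fixed crown age
are the object of study, and the one a fixed-crown-age reference output
implies.  `conditioning="any"` (any survivor) and `"none"` are
available; richness under `"any"` runs roughly a third lower at the
bird-scenario rates because crown-extinct halves are kept.

**The Gillespie scheme** is exact: with `n_g` good and `n_i` incipient
lineages the total hazard is `n_g(λ′_g+μ′_g) + n_i(λ′_i+χ+μ′_i)`; the
waiting time is exponential in that total and a single uniform draw
selects class, lineage and event type.  Event-time ties have measure
zero in continuous time; no tie-breaking is needed beyond deterministic
iteration order.

## Rate calibration

Macro-level birth-death rates are compound.  The bridges implemented:

* χ = 1/(2t) from the mean sister-species age t (each side of an extant
  pair of age t has waited t on average for completion);
* λ = λ′·χ, hence λ′ = λ/χ;
* a species survives while any of its populations does; with e^{λ′t}
  populations per species per unit time, of which a fraction (1−χ)
  remains intra-specific, μ = μ′^(e^{λ′t}(1−χ)), inverted as
  μ′ = μ^(1/(e^{λ′t}(1−χ))).  The horizon defaults to t = 1 because
  rates are per Myr; it is exposed as a parameter.  The exponent form
  uses the deterministic expectation e^{λ′t} for the population count;
  no stochastic compounding over population number is attempted —
  the printed formula is the model.

`calibrate` returns full precision.  `calibrate_reported` rounds
stage-wise (χ to 2 decimals, then λ′ computed *from the rounded χ* and
rounded to 2 decimals, then μ′ to 1 decimal), which is how such tables
are published and is what the scenario defaults use; with t = 3.4 the
two chains genuinely differ (λ′ = 1.13 staged vs 1.156 full precision).
The inverse extinction map is the package's own algebraic inversion of
the forward statement; the two round-trip to 1e-12 relative error
(property-tested).  The inverse requires χ < 1 (otherwise the exponent
is non-positive and the map is not invertible) and μ ≤ 1 (the quantity
is probability-like in the derivation); both are enforced as domain
errors.

## Species trees

`sample_species_tree` keeps one uniformly chosen extant lineage per
extant species and returns the induced subtree: internal nodes at the
original splitting times, branch lengths in Myr, tips at the present
(ultrametric; a single-species genealogy gives a one-tip tree).  The
construction works directly on the event table (nearest common lineage,
earlier branch-off time) rather than building and pruning the full
population tree; tests verify it against a brute-force path-based
oracle.  Only the *random* representative rule is implemented — no
oldest/youngest variants, and no incomplete-sampling models.

Sister species are **cherries** (internal nodes with two tip children),
and "sister divergence" is reported as the full cophenetic path
distance between the two tips — twice the cherry age — matching the R
`cophenetic` convention.  This doubles what a naive "node age" reading
would give; the scenario means (~2–3 Myr for 6-Myr trees) only make
sense under the path-distance convention.  Ultrametricity is checked to
1e-9 Myr absolute; simulator output is exact by construction and Newick
round trips are bit-exact (`%.17g` branch lengths), so the tolerance
only guards externally produced files.

Welch's t (two-sided, Welch–Satterthwaite df) compares scenario
statistics.  For sister divergence the unit of analysis is the pooled
cherry across all replicate trees of a scenario, not the tree — the
published degrees of freedom (thousands) are only consistent with
pooling.

## Birth-death re-estimation

The constant-rate reconstructed-process log-likelihood on branching
times t₁ > … > t_{n−1} (t₁ the crown age), crown-conditioned on the
survival of both crown lineages:

    logL = (n−2)·ln λ + Σ_{i≥2} ln p1(t_i) + 2·ln p1(t₁) − 2·ln(1−E(t₁))

with r = λ−μ, p1(t) = r²e^{−rt}/(λ−μe^{−rt})², E(t) =
μ(1−e^{−rt})/(λ−μe^{−rt}).  Parameter-independent combinatorial
constants are omitted: only MLE locations and likelihood differences
are used.  Numerically everything is evaluated through
x = rt, φ(x) = −expm1(−x)/x:

    ln p1(t) = −x − 2·log1p(μ t φ(x)),   ln(1−E(t)) = −log1p(μ t φ(x)),

which is exact and smooth through λ = μ (φ(0)=1 recovers the classical
1/(1+λt)² limit) and cannot cancel catastrophically near criticality; a
log-space branch guards e^{−x} overflow in the strongly subcritical
regime.  The implementation is verified against a 30-digit symbolic
evaluation of the raw expression.

`bd_ml` maximises over (ln λ, ln μ) with L-BFGS-B (ftol 1e-12) from a
Yule-based initial point plus five spread starts including a
declining-diversity (μ > λ) start — μ > λ is allowed, as in the
standard ML fitters for this likelihood — and always evaluates the
exact pure-birth profile λ̂ = (n−2)/(2t₁+Σ_{i≥2}t_i), μ = 0 as a
boundary candidate.  Estimates with μ̂ < 1e-6 are snapped to the μ = 0
boundary and flagged `at_boundary` (two-tip trees, whose conditioned
likelihood is monotone, are likewise flagged).  Trees with fewer than
two species cannot be fitted and are excluded and counted upstream.

**Known property, deliberately not "fixed":** ML extinction-rate
estimates from reconstructed trees of a few tens to hundreds of tips
are upward-biased on average (the μ̂ distribution is a point mass at 0
plus a heavy right tail).  At (λ=0.3, μ=0.1, crown age 15, ~60-tip
trees) the mean μ̂ over 500 replicates is ≈0.15; an independent
reference fitter (ape's `birthdeath`) shows the same behaviour on the
identical trees (≈0.13, with its d/b < 1 constraint accounting for the
difference).  λ̂ is recovered without detectable bias at the same
settings.  The recovery test asserts strict unbiasedness for both
parameters and therefore fails for μ̂ — kept red intentionally as an
honest statement about the estimator rather than relaxed.

## The experiments

**LDG scenarios** (defaults): three 6-Myr, 100-replicate scenarios —
temperate-1 (λ′=1.16, χ=0.5, μ′=0.6; calibrated from λ=0.58, μ=0.45,
t=1), tropical (1.13, 0.15, 0.3; from λ=0.17, μ=0.04, t=3.4), and
temperate-2 (1.3, 0.15, 0.6; faster splitting, tropical-level
conversion).  The scenario defaults are the *stage-rounded* calibration
values, since those are the natural published inputs; the calibration
module regenerates them.  Outputs: per-replicate richness table, pooled
cherry distances, Welch comparisons, Newick archives, JSON run
metadata.  Replicates ending with one species contribute richness 1 but
nothing to the distance pool (counted as `n_singletons`).

Converged behaviour under these defaults (1,200–1,500-replicate
estimates): mean richness ≈ 45.7 / 56.6 / 36.5 and mean sister
divergence ≈ 2.06 / 3.02 / 3.10 Myr for temperate-1 / tropical /
temperate-2.  The tropical−temperate-1 richness gap (~11 species,
per-scenario SDs ~30–40) yields an expected Welch t around 2 at 100
replicates, so the "richness significantly higher in the tropics at
p<0.001" outcome reproduces only on favourable draws; the corresponding
acceptance test is left red with this explanation.  The divergence-time
contrasts are enormous (t ≈ 15–19) and reproduce at every seed tried.

**Micro-parameter grid**: 5×5×5 over λ′ ∈ {0.50…0.70}, χ ∈
{0.01…0.21}, μ′ ∈ {0.25…0.45} (evenly spaced; the two interior values
quoted in published results confirm the spacing), 15 Myr, birth-death
ML per species tree, per-cell means over converged fits.  The full
published design uses 200 replicates per cell; the packaged acceptance
runs use 20 per cell, which takes ~3 minutes on one core and already
brackets the published per-cell mean λ̂ range (≈0.02–0.27);
`n_reps=200` is a flag away.  `confounding_report` enumerates cell
pairs with near-equal mean estimates whose micro parameters differ on
at least two axes, sorted by decreasing parameter distance — the most
mechanistically different confounded pairs first.

## Randomness and reproducibility

All randomness flows from `numpy.random.SeedSequence`.  Replicate `r`
of stream `s` in experiment domain `d` uses
`SeedSequence(master_seed, spawn_key=(d, s, r, k))` (`k` = 0 for the
simulation, 1 for representative sampling); rejected attempts consume
successive children of the replicate's simulation stream.  Results are
therefore bit-reproducible, order-independent, and unaffected by how
many restarts other replicates needed.  Identical seed + configuration
gives bit-identical output tables (tested).

## What the simulator does and does not emulate

The generator *is* the study system: no empirical phylogenies enter
anywhere.  It emulates lineage-level diversification with constant,
state-independent rates — no diversity dependence, trait or geography
dependence, time-varying rates, or incomplete sampling.  Passing tests
therefore demonstrate internal consistency of the protracted model,
the calibration algebra, and the estimator chain, and say nothing about
how well constant-rate protracted speciation describes any real clade.

## Known limitations

* Richness under slow conversion is sensitive to the survival-
  conditioning rule and to the species-identity convention; both are
  configurable and the defaults are documented above.
* The extinction-rate surface of the grid is dominated by μ̂ = 0
  boundary fits in low-μ′ cells — a real feature of the estimator on
  protracted trees (their young-node deficit mimics low extinction).
* `bd_loglik` omits constants; absolute log-likelihood values are not
  comparable across other software's conventions, only differences and
  argmaxes are.
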