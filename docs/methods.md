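# Methods

## The diversity model

All diversity measures are Hill numbers ("effective numbers of species").
For one community with relative abundances `p`, `^qD = (Σ p_i^q)^(1/(1−q))`
with the analytic Shannon limit at `q = 1`. The limit branch is taken
whenever `|q − 1| < 1e−9`, never approached numerically from nearby q —
this removes the floating-point blow-up of `1/(1−q)` while keeping the
profile continuous to better than `1e−4` across the switch (tested).

For `N` communities with equal weights, gamma is the Hill number of the
pooled mean proportions `p̄_i = (1/N) Σ_j p_ij` and alpha is
`[(1/N) Σ_j Σ_i p_ij^q]^(1/(1−q))` (exponential of the mean Shannon
entropy at `q = 1`). Their ratio `D_β` is mathematically confined to
`[1, N]`; a computed value outside these bounds by more than `1e−6` is
treated as an internal error rather than clipped silently. The overlap
transform `C_qN` and its complement `^qβ = 1 − C_qN` are as given in the
README; at `N = 2` they coincide with classic Sørensen (q=0), Horn (q=1)
and Morisita–Horn (q=2) indices, an identity the test suite checks to
`1e−9` against independently coded closed forms.

Equal community weights are assumed throughout; unequal-weight and
incidence-based variants are out of scope. Every operation renormalises
rows of whatever matrix it receives, so proportions are never carried
through pooling — pooling conserves mass, and proportions are recomputed
at each grain.

## Biomass as the abundance currency

Counts are converted to biomass because the proportional biomass of a
species tracks its potential influence on ecosystem processes better than
raw counts when body size spans orders of magnitude. Each (species,
caste) gets a mean individual dry weight in mg: the mean of measured
specimens when at least three were weighed, otherwise a prediction from a
straight-line fit of log weight on log body dimension (a power law, the
standard form for mass–length allometry; the regression form is the one
conventional in ant allometry work). One regression is fitted per
dimension type — head length (Dolichoderinae, Formicinae,
Pseudomyrmecinae), hind-tibia length (Ponerinae), pronotum width
(Myrmicinae) — because the dimension measured, not the subfamily, defines
a common scale; subfamilies outside that mapping fall back to a pooled
all-species model. Caste-level count columns (`species|major`) are
converted separately and summed into one species column, so total biomass
is exactly `Σ count × weight`. In `fit_allometry`, a dimension-type group
with fewer than two distinct dimensions is an error by default; the
pipeline uses the non-strict mode, in which such a group simply falls
back to the pooled model.

## Sampling grains

Grain 1 is the plot. Higher grains pool pairs of same-habitat units
chosen by greedy matching on ascending great-circle distance (haversine,
Earth radius 6371 km), subject to a distance cap: 5 km at grain 2
(bracketing realistic within-cluster plot spacing of 1–4 km) and 45 km at
grain 3. Greedy matching with lexicographic tie-breaks makes the pairing
deterministic and auditable; an optimal minimum-weight matching would add
complexity without changing any of the clustered layouts this design
targets, and an explicit user-supplied pairing can override the matcher.
Units that cannot be paired are listed as omitted with a reason, never
silently dropped. Total sampled area per retained unit is therefore fixed
within a level, and column totals over retained plots are conserved
exactly at every pooling step (asserted in tests).

## Inference

Standard errors come from bootstrap resampling. Two schemes exist because
grain-1 units are single plots, where whole-unit resampling degenerates:
at grain 1 each plot's individuals are redrawn from a multinomial at the
observed depth (counts are resampled and converted to biomass inside the
statistic via the fixed per-species weight vector); at grains 2–3 whole
units are resampled with replacement. Defaults are B = 1000 for
multi-assemblage quantities and B = 500 for mean pairwise similarities;
both are overridable, and the run manifest records which scheme ran at
each grain. Mean pairwise similarity exploits the fact that unit
resampling only reweights existing pairs, so the precomputed pairwise
similarity matrix is re-indexed per iteration rather than recomputed.

Differences are assessed by two-sided standardized Z tests,
`z = (e₁ − e₂)/√(se₁² + se₂²)`. Families for BH-FDR correction are the
between-grain contrasts for a fixed q (and habitat, for within-habitat
comparisons) — i.e. correction is over grain levels. On very small
problems a contrast can have two exactly-zero SEs; the pipeline records
such a contrast with `p = NaN`, excludes it from the FDR family and never
flags it significant, while the library-level `z_test` keeps its strict
error contract. BH itself is the statsmodels step-up implementation,
cross-checked in the tests against a brute-force evaluation of the
step-up definition.

Singletons (species with total count 1 within the habitat dataset under
analysis — the most conservative reading; not per plot, not across both
habitats) are included in the main run and zeroed per habitat for a
repeated run, whose outputs differ from the main run exactly when
singletons exist.

## The synthetic landscape generator

The generator emulates the study conditions so that downstream stages can
be validated against known truth. Defaults: 26 oil-palm and 21 forest
plots; species pools of 105 and 181 sharing 63; ~550 individuals per plot
(the study's printed totals divided by its plot counts give ≈559 and
≈548); log-series rank abundances `p_k ∝ x^k/k` with `x = 0.99`, chosen
once so that the rare tail produces singletons at study-scale depth while
every pool species remains detectable under deep sampling (the
parameter-recovery regime); each habitat permutes abundance ranks over
its pool independently, so dominant species differ between habitats (a
flag disables this to create identical expected communities for null
designs). Plots are laid out two per cluster centre 1.2–2.5 km apart,
with centres on an 8-km grid (inside the 6–45 km bracket that grain-3
pooling assumes); an odd plot count leaves one isolated plot that the
grain-2 pairing must omit, and an odd number of grain-2 units leaves one
pair omitted at grain 3 — reproducing the 26→13→6 and 21→10→5 unit
structure. Body sizes and dry weights follow per-subfamily power laws
with lognormal scatter; a quarter of species get fewer than three
specimens so the allometric prediction path is always exercised.
Landscapes are caste-monomorphic by default; the caste machinery is
exercised with hand-built fixtures instead.

What the generator does *not* emulate: spatially explicit dispersal or
colonisation dynamics, within-habitat environmental gradients, trap-level
detection bias, and temporal turnover. Passing tests therefore show that
the estimators and the inference machinery behave correctly under
multinomial sampling from fixed pools — not that real ant communities
satisfy those assumptions.

## Numerical and design notes

- Zero abundances contribute nothing to any Hill sum (`0^0` never
  evaluated); empty inputs yield diversity 0 by convention.
- Relative-abundance rows must sum to 1 within `1e−9`; count matrices
  must be integral; all-zero samples are rejected at load (a trap set
  that yields no ants is suspect data, not a zero).
- Rank–biomass tables sort by mean biomass per unit, descending, with
  ties broken by species id for determinism.
- Rarefaction is interpolation-only (extrapolation and asymptotic
  richness estimators are out of scope); expected richness uses exact
  integer binomial coefficients, and coverage-by-effort curves enumerate
  all subsets when there are ≤ 500, else average 200 seeded random
  subsets.
- All pipeline randomness derives from one seed via labelled child
  generators (crc32 of the stage label), so reports are byte-identical
  across reruns with the same configuration and seed.
- Problem sizes in the test suite and acceptance script (e.g. 3 or 5
  seeds for recovery, 100–200 replicates at B = 200 for null
  calibration, depths up to 20,000 individuals per plot) were chosen as
  the smallest designs that make the statistical assertions sharp.

## Known limitations

- No public field dataset accompanies this study design, so the package
  validates its estimators on synthetic truth and on closed-form
  arithmetic rather than against field-measured beta values.
- Bootstrap SEs at grain 1 condition on the observed per-plot
  proportions (a plug-in bootstrap); under-coverage is possible for very
  shallow plots.
- Greedy pairing is not guaranteed optimal for adversarial geometries;
  use the pairing override for manual designs.
- Measurement error from specimen weighing is not propagated into
  downstream SEs.
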