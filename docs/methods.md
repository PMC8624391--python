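# Methods

## The design being modelled

The pipeline targets the standard introgression-line (IL) QTL assay: a
library of near-isogenic lines, each carrying one donor chromosomal segment
on a centimorgan map, scored together with the recurrent parent in a
completely randomized design of line × treatment × replicate.  The default
geometry is 50 ILs + 1 parent, three treatments whose first element is the
control (control, 75 mM, 150 mM NaCl), three replicate boxes of 45 seeds,
and a 10-day germination window.  Because each IL differs from the parent
by a single homozygous segment, a significant line-vs-parent contrast is
attributed to a QTL inside that segment; there is no dominance and no
within-line segregation to model.

## Trait metrics

Germination metrics are computed per replicate box from the daily counts of
newly germinated seeds, and enter the downstream ANOVA/Dunnett stages as
replicate-level observations (computing them per replicate rather than on
pooled seeds is required for the tests to have an error term).  GI uses
weights tied to the window length (w + 1 − d for day d), which yields the
algebraic identity MGT = w + 1 − GI/ΣN — asserted as a property test.
A box with zero germination has undefined MGT and propagates as missing.

Derived traits are composed per observation cell (SL = ShL + RL,
RSR = RL/ShL, SVI = GP·SL with GP in percent and SL in cm — the
percent-scaled variant, giving SVI magnitudes in the hundreds-to-thousands
range — WCP = 100(SFW − SDW)/SFW).  RSR and WCP are missing when their
denominator is zero.  Stress tolerance indices are computed replicate-wise
(salt replicate j over control replicate j of the same line), so STI traits
remain replicated observations that can themselves be scanned for QTL; the
treatment label of an STI observation names the salt level of the contrast.

Reduction percentage R% and relative performance RP% are both plain signed
percentages of a mean against a reference mean; internal computation is at
full precision and printed-precision rounding (1 dp for means/percentages,
2 dp for indices, 4 dp for p-values) is applied only when tables are
serialised.

## ANOVA and heritability

F tests use fixed-effects sums of squares (one-way per treatment; balanced
two-way G + T + G×T across treatments, every term tested against the error
MS), while the heritability estimator interprets the genotype term under
random-genotype expected mean squares: σ̂²_e = MS_E,
σ̂²_g = max(0, (MS_G − MS_E)/r), H_b = σ̂²_g/(σ̂²_g + σ̂²_e/r).  Mixing the
two conventions is deliberate — it is how this type of analysis is normally
run — and both are implemented explicitly.  Negative genotypic-variance
estimates are truncated at zero, so H_b ∈ [0, 100] and
H_b = 100(1 − MS_E/MS_G) whenever MS_G > MS_E.  R² is reported from the
genotype-only (one-way) model.  Unbalanced two-way layouts raise under the
default strict policy; the tolerant policy falls back to a Type-II OLS
decomposition (via statsmodels) as a proportional-subclass approximation,
with a warning.  Trait correlations are Pearson correlations of per-line
means within a treatment (replicate-level correlation is available behind a
flag); zero-variance traits give missing entries.

## The Dunnett scan

For k lines against the parent with error variance pooled over all k + 1
groups, the statistics follow a k-variate t with correlation
ρ_ij = γ_i γ_j, γ_i = √(n_i/(n_i + n_0)).  The two-sided adjusted p-value
P(max_j |T_j| ≥ |t_i|) is evaluated by conditioning on the shared control
factor Z₀ and the studentising factor W = √(χ²_ν/ν), which factorises the
joint CDF into a product of normal CDFs; the resulting two-dimensional
integral is computed with 128-node Gauss–Hermite × 96-node Gauss–Legendre
quadrature (the Legendre rule applied to the probability transform of W).
Absolute accuracy is ~10⁻⁵ or better over the relevant range, verified
against Monte-Carlo simulation of the max-|T| statistic and against an
independent library implementation in the test suite.  A family of one
comparison is marginally an ordinary Student t and is returned analytically.
The adjusted p is floored at the unadjusted two-sided t p-value (they are
equal at k = 1 and the adjustment can only increase p).  A family with zero
pooled variance (possible in noise-free simulations) is defined explicitly:
p = 0 where means differ, 1 otherwise.

Contexts: each treatment separately, plus an "overall" context defined as
Dunnett on treatment-pooled replicate values — replicate j's value is the
mean over treatments of that line's replicate-j observations — which keeps
r replicated values per line.  This is one of several defensible readings
of an "overall treatments" comparison; it was chosen because it preserves
the replicate structure the test needs.  Note the pooled contrast has
roughly 0.58× the single-treatment t for a salt-only effect, so strong
interaction effects can also trigger the main-effect route — both classes
may hold simultaneously, which is expected behaviour.

Classification (thresholds configurable): **interaction** iff the adjusted
p is below 0.01 in exactly one or two of the three treatments (the control
counts as a treatment here); **main effect** iff p < 0.05 in all three
treatments or in the overall context.  A line × trait with neither flag is
not an association.  The effect sign is taken from the significant contexts
(p < 0.05); disagreeing signs mark the association "mixed", which never
merges.

Merging: per trait × chromosome, associations are nodes and an edge joins
two lines iff any pair of their intervals overlaps (closed intervals; a
shared endpoint counts) and their signs agree; connected components become
one call spanning the union of member intervals.  Names are
`Q<Trait>.<LIB>.<chr>` with letter suffixes a, b, … by merged-interval
start (then end, then first line id) only when a trait × chromosome has
several calls.  Both the per-line association table and the merged calls
are emitted, since real catalogues sometimes keep overlapping same-sign
lines under separate names; the per-line table is the primary output and
the clusters are the summary.  A line with intervals on several
chromosomes yields one candidate per chromosome, flagged.

## The synthetic generator

Each simulated line receives one interval: chromosome uniform over a
7-chromosome map (130–180 cM), length uniform on 10–60 cM (matching
realistic introgression spans), clipped to the chromosome.  Planted QTL
attach to distinct lines, cycling over the modelled traits plus
germination, alternating all-treatment ("main") with salt-only
("interaction") patterns and alternating signs; effect sizes are expressed
in residual-SD units (default 2.5) and converted to trait units, or applied
on the logit scale for germination (default 1.0 logit).

Germination is per-seed: success with probability logistic(baseline logit +
planted shift), day from a gamma (shape 6) with treatment-specific mean,
discretised to days 1..w; seeds past the window count as non-germinated.
Defaults (final germination 0.93/0.83/0.82; mean day 3.1/3.7/3.3 by
treatment) produce the characteristic pattern of salinity lowering and
delaying germination.  Seedling primitives (ShL, RL, SFW, SDW) are Gaussian
around treatment-specific means chosen to be realistic for barley
germination-box assays (e.g. ShL 9.5/6.0/4.1 cm with residual SD 1 cm);
shoot length is floored at 0.1 cm so RSR stays defined.  Derived traits are
composed from the primitives, so their internal consistency holds by
construction.

What the generator does **not** emulate: linkage disequilibrium or shared
segments between lines (each line's interval is drawn independently, so
overlapping planted QTL arise only by chance), multi-QTL epistasis,
correlated residuals between traits beyond what composition induces,
non-Gaussian measurement error, and any physiological mechanism of osmotic
stress.  Passing tests therefore demonstrate that the statistical machinery
is correct under its own assumptions, not that those assumptions hold in a
real assay.

## Simulation studies and problem sizes

The operating-characteristic studies use a single measured trait on the
default 50-line geometry so repeated simulation stays cheap: QTL recovery
is estimated over 200 libraries with one planted 2.5-SD all-treatment
effect (recovery = some call's merged interval overlaps the truth), and
null calibration over 300 libraries with no planted effects.  Under the
null each Dunnett statistic is marginally Student t, so the per-line
probability of an adjusted p below α is exact from the max-|T| critical
value, and with independent treatment contexts the expected count of
interaction-class lines per library is closed-form; the simulation is
compared against that expectation (counts are overdispersed across
libraries because lines within a library share the control and the pooled
error, so comparisons use the empirical across-library standard error).
Heritability recovery uses 500 one-way layouts at σ²_g = 3, σ²_e = 1,
r = 3 (true H_b = 90%).

## Numerical and policy choices

- Missing phenotype values ("NA") are accepted and propagate as missing;
  LS-means average whatever replicates are present, and classification
  with a missing context is flagged partial.
- LS-means equal arithmetic means in the balanced design (no covariates in
  the model), so no projection machinery is used.
- Output serialisation is deterministic (fixed column order and decimals),
  making pipeline runs byte-for-byte reproducible from the manifest
  (config snapshot + rng seed + checksums).
- All generators are seeded through `numpy.random.SeedSequence` spawning,
  so every stage is reproducible and stages are independently perturbable.

## Known limitations

- The tolerant unbalanced-ANOVA path is an approximation, not a mixed
  model; heavily unbalanced designs deserve REML, which is out of scope.
- The Dunnett family is all lines vs parent within one trait × context; no
  additional multiple-testing control is applied across traits or
  contexts (matching standard practice for this design, where each trait
  is reported separately).
- The "overall" context definition and the replicate-wise STI are
  documented choices among several defensible ones; both are isolated
  behind small functions if a different convention is needed.
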