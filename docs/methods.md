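# Methods

## δ notation and preservation correction

Isotope abundances are expressed as δX (‰) = (R_sample/R_reference − 1) ×
1000 with R_VPDB = 0.0112372 (¹³C/¹²C) and R_airN₂ = 0.0036765 (¹⁵N/¹⁴N).
These constants are fixed, not configurable. δ values are stored and
compared at full float precision; only *reported* values are rounded, at
0.1‰ (the precision of published tables), using half-up rounding because
that is the convention the printed values follow (1.474 → 1.5, 3.21 → 3.2).

Formalin preservation depletes tissue δ¹³C by ≈1‰ and leaves δ¹⁵N
essentially unchanged, so the correction defaults to +1.0‰ on δ¹³C and
0‰ on δ¹⁵N. It is opt-in via a `preserved_formalin` flag rather than
applied silently — sediment samples are not formalin-preserved — and a
`corrected` flag makes the operation idempotent by construction: applying
it twice, or to unpreserved material, is an error.

## Diet mixing model

For consumer *i* and isotope *d*:

    X_id = Σ_j p_j (S_jd + C_jd) + ε_id
    S_jd ~ Normal(μ_jd, ω_jd)      (source signature)
    C_jd ~ Normal(λ_d, τ_d)        (trophic enrichment factor)
    ε_id ~ Normal(0, σ_d)          (residual)
    p ~ Dirichlet(α),  σ_d ~ HalfNormal(s_d)

Defaults: λ = (1.0, 3.8)‰ per trophic level for (δ¹³C, δ¹⁵N) with τ = 0;
α = 1 (uniform on the simplex). Source and TEF uncertainty are
marginalised analytically — X_id | p is Normal with mean Σ_j p_j (μ_jd +
λ_d) and variance Σ_j p_j² (ω_jd² + τ_d²) + σ_d² — which leaves the same
marginal likelihood as sampling S and C explicitly but with far fewer
parameters.

**Sampler.** Adaptive random-walk Metropolis on additive-log-ratio (ALR)
transformed proportions (reference = last source), jointly with log σ.
The ALR keeps the simplex constraint implicit; the Dirichlet density plus
the ALR Jacobian reduce to Σ_j α_j log p_j. The proposal is an isotropic
Gaussian whose scale starts at 2.4/√dim and is adapted in batches of 50
iterations toward ~30% acceptance *during burn-in only*, so retained
draws come from a fixed-kernel chain. Defaults: 4 chains × 10 000
iterations, 50% burn-in, thin 1, explicit seed (chains use seeds spawned
from one `SeedSequence`; identical seed + configuration ⇒ identical
draws). Convergence is summarised by split-R̂ and effective sample size
(computed with ArviZ on the in-package sampler's draws); R̂ > 1.1 raises
a warning and is recorded in the diagnostics, never an exception.

**Residual prior.** Conventions for the residual term vary across
mixing-model implementations; the half-normal scale defaults to the empirical
per-isotope consumer SD ("empirical"), can be fixed numerically, or
disabled (σ ≡ 0) when source/TEF spread alone should carry the
variability — the grid-oracle tests use the disabled form so the oracle
is one-dimensional.

**Validation.** The original per-site posteriors are *not* reproduced:
the end-member measurements live in external datasets that were never
published with the study. The shipped end-member table is a clearly
labelled synthetic stand-in. The model is instead validated by (a)
symmetry (a consumer equidistant from two equal-spread sources splits
50:50), (b) agreement within 0.02 with a 2001-point grid integration of
the 2-source/1-isotope posterior, (c) parameter recovery on synthetic
consumers (20 consumers at p = (0.7, 0.3) recovered within ±0.10), and
(d) ~95% empirical coverage of the 95% equal-tailed intervals over 100
simulated replicates.

## Trophic levels and Layman metrics

TL = (δ¹⁵N_consumer − δ¹⁵N_sediment)/Δ + 1 with Δ = 3.8‰ per level, the
enrichment established for this regional food web. The baseline is the
per-site bulk surface-sediment δ¹⁵N (NOW 7.4 ± 0.1‰, LS 8.3 ± 0.3‰ in
the packaged tables), treated as a point value: its SD is carried on the
type but not propagated, matching the deterministic form of the
equation. Food-web length is the maximum TL. Integer trophic-class
tallies use nearest-integer assignment with half-up ties; published
tallies rarely state their banding rule, so cross-study comparisons of
class counts should be made cautiously (the printed tallies of the study
system are not reproducible under any single obvious rule and are kept
in the fixtures as context only).

CD (mean Euclidean distance of taxa to the δ¹³C–δ¹⁵N centroid) and NND
(mean nearest-neighbour distance) operate on unscaled ‰ coordinates, per
the community-metric convention for isotope biplots. Duplicate points
yield zero NND contributions — complete trophic redundancy — and are not
an error. The study's printed CD/NND values cannot be recomputed because
the underlying per-taxon biplot coordinates appear only in a figure;
both metrics are instead verified against brute-force O(n²) oracles to
1e−12 and against closed-form configurations.

## Community summaries

Per-core totals are scaled by 1/area to ind. m⁻² and mg m⁻², then
averaged over replicate cores; SE uses ddof = 1 over n cores. The exact
sub-core area is not published ("~10 cm diameter" half-cores); fixtures
and the generator use a nominal 0.003927 m² (half of a 10 cm circle),
documented as nominal. Site totals pool layers by **summing layer
means**, which reproduces the published pooled totals exactly
(10 952 ind. m⁻² and 3190 mg C m⁻²); pooling per core and then averaging
is available as an option and is equivalent only when every core has
every layer. Because per-core raw counts were never published, the
layer-level means ± SE are fixture-encoded, not recomputed. (The LS
pooled density prints as 8355 while the rounded layer means sum to 8356
— rounding of unpublished unrounded means; only the exactly-reproducing
totals are asserted.)

Headless specimens and unidentified fragments are flagged and excluded
from density but included in biomass. The megafauna screen ranks
per-individual C biomass and excludes the prefix above the first
factor-k gap (default k = 10, an order-of-magnitude criterion); a single
ranked record has no comparison basis and is never excluded.

Comparison statistics delegate to scipy/statsmodels where those provide
the test (t tests, Mann-Whitney, Kruskal-Wallis, one-way ANOVA, two-way
ANOVA via OLS with a type-II table, Shapiro-Wilk). Residual normality is
gated by Shapiro-Wilk at α = 0.05; variance homogeneity uses a
median-centred Levene test — an explicit check where the original
workflow assessed homogeneity visually, which is a deliberate deviation
toward reproducibility. Zero-variance groups on a parametric path fall
back to the rank test with a warning. Welch's one-way ANOVA and the
Games-Howell post hoc are implemented in-package (neither ships with
scipy or statsmodels): Games-Howell refers |t|·√2, with Welch-adjusted
df per pair, to the studentized-range distribution with k groups. With
k = 2 this reduces exactly to the two-sided Welch t-test; under a
k = 3 Gaussian null its family-wise error is calibrated by simulation to
5% ± 1 point.

## Synthetic data

The generator emulates the study design: per-taxon pooled consumer
samples whose signatures follow the mixing model's generative form
(sources and TEF drawn per sample, Gaussian noise per isotope, default
0.5‰ — larger than instrument precision to stand in for biological
variability), optionally with δ¹⁵N pinned by inverting the TL equation
around the baseline so zero-noise scenarios recover specified trophic
levels exactly. Default diets are POM-dominated (Beta(7, 3) POM share,
mean 0.7), matching the source partitioning regime the analysis
targets. Replicate-core counts are negative-binomial (var = μ(1 + φμ);
φ = 0 recovers Poisson) because published replicate SEs imply
overdispersion; per-individual C biomass is lognormal around 0.25 mg C
with σ_log = 1, and N biomass follows C through a C/N ratio of 6.5.
These distributional choices are modelling assumptions of the generator,
not facts about the study system. Scenario defaults (18 taxa, 15 cores,
~1.5 individuals per taxon per core, 95:5 layer split) reproduce the
order of magnitude of the published community. All randomness flows from
one seeded generator; isotope and core streams are decoupled via spawned
seed sequences so changing one scenario block does not perturb the
other.

What passing tests on synthetic data do **not** show: the generator has
no spatial structure, no seasonal isotope dynamics or tissue-turnover
lag, no taxon-specific TEFs, and Gaussian isotope noise — real consumer
data violate all of these to some degree, so recovery results bound
performance under the model's own assumptions only.

## Pipeline and numerical choices

The CLI pipeline runs ingest → preservation correction → trophic
metrics → mixing model → community metrics and writes a manifest with a
config hash and SHA-256 checksums of every output; manifests contain no
timestamps, so identical inputs + seed give byte-identical manifests
(MCMC included, via per-group seeds spawned deterministically from the
run seed). Unknown config keys are rejected up front. Stage failures
raise errors naming the stage; CLI exit codes separate config (2), data
(3) and numerical (4) failures.

Degenerate-input conventions: empty collections are errors wherever a
mean or maximum is undefined; a mixing fit with all source/TEF SDs zero
and the residual disabled is rejected as a degenerate likelihood;
pigment ratio with zero phaeopigments is reported as missing rather than
raised.

Test problem sizes (2–4 chains × 1500–10 000 iterations, 100 coverage
replicates, 10 000 family-wise-error datasets) were chosen so the
complete suite exercises every calibration at Monte-Carlo error well
below the asserted tolerances while remaining quick to run on one CPU.
The family-wise-error simulation converts q statistics to accept/reject
via interpolated studentized-range critical values — mathematically the
same decision rule as p < α, verified against direct p-values within the
test — because element-wise `studentized_range.sf` is too slow for
30 000 evaluations.

## Known limitations

- Two-source, single-mixture model: no concentration dependence, no
  isotope routing, no hierarchical pooling across taxa/guilds (groups
  are fitted independently, as in the original per-taxon/per-guild use).
- The baseline SD and TEF uncertainty are not propagated into TL point
  estimates (deterministic TL equation).
- The Games-Howell studentized-range reference is asymptotic in the
  Welch df; very small groups (n < 5) can be mildly conservative.
- Fixture tables transcribe printed, rounded values; quantities that the
  original study derived from unpublished raw data (per-core counts,
  biplot coordinates, end-member measurements) are represented by
  clearly labelled synthetic stand-ins and are validated property-based
  rather than against printed numbers.
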