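# Methods

This note documents the statistical procedures, the synthetic-data
model behind the test and benchmark suites, the numerical choices, and
the places where the design was genuinely open.

## Site-wise linear model

Each CpG's methylation fraction β is regressed by OLS on an intercept,
a case indicator (0 = control, 1 = case), age in years, sex (M = 1),
and the first two correspondence-analysis scores of the estimated cell
composition. Models are fit on β fractions rather than M-values because
effect sizes are reported and tabulated as β differences ("mean β
difference", percentage points); `beta_to_m`/`m_to_beta` are provided
for users who prefer the variance-stabilized scale, and every fitting
function accepts whatever matrix it is given. The matched-pair
structure of the cohort is deliberately not modelled (no pair random
effect): pairing is handled by adjusting for the matching variables
(age, sex) plus cell composition, which keeps the model identical to
what one would fit on an unmatched cohort.

Empirical-Bayes variance moderation follows the scaled inverse-chi-
square hierarchy: s²|σ² ~ σ²χ²_d/d with prior σ² ~ s0²·d0/χ²_d0. The
hyperparameters are estimated by moment matching on log s²: d0 solves
trigamma(d0/2) = var(log s²) − trigamma(d/2) (Newton iteration on the
monotone trigamma; d0 = ∞ when the right-hand side is ≤ 0, i.e. the
observed spread of variances is no wider than chi-square sampling noise
alone), and s0² comes from the mean of log s² with the digamma bias
corrections. The moderated variance is (d0·s0² + d·s²)/(d0 + d) and the
t statistic gains d0 degrees of freedom. Moderation is on by default;
`moderate=False` gives textbook OLS, which the unit tests compare
against independent normal-equation oracles to 1e−9.

Two-sided p-values are BH-adjusted jointly across all analyzed probes.
The cohort-level significance summary is the count of probes with
q < 0.05.

### Interaction test

The group×age product column tests whether cases and controls differ in
their methylation-vs-age slope, as opposed to a constant offset. It is
only identifiable when both groups span an age range; a single-age
cohort raises an error. A cohort in which disease effects are constant
offsets should produce (after BH) no significant interactions — the
null-calibration suite checks exactly this.

## Region calling

The caller mirrors the comb-p approach:

1. **Autocorrelation.** p-values are probit-transformed
   (z = Φ⁻¹(1 − p), clamped to [1e−15, 1 − 1e−15]) and the Pearson
   correlation of z-pairs is computed per base-pair lag bin (width
   50 bp, window 1,000 bp), symmetrized over both pair orientations.
   Bins with fewer than 10 pairs inherit the previous bin's value (0
   for the first); negative estimates are clipped to 0 so the combined
   variance below stays valid and conservative.
2. **SLK smoothing.** Each probe's p-value is replaced by the
   Stouffer–Liptak combination of all p-values within ±1,000 bp,
   Z = Σz/√(Σσ), with σ taken from the lag-binned ACF (1 on the
   diagonal, 0 beyond the window). Isolated probes keep their p.
3. **Peak finding.** Regions seed at probes with SLK p < 0.05 and
   extend while the *next* probe is also below the threshold and within
   1,000 bp of the previous member. Requiring the next probe itself to
   be sub-threshold (rather than merely nearby) prevents regions from
   swallowing flat neighbours; the seed threshold plays both roles.
   Runs of fewer than `min_probes` (default 2) are dropped. Seeding
   operates on the SLK p itself, not on a q-value of it.
4. **Region significance.** Each region is scored by a Stouffer–Liptak
   combination of its original (pre-smoothing) p-values with
   ACF-derived pairwise correlations, then Sidak-corrected:
   p_sidak = 1 − (1 − p)^(L/ℓ), computed via log1p/expm1, where ℓ is
   the region's base-pair span and L the total analyzed territory. The
   "number of possible regions of the same size" needs a totality
   definition; L is taken as the probe-covered span per chromosome
   (last analyzed position − first + 1), summed — the least arbitrary
   choice at desk scale, and recorded in the audit output.

Direction is not used during combination (p-values are two-sided and
unsigned); it is recovered afterwards from the sign of the mean
case-minus-control β difference over member probes. Internal
coordinates are 1-based inclusive; BED export converts to 0-based
half-open, and the table reports length as end − start, the convention
used in printed DMR tables for this array family.

## Cell composition and ordination

Cell proportions solve min‖y − Rw‖² subject to w ≥ 0, Σw = 1 (SLSQP,
function tolerance 1e−12, result clipped/renormalized onto the
simplex), against a reference panel of cell-type-informative CpGs. The
covariate scores are the row principal coordinates (axes 1–2) of a
correspondence analysis of the samples × cell-types table; cell types
estimated zero everywhere are dropped first, and a composition table
with no variation yields zero scores.

Correspondence analysis itself follows the standard chi-square-metric
SVD: S = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2), principal coordinates
D^(−1/2)UΣ and D^(−1/2)VΣ, per-axis inertia σ_k², total inertia =
Pearson chi-square / grand total (an identity the tests verify to
1e−9). Axis signs are fixed so the largest-magnitude coordinate on each
axis is positive, removing SVD backend ambiguity. Sample ordination
runs on the top-k most variable sites (variance computed on the β
scale, default k = 10,000) with samples as columns; β values enter the
CA untransformed, which is well-defined because they are non-negative.

## Synthetic cohorts

The generator emulates what the analysis assumes about real blood
methylomes:

* **Manifest.** Probes clustered into CpG islands of 5–30 probes,
  20–100 bp apart within islands and 1.5–5 kb between islands, spread
  over several chromosomes — so the 1,000-bp window never bridges
  islands and spatial autocorrelation is a within-island phenomenon. A
  2% fraction of probes is flagged SNP-overlapping to exercise
  filtering.
* **Baselines.** Island-shared logit-scale baselines drawn from a
  bimodal mixture: 60% unmethylated (β 0.05–0.2), 30% methylated
  (0.7–0.95), 10% intermediate. Sharing the baseline within an island
  is what induces the neighbour correlation the SLK stage estimates.
* **Effects.** DMRs occupy whole islands, with a per-region offset on
  the natural-logit scale (direction +1 with probability 0.78 by
  default, matching the hypermethylation excess typical of this
  disease setting). When a target β-scale difference is requested, the
  logit offset is derived from the island's baseline so the noiseless
  group difference hits the target. Age and interaction slopes act
  additively on the β scale (units: fraction per year, i.e. percentage
  points/100), applied after the inverse logit — this keeps the
  injected slope exactly the quantity the linear model estimates, so
  noiseless recovery is exact. Age/interaction probes are disjoint
  from DMR and panel probes by default.
* **Cell mixture.** A 6-type leukocyte panel (600 probes, reference β
  drawn uniform on [0.05, 0.95]); per-sample proportions from a
  Dirichlet with concentration (0.55, 0.12, 0.08, 0.06, 0.07, 0.12)×50,
  i.e. realistic mean blood composition with moderate between-subject
  spread. Panel probes take the mixture mean R·w.
* **Noise.** Gaussian noise (sd 0.15) on the logit scale plus additive
  measurement noise (sd 0.01) on the β scale, clipped to
  [1e−6, 1 − 1e−6]. No published quantitative noise model exists for
  this setting; these are package defaults chosen to give per-probe β
  standard deviations of a few percentage points at mid-range
  baselines, and they are stated as such, not as facts about any
  dataset.
* **Repeat assay.** Per-family per-sample mean methylation percentages
  with Gaussian between-sample spread around whole-blood-typical
  baselines (ALU 25.0 ± 1.0, LINE1 84.0 ± 1.5, α-satellite 88.4 ± 1.5,
  rDNA promoter 18 ± 5 percentage points) and an optional group offset.

What the generator does **not** emulate: probe-type (Infinium I/II)
chemistry biases, batch effects, sex-chromosome dosage, cross-reactive
probes, long-range correlation beyond island membership, and any
intensity-level artefact — so passing benchmarks demonstrate that the
statistical machinery recovers the effects it models, not that it is
robust to every artefact of real arrays.

## Benchmark suites and problem sizes

The null calibration runs 20 seeded cohorts (18 + 18 samples, 5,000
probes, no injected effects, cell mixture active) and reports the raw
site-wise type-I rate at 0.05, the mean count of Sidak-significant
regions, and the count of BH-significant interaction sites.

The recovery benchmark runs four cohorts at n = 18 + 18: (i) 40 regions
of ≥ 5 CpGs with target |Δβ| 0.08–0.12 on a 6,000-probe manifest,
scored by interval-overlap recall/precision and direction accuracy;
(ii) 2,000 probes with 34 (1.7%) carrying a +0.0014 fraction/year age
slope, scored by the mean estimated slope over injected probes; (iii)
2,000 probes with 50 interaction probes at 0.004 fraction/year slope
difference, scored by power at uncorrected p < 0.05; (iv) 200 regions
at hyper-fraction 0.78 on a 24,000-probe manifest, scored by the
hypermethylated fraction among called regions.

Injected effects are kept sparse relative to the manifest throughout
(a fraction of a percent to a few percent of probes, as in real
cohorts, where age-affected sites are ~1.7% of the array). This
matters because quantile normalization — which forces every sample onto
the mean sorted profile — assumes samples share nearly identical
marginal distributions; saturating a small synthetic genome with
one-signed effects breaks that assumption and attenuates or distorts
the very effects being scored, a distortion no realistically sparse
cohort exhibits.

## Numerical choices and degenerate inputs

* β clipped to [ε, 1 − ε], ε = 1e−6, before any logit.
* p-values clamped to [1e−15, 1 − 1e−15] before probit.
* Sidak via −expm1(ratio·log1p(−p)) for stability at tiny p.
* Quantile normalization resolves ties by assigning the mean of the
  reference values across the tie group; a single-sample matrix is
  returned unchanged with a warning.
* Variable-site ranking breaks variance ties by probe id ascending.
* Zero-variance probes with zero residual get p = 1 rather than NaN.
* Probes with no neighbour within the window keep their original p.
* An all-zero ACF (no pairs at all) triggers a warning, after which
  the chain reduces to plain Stouffer combination.
* Missing β values are rejected at read time; the pipeline assumes
  complete matrices.

## Known limitations

* Quantile normalization operates on β values because the package's
  inputs are β matrices; intensity-level normalization of the original
  arrays is out of scope and not reproducible from β.
* The reference panel is idealized (uniform random β profiles with
  full column rank), not a curated leukocyte reference; only the
  estimation mechanics are validated.
* Gene-set enrichment implements the Fisher/BH mechanics against a
  user-supplied term↔gene annotation; it does not reproduce any web
  service's background universe or ontology propagation.
* The two-sided Fisher p uses the minimum-likelihood convention (sum
  of tables no more likely than observed); two-sided definitions
  differ between tools, which is documented here because fold
  enrichments are convention-independent but p-values are not.
* Multi-group cohorts are analysed one case group versus the shared
  controls at a time; no joint multi-group model is provided.
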