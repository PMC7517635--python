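# Methods

## The model

A cybrid collection pairs each of k nuclear backgrounds with each of k
mitochondrial haplotypes (mitotypes). Within one growth environment the
normalized fitness of replicate r of genotype (mitotype i, nucleus j) is
modeled as a crossed random-effects ANOVA,

    y_ijr = μ + mt_i + n_j + (mt×n)_ij + ε_ijr,

with every term an independent zero-mean normal: mt_i ~ N(0, σ²_mt),
n_j ~ N(0, σ²_n), (mt×n)_ij ~ N(0, σ²_mt×n), ε ~ N(0, σ²_e). Across
environments the model extends to

    y = μ + mt + n + e + (mt×n) + (mt×e) + (n×e) + (mt×n×e) + ε,

where e is the environment (media × temperature). The quantities of interest
are the variance components and their shares of total phenotypic variance
V_p = Σ σ²; the mitonuclear share σ²_mt×n / V_p measures epistasis at the
population level. Treating genotype effects as random matches the sampling
view of the design: the isolates stand in for a species-wide population.

## Estimation

Two estimators are implemented and cross-checked against each other:

* **EMS (method of moments).** For a balanced a × b × r layout the expected
  mean squares give closed forms: σ̂²_e = MS_E, σ̂²_mt×n = (MS_mt×n − MS_E)/r,
  σ̂²_mt = (MS_mt − MS_mt×n)/(rb), σ̂²_n = (MS_n − MS_mt×n)/(ra). Negative
  solutions are clipped to zero and flagged. Requires balance and r ≥ 2.

* **REML.** Components are constrained non-negative and estimated by
  maximizing the restricted likelihood. Balanced two-factor data use the
  spectral (strata) representation — the likelihood factorizes over the four
  ANOVA strata with eigenvalues λ_mt = σ²_e + rσ²_g + rbσ²_mt, etc. — with
  the ANOVA estimators accepted directly when they solve the stationarity
  equations in the interior, and a bounded quasi-Newton search otherwise.
  Unbalanced data and environment models use the general mixed-model
  restricted likelihood, profiled over σ²_e and evaluated via the Woodbury
  identity (so the per-iteration cost scales with the number of random-effect
  levels, not observations). On balanced interior data the two estimators
  coincide, which the tests assert; the test suite additionally checks both
  engines against R's lme4 on a 15×15×3 fixture (variance components to
  1e-3 relative, identical REML log-likelihood).

* **Term tests.** A component is tested by the REML likelihood ratio of the
  full model against the model lacking the term. Because σ² = 0 is a
  boundary value, the default reference distribution is the 50:50 mixture
  ½χ²₀ + ½χ²₁; plain χ²₁ is available as a compatibility switch since
  published analyses do not always state a correction. Main-effect variances
  may be dropped while the interaction stays — variance-component models
  carry no fixed-effects marginality constraint. Null simulations put the
  boundary-corrected test's rejection rate near 0.04–0.05 at α = 0.05
  (slightly conservative, as expected).

## Per-exchange epistasis and ΔΔ

Each mtDNA exchange between parental strains i and j yields a 2×2 genotype
set (two originals, two cybrids). Epistasis is the interaction term of a
fixed-effect two-way ANOVA on that subset (statsmodels OLS, type-II table;
interaction on 1 numerator df). The effect size is

    ΔΔ = |(y_ij − y_ii) − (y_jj − y_ji)|,

the absolute difference between the two backgrounds' fitness changes upon
receiving the foreign mtDNA — identically the magnitude of the 2×2
interaction contrast, computed from cell means (equal to fitted means in
the saturated model). The signed contrast is retained as the "direction" of
epistasis before the absolute value. Within- vs between-clade exchanges are
compared two ways: significance frequencies by a 2×2 χ² without continuity
correction (switching to Fisher's exact test when an expected count falls
below 5), and effect sizes by a two-sided Mann–Whitney test — chosen because
ΔΔ is non-negative and right-skewed, so a rank test is the robust default
where the comparison method is otherwise unconstrained.

## Coadaptation profiles

For a background tested in the environment matched to its isolation niche
(the niche map is supplied as configuration, not inferred), a one-way ANOVA
runs across the k mitotypes; each original-vs-foreign contrast uses the
pooled within-group error (t on N − k df) at per-comparison α = 0.05 with no
family-wise correction — the convention for this figure-style analysis; a
correction flag exists but defaults off. A background "prefers its own
mtDNA" only when every foreign contrast is a significant advantage. Reported
fitness is normalized to the original genotype (its own entry is 1.0).

## SNP association and diversity

SNPs are the polymorphic columns of a gapped multi-FASTA alignment of
mitochondrial coding sequence (one record per mitotype). Columns containing
any gap are excluded from the SNP table by default (a conservative policy;
gap-as-allele is available). Alleles are unordered factor codes, so
multiallelic sites are tested on k − 1 numerator df. Each SNP is tested by
one-way ANOVA of a per-mitotype phenotype (the genotype mean within the
environment of interest) on allele class; sites lacking two allele classes
with ≥ 2 strains are skipped and excluded from the Bonferroni m. The family
threshold is α/m. With only 15 strains the module emits a low-power warning
rather than altering the test. Nucleotide diversity π is the mean over
sequence pairs of (pairwise differences / pairwise-comparable sites), with
gaps excluded pairwise.

## The synthetic collection

The generator inverts the analysis model: it draws all random effects at
their configured variances, builds the genotype × environment fitness
surface, and renders it as colony arrays. Key choices:

* **Fitness-to-size mapping.** A spot's logistic span is
  exp(f − μ) × reference_span, keeping colony sizes positive and making the
  reference-normalized ratio well defined; at the default total variance
  (0.04 on the log scale) the exp mapping is near-linear and variance shares
  pass through with only second-order distortion.
* **Layout.** 32 × 48 plates; the two outermost rings carry reference-strain
  border colonies (so edge filtering is exercised and removes them), plus
  five fixed interior reference spots per plate (four interior corners and
  the centre) that survive filtering and anchor normalization. Genotype
  spots spill onto additional plates when a plate fills.
* **Replication.** 2 biological replicates per genotype; technical
  replicates drawn uniformly from 2–3 per biological replicate, so the
  balancing step always has work to do.
* **Noise.** Per-spot fitness deviation N(0, σ²_resid) (the biological
  residual), multiplicative log-normal size noise (CV 3%) and additive
  measurement noise (1 size unit) on each reading; 2% of spots flagged as
  circularity failures. 18 time points over 96 h; growth rate
  ~N(0.15, 0.015) h⁻¹, midpoint ~N(36, 4) h.
* **Default variance regime.** Within an environment the defaults put the
  shares at mt 0, nuclear 0.40, mt×n 0.20, residual 0.40 — no marginal
  mtDNA effect, a sizeable mitonuclear interaction — which is the regime the
  factorial design exists to detect.
* **Sequence simulator.** 8.4 kb of coding alignment with 198 biallelic
  segregating sites (minor allele in 2–7 of 15 strains) and a few gapped
  columns, placing π near 0.01 — the level typical of *S. cerevisiae*
  mitochondrial coding sequence.
* **Seeding.** One root seed; per-environment generators derive from spawned
  `SeedSequence` children, so runs are reproducible and environments
  independent.

What the generator does **not** emulate: spatial gradients within plates
(beyond edge effects), pixel-level image artifacts, mtDNA copy-number or
heteroplasmy dynamics, linkage structure among SNPs, and real clade-specific
effect structure (effects are exchangeable draws). Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every artifact of real colony imaging.

## Numerical choices and degenerate inputs

* Logistic fits are bounded least squares over (y_min, span ≥ 0, r ≥ 0,
  t_mid), initialized from the data (half-range crossing for t_mid, 10–90%
  rise time for r); flat series short-circuit to span 0; fits whose midpoint
  leaves the (padded) observation window are marked non-converged and later
  treated as outliers.
* Outlier rule: |span − group median| > 4 × MAD within genotype ×
  environment (groups of < 3 are exempt). Plain MAD at k = 4 corresponds to
  roughly ±2.7σ for normal data; on small groups it overflags mildly, which
  costs replicates but never biases cell means directionally. Trimming does
  shrink the residual variance slightly, so downstream variance shares for
  the genetic terms run a few points above their generating values (the
  mt×n share recovers near 0.23 when 0.20 was simulated) — a property of
  any outlier-trimmed pipeline, visible here because the truth is known.
* Reference normalization uses the plate **median** of reference spans
  (robust to a single aberrant control spot).
* Replicate balancing subsamples without replacement, seeded, after sorting,
  so results are stable across runs and platforms.
* Variance components are clipped at zero (EMS) or constrained (REML);
  clipping events are recorded on the result object.
* All stage outputs are TSV with 6-significant-digit floats and a commented
  header carrying the seed and config digest, so reruns diff byte-for-byte.

## Problem sizes used in the test suite

Simulation-backed checks run at the collection's natural scale (15 × 15
genotypes) with 2–3 replicates and one to four environments per check;
calibration checks use 300–500 simulated tests; the full-pipeline recovery
property averages 20 independent collections. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances.

## Known limitations

* EMS requires exact balance; unbalanced designs must go through REML (the
  error message says so). Satterthwaite-style unbalanced EMS is out of scope.
* The general REML path optimizes over a handful of variance ratios with
  numerical gradients; models with many environment interaction terms and
  large panels are slower (seconds, not milliseconds).
* The per-condition epistasis test roster depends on which exchanges are
  testable in the data at hand; no fixed roster size is assumed.
* With 15 mitotypes, SNP association is underpowered by construction; the
  module warns rather than pretending otherwise.
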