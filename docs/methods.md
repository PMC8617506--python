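# Methods

## Model and procedure

### Anchor normalization

Multiplexed isobaric-label proteomics delivers abundances in runs (plexes)
with arbitrary multiplicative scale. With an anchor genotype present in every
run, each feature's value in a sample is divided by the arithmetic mean of the
anchor replicates of the *same run*:

    x'_is = x_is / mean_{a in anchor(run(s))} x_ia

This removes any per-run multiplicative effect exactly and puts all runs on a
common ratio-to-anchor scale. Features whose anchor mean is missing or zero in
a run are set missing for that whole run: no ratio is fabricated where the
reference was not quantified. No further between-run adjustment (quantile,
variance stabilization) is applied. For count data the package offers
counts-per-million scaling instead (each column scaled to a sum of 10⁶).

Floating-point status of the exactness claims: after normalization the per-run
anchor mean equals 1 and re-normalizing is the identity, both up to the final
IEEE rounding of a mean of ratios (relative error ≲ 10⁻¹⁵; with a single
anchor replicate per run both are bit-exact). An injected per-run factor
cancels bit-exactly when the factor is a power of two and to ≲ 10⁻¹⁵ relative
otherwise.

### Contrasts and classification

Per genotype and tissue, replicate summaries (mean, unbiased variance, count)
are computed over non-missing values; a feature needs at least `min_reps`
(default 2) replicates to enter a contrast. For a hybrid with parents P₁, P₂:

* MP = (mean₁ + mean₂)/2, HP = max(mean₁, mean₂), LP = min(mean₁, mean₂);
* ratios hybrid/MP, hybrid/HP, hybrid/LP are reported on the linear scale
  (so 1.19 means 19% above the reference), with log₂ versions alongside;
* significance comes from Welch's unequal-variance t test on log₂ values:
  hybrid vs the HP parent's replicates, vs the LP parent's replicates, and vs
  *pseudo-midparent* replicates — replicate k of P₁ averaged with replicate k
  of P₂ (pairing by replicate order, truncated to the shorter parent). The
  pseudo-MP device gives the midparent a sampling distribution without
  assuming equal parental variances. In the degenerate zero-variance limit the
  test returns p = 1 for equal means and p = 0 otherwise, so noise-free
  simulations behave sensibly.
* Benjamini–Hochberg q-values are computed within each contrast, and exactly
  one category is assigned by an ordered decision tree:
  `above_HP` (q_HP ≤ α and mean > HP), else `below_LP` (q_LP ≤ α and
  mean < LP), else `between_MP_HP` / `between_LP_MP` (q_MP ≤ α and mean on the
  corresponding side of MP), else `MP`. α defaults to 0.05; there is no
  fold-change floor. Records with missing q-values fall back to `MP` and are
  flagged. Tissues are analyzed separately.

The HP/LP checks precede the MP checks so a feature significant in several
contrasts lands in the strongest category; swapping the parent labels leaves
every record unchanged because HP/LP are order statistics.

Group summaries: the mean percent excess of an annotated group over a baseline
is 100 × (mean ratio − 1); the group-shift test is a two-sided Wilcoxon
signed-rank test of the group's log₂ ratios against zero (minimum group size
3, zeros dropped per the standard procedure). Volcano exports list one row per
feature (log₂ ratio, −log₁₀ q with q clamped at 10⁻³⁰⁰, category, groups),
sorted by q, then |log₂ ratio|, then feature id.

### Panel correlation

Trait heterosis per hybrid is h_j = trait(hybrid)/midparent trait. Expression
heterosis per feature and hybrid is the hybrid/MP ratio from the records. Each
feature's available (eᵢⱼ, h_j) pairs give a sample Pearson r (centered
two-pass computation), with p from the t transform on n − 2 degrees of
freedom. Features with fewer than `min_hybrids` pairs (default 5, to avoid ±1
artifacts under missingness) or zero variance are omitted and counted.
Reciprocal hybrids are independent panel points. Spearman is intentionally not
the default; Pearson matches the ratio-scale definition of the quantities.

Selection and enrichment: threshold sets (r above/below a cutoff) and the
top-⌈fraction·n⌉ set (ties broken by feature id) feed a one-sided
hypergeometric enrichment over the annotation groups intersected with the
universe, BH-corrected across groups. Group correlation densities use a
Gaussian kernel with Silverman's rule per group (bandwidth floored at 0.01 so
degenerate groups remain representable) on a fixed 512-point grid over
[−1.05, 1.05]; kernels are truncated at the grid and each curve is
renormalized to integrate to 1 there, and group values are sorted before
summation so identical groups give bit-identical curves.

The negative control correlates per-genotype *mean expression levels* with
*raw trait values* across genotypes. Under the heterosis model only the
hybrid/MP ratios, not the levels, should track the trait; the package reports
the per-feature r distribution (median, median |r|, IQR) for this check.

### Phenocopy concordance and discordance

A mutant contrast (mutant vs inbred background, same Welch/BH machinery)
yields up/unchanged/down calls at q ≤ α. The hybrid's five categories are
collapsed to above_MP / MP / below_MP and crossed with the mutant calls in a
3×3 contingency table whose cells sum to the shared feature universe; the
discordant cells (above_MP ∧ down, below_MP ∧ up) are reported explicitly, and
the concordance rate is computed over features called in both directions.
Discordance statistics between two heterosis tables (e.g. protein vs
transcript) report sign agreement of the log₂ MP-ratios, the Pearson r between
the two log₂ MP-ratio vectors (symmetric in up/down), category agreement, and
a per-group breakdown when an annotation is supplied.

## Synthetic panels

The generator emulates a two-pool inbred diallel profiled by multiplexed
proteomics:

* feature baseline log₂ abundance μᵢ ~ N(10, 1); parent levels
  2^(μᵢ + aᵢₚ) with genetic effects aᵢₚ ~ N(0, σ_g), σ_g = 0.5 (log₂);
* hybrid true level = MP × f, f = max(1 + δᵢ + βᵢ(h_j − 1) + ε, 0.05),
  ε ~ N(0, σ_c); δᵢ is the dominance deviation on the ratio scale
  (additive 70%: δ = 0; dominant 15%: |δ| ~ U(0.1, 0.4), random sign;
  over/underdominant 7.5% each: |δ| ~ U(0.3, 0.8)); a 100-feature coupled
  group (β = 1, σ_c = 0.05) stands in for the plastid-ribosome biomarkers and
  is annotated half nuclear-, half plastid-encoded;
* replicate observations multiply the true level by 2^N(0, σ_r) (σ_r = 0.15,
  the replicate scatter of reporter-ion data) and a per-run effect
  2^N(0, σ_b) (σ_b = 0.3);
* the design is a complete block: replicate k of every genotype sits in run k
  (4 replicates/runs by default), and the anchor inbred contributes 4
  reference replicates to every run, mirroring how the anchor is replicated
  within each plex so its per-run mean is stable;
* inbred heights ~ N(150, 10) cm; hybrid height = midparent height × h_j with
  h_j ~ U(1.2, 1.8), a plausible spread of maize plant-height heterosis;
* structure (genetics, heights), noise (coupling, replicates) and run effects
  come from three separate child streams of the seed, so run effects can be
  switched off without disturbing any other draw; all outputs are
  bit-reproducible from the seed, and the emitted matrix factorizes exactly
  into the recorded truth (levels × replicate noise × run effect).

The mutant simulator phenocopies a reference hybrid (by default the most
heterotic): every feature nonadditive there (δ ≠ 0 or β ≠ 0) gets a
mutant/background true ratio equal to the hybrid's realized f with probability
π and 1/f otherwise; additive features are unchanged. The RIL module draws
fully inbred recombinant lines with independent loci from two founders;
backcrosses to a founder are heterozygous exactly where the RIL carries the
other founder's allele, giving the textbook expectation of 50% of the F1's
heterozygosity.

What the generator does *not* emulate: peptide-level roll-up, missingness
mechanisms that depend on abundance (missingness only arises downstream of
user data), isotope-impurity interference, correlated features (complex
stoichiometry), linkage between loci, or genotype-by-environment effects.
Passing tests therefore certify the statistical pipeline, not instrument-level
behavior on real spectra.

Two operating characteristics of the default conditions are worth knowing.
First, with σ_r = 0.15 and 4 replicates, the Welch/BH classifier has ~30%
power at a ratio deviation of 1.25 above MP (log₂ = 0.32, df ≈ 6, BH threshold
near p ≈ 0.012 at these signal densities), so recovery of above-MP features
with δ ≥ 0.25 plateaus near 70–75% (below-MP recovery is higher, ~90%, because
the same |δ| is a larger log₂ change downward). Second, trait-coupled
features' *levels* retain a residual association with raw height across a
panel mixing inbreds and hybrids — the coupling factor f is part of the level —
so the negative control's "levels don't track the trait" statement applies to
the feature population (median |r| ≈ 0.2 at defaults), not to every coupled
feature individually.

## Tunable parameters

| parameter | default | units / scale | role |
|---|---|---|---|
| `alpha` | 0.05 | — | BH q-value threshold per contrast |
| `min_reps` | 2 | replicates | minimum replicates per genotype per feature |
| `min_hybrids` | 5 | hybrids | minimum pairs for a panel correlation |
| `sigma_r` | 0.15 | log₂ | replicate noise |
| `sigma_b` | 0.3 | log₂ | per-run multiplicative effect |
| `sigma_g` | 0.5 | log₂ | parental genetic effect |
| `sigma_c` | 0.05 | ratio | coupling noise on the heterosis factor |
| `coupled_size`, `coupling_beta` | 100, 1.0 | features, ratio/ratio | trait-coupled group |
| `replicates` | 4 | — | biological replicates per genotype (one per run) |
| `anchor_reps_per_run` | 4 | — | anchor reference replicates per run |
| `h_range` | (1.2, 1.8) | ratio | plant-height heterosis spread |
| `f_floor` | 0.05 | ratio | floor keeping expression positive |

## Numerical conventions and edge cases

* TSV, UTF-8, header row mandatory, `NA` the only missing marker (empty
  abundance cells also read as missing); writers and readers round-trip.
* Genotype labels are case-sensitive opaque strings; A×B and B×A are distinct.
* Unknown annotation labels are retained under `other` (with a warning), so
  enrichment universes never shrink silently.
* Tests run on log₂ values; values ≤ 0 are treated as missing for testing.
* Ties in HP/LP selection (equal parent means) are harmless: both parents give
  the same test, and hp = lp = mp.
* Pearson r is clipped to [−1, 1] after the centered computation; |r| = 1
  maps to p = 0.
* `top_fraction` uses a ceiling and lexicographic tie-break, making selections
  deterministic across platforms.
* Seeds: a single integer seed drives three named child streams
  (structure / noise / run); regenerating with a different σ_b changes only
  the run-effect magnitudes, which is what makes the run-effect cancellation
  check exact.

## Known limitations

* No moderated-variance (limma-style) testing and no imputation; features
  missing a parent are dropped from that hybrid's contrast (counts logged).
* The MP contrast's pseudo-midparent pairing is one defensible choice among
  several; it is stated openly rather than estimated from data.
* Correlations use linear-scale heterosis ratios; a log-scale option would
  change little at these effect sizes but is not currently exposed.
* The concordance estimate conditions on features called in both the hybrid
  and mutant analyses; with very low power it would be estimated from few
  features (the default conditions call several hundred).
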