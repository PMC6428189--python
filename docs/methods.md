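# Methods

This note documents the statistical model behind `groupsim`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical edge cases.

## Similarity indices

**Cohen's d.** `cohen_d(a, b)` returns (M_A − M_B)/s. The default
denominator is the pooled SD with n−1 weights (the Cohen convention); an
`average_sd` option uses the unweighted mean of the two SDs, which is how
the index is often explained verbally. The two coincide for equal group
sizes and equal variances; both are exposed because consumers of published
values may need either. The sign follows the caller's argument order.

**PCR.** For two normal densities with common variance separated by d
standard deviations, the overlapping coefficient has the closed form
OVL = 2Φ(−|d|/2), so `pcr_from_d(d) = 100·2Φ(−|d|/2)`. It is an even,
strictly decreasing function of |d| with PCR(0) = 100 and limit 0. The
normality and equal-variance assumptions are *not* checked: PCR is always
computed from d, whatever the observed shapes, and PCS serves as its
distribution-free companion. The test suite verifies the closed form
against numerical quadrature of ∫ min(φ(x), φ(x−d)) dx to 1e−6 on the
proportion scale.

**PCS.** The empirical analogue. Both samples are binned on a common grid
of `scale.n_categories` equal-width bins spanning [minimum, maximum]
(overridable via `n_bins`), and PCS = 100·Σₖ min(f_A(k), f_B(k)) over the
per-bin *relative* frequencies. Relative frequencies make the index
invariant to replicating either sample (sample-size control); the common
grid standardizes across response-scale lengths; and the index equals
100·(1 − TV), TV the total variation distance between the binned
distributions. Composite (non-integer) scores are binned on the same grid.
This is a reconstruction of the index from its stated properties — the
binning convention (equal-width bins, right-closed last bin, as in
`numpy.histogram`) is ours, and tie/grid conventions for unusual scales may
differ from other implementations.

**AE.** 100·|median_A − median_B|/(max − min); equivalently the absolute
difference of the two median POMP scores. The absolute value is taken
because the index is reported unsigned everywhere we are aware of; the
median is the plain sample median (mean of the central order statistics
for even n), with no interpolation for ties and no survey weighting.

**Probability of superiority.** P(X_A > X_B) + ½P(X_A = X_B), computed
exactly over all n_A·n_B pairs via sorted search; identical to the
Mann–Whitney U statistic divided by n_A·n_B.

## Inference

**Welch's t** uses the standard unequal-variance statistic with
Welch–Satterthwaite fractional df and a two-sided p. Only the two-sided
test is offered.

**Bootstrap CIs** (`bootstrap_ci`) use the percentile method with
stratified resampling (with replacement, within each group),
default n_boot = 2,000 and level 0.95. The percentile method was chosen as
the least-assumption default; 2,000 replicates give stable 95% endpoints.
Two refinements:

- The group order is canonicalized by label before resampling, so the
  interval is invariant to argument order (all three supported statistics
  are symmetric).
- The interval is widened, if necessary, to bracket the plug-in point
  estimate. For PCS the resampling noise biases replicates downward (the
  overlap of two *resampled* histograms is stochastically smaller than the
  overlap of the originals), so a raw percentile interval can exclude the
  point estimate; bracketing restores the invariant lower ≤ point ≤ upper
  without materially changing coverage. For PCR the bootstrap coverage at
  nominal .95 measures ≈ .96 in the suite's 500-study simulation
  (n = 200/group).

Replicates on which a statistic is undefined (zero pooled variance for
PCR) are redrawn, with a capped number of passes, after which a
degenerate-variance error is raised — so constant samples fail loudly
rather than silently.

All resampling is governed by a single integer seed; there is no global
RNG state. Sub-seeds for multiple CIs inside one record are derived
deterministically from the record seed.

**Verdict rule** (`classify_similarity`): strict inequalities, so an exact
50 on either index yields `undetermined`. The rule is exhaustive on
[0,100]² by construction.

## The pairwise survey engine

`run_pairwise` compares every unordered pair of groups within each
category on every configured variable. Conventions:

- **Composites** are the mean of a respondent's available items after
  reflecting reverse-coded items about the scale midpoint
  (min + max − x); a respondent missing all items gets a missing
  composite. Cronbach's α is computed on complete cases and reported in
  the run provenance. Item-to-variable assignment is a config input, not
  inferred.
- **Pairwise deletion**: missingness on variable v removes a respondent
  only from v's comparisons.
- **Eligibility**: a group enters a variable's comparisons when it retains
  at least `min_group_size` responses (default 30 — large enough for the
  normal-theory PCR to be meaningful, small enough to keep realistic
  subgroups; configurable). A category with fewer than two eligible groups
  on every variable is skipped with a logged warning, not an error.
- **Ordering**: pairs are ordered lexicographically by group label, which
  fixes the sign of d; PCR/PCS/AE and the verdict are order-free. Results
  are invariant to the row order of the input table.
- **Aggregation** (`summarize_category`): pairs are averaged within each
  variable first, then the per-variable means are summarized across
  variables. This matches per-variable reporting practice; pooling all
  pairs directly would weight variables by their pair counts instead.
  The "extreme pair" per variable is the least similar one (minimum for
  PCR/PCS, maximum magnitude for AE and d).
- **Bootstrap CIs** for the full table are off by default (a 42,000-record
  run with 2,000 replicates per record is an overnight job, not an
  interactive one) and enabled via the config's `bootstrap` block; single
  comparisons get CIs through `compare_groups`/the `compare` subcommand.

Each pair needs only per-group summaries (n, mean, SD, median, binned
relative frequencies), so blocks are computed vectorized over all pairs;
the six-category, 22-variable benchmark layout (1,918 pairs per variable,
42,196 comparison records, 168,784 statistic-level results) runs in a few
seconds. Pairs with zero pooled variance get NaN d/PCR and a logged count.

## Synthetic data

`generate_pair` draws latent scores from N(μ ± d·σ/2, σ²) — so the
standardized difference between the group means is exactly d — and either
clips them to the scale bounds (continuous mode) or rounds them to the
nearest admissible category and clips (discretized mode). The continuous
defaults mirror a published survey-simulation setting: 1,500 respondents
per group, σ = 0.8, overall mean 3. Discretization is the extension needed
to exercise PCS and AE on realistic ordinal data; rounding to k ≥ 6
categories inflates the SD slightly and shrinks the realized d by a few
percent — bounded to |bias| ≤ 0.1 at n = 10,000 in the test battery.

`generate_survey` builds a full respondent table: balanced random
assignment to each category's levels (independently per category, as when
demographic attributes cross-cut), one latent normal per variable with
per-(category, variable) mean shifts spread linearly across the category's
levels so the extreme levels differ by the requested d, optional shared
latent + item noise for multi-item composites, optional MCAR missingness,
and a matching declarative config. `study1_shape` is the six-category
(60 countries, 7 denominations, 2 genders, 9 education levels, 10 income
bands, 10 age cohorts), 22-variable layout with a few injected effects,
at 150 respondents per country (9,000 total) — a deliberately scaled-down
group size relative to the ~1,400-per-country surveys it is shaped after;
the pair-count identities are size-independent.

What the generator does **not** emulate: item-level factor structure,
ordinal response styles (acquiescence, extreme responding), survey
weights, clustered sampling, correlated category memberships, or
missingness that depends on the response. Tests passing on these fixtures
therefore validate the *computational* claims (closed forms, invariances,
calibration under the stated model), not the substantive survey findings
obtainable only from real data.

## Visualization

`plot_pair` implements both graphical rhetorics. The similarity modes draw
the two distributions superimposed (normal densities from each group's
mean/SD with the pointwise-minimum overlap shaded; relative-frequency
histograms on a common grid; Silverman-bandwidth KDEs). The difference
modes draw group-mean barplots with error bars (t-based 95% CIs by
default — the conservative choice, since SE bars make differences look
larger). The *restricted* barplot truncates the y-axis to
[min mean − 3·max SE, max mean + 3·max SE], snapped outward to scale
ticks and clamped to the scale bounds — a deterministic rule that
reproduces the visual exaggeration truncated axes cause; the
*unrestricted* barplot spans exactly the full scale. A degenerate SD in
the normal mode falls back to histograms with a logged warning.
`plot_radar` closes one polygon per group over ≥ 3 variable axes with the
radial range equal to the full scale range (the radial minimum is the
scale minimum, not zero). All figure-producing functions return the
matplotlib Figure before writing, so tests assert on artists rather than
pixels.

## Numerical choices and limitations

- Indices are computed at full precision; rounding to integer percent
  (half away from zero) happens only in the CLI/report layer.
- PCR assumes normal, equal-variance populations; it is reported for any
  data, by design, with PCS as the robustness check.
- AE requires finite scale bounds; it is undefined for unbounded
  responses.
- The engine applies no multiple-testing correction across the pairwise
  table; the indices are descriptive.
- Bootstrap intervals are percentile-based; no BCa correction is applied.
- `min_group_size` guards eligibility, and `compare_groups` logs (but does
  not fail on) samples below it.
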