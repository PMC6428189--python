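# groupsim

Effect sizes that quantify how much two groups of people **share**, not just
how they differ — for bounded-scale (Likert-type) survey data.

Most group comparisons in the social and health sciences are reported as a
mean difference: a t test, a p value, a Cohen's *d*. But even a "large"
*d* = 0.80 corresponds to two response distributions that overlap by 69%.
`groupsim` implements a small family of similarity indices that make this
overlap explicit, together with the inferential and graphical machinery to
use them in practice:

- **PCR — percentage of common responses.** For two equal-variance normal
  distributions separated by *d* standard deviations, the overlapping
  coefficient is OVL = 2Φ(−|d|/2) (Φ the standard normal CDF); PCR = 100·OVL.
  A medium effect of *d* = 0.50 gives PCR = 80; *d* = 0.20 gives 92.
- **PCS — percentage of common scores.** A nonparametric companion: both
  samples are binned on the common grid of the scale's response categories,
  and PCS = 100·Σₖ min(f_A(k), f_B(k)) over the relative frequencies — the
  shared mass of the two empirical distributions (the complement of their
  total variation distance). Robust to non-normality; controls for unequal
  group sizes by construction.
- **AE — absolute effect.** The median difference as a percentage of the
  maximum possible difference on the scale:
  AE = 100·|median_A − median_B| / (scale max − scale min), i.e. the
  difference of the two groups' median POMP (percentage of maximum possible
  score) values. A median difference of 0.5 on a 1–6 scale gives AE = 10.
  Unlike *d* or PCR, AE is independent of the dispersion and tells you
  whether the groups sit on the same side of the scale.
- **Decision taxonomy.** PCR > 50 *and* AE < 50 ⇒ the groups are more
  similar than different; PCR < 50 *and* AE > 50 ⇒ more different than
  similar; anything else (including an exact 50) is undetermined.

Around these sit Welch's *t* (with Satterthwaite df), the probability of
superiority, seeded percentile-bootstrap confidence intervals for
PCR/PCS/AE, an all-pairs comparison engine for multi-category surveys
(compare every pair of countries, education levels, age cohorts, ... on
every variable, with composite-scale construction and Cronbach's α), the
contrasting display modes (superimposed normal densities / histograms /
KDE overlays vs. restricted- and full-axis barplots, radar charts), and a
fully seeded synthetic Likert-data generator.

## Worked example

Simulate two groups of 1,500 respondents on a 6-point scale with a target
standardized mean difference of *d* = 0.5, then compare them:

```python
import groupsim as gs

a, b = gs.generate_pair(gs.SynthSpec(
    scale=gs.ScaleSpec(1, 6, 6), n_a=1500, n_b=1500,
    target_d=0.5, latent_sd=1.0, seed=42,
))
result = gs.compare_groups(a, b, ci_statistics=("pcr", "ae"), seed=1)
```

or, equivalently, from the shell (`demo.csv` has columns `group,score`):

```text
$ groupsim --seed 1 compare demo.csv --group-col group --group-a A --group-b B \
    --variable score --scale-min 1 --scale-max 6 --categories 6
Comparison: A vs B on 'score' (scale 1-6)
  n       A=1500  B=1500
  M       A=3.73  B=3.21
  SD      A=1.03  B=1.05
  median  A=4.00  B=3.00
  d = 0.50 (pooled)
  PCR = 80, 95% CI [78, 83]
  PCS = 79
  AE = 20, 95% CI [20, 20]
  Probability of superiority = 0.63
  Welch t(2996.58) = 13.58, p = 8.29e-41
  Verdict: more similar than different
```

Reading it: the Welch test is overwhelmingly "significant"
(p ≈ 10⁻⁴¹), yet 80% of the two groups' responses overlap (PCR, with the
nonparametric PCS agreeing at 79), and the medians differ by only a fifth
of the scale range (AE = 20). By the PCR/AE rule the groups are more
similar than different — the similarity information the difference
statistics alone would hide.

The other subcommands: `groupsim pairwise data.csv config.yaml --out-dir out/`
runs every within-category group pair on every configured variable and
writes a long CSV plus per-category JSON summaries; `groupsim plot`
renders any of the display modes; `groupsim simulate` writes seeded
synthetic fixtures. Every run that produces files writes a `manifest.json`
(inputs, digests, seed, package version) next to them.

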