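# Methods

This note records the model behind `devgraph`, the defaults it ships with,
why they were chosen, and what the validation suite does and does not show.

## The deviation-value model

The diagnostic treats each indicator independently.  For indicator *j* with
raw values *x₍ᵢⱼ₎* over the countries *i* that report it:

    y = ((x + c)^λ − 1) / λ        λ ≠ 0
    y = ln(x + c)                  λ = 0
    T = 50 + 10 · (y − ȳ) / s      (s = sample SD, n − 1 denominator)

so that each indicator's scores have mean 50 and SD 10 across reporting
countries, and 10 points correspond to one cross-country SD.  A published
formulation of this score divides by (SD × 10) rather than multiplying the
standardized residual by 10; that parenthesization contradicts its own
stated reading (one SD above the mean ↦ 60) and the standard T-score
definition, so the standard form above is implemented.

Indicators whose polarity is *lower-desirable* are reflected about 50
(`T ↦ 100 − T`) after scoring.  Reflection is equivalent to negating the raw
variable before standardization, is an involution, and preserves the
mean-50 / SD-10 calibration, so "right of 50" always reads as favourable.
*Neutral* polarity (total population) is standardized and plotted but is
excluded from strength/weakness readings.

Assumptions worth stating:

- **Relative, not absolute.**  Scores are positions within the reporting
  set.  Removing or adding a country with data changes every other
  country's score on that indicator; missing data in some countries
  therefore shifts the meaning of everyone else's scores.  The suite pins
  this down exactly: withholding one country's value reproduces the scores
  of the table without that country.
- **Per-indicator independence.**  No attempt is made to model or exploit
  correlation between indicators; the deviation graph is deliberately a
  panel of univariate positions, not a composite index.
- **Global reference.**  λ estimation and standardization always use all
  countries with data, never an income subgroup; income classes are a
  display grouping applied afterwards.  (Scoring within a subgroup is
  possible by scoring a stratified table explicitly, but it changes the
  meaning of 50 and is not the default.)

## Box–Cox estimation

λ is estimated per indicator by maximizing the profile log-likelihood
(scipy's `boxcox_llf`) on the grid −3…3 in steps of 0.05, refined by
golden-section search between the best grid point's neighbours (bounded
refinement when the maximum lands on a grid edge).  The range covers every
transform used in practice (inverse-cube to cube); fitted λ and shift are
exportable to CSV so a run can be audited and frozen.

Because prevalences and mortality rates are legitimately zero, a shift *c*
is applied before transforming: zero if all values are positive, otherwise
`−min + ε` with ε = 1% of the observed range (0.5 if the range is
degenerate).  The shift is data-driven and recorded in the fit; joint
two-parameter (λ, c) maximum likelihood is out of scope, as is the
Yeo–Johnson family.

No post-transform normality gate is applied: the transform is the best
monotone power normalization available and the pipeline's calibration
(mean 50 / SD 10) holds regardless of residual non-normality; skewness of
the result is visible in the modality report instead.

A numerical note: evaluating `((x^λ − 1)/λ)` naively within ~1e−12 of λ = 0
cancels catastrophically; the implementation routes through scipy's stable
Box–Cox kernel, and the test oracle guards its own grid the same way.

With a weak-signal indicator the λ maximum-likelihood estimate is itself
noisy: for Normal(50, 5) data (coefficient of variation 0.1) the sampling
SD of λ̂ at n = 194 is about 0.45, which is a property of the likelihood,
not of the optimizer.  Recovery tests therefore check the mean λ̂ over a
fixed block of 20 seeds (standard error ≈ 0.1) as well as exact agreement
of every single estimate with a brute-force grid scan.

## Ceiling indicators and the percentile method

Variables compressed against an upper bound (primary-school participation,
adult literacy, vitamin A supplementation — routinely ≥ 99%) carry most of
their information in rank, not distance.  They are scored by
`T = 50 + 10·Φ⁻¹(p)` with `p = (rank − ½)/n` and midranks for ties.  The
`−½` plotting position avoids the infinite quantiles at p ∈ {0, 1}; the
alternative conventions `rank/(n+1)` and the empirical CDF differ only in
the extreme tails and the choice is recorded in the export for audit.

Which indicators use the method is governed by the registry's `ceiling`
flag.  A heuristic (≥ 25% of values within 1% of the attainable maximum,
taken as 100 for percentage-like variables) *warns* when an unflagged
indicator looks ceiling-shaped, but never switches silently — scoring
method is a declaration, not a guess.

## Distribution-shape classification

The four-label taxonomy (`normal`, `distorted`, `bimodal`, `trimodal`)
is operationalized as parametric model selection: fit a normal (2 df), a
skew-normal (3 df), and tied-variance Gaussian mixtures with 2 and 3
components (4 and 6 df) to the standardized values, select by AIC, and
count the modes of the *selected fitted density* (a prominence gate of 5%
of the peak density suppresses shoulder artefacts; overlapping components
can merge into one mode, which is exactly what distinguishes a skewed
unimodal fit from a genuine two-cluster fit).  One mode with |skewness| >
0.8 is `distorted`, otherwise `normal`; more than three modes collapse to
`trimodal` to stay within the taxonomy.

A KDE mode count with Silverman bandwidth was evaluated first and
rejected: with mixture modes three component-SDs apart at n ≈ 194 — the
separation the synthetic generator produces — no fixed bandwidth
multiplier/prominence pair resolves the trimodal family without
fabricating modes on Gaussian data (the best joint setting recovered under
half of trimodal replicates).  The mixture-based classifier recovers all
four generative families in ≥ 90% of seeded replicates at those
separations.  Its thresholds (prominence, skew gate, component cap,
minimum n) are exposed in `ModalityConfig` because they are this package's
convention, not a community standard; vectors with fewer than 20 values are
labelled `normal` with a `low_confidence` flag rather than classified.
Standardizing (and sign-fixing) input internally makes labels exactly
invariant under affine rescaling.  Formal significance testing of
multimodality (dip test) is intentionally out of scope — the labels are a
reproducible description, not an inference.

## Banding and profiles

Verbal bands are a deterministic function of the score:
very_low < 35 ≤ low < 45 ≤ middle ≤ 55 < high < 72 ≤ very_high.
The cutpoints were reverse-engineered from the way such graphs are read in
practice (scores around 25 called "very low", 36–43 "low", 50–53 "middle",
58–71 "high", 73+ "very high"); because that verbal convention is fuzzy at
the margins the cutpoints are a parameter, not a constant.

Profiles store oriented values but carry `raw_direction_value`
(= 100 − value for reflected indicators) so that a narration like "raised
blood pressure very high at 75" remains recoverable next to its oriented
score of 25.  Rendered graphs always write a sidecar CSV with the exact
plotted numbers; tests assert on the CSV, never on pixels.

## Synthetic data: what it shows and what it cannot

The generator exists to prove pipeline properties under every distribution
shape the method claims to handle, without any external download.  Defaults
are study-shaped: 194 countries in income classes of 55/57/48/34, one
model per packaged-registry indicator.  Families:

- `gaussian` N(μ, σ);
- `skewed`: gamma(shape 2; skewness ≈ 1.4) affine-mapped to the target
  mean/SD;
- `bimodal` / `trimodal`: equal-weight Gaussian mixtures with adjacent
  means 3 component-SDs apart — separated enough to be real structure,
  close enough to be a non-trivial detection problem;
- `ceiling`: 100·Beta(1 + c, 1/(1 + c)), c = 2 by default, putting roughly
  a third of countries within 1% of 100; c → 0 degenerates to uniform.

Missingness is completely at random, 3% by default, 15% for education/
WASH/tobacco indicators and 60% for the two notoriously under-reported
ones (vitamin A supplementation, WASH-attributable diarrhoea deaths),
mirroring the uneven reporting of the real sources.

What passing tests on this generator show: the calibration, orientation,
conservation and shape-recovery properties hold under realistic marginal
shapes and missingness.  What they cannot show: behaviour under correlated
indicators, non-random missingness (countries that fail to report are not
a random subset), reporting-year mismatch between sources, or real-world
measurement error.  Conclusions about any real country require the real
tables.

## Validation sizes

The default suite and the acceptance script use n = 194 vectors, 20-seed
blocks for calibration/recovery properties and 100 seeded replicates per
family for shape recovery — sizes chosen to estimate each property's rate
with useful precision while keeping a full run in the order of a minute.

## Known limitations

- λ is frozen per run; longitudinal comparisons would need a policy for
  freezing or re-estimating λ across years (not implemented).
- The ceiling heuristic assumes an attainable maximum of 100 for
  percentage-like variables; indicators with other natural ceilings need
  the registry flag.
- Band cutpoints and modality thresholds are conventions; alternative
  choices change labels, not scores.
- The packaged registry is a best-effort template of a commonly used
  54-indicator set, not an authoritative list.
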