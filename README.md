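# devgraph

Country-level **deviation-graph** diagnostic for the double burden of
malnutrition.

Public-health agencies publish dozens of nutrition-related indicators per
country — stunting and wasting rates, breastfeeding coverage, water and
sanitation access, adult obesity, NCD mortality.  Comparing a country against
its economic peers across all of them at once is hard because every indicator
lives on its own scale and few are normally distributed across countries.
`devgraph` turns a countries × indicators table into **deviation values**
(T-scores): for each indicator, every country gets a score with cross-country
mean 50 and SD 10, oriented so that *higher is always more desirable*.  A
country's scores, drawn as one bar chart grouped by life stage (gestation →
infancy → environment → adult lifestyle → adult biology → cause of death),
form its deviation graph: strengths stick out to the right of 50, weaknesses
to the left.

It is written for nutrition epidemiologists and global-health analysts who
want a reproducible version of this diagnostic: the scoring pipeline, the
supporting distribution diagnostics, and a generator of statistically
realistic synthetic tables for validation.

## Method

For each indicator with values `x` over the countries reporting it:

1. **Box–Cox normalization.**  `y = ((x + c)^λ − 1)/λ` (`ln(x + c)` at
   `λ = 0`), with shift `c` chosen so all values are positive and `λ`
   estimated per indicator by profile maximum likelihood (grid −3…3 step
   0.05, golden-section refinement).  Cross-country indicator distributions
   are routinely skewed or multimodal; the power transform makes the
   subsequent standardization meaningful.
2. **T-score.**  `T = 50 + 10·(y − ȳ)/s`, with the sample SD (n−1).  By
   construction each indicator has mean 50 and SD 10 over the countries
   with data; 10 points = 1 SD.
3. **Ceiling indicators** (near-100% literacy, school participation,
   supplementation coverage) are piled against their upper bound, so mean/SD
   are uninformative.  They are scored by rank instead: percentile
   `p = (rank − ½)/n` (midranks for ties), then `T = 50 + 10·Φ⁻¹(p)`.
4. **Orientation.**  Indicators where a lower raw value is better (stunting,
   smoking, blood pressure) are reflected about 50 (`T ↦ 100 − T`), so every
   profile reads "right of 50 = good".
5. **Shape diagnostics.**  Each indicator's score distribution is classified
   as `normal`, `distorted` (skewed unimodal), `bimodal` or `trimodal` by
   AIC model selection among a normal, a skew-normal and 2–3 component
   Gaussian mixtures, counting the modes of the winning density.
6. **Profiles and groups.**  Scores are grouped by World Bank income class
   (high / upper-middle / lower-middle / low) for peer comparison, banded
   verbally (very_low < 35 ≤ low < 45 ≤ middle ≤ 55 < high < 72 ≤
   very_high), and rendered per country as a deviation graph with a sidecar
   CSV carrying the exact plotted numbers.

Scores are *relative positions*: adding or removing a country with data
shifts everyone else's scores on that indicator, so profiles must always be
read against the stated reference set.

## Worked example

No real agency table ships with the package (those sources are external and
unversioned); the built-in generator produces a study-shaped stand-in —
194 countries in income classes of 55/57/48/34, 54 indicators with gaussian,
skewed, bimodal, trimodal and ceiling-type marginals, and realistic
missingness:

```python
import devgraph as dg

table = dg.generate_table(dg.default_config(seed=42))
matrix = dg.score_table(table)

matrix.method.value_counts().to_dict()
# {'boxcox_tscore': 51, 'percentile': 3}

fit = matrix.fits["stunting_u5"]
print(f"lambda={fit.lmbda:.3f} shift={fit.shift:.3f} n={fit.n}")
# lambda=0.934 shift=1.320 n=185

prof = dg.build_profile(matrix, table, "SYN150")
for e in prof.entries[:5]:
    print(f"{e.indicator:28s} {e.life_stage:15s} {e.value:6.1f}  {e.band}")
# total_population             socioeconomic     52.4  middle
# gni_per_capita               socioeconomic      nan  None
# preprimary_enrollment_m     socioeconomic     37.7  low
# preprimary_enrollment_f     socioeconomic     47.4  middle
# primary_enrollment           socioeconomic     50.8  middle

dg.flag_extremes(prof)[:3]
# [('raised_bp_m', 'weakness'), ('insufficient_activity_m', 'weakness'),
#  ('tobacco_smoking_f', 'strength')]
```

Reading: this synthetic lower-middle-income country sits near the middle on
population and primary enrollment, is one-plus SD below its reference on
preprimary enrollment (37.7, "low"), has a missing GNI value carried as
missing, and — after orientation — its largest weakness is raised blood
pressure in men.  The shape diagnostics recover the generator's families:

```python
rep = dg.classify_table(matrix)
rep["label"].value_counts().to_dict()
# {'normal': 40, 'bimodal': 12, 'trimodal': 2}
rep.loc["under5_mortality", "label"]
# 'trimodal'
```

The same workflow is available from the shell:

```bash
devgraph generate --out-table table.csv --out-registry registry.csv --seed 42
devgraph score    --table table.csv --registry registry.csv --out scores.csv
devgraph profile  --table table.csv --registry registry.csv \
                  --country SYN150 --out-dir report/
```

## Layout

- `src/devgraph/indicators.py` — registry and table I/O, income stratification
- `src/devgraph/transform.py` — Box–Cox fitting and application
- `src/devgraph/deviation.py` — T-scores, percentile scores, orientation, table scoring
- `src/devgraph/modality.py` — distribution-shape classification
- `src/devgraph/profile.py` — country profiles, banding, deviation graphs, group summaries
- `src/devgraph/synthetic.py` — study-shaped synthetic table generator
- `src/devgraph/data/example_registry.csv` — packaged 54-indicator example registry
- `docs/methods.md` — modelling choices, defaults and limitations
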