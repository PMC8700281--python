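# Methods

## The model chain

The package asks a single quantitative question: how much tumor-derived
DNA does a routine blood draw actually capture, and what does that imply
for ctDNA-based early cancer screening? The chain has four deterministic
links and one stochastic one.

**Geometry.** A tumor is idealised as a spherical nodule. A diameter
*d* (mm) maps to volume *V* = (π/6)(*d*/10)³ cm³; tissue density is
1 g/cm³ (so weight in mg is 1000·*V*) and cell density 10⁹ cells/cm³.
These are the standard rules of thumb for solid tumors: 1 cm³ ≈ 1 g ≈
10⁹ cells ≈ 1.2 cm diameter.

**Shedding.** The mutant allele fraction (MAF) of plasma cfDNA is taken
proportional to tumor volume, MAF = *s*·*V* with *s* = 10⁻⁴ per cm³ by
default — the anchor "1 cm³ → MAF 1:10,000" (equivalently 10 cm³ →
1:1000). Whether shedding is truly linear in volume is an open empirical
question; *s* is a plain configurable constant (`ShedModel.maf_per_cm3`)
and nothing downstream assumes more than monotonicity.

**Genome equivalents.** Plasma cfDNA concentration *c* (default
5 ng/mL; the healthy range is 1–10) divided by the mass of one haploid
genome gives genome equivalents per mL. With a genome mass of 2 × 10¹²
Da and Avogadro's constant 6.02214 × 10²³ Da/g, one genome weighs
3.32 × 10⁻³ ng, so 5 ng/mL ≈ 1505.5 genomes/mL — the familiar "1500
genomes per mL" at two significant figures. A 10 mL blood draw at
plasma fraction 0.4 yields 4 mL of plasma and ≈6022 genome equivalents.

Two conventions coexist deliberately. The exact concentration-derived
total (6022.14 for the default draw) is the default everywhere. The
rounded constant `PAPER_GENOMES_PER_DRAW = 6000` is the convention under
which the reference table's genome-count column (6, 0.6, 0.3, 0.15,
"<0.1") is bit-reproducible, and every detection function accepts it via
the `total_genomes` argument. The two differ by 0.4 %, which never moves
a headline number: both give a MAF decade limit of 0.01 % and a minimum
detectable diameter of 14.7 mm at 0.1 mm rounding.

**Sampling.** Tumor genome copies are a tiny fraction of a large
molecule pool, so the number captured by a draw is modelled as Poisson
with mean λ = (total genome equivalents) × MAF. Poisson rather than
binomial because the per-molecule inclusion probability is minute while
the pool is huge; the distinction is numerically irrelevant here.

## Detection criteria and limits

`DetectionCriterion` makes "detected" explicit:

* **expected-value mode (default, k = 1)** — a draw is informative iff
  λ ≥ k. This is the argument "a draw expected to contain less than one
  complete cancer genome cannot support a diagnosis", made operational.
* **probabilistic mode** — informative iff P(X ≥ k) ≥ *p* under
  X ~ Poisson(λ). The default threshold 0.5 asks for a coin-flip chance
  of at least one molecule in the tube.

Inverting the chain gives the limits. In expected-value mode both are
closed-form: minimum detectable volume k/(G·s) and MAF limit k/G for a
draw of G genome equivalents. With G = 6000 and k = 1: MAF limit
1.67 × 10⁻⁴, minimum volume 1.67 cm³, minimum diameter 14.7 mm — inside
the 10–15 mm band where imaging already competes. The canonical "0.01 %
detection limit" is the largest power-of-ten MAF strictly below the
exact limit (`maf_decade_floor`), because the decade, not the third
significant figure, is the communicable number. In probabilistic mode
the inversion is a bisection on volume to 10⁻⁶ cm³ (p_detect is
continuous and strictly increasing in λ, so plain bisection is exact to
tolerance and deterministic); an unsatisfiable criterion — e.g. a
probability threshold unreachable even at the MAF cap of 1 — raises
`DetectionUnsatisfiableError` rather than returning a sentinel.

## Screening statistics

`ppv`/`npv`/`expected_confusion` are ordinary Bayes arithmetic on
(sensitivity, specificity, prevalence), with empty denominators raised
as `UndefinedMetricError`. The reference scenario `grail-ccga3`
packages the stage-stratified sensitivities of a large published
case-control validation of a methylation-based multi-cancer test
(Stage I 17 %, Stage II 40 %, Stages I-II 28 %, Stages III-VI 84 %,
overall 52 %, specificity 99.5 %) as constants — external trial
results, never recomputed.

Display convention: integer percent at ≥10 %, two significant figures
below, which renders the benchmark scenario (10 % sensitivity, 99.5 %
specificity, 1 % prevalence) as PPV "17%". At 0.1 % prevalence exact
Bayes gives 1.96 %; the often-quoted 1.7 % is a linear scaling of 17 %
and is not what this package reports — the exact value is.

## The synthetic cohort

`generate_cohort` emulates one round of population screening: cancer
status Bernoulli(prevalence); case tumor diameters from a configurable
distribution; sampled genome copies Poisson(λ) per case; controls shed
zero tumor copies (clonal hematopoiesis and other biological background
are out of scope — the simulator's false positives are a single assay-
level Bernoulli at rate 1 − specificity when a `TestPerformance` is
attached). Two positivity regimes:

* `sampling` (default) — a case is positive iff its draw captured at
  least `min_molecules` copies: the mechanistic model, used to verify
  the Poisson closed forms and the size–sensitivity curve;
* `test` — positivity is Bernoulli(sensitivity) for cases: the purely
  performance-defined regime, used to verify the PPV/NPV arithmetic.

The default size distribution is lognormal with median 8 mm and log-sd
0.5. The choice is structural, not epidemiological: it places
substantial mass on both sides of the 10–15 mm detectability band so a
simulated cohort exercises the transition. Real screening populations
have size distributions shaped by incidence and sojourn time that this
does not attempt to capture; passing tests therefore validate the
arithmetic of the model under its own assumptions, not the clinical
sensitivity of any real assay. Likewise the simulator has no
longitudinal rounds, tumor growth, or interval cancers.

All randomness flows from one `numpy.random.Generator` seeded by the
config with a fixed draw order, so identical configs give byte-identical
cohorts (tested). Empirical sensitivity/specificity/PPV/NPV are
counts-based with Wilson 95 % intervals (statsmodels); undefined metrics
(empty denominator) are flagged, never NaN-propagated. Monte Carlo
validation runs at n = 10⁵ for the screening scenario and n = 5 × 10⁴
for fixed-size detection cohorts — large enough that Wilson intervals
are a few tenths of a percent wide, small enough that the whole suite
runs in seconds.

## The reference table

`generate_table1` reproduces the canonical 12-row tumor-size table
(27 mm down to 1.1 mm). Printed mode carries the published geometry
columns and MAF-ratio strings verbatim: the published diameter/weight
pairs follow a rounded halving series, not sphere arithmetic (the 5 mm
row lists 62 mg where the sphere gives 65.4 mg; the 1.1 mm row's
diameter matches no standard rounding of the exact 1.15 mm), and the
published ratio column is itself a rounded doubling series that drifts
from round(1/MAF) below 0.25 cm³. The numeric MAF and genome-count
columns are computed from the tabulated volumes, which reproduces every
printed genome count exactly, including the "<0.1" display token
(emitted whenever the value is below 0.1, with the float preserved in a
parallel numeric column). Exact mode recomputes everything from the
sphere model at the same diameters and flags cells that disagree with
print at two significant figures. The two literature columns (chance of
progression, mammographic screen sensitivity) are static packaged data
keyed by diameter.

## Numerical choices

* Avogadro 6.02214 × 10²³ Da/g; two-significant-figure rounding is a
  display convention (`round_sig`), never used in computation.
* MAF capped at 1; the cap triggers only above 10⁴ cm³ at the default
  anchor.
* Bisection tolerance 10⁻⁶ cm³; decade floor uses a 10⁻¹² relative
  guard so an exact power-of-ten limit rounds down a full decade
  ("strictly below").
* Units are fixed package-wide (mm, cm³, mg, mL, ng/mL) and converted
  only inside `model.py`.

## Known limitations

The proportionality constant, cfDNA concentration and plasma fraction
are population averages treated as deterministic; between-subject
variability in shedding is not modelled. "Molecule present in the tube"
is equated with "detectable molecule" — assay chemistry, sequencing
error and duplicate consensus are out of scope, so the computed limits
are optimistic physical bounds, not assay specifications. Tumor-type-
specific shedding and cfDNA fragmentation are likewise out of scope.
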