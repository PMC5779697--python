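# Methods

`lipiddiff` analyzes shotgun-lipidomics abundance tables from two study
designs: a 2×2 factorial mouse heart-failure experiment (genotype wt vs
adipose-tissue-specific ATGL knockout, crossed with sham vs transverse
aortic constriction, TAC) and a human case/control plasma cohort (healthy
controls vs HFrEF patients).  This note records the models, the defaults
and the reasoning behind the choices that were genuinely open.

## Nomenclature

Species names follow the compact shorthand of shotgun-lipidomics software:
`CLASS C:D[;H]` for a sum composition (total acyl carbons : double bonds,
optional hydroxylation count) or per-chain forms such as `PE 16:0-18:2`.
Ether classes carry an `O-` suffix; hyphen, en-dash and slash separators
and optional whitespace are accepted, and every species has one canonical
spelling (hyphens, single space) that round-trips through the parser.  Two
raw spellings that canonicalize to the same species in one table are
treated as a data error, not silently merged.

Chain matching ("matched FAs") is multiset equality of `(carbons,
double_bonds, hydroxylations)` triples with sn-position deliberately
discarded, because the upstream identification cannot fix sn-position and
published species lists write the same pair in both orders.  Hydroxylation
counts participate in the equality.  Ether species are excluded from PC/PE
matching by default (the ratio is defined on diacyl pairs); an option
matches PC O-/PE O- pairs among themselves.

## Ingest and normalization

Raw tables hold pmol per sample per species.  Zeros and blanks are both
recorded as *missing*: shotgun identification only reports species above a
signal-to-noise threshold, so a zero is censoring, not a measured absence,
and the downstream log transform would otherwise be undefined.  No
pseudocounts are used anywhere.

Species filtering retains a species iff in at least one experimental group
its observed fraction is ≥ 1 − `max_missing_fraction` (default 0.5,
evaluated within groups).  The within-group rule keeps species that are
cleanly detected in one condition but censored in another — exactly the
species a differential analysis must not discard.  Filtering is monotone
in the threshold.

Mole percent is computed per sample over the *retained* species (100 ×
pmol / Σ observed pmol); missing entries stay missing, and each sample's
observed values sum to 100.  The alternative denominator (pre-filter
totals) is available but not default, since all downstream statistics are
computed on the filtered set.  Log transformation is base 2 throughout, so
fold changes read directly in doublings.

For class-level comparisons only, missing values are imputed (group median
by default, or least-squares regression on group indicators, which equals
group means on balanced designs; overall species median as fallback).
Species-level models never impute — they drop missing observations
casewise — because imputation would manufacture degrees of freedom for
per-species inference.

## Class-level statistics

Species are summed into class totals per sample.  Each class is compared
between conditions with a two-sided Mann-Whitney U test: exact null
enumeration when n₁+n₂ ≤ 20 and the data are tie-free, otherwise the
normal approximation with tie and continuity corrections (exact
enumeration assumes continuity, so ties force the approximation).
Benjamini-Hochberg adjustment runs within one comparison family — all
classes of one genotype's sham-vs-TAC comparison, or all classes of the
case/control comparison — never pooled across families.  Display tiers
(0.05/0.01/0.001 stars) are reported alongside the pipeline-wide discovery
rule, adjusted p < 0.1.

## Species-level factorial models

Each species' log2 mole percent is fitted by ordinary least squares with
treatment coding (reference wt, sham):

    y = β₀ + β₁·G + β₂·I + β₃·G·I + ε

Three hypotheses are tested from the single fit: β₁ = 0 (genotype t-test),
β₂ = 0 (intervention t-test), and β₁ = β₂ = β₃ = 0 (joint F against
intercept-only — "genotype + intervention + their interaction").  BH runs
separately within each family across species; a species is *retained* when
any adjusted p < 0.1.  A fit needs ≥ 5 observations spanning ≥ 3 design
cells and a full-rank design; zero residual variance yields "inestimable",
never p = 0.  Inestimable species are excluded from the BH families but
kept in the output.

Retained species are grouped by agglomerative hierarchical clustering
(Ward linkage, Euclidean distance; both configurable) of the per-species
vector (t_genotype, t_intervention, signed √F), each component z-scored
across species.  The √F component carries the sign of the largest
coefficient so that up- and down-regulated species with similar overall
evidence separate.  The tree is cut at k = 4 — the number of regulation
patterns the 2×2 design supports (up/down × TAC-driven/genotype-driven).
Species enter in canonical-name order and clusters are renumbered in
dendrogram-leaf order, making labels invariant to input order.  The display
matrix holds row z-scores of the four cell means (population SD over the
four values; an all-equal row becomes zeros).

Per-genotype fold changes use log2FC = mean(log2 TAC) − mean(log2 sham)
with an equal-variance two-sample t-test per species (Mann-Whitney as an
option — the factorial model's intervention test restricted per genotype is
the other defensible reading, and both are exposed), BH across species
within the genotype.  The discovery rule is the dual threshold: adjusted
p < 0.1 **and** |log2FC| ≥ 0.5.

## PC/PE ratios

For each chain-matched (PC, PE) pair the per-sample ratio of mole percents
is computed; log2(ratio) = log2(PC) − log2(PE) exactly, and ratios are
invariant to the per-sample normalization.  A sample missing either member
has a missing ratio — ratios are never imputed.  Sham-vs-TAC Mann-Whitney
runs per pair within each genotype with BH across pairs per genotype
(per-genotype families mirror the fold-change analysis).  Pairs with less
than half of a family's ratios observed, or fewer than two observations in
a group, are flagged untestable and excluded from the BH family rather
than tested on near-empty groups.

## Plasma arm

The cohort confounds disease with age and BMI (cases average ~16 years
older and ~2 kg/m² heavier), so:

- **Class totals** are residualized on age and BMI by pooled least squares
  (both groups together) with the grand mean added back.  Pooling is
  essential: residualizing within groups would leave group differences
  untouched by construction and answer a different question.  Corrected
  values have exactly zero sample correlation with both covariates and the
  correction is idempotent.  The group comparison on corrected totals is
  the same Mann-Whitney/BH machinery as the mouse arm.
- **Species models** fit log2 mole percent on group, age and BMI by Huber
  M-estimation (tuning constant 1.345, 95% Gaussian efficiency; IRLS to
  convergence).  When every residual falls inside the Huber threshold the
  fit coincides with least squares, which is also available as an option.
  The group coefficient is the estimated log2 fold change with its
  regression standard error; p-values for it are referred to Student t
  with the fit's residual degrees of freedom rather than the asymptotic
  normal, which at cohort scale (n = 23, 4 parameters) is measurably
  anti-conservative.  BH runs across all species (not within class), and
  the dual threshold flags discoveries.  The "estimated control mean mole
  percent" is 2^(prediction at group = control, cohort-mean age and BMI).

## Synthetic studies

The simulator generates studies with known ground truth for
parameter-recovery testing; it is first-class, tested code.

**Catalogs.**  Heart mode: 225 species in 18 classes, composition
dominated by PC (35%), PE (25%) and CL (12%); plasma mode: 147 species in
13 classes dominated by PC (30%), TAG (25%) and sterol esters (15%), with
PE a minor class as in circulation.  Within a class, species weights decay
geometrically with rank (rate 0.25), giving a few dominant and many minor
species; the baseline composition sums to 100 and is deterministic.
Chain-resolved names are assembled from a shared 18-FA pool (so matched
PC/PE pairs exist by construction); SM, Cer, CL and TAG species carry sum
compositions, as they commonly do in deposited tables.

**Generative model.**  Per sample, species log2 mole fractions are
baseline + planted effects + covariate terms (plasma) + Gaussian noise
(default SD 0.5 log2 units, the scale at which a 2-fold effect is a clear
but not trivial signal at n = 7/cell).  The vector is renormalized to a
composition and scaled to a lognormal total pmol (2×10⁵ ± 0.25 log2).
Effects are planted *before* renormalization; default scenarios perturb
≤ a few percent of total mass, so the compositional distortion of
unperturbed species is ≲ 0.05 log2 and is documented rather than
corrected.  For the same reason the plasma scenario plants its effects on
low/mid-abundance PE/DAG/Cer/PC O- species rather than the dominant PCs.

Effect factors: `genotype` (all KO samples), `intervention` (all TAC),
`interaction` (wt-TAC cell only — equivalently β₂ = +e, β₃ = −e — the
wt-restricted induction pattern the factorial design exists to detect),
`group` (all cases).  Plasma mode draws ages ~N(43.3, 12) for controls and
N(59.2, 12) for cases, BMI ~N(25.5, 2.7) and N(27.3, 3.6), reproducing the
cohort's confounding, plus small random per-species age/BMI slopes
(SD 0.005 and 0.01 log2 per unit).

**Missingness** is abundance-dependent, not completely at random:
P(missing) = logistic(−3 − 1.5·z) where z is the entry's log2 abundance
standardized against the catalog's baseline spread.  This yields ~10%
overall missingness concentrated in minor species, exercising the
filtering and imputation paths the way real below-detection censoring
does.

**What the simulator does not emulate:** instrument drift and batch
effects, isotope interference, correlated within-class biological
variation beyond the compositional constraint, heavy-tailed biological
outliers (except where tests inject them explicitly), and real catalogs'
irregular chain compositions.  Passing recovery tests therefore shows the
statistical machinery is calibrated under the stated generative model, not
that any particular biological dataset will behave identically.

## Recovery operating point

Under the default recovery scenario (10 interaction effects of +1 log2 on
mid-abundance PE species, n = 7/cell, SD 0.5, 50 replicates through the
full pipeline) the wt fold-change estimates on planted species center on
0.95–0.97 (the ~0.03 shortfall is the documented renormalization
attenuation), knockout fold changes center on zero, the observed
false-discovery proportion of the dual-threshold rule averages ~0.09, and
sensitivity averages ~0.4–0.5.  Sensitivity is intrinsically moderate
here: BH at level 0.1 with 10 true effects among ~220 species drives the
effective per-species α to ~0.003, where a two-sample t-test with n = 7
per group and a 2-SD effect has 50–60% power.  The suite asserts the
levels this operating point supports (mean log2FC within 0.1 of the
planted value, mean sensitivity ≥ 0.35, mean FDP ≤ 0.15, |KO mean
log2FC| ≤ 0.1); a larger per-cell n or effect size raises sensitivity but
describes a different experiment.  Under a 100-replicate global null the
fraction of replicates with any wt-family dual-threshold discovery is
~0.1, matching the FDR level.

## Numerical conventions

Log base 2 everywhere; BH via the standard step-up rule with stable-sort
tie handling; exact Mann-Whitney p clipped to (0, 1]; OLS via QR with
rank checks, zero residual variance reported as inestimable; Huber IRLS
with MAD scale; CSV output with 10 significant digits so reruns are
byte-identical; one seed drives every random draw in a run.
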