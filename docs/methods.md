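# Methods

`lineagevar` analyses how phenotypic variability arises and propagates in
bacterial micro-colonies under sub-inhibitory antibiotic stress, and ships
a stochastic lineage simulator that generates the tracking data the
analyses consume.  This note records the models, estimators, numerical
choices and known limitations.

## Data model

A micro-colony is a rooted binary lineage tree of cell records.  Each
record spans one cell from birth to division, growth arrest, or the end of
observation, and carries per-frame measurements (length in µm, centroid in
px, fluorescence channels in a.u.).  Times are minutes throughout.  The
division instant belongs to both the mother (her end) and the daughters
(their birth); census queries count the daughters at that instant.
Generation 0 is the founder; the *colony-stage* generation, used as the
time axis of autocorrelation curves, is `floor(log2(colony size))`.

Tracking tables are TSV, one row per cell per frame, with two metadata
comment lines (frame interval and induction time).  Birth/end times are
reconstructed deterministically from frames so that write → load → write
round-trips to identical bytes.

## Differentiation statistics

For cells alive at time `t`, grouped by their ancestor alive at an earlier
start time `s` (`N_s` groups of sizes `n_i`, group means `x̄_i`, grand mean
`x̄` over all `N_t` cells):

* `IDCV = sd(x, ddof=1) / x̄` — individual-cell coefficient of variation;
* `SLCV = sqrt( Σ_i n_i (x̄_i − x̄)² / (N_s − 1) ) / x̄` — sub-lineage CV,
  the size-weighted between-group mean square normalised by the grand mean.

This estimator satisfies two structural constraints: with `s = t` every
group is a singleton and SLCV equals IDCV identically, and for values
i.i.d. across the colony (however grouped) the between-group mean square
is an unbiased estimate of the individual variance, so the two statistics
have equal expectation.  An unweighted-group-mean variant is available
(`weighted=False`).  Extinct sub-lineages are dropped with a warning.
Multi-colony curves average per-colony curves on the shared frame grid;
cells are never pooled across colonies.

**Caveat on the "no differentiation" baseline.**  Equality of SLCV and
IDCV in expectation holds for i.i.d. phenotypes.  A *heritable* phenotype
measured without noise violates that premise even without any stress:
cells that share a recent ancestor are correlated, which inflates the
between-group mean square, and the unstressed simulator (one-generation
expression memory) shows a stable SLCV/IDCV ratio of roughly 1.2–1.6
rather than exactly 1.  Real microscopy data sit closer to 1 because
measurement noise dilutes the heritable share of the variance.  The
differentiation signal is therefore always read as the *contrast* between
stressed and unstressed colonies, or between a tree and its
lineage-randomized counterpart, not against an absolute ratio of 1.

## Fate classification

Growth rates at a reference time are fitted with a two-component Gaussian
mixture (scikit-learn); the threshold separating the death-prone slow mode
from the growing mode is the equal-posterior point between the component
means.  If the means are closer than the pooled standard deviation the
data are effectively unimodal and a manual threshold is required.  A cell
is called dead when it never divides again and its growth rate stays below
the threshold for at least 60 minutes at the end of its record (prolonged
growth arrest).  The birth time of the root of each maximal all-dead
subtree bounds when that sub-lineage committed to death.

## Pre-disposition tests

For a mother that divided before stress induction, the two sisters'
descendant groups at the final time are compared with a Welch two-sample
T-test (unequal variances; a pooled-variance option exists).  The
direction of a significant node compares the sisters' own lifetime-mean
fluorescence — at birth the two are near-identical because contents split
with volume; what distinguishes them is the expression they accumulate
from their inherited damage — with which descendant group is more stressed
(brighter, or slower-growing when the phenotype is growth rate).  The
direction bias over significant nodes is tested with a one-sided exact
binomial test against P = 1/2 (the hypothesis is directional; a two-sided
option exists).  No multiple-testing correction is applied across nodes;
the per-node false-positive rate is instead measured empirically by the
progeny-reassignment null: pooling both groups and re-splitting at random
into the original sizes, 500 times by default, makes the null true by
construction and the significant fraction estimates the realised alpha.

The combinatorial probability of a tree with `k` significant nodes out of
`n` defaults to the bare product `C(n, k)·p^k` to reproduce the
conventional printed form; the omitted `(1−p)^(n−k)` factor changes the
result by only a few percent at per-node rates around 0.02.  An exact
binomial upper-tail mode is provided and is the better-founded quantity.

## Lineage-switch randomization

For a colony with final population `N`, `N` pairs of cells born after
induction and of equal division-count generation are drawn and their
subtrees exchanged (each cell keeps its own descendants and measurements).
Swapping preserves per-generation counts, lifetimes, and the full multiset
of per-frame measurements — IDCV is unchanged at every time point to
machine precision — while sub-lineage membership is scrambled, so a
genuine lineage signal collapses the SLCV excess.  Because same-generation
cells are born a few frames apart, the mother-end = daughter-birth
identity is relaxed in randomized trees (they validate with
`strict_division_times=False`, and the loader accepts them with a
warning).  A residual SLCV excess of order 10–30% survives randomization
whenever phenotype correlates with generation — growth-arrested cells stop
dividing and therefore sit in earlier generations, and same-generation
swaps cannot mix across that stratification.  A values-only mode swaps
fluorescence values at shared frame times instead, leaving the topology
untouched.

## Lineage autocorrelation and memory half-life

`AF(g)` is the Pearson correlation, over all (ancestor alive at `s`,
descendant alive when the colony stage has advanced by `g`) pairs, between
the ancestor's phenotype at `s` and the descendant's phenotype at the
later frame.  Pairs are equally weighted (an ancestor-averaged variant
exists); points with fewer than `min_pairs = 16` pairs are omitted.
`AF(0) = 1` by construction.

The half-life is the least-squares slope of `log2 AF` versus `g` over
points above a floor (default 0.1; the log of near-zero correlations is
meaningless), as `−1/slope` in colony generations.  Two estimator
subtleties matter and are handled explicitly:

* *Finite-ancestor attenuation.*  With ~16 ancestors the clustered-pair
  Pearson estimate is attenuated by a roughly constant factor at every
  lag ≥ 1, while the lag-0 point is exactly 1.  Fitting all lags therefore
  steepens the slope.  For the unstressed measurement the fit drops lag 0
  (`skip_zero_lag=True`, floor 0.05) so the attenuation is absorbed by the
  intercept.  The stressed measurement keeps lag 0, which can only bias
  the half-life *short* — conservative for a lower-bound claim.
* *Stage duration.*  A colony stage increments when the last division of a
  wave completes, so one stage takes slightly longer than the single-cell
  doubling time (≈25.4 min versus 23 at the default parameters).  AF
  curves record their evaluation times; `AFCurve.stage_duration()`
  converts fitted generations to minutes.

For a stable product made at a constant rate and diluted by growth, the
concentration relaxes at `γ = ln2/T_d + d − b` (dilution, extra decay `d`,
linearised feedback gain `b`) and its autocorrelation decays as
`exp(−γt)`: half-life `ln2/γ`, equal to the doubling time in the simplest
case and diverging as feedback approaches criticality
(`linear_model_halflife`).

## The stochastic lineage simulator

State per cell: length `L`, intracellular drug `D`, damage `S`, stress
reporter `F`, optional co-reporter `F2` (all concentration-like).  With
`k = k_max·vigor/(1 + (S/K_g)^m)` and `k_max = ln2/T_d`:

    dD/dt  = u0 (1 + βS) D_out − (u_out + k) D
    dS/dt  = (σ_s D + σ_0) k − k S            [+ η_s √S ξ_S]
    dF/dt  = [α0 + α1 S^h/(K^h + S^h)]·vigor² − k F   [+ η √F ξ]
    dF2/dt = u0 (1 + βS) A_out − k F2
    dL/dt  = k L

Interpretation: drug enters through a membrane whose permeability grows
with damage (`β`, the positive feedback), and passively re-equilibrates
out (`u_out`; aminoglycoside/tetracycline-class half-equilibration of tens
of minutes).  Damage is produced by mistranslation — proportional to drug
times translational activity, hence to growth — on top of a small
drug-free misfolding load `σ_0`, and is diluted by growth, so damage
freezes in arrested cells.  Expression responds to damage through a Hill
function; growth is inhibited by damage through a steep Hill
(`m = 8, K_g = 1.3`), which keeps growth essentially unperturbed at basal
damage and collapses it once damage runs away.  `ξ` terms are white
noises; `η √F` keeps the reporter non-negative with the mean–variance
scaling of bursty expression (an additive mode exists), and `η_s √S`
models random bursts of membrane/protein damage.

A cell divides when its length doubles its birth length (with a small
lognormal jitter, `div_size_cv = 0.05`, which desynchronises division
waves).  Volume splits with fraction `q ~ N(0.5, cv_div/2)` truncated to
(0.2, 0.8); each species' content — concentration × length ×
`molecule_scale`, rounded to integer molecules — is partitioned
`Binomial(n, q)`, conserving molecules exactly.  Damage uses its own split
probability drawn with `damage_partition_cv`: aggregated misfolded
material segregates far more asymmetrically than volume, and this
asymmetric damage inheritance is what creates sister-cell pre-disposition.
An optional heritable `vigor` factor (log-AR(1) across divisions, off by
default) scales growth and, super-linearly, expression capacity; it exists
to reproduce the positive growth–expression correlation of unstressed
cells and is not part of the null model.

Integration: frames every 1.5 min, 10 substeps per frame.  Within a
substep the drift is linear with rates frozen at the substep start and is
integrated exactly (exponential integrator; damage production sees the
trapezoidal mean drug level), noise is added Euler–Maruyama, and length
multiplies by `exp(k·dt)` so noise-free growth is exactly exponential.
Negative states are clamped to zero.  Division-threshold crossings are
detected during integration and effectuated at the next frame boundary so
records stay one-row-per-frame.  Cells whose growth rate stays below
`death_rate_floor` for `arrest_duration` are flagged arrested and never
divide again, but remain in the colony and in every census.  Identical
seeds give bit-identical trees.

### Presets and calibration

Defaults describe the unstressed null condition: no drug, no feedback, no
basal damage, constant stochastic production — the regime whose lineage
autocorrelation half-life is one doubling time by construction.  The
`stressed` preset (`D_out = 1, β = 4.5, σ_s = 0.55, σ_0 = 0.2,
η_s = 0.03, damage_partition_cv = 0.35, α1 = 45, η = 0.35`, colonies to
600 cells) is *calibrated, not measured*: its values were chosen so the
simulator reproduces the qualitative stressed phenomenology —

* a bimodal growth-rate distribution (~40% slow / ~45% fast at the end of
  a run) with a growth-arrested, death-prone sub-population whose deaths
  cluster within subtrees;
* a strongly negative growth–expression correlation under stress;
* SLCV rising above IDCV after induction, strongest for sub-lineages
  rooted at the ~8-cell induction stage;
* an expression autocorrelation half-life of ≥ 3–4 generations when
  measured from a late (4 colony generations post-induction) start,
  versus 1 doubling time without stress;
* a directional bias at significant pre-induction nodes: the sister with
  higher lifetime expression founds the more stressed sub-lineage;
* a strong positive correlation between the stress reporter and a passive
  co-reporter under stress, which vanishes (|r| < 0.1) when the
  permeability feedback is switched off
  (`stressed_coreporter` / `stressed_coreporter_nofeedback` presets).

With `β = 0` the drug–damage map is monostable and mild; with the preset's
`β` the low-damage state is destabilised and cells transit to arrest at
times spread by partition noise, which is what sustains the coexisting
sub-populations over the observation window.

### What the generator does and does not emulate

It emulates micro-colony growth from a single founder at ~23 min doubling,
90 s frames, stress switched on at the 8-cell stage, heritable stress
states, bimodal post-stress growth and clustered death.  It does not model
cell shape, pushing or spatial nutrient gradients (positions are a
decorative random spread; the border-distance control is exercised on
geometric fixtures), segmentation or measurement noise (fluorescence is
recorded exactly, which is why the null SLCV/IDCV ratio sits above 1 and
AF curves lack a measurement nugget), lysis (dead cells persist), or the
ribosome/chaperone feedback alternatives.  Passing tests demonstrate the
statistical machinery and the feedback mechanism's qualitative
consequences, not quantitative agreement with any particular experiment.

## Promoter activity

`activity(t) = dF/dt + k·F` (central finite differences on the common
frame grid): the dilution-corrected production rate per unit volume.  The
exact published form of this quantity was not available to us; the
implementation is the standard dilution correction consistent with its
symbols and is flagged here as a reconstruction.

## Border distance

Border cells are those whose centroid lies on the convex hull (vertices
and points on hull edges) of all centroids at the query frame; interior
cells take the minimum centroid distance to a border cell.  This is a good
approximation while the colony is near-convex; fewer than three cells, or
a collinear colony, are all border.

## Problem sizes

The shipped verification runs use 200 unstressed colonies (~200 cells
each) for the null half-life, 14 stressed colonies (~600 cells) for the
stressed half-life, 50 small colonies × 3 nodes × 500 reassignments for
the null calibration, 20 stressed colonies for the direction bias, and 8
colonies per condition for CV ratios and fate fractions — sizes at which
the reported means are stable to a few percent while a full run of the
suite plus the acceptance script completes in a few minutes.
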