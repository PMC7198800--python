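# Methods

This note documents the models, numerical choices and limitations of the
package. It covers four computational layers — constraint-based growth
prediction with ensemble gapfilling, phenotype-microarray scoring,
model-vs-experiment evaluation, and label-free proteomics statistics —
plus the synthetic-data generators that stand in for the wet-lab inputs.

## Constraint-based core

### Flux balance analysis

A metabolic network is a set of mass-balanced reactions with flux bounds,
boundary (exchange) reactions and exactly one biomass reaction. Growth on a
medium is the optimum of

    maximize  v_bio   s.t.   S v = 0,   lb <= v <= ub

solved with HiGHS (`scipy.optimize.linprog`). Exchange fluxes are positive
for secretion and negative for uptake; a medium maps each open exchange to
a maximum uptake `u >= 0` (lower bound `-u`), unlisted exchanges are closed
to uptake and open to secretion (upper bound 1000, the generic magnitude
bound of the toy unit system, nominally mmol·gDW⁻¹·h⁻¹). Infeasible LPs
are reported as zero growth with an explicit flag; solver failures raise.
The steady-state residual of returned solutions is below 1e-6 (HiGHS
primal feasibility tolerance 1e-7).

A network *grows* when the objective strictly exceeds the growth threshold
`epsilon` (default 1e-3 flux units, configurable). The threshold exists to
separate numerical noise from biological growth; strict inequality makes
the boundary case deterministic.

### Positive gapfilling

Finding the smallest set of database reactions whose addition enables
growth is solved exactly as a mixed-integer LP: one binary indicator per
candidate reaction gates its flux bounds (`v_j <= ub_j y_j`,
`v_j >= lb_j y_j`), the biomass flux is constrained to at least
`min_growth` (default 1e-2, a decade above `epsilon` so the post-condition
is robust to solver tolerance), and the sum of indicators is minimized. At
the network sizes used here (tens to low hundreds of reactions) HiGHS
solves these in milliseconds and the solution is a certified minimum;
the cardinality is verified against exhaustive subset enumeration in the
test suite.

Equal-cardinality ties are broken toward lexicographically earlier
reaction ids. The default mode encodes the preference as tiny
rank-dependent costs added to the unit indicator costs (scaled so any
subset's extra cost stays below 1, hence cardinality always dominates);
this needs a single solve and picks the lexicographically smaller id
whenever alternatives differ by one reaction. An exact mode
(`tie_break="lexicographic"`) certifies the lexicographically smallest
sorted id-tuple by a greedy sequence of MILP feasibility solves; it is
linear in the candidate count and used for small instances and tests.

### Negative gapfilling (trimming)

No canonical algorithm exists for making a false-positive medium
non-growing, so the package uses a deliberately conservative greedy
procedure: only reactions previously *added* by gapfilling are removable
(the draft's own content is never touched); candidates are the removable
reactions carrying flux on the negative condition, tried in a seeded random
order; a removal is kept only if every satisfied positive condition still
grows; rounds repeat until the negative stops growing or no removal is
possible. An unresolvable negative returns the original network with a
flag — never an error, and never a broken positive.

### Ensembles

`build_ensemble(draft, db, positives, negatives, size, n_pos, n_neg, seed)`
draws, per member, a without-replacement subset of `n_pos` positives and
`n_neg` negatives (member stream seeded by `SeedSequence([seed, member,
attempt])`, so ensembles are bit-reproducible), gapfills positives in drawn
order, trims negatives in drawn order, and verifies the training guarantee:
every member grows on all its training positives and on no training
negative that is not flagged unresolvable. A member whose draw contains an
ungapfillable positive is redrawn (bounded retries). The study-scale
configuration — 50 members, 26 positive and 11 negative training substrates
— is the pipeline default; tests and the analysis scripts run 3–10-member
ensembles on 8–24-substrate panels, which keeps the full suite around half
a minute while exercising the identical code paths.

Predictions aggregate as:

* vote fraction = members growing / size; binary call at fraction >= 0.5
  (configurable);
* activity = (mean growth rate over growing members) × fraction, identical
  to the all-member mean with non-growers contributing zero — the two
  published readings of "weighted average growth rate" coincide under this
  formula, which is why it was chosen;
* weighted flux per reaction = (mean flux over members where it carries
  flux) × (fraction of members where it does); members lacking the
  reaction count only in the denominator. Flux fold changes compare
  magnitudes (reversible reactions), floor zeros at a pseudo-flux of 1e-6
  before the log2, and keep |log2FC| > 1.

Plain FBA optima are used for member fluxes; alternate optima are not
resolved (no pFBA), which is irrelevant for growth calls and activity but
means individual weighted fluxes are solver-determined among degenerate
optima. HiGHS is deterministic for fixed input, so results are
reproducible.

## Growth scoring

Kinetic series (A590 for phenotype microarrays, OD600 for batch curves)
are background-subtracted per plate and replicate against the negative
control well A1 (the control is kept unmodified for QC), clipped at zero
(subtraction can produce small negatives), and fitted to the logistic model

    N(t) = K / (1 + ((K - N0)/N0) exp(-r t))

by bounded nonlinear least squares (initialization N0 = first value floored
at 1e-3, K = max value, r = 0.2 h⁻¹; bounds K in (0, 2·max], r in (0, 5],
N0 in (0, max]). Series whose dynamic range is below 0.01 absorbance, and
fits that fail to converge, are flagged with K = max observed value and
r = 0. The AUC is the closed-form integral of the *fitted* curve (the
degenerate flat curve for flagged wells), computed in an overflow-safe
form; an empirical trapezoid alternative would change intensities only
through rank shifts and is not the default.

A well is growth-positive when K > 0.1 in at least 2 of 3 replicates (both
thresholds configurable; the call is invariant to replicate order). For
each strain, growth-positive AUCs are z-scored within each replicate assay
(sample sd, ddof 1; constant assays warn and map to zero), averaged across
replicates, and split at the empirical quartiles of the averaged z-scores
(linear-interpolation quantiles; boundary ties fall to the lower bin),
giving intensities 1–4; non-growth wells are 0. Z-scoring before averaging
follows the stated order of operations of the assay protocol. Fewer than 4
growth-positive substrates make quartiles meaningless and raise an error.
Known high-background wells are excluded by configuration before scoring.

## Evaluation

Ensemble growth calls are scored against an experimental truth table with
per-member masking: a member abstains on every condition in its own
training record, so each condition is judged only by members that never saw
it (a global-holdout mode, where a condition set is excluded from training
entirely and all members vote, is available as a switch). Conditions with
all members masked are excluded and reported. Precision and recall are
null when undefined (zero denominators).

The random baseline draws i.i.d. Bernoulli predictions per condition —
probability equal to the truth prevalence by default, 0.5 as the
information-free alternative — and reports the empirical metric
distribution; the benchmark requirement is masked accuracy above the
baseline's 95th percentile. Quantitative agreement converts predicted
activity and experimental mean intensity z-scores to percentile ranks
(average ranks on ties) and reports the squared Pearson correlation;
constant vectors yield null.

## Proteomics statistics

All tests operate on log2 LFQ intensities; missing values are "not
detected" and are never imputed (MaxQuant-style zeros are read as
missing). Per treatment pair:

* proteins with >= 3 detected replicates in both groups are tested with
  Welch's t (unequal variances; Student's t available by flag), log2FC =
  difference of group means of log2 values;
* zero-variance groups get p = 1 when means are identical and p = 0
  otherwise (the t statistic is undefined there; the limits are used);
* BH adjustment is applied within one strain × one comparison (matching
  per-volcano presentation); a DEP has |log2FC| > 1 and BH p < 0.05;
* proteins detected (>= 3) in one group and never in the other are routed
  to presence/absence calls and excluded from the test.

KEGG-ortholog matching keeps KOs detected (>= 3 replicates; 4 is the
stricter variant some presentations use — it is a knob) in every treatment
of every strain; when several proteins of a strain share a KO, the one with
the highest grand-mean LFQ across all samples represents it (missing
counted as zero, as LFQ reports). The KO table exposes a within-strain
z-scored view (per-KO across treatments, ddof 1) and an
ammonium-normalized view (log2 ratio to the reference treatment).

Pathway significance combines the BH-adjusted p-values of a pathway's
tested constituent proteins with Fisher's method, X = −2 Σ ln p against
chi-square with 2k df; pathways with fewer than 3 tested proteins, and
blacklisted (non-bacterial) pathways, are excluded; zero p-values are
floored at 1e-300 with a warning. The phrase "Fisher's exact test" used
for this step in parts of the field's literature conflates two different
procedures; a genuine 2×2 enrichment variant (DEP membership × pathway
membership, one-sided Fisher exact) is provided behind `method=
"enrichment"` for comparison. Note that BH adjustment is *not* idempotent
(re-adjusting [1.0, 0.25] → [1.0, 0.5] gives [1.0, 1.0]); the tests assert
the true property (re-adjustment never decreases).

### PII screen

For each protein, the Pearson correlation between its treatment-mean log2
profile and the PII protein's profile, and the OLS slope of the protein's
profile on the *z-scored* PII profile — i.e. log2 units of change per one
PII standard deviation. Classification: positive at correlation > 0.75 and
slope > 2; negative at correlation < −0.75 and slope < −2 (the published
threshold statement omits the minus sign on the correlation; the symmetric
reading is implemented). The slope is deliberately *not* computed between
two z-scored profiles: that slope equals the correlation, is bounded by 1
in magnitude, and could never exceed a threshold of 2 — whereas slopes of
±3 and beyond are exactly what the screen is meant to find. Measuring the
protein's response in absolute log2 units per PII-SD preserves amplitude,
makes the thresholds attainable, and recovers the coupling slopes planted
by the generator. Constant or incomplete profiles are unclassifiable.

## Synthetic data

The generators emulate the *statistical shape* of the study's inputs, not
their content:

* **Universe** (`generate_universe`): a universal reaction database built
  from a glucose backbone, one catabolic pathway per nitrogen source
  (exchange → transport → 1–2 chain steps; the final step releases one
  ammonium per nitrogen atom of the substrate, 1 or 2), shared deamination
  hubs that ~75% of sources funnel through (so gapfilling one substrate
  can generalize to held-out ones, as shared catabolic infrastructure does
  in real networks), occasional alternative transporters (route
  redundancy), and dead-end decoy reactions filling the database to its
  nominal size. True networks per strain include a random ~60% of source
  pathways; media share the carbon backbone and differ only in the
  nitrogen source, with per-substrate uptake capacities below the carbon
  limit so growth rates differ across sources (nitrogen limitation). The
  truth matrix is FBA on the true networks. Drafts delete a fraction of
  reactions greedily, skipping any deletion that would break ammonium
  growth. Defaults: 40 metabolites, 120 database reactions, 12 sources, 3
  strains — large enough for non-trivial gapfilling, small enough for
  exhaustive oracles.
* **Plates** (`simulate_plate`): logistic kinetics on a 10-min grid over
  72 h, 3 replicates, Gaussian noise (sd 0.01 default), a shared drifting
  background captured by control well A1, one planted high-background
  substrate to exercise the exclusion rule, growth-well K in [0.15, 0.6]
  and non-growth K in [0.005, 0.05] (cleanly separated by the 0.1 call
  threshold at low noise). Growth-well K can optionally track a
  metabolic-activity map (true-network FBA rates) through the substrate's
  activity percentile mixed 65:35 with uniform noise — emulating that dye
  reduction partly reflects metabolic rate — which gives the
  activity-vs-intensity rank correlation genuine signal of realistic,
  moderate strength.
* **Proteomes** (`simulate_proteomics`): per-strain baselines ~ N(26, 1.5)
  on the log2 scale, 5 treatments × 4 replicates, i.i.d. replicate noise
  (sd 0.25 log2 units), planted ±3 log2 effects (12 proteins per
  non-reference treatment), 50 exact nulls, a PII protein with a unit-SD
  treatment profile plus 15 coupled (slope +3) and 5 anti-coupled (−3)
  proteins, a low-abundance block just above the detection limit pushed
  below it in one treatment (left-censoring: values under log2 LFQ 19
  become missing, matching LFQ dropout, the behavior the presence/absence
  logic assumes), and KO/pathway maps shared across strains. The planted
  DEP truth lists, per treatment pair, the proteins whose planted contrast
  reaches the design effect size.

What passing tests on these data do **not** show: recovery under real
biological variance structure (correlated replicates, batch effects,
compositional normalization), genome-scale network degeneracy, non-logistic
growth (lag phases, diauxie), or MS-specific artifacts (shared peptides,
match-between-runs). The generators are pure functions of (parameters,
seed); every stochastic component in the package draws from an explicit
seed hierarchy.

## Problem sizes and determinism

The test suite runs 3-member ensembles across 20 universes (training
guarantee), 10-member ensembles for the end-to-end benchmark, 200 wells for
logistic recovery, and the full 3-strain × 10-pair proteomics recovery —
about half a minute in total. The acceptance script scales the ensemble
benchmark to a 24-substrate panel (pooling within-strain percentile ranks
across strains stabilizes the rank-r² estimate). All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; identical
inputs and seeds reproduce ensembles, plates and matrices bit-for-bit, and
the pipeline caches stages by parameter/input hash so reruns are
byte-stable.

## Known limitations

* The biomass reaction is a two-metabolite toy; genome-scale biomass
  definitions materially affect predictions and are out of scope.
* Negative trimming is a stand-in for an undocumented procedure; it is
  conservative (never breaks positives) but not minimal in any certified
  sense.
* Weighted fluxes inherit LP degeneracy (no pFBA/FVA).
* The default rank-weighted tie-break approximates the lexicographic rule
  exactly only when tied optima differ by a single reaction; the exact
  mode is available but slower.
* Quartile binning uses linear-interpolation quantiles with ties to the
  lower bin; other quantile conventions shift intensities of near-boundary
  wells by one level.
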