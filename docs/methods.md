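# Methods

This note documents the algorithms, the simulator model, the tunable
parameters and the deliberate design choices. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Acidification-parameter extraction

Each fermentation step's pH trace (nominally one reading per 5 min; F1
lasts 24 h, F2–F6 last 18 h) yields three parameters.

**Maximum acidification rate (MAR).** Ordinary least squares is fitted on
every window of `window_points` consecutive samples (default 20, i.e.
95 min at 5-min logging; the window is a point count, not a duration, and
the same count applies to F1). The MAR is the lowest slope over all
windows, kept **signed** — acidifying curves give negative values — with an
`abs_mar` convenience column in the output table. Fits use the actual
timestamps, so irregular logs are handled; on uniform grids this equals
index-based fitting. Ties for the minimum are broken toward the earliest
window; because two algebraically equal OLS routes can differ by a few
ulps, slopes within `64·eps` of the minimum are treated as exact ties. A
curve needs at least two full windows (40 points) to be eligible;
shorter curves are flagged, not errors.

**Lag time.** The MAR window's fitted line `pH = b + m·t` is intersected
with the horizontal line at the curve's first pH value:
`t* = (pH(0) − b)/m`. On a noiseless lag/drop curve this is exactly the
change point. A negative intersection (possible when noise puts the
steepest window at the very start) is clamped to 0 and flagged
`lag_clamped`. If the minimum slope is non-negative (within round-off) the
curve never acidified: the lag is undefined (NaN) with a `non_acidifying`
flag rather than an error, so batch runs never abort. Whether the original
procedure clamped at zero is not documentable; clamping is this package's
policy.

**Final pH.** OLS over the last `window_points` samples, evaluated at the
step's nominal horizon (24 h for F1, 18 h for F2–F6). The evaluation is
performed whether the horizon falls inside (interpolation) or beyond the
record; extrapolating more than 2 h past the last timestamp adds a
`long_extrapolation` flag.

Exactness guarantees verified by the tests: on noiseless piecewise-linear
curves the MAR equals the planted slope to ~1e-13, the lag equals the
planted change point to ~1e-12 h, and the final pH equals the plateau to
~1e-15; under 0.01-pH observation noise the lag is recovered within
0.25 h in ≥95 % of replicates.

## Diversity and composition

All metrics operate on relative abundances; no rarefaction or other count
normalisation is applied. Richness is the observed ASV count
(abundance > 0). Shannon entropy uses the natural log by default
(configurable base): values on diverse milk communities ("above 2.5") are
consistent with nats, the default of the ecology toolchain. Bray–Curtis
dissimilarity is `Σ|pᵢ−qᵢ|/Σ(pᵢ+qᵢ)` on the union of the two ASV sets;
pairwise matrices are computed after aligning all samples on the global
ASV table. Adjacent-step series run F2→F6 for Bray–Curtis and over all
fermented steps for the alpha-diversity fluctuation sums (sums of
|adjacent differences|).

Genus-level composition pools a genus into "Other" unless it reaches the
`minor_genus_threshold` (default 5 %) in **at least one step of the
lineage's series** — a genus kept anywhere is shown everywhere, matching
per-lineage barplot conventions. The LAB fraction sums the Lactobacillales
genera (Enterococcus, Lactobacillus sensu lato, Lactococcus, Leuconostoc,
Oenococcus, Pediococcus, Streptococcus, Weissella); "Lactobacillus sensu
lato" is resolved through a configurable alias list covering the 2020
split of the former genus (Lacticaseibacillus, Lactiplantibacillus, …).
The dominant-taxon call compares the summed abundance of the categories
{Lactobacillus sensu lato, Lactococcus, Streptococcus, other-LAB,
Pseudomonadota} and reports the maximum only if strictly above the
dominance threshold (default 0.5, i.e. ">50 %"), else "none".

## Ordination, trajectories and stability labels

NMDS minimises Kruskal stress-1 via SMACOF with monotone regression
(scikit-learn), k = 2 by default, best of 32 restarts. Restarts are looped
explicitly over seeds derived from the configured seed, which makes the
result deterministic and guarantees the best-of-n stress cannot worsen as
restarts are added. Coordinates are centered per axis. An all-zero
dissimilarity matrix short-circuits to coincident points with stress 0
(the iterative solver is undefined there).

A lineage's trajectory through ordination space is summarised by Euclidean
segment lengths between consecutive steps, their total, the net F2→F6
displacement (total ≥ net always), and the direction angle
`atan2(Δaxis2, Δaxis1)`. Trajectory parallelism is the mean pairwise
cosine of direction angles; zero-displacement trajectories carry no
direction and are excluded with a warning.

The stability classifier is an explicit, threshold-based surrogate for
what is, in practice, a visual grouping of lineages. With the mean
adjacent-step Bray–Curtis `m`, its trend `r` across the series, and the
dominant-category switch between the first and last steps:
`stable` if `m < 0.08`; `successional` if the dominant category switches
or (`m ≥ 0.20` and `r < 0`, i.e. large early reorganisation that settles);
otherwise `drifting`; `unclassified` below 3 pairs. The thresholds are
calibrated against the reported group levels of adjacent-step
dissimilarity (≈0.03 stable, ≈0.13 drifting, 0.31→0.14 successional) and
are configurable. The labels deliberately avoid the original group names:
the classifier approximates, not replicates, that grouping — on simulated
cohorts, drifting lineages near the 0.08 boundary are regularly labelled
stable.

`pearson_trend` and `correlate_structure_function` are plain Pearson
correlations (two-sided p from the t distribution, n−2 df); the
structure–function statistic correlates adjacent-step Bray–Curtis with
**|Δ final pH|** by default (the magnitude is the claim of interest and
the sign convention of the underlying plot is not fixed); a signed option
exists. No multiple-testing correction is applied in this module.

**Broken-stick regression.** The lag-vs-LAB relationship is fitted as a
continuous two-segment line `y = a + b·x + c·(x − ψ)₊`, with the
breakpoint ψ chosen by grid search on multiples of `grid_step` strictly
inside the x-range (ties to the smaller candidate, ≥2 points required per
side), minimising RSS; the hinge family contains the single line, so the
fitted RSS never exceeds the single-line RSS. Grid search plus constrained
OLS was chosen over iterative breakpoint estimation because it is
deterministic and auditable at these sample sizes (n ~ 10²). The default
grid step is 0.005 on a fraction scale; the pipeline fits lag (h) against
LAB **percentage** and passes 0.5 accordingly. Recovery, verified by
tests: a planted break at 88 % with slopes 0 and 0.09 h/% is found exactly
(to grid resolution) without noise and within ±3 percentage points in
≥90 % of replicates at noise σ = 0.15 h.

## The synthetic cohort generator

The simulator emulates the study design — 26 lineages, T0 raw-milk profile
plus six fermentation steps, 1:100 transfers, pH every 5 min — so that
every pipeline stage runs on realistic files with known ground truth. It
is an explicit stand-in: the real study fits no mechanistic model, and
none of the simulator's parameters are estimates of real strains.

**Within a step.** Species `i` with biomass `Bᵢ` follows

    dBᵢ/dt = r_maxᵢ · gᵢ(pH) · Bᵢ · (1 − ΣB/K)        for t ≥ lagᵢ
    gᵢ(pH) = max(0, (pH − ph_minᵢ)/(ph0 − ph_minᵢ))
    dpH/dt = −Σᵢ acid_yieldᵢ · (dBᵢ/dt)₊              clamped at ph_floor

integrated by explicit Euler (dt = 1 min; halving dt moves the final pH by
<0.01, tested), sampled every 5 min. pH is driven directly by growth — no
explicit lactate/titration chemistry — to keep ground-truth kinetics
tractable. The noiseless pH is non-increasing and bounded in
[ph_floor, ph0]; Gaussian observation noise (σ = 0.01 pH) is added to the
**emitted** curves only, and ground-truth parameters are extracted from
the noiseless signal with the package's own kinetics module.

**Between steps.** Transfer multiplies biomass by the dilution (0.01) —
an exact scalar, so composition is conserved to machine precision — then
species below 1e-6 relative abundance are dropped (a deterministic proxy
for bottleneck loss; a seeded multinomial bottleneck is available behind
`stochastic_bottleneck`). Two carry-over mechanisms act at each transfer:

1. *Batch effects*: each species' growth rate is scaled by a lognormal
   factor (sd 0.05 in log space) per step, representing day-to-day process
   variability. Without it, deterministic competition converges and
   multi-species lineages stop fluctuating.
2. *Acid-stress carry-over*: cells harvested at a pH below their own
   growth floor start the next fermentation with a longer lag —
   `lag + 6 h/pH · sens · max(0, ph_min − pH_harvest)` — where the
   per-species sensitivity is low for lactobacilli and enterobacteria
   (dedicated acid-resistance systems) and high for lactococci. This is
   the mechanism that lets an acid-tolerant species compound its advantage
   across transfers.

**Archetypes.** Three lineage archetypes, mixed 5:9:12 over 26 lineages to
mirror the observed group sizes:

- *stable*: one fast starter LAB at 75–80 % initial share over a weaker
  background (a slightly less fit second LAB, Leuconostoc-like and
  Gram-negative minorities). The dominant locks in by F2; adjacent-step
  dissimilarity stays small and the final pH pins near the dominant's
  floor.
- *drifting*: four LAB pulled to a common growth rate (±3 %), lag and acid
  floor (4.45 ± 0.08), so none holds a structural advantage and batch
  effects keep shares moving without a takeover.
- *successional*: a Lactococcus-like starter (r ≈ 1.55 h⁻¹, floor 4.6) and
  a rarer Lactobacillus-like species (initial share 1–2.5 %, floor 4.15 —
  ≥0.3 below the starter — higher acid yield 2.8, longer lag), plus
  enterobacteria. The tolerant species grows through the post-stall
  window of each step and, via stress carry-over, overtakes between F3 and
  F6 in most seeds.

Trait values (growth rates ~1.0–1.6 h⁻¹, acid floors 4.15–5.6, yields
0–3 pH per unit biomass, K = 2.2, initial F1 biomass 1e-6 of scale —
mimicking raw milk's ~10³–10⁴ CFU/mL versus ~10⁹ at saturation) were
chosen once so that the archetype phenotypes hold across seeds: they give
F1 lags of ~9 h versus ~3 h for re-inoculated steps, plateaus between 3.9
and 4.9, a positive pooled correlation between adjacent-step dissimilarity
and |Δ final pH| (stable lineages change neither; successional lineages
change both), and a dominance switch in ≥80 % of successional seeds.
T0 profiles are generated separately as high-richness (~55–75 ASVs from a
shared background pool), Pseudomonas-dominated compositions with the
lineage's fermenting species rare, and carry no pH curve. Composition
tables are emitted noise-free as pseudo-counts (relative abundance × 10⁵,
rounded); multinomial resampling at a configurable depth mimics sequencing
counts if wanted.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: strain-level diversity, immigration (richness
can only decrease after F1), milk buffering chemistry (the simulated MAR
magnitudes run steeper than typical logger values), temperature effects,
and measurement artifacts other than i.i.d. Gaussian pH noise. In
particular, the simulated lag-vs-LAB% relationship is dominated by the
acidifier-inoculum effect (lower LAB % → longer lag) rather than by a
slow-lactobacillus effect above a high-LAB threshold, so the cohort-level
broken-stick fit is demonstrated on planted data, not on the cohort.

## Numerical and policy choices

- Internal time unit is hours; minute-based logger files convert on read.
- Missing steps are tolerated and flagged; adjacent-pair series simply
  omit affected pairs (a missing middle step removes both its pairs).
- Counts may be integral or fractional; all diversity math treats them
  uniformly.
- Zero-variance inputs to correlations return NaN with a flag, not errors.
- `write_results` uses pandas' repr-based float formatting: re-reading
  reproduces every numeric column exactly, and a rerun with the same seed
  and config is byte-identical.
- Seeds: every stochastic component (cohort generation, NMDS restarts)
  derives from a single configured seed via spawned child generators.

## Problem sizes

The shipped tests and the acceptance script use the study-scale design
(26 lineages × 6 steps; 217–289 points per curve), 50 seeds for the
archetype phenotype studies, 500 replicates for noisy lag recovery, 200
for breakpoint recovery and 1,000 random pairs for the Bray–Curtis oracle
— sizes at which the stochastic rates in the tests are stable from seed to
seed.
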