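# backslop

Acidification kinetics and bacterial community dynamics of serially
propagated ("backslopped") milk fermentations.

## The problem

Backslopping — inoculating fresh milk with a small fraction (here 1:100) of
a previous fermentation — is the oldest way of propagating a fermenting
microbial community, and a candidate top-down approach for engineering
starter cultures from raw-milk diversity. The open question it poses is the
balance between **propagation** (keeping community structure and function
stable across transfers) and **shaping** (letting selection reorganise the
community). This package implements the quantitative toolkit for studying
that balance in a design of 26 raw-milk lineages, each fermented six times
(F1 for 24 h, then five 18-h steps), with pH logged every 5 min and a
16S ASV composition profile per step:

- **Acidification kinetics** per pH curve: the maximum acidification rate
  (MAR) is the lowest slope among ordinary-least-squares lines fitted on a
  20-point sliding window, `MAR = min_i slope(OLS(t, pH; i..i+19))`; the
  lag time is where that steepest line crosses the initial pH,
  `t* = (pH(0) − b) / m`; the final pH is the OLS line over the last 20
  points evaluated at the nominal horizon (24 h for F1, 18 h otherwise).
- **Community dynamics** per lineage: observed richness, Shannon entropy
  (nats), Bray–Curtis dissimilarity `BC(p, q) = Σ|pᵢ−qᵢ| / Σ(pᵢ+qᵢ)`
  between adjacent steps F2→F6 and its sum, genus-level composition with
  <5 % genera pooled as "Other", the lactic-acid-bacteria (LAB) fraction,
  and a dominant-taxon call (>50 %).
- **Trajectory statistics**: non-metric multidimensional scaling (Kruskal
  stress-1, SMACOF, seeded restarts) of the Bray–Curtis matrix; per-lineage
  trajectory length, net displacement and direction; a threshold-based
  stable / drifting / successional classifier; Pearson correlation of
  adjacent-step BC with |Δ final pH|; and a continuous two-segment
  ("broken-stick") regression of lag time on LAB percentage with a
  grid-searched breakpoint.
- **A mechanistic simulator** of serially propagated acidifying
  communities (logistic growth × linear pH inhibition, growth-coupled
  acidification, 1:100 transfers with bottleneck extinction) that emits the
  full file set the pipeline reads, with noiseless ground truth for every
  extracted parameter — so the entire analysis runs and is tested without
  any external data.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
cohort (everything below is deterministic for a seed):

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_extract_kinetics.py --seed 0
python analysis/03_community_dynamics.py --seed 0
python analysis/04_trajectories_and_function.py --seed 0
```

which prints (seed 0):

```
cohort written to results/raw
  lineages by archetype: {'stable': 5, 'drifting': 9, 'successional': 12}
  pH curves: 156; samples incl. T0: 182
extracted parameters for 156 curves
  F1:    lag  9.00 h, MAR -0.625 pH/h, final pH 4.49
  F2-F6: lag  3.31 h, MAR -0.667 pH/h, final pH 4.34
dynamics for 26 lineages; labels: {'stable': 10, 'successional': 15, 'drifting': 1}
  drifting     mean adjacent BC 0.095 (n = 1)
  stable       mean adjacent BC 0.038 (n = 10)
  successional mean adjacent BC 0.204 (n = 15)
  richness T0 65.5 -> F6 3.1
NMDS stress: 0.146
  trajectory length (drifting): 0.50 (n = 1)
  trajectory length (stable): 0.24 (n = 10)
  trajectory length (successional): 0.86 (n = 15)
structure-function: r = 0.344, p = 3.50e-04, n = 104 (BC vs |d final pH|, pooled adjacent pairs)
lag vs LAB%: breakpoint 99.5%, slopes -0.009 / -0.590 h per % (p_right = 0.00119)
```

Reading this: the first spontaneous fermentation starts from a tiny
acidifying population, so its lag (9 h) is roughly three times that of the
re-inoculated steps; raw-milk richness (~65 ASVs) collapses to ~3 surviving
species per lineage; stable lineages barely move between steps (mean
adjacent Bray–Curtis 0.04) while successional lineages — where a
*Lactobacillus*-like acid-tolerant species progressively replaces the
*Lactococcus*-like starter — travel five times further through ordination
space; and pooled over all lineages, the compositional change between two
steps correlates positively with the change in the fermentation's final pH
(r = 0.34): structural stability and functional stability go together.

The same pipeline is exposed as a CLI (`backslop simulate`,
`backslop extract-kinetics`, `backslop dynamics`, `backslop run-all`) for
running on real logger/ASV tables; see `--help` on each subcommand for the
file formats.

## Layout

```
src/backslop/       io_formats, kinetics, community_metrics,
                    trajectory_stats, synthetic_data, pipeline, cli
analysis/           numbered narrative drivers (simulate → kinetics →
                    dynamics → trajectories)
tests/              pytest suite incl. end-to-end acceptance checks
docs/methods.md     model and algorithm documentation
```
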