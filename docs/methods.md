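# Methods

## Model

The network couples 25 metabolite pools (amounts in nmol per g dry
weight) through 32 irreversible reactions covering glycolysis
(glucose-1-phosphate through pyruvate), fermentation (alcohol
dehydrogenase and lactate dehydrogenase branches from pyruvate), the TCA
cycle (citrate synthase through malate dehydrogenase), the GABA shunt
(glutamate → GABA → succinic semialdehyde → succinate) and amino-acid
linkers (alanine and aspartate transaminases, glutamine synthetase,
protein-synthesis sinks). Each reaction follows an irreversible
Michaelis–Menten law with one Km per substrate and multiplicative
saturation,

    v = Vmax · Π_s S_s / (K_s + S_s),

the minimal rate family consistent with a Km/Vmax parameterization.
Substrate-free reactions are constant boundary sources (v = Vmax): one
sucrose-derived influx into G6P and a smaller starch-derived influx into
G1P. The system is open — sources plus quasi-first-order sinks on
terminal amino acids — so no mass-conservation invariant holds or is
asserted. Cofactors (NAD(H), ATP, CoA) are not tracked: the reduction-
ratio statistic depends only on carbon-skeleton pools, and cofactor
balancing would require a thermodynamic treatment that is out of scope,
as are reversible kinetics, enzyme mechanism detail and
compartmentalization.

Consequences of irreversibility worth knowing: a perturbation can only
propagate *downstream* of the modified reaction (plus sideways through
shared substrates), so over-expressing an enzyme lowers its substrate
pool and transiently raises products until downstream capacity absorbs
the extra flux. Upstream effects seen in reversible formulations do not
occur here.

### Packaged soybean network

`data/soybean_network_synthetic.json` carries the flooding-response network
*topology* — 15 modifiable reactions split 8 glycolysis / 1 fermentation
/ 6 TCA (R1 aconitase, R2 isocitrate dehydrogenase, R3 2-oxoglutarate
dehydrogenase, R5 succinate dehydrogenase, R7 malate dehydrogenase, R8
citrate synthase, R11 alcohol dehydrogenase, R14 pyruvate kinase, R18
PEP carboxylase, R25 enolase, R26 phosphoglycerate mutase, R27
phosphoglycerate kinase, R28 GAPDH, R29 aldolase, R32
phosphoglucomutase), 16 fitting-target metabolites, and non-modifiable
linkers on the remaining R-numbers — but its kinetic constants are a
**synthetic parameterization authored here** (no reference constants
are available for this network). They were chosen once, by design, to give
flooding-like behaviour:

- baseline fluxes are balanced near steady state (glycolytic throughput
  ~1000 nmol/g/day after the aldolase doubling, TCA throughput ~160);
- lactate has no consumer and accumulates ~200 nmol/g/day, the hypoxic
  signature;
- consumer enzymes keep capacity headroom (operating amounts at or below
  Km), so perturbation flux is absorbed by sinks rather than piling up
  in downstream pools.

The last property is what makes enzyme over-expression *reduce* average
accumulation, the qualitative behaviour the screen is built around — with
tight downstream capacities the same perturbations inflate product
pools instead.

The "EP" and "LDHi" species sometimes drawn alongside this network
have no documented kinetics and are omitted;
lactate is fed directly by the LDH linker.

## Simulation and the accumulation statistic

Profiles are integrated with LSODA (stiff-capable; Km values span
orders of magnitude) at rtol 1e-6, atol 1e-9, sampled on the day grid
{0, 0.5, …, 4}. Michaelis–Menten rates cannot drive a pool negative,
so only integrator-tolerance-sized negative excursions can occur; they
are clipped to 0 in the output. Integration failure raises an error
carrying the last reached time.

A metabolite's accumulation over the stress window is the trapezoidal
area under its temporal profile (amount·days) on the shared grid; the
**accumulation reduction ratio** of a modification scenario is
AUC(modified)/AUC(unmodified), both areas on identical grids. Enzyme
modification itself is a pure Vmax rescaling (fold > 1 over-expression,
fold < 1 suppression), leaving Km untouched.

## Calibration

Vmax values are calibrated to observed time courses by bounded local
least squares on the sum of squared log10 residuals, pooled over the 16
fitting-target metabolites and the observed days of the flooded
condition (the unstressed condition is display-only). Decision
variables are log10 fold changes relative to the initial Vmax vector,
bounded by [1/50, 50]; by default only the 15 modifiable reactions are
free (linker kinetics are treated as structural), which keeps the
problem well-identified at 64 observation points; `free_reactions`
widens the set when desired. Five seeded multi-start restarts (the
first unperturbed, the rest log-uniform perturbations of the start) are
the default; the final result never scores worse than the starting
vector. Joint fitting is used rather than a per-reaction sweep: the
reactions share intermediates, so single-reaction adjustments are not
separable; a sequential sweep can be emulated by calling `fit_vmax`
with a one-element `free_reactions` list per reaction.

Goodness of fit is r² = squared Pearson correlation of the pooled
log10(simulated) vs log10(observed) pairs — the scatter-plot-with-fit-
line reading, not 1 − SSres/SStot (the two coincide only for a perfect
y = x relation; the correlation form is invariant to a constant
multiplicative bias, which is the conventional reading for this
statistic). r² ≥ 0.95 is the acceptance level for a calibrated model.
Observed amounts must be strictly positive (zeros are rejected at
load); simulated amounts are floored at 1e-9 before the log.

## Modification scan, clustering, screen

The scan applies 4× and 0.25× Vmax to each modifiable reaction in turn
(30 simulations + 1 baseline) and keeps, per (enzyme, metabolite) cell,
the smaller of the two reduction ratios, recording the direction; ties
go to over-expression. Min-selection is per cell, not per row — the
natural reading of "keep whichever direction reduces this metabolite
more".

Both matrix axes are clustered by agglomerative centroid linkage on
Euclidean distances of the raw ratio vectors (no standardization — all
cells share the dimensionless ratio scale; the min-selected matrix is
clustered, not the two fold matrices jointly). Enzyme labels E1…Ek are
assigned in ascending order of group-mean ratio, so E1 is always the
strongest-reducing group. The metabolite tree is cut at k = 4 with the
three largest clusters labelled M1–M3 (same ordering) and smaller
clusters kept as named singletons — the slot a lone metabolite such as
PEP occupies. Effective pairs are cells strictly below 0.9.

The proteomic screen reduces each reaction's abundance series to
time-average ratios over the four post-treatment points only; the
shared 2-day-old baseline of 1 is excluded (including it drags every
average toward 1 and away from the values the screen is defined on).
The candidate filter requires U/F > 1, A/F > 1 and M/F > 1 strictly;
within each enzyme group the filtered reaction with the largest M/F is
kept (ties: larger A/F, then lexicographically smaller id). This
group-maximal rule is an explicit interpretation of "collect effective
enzymes from each group" — the narrowing step is recorded per reaction
in the selection trace, so alternative choices are auditable. The
over-expression fold assigned to a candidate is its M/F truncated (not
rounded) to one decimal: truncation is the only rule consistent with
the conventional fold/ratio pairs 3.23→3.2, 1.81→1.8, 1.67→1.6. The
packaged ratio tables give M/F = 3.22 for R1 and 1.64 for R3,
reproducing the reference folds 3.2 and 1.6; the R28 value derived
from the rounded table cells is 1.57 (fold 1.5) where unrounded source
abundances gave 1.81 — table-derived values are the package's testable
ground truth, and ratios recomputed from rounded cells can differ from
ones computed on unrounded source data.

Protein profile clustering (where needed) uses log2 ratios and the same
centroid/Euclidean choices as the reduction matrix, for internal
consistency.

## Synthetic data

`generate_model` redraws kinetics on a fixed topology: Km log-uniform
over [0.1, 10] × the substrate's initial amount, Vmax log-uniform over
[0.5, 5] × the carbohydrate source flux, sources pinned so the scale is
anchored; everything is deterministic per seed. `generate_profiles`
samples the simulation at days {1, 2, 3, 4} (day 0 is the known initial
state, matching a 1–4-day stress design) and multiplies by lognormal
noise with CV 0.05 by default — metabolite abundances are positive and
fitted on the log scale, so multiplicative noise is the natural model;
the true variance of field data is unknown and 0.05 is a stand-in, one
replicate per time point by default. `generate_protein_table` plants
candidates by construction: planted reactions have each tolerant-like
condition's time-average pinned to an exact factor > 1 of the flooded
average; every non-candidate has its U series forced strictly below the
flooded average, so the filter's positive and negative cases are both
guaranteed. Passing tests on these data show the pipeline's logic and
identifiability, not field realism: real proteomic ratios are noisier,
share no exact baselines, and real metabolite variance is unknown.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 25-pool network
(~5 ms per 4-day integration), 31 simulations per scan, and calibrations
of 15 free parameters against 64 points; the 20-seed noise study uses
one optimiser start per seed (the start equals the generating model, so
restarts add nothing there), while recovery-from-perturbation fits use
two. Degenerate inputs are defined errors, not silent results: zero
baseline AUC (undefined ratio), zero log-variance (undefined r²),
non-positive folds/Km/Vmax, cluster counts exceeding item counts.

## Known limitations

- Irreversible kinetics cannot reproduce upstream accumulation
  reductions; the reduced set under a concurrent scenario is therefore
  dominated by substrates and branch competitors of the modified
  enzymes.
- The packaged parameterization is synthetic; group memberships
  (E1/E3, M1–M3) and the exact reduced set depend on it, so they are
  asserted only on constructed block fixtures and planted-truth data,
  never as reproductions of any external reference memberships.
- Vmax identifiability degrades if linker kinetics are freed jointly
  with the modifiable set (more parameters than informative directions);
  the default keeps linkers fixed.
- SBML export is not provided; the JSON/TOML config schema is the
  interchange format.
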