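# floodmet

Kinetic modelling and in-silico enzyme-modification screening of soybean
central carbon metabolism under flooding stress.

Flooding starves soybean seedling roots of oxygen; glycolysis,
fermentation and the TCA cycle respond with broad metabolite
accumulation. A practical question for breeding flood-tolerant lines is
*which enzymes, if over- or under-expressed, would most effectively damp
that accumulation*. `floodmet` answers it with a small, fully testable
pipeline:

1. **Kinetic network model.** Metabolite pools (nmol/g dry weight)
   coupled by irreversible Michaelis–Menten reactions,
   `v = Vmax · Π_s S_s/(K_s + S_s)`, spanning glycolysis, fermentation,
   the TCA cycle and the GABA shunt, with a constant carbohydrate source
   and first-order amino-acid sinks. Profiles are integrated over 0–4
   days after stress onset (LSODA, rtol 1e-6 / atol 1e-9).
2. **Vmax calibration.** Enzyme `Vmax` values are fitted so simulated
   fitting-target metabolites match observed time courses; agreement is
   scored as r² of log10(simulated) vs log10(observed) pooled over the 16
   target metabolites and all days, with r² ≥ 0.95 the acceptance level.
3. **Genetic modification effectiveness analysis.** Every modifiable
   enzyme is virtually over-expressed (4× Vmax) and suppressed (0.25×);
   each metabolite's *accumulation reduction ratio* = AUC(modified
   profile)/AUC(unmodified profile) is tabulated (per cell the smaller of
   the two directions is kept), the 15×16 matrix is clustered
   (centroid linkage, Euclidean distance) into enzyme groups E1–E3 and
   metabolite groups, and cells below 0.9 are flagged as effective
   enzyme–metabolite pairs.
4. **Proteomic screen.** Per-reaction protein abundance ratios (vs a
   2-day-old unstressed baseline) in four conditions — U unstressed,
   F flooded wild type, A ABA-treated flooded, M flood-tolerant mutant —
   are reduced to time-average ratios U/F, A/F, M/F. Reactions with all
   three > 1 (protein maintained in every tolerant-like condition) are
   candidates; at most one per enzyme group is kept (largest M/F), and
   its over-expression fold is M/F truncated to one decimal.
5. **Concurrent modification.** All candidate folds are applied in a
   single simulation; the report lists per-metabolite reduction ratios,
   the reduced set (< 1), their mean over the 16 targets and the effect
   `1 − mean`.

A synthetic-data module generates seeded ground-truth models, noisy
observed time courses (multiplicative lognormal noise) and protein
tables with planted candidates, so the whole pipeline is exercised
end-to-end without any downloads. The packaged soybean network
(`floodmet/data/soybean_network_synthetic.json`) carries the
flooding-response topology with a synthetic kinetic parameterization;
the packaged protein ratio tables hold measured per-reaction abundance
ratios from flooded soybean seedlings.

## Worked example

```python
import floodmet as fm
from floodmet.io import packaged_protein_table

model = fm.build_model(fm.soybean_network())          # 25 pools, 32 reactions
observed = fm.generate_profiles(model, fm.SyntheticSpec(seed=1, noise_cv=0.05))
fit = fm.fit_vmax(model, observed, seed=1, n_restarts=2)
print(f"r2 = {fit.r2:.4f}")                         # r2 = 0.9985

matrix = fm.modification_scan(fit.fitted_model)     # 15 x 16 reduction ratios
grouping = fm.cluster_groups(matrix)                # E1..E3 + metabolite groups
ratios = fm.time_average_ratios(packaged_protein_table())
candidates = fm.select_candidates(ratios, grouping)
print(candidates.members)
# [('R18', 'E1', 1.6), ('R1', 'E2', 3.2), ('R2', 'E3', 3.1)]

report = fm.concurrent_modification(fit.fitted_model, candidates)
print(f"average reduction ratio {report.average_reduction_ratio:.3f}, "
      f"{len(report.reduced_set)} of 16 metabolites reduced")
# average reduction ratio 0.890, 6 of 16 metabolites reduced
```

The r² of 0.9985 says the calibrated model reproduces the (synthetic)
flooded time courses on the log scale. The candidate list pairs each
selected enzyme with its cluster group and the over-expression fold
taken from its M/F protein ratio (aconitase R1 → 3.2 from the packaged
tables); which enzyme wins each group depends on the clustering of the
calibrated model. An average concurrent reduction ratio below
1 means the combined over-expression lowers total metabolite
accumulation over the 4-day flooding window.

The same stages are available from a shell:

```sh
floodmet run --seed 1 --out-dir run/          # full pipeline + manifest
floodmet scan --out matrix.csv                # reduction-ratio matrix
floodmet synth --network toy --seed 1 --out-dir synth/
```

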