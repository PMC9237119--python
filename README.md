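# droughtmark

Selecting efficient drought-phenotyping markers in contrasting soybean
genotypes.

Breeding for drought tolerance needs phenotyping markers that are (i)
accurate across phenological stages, (ii) cheap and easy to score, and (iii)
strongly tied to the phenotypic variability that separates tolerant from
susceptible material. `droughtmark` implements, as a tested Python library,
the full marker-selection analysis for a trial of two contrasting soybean
genotypes (drought-tolerant MUNASQA, susceptible TJ2049) under mild water
deficit at the V3 (vegetative) and R5 (seed-fill) stages:

* **Synthetic trial regeneration** — the published record of the trial is a
  set of per-cell means and standard errors (n = 10 plants per genotype ×
  treatment × stage × sampling day). The generator redraws replicate-level
  data around those means with SD = SE·√n, and inverts the index formulas to
  emit raw primitives (weights, areas, water, temperatures), so every
  downstream stage is testable with no external data.
* **Phenotyping indices** — functional growth analysis
  (RGR = Δln W/Δt, NAR = (ΔW/Δt)(Δln A/ΔA), CGR = ΔW/(GA·Δt), LAI = A/GA,
  LAR = A/W), water status (RWC = 100(FW−DW)/(TW−DW), WUE = W/water,
  CTD = T_air − T_canopy) and the Fischer–Maurer drought susceptibility
  index DSI_g = (1 − Ys_g/Yp_g)/D with D = 1 − Xs/Xp.
* **Univariate statistics** — group summaries with one-way ANOVA + Tukey HSD
  compact letter displays in the tables' dual-letter convention (uppercase
  compares genotype × treatment groups within a DAS column, lowercase
  compares sampling days within a group row), and two-way ANOVA.
* **Stage-accuracy screening** — Pearson correlation of each marker's V3
  stream against its R5 stream, Bonferroni-adjusted over the screen family,
  classified Strong (|r| ≥ 0.60) or Weak.
* **Grouped PCAs** — standardized PCA per biological-process marker set
  (stress-response, growth, water-use), exposing variance-explained
  percentages and the loading vectors e1, e2.
* **The CF × SW rubric** — cost-feasibility categories (1 easy/cheap … 4
  complicated/expensive) keep the nine practical markers; High/Low
  statistical weights on PC1 and PC2 reselect the four markers that also
  dominate the variability: abaxial/adaxial stomatal density, abaxial
  trichome density and canopy temperature depression.

## Worked example

```python
from droughtmark import PipelineConfig, render_selection_table, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=1))
for name, res in bundle["pcas"].items():
    print(f"PCA {name}: PC1+PC2 = {res.pc_variance(2):.1f}%")
print(render_selection_table(bundle["selection"]).to_string(index=False))
```

prints

```
PCA stress-response: PC1+PC2 = 98.1%
PCA growth: PC1+PC2 = 97.3%
PCA water-use-physiological: PC1+PC2 = 90.1%
PCA water-use-morphological: PC1+PC2 = 96.6%
 CF Marker SW PC1 SW PC2 Sel
  1    LAI   High    Low   -
  1    WUE   High    Low   -
  2    MDA    Low   High   -
  2    CAR   High    Low   -
  2    CTD   High   High Sel
  2  TD_AB   High   High Sel
  2  TD_AD   High    Low   -
  2  SD_AB   High   High Sel
  2  SD_AD   High   High Sel
```

Each grouped PCA concentrates nearly all variance on its first two
components (pooling all 22 markers in one PCA yields a diffuse ~54–78%
depending on the observation unit), and the rubric keeps exactly the four
markers that are both cheap to score and High-weight on both components.
The `examples/` directory holds one short script per capability
(simulation, indices, screening, PCA, selection, full pipeline).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the stress-response marker data from the shipped cell
parameters (20 independent seeds derived from `--seed`), fits the
standardized group-mean PCA and reports the mean percentage of variance
carried by the first two components.
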