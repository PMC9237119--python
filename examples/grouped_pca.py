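"""Biological-process-grouped PCAs.

Pooling all 22 markers in one PCA dilutes the variance over many components;
running one standardized PCA per biological-process set (stress-response,
growth, water-use physiological / morphological) concentrates it on the first
two components, whose loading vectors (e1, e2) feed the statistical-weight
labels used in marker selection.
"""
from droughtmark import (all_markers_pca, build_default_design,
                         generate_measurements, generate_yield, grouped_pca,
                         load_cell_parameters, load_marker_registry)

design = build_default_design(seed=1)
params = load_cell_parameters()
registry = load_marker_registry()
tab = generate_measurements(design, params, registry)

full = all_markers_pca(tab, registry, yields=generate_yield(design),
                       obs_mode="cell-means")
print(f"all markers + yield (cell means): "
      f"PC1+PC2 = {full.pc_variance(2):.1f}% of variance (diffuse)")
print()
for name, subset in [("stress-response", None), ("growth", None),
                     ("water-use physiological", ("RWC", "WUE", "CTD")),
                     ("water-use morphological",
                      ("LT", "TD_AB", "TD_AD", "SD_AB", "SD_AD"))]:
    res = grouped_pca(tab, registry, name.split()[0] if " " not in name
                      else "water-use", markers=subset)
    v = res.variance_explained
    print(f"{name:26s} PC1 = {v[0]:5.1f}%  PC2 = {v[1]:5.1f}%  "
          f"PC1+PC2 = {v[0] + v[1]:5.1f}%")
print()
res = grouped_pca(tab, registry, "stress-response")
print("stress-response loadings (e1, e2):")
print(res.loadings[["e1", "e2"]].round(3).to_string())
# A large |coefficient| means the marker drives that component's separation
# of the genotype x treatment groups.
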