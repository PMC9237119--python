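"""The cost-feasibility x statistical-weight selection rubric.

CF categories (1 easy/cheap ... 4 complicated/expensive) first keep the nine
markers practical for a breeding program; the published High/Low statistical
weights on PC1 and PC2 then reselect the markers that also dominate the
phenotypic variability.
"""
from droughtmark import (cf_filter, load_marker_registry,
                         render_selection_table,
                         select_with_published_labels)

registry = load_marker_registry()
passing = cf_filter(registry)
print(f"CF filter (categories 1-2): {len(passing)} of {len(registry)} markers")
print(", ".join(passing["marker"]))
print()
result = select_with_published_labels(registry)
print(render_selection_table(result).to_string(index=False))
print()
print(f"selected ({len(result.selected)}): {', '.join(result.selected)}")
# The four Sel markers are cheap/easy to score AND carry High weight on both
# leading components: abaxial/adaxial stomatal density, abaxial trichome
# density and canopy temperature depression.
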