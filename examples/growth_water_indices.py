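"""Compute the growth and water-use indices and yield-based DSI by hand.

A small worked set of primitive measurements for one plant stand, pushed
through each index, plus the drought susceptibility index for a two-genotype
trial.
"""
from droughtmark import (GrowthInterval, WaterStatus, compute_cgr, compute_ctd,
                         compute_dsi, compute_lai, compute_lar, compute_nar,
                         compute_rgr, compute_rwc, compute_wue)

# one growth interval: 0 -> 4 days, biomass 2 -> 4 g, leaf area 300 -> 500 cm2
iv = GrowthInterval(t1=0, t2=4, W1=2.0, W2=4.0, A1=300.0, A2=500.0, GA=400.0)
print(f"RGR = {compute_rgr(iv):.4f} g g-1 day-1   (log-biomass gain per day)")
print(f"NAR = {compute_nar(iv):.6f} g cm-2 day-1 (biomass gain per leaf area)")
print(f"CGR = {compute_cgr(iv):.6f} g cm-2 day-1 (biomass gain per ground area)")
print(f"LAI = {compute_lai(500.0, 400.0):.3f}            (leaf area per ground area)")
print(f"LAR = {compute_lar(500.0, 4.0):.1f} cm2 g-1     (leaf area per biomass)")

# leaf water status: fresh 80 g, turgid 100 g, dry 20 g
ws = WaterStatus(FW=80.0, TW=100.0, DW=20.0)
print(f"RWC = {compute_rwc(ws):.1f} %            (fraction of full turgor)")
print(f"WUE = {compute_wue(4.0, 0.8):.2f} g kg-1       (biomass per kg water)")
print(f"CTD = {compute_ctd(25.0, 26.32):.2f} degC        "
      "(negative: canopy warmer than air, stomata closed)")

# DSI: susceptible genotype loses 50%, tolerant 30%; trial-wide loss D = 0.4
dsi = compute_dsi({"susceptible": (5.0, 10.0), "tolerant": (7.0, 10.0)})
print(f"DSI susceptible = {dsi['susceptible']:.2f}, "
      f"tolerant = {dsi['tolerant']:.2f}  (>1 = less stable than trial mean)")
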