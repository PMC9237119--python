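"""Synthetic regeneration of the phenotyping trial.

The published record of the trial is a set of cell means and standard errors
(n = 10 replicate plants per cell), so the generator draws independent normal
replicates around each cell mean with SD = SE * sqrt(n) — the inverse of the
reporting convention.  Three tables are produced:

* a tidy replicate-level marker table (one row per plant x marker),
* a primitive-trait table (weights, areas, water, temperatures) constructed
  by inverting the index formulas so that indices recomputed from the
  primitives recover the target cell means (exactly at zero noise),
* a per-plant yield table over the control / V3-stress / R5-stress arms.

Values that are physically nonnegative are floored at a small positive value
after sampling; truncation events are logged.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import StudyDesign
from .parameters import RATE_MARKERS, check_covers_design

logger = logging.getLogger("droughtmark")

#: markers that may legitimately be negative (temperature depressions and
#: interval rates); everything else is floored at POSITIVE_FLOOR
SIGNED_MARKERS = ("CTD", "NAR", "RGR", "CGR")
POSITIVE_FLOOR = 1e-6

#: fixed stand geometry and environment used when inverting the index math
GROUND_AREA_CM2 = 400.0          # pot spacing per plant
DRY_MATTER_OF_TURGID = 0.30      # DW / TW of the sampled leaf material
AIR_TEMP_BY_STAGE = {"V3": 25.0, "R5": 28.0}  # degC at sampling

#: default per-plant yield parameters (g): mean, SD per genotype x arm.
#: Per-plant yields were never published; these are realistic greenhouse
#: soybean yields with the susceptible genotype (TJ2049) losing more under
#: stress than the tolerant one (MUNASQA), so DSI orders as published.
DEFAULT_YIELD_PARAMS = {
    ("MUNASQA", "control"): (21.0, 3.2),
    ("MUNASQA", "V3-stress"): (17.2, 2.6),
    ("MUNASQA", "R5-stress"): (15.1, 2.3),
    ("TJ2049", "control"): (24.0, 3.6),
    ("TJ2049", "V3-stress"): (15.6, 2.3),
    ("TJ2049", "R5-stress"): (10.8, 1.6),
}

MEASUREMENT_COLUMNS = ["plant_id", "genotype", "treatment", "stage", "das",
                       "marker", "value", "units"]


def _sorted_params(params: pd.DataFrame) -> pd.DataFrame:
    return params.sort_values(
        ["marker", "genotype", "treatment", "stage", "das"], kind="stable")


def generate_measurements(design: StudyDesign, params: pd.DataFrame,
                          registry: pd.DataFrame | None = None,
                          check_coverage: bool = False) -> pd.DataFrame:
    """Draw replicate-level marker values for every parameterized cell.

    Each cell-parameter row yields ``n`` replicates (its own ``n`` if given,
    else ``design.replicates_per_cell``) from N(mean, (SE*sqrt(n))^2).
    Deterministic for a fixed ``design.seed``.
    """
    if check_coverage:
        core = [m for m in params["marker"].unique()
                if set(params.loc[params["marker"] == m, "das"])
                >= set(design.sampling_days) - ({min(design.sampling_days)}
                                                if m in RATE_MARKERS else set())]
        check_covers_design(params, design, markers=core)
    units = registry["units"] if registry is not None else {}
    rng = np.random.default_rng(design.seed)
    rows = []
    n_trunc = 0
    for _, p in _sorted_params(params).iterrows():
        n = int(p["n"]) if ("n" in p and pd.notna(p["n"]) and p["n"] != "") \
            else design.replicates_per_cell
        sd = float(p["se"]) * np.sqrt(n)
        vals = p["mean"] + sd * rng.standard_normal(n)
        if p["marker"] not in SIGNED_MARKERS:
            low = vals < POSITIVE_FLOOR
            n_trunc += int(low.sum())
            vals = np.where(low, POSITIVE_FLOOR, vals)
        for i, v in enumerate(vals, start=1):
            rows.append((f"{p['genotype']}-{p['treatment']}-{p['stage']}-"
                         f"{p['das']}-r{i:02d}", p["genotype"], p["treatment"],
                         p["stage"], int(p["das"]), p["marker"], float(v),
                         units.get(p["marker"], "") if len(units) else ""))
    if n_trunc:
        logger.info("generate_measurements: floored %d negative draws", n_trunc)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


PRIMITIVE_COLUMNS = ["plant_id", "genotype", "treatment", "stage", "das",
                     "FW", "TW", "DW", "A", "GA", "water_applied",
                     "T_air", "T_canopy"]

_PRIMITIVE_TARGETS = ("RWC", "WUE", "CTD", "LAI", "LAR")


def generate_primitives(design: StudyDesign, params: pd.DataFrame) -> pd.DataFrame:
    """Emit raw primitives (weights, areas, water, temperatures) per plant.

    Per replicate, target values for RWC, WUE, CTD, LAI and LAR are sampled
    from their cell parameters and the index formulas are inverted:

    * A  = LAI * GA (fixed ground area per plant),
    * DW = A / LAR (plant dry biomass),
    * TW = DW / 0.3, FW = DW + RWC/100 * (TW - DW),
    * water_applied = DW / WUE,
    * T_canopy = T_air - CTD.

    At zero SE the recomputed indices equal the cell means exactly.  Raises
    on infeasible targets (RWC mean outside (0, 100], nonpositive LAI/LAR/WUE
    means); noisy draws are clipped into the feasible region with a log note.
    """
    sub = params[params["marker"].isin(_PRIMITIVE_TARGETS)]
    have = set(sub["marker"])
    if have != set(_PRIMITIVE_TARGETS):
        raise ValueError("primitive generation needs parameters for "
                         f"{sorted(set(_PRIMITIVE_TARGETS) - have)}")
    wide = sub.pivot_table(index=["genotype", "treatment", "stage", "das"],
                           columns="marker", values="mean")
    se = sub.pivot_table(index=["genotype", "treatment", "stage", "das"],
                         columns="marker", values="se")
    bad = wide[(wide["RWC"] > 100) | (wide["RWC"] <= 0)]
    if len(bad):
        raise ValueError(f"infeasible RWC target(s): {bad['RWC'].tolist()} "
                         f"at {list(bad.index)}")
    for m in ("LAI", "LAR", "WUE"):
        if (wide[m] <= 0).any():
            raise ValueError(f"infeasible nonpositive {m} target")
    rng = np.random.default_rng(design.seed + 1)
    n = design.replicates_per_cell
    rows = []
    n_clip = 0
    for key in sorted(wide.index):
        g, t, s, d = key
        draws = {}
        for m in _PRIMITIVE_TARGETS:
            sd = se.loc[key, m] * np.sqrt(n)
            draws[m] = wide.loc[key, m] + sd * rng.standard_normal(n)
        rwc = draws["RWC"]
        clip = (rwc <= 0) | (rwc > 100)
        n_clip += int(clip.sum())
        rwc = np.clip(rwc, 0.1, 100.0)
        for m in ("LAI", "LAR", "WUE"):
            clip = draws[m] < POSITIVE_FLOOR
            n_clip += int(clip.sum())
            draws[m] = np.maximum(draws[m], POSITIVE_FLOOR)
        A = draws["LAI"] * GROUND_AREA_CM2
        DW = A / draws["LAR"]
        TW = DW / DRY_MATTER_OF_TURGID
        FW = DW + rwc / 100.0 * (TW - DW)
        water = DW / draws["WUE"]
        t_air = AIR_TEMP_BY_STAGE.get(s, 25.0)
        t_canopy = t_air - draws["CTD"]
        for i in range(n):
            rows.append((f"{g}-{t}-{s}-{d}-r{i + 1:02d}", g, t, s, int(d),
                         float(FW[i]), float(TW[i]), float(DW[i]), float(A[i]),
                         GROUND_AREA_CM2, float(water[i]), t_air,
                         float(t_canopy[i])))
    if n_clip:
        logger.info("generate_primitives: clipped %d infeasible draws", n_clip)
    return pd.DataFrame(rows, columns=PRIMITIVE_COLUMNS)


def generate_yield(design: StudyDesign, yield_params=None,
                   seed: int | None = None) -> pd.DataFrame:
    """Per-plant yield table over the control and stress arms (n = 300 default).

    ``yield_params`` maps (genotype, arm) -> (mean_g, sd_g); defaults to
    :data:`DEFAULT_YIELD_PARAMS` restricted to the design's genotypes/arms.
    """
    if yield_params is None:
        yield_params = {k: v for k, v in DEFAULT_YIELD_PARAMS.items()
                        if k[0] in design.genotypes and k[1] in design.yield_arms}
    for (g, a), (mean, sd) in yield_params.items():
        if mean <= 0:
            raise ValueError(f"non-positive yield mean for ({g}, {a})")
        if sd < 0:
            raise ValueError(f"negative yield SD for ({g}, {a})")
    rng = np.random.default_rng(design.seed + 2 if seed is None else seed)
    rows = []
    for g in design.genotypes:
        for arm in design.yield_arms:
            if (g, arm) not in yield_params:
                raise ValueError(f"no yield parameters for ({g}, {arm})")
            mean, sd = yield_params[(g, arm)]
            vals = mean + sd * rng.standard_normal(design.yield_plants_per_arm)
            vals = np.maximum(vals, POSITIVE_FLOOR)
            for i, v in enumerate(vals, start=1):
                rows.append((f"{g}-{arm}-p{i:03d}", g, arm, float(v)))
    return pd.DataFrame(rows, columns=["plant_id", "genotype", "arm", "yield_g"])
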