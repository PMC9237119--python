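"""Functional growth analysis and water-status indices, plus yield-based
drought susceptibility.

The growth indices are the classical ones: over an interval (t1, t2) with
total dry biomass W1 -> W2, total leaf area A1 -> A2 and ground area GA,

    RGR = (ln W2 - ln W1) / (t2 - t1)                [g g-1 day-1]
    NAR = (W2 - W1)/(t2 - t1) * (ln A2 - ln A1)/(A2 - A1)   [g cm-2 day-1]
    CGR = (W2 - W1) / (GA * (t2 - t1))               [g cm-2 day-1]
    LAI = A / GA,   LAR = A / W

Water status:

    RWC = 100 * (FW - DW) / (TW - DW)                [%]
    WUE = dry biomass / water applied                [g kg-1]
    CTD = T_air - T_canopy                           [degC]

CTD is positive when the canopy is cooler than the air (stomata open,
transpiring) and negative when it is warmer (stomata closed under stress).

The drought susceptibility index (DSI) normalizes a genotype's relative
yield loss by the trial-wide stress intensity D:

    DSI_g = (1 - Ys_g / Yp_g) / D,   D = 1 - Xs / Xp

where Ys/Yp are the genotype's stressed/potential mean yields and Xs/Xp the
corresponding trial-wide means over all genotypes.  DSI < 1 flags yield more
stable than the trial average (tolerance), DSI > 1 more susceptible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class GrowthInterval:
    """Biomass/leaf-area bookends of one growth interval of one plant stand."""

    t1: float
    t2: float
    W1: float
    W2: float
    A1: float
    A2: float
    GA: float

    def __post_init__(self) -> None:
        if self.t2 <= self.t1:
            raise ValueError("t2 must exceed t1")
        for name in ("W1", "W2", "A1", "A2", "GA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WaterStatus:
    """Leaf water fractions, cumulative water applied, canopy/air temperature."""

    FW: float
    TW: float
    DW: float
    water_applied: float = math.nan
    T_air: float = math.nan
    T_canopy: float = math.nan


@dataclass(frozen=True)
class YieldPair:
    """Per-genotype stressed/potential mean yields plus the trial-wide means."""

    Y_stress: float
    Y_potential: float
    X_stress: float
    X_potential: float


def compute_rwc(ws: WaterStatus) -> float:
    """Relative water content in percent: 100 (FW - DW)/(TW - DW)."""
    if ws.TW == ws.DW:
        raise ValueError("turgid and dry weight coincide; RWC undefined")
    return 100.0 * (ws.FW - ws.DW) / (ws.TW - ws.DW)


def compute_wue(biomass_g: float, water_kg: float) -> float:
    """Water use efficiency: dry biomass (g) per water applied (kg)."""
    if water_kg <= 0:
        raise ValueError("water applied must be positive")
    return biomass_g / water_kg


def compute_ctd(T_air: float, T_canopy: float) -> float:
    """Canopy temperature depression: air minus canopy temperature (degC)."""
    return T_air - T_canopy


def compute_lai(A: float, GA: float) -> float:
    """Leaf area index: total leaf area per ground area."""
    if GA <= 0:
        raise ValueError("ground area must be positive")
    return A / GA


def compute_lar(A: float, W: float) -> float:
    """Leaf area ratio: leaf area per unit dry biomass (cm2 g-1)."""
    if W <= 0:
        raise ValueError("biomass must be positive")
    return A / W


def compute_rgr(iv: GrowthInterval) -> float:
    """Relative growth rate: mean log-biomass gain per day."""
    return (math.log(iv.W2) - math.log(iv.W1)) / (iv.t2 - iv.t1)


def compute_nar(iv: GrowthInterval) -> float:
    """Net assimilation rate: biomass gain per leaf area per day.

    The leaf-area weighting uses the log-mean area; when A1 == A2 the formula
    degenerates to (W2 - W1)/(A1 (t2 - t1)), its analytic limit.
    """
    dWdt = (iv.W2 - iv.W1) / (iv.t2 - iv.t1)
    if iv.A1 == iv.A2:
        return dWdt / iv.A1
    return dWdt * (math.log(iv.A2) - math.log(iv.A1)) / (iv.A2 - iv.A1)


def compute_cgr(iv: GrowthInterval) -> float:
    """Crop growth rate: biomass gain per ground area per day."""
    return (iv.W2 - iv.W1) / (iv.GA * (iv.t2 - iv.t1))


def compute_dsi(genotype_yields: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Drought susceptibility index per genotype.

    Parameters
    ----------
    genotype_yields : mapping genotype -> (Y_stress, Y_potential)
        Mean yield under stress and under the well-watered control.

    Returns
    -------
    dict genotype -> DSI.  The trial stress intensity D is computed from the
    across-genotype mean yields; the Yp-weighted mean DSI is 1 by construction.
    """
    if not genotype_yields:
        raise ValueError("no genotypes supplied")
    for g, (ys, yp) in genotype_yields.items():
        if ys < 0 or yp <= 0:
            raise ValueError(f"invalid yields for {g}: ({ys}, {yp})")
    xs = sum(v[0] for v in genotype_yields.values()) / len(genotype_yields)
    xp = sum(v[1] for v in genotype_yields.values()) / len(genotype_yields)
    D = 1.0 - xs / xp
    if D == 0:
        raise ValueError("stress intensity D = 0: trial shows no yield loss")
    return {g: (1.0 - ys / yp) / D for g, (ys, yp) in genotype_yields.items()}


def percent_change(reference: float, observed: float) -> float:
    """Percent change of ``observed`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (observed - reference) / reference


# ---------------------------------------------------------------------------
# table-level computation on the primitives schema

def indices_from_primitives(primitives) -> "pd.DataFrame":
    """Compute per-plant point indices (RWC, WUE, CTD, LAI, LAR) from a
    primitive-trait table and return them in the tidy marker-value schema.

    Expects the columns plant_id, genotype, treatment, stage, das, FW, TW,
    DW, A, GA, water_applied, T_air, T_canopy.
    """
    import pandas as pd

    out = []
    for _, r in primitives.iterrows():
        ws = WaterStatus(FW=r["FW"], TW=r["TW"], DW=r["DW"])
        vals = {
            "RWC": compute_rwc(ws),
            "WUE": compute_wue(r["DW"], r["water_applied"]),
            "CTD": compute_ctd(r["T_air"], r["T_canopy"]),
            "LAI": compute_lai(r["A"], r["GA"]),
            "LAR": compute_lar(r["A"], r["DW"]),
        }
        for marker, v in vals.items():
            out.append((r["plant_id"], r["genotype"], r["treatment"],
                        r["stage"], int(r["das"]), marker, float(v), ""))
    return pd.DataFrame(out, columns=["plant_id", "genotype", "treatment",
                                      "stage", "das", "marker", "value", "units"])


def growth_rates_from_primitives(primitives) -> "pd.DataFrame":
    """Interval growth rates (RGR, NAR, CGR) from per-cell mean trajectories.

    Rates are computed over consecutive sampling-day intervals per genotype x
    treatment x stage and assigned to the interval's right endpoint, so a
    0/4/8-DAS trajectory yields rates at 4 and 8 DAS and none at 0 DAS.
    """
    import pandas as pd

    cell = (primitives.groupby(["genotype", "treatment", "stage", "das"])
            [["DW", "A", "GA"]].mean().reset_index())
    out = []
    for (g, t, s), traj in cell.groupby(["genotype", "treatment", "stage"]):
        traj = traj.sort_values("das")
        rows = traj.to_dict("records")
        for prev, cur in zip(rows, rows[1:]):
            iv = GrowthInterval(t1=prev["das"], t2=cur["das"],
                                W1=prev["DW"], W2=cur["DW"],
                                A1=prev["A"], A2=cur["A"], GA=cur["GA"])
            for marker, fn in (("RGR", compute_rgr), ("NAR", compute_nar),
                               ("CGR", compute_cgr)):
                out.append((f"{g}-{t}-{s}-{cur['das']}", g, t, s,
                            int(cur["das"]), marker, float(fn(iv)), ""))
    return pd.DataFrame(out, columns=["plant_id", "genotype", "treatment",
                                      "stage", "das", "marker", "value", "units"])


def dsi_from_yield_table(yields, stress_arm: str,
                         control_arm: str = "control") -> dict[str, float]:
    """DSI per genotype from a per-plant yield table for one stress arm."""
    means = yields.groupby(["genotype", "arm"])["yield_g"].mean()
    pairs = {}
    for g in sorted(yields["genotype"].unique()):
        pairs[g] = (means[(g, stress_arm)], means[(g, control_arm)])
    return compute_dsi(pairs)
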