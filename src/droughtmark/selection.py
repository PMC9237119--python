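"""The marker-selection rubric: cost-feasibility (CF) filtering, statistical-
weight (SW) labelling of PCA loadings, and their intersection.

A marker is selected as an efficient breeding/phenotyping marker when it is
cheap or easy to measure (CF category 1 or 2) AND carries High statistical
weight on both of the first two principal components of its biological-
process PCA.

The published SW scale "[-2, 2]" cannot apply to raw unit-norm loading
coefficients (bounded by 1 in magnitude), so the transform from loadings to
the labelled scale is pluggable:

* ``zscore`` (default): standardize each component's coefficients across
  markers; High iff |z| > threshold.
* ``rank`` : rank-based robust score (coefficient - median)/(1.4826 * MAD);
  High iff |score| > threshold.  (A literal rank-then-z-score transform is
  bounded by sqrt(3) < 2 for any number of markers and can never produce a
  High call at the default threshold; see docs/methods.md.)
* ``external``: pass through published High/Low calls unchanged, recording
  their provenance.  The shipped fixture carries the published calls for the
  nine CF-passing markers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import load_sw_labels

TRANSFORMS = ("zscore", "rank", "external")


@dataclass(frozen=True)
class SWLabel:
    """High/Low statistical-weight call for one marker on one component."""

    marker: str
    pc: int
    label: str
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.label not in ("High", "Low"):
            raise ValueError(f"SW label must be High or Low, got {self.label!r}")
        if self.pc not in (1, 2):
            raise ValueError("SW labels are defined on PC1 and PC2")


@dataclass
class SelectionResult:
    """Per-marker CF category, SW labels and the boolean selection."""

    table: pd.DataFrame                      # marker, cf, sw_pc1, sw_pc2, selected
    provenance: dict = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "marker"].tolist()


def cf_filter(registry: pd.DataFrame) -> pd.DataFrame:
    """Markers with CF category 1 (easy/cheap) or 2 (easy/expensive).

    Order-stable: rows keep their registry order.
    """
    return registry[registry["cf"].isin((1, 2))].copy()


def classify_sw(loadings: pd.Series, pc: int, transform: str = "zscore",
                threshold: float = 2.0,
                external_labels: pd.Series | None = None) -> list[SWLabel]:
    """Label each marker High or Low on one component.

    ``loadings`` is the component's coefficient vector indexed by marker
    (e.g. ``result.loadings["e1"]``).  High iff the transformed score falls
    outside [-threshold, threshold].
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; "
                         f"expected one of {TRANSFORMS}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if transform == "external":
        if external_labels is None:
            raise ValueError("external transform needs external_labels")
        missing = set(loadings.index) - set(external_labels.index)
        if missing:
            raise ValueError(f"no external SW label for: {sorted(missing)}")
        return [SWLabel(m, pc, str(external_labels[m])) for m in loadings.index]
    if len(loadings) < 2:
        raise ValueError("need loadings for at least two markers")
    vals = loadings.astype(float)
    if transform == "zscore":
        sd = vals.std(ddof=1)
        scores = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
    else:  # rank-based robust score
        med = vals.median()
        mad = (vals - med).abs().median()
        if mad > 0:
            scores = (vals - med) / (1.4826 * mad)
        else:  # degenerate spread: fall back to the z-score
            sd = vals.std(ddof=1)
            scores = (vals - med) / sd if sd > 0 else vals * 0.0
    return [SWLabel(m, pc, "High" if abs(s) > threshold else "Low", float(s))
            for m, s in scores.items()]


def select_markers(registry: pd.DataFrame, sw_pc1: list[SWLabel],
                   sw_pc2: list[SWLabel],
                   provenance: dict | None = None) -> SelectionResult:
    """Apply the full rubric: CF in {1, 2} AND High on PC1 AND High on PC2.

    ``sw_pc1``/``sw_pc2`` must cover every CF-passing marker; a missing label
    raises.  Deterministic and order-stable.
    """
    pc1 = {l.marker: l.label for l in sw_pc1}
    pc2 = {l.marker: l.label for l in sw_pc2}
    passing = cf_filter(registry)
    missing = [m for m in passing["marker"] if m not in pc1 or m not in pc2]
    if missing:
        raise ValueError(f"SW label missing for CF-passing markers: {missing}")
    rows = []
    for _, r in passing.iterrows():
        m = r["marker"]
        sel = pc1[m] == "High" and pc2[m] == "High"
        rows.append({"marker": m, "cf": int(r["cf"]), "sw_pc1": pc1[m],
                     "sw_pc2": pc2[m], "selected": sel})
    table = pd.DataFrame(rows)
    return SelectionResult(table=table, provenance=dict(provenance or {}))


def select_with_published_labels(registry: pd.DataFrame,
                                 labels: pd.DataFrame | None = None) -> SelectionResult:
    """Run the rubric with the published SW calls (the default pipeline path)."""
    if labels is None:
        labels = load_sw_labels()
    passing = cf_filter(registry)
    mk = passing["marker"]
    sw1 = classify_sw(pd.Series(np.nan, index=mk), 1, "external",
                      external_labels=labels["sw_pc1"])
    sw2 = classify_sw(pd.Series(np.nan, index=mk), 2, "external",
                      external_labels=labels["sw_pc2"])
    return select_markers(registry, sw1, sw2,
                          provenance={"sw_source": "published labels",
                                      "transform": "external"})
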