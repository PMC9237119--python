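"""Marker registry: the 22 phenotyping markers, their biological-process sets
and cost-feasibility (CF) categories.

CF encodes lab economics, not computation: 1 = easy and cheap, 2 = easy and
expensive, 3 = complicated and cheap, 4 = complicated and expensive.  The
shipped default registry covers the three biological-process sets
(stress-response, growth, water-use) and reproduces the published CF
assignments for the nine markers that pass the CF filter.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

BP_SETS = ("stress-response", "growth", "water-use")
CF_CATEGORIES = (1, 2, 3, 4)


@dataclass(frozen=True)
class MarkerSpec:
    """Registry entry for one phenotyping marker."""

    name: str
    bp_set: str
    units: str
    cf: int
    subgroup: str = ""
    long_name: str = ""

    def __post_init__(self) -> None:
        if self.bp_set not in BP_SETS:
            raise ValueError(f"unknown biological-process set: {self.bp_set!r}")
        if self.cf not in CF_CATEGORIES:
            raise ValueError(f"CF category must be in {CF_CATEGORIES}, got {self.cf}")


def _data_path(name: str):
    return resources.files("droughtmark") / "data" / name


def load_marker_registry(source=None) -> pd.DataFrame:
    """Load a marker registry table (default: the shipped 22-marker registry).

    Parameters
    ----------
    source : path-like, file-like or None
        Delimiter-separated table with columns ``marker, bp_set, subgroup,
        units, cf`` (extra columns preserved).  ``None`` loads the default.

    Returns
    -------
    pandas.DataFrame indexed by marker name, validated.
    """
    if source is None:
        source = _data_path("marker_registry.csv")
    df = pd.read_csv(source, keep_default_na=False)
    required = {"marker", "bp_set", "units", "cf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    if df["marker"].duplicated().any():
        dups = df.loc[df["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"duplicate marker names in registry: {dups}")
    bad_bp = set(df["bp_set"]) - set(BP_SETS)
    if bad_bp:
        raise ValueError(f"unknown biological-process sets: {sorted(bad_bp)}")
    df["cf"] = df["cf"].astype(int)
    if not df["cf"].isin(CF_CATEGORIES).all():
        bad = sorted(df.loc[~df["cf"].isin(CF_CATEGORIES), "marker"])
        raise ValueError(f"CF outside 1-4 for markers: {bad}")
    return df.set_index("marker", drop=False)


def registry_specs(registry: pd.DataFrame) -> list[MarkerSpec]:
    """Materialize a registry table as :class:`MarkerSpec` records."""
    return [
        MarkerSpec(name=row["marker"], bp_set=row["bp_set"], units=row["units"],
                   cf=int(row["cf"]), subgroup=row.get("subgroup", ""),
                   long_name=row.get("name", ""))
        for _, row in registry.iterrows()
    ]


def load_sw_labels(source=None) -> pd.DataFrame:
    """Published High/Low statistical-weight calls (external-labels fixture)."""
    if source is None:
        source = _data_path("sw_labels.csv")
    df = pd.read_csv(source)
    for col in ("marker", "sw_pc1", "sw_pc2"):
        if col not in df.columns:
            raise ValueError(f"SW label table missing column {col!r}")
    bad = set(df["sw_pc1"]) | set(df["sw_pc2"]) - {"High", "Low"}
    if not bad <= {"High", "Low"}:
        raise ValueError(f"SW labels must be High/Low, got {sorted(bad)}")
    return df.set_index("marker", drop=False)


def load_printed_correlations() -> pd.DataFrame:
    """Published stage-accuracy and yield correlation coefficients with their
    printed Strong/Weak labels and significance stars."""
    df = pd.read_csv(_data_path("printed_correlations.csv"), keep_default_na=False)
    return df
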