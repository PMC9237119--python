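"""Per-cell generating parameters: the printed group means and standard errors.

Each design cell of each marker carries one (mean, SE) pair transcribed from
the published summary tables; the replicate-level standard deviation used for
sampling is reconstructed as SE * sqrt(n), the inverse of how an SE of a mean
is reported.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .design import StudyDesign

#: markers whose rate nature leaves the 0-DAS cells undefined
RATE_MARKERS = ("NAR", "RGR", "CGR")


@dataclass(frozen=True)
class CellParameter:
    """Generating mean/SE for one marker in one design cell."""

    marker: str
    genotype: str
    treatment: str
    stage: str
    das: int
    mean: float
    se: float
    n: int | None = None  # replicate count the SE refers to; None = design default

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError(f"negative SE for {self.key()}: {self.se}")

    def key(self):
        return (self.marker, self.genotype, self.treatment, self.stage, self.das)

    def replicate_sd(self, n_default: int) -> float:
        n = self.n if self.n else n_default
        return self.se * math.sqrt(n)


def default_parameter_path():
    return resources.files("droughtmark") / "data" / "cell_parameters.csv"


def load_cell_parameters(source=None) -> pd.DataFrame:
    """Load and validate a cell-parameter table.

    The table must have columns ``marker, genotype, treatment, stage, das,
    mean, se`` (optional ``n``, ``source``).  Validation rejects negative SEs
    and duplicate cells, and requires every marker to cover the complete
    genotype x treatment grid for each (stage, das) layout it appears in, so
    that a single missing cell is reported by name.
    """
    if source is None:
        source = default_parameter_path()
    df = pd.read_csv(source)
    required = {"marker", "genotype", "treatment", "stage", "das", "mean", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    df["das"] = df["das"].astype(int)
    if (df["se"] < 0).any():
        bad = df.loc[df["se"] < 0].iloc[0]
        raise ValueError(
            f"negative SE for cell ({bad['marker']}, {bad['genotype']}, "
            f"{bad['treatment']}, {bad['stage']}, {bad['das']})")
    keycols = ["marker", "genotype", "treatment", "stage", "das"]
    dup = df.duplicated(subset=keycols)
    if dup.any():
        bad = df.loc[dup, keycols].iloc[0].tolist()
        raise ValueError(f"duplicate cell parameter: {tuple(bad)}")
    # coverage: per marker, full genotype x treatment grid at every layout cell
    for marker, sub in df.groupby("marker"):
        groups = set(zip(sub["genotype"], sub["treatment"]))
        layout = set(zip(sub["stage"], sub["das"]))
        have = set(zip(sub["genotype"], sub["treatment"], sub["stage"], sub["das"]))
        for g, t in sorted(groups):
            for s, d in sorted(layout):
                if (g, t, s, d) not in have:
                    raise ValueError(
                        f"missing cell parameter ({marker}, {g}, {t}, {s}, {d})")
    return df


def cell_parameters_for(df: pd.DataFrame, marker: str) -> pd.DataFrame:
    sub = df[df["marker"] == marker]
    if sub.empty:
        raise KeyError(f"no parameters for marker {marker!r}")
    return sub


def check_covers_design(params: pd.DataFrame, design: StudyDesign,
                        markers=None) -> None:
    """Require parameters for every design cell of the given markers.

    Rate markers are exempt from the 0-DAS cells (undefined for interval
    rates); morphology markers live on their own reduced layout and should
    not be passed here.
    """
    have = set(zip(params["marker"], params["genotype"], params["treatment"],
                   params["stage"], params["das"]))
    markers = list(markers) if markers is not None else sorted(set(params["marker"]))
    for m in markers:
        for g, t, s, d in design.cells():
            if m in RATE_MARKERS and d == min(design.sampling_days):
                continue
            if (m, g, t, s, d) not in have:
                raise ValueError(f"parameters do not cover design cell "
                                 f"({m}, {g}, {t}, {s}, {d})")
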