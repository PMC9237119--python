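"""End-to-end orchestration: simulate -> indices -> stats -> pca -> select,
with tidy-table I/O and report rendering.

Every run is a pure function of (config, shipped fixtures, seed); all output
tables carry a provenance header (config hash, seed, package version) as
``#``-prefixed comment lines above the CSV header.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .design import StudyDesign, build_default_design
from .indices import dsi_from_yield_table, indices_from_primitives
from .parameters import load_cell_parameters
from .pca import grouped_pca
from .registry import load_marker_registry, load_sw_labels
from .selection import SelectionResult, classify_sw, select_markers
from .simulate import (generate_measurements, generate_primitives,
                       generate_yield)
from .stats import (correlation_results_table, dual_letter_summary,
                    stage_accuracy_screen, yield_association_screen)

logger = logging.getLogger("droughtmark")

MEASUREMENT_SCHEMA = ["plant_id", "genotype", "treatment", "stage", "das",
                      "marker", "value"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, with logged defaults.

    Round-trips losslessly through :meth:`to_json` / :meth:`from_json`.
    """

    seed: int = 0
    parameter_path: str | None = None     # None = shipped fixture
    registry_path: str | None = None      # None = shipped 22-marker registry
    pairing: str = "replicate"            # correlation pairing mode
    obs_mode: str = "group-means"         # PCA observation unit
    sw_transform: str = "external"        # zscore | rank | external
    sw_threshold: float = 2.0
    alpha: float = 0.05
    out_dir: str | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def digest(self) -> str:
        """Hash of the analysis-relevant options (where output goes is not
        part of the analysis identity)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# table I/O

def write_measurements(table: pd.DataFrame, path,
                       provenance: dict | None = None) -> None:
    """Write a tidy table with a ``#`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        table.to_csv(fh, index=False)


def read_measurements(path) -> pd.DataFrame:
    """Read a tidy measurement table, validating the mandatory schema."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MEASUREMENT_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing column(s): {missing}")
    if not pd.api.types.is_numeric_dtype(df["value"]):
        bad = df.loc[pd.to_numeric(df["value"], errors="coerce").isna(),
                     "value"].head(3).tolist()
        raise ValueError(f"non-numeric values in 'value': {bad}")
    df["das"] = df["das"].astype(int)
    return df


# ---------------------------------------------------------------------------
# report rendering

def render_summary_table(summary: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Wide mean+letters layout for one marker: rows = genotype x treatment,
    columns = stage/DAS; cells like ``183.55 Cc`` (uppercase letter = column
    family, lowercase = row family)."""
    sub = summary[summary["marker"] == marker].copy()
    sub["cell"] = (sub["mean"].map(lambda v: f"{v:.2f}") + " "
                   + sub["letter_col"] + sub["letter_row"])
    wide = sub.pivot_table(index="group", columns=["stage", "das"],
                           values="cell", aggfunc="first", sort=False)
    wide.columns = [f"{s} {d} DAS" for s, d in wide.columns]
    return wide


def render_selection_table(result: SelectionResult) -> pd.DataFrame:
    """Published-style CF / SW / Sel table."""
    out = result.table.copy()
    out["Sel"] = out["selected"].map({True: "Sel", False: "-"})
    return out[["cf", "marker", "sw_pc1", "sw_pc2", "Sel"]].rename(
        columns={"cf": "CF", "marker": "Marker",
                 "sw_pc1": "SW PC1", "sw_pc2": "SW PC2"})


# ---------------------------------------------------------------------------
# the pipeline

#: the grouped PCAs run by default: (name, bp_set, marker subset or None)
DEFAULT_PCA_GROUPS = (
    ("stress-response", "stress-response", None),
    ("growth", "growth", None),
    ("water-use-physiological", "water-use", ("RWC", "WUE", "CTD")),
    ("water-use-morphological", "water-use",
     ("LT", "TD_AB", "TD_AD", "SD_AB", "SD_AD")),
)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute the full analysis and return a result bundle.

    Stages: simulate (measurements, primitives, yield) -> indices ->
    group summaries with dual Tukey letters -> stage-accuracy and yield
    correlation screens -> grouped PCAs -> CF x SW selection.  Writes all
    intermediate tables to ``config.out_dir`` when set.  Any stage failure is
    re-raised with the stage name attached.
    """
    config = config or PipelineConfig()
    bundle: dict = {"config": config}
    stage = "validate"
    try:
        registry = load_marker_registry(config.registry_path)
        if registry.empty:
            raise ValueError("marker registry is empty")
        params = load_cell_parameters(config.parameter_path)
        design = build_default_design(seed=config.seed)
        bundle["design"] = design

        stage = "simulate"
        measurements = generate_measurements(design, params, registry)
        primitives = generate_primitives(design, params)
        yields = generate_yield(design)
        logger.info("simulate: %d measurement rows, %d primitive rows, "
                    "%d yield rows", len(measurements), len(primitives),
                    len(yields))
        bundle.update(measurements=measurements, primitives=primitives,
                      yields=yields)

        stage = "indices"
        recomputed = indices_from_primitives(primitives)
        bundle["recomputed_indices"] = recomputed
        bundle["dsi"] = {
            arm: dsi_from_yield_table(yields, arm)
            for arm in design.yield_arms if arm != "control"}

        stage = "stats"
        core = measurements[measurements["das"].isin(design.sampling_days)]
        summary = dual_letter_summary(core, alpha=config.alpha)
        screen = stage_accuracy_screen(core, pairing=config.pairing)
        yscreen = yield_association_screen(core, yields)
        logger.info("stats: %d summary cells, %d stage correlations",
                    len(summary), len(screen))
        bundle.update(summary=summary, stage_screen=screen,
                      yield_screen=yscreen)

        stage = "pca"
        pcas = {}
        for name, bp, subset in DEFAULT_PCA_GROUPS:
            pcas[name] = grouped_pca(measurements, registry, bp,
                                     markers=subset, obs_mode=config.obs_mode)
        bundle["pcas"] = pcas

        stage = "select"
        passing_markers = registry.loc[registry["cf"].isin((1, 2)), "marker"]
        if config.sw_transform == "external":
            labels = load_sw_labels()
            sw1 = classify_sw(pd.Series(float("nan"), index=passing_markers),
                              1, "external", external_labels=labels["sw_pc1"])
            sw2 = classify_sw(pd.Series(float("nan"), index=passing_markers),
                              2, "external", external_labels=labels["sw_pc2"])
        else:
            sw1, sw2 = [], []
            for m in passing_markers:
                bp = registry.loc[m, "bp_set"]
                name = next(n for n, b, sub in DEFAULT_PCA_GROUPS
                            if b == bp and (sub is None or m in sub))
                res = pcas[name]
                sw1.extend(l for l in classify_sw(
                    res.loadings["e1"], 1, config.sw_transform,
                    config.sw_threshold) if l.marker == m)
                sw2.extend(l for l in classify_sw(
                    res.loadings["e2"], 2, config.sw_transform,
                    config.sw_threshold) if l.marker == m)
        selection = select_markers(
            registry, sw1, sw2,
            provenance={"transform": config.sw_transform,
                        "threshold": config.sw_threshold,
                        "pca_obs_mode": config.obs_mode,
                        "config": config.digest(), "seed": config.seed})
        logger.info("select: %d markers pass CF, %d selected",
                    len(selection.table), len(selection.selected))
        bundle["selection"] = selection
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config": config.digest(), "seed": config.seed,
            "version": __version__}
    write_measurements(bundle["measurements"], out / "measurements.csv", prov)
    write_measurements(bundle["primitives"], out / "primitives.csv", prov)
    write_measurements(bundle["yields"], out / "yields.csv", prov)
    write_measurements(bundle["recomputed_indices"],
                       out / "recomputed_indices.csv", prov)
    write_measurements(bundle["summary"], out / "group_summary.csv", prov)
    write_measurements(correlation_results_table(bundle["stage_screen"]),
                       out / "stage_accuracy.csv", prov)
    write_measurements(correlation_results_table(bundle["yield_screen"]),
                       out / "yield_association.csv", prov)
    for name, res in bundle["pcas"].items():
        write_measurements(
            res.loadings.reset_index(names="marker"),
            out / f"pca_{name}_loadings.csv",
            prov | {"variance_explained":
                    [round(v, 3) for v in res.variance_explained]})
    write_measurements(render_selection_table(bundle["selection"]),
                       out / "selection.csv",
                       prov | bundle["selection"].provenance)
    config.to_json(out / "config.json")
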