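"""Standardized principal component analysis per biological-process marker set.

Markers live on wildly different scales (enzyme activities in umol/g/min,
temperatures in degC, dimensionless ratios), so PCA is run on the correlation
matrix by default.  The observation unit defaults to genotype x treatment
group means — the aggregation that reproduces the published variance splits —
with design-cell means and raw replicates available as alternatives.

Loadings (the component coefficient vectors e1, e2, ...) are unit-norm with a
deterministic sign convention: the largest-magnitude coefficient of each
component is positive.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OBS_MODES = ("group-means", "cell-means", "replicates")


@dataclass
class PCAResult:
    """Eigendecomposition of a standardized observation x marker matrix."""

    variables: list[str]
    observations: list
    eigenvalues: np.ndarray
    variance_explained: np.ndarray   # percent, sums to 100
    loadings: pd.DataFrame           # variables x components (e1, e2, ...)
    scores: pd.DataFrame             # observations x components
    scaled: bool
    provenance: dict = field(default_factory=dict)

    def pc_variance(self, k: int = 2) -> float:
        """Percent of total variance carried by the first ``k`` components."""
        return float(self.variance_explained[:k].sum())


def fit_pca(matrix: pd.DataFrame, scale: bool = True,
            provenance: dict | None = None) -> PCAResult:
    """PCA of an observations x variables table.

    With ``scale=True`` (default) variables are standardized (ddof = 1), i.e.
    the correlation matrix is decomposed; otherwise the covariance matrix.
    Components are ordered by descending eigenvalue; tiny negative
    eigenvalues from round-off are clipped to zero.

    Raises on missing values and on constant columns when scaling.
    """
    X = matrix.astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 observations and 2 variables")
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in variables: {bad}")
    variables = list(X.columns)
    obs = list(X.index)
    Xc = X.values - X.values.mean(axis=0)
    sd = X.values.std(axis=0, ddof=1)
    if scale:
        if (sd == 0).any():
            bad = [v for v, s in zip(variables, sd) if s == 0]
            raise ValueError(f"constant column(s): {bad}")
        Xc = Xc / sd
    C = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: the largest-|coefficient| entry of each component > 0
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    if total == 0:
        raise ValueError("degenerate input: zero total variance")
    comp_names = [f"e{j + 1}" for j in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=variables, columns=comp_names)
    scores = pd.DataFrame(Xc @ evecs, index=obs, columns=comp_names)
    return PCAResult(
        variables=variables, observations=obs, eigenvalues=evals,
        variance_explained=100.0 * evals / total, loadings=loadings,
        scores=scores, scaled=scale, provenance=dict(provenance or {}))


def _observation_matrix(records: pd.DataFrame, markers: list[str],
                        obs_mode: str, value: str = "value") -> pd.DataFrame:
    if obs_mode not in OBS_MODES:
        raise ValueError(f"unknown observation mode {obs_mode!r}; "
                         f"expected one of {OBS_MODES}")
    rec = records[records["marker"].isin(markers)]
    if obs_mode == "group-means":
        idx = ["genotype", "treatment"]
    elif obs_mode == "cell-means":
        idx = ["genotype", "treatment", "stage", "das"]
    else:
        rec = rec.sort_values(["marker", "genotype", "treatment", "stage",
                               "das"], kind="stable").copy()
        rec["rep"] = rec.groupby(["marker", "genotype", "treatment", "stage",
                                  "das"]).cumcount()
        idx = ["genotype", "treatment", "stage", "das", "rep"]
    wide = rec.pivot_table(index=idx, columns="marker", values=value,
                           aggfunc="mean")
    # markers confined to a reduced layout (e.g. morphology, measured in one
    # stage only) cannot enter a finer-grained observation matrix: first drop
    # observations carrying less than half the variables (reduced-layout-only
    # rows), then variables covering less than half the remaining rows, then
    # any still-incomplete row listwise (rate indices lack 0-DAS cells)
    wide = wide.loc[wide.notna().mean(axis=1) >= 0.5]
    wide = wide.loc[:, wide.notna().mean() >= 0.5]
    wide = wide.dropna(axis=0, how="any")
    return wide.reindex(columns=[m for m in markers if m in wide.columns])


def grouped_pca(records: pd.DataFrame, registry: pd.DataFrame, group: str,
                markers: list[str] | None = None,
                obs_mode: str = "group-means", scale: bool = True,
                value: str = "value") -> PCAResult:
    """Standardized PCA over one biological-process marker set.

    ``group`` selects the registry's bp_set ("stress-response", "growth",
    "water-use"); ``markers`` restricts to an explicit subset (e.g. the
    physiological vs morphological water-use markers).  Observations default
    to genotype x treatment group means.
    """
    pool = registry.loc[registry["bp_set"] == group, "marker"].tolist()
    if markers is not None:
        unknown = set(markers) - set(pool)
        if unknown:
            raise ValueError(f"markers not in {group} set: {sorted(unknown)}")
        pool = [m for m in pool if m in set(markers)]
    present = [m for m in pool if m in set(records["marker"])]
    if len(present) < 2:
        raise ValueError(f"group {group!r} has fewer than two markers "
                         f"with data (found {present})")
    mat = _observation_matrix(records, present, obs_mode, value)
    return fit_pca(mat, scale=scale,
                   provenance={"group": group, "markers": list(mat.columns),
                               "obs_mode": obs_mode, "scale": scale})


def all_markers_pca(records: pd.DataFrame, registry: pd.DataFrame,
                    yields: pd.DataFrame | None = None,
                    obs_mode: str = "group-means", scale: bool = True,
                    value: str = "value") -> PCAResult:
    """Single PCA over every registry marker, optionally plus absolute yield.

    With a yield table, each observation gains a yield variable: the mean
    yield of the matching genotype and arm(s) (control observations take the
    control arm; stress observations average the stress arms they cover).
    """
    markers = [m for m in registry["marker"] if m in set(records["marker"])]
    mat = _observation_matrix(records, markers, obs_mode, value)
    if yields is not None:
        arm_means = yields.groupby(["genotype", "arm"])["yield_g"].mean()
        yvals = []
        for key in mat.index:
            g, t = key[0], key[1]
            if t == "control":
                yvals.append(arm_means[(g, "control")])
            else:
                stages = [key[2]] if len(key) > 2 else ["V3", "R5"]
                yvals.append(np.mean([arm_means[(g, f"{s}-stress")]
                                      for s in stages]))
        mat = mat.assign(Yield=yvals)
    return fit_pca(mat, scale=scale,
                   provenance={"group": "all", "markers": list(mat.columns),
                               "obs_mode": obs_mode, "scale": scale,
                               "with_yield": yields is not None})
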