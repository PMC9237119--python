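"""Univariate and correlation statistics.

Group summaries (mean +/- SE), one-way ANOVA with Tukey HSD compact letter
displays (the tables' dual-letter convention: uppercase letters compare the
genotype x treatment groups within a stage x DAS column, lowercase letters
compare sampling days within a group x stage row), two-way ANOVA, and the
Pearson/Bonferroni stage-accuracy screen with the Strong/Weak classification
(Strong iff |r| >= 0.60).
"""
from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

STRONG_THRESHOLD = 0.60


# ---------------------------------------------------------------------------
# group summaries

def summarize_groups(records: pd.DataFrame, grouping: list[str],
                     value: str = "value") -> pd.DataFrame:
    """Per-group n, mean and SE (= SD/sqrt(n), ddof=1; SE = 0 for n = 1)."""
    if records.empty:
        raise ValueError("no records to summarize")
    def _se(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    out = (records.groupby(grouping, sort=True)[value]
           .agg(n="size", mean="mean", se=_se).reset_index())
    if (out["n"] == 0).any():
        raise ValueError("empty group encountered")
    return out


# ---------------------------------------------------------------------------
# Tukey HSD compact letter display

def _compact_letters(names: list, means: dict, sig_pairs: set,
                     letters: str) -> dict:
    """Insert-and-absorb compact letter display.

    ``sig_pairs`` holds frozensets of group-name pairs that differ
    significantly.  Groups sharing a letter are never a significant pair, and
    every non-significant pair shares at least one letter.  Ties are broken by
    ascending group mean (letter columns are ordered by their smallest mean).
    """
    order = sorted(names, key=lambda g: (means[g], str(g)))
    cols: list[set] = [set(order)]
    for pair in sorted(sig_pairs, key=lambda p: sorted(map(str, p))):
        a, b = sorted(pair, key=lambda g: (means[g], str(g)))
        new_cols = []
        for col in cols:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb columns that are subsets of another
        cols = []
        for col in sorted(new_cols, key=len, reverse=True):
            if col and not any(col <= kept for kept in cols):
                cols.append(col)
    cols.sort(key=lambda col: min((means[g], str(g)) for g in col))
    if len(cols) > len(letters):
        raise RuntimeError("ran out of letters for the compact display")
    assign: dict = {g: "" for g in names}
    for letter, col in zip(letters, cols):
        for g in col:
            assign[g] += letter
    return {g: "".join(sorted(assign[g])) for g in names}


@dataclass
class TukeyResult:
    """One-way ANOVA F-test plus all-pairs Tukey HSD and letter codes."""

    f_statistic: float
    p_value: float
    letters: dict
    pairwise_p: pd.DataFrame
    alpha: float = 0.05
    degenerate: bool = False


def anova_tukey(records: pd.DataFrame, factor: str, value: str = "value",
                alpha: float = 0.05, uppercase: bool = True) -> TukeyResult:
    """One-way ANOVA with Tukey HSD post hoc and a compact letter display.

    Groups sharing any letter do not differ at ``alpha``; letters start at
    A (or a with ``uppercase=False``) and are assigned in order of ascending
    group mean.  With zero variance everywhere but unequal means the Tukey
    distribution degenerates; distinct letters are returned with a warning.
    """
    groups = {name: np.asarray(sub[value], float)
              for name, sub in records.groupby(factor, sort=True)}
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least two replicates per group")
    means = {g: float(v.mean()) for g, v in groups.items()}
    letters_pool = (string.ascii_uppercase if uppercase
                    else string.ascii_lowercase)
    pooled_var = np.concatenate([v - v.mean() for v in groups.values()]).var(ddof=0)
    if pooled_var == 0:
        distinct_means = len(set(means.values()))
        if distinct_means == 1:
            letters = {g: letters_pool[0] for g in names}
            pw = pd.DataFrame(1.0, index=names, columns=names)
            return TukeyResult(0.0, 1.0, letters, pw, alpha)
        warnings.warn("zero within-group variance with unequal means; "
                      "assigning distinct letters", RuntimeWarning)
        ranked = sorted(set(means.values()))
        letters = {g: letters_pool[ranked.index(means[g])] for g in names}
        pw = pd.DataFrame([[1.0 if means[a] == means[b] else 0.0
                            for b in names] for a in names],
                          index=names, columns=names)
        return TukeyResult(np.inf, 0.0, letters, pw, alpha, degenerate=True)
    f_stat, p_val = sps.f_oneway(*groups.values())
    hsd = sps.tukey_hsd(*groups.values())
    pw = pd.DataFrame(hsd.pvalue, index=names, columns=names)
    sig = {frozenset((a, b)) for i, a in enumerate(names)
           for j, b in enumerate(names) if i < j and pw.iloc[i, j] <= alpha}
    letters = _compact_letters(names, means, sig, letters_pool)
    return TukeyResult(float(f_stat), float(p_val), letters, pw, alpha)


def dual_letter_summary(records: pd.DataFrame, alpha: float = 0.05,
                        value: str = "value") -> pd.DataFrame:
    """Per-cell summary with the tables' two Tukey letter families.

    For each marker x stage: uppercase letters compare the genotype x
    treatment groups within each DAS column; lowercase letters compare the
    sampling days within each group row.  Each family is tested at ``alpha``.
    """
    records = records.copy()
    records["group"] = records["genotype"] + " " + records["treatment"]
    out = summarize_groups(records, ["marker", "stage", "group", "das"], value)
    out["letter_col"] = ""
    out["letter_row"] = ""
    for (marker, stage), sub in records.groupby(["marker", "stage"]):
        for das, col in sub.groupby("das"):
            if col["group"].nunique() < 2:
                continue
            res = anova_tukey(col, "group", value, alpha, uppercase=True)
            for g, let in res.letters.items():
                m = ((out["marker"] == marker) & (out["stage"] == stage)
                     & (out["group"] == g) & (out["das"] == das))
                out.loc[m, "letter_col"] = let
        for g, row in sub.groupby("group"):
            if row["das"].nunique() < 2:
                continue
            res = anova_tukey(row, "das", value, alpha, uppercase=False)
            for das, let in res.letters.items():
                m = ((out["marker"] == marker) & (out["stage"] == stage)
                     & (out["group"] == g) & (out["das"] == das))
                out.loc[m, "letter_row"] = let
    return out


# ---------------------------------------------------------------------------
# two-way ANOVA

def two_way_anova(records: pd.DataFrame, factor1: str = "genotype",
                  factor2: str = "treatment",
                  value: str = "value") -> pd.DataFrame:
    """Two-way ANOVA with interaction (type-II sums of squares).

    Returns a tidy table with one row per effect (factor1, factor2,
    factor1:factor2, Residual) and columns sum_sq, df, F, p.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cells = records.groupby([factor1, factor2]).size()
    expected = records[factor1].nunique() * records[factor2].nunique()
    if len(cells) != expected:
        raise ValueError("missing cell in the two-way layout")
    df = records[[factor1, factor2, value]].rename(
        columns={factor1: "f1", factor2: "f2", value: "y"})
    model = smf.ols("y ~ C(f1) * C(f2)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    tab = tab.rename(index={"C(f1)": factor1, "C(f2)": factor2,
                            "C(f1):C(f2)": f"{factor1}:{factor2}"})
    tab = tab.rename(columns={"PR(>F)": "p"})
    tab.index.name = "effect"
    return tab.reset_index()


# ---------------------------------------------------------------------------
# Pearson / Bonferroni correlation screen

def classify_strength(r: float) -> str:
    """Strong iff |r| >= 0.60, else Weak (the published classification)."""
    if not -1.0000001 <= r <= 1.0000001:
        raise ValueError(f"correlation out of range: {r}")
    return "Strong" if abs(r) >= STRONG_THRESHOLD else "Weak"


def significance_stars(p_adj: float) -> str:
    if p_adj <= 0.001:
        return "***"
    if p_adj <= 0.01:
        return "**"
    if p_adj <= 0.05:
        return "*"
    return "ns"


@dataclass
class CorrelationResult:
    """Pearson correlation of two paired value streams with Bonferroni
    adjustment over the screen's family."""

    pair: tuple
    n: int
    r: float
    p_raw: float
    family_size: int = 1
    p_adj: float = field(init=False)
    stars: str = field(init=False)
    strength: str = field(init=False)

    def __post_init__(self) -> None:
        self.p_adj = min(1.0, self.p_raw * self.family_size)
        self.stars = significance_stars(self.p_adj)
        self.strength = classify_strength(self.r)


def pearson_bonferroni(x, y, family_size: int = 1,
                       pair: tuple = ("x", "y")) -> CorrelationResult:
    """Sample Pearson r with two-sided t-test p, Bonferroni-adjusted."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("streams differ in length")
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input stream; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(pair=pair, n=len(x), r=float(r), p_raw=float(p),
                             family_size=family_size)


def _replicate_rank(records: pd.DataFrame) -> pd.Series:
    return (records.groupby(["marker", "genotype", "treatment", "stage", "das"])
            .cumcount())


def stage_accuracy_screen(records: pd.DataFrame, pairing: str = "replicate",
                          by_group: bool = False,
                          value: str = "value") -> list[CorrelationResult]:
    """Correlate each marker's V3 stream against its R5 stream.

    Measures marker accuracy across phenological stages: a marker that ranks
    plants the same way at V3 and R5 is stage-robust.  Streams are matched by
    (genotype, treatment, DAS, replicate rank) (``pairing="replicate"``) or
    collapsed to cell means first (``pairing="cell-mean"``).  With
    ``by_group=True`` one correlation per marker x genotype x treatment is
    returned, mirroring the published tables.  The Bonferroni family is the
    set of correlations computed in this invocation.
    """
    if pairing not in ("replicate", "cell-mean"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    stages = set(records["stage"])
    if not {"V3", "R5"} <= stages:
        raise ValueError("screen needs records at both V3 and R5")
    rec = records[records["stage"].isin(["V3", "R5"])].copy()
    if pairing == "cell-mean":
        rec = (rec.groupby(["marker", "genotype", "treatment", "stage", "das"])
               [value].mean().reset_index())
        rec["rep"] = 0
    else:
        rec = rec.sort_values(["marker", "genotype", "treatment", "stage",
                               "das"], kind="stable")
        rec["rep"] = _replicate_rank(rec)
    idx = ["marker", "genotype", "treatment", "das", "rep"]
    wide = rec.pivot_table(index=idx, columns="stage", values=value)
    wide = wide.dropna(subset=["V3", "R5"]).reset_index()
    if wide.empty:
        raise ValueError("no pairable V3/R5 observations")
    keys = ["marker", "genotype", "treatment"] if by_group else ["marker"]
    grouped = list(wide.groupby(keys))
    m = len(grouped)
    out = []
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        out.append(pearson_bonferroni(sub["V3"], sub["R5"], family_size=m,
                                      pair=key + ("V3_vs_R5",)))
    return out


def yield_association_screen(records: pd.DataFrame, yields: pd.DataFrame,
                             by_group: bool = False,
                             value: str = "value") -> list[CorrelationResult]:
    """Correlate marker replicate streams with per-plant yield.

    Marker records are matched to yields of the same genotype and arm
    (stress records at stage S -> the "S-stress" arm; control records -> the
    control arm), by replicate rank within the arm.
    """
    rec = records.copy()
    rec["arm"] = np.where(rec["treatment"] == "control", "control",
                          rec["stage"].astype(str) + "-stress")
    rec = rec.sort_values(["marker", "genotype", "treatment", "stage", "das"],
                          kind="stable")
    rec["rep"] = _replicate_rank(rec)
    ys = yields.sort_values(["genotype", "arm"], kind="stable").copy()
    ys["rep"] = ys.groupby(["genotype", "arm"]).cumcount()
    merged = rec.merge(ys[["genotype", "arm", "rep", "yield_g"]],
                       on=["genotype", "arm", "rep"], how="inner")
    if merged.empty:
        raise ValueError("no marker records could be matched to yields")
    keys = ["marker", "genotype", "treatment"] if by_group else ["marker"]
    grouped = list(merged.groupby(keys))
    m = len(grouped)
    out = []
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        out.append(pearson_bonferroni(sub[value], sub["yield_g"],
                                      family_size=m, pair=key + ("vs_yield",)))
    return out


def correlation_results_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy table of screen results (one row per correlation)."""
    return pd.DataFrame([
        {"pair": "|".join(map(str, c.pair)), "n": c.n, "r": c.r,
         "p_raw": c.p_raw, "p_adj": c.p_adj, "stars": c.stars,
         "strength": c.strength, "family_size": c.family_size}
        for c in results])
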