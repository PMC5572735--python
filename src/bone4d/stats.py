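"""Study-level statistics: interlimb and percent differences, paired and
independent t-tests, and the mixed-design (split-plot) ANOVA.

Design: loading is within-subject (loaded vs contralateral control limb, 2
levels), genotype (KO vs LC) and age (10 vs 26 wk) are between-subject.  With
a 2-level within factor the classical split-plot decomposition is exact and
sphericity is trivially satisfied: the between stratum is an ordinary
two-way ANOVA on each animal's limb mean, the within stratum an ANOVA (with
intercept) on each animal's half-difference.  Type III sums of squares via
Wald tests on the sum-to-zero coded full-factorial model — for 2-level
factors every term has one coefficient, so F = (β/SE)².

A separate between-subjects ANOVA on the interlimb difference Δ = loaded −
control serves the "relative values" analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

#: significance-letter convention used in the group tables:
#: (a) genotype, (b) age, (c) loading, (d) genotype & age,
#: (e) genotype & loading, (f) age & loading
EFFECT_LETTERS = {
    "genotype": "a", "age": "b", "loading": "c",
    "genotype_x_age": "d", "genotype_x_loading": "e", "age_x_loading": "f",
}


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA


@dataclass
class EffectReport:
    effects: Dict[str, EffectResult] = field(default_factory=dict)
    alpha: float = ALPHA

    def letters(self) -> str:
        """Significance letters (a)–(f) for the terms below alpha."""
        return ", ".join(EFFECT_LETTERS[t] for t in EFFECT_LETTERS
                         if t in self.effects and self.effects[t].p <= self.alpha)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"term": t, "F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p,
                 "significant": e.p <= self.alpha}
                for t, e in self.effects.items()]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# elementary contrasts
# --------------------------------------------------------------------------- #

def interlimb_difference(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Per-animal Δ_interlimb = loaded − control for one outcome.

    Animals missing either limb are excluded with a warning column dropped
    silently (the exclusion is logged through the returned frame's length).
    """
    sub = table[table["outcome"] == outcome] if "outcome" in table.columns else table
    wide = sub.pivot_table(index=[c for c in ("animal", "genotype", "age") if c in sub.columns],
                           columns="limb", values="value")
    wide = wide.dropna(subset=["loaded", "control"])
    wide["delta"] = wide["loaded"] - wide["control"]
    return wide.reset_index()


def percent_difference(loaded: float, control: float) -> float:
    """%Δ = (loaded − control) / control × 100."""
    if control == 0:
        raise ZeroDivisionError("percent difference undefined for control = 0")
    return (loaded - control) / control * 100.0


def paired_t(a, b) -> Tuple[float, int, float]:
    """Two-sided paired t-test on matched values; returns (t, df, p).

    Degenerate zero-variance differences: all-zero differences give t = 0,
    p = 1 (exact tie); identical nonzero differences give p = 0 with
    t = ±inf (the shift is certain under the permutation view).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 matched pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, len(d) - 1, 1.0
        return math.copysign(math.inf, d.mean()), len(d) - 1, 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), len(d) - 1, float(p)


def independent_t(a, b, equal_var: bool = True) -> Tuple[float, float, float]:
    """Two-sided two-sample t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, len(a) + len(b) - 2, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), len(a) + len(b) - 2, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2
    else:
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return float(t), float(df), float(p)


# --------------------------------------------------------------------------- #
# split-plot ANOVA
# --------------------------------------------------------------------------- #

def _sum_coded_anova(y: np.ndarray, g: np.ndarray, a: np.ndarray,
                     test_intercept: bool) -> Dict[str, EffectResult]:
    """Type III F-tests for the 2×2 between model y ~ G*A (sum coding).

    Returns {'intercept', 'g', 'a', 'ga'} (intercept only when requested).
    Degenerate sub-designs (a single level of G and/or A) drop the missing
    terms, reducing to the nested model.
    """
    cols = [np.ones_like(y)]
    names = ["intercept"]
    gl, al = np.unique(g), np.unique(a)
    if len(gl) == 2:
        cols.append(np.where(g == gl[0], 1.0, -1.0))
        names.append("g")
    elif len(gl) > 2:
        raise ValueError("genotype must have at most 2 levels")
    if len(al) == 2:
        cols.append(np.where(a == al[0], 1.0, -1.0))
        names.append("a")
    elif len(al) > 2:
        raise ValueError("age must have at most 2 levels")
    if "g" in names and "a" in names:
        cols.append(cols[names.index("g")] * cols[names.index("a")])
        names.append("ga")

    X = np.column_stack(cols)
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough subjects for the design")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df2 = n - p
    sigma2 = float(resid @ resid) / df2
    out: Dict[str, EffectResult] = {}
    for j, name in enumerate(names):
        if name == "intercept" and not test_intercept:
            continue
        if sigma2 == 0:
            F = math.inf if beta[j] != 0 else 0.0
            pval = 0.0 if beta[j] != 0 else 1.0
        else:
            F = float(beta[j] ** 2 / (sigma2 * xtx_inv[j, j]))
            pval = float(sps.f.sf(F, 1, df2))
        out[name] = EffectResult(F=F, df1=1, df2=df2, p=pval)
    return out


def _check_cells(df: pd.DataFrame) -> None:
    for (gv, av), cell in df.groupby(["genotype", "age"], sort=True):
        if len(cell) < 2:
            raise ValueError(f"cell genotype={gv!r}, age={av!r} has n={len(cell)} < 2")


def rm_anova(table: pd.DataFrame, outcome: str) -> EffectReport:
    """Split-plot ANOVA: loading (within) × genotype × age (between).

    Input is the long study table with columns (animal, genotype, age, limb,
    outcome, value); each animal contributes one loaded and one control value.
    Reports F, df and p for genotype, age, loading and all interactions.
    """
    wide = interlimb_difference(table, outcome)
    if wide.empty:
        raise ValueError(f"no complete limb pairs for outcome {outcome!r}")
    _check_cells(wide)
    g = wide["genotype"].to_numpy()
    a = wide["age"].to_numpy()
    u = ((wide["loaded"] + wide["control"]) / 2.0).to_numpy(dtype=float)  # between stratum
    v = ((wide["loaded"] - wide["control"]) / 2.0).to_numpy(dtype=float)  # within stratum

    between = _sum_coded_anova(u, g, a, test_intercept=False)
    within = _sum_coded_anova(v, g, a, test_intercept=True)

    report = EffectReport()
    mapping_between = {"g": "genotype", "a": "age", "ga": "genotype_x_age"}
    mapping_within = {"intercept": "loading", "g": "genotype_x_loading",
                      "a": "age_x_loading", "ga": "genotype_x_age_x_loading"}
    for k, name in mapping_between.items():
        if k in between:
            report.effects[name] = between[k]
    for k, name in mapping_within.items():
        if k in within:
            report.effects[name] = within[k]
    return report


def interlimb_anova(table: pd.DataFrame, outcome: str) -> EffectReport:
    """Between-subjects ANOVA (genotype × age) on Δ_interlimb — the separate
    analysis run on relative values."""
    wide = interlimb_difference(table, outcome)
    if wide.empty:
        raise ValueError(f"no complete limb pairs for outcome {outcome!r}")
    _check_cells(wide)
    d = wide["delta"].to_numpy(dtype=float)
    res = _sum_coded_anova(d, wide["genotype"].to_numpy(), wide["age"].to_numpy(),
                           test_intercept=False)
    report = EffectReport()
    for k, name in {"g": "genotype", "a": "age", "ga": "genotype_x_age"}.items():
        if k in res:
            report.effects[name] = res[k]
    return report


def group_table(table: pd.DataFrame, outcome: str,
                report: Optional[EffectReport] = None) -> pd.DataFrame:
    """mean ± SD per (genotype, age, limb) with paired-test asterisks and the
    ANOVA significance letters, formatted like the published group tables."""
    sub = table[table["outcome"] == outcome] if "outcome" in table.columns else table
    rows = []
    for (gv, av), cell in sub.groupby(["genotype", "age"], sort=True):
        wide = cell.pivot_table(index="animal", columns="limb", values="value")
        wide = wide.dropna(subset=["loaded", "control"])
        star = ""
        if len(wide) >= 2:
            _, _, p = paired_t(wide["loaded"], wide["control"])
            star = "*" if p <= ALPHA else ""
        for limb in ("control", "loaded"):
            vals = wide[limb]
            rows.append({
                "outcome": outcome, "genotype": gv, "age": av, "limb": limb,
                "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                "n": int(len(vals)),
                "paired_significant": star if limb == "loaded" else "",
                "anova_letters": report.letters() if report is not None else "",
            })
    return pd.DataFrame(rows)
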