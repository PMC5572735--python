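"""Strain-gauge load calibration and qPCR relative expression.

Strain-matched loading requires, per group, the linear relation between the
applied peak load (N, compressive = negative) and the peak strain measured at
the gauge site (µε).  Load is regressed on strain per animal (slope in N/µε);
the load producing a target strain (here +900 µε) is slope × strain, reported
to 0.1 N (half-away-from-zero).

qPCR uses the ΔCt method with B2m as the reference gene: ΔCt = Ct_gene −
Ct_ref per block; fold change between conditions is 2^−(ΔΔCt) with the test
performed on the ΔCt values (paired for loaded vs control within animals,
independent otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import round_half_away
from .stats import independent_t, paired_t

REFERENCE_GENE = "B2m"
TARGET_STRAIN_UE = 900.0


@dataclass(frozen=True)
class StrainLoadFit:
    slope: float           # N/µε
    intercept: float       # N
    slope_se: float
    n_points: int
    animal: Optional[str] = None


@dataclass(frozen=True)
class GroupStrainFit:
    group: str
    slope_mean: float
    slope_sd: float
    n_animals: int


def fit_strain_load(series: pd.DataFrame) -> StrainLoadFit:
    """OLS fit of load (N) on strain (µε) for one animal's series."""
    load = np.asarray(series["load_N"], dtype=float)
    strain = np.asarray(series["strain_ue"], dtype=float)
    if len(np.unique(load)) < 3:
        raise ValueError("need at least 3 distinct load levels")
    if not np.all(np.isfinite(strain)):
        raise ValueError("strains must be finite")
    if np.ptp(strain) == 0:
        raise ValueError("rank-deficient design: strain is constant across loads")
    res = sps.linregress(strain, load)
    animal = str(series["animal"].iloc[0]) if "animal" in series else None
    return StrainLoadFit(slope=float(res.slope), intercept=float(res.intercept),
                         slope_se=float(res.stderr), n_points=len(load), animal=animal)


def fit_strain_load_group(series: pd.DataFrame, group: str = "") -> GroupStrainFit:
    """Per-animal OLS slopes summarized as mean ± SD across animals."""
    slopes = [fit_strain_load(g).slope for _, g in series.groupby("animal", sort=True)]
    return GroupStrainFit(group=group, slope_mean=float(np.mean(slopes)),
                          slope_sd=float(np.std(slopes, ddof=1)) if len(slopes) > 1 else 0.0,
                          n_animals=len(slopes))


def load_for_target_strain(slope: float, target_strain: float = TARGET_STRAIN_UE,
                           intercept: float = 0.0, decimals: int = 1) -> float:
    """Load (N) producing the target strain: slope × strain (+ intercept),
    rounded half-away-from-zero to the reporting precision (0.1 N)."""
    return round_half_away(slope * target_strain + intercept, decimals)


# --------------------------------------------------------------------------- #
# qPCR
# --------------------------------------------------------------------------- #

def delta_ct(table: pd.DataFrame, reference_gene: str = REFERENCE_GENE) -> pd.DataFrame:
    """ΔCt = Ct_gene − Ct_reference within each measurement block.

    A block is one (animal, limb[, time point]) combination; undetected genes
    (NaN Ct) propagate as missing.  A block without the reference gene raises.
    """
    block_cols = [c for c in ("animal", "group", "limb", "time_point") if c in table.columns]
    out = []
    for keys, block in table.groupby(block_cols, sort=True, dropna=False):
        ref = block.loc[block["gene"] == reference_gene, "ct"]
        if len(ref) == 0 or ref.isna().all():
            raise ValueError(f"block {keys!r}: reference gene {reference_gene!r} missing")
        ref_ct = float(ref.mean())
        sub = block[block["gene"] != reference_gene].copy()
        sub["delta_ct"] = sub["ct"] - ref_ct
        out.append(sub.drop(columns=["ct"]))
    return pd.concat(out, ignore_index=True)


def fold_change(delta_ct_a: pd.Series | np.ndarray,
                delta_ct_b: pd.Series | np.ndarray,
                paired: bool = False) -> Tuple[float, float]:
    """(fold change of a relative to b, two-sided p on the ΔCt values).

    fold = 2^−(mean ΔCt_a − mean ΔCt_b); the t-test is paired (values matched
    by animal, same order) or independent.
    """
    a = np.asarray(delta_ct_a, dtype=float)
    b = np.asarray(delta_ct_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    fold = float(2.0 ** (-(a.mean() - b.mean())))
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires matched samples")
        _, _, p = paired_t(a, b)
    else:
        _, _, p = independent_t(a, b)
    return fold, float(p)


def fold_change_table(dct: pd.DataFrame, contrast: str = "loaded_vs_control",
                      by=("group", "gene")) -> pd.DataFrame:
    """Loaded-vs-control fold change per (group, gene), paired by animal."""
    if contrast != "loaded_vs_control":
        raise ValueError(f"unsupported contrast {contrast!r}")
    rows = []
    for keys, sub in dct.groupby(list(by), sort=True):
        wide = sub.pivot_table(index="animal", columns="limb", values="delta_ct")
        wide = wide.dropna(subset=["loaded", "control"])
        if len(wide) < 2:
            continue
        fold, p = fold_change(wide["loaded"], wide["control"], paired=True)
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        rec.update({"fold_change": fold, "p_value": p, "n": len(wide)})
        rows.append(rec)
    return pd.DataFrame(rows)
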