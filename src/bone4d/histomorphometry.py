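"""Dynamic histomorphometry from fluorochrome double-labeling.

Per-section label perimeters on the endocortical (Ec) and periosteal (Ps)
envelopes yield sLS/BS and dLS/BS; the mineralizing surface is
MS/BS = 0.5·sLS/BS + dLS/BS, the mineral apposition rate (MAR) is the mean
double-label distance over the labeling interval (9 days: injections on days
3 and 12), and BFR/BS = MAR · MS/BS / 100.  A section with no double label
(dLS/BS = 0) carries no MAR and therefore no BFR/BS ("no data" rule); such
values are excluded listwise from group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

DEFAULT_LABEL_INTERVAL_DAYS = 9.0


@dataclass(frozen=True)
class HistoSection:
    animal: str
    envelope: str                      # "Ec" | "Ps"
    limb: str                          # "loaded" | "control"
    single_label_length: float         # µm
    double_label_length: float         # µm
    total_surface_length: float        # µm
    interlabel_distances: Tuple[float, ...] = ()
    label_interval: float = DEFAULT_LABEL_INTERVAL_DAYS

    def __post_init__(self):
        if min(self.single_label_length, self.double_label_length,
               self.total_surface_length) < 0:
            raise ValueError("label lengths must be >= 0")
        if self.single_label_length + self.double_label_length > self.total_surface_length * (1 + 1e-9):
            raise ValueError("single + double label length exceeds total surface")
        if any(d < 0 for d in self.interlabel_distances):
            raise ValueError("interlabel distances must be >= 0")
        if self.label_interval <= 0:
            raise ValueError("label interval must be positive")


def label_fractions(section: HistoSection) -> Tuple[float, float, float]:
    """(sLS/BS %, dLS/BS %, MS/BS %) with MS/BS = 0.5·sLS/BS + dLS/BS."""
    if section.total_surface_length == 0:
        raise ValueError("total surface length is zero")
    sls = 100.0 * section.single_label_length / section.total_surface_length
    dls = 100.0 * section.double_label_length / section.total_surface_length
    return sls, dls, 0.5 * sls + dls


def mineral_apposition_rate(section: HistoSection) -> Optional[float]:
    """MAR (µm/day): mean interlabel distance / labeling interval.

    Returns None ("no data") when the section has no double-labeled surface.
    """
    if section.double_label_length == 0 or len(section.interlabel_distances) == 0:
        return None
    return float(np.mean(section.interlabel_distances)) / section.label_interval


def bone_formation_rate(ms_bs: float, mar: Optional[float]) -> Optional[float]:
    """BFR/BS (µm³/µm²/day) = MAR · MS/BS / 100; None propagates from MAR."""
    if not (0 <= ms_bs <= 100):
        raise ValueError("MS/BS must be a percentage in [0, 100]")
    if mar is None:
        return None
    return mar * ms_bs / 100.0


def section_outcomes(section: HistoSection) -> dict:
    sls, dls, ms = label_fractions(section)
    mar = mineral_apposition_rate(section)
    return {
        "animal": section.animal, "envelope": section.envelope, "limb": section.limb,
        "sLS_BS": sls, "dLS_BS": dls, "MS_BS": ms,
        "MAR": mar if mar is not None else np.nan,
        "BFR_BS": (bone_formation_rate(ms, mar) if mar is not None else np.nan),
    }


def _parse_distances(cell) -> Tuple[float, ...]:
    if isinstance(cell, (list, tuple)):
        return tuple(float(v) for v in cell)
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return ()
    return tuple(float(v) for v in str(cell).split(";") if v != "")


def compute_outcomes(sections: pd.DataFrame) -> pd.DataFrame:
    """Per-section outcomes from a table of label measurements.

    Expects the column layout written by
    :func:`bone4d.synthetic.make_histo_dataset`; grouping columns (genotype,
    age, ...) are carried through.
    """
    carry = [c for c in ("genotype", "age") if c in sections.columns]
    rows: List[dict] = []
    for _, r in sections.iterrows():
        sec = HistoSection(
            animal=str(r["animal"]), envelope=str(r["envelope"]), limb=str(r["limb"]),
            single_label_length=float(r["single_label_length_um"]),
            double_label_length=float(r["double_label_length_um"]),
            total_surface_length=float(r["total_surface_length_um"]),
            interlabel_distances=_parse_distances(r.get("interlabel_distances_um")),
            label_interval=float(r.get("label_interval_days", DEFAULT_LABEL_INTERVAL_DAYS)),
        )
        out = section_outcomes(sec)
        for c in carry:
            out[c] = r[c]
        rows.append(out)
    return pd.DataFrame(rows)


def group_summary(outcomes: pd.DataFrame,
                  group_cols: List[str] = None) -> pd.DataFrame:
    """mean ± SD per group, per animal first then across animals.

    Multiple sections per animal are averaged per animal before group
    statistics; missing MAR/BFR values are excluded listwise.
    """
    group_cols = group_cols or [c for c in ("genotype", "age", "limb", "envelope")
                                if c in outcomes.columns]
    metrics = ["sLS_BS", "dLS_BS", "MS_BS", "MAR", "BFR_BS"]
    per_animal = (outcomes.groupby(group_cols + ["animal"], dropna=False)[metrics]
                  .mean().reset_index())
    agg = per_animal.groupby(group_cols)[metrics].agg(["mean", "std", "count"])
    agg.columns = [f"{m}_{stat}" for m, stat in agg.columns]
    return agg.reset_index()
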