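"""Published group-level summary values from the in vivo mouse tibial-loading
study of Sost knockout (KO) vs littermate control (LC) mice.

These printed mean ± SD values parameterize the synthetic-data generators
(the raw scans were never deposited) and supply the inputs for the worked
examples: percent differences, interlimb differences, calibrated load levels
and the MS/BS / BFR/BS arithmetic are all recomputed from these numbers.

Groups are keyed (genotype, age) with genotype ∈ {"LC", "KO"} and age ∈
{10, 26} weeks; limbs are "control" / "loaded".
"""

from __future__ import annotations

import pandas as pd

GROUPS = [("LC", 10), ("LC", 26), ("KO", 10), ("KO", 26)]

#: per-animal OLS strain-load regression slopes, mean ± SD (N/µε)
STRAIN_SLOPES = {
    ("KO", 10): (-0.0143, 0.0021),
    ("KO", 26): (-0.0161, 0.0016),
    ("LC", 10): (-0.0077, 0.0016),
    ("LC", 26): (-0.0079, 0.0006),
}

#: load levels (N) applied to reach +900 µε at the gauge site, as printed
PUBLISHED_LOADS_N = {("KO", 10): -12.9, ("KO", 26): -14.5,
                     ("LC", 10): -7.0, ("LC", 26): -7.0}

#: tibial lengths (mm), mean ± SD, by caliper at dissection
TIBIAL_LENGTH_MM = {
    ("LC", 10): (17.3, 0.4), ("LC", 26): (18.4, 0.3),
    ("KO", 10): (17.7, 0.3), ("KO", 26): (18.4, 0.3),
}

#: control-limb eroded volume fraction EV/BV day 0–15, mean ± SD
EV_BV_CONTROL = {
    ("LC", 10): (0.002, 0.001), ("KO", 10): (0.004, 0.003),
    ("LC", 26): (0.024, 0.012), ("KO", 26): (0.018, 0.007),
}

# ---- static micro-CT group table (day 0 / day 15, mean, sd per limb) ------- #
# values[outcome][(genotype, age, limb)] = (mean, sd)
_MICRO_CT = {
    0: {
        "Imax": [(0.06, .01), (0.06, .01), (0.07, 0), (0.07, .01),
                 (0.13, .02), (0.14, .02), (0.22, .01), (0.22, .01)],
        "Imin": [(0.04, .01), (0.04, 0), (0.06, 0), (0.06, 0),
                 (0.11, .01), (0.11, .01), (0.18, .01), (0.19, .01)],
        "Ct.Ar": [(0.46, .02), (0.45, .03), (0.57, .02), (0.55, .03),
                  (0.85, .05), (0.85, .06), (1.25, .05), (1.27, .06)],
        "T.Ar": [(0.95, .05), (0.96, .05), (1.05, .06), (1.05, .04),
                 (1.41, .09), (1.42, .08), (1.75, .03), (1.75, .04)],
        "Ct.Ar/T.Ar": [(0.48, .01), (0.46, .01), (0.54, .02), (0.52, .01),
                       (0.60, .02), (0.60, .02), (0.72, .03), (0.72, .02)],
        "Ct.Th": [(158, 5), (152, 6), (185, 7), (184, 8),
                  (254, 13), (250, 15), (337, 16), (346, 19)],
        "Ct.vTMD": [(1263, 13), (1239, 21), (1316, 19), (1320, 13),
                    (1268, 16), (1263, 19), (1309, 8), (1326, 24)],
    },
    15: {
        "Imax": [(0.06, .01), (0.06, 0), (0.07, .01), (0.07, .01),
                 (0.14, .02), (0.15, .02), (0.22, .01), (0.22, .02)],
        "Imin": [(0.04, .01), (0.05, 0), (0.06, .01), (0.06, .01),
                 (0.11, .01), (0.12, .01), (0.18, .01), (0.19, .02)],
        "Ct.Ar": [(0.49, .03), (0.50, .02), (0.56, .02), (0.55, .03),
                  (0.87, .06), (0.94, .06), (1.24, .06), (1.30, .06)],
        "T.Ar": [(0.97, .05), (0.99, .04), (1.08, .04), (1.06, .04),
                 (1.42, .07), (1.46, .05), (1.74, .05), (1.75, .06)],
        "Ct.Ar/T.Ar": [(0.50, .01), (0.50, .01), (0.51, .01), (0.52, .01),
                       (0.61, .02), (0.64, .03), (0.71, .03), (0.74, .02)],
        "Ct.Th": [(168, 6), (170, 3), (181, 7), (183, 6),
                  (260, 18), (278, 19), (328, 22), (357, 28)],
        "Ct.vTMD": [(1279, 11), (1255, 13), (1321, 14), (1310, 9),
                    (1255, 17), (1273, 26), (1315, 10), (1330, 8)],
    },
}

# ---- dynamic histomorphometry group table (mean, sd per limb) -------------- #
_HISTO = {
    "Ec.sLS/BS": [(20.6, 7), (11.9, 4.6), (28.1, 7.4), (38.7, 10.1),
                  (23.6, 20.4), (7.3, 7.6), (27.7, 15.4), (23.5, 9.3)],
    "Ec.dLS/BS": [(53.1, 11.3), (68.2, 7.7), (19.0, 10), (20.2, 10.8),
                  (66.5, 19.8), (84.6, 9.2), (33.8, 6.3), (55.3, 13.5)],
    "Ec.MS/BS": [(63.5, 10.9), (74.2, 8), (33.1, 9.3), (39.5, 9.5),
                 (78.3, 11.4), (88.2, 7.7), (47.6, 8.5), (67.1, 10.8)],
    "Ec.MAR": [(1.21, 0.21), (1.50, 0.21), (0.94, 0.22), (1.11, 0.2),
               (1.22, 0.16), (1.61, 0.15), (1.24, 0.41), (1.61, 0.38)],
    "Ec.BFR/BS": [(0.76, 0.12), (1.11, 0.19), (0.32, 0.12), (0.45, 0.17),
                  (0.94, 0.08), (1.42, 0.16), (0.57, 0.13), (1.08, 0.29)],
    "Ps.sLS/BS": [(25.6, 12), (28.7, 14), (21.3, 4.8), (24.9, 16.9),
                  (49.4, 25.6), (12.4, 13.2), (35.0, 8.2), (37.1, 10.7)],
    "Ps.dLS/BS": [(13.3, 7.5), (19.6, 13.2), (1.9, 1.6), (4.8, 3),
                  (13.4, 7.5), (83.2, 19.4), (16.0, 10.2), (59.1, 13.8)],
    "Ps.MS/BS": [(22.4, 13.2), (34.0, 9.9), (11.9, 3.6), (16.5, 8.2),
                 (33.6, 15.4), (89.4, 12.8), (31.2, 11.5), (77.7, 8.7)],
    "Ps.MAR": [(0.92, 0.33), (0.89, 0.31), (0.57, 0.13), (0.72, 0.22),
               (0.95, 0.19), (1.63, 0.1), (0.63, 0.08), (1.09, 0.11)],
    "Ps.BFR/BS": [(0.28, 0.17), (0.32, 0.16), (0.07, 0.02), (0.13, 0.09),
                  (0.34, 0.21), (1.46, 0.23), (0.21, 0.08), (0.84, 0.09)],
}

_LIMB_ORDER = [("LC", 10, "control"), ("LC", 10, "loaded"),
               ("LC", 26, "control"), ("LC", 26, "loaded"),
               ("KO", 10, "control"), ("KO", 10, "loaded"),
               ("KO", 26, "control"), ("KO", 26, "loaded")]


def _expand(table: dict, day=None) -> pd.DataFrame:
    rows = []
    for outcome, cells in table.items():
        for (gt, age, limb), (mean, sd) in zip(_LIMB_ORDER, cells):
            row = {"outcome": outcome, "genotype": gt, "age": age, "limb": limb,
                   "mean": float(mean), "sd": float(sd)}
            if day is not None:
                row["day"] = day
            rows.append(row)
    return pd.DataFrame(rows)


def microct_summary() -> pd.DataFrame:
    """Static micro-CT group means ± SD (days 0 and 15), long format."""
    return pd.concat([_expand(_MICRO_CT[0], day=0), _expand(_MICRO_CT[15], day=15)],
                     ignore_index=True)


def histomorphometry_summary() -> pd.DataFrame:
    """Dynamic histomorphometry group means ± SD, long format."""
    return _expand(_HISTO)


def microct_cell(outcome: str, genotype: str, age: int, limb: str, day: int):
    df = microct_summary()
    m = df[(df.outcome == outcome) & (df.genotype == genotype) & (df.age == age)
           & (df.limb == limb) & (df.day == day)]
    return float(m["mean"].iloc[0]), float(m["sd"].iloc[0])


def histo_cell(outcome: str, genotype: str, age: int, limb: str):
    df = histomorphometry_summary()
    m = df[(df.outcome == outcome) & (df.genotype == genotype) & (df.age == age)
           & (df.limb == limb)]
    return float(m["mean"].iloc[0]), float(m["sd"].iloc[0])
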