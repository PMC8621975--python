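"""Tab-delimited data-table dialect shared by the balancer, the synthetic
data generator, and the CLI.

Data tables carry one row per measurement with columns ``!QuantityType``,
``!Reaction``, ``!Compound``, ``!State``, ``!Mean``, ``!GeometricStd``;
values are on linear scale (mM, 1/s, dimensionless) and transformed to
natural logs internally. Recognised quantity types:

* ``equilibrium constant``
* ``forward catalytic rate constant`` / ``backward catalytic rate constant``
* ``velocity constant``
* ``Michaelis constant``          (needs !Reaction and !Compound)
* ``concentration``               (needs !Compound and !State)
* ``enzyme concentration``        (needs !Reaction and !State)
* ``flux``                        (needs !Reaction and !State; may be <= 0,
                                   no GeometricStd interpretation)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DATA_COLUMNS = [
    "!QuantityType",
    "!Reaction",
    "!Compound",
    "!State",
    "!Mean",
    "!GeometricStd",
]

QUANTITY_TYPES = {
    "equilibrium constant": "keq",
    "forward catalytic rate constant": "kcat_fwd",
    "backward catalytic rate constant": "kcat_bwd",
    "velocity constant": "kv",
    "Michaelis constant": "km",
    "concentration": "conc",
    "enzyme concentration": "enzyme",
    "flux": "flux",
}
QUANTITY_NAMES = {v: k for k, v in QUANTITY_TYPES.items()}


def empty_data_table() -> pd.DataFrame:
    return pd.DataFrame(columns=DATA_COLUMNS)


def data_row(kind, mean, gsd=np.nan, reaction="", compound="", state="") -> dict:
    return {
        "!QuantityType": QUANTITY_NAMES[kind],
        "!Reaction": reaction,
        "!Compound": compound,
        "!State": state,
        "!Mean": mean,
        "!GeometricStd": gsd,
    }


def read_data_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("!QuantityType", "!Mean") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in DATA_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df["!Mean"] = df["!Mean"].astype(float)
    df["!GeometricStd"] = df["!GeometricStd"].replace("", "nan").astype(float)
    bad = set(df["!QuantityType"]) - set(QUANTITY_TYPES)
    if bad:
        raise ValueError(f"{path}: unknown quantity types {sorted(bad)}")
    return df[DATA_COLUMNS]


def write_data_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def flux_matrix(table: pd.DataFrame, reaction_ids: list[str]) -> pd.DataFrame:
    """Extract the per-state flux matrix (reactions x states) from a data
    table; every (reaction, state) pair must be present exactly once."""
    rows = table[table["!QuantityType"] == QUANTITY_NAMES["flux"]]
    if rows.empty:
        raise ValueError("no flux rows in table")
    states = sorted(rows["!State"].unique())
    mat = pd.DataFrame(np.nan, index=reaction_ids, columns=states)
    for _, r in rows.iterrows():
        mat.loc[r["!Reaction"], r["!State"]] = r["!Mean"]
    if mat.isna().any().any():
        missing = [
            (i, c) for i in mat.index for c in mat.columns if np.isnan(mat.loc[i, c])
        ]
        raise ValueError(f"incomplete flux table; missing {missing[:5]}...")
    return mat


def read_priors(path) -> dict[str, tuple[float, float]]:
    """Priors table with columns !QuantityType, !Median, !GeometricStd;
    returns kind -> (median, gsd)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, tuple[float, float]] = {}
    for _, r in df.iterrows():
        qt = r["!QuantityType"]
        kind = QUANTITY_TYPES.get(qt, qt)
        out[kind] = (float(r["!Median"]), float(r["!GeometricStd"]))
    return out
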