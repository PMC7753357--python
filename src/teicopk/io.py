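"""File formats: NONMEM-style event CSV, MIC CSV, YAML config, reports.

Event datasets use the column layout
``ID,TIME,AMT,RATE,DV,EVID,MDV,WT,SCR,AGE,SEX,LLOQFL`` with times in hours
from each subject's first dose, ``DV`` written as ``.`` on dose rows, and
SEX coded 1 = male / 0 = female.  Report CSVs carry a provenance header
(``# key: value`` comment lines: config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .targets import MICDistribution

__all__ = [
    "write_tdm_csv",
    "read_tdm_csv",
    "read_mic_csv",
    "write_report",
    "read_report",
    "config_hash",
]

TDM_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "WT", "SCR", "AGE", "SEX", "LLOQFL"]


def write_tdm_csv(df: pd.DataFrame, path) -> None:
    """Write an event-record dataset; missing DV/AMT/RATE become ``.``."""
    out = df.reindex(columns=TDM_COLUMNS).copy()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(TDM_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            cells = []
            for col, val in zip(TDM_COLUMNS, row):
                if isinstance(val, float) and np.isnan(val):
                    cells.append(".")
                elif col in ("ID", "EVID", "MDV", "SEX", "LLOQFL"):
                    cells.append(str(int(val)))
                else:
                    cells.append(format(float(val), ".10g"))
            fh.write(",".join(cells) + "\n")


def read_tdm_csv(path) -> pd.DataFrame:
    """Read an event-record dataset written by :func:`write_tdm_csv`."""
    df = pd.read_csv(path, na_values=["."], comment="#")
    missing = [c for c in ("ID", "TIME", "DV", "EVID") if c not in df.columns]
    if missing:
        raise ValueError(f"dataset at {path} lacks required columns {missing}")
    for col in ("ID", "EVID"):
        df[col] = df[col].astype(int)
    for col in ("MDV", "SEX", "LLOQFL"):
        if col in df.columns:
            df[col] = df[col].fillna(0).astype(int)
    bad = df[(df["EVID"] == 0) & (~np.isfinite(df["DV"]))]
    if len(bad):
        rows = (bad.index + 2).tolist()  # +2: header line and 1-based numbering
        raise ValueError(f"observation rows with missing DV at lines {rows}")
    return df


def read_mic_csv(path) -> MICDistribution:
    """Read a MIC distribution (columns ``mic_mg_per_L,frequency``)."""
    return MICDistribution.from_csv(path)


def config_hash(config) -> str:
    """Short stable hash of a configuration object (dataclass or mapping)."""
    obj = asdict(config) if is_dataclass(config) else dict(config)
    obj.pop("outdir", None)  # where results land is not part of the analysis
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(df: pd.DataFrame, path, seed=None, config=None, extra: dict | None = None) -> None:
    """Write a tidy CSV with a ``#``-comment provenance header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"teicopk_version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_hash"] = config_hash(config)
    if extra:
        meta.update(extra)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
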