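"""Delimited-text readers and writers for every pipeline table.

All formats are headed, delimiter-configurable plain text; every writer's
output round-trips through the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import gaskin, vfa as vfa_mod
from .community import OtuTable
from .errors import InvalidParameterError

DEFAULT_SEP = "\t"


# -- cow records -----------------------------------------------------------

def write_cow_table(cows: pd.DataFrame, path, sep: str = DEFAULT_SEP) -> None:
    cows.to_csv(path, sep=sep, index=False)


def read_cow_table(path, sep: str = DEFAULT_SEP) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype={"cow_id": str, "period": str})


# -- gas curves ------------------------------------------------------------

def write_gas_curves(curves, gas_path, bottles_path, sep: str = DEFAULT_SEP) -> None:
    """Long-format recordings plus a bottle metadata table."""
    recs, bottles = [], []
    for c in curves:
        recs.append(pd.DataFrame({"bottle_id": c.bottle_id, "time_h": c.time,
                                  "cum_gas_ml": c.volume}))
        bottles.append({"bottle_id": c.bottle_id, "sample_mass": c.sample_mass,
                        **{k: c.meta.get(k) for k in
                           ("run", "emitter", "diet", "cnsl", "replicate", "is_blank")}})
    pd.concat(recs, ignore_index=True).to_csv(gas_path, sep=sep, index=False)
    pd.DataFrame(bottles).to_csv(bottles_path, sep=sep, index=False)


def read_gas_curves(gas_path, bottles_path, sep: str = DEFAULT_SEP):
    long = pd.read_csv(gas_path, sep=sep, dtype={"bottle_id": str})
    bottles = pd.read_csv(bottles_path, sep=sep, dtype={"bottle_id": str}).set_index("bottle_id")
    curves = []
    for bid, grp in long.groupby("bottle_id", sort=False):
        grp = grp.sort_values("time_h")
        row = bottles.loc[bid]
        meta = {k: row[k] for k in ("run", "emitter", "diet", "cnsl", "replicate")}
        meta["is_blank"] = bool(row["is_blank"])
        curves.append(gaskin.GasCurve(bid, grp["time_h"].to_numpy(),
                                      grp["cum_gas_ml"].to_numpy(),
                                      sample_mass=float(row["sample_mass"]), meta=meta))
    return curves


# -- headspace series ------------------------------------------------------

def write_headspace(series, path, sep: str = DEFAULT_SEP) -> None:
    """Concentrations are stored as percentages, as recorded."""
    recs = [pd.DataFrame({"bottle_id": s.bottle_id, "time_h": s.time,
                          "ch4_pct": s.ch4_fraction * 100.0}) for s in series]
    pd.concat(recs, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_headspace(path, sep: str = DEFAULT_SEP):
    long = pd.read_csv(path, sep=sep, dtype={"bottle_id": str})
    out = []
    for bid, grp in long.groupby("bottle_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(gaskin.HeadspaceSeries(bid, grp["time_h"].to_numpy(),
                                          grp["ch4_pct"].to_numpy() / 100.0))
    return out


# -- VFA profiles ----------------------------------------------------------

def write_vfa_table(profiles, path, sep: str = DEFAULT_SEP) -> None:
    rows = []
    for i, p in enumerate(profiles):
        row = {"sample_id": p.meta.get("sample_id", f"vfa{i + 1}"),
               "mode": p.mode, "total": p.total}
        row.update({a: getattr(p, a) for a in vfa_mod.ACIDS})
        row.update({k: p.meta.get(k) for k in ("run", "emitter", "diet", "cnsl", "is_blank")})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_vfa_table(path, sep: str = DEFAULT_SEP):
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    profiles = []
    for _, row in df.iterrows():
        meta = {k: row[k] for k in ("run", "emitter", "diet", "cnsl") if k in row}
        meta["is_blank"] = bool(row["is_blank"]) if "is_blank" in row else False
        meta["sample_id"] = row["sample_id"]
        profiles.append(vfa_mod.VFAProfile(
            *[float(row[a]) for a in vfa_mod.ACIDS],
            total=float(row["total"]), mode=str(row["mode"]), meta=meta))
    return profiles


# -- OTU tables ------------------------------------------------------------

def write_otu_table(table: OtuTable, otu_path, meta_path, sep: str = DEFAULT_SEP) -> None:
    """OTUs as rows, samples as columns, final column the taxonomy string."""
    out = table.counts.T.copy()
    out.insert(len(out.columns), "taxonomy", table.taxonomy.loc[out.index])
    out.to_csv(otu_path, sep=sep, index_label="otu_id")
    table.metadata.to_csv(meta_path, sep=sep, index_label="sample_id")


def read_otu_table(otu_path, meta_path, sep: str = DEFAULT_SEP) -> OtuTable:
    df = pd.read_csv(otu_path, sep=sep, dtype={"otu_id": str}).set_index("otu_id")
    if "taxonomy" not in df.columns:
        raise InvalidParameterError("OTU table must have a final taxonomy column")
    taxonomy = df["taxonomy"].rename_axis(None)
    counts = (df.drop(columns=["taxonomy"]).T.astype(np.int64)
              .rename_axis(index=None, columns=None))
    metadata = (pd.read_csv(meta_path, sep=sep, dtype={"sample_id": str})
                .set_index("sample_id").rename_axis(None))
    return OtuTable(counts=counts, metadata=metadata, taxonomy=taxonomy)


def write_clade_map(clade_map: dict, path, sep: str = DEFAULT_SEP) -> None:
    pd.DataFrame({"pattern": list(clade_map), "clade": list(clade_map.values())}).to_csv(
        path, sep=sep, index=False)


def read_clade_map(path, sep: str = DEFAULT_SEP) -> dict:
    df = pd.read_csv(path, sep=sep)
    return dict(zip(df["pattern"], df["clade"]))


# -- generic helpers -------------------------------------------------------

def write_table(df: pd.DataFrame, path, sep: str = DEFAULT_SEP, index=False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index)


def read_table(path, sep: str = DEFAULT_SEP) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)
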