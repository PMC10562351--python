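"""Flat-file persistence for synthetic site datasets.

One directory per site: stays.csv, events_creatinine.csv,
events_urine.csv, events_vitals.csv, events_labs.csv, medications.csv,
dialysis.csv. Times are decimal hours, 0-based at ICU admission
(pre-admission records are negative). Vitals/labs tables are long-form
(stay_id, variable, time_h, value).
"""

from __future__ import annotations

import os
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .types import EventStream, IcuStay

__all__ = ["write_site", "load_site"]

STAY_COLUMNS = ["stay_id", "site_id", "age", "sex", "weight",
                "admission_source", "discharge_time", "era", "esrd",
                "prior_rrt", "first_icu_admission"]


def write_site(stays: Sequence[IcuStay], out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame([{c: getattr(s, c) for c in STAY_COLUMNS}
                  for s in stays]).to_csv(
        os.path.join(out_dir, "stays.csv"), index=False)

    def _long(rows: List[dict], name: str, cols: List[str]) -> None:
        pd.DataFrame(rows, columns=cols).to_csv(
            os.path.join(out_dir, name), index=False)

    creat, urine, vitals, labs, meds, hd = [], [], [], [], [], []
    for s in stays:
        creat += [{"stay_id": s.stay_id, "time_h": t, "value": v}
                  for t, v in zip(s.creatinine.times, s.creatinine.values)]
        urine += [{"stay_id": s.stay_id, "time_h": t, "volume_ml": v}
                  for t, v in zip(s.urine.times, s.urine.values)]
        for var, es in s.vitals.items():
            vitals += [{"stay_id": s.stay_id, "variable": var,
                        "time_h": t, "value": v}
                       for t, v in zip(es.times, es.values)]
        for var, es in s.labs.items():
            labs += [{"stay_id": s.stay_id, "variable": var,
                      "time_h": t, "value": v}
                     for t, v in zip(es.times, es.values)]
        meds += [{"stay_id": s.stay_id, "drug_class": c, "time_h": t}
                 for c, t in s.medications]
        hd += [{"stay_id": s.stay_id, "time_h": t} for t in s.dialysis_times]
    _long(creat, "events_creatinine.csv", ["stay_id", "time_h", "value"])
    _long(urine, "events_urine.csv", ["stay_id", "time_h", "volume_ml"])
    _long(vitals, "events_vitals.csv", ["stay_id", "variable", "time_h", "value"])
    _long(labs, "events_labs.csv", ["stay_id", "variable", "time_h", "value"])
    _long(meds, "medications.csv", ["stay_id", "drug_class", "time_h"])
    _long(hd, "dialysis.csv", ["stay_id", "time_h"])


def _streams_by_stay(df: pd.DataFrame, value_col: str
                     ) -> Dict[str, EventStream]:
    out = {}
    for sid, g in df.groupby("stay_id", sort=False):
        g = g.sort_values("time_h")
        out[sid] = EventStream(g["time_h"].to_numpy(),
                               g[value_col].to_numpy())
    return out


def load_site(in_dir: str) -> List[IcuStay]:
    def _read(name: str) -> pd.DataFrame:
        return pd.read_csv(os.path.join(in_dir, name))

    stays_df = _read("stays.csv")
    creat = _streams_by_stay(_read("events_creatinine.csv"), "value")
    urine = _streams_by_stay(_read("events_urine.csv"), "volume_ml")
    vitals_df = _read("events_vitals.csv")
    labs_df = _read("events_labs.csv")
    meds_df = _read("medications.csv")
    hd_df = _read("dialysis.csv")

    def _nested(df: pd.DataFrame) -> Dict[str, Dict[str, EventStream]]:
        out: Dict[str, Dict[str, EventStream]] = {}
        if df.empty:
            return out
        for (sid, var), g in df.groupby(["stay_id", "variable"], sort=False):
            g = g.sort_values("time_h")
            out.setdefault(sid, {})[var] = EventStream(
                g["time_h"].to_numpy(), g["value"].to_numpy())
        return out

    vitals = _nested(vitals_df)
    labs = _nested(labs_df)
    meds: Dict[str, list] = {}
    for _, r in meds_df.iterrows():
        meds.setdefault(r["stay_id"], []).append((r["drug_class"],
                                                  float(r["time_h"])))
    hd: Dict[str, list] = {}
    for _, r in hd_df.iterrows():
        hd.setdefault(r["stay_id"], []).append(float(r["time_h"]))

    stays = []
    for _, row in stays_df.iterrows():
        sid = row["stay_id"]
        stays.append(IcuStay(
            stay_id=sid, site_id=row["site_id"], age=float(row["age"]),
            sex=row["sex"], weight=float(row["weight"]),
            admission_source=row["admission_source"],
            discharge_time=float(row["discharge_time"]), era=row["era"],
            esrd=bool(row["esrd"]), prior_rrt=bool(row["prior_rrt"]),
            first_icu_admission=bool(row["first_icu_admission"]),
            creatinine=creat.get(sid, EventStream.empty("mg/dL")),
            urine=urine.get(sid, EventStream.empty("mL")),
            vitals=vitals.get(sid, {}), labs=labs.get(sid, {}),
            medications=meds.get(sid, []), dialysis_times=hd.get(sid, []),
        ))
    return stays
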