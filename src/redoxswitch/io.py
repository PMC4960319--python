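"""CSV/JSON readers and writers for traces, rate tables, titrations and ITC.

File conventions:

* traces: ``time_s,<channel>`` with a JSON sidecar for metadata;
* kobs tables: ``conc_M,kobs_per_s``;
* redox titrations: ``gsh_M,gssg_M,fraction_reduced`` or the raw-control
  form ``gsh_M,gssg_M,signal_pos,signal_neg,signal_exp``;
* ITC injection tables: ``inj_vol_L,heat_kcal`` plus a JSON config block
  for cell/syringe concentrations.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .scheme import Trace
from .thermo import ITCExperiment, RedoxTitration

__all__ = [
    "write_trace", "read_trace", "write_kobs_table", "read_kobs_table",
    "write_titration", "read_titration", "write_itc", "read_itc",
    "dump_json",
]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def dump_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path


def write_trace(trace: Trace, path: str | Path, sidecar: bool = True) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, trace.channel: trace.signal}).to_csv(
        path, index=False)
    if sidecar:
        dump_json({"channel": trace.channel, "meta": trace.meta},
                  path.with_suffix(".meta.json"))
    return path


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] != 2 or df.columns[0] != "time_s":
        raise ValueError(f"{path}: expected columns time_s,<channel>")
    channel = df.columns[1]
    meta = {}
    side = path.with_suffix(".meta.json")
    if side.exists():
        meta = json.loads(side.read_text()).get("meta", {})
    return Trace(times=df["time_s"].to_numpy(), signal=df[channel].to_numpy(),
                 channel=channel, meta=meta)


def write_kobs_table(points, path: str | Path) -> Path:
    pts = np.asarray(points, dtype=float)
    pd.DataFrame({"conc_M": pts[:, 0], "kobs_per_s": pts[:, 1]}).to_csv(
        Path(path), index=False)
    return Path(path)


def read_kobs_table(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"conc_M", "kobs_per_s"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns conc_M,kobs_per_s")
    return df[["conc_M", "kobs_per_s"]].to_numpy()


def write_titration(titr: RedoxTitration, path: str | Path) -> Path:
    cols = {"gsh_M": titr.gsh, "gssg_M": titr.gssg}
    if titr.signal_exp is not None:
        cols.update({"signal_pos": titr.signal_pos, "signal_neg": titr.signal_neg,
                     "signal_exp": titr.signal_exp})
    else:
        cols["fraction_reduced"] = titr.fraction_reduced
    pd.DataFrame(cols).to_csv(Path(path), index=False)
    return Path(path)


def read_titration(path: str | Path) -> RedoxTitration:
    df = pd.read_csv(path)
    if not {"gsh_M", "gssg_M"} <= set(df.columns):
        raise ValueError(f"{path}: expected gsh_M and gssg_M columns")
    kw = dict(gsh=df["gsh_M"].to_numpy(), gssg=df["gssg_M"].to_numpy())
    if "fraction_reduced" in df.columns:
        kw["fraction_reduced"] = df["fraction_reduced"].to_numpy()
    elif {"signal_pos", "signal_neg", "signal_exp"} <= set(df.columns):
        kw.update(signal_pos=df["signal_pos"].to_numpy(),
                  signal_neg=df["signal_neg"].to_numpy(),
                  signal_exp=df["signal_exp"].to_numpy())
    else:
        raise ValueError(f"{path}: no fraction_reduced or control-signal columns")
    return RedoxTitration(**kw)


def write_itc(exp: ITCExperiment, path: str | Path) -> Path:
    path = Path(path)
    heats = exp.heats if exp.heats is not None else np.full(len(exp.injections), np.nan)
    pd.DataFrame({"inj_vol_L": exp.injections, "heat_kcal": heats}).to_csv(
        path, index=False)
    dump_json({"cell": exp.cell, "syringe": exp.syringe, "model": exp.model,
               "cell_volume": exp.cell_volume, "temperature": exp.temperature,
               "competitor_Kd": exp.competitor_Kd},
              path.with_suffix(".config.json"))
    return path


def read_itc(path: str | Path) -> ITCExperiment:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"inj_vol_L", "heat_kcal"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns inj_vol_L,heat_kcal")
    cfg_path = path.with_suffix(".config.json")
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing ITC config block {cfg_path}")
    cfg = json.loads(cfg_path.read_text())
    heats = df["heat_kcal"].to_numpy()
    return ITCExperiment(
        cell=cfg["cell"], syringe=cfg["syringe"],
        injections=list(df["inj_vol_L"].to_numpy()),
        heats=None if np.all(np.isnan(heats)) else heats,
        model=cfg.get("model", "single_site"),
        cell_volume=cfg.get("cell_volume", 200e-6),
        temperature=cfg.get("temperature", 308.15),
        competitor_Kd=cfg.get("competitor_Kd"),
    )
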