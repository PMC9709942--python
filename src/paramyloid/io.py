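"""Tabular input/output: plate-reader CSVs, relaxation tables, gradient decays.

All on-disk formats are plain text (long-format CSV plus YAML for
configuration) so datasets remain diffable and portable.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import yaml

from .diffusion import DiffusionDataset
from .kinetics_fit import AggregationTrace
from .paramag import RelaxationSeries, VisibilityRecord

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_relaxation_csv",
    "read_relaxation_csv",
    "write_visibility_csv",
    "read_visibility_csv",
    "write_diffusion_csv",
    "read_diffusion_csv",
    "load_config",
    "dump_json",
]


def write_traces_csv(traces, path) -> None:
    """Long-format plate-reader export: one row per (well, time point)."""
    rows = []
    for i, tr in enumerate(traces):
        for t, s in zip(tr.t, tr.signal):
            rows.append(
                {
                    "time_s": t, "well": i, "signal": s, "cu_M": tr.cu_conc,
                    "ab_M": tr.ab_conc, "dye": tr.dye, "seeded": tr.seeded,
                    "seed_mass_M": tr.seed_mass, "replicate": tr.replicate,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces_csv(path):
    df = pd.read_csv(path)
    traces = []
    for _, g in df.groupby("well", sort=True):
        g = g.sort_values("time_s")
        traces.append(
            AggregationTrace(
                t=g["time_s"].to_numpy(),
                signal=g["signal"].to_numpy(),
                cu_conc=float(g["cu_M"].iloc[0]),
                ab_conc=float(g["ab_M"].iloc[0]),
                dye=str(g["dye"].iloc[0]),
                seeded=bool(g["seeded"].iloc[0]),
                seed_mass=float(g["seed_mass_M"].iloc[0]),
                replicate=int(g["replicate"].iloc[0]),
            )
        )
    return traces


def write_relaxation_csv(series, path) -> None:
    rows = []
    for s in series:
        for d, i in zip(s.delays, s.intensities):
            rows.append(
                {
                    "residue": s.residue, "atom": s.atom, "delay_s": d,
                    "intensity": i, "state": s.state, "kind": s.kind,
                    "j_hnha_hz": s.j_hnha if s.j_hnha is not None else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_relaxation_csv(path):
    df = pd.read_csv(path)
    series = []
    for (res, atom, state, kind), g in df.groupby(
        ["residue", "atom", "state", "kind"], sort=True
    ):
        g = g.sort_values("delay_s")
        j = g["j_hnha_hz"].iloc[0]
        series.append(
            RelaxationSeries(
                residue=int(res), atom=str(atom),
                delays=g["delay_s"].to_numpy(),
                intensities=g["intensity"].to_numpy(),
                state=str(state), kind=str(kind),
                j_hnha=None if pd.isna(j) else float(j),
            )
        )
    return series


def write_visibility_csv(records, path) -> None:
    pd.DataFrame(
        [
            {
                "residue": r.residue, "atom": r.atom, "experiment": r.experiment,
                "dia_visible": r.dia_visible, "para_visible": r.para_visible,
                "nucleus_class": r.nucleus_class,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_visibility_csv(path):
    df = pd.read_csv(path)
    return [
        VisibilityRecord(
            residue=int(r.residue), atom=str(r.atom), experiment=str(r.experiment),
            dia_visible=bool(r.dia_visible), para_visible=bool(r.para_visible),
            nucleus_class=str(r.nucleus_class),
        )
        for r in df.itertuples()
    ]


def write_diffusion_csv(datasets, path) -> None:
    rows = []
    for i, ds in enumerate(datasets):
        for g, inten in zip(ds.gradients, ds.intensities):
            rows.append(
                {
                    "series_id": i, "gradient": g, "intensity": inten,
                    "delta_s": ds.delta, "big_delta_s": ds.big_delta,
                    "temperature_K": ds.temperature, "metal": ds.metal,
                    "ratio": ds.ratio,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_diffusion_csv(path):
    df = pd.read_csv(path)
    datasets = []
    for _, g in df.groupby("series_id", sort=True):
        datasets.append(
            DiffusionDataset(
                gradients=g["gradient"].to_numpy(),
                intensities=g["intensity"].to_numpy(),
                delta=float(g["delta_s"].iloc[0]),
                big_delta=float(g["big_delta_s"].iloc[0]),
                temperature=float(g["temperature_K"].iloc[0]),
                metal=str(g["metal"].iloc[0]),
                ratio=float(g["ratio"].iloc[0]),
            )
        )
    return datasets


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
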