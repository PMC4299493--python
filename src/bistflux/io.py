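"""Plain-text persistence for event sets, time series and fit reports.

Cytometry events are written one CSV per timepoint (columns ``event_id,
log10_fl``) with a JSON sidecar carrying the timepoint metadata, plus a
manifest CSV (``path, time_h``) tying a series together.  Tidy CSV is used
for growth, depletion and promoter series; fit reports go to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CytometryEventSet, DepletionTrace, GrowthCurve


def write_event_series(events: list[CytometryEventSet], outdir) -> Path:
    """Write one CSV + JSON sidecar per timepoint and a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ev in enumerate(events):
        stem = f"timepoint_{i:02d}"
        pd.DataFrame({
            "event_id": np.arange(ev.n),
            "log10_fl": ev.values,
        }).to_csv(outdir / f"{stem}.csv", index=False)
        with open(outdir / f"{stem}.json", "w") as fh:
            json.dump({"time_h": ev.time, **ev.meta}, fh, indent=1)
        rows.append({"path": f"{stem}.csv", "time_h": ev.time})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_event_series(manifest) -> list[CytometryEventSet]:
    """Load a series previously written by :func:`write_event_series`."""
    manifest = Path(manifest)
    base = manifest.parent
    out = []
    for _, row in pd.read_csv(manifest).iterrows():
        df = pd.read_csv(base / row["path"])
        sidecar = (base / row["path"]).with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        meta.pop("time_h", None)
        out.append(CytometryEventSet(
            time=float(row["time_h"]),
            values=df["log10_fl"].to_numpy(),
            meta=meta,
        ))
    return out


def growth_curve_frame(curve: GrowthCurve) -> pd.DataFrame:
    return pd.DataFrame({"time_h": curve.times, "counts_per_ml": curve.counts})


def depletion_frame(trace: DepletionTrace) -> pd.DataFrame:
    return pd.DataFrame({
        "time_h": trace.times,
        "substrate_g_per_l": trace.substrate,
        "counts_per_ml": trace.counts,
    })


def write_fit_report(fit, path) -> None:
    """Serialize a dataclass fit result (nested dataclasses included) to JSON."""

    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(fit, fh, default=enc, indent=1)
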