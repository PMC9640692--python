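"""File writers and readers for traces, events and run metadata.

Outputs are plain CSV/JSON with 9 significant digits, deterministic for a
fixed config + seed:

* ``trace.csv``   — ``time_min,volume_um3,n_ori,<model columns>``
* ``events.csv``  — ``event,time_min,volume_um3,n_ori_before,v_star,generation``
* ``meta.json``   — full parameter echo including the seed
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .engine import LineageRecord

_FMT = "%.9g"

# provenance of the default parameter values, echoed into meta.json: keys
# anchored in the primary literature vs. calibration decisions of this
# package (see docs/methods.md)
DEFAULT_PROVENANCE = {
    "t_c": "literature",
    "tau_b": "literature",
    "tau_d2": "literature",
    "alpha_l": "literature-ratio",  # 4.6x the datA rate
    "beta_data": "literature-scale",
}


def write_outputs(
    record: LineageRecord,
    config: RunConfig,
    outdir: str | Path,
    stats: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write the deterministic file set for one run; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    trace_path = outdir / "trace.csv"
    record.trace.to_csv(trace_path, index=False, float_format=_FMT)
    paths["trace"] = trace_path

    ini = record.initiations.copy()
    ini.insert(0, "event", "initiation")
    div = pd.DataFrame(
        {
            "event": "division",
            "time_min": record.divisions["time_min"],
            "volume_um3": record.divisions["volume_before"],
            "n_ori_before": np.nan,
            "v_star": np.nan,
            "generation": record.divisions["generation"],
        }
    )
    events = pd.concat([ini, div], ignore_index=True)
    events = events.sort_values(
        ["time_min", "event"], kind="stable"
    ).reset_index(drop=True)
    events_path = outdir / "events.csv"
    events.to_csv(events_path, index=False, float_format=_FMT)
    paths["events"] = events_path

    meta = {
        "replisim_version": __version__,
        "config": config.to_dict(),
        "seed": config.engine.seed,
        "n_initiations": int(len(record.initiations)),
        "n_divisions": int(len(record.divisions)),
        "defaults_provenance": DEFAULT_PROVENANCE,
    }
    meta_path = outdir / "meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=_json_default) + "\n")
    paths["meta"] = meta_path

    for name, frame in (stats or {}).items():
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format=_FMT)
        paths[name] = p
    return paths


def read_events(path: str | Path) -> pd.DataFrame:
    """Reload an events.csv written by :func:`write_outputs`."""
    return pd.read_csv(path)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
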