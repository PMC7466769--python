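"""Output writers: beat-summary CSV, full-trace HDF5, run manifest JSON.

Every run writes a manifest carrying the configuration hash, package
version and wall time, so any result file can be traced back to the exact
experiment that produced it.  Reruns of the same configuration are
bit-identical (the model has no stochastic elements).
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .analytics import extract_beat_metrics, espvr_multibeat
from .engine import Timecourse

__all__ = ["write_outputs", "beat_summary"]


def beat_summary(timecourse: Timecourse) -> pd.DataFrame:
    """One row per beat with the system-level properties.

    Beats that are not at periodic steady state keep their values but are
    flagged in the ``steady`` column.
    """
    try:
        espvr = espvr_multibeat(timecourse)
    except ValueError:
        espvr = np.nan
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for beat in range(timecourse.n_beats):
            metrics = extract_beat_metrics(timecourse, beat, espvr=espvr)
            row = metrics.as_series()
            row["beat"] = beat + 1
            row["steady"] = metrics.steady
            rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["beat"] + [c for c in df.columns if c not in ("beat",)]
    return df[cols]


def write_outputs(timecourse: Timecourse, destination: str | Path,
                  wall_time_s: float | None = None) -> dict[str, Path]:
    """Write the standard output bundle for a completed run.

    Produces ``beats.csv`` (per-beat metrics), ``timecourse.h5`` (full
    1 kHz trace) and ``manifest.json`` (config + hash + provenance) under
    ``destination``.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    beats_path = dest / "beats.csv"
    summary = beat_summary(timecourse)
    summary.to_csv(beats_path, index=False)

    h5_path = dest / "timecourse.h5"
    with h5py.File(h5_path, "w") as fh:
        grp = fh.create_group("timecourse")
        for col in timecourse.data.columns:
            grp.create_dataset(col, data=timecourse.data[col].to_numpy(),
                               compression="gzip", compression_opts=4)
        fh.attrs["config_hash"] = timecourse.config.content_hash()
        fh.attrs["version"] = __version__

    config_path = dest / "config.yaml"
    config_path.write_text(timecourse.config.to_yaml())

    manifest_path = dest / "manifest.json"
    manifest = {
        "config_hash": timecourse.config.content_hash(),
        "version": __version__,
        "n_beats": timecourse.n_beats,
        "n_samples": len(timecourse.data),
        "wall_time_s": wall_time_s if wall_time_s is not None
        else time.time() - t0,
        "files": {"beats": beats_path.name, "timecourse": h5_path.name,
                  "config": config_path.name},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {"beats": beats_path, "timecourse": h5_path,
            "config": config_path, "manifest": manifest_path}
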