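"""Delimited-text readers and writers for the pipeline's exchange objects.

All formats are tab-separated with a header row; trace and dataset files
carry scalar metadata in ``# key=value`` comment lines so a file round-trips
without sidecar information.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clamp import ClampDataset, ClampTrace
from .kinetics import LifetimeForceCurve

__all__ = [
    "write_curve", "read_curve",
    "write_datasets", "read_datasets",
    "write_trace", "read_trace",
    "write_counts", "read_counts",
    "write_ensemble",
]


def write_curve(curve: LifetimeForceCurve, path: str | Path) -> None:
    df = pd.DataFrame({
        "force_pN": curve.forces,
        "lifetime_s": curve.mean_lifetimes,
        "error_s": curve.errors if curve.errors is not None else np.nan,
    })
    df.to_csv(path, sep="\t", index=False)


def read_curve(path: str | Path) -> LifetimeForceCurve:
    df = pd.read_csv(path, sep="\t", comment="#")
    errors = None
    if "error_s" in df and not df["error_s"].isna().all():
        errors = df["error_s"].to_numpy()
    return LifetimeForceCurve(
        forces=df["force_pN"].to_numpy(),
        mean_lifetimes=df["lifetime_s"].to_numpy(),
        errors=errors,
    )


def write_datasets(datasets: list[ClampDataset], path: str | Path) -> None:
    rows = []
    for ds in datasets:
        for lt, c in zip(ds.lifetimes, ds.censored):
            rows.append((ds.clamp_force, lt, int(c)))
    df = pd.DataFrame(rows, columns=["force_pN", "lifetime_s", "censored"])
    with open(path, "w") as fh:
        fh.write(f"# max_duration_s={datasets[0].max_duration}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_meta(path: str | Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = float(v)
    return meta


def read_datasets(path: str | Path) -> list[ClampDataset]:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for f, grp in df.groupby("force_pN", sort=True):
        out.append(ClampDataset(
            clamp_force=float(f),
            lifetimes=grp["lifetime_s"].to_numpy(),
            censored=grp["censored"].to_numpy().astype(bool),
            max_duration=meta.get("max_duration_s", np.inf),
        ))
    return out


def write_trace(trace: ClampTrace, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": trace.time,
        "force_pN": trace.force,
        "height_nm": trace.height,
    })
    with open(path, "w") as fh:
        fh.write(f"# setpoint_pN={trace.setpoint}\n")
        fh.write(f"# sampling_rate_hz={trace.sampling_rate}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trace(path: str | Path) -> ClampTrace:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return ClampTrace(
        time=df["time_s"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        height=df["height_nm"].to_numpy(),
        setpoint=meta["setpoint_pN"],
        sampling_rate=meta["sampling_rate_hz"],
    )


def write_counts(forces: np.ndarray, counts: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame({
        "force_pN": forces,
        "n1": counts[:, 0].astype(int),
        "n2": counts[:, 1].astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path):
    df = pd.read_csv(path, sep="\t", comment="#")
    return df["force_pN"].to_numpy(), df[["n1", "n2"]].to_numpy()


def write_ensemble(result, path: str | Path) -> None:
    df = pd.DataFrame({
        "force": result.forces,
        "mean_lifetime": result.mean_lifetimes,
        "sem": result.sem,
        "n": result.n_runs,
    })
    with open(path, "w") as fh:
        fh.write(f"# arrangement={result.arrangement}\n")
        fh.write(f"# seed={result.seed}\n")
        df.to_csv(fh, sep="\t", index=False)
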