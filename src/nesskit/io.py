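"""Serialisation of decompositions and trajectories (plain-text formats).

Decomposition parameters are stored as JSON documents carrying the basis
ordering version, so coefficient indices are unambiguous; trajectories as
CSV with a JSON sidecar describing integration settings.  Round trips are
exact (JSON preserves double precision).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .helmholtz import FitReport, HelmholtzParams
from .polybasis import ORDERING_VERSION, enumerate_monomials
from .systems import Trajectory

__all__ = ["save_params", "load_params", "save_trajectory", "load_trajectory"]


def params_to_dict(params: HelmholtzParams) -> dict:
    doc = {
        "format": "nesskit-helmholtz-params",
        "ordering_version": ORDERING_VERSION,
        "n": params.basis.n,
        "m": params.basis.m,
        "h": list(map(float, params.h)),
        "q": {
            f"{i + 1},{j + 1}": list(map(float, blk))
            for (i, j), blk in sorted(params.q.items())
            if np.any(blk != 0)
        },
        "Gamma": list(map(float, params.Gamma)),
        "diagonal_free": bool(params.diagonal_free),
        "gauge": {k: float(v) if isinstance(v, (int, float)) else v
                  for k, v in params.gauge.items()},
    }
    if params.fit_report is not None:
        doc["fit_report"] = dataclasses.asdict(params.fit_report)
    return doc


def save_params(params: HelmholtzParams, path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=1))


def load_params(path) -> HelmholtzParams:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "nesskit-helmholtz-params":
        raise ValueError(f"{path}: not a decomposition parameter document")
    if doc.get("ordering_version") != ORDERING_VERSION:
        raise ValueError(
            f"{path}: basis ordering version {doc.get('ordering_version')!r} "
            f"does not match this build ({ORDERING_VERSION}); refusing to "
            "reinterpret coefficient indices"
        )
    for fieldname in ("n", "m", "h", "Gamma"):
        if fieldname not in doc:
            raise ValueError(f"{path}: missing required field {fieldname!r}")
    basis = enumerate_monomials(doc["n"], doc["m"])
    q = {}
    for key, blk in doc.get("q", {}).items():
        i, j = (int(t) for t in key.split(","))
        q[(i - 1, j - 1)] = np.asarray(blk, dtype=float)
    report = None
    if "fit_report" in doc:
        report = FitReport(**doc["fit_report"])
    return HelmholtzParams(
        basis=basis,
        h=np.asarray(doc["h"], dtype=float),
        q=q,
        Gamma=np.asarray(doc["Gamma"], dtype=float),
        diagonal_free=doc.get("diagonal_free", True),
        gauge=doc.get("gauge", {}),
        fit_report=report,
    )


def save_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    cols = {"time": traj.times}
    for i in range(traj.n):
        cols[f"x{i + 1}"] = traj.states[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "dt": traj.dt,
        "scheme": traj.scheme,
        "seed": traj.seed,
        "noise_variance": None
        if traj.noise_variance is None
        else list(map(float, traj.noise_variance)),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_trajectory(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    states = df[[c for c in df.columns if c != "time"]].to_numpy()
    times = df["time"].to_numpy()
    dt = float(meta.get("dt", times[1] - times[0]))
    return Trajectory(
        times=times,
        states=states,
        dt=dt,
        scheme=meta.get("scheme", "unknown"),
        seed=meta.get("seed"),
        noise_variance=None
        if meta.get("noise_variance") is None
        else np.asarray(meta["noise_variance"], dtype=float),
    )
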