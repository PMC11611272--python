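"""Result serialization: CSV tables plus JSON provenance manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import params_to_dict
from .sensitivity import OATResult, SobolResult
from .simulate import Trajectory
from .steady import BifurcationPoint, SteadyStateResult

__all__ = [
    "write_trajectory",
    "write_steady_state",
    "write_bifurcation",
    "write_oat",
    "write_sobol",
    "write_manifest",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def write_trajectory(traj: Trajectory, outdir, stem: str = "trajectory"):
    """CSV (time,T,M,C1..CN,TFR or the dimensionless header) + meta JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    traj.to_csv(csv_path)
    _dump(
        {
            "parameters": params_to_dict(traj.params),
            "solver": traj.solver_opts,
            "nfev": traj.nfev,
            "conservation_drift": traj.conservation_drift(),
        },
        outdir / f"{stem}.meta.json",
    )
    return csv_path


def write_steady_state(res: SteadyStateResult, outdir, stem="steady_state"):
    """Fixed point, spectrum and stability class as one JSON document."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{stem}.json"
    _dump(
        {
            "parameters": params_to_dict(res.params),
            "fixed_point": res.fixed_point,
            "residual_norm": res.residual_norm,
            "eigenvalues_re": res.eigenvalues.real,
            "eigenvalues_im": res.eigenvalues.imag,
            "n_zero": res.n_zero,
            "max_re_nonzero": res.max_re_nonzero,
            "stable": bool(res.stable),
            "tfr_fixed": res.tfr,
            "newton_iterations": res.n_iter,
        },
        path,
    )
    return path


def write_bifurcation(points: list[BifurcationPoint], outdir,
                      stem="bifurcation"):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{stem}.csv"
    pd.DataFrame([asdict(p) for p in points])[
        ["mu", "stable", "tfr_fixed", "tfr_max", "tfr_min",
         "max_re_nonzero", "oscillation"]
    ].to_csv(path, index=False)
    return path


def write_oat(result: OATResult, outdir, stem=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"oat_{result.parameter}"
    path = outdir / f"{stem}.csv"
    rows = []
    for m in result.multipliers:
        rows.append({
            "parameter": result.parameter,
            "multiplier": m,
            "cumulative_tf": result.cumulative.get(m, np.nan),
            "oscillation": result.oscillation.get(m, "error"),
            "error": result.errors.get(m, ""),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_sobol(res: SobolResult, outdir, stem=None):
    """Indices CSV, pairwise-S2 CSV and a provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"sobol_{res.case_id}"
    main, pairs = res.to_frames()
    main.to_csv(outdir / f"{stem}.csv", index=False)
    pairs.to_csv(outdir / f"{stem}_pairs.csv", index=False)
    _dump(
        {
            "case": res.case_id,
            "base_N": res.base_N,
            "n_samples": res.n_samples,
            "seed": res.seed,
            "n_boot": res.n_boot,
            "n_failed": res.n_failed,
            "S1": dict(zip(res.names, res.S1)),
            "ST": dict(zip(res.names, res.ST)),
            "S2": {f"{i}:{j}": v for (i, j), v in res.S2.items()},
            "significant_S1": res.significant(1),
            "significant_S2": {f"{i}:{j}": v
                               for (i, j), v in res.significant(2).items()},
        },
        outdir / f"{stem}.json",
    )
    return outdir / f"{stem}.csv"


def write_manifest(outdir, command: str, **provenance):
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("mitofission")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    _dump({"command": command, "package_version": pkg_version, **provenance},
          path)
    return path
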