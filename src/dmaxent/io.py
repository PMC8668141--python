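"""CSV/JSON writers shared by the CLI subcommands.

Everything is plain text: densities and force paths as CSV, run metadata as
a JSON manifest (parameters, seeds, tolerances, package version) written
alongside every output set so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GriddedDensity

__all__ = ["write_manifest", "write_density", "write_forces",
           "write_observables", "write_report"]

_FLOAT_FMT = "%.12g"


def _version() -> str:
    from . import __version__
    return __version__


def write_manifest(outdir, payload: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "dmaxent_version": _version(),
        "python": platform.python_version(),
        **payload,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                               default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_density(dens: GriddedDensity, path, x_name: str = "x") -> Path:
    """Write a density snapshot; verifies the written table still integrates
    to 1 within 1e-6."""
    path = Path(path)
    dens = dens.normalized()  # trapezoid normalization is the file contract
    df = pd.DataFrame({x_name: dens.grid, "density": dens.values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    back = pd.read_csv(path)
    mass = np.trapezoid(back["density"].to_numpy(), back[x_name].to_numpy())
    if abs(mass - 1.0) > 1e-6:
        raise RuntimeError(f"written density integrates to {mass}, not 1")
    return path


def write_forces(times, alpha_path, path, names=None,
                 applied_path=None) -> Path:
    path = Path(path)
    alpha_path = np.asarray(alpha_path)
    d = alpha_path.shape[1]
    names = names or [f"alpha{i}" for i in range(d)]
    data = {"t": np.asarray(times)}
    for i, nm in enumerate(names):
        data[f"{nm}_eff"] = alpha_path[:, i]
    if applied_path is not None:
        applied_path = np.asarray(applied_path)
        for i, nm in enumerate(names):
            data[f"{nm}_applied"] = applied_path[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_observables(times, observables: dict, path, obs_names,
                      ses: dict | None = None) -> Path:
    """One wide CSV: t, then <obs>_<method> columns (and optional SEs)."""
    path = Path(path)
    data = {"t": np.asarray(times)}
    for method, arr in observables.items():
        arr = np.asarray(arr)
        for i, nm in enumerate(obs_names):
            data[f"{nm}_{method}"] = arr[i]
    if ses:
        for method, arr in ses.items():
            arr = np.asarray(arr)
            for i, nm in enumerate(obs_names):
                data[f"{nm}_{method}_se"] = arr[i]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_report(report, outdir, obs_names, force_names,
                 manifest_extra: dict | None = None) -> list[Path]:
    """Write a ComparisonReport as a directory of CSVs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if report.observables:
        written.append(write_observables(
            report.times, report.observables, outdir / "observables.csv",
            obs_names, ses=report.ses or None))
    if report.alpha_path is not None:
        written.append(write_forces(report.times, report.alpha_path,
                                    outdir / "forces.csv", names=force_names,
                                    applied_path=report.applied_path))
    if report.kl is not None:
        pd.DataFrame({"t": report.times, "kl": report.kl}).to_csv(
            outdir / "relative_entropy.csv", index=False,
            float_format=_FLOAT_FMT)
        written.append(outdir / "relative_entropy.csv")
    for method, snaps in report.snapshots.items():
        for t, dens in snaps.items():
            if isinstance(dens, GriddedDensity):
                written.append(write_density(
                    dens, outdir / f"density_{method}_t{t:g}.csv"))
            else:  # transition-matrix pmf
                pd.DataFrame({"n": np.arange(len(dens)), "pmf": dens}).to_csv(
                    outdir / f"pmf_{method}_t{t:g}.csv", index=False,
                    float_format=_FLOAT_FMT)
                written.append(outdir / f"pmf_{method}_t{t:g}.csv")
    payload = dict(report.manifest)
    payload.update(manifest_extra or {})
    written.append(write_manifest(outdir, payload))
    return written
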