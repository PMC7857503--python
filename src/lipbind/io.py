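"""File input/output: titration/trace CSV dialects, PDB frames, configs.

CSV files carry ``# key: value`` header lines for assay context followed
by a regular comma-separated table. Coordinate frames use PDB format
(ATOM/HETATM records, multi-frame input as concatenated MODEL/ENDMDL
blocks, CRYST1 for the box), parsed with MDAnalysis.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .docking import PoseSet, SiteDefinition
from .errors import ConfigurationError, InvalidArgumentError
from .geometry import Frame
from .kinetics import KineticTrace
from .titration import TitrationCurve

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_frames_pdb",
    "write_frames_pdb",
    "read_poses_csv",
    "write_poses_csv",
    "load_sites_yaml",
    "load_config",
]

PathLike = Union[str, Path]


def _read_commented_csv(path: PathLike) -> tuple[dict, pd.DataFrame]:
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    body = "\n".join(lines[body_start:])
    df = pd.read_csv(_io.StringIO(body))
    return meta, df


def read_titration_csv(path: PathLike) -> TitrationCurve:
    """Read a titration curve CSV (columns titrant_conc_uM, fluorescence)."""
    meta, df = _read_commented_csv(path)
    required = {"titrant_conc_uM", "fluorescence"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"titration CSV needs columns {sorted(required)}")
    return TitrationCurve.from_arrays(
        df["titrant_conc_uM"].to_numpy(),
        df["fluorescence"].to_numpy(),
        titrant_kind=meta.get("titrant_kind", "IP6"),
        protein_conc=float(meta.get("protein_conc_uM", 1.0)),
        total_lipid_conc=float(meta.get("total_lipid_uM", 125.0)),
        composition_label=meta.get("composition_label", ""),
    )


def write_titration_csv(curve: TitrationCurve, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# titrant_kind: {curve.titrant_kind}\n")
        fh.write(f"# protein_conc_uM: {curve.protein_conc}\n")
        fh.write(f"# total_lipid_uM: {curve.total_lipid_conc}\n")
        fh.write(f"# composition_label: {curve.composition_label}\n")
        fh.write("titrant_conc_uM,fluorescence\n")
        for p in curve.points:
            fh.write(f"{float(p.titrant_conc)!r},{float(p.fluorescence)!r}\n")


def read_trace_csv(path: PathLike) -> list[KineticTrace]:
    """Read kinetic traces (columns time_s, signal[, replicate]).

    A ``replicate`` column yields one trace per replicate id, in order of
    first appearance.
    """
    meta, df = _read_commented_csv(path)
    if not {"time_s", "signal"}.issubset(df.columns):
        raise ConfigurationError("trace CSV needs columns time_s, signal")
    dead_time = float(meta.get("dead_time_s", 1.4e-3))
    traces = []
    if "replicate" in df.columns:
        for _, grp in df.groupby("replicate", sort=False):
            traces.append(
                KineticTrace(
                    time=grp["time_s"].to_numpy(),
                    signal=grp["signal"].to_numpy(),
                    dead_time=dead_time,
                )
            )
    else:
        traces.append(
            KineticTrace(
                time=df["time_s"].to_numpy(),
                signal=df["signal"].to_numpy(),
                dead_time=dead_time,
            )
        )
    return traces


def write_trace_csv(
    traces: Sequence[KineticTrace], path: PathLike, dead_time: Optional[float] = None
) -> None:
    if not traces:
        raise InvalidArgumentError("no traces to write")
    if dead_time is None:
        dead_time = max(tr.dead_time for tr in traces)
    with open(path, "w") as fh:
        fh.write(f"# dead_time_s: {dead_time}\n")
        fh.write("replicate,time_s,signal\n")
        for i, tr in enumerate(traces):
            for t, s in zip(tr.time, tr.signal):
                fh.write(f"{i},{float(t)!r},{float(s)!r}\n")


def read_frames_pdb(path: PathLike, frame_dt_ns: float = 0.1) -> list[Frame]:
    """Read one or more PDB MODELs into Frame objects.

    Element (hence mass) is inferred from the atom name when the element
    column is empty; frame times are ``frame_index * frame_dt_ns``.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    frames = []
    for i, _ in enumerate(u.trajectory):
        atoms = u.atoms
        box = None
        dims = atoms.dimensions
        if dims is not None and all(d > 0 for d in dims[:3]):
            box = (float(dims[0]), float(dims[1]), float(dims[2]))
        segids = (
            atoms.segids
            if hasattr(atoms, "segids") and len(set(atoms.segids)) > 0
            else np.array([""] * len(atoms))
        )
        frames.append(
            Frame(
                atom_names=atoms.names.astype(object),
                resnames=atoms.resnames.astype(object),
                resids=atoms.resids,
                segids=np.asarray(segids, dtype=object),
                xyz=atoms.positions.astype(float),
                box=box,
                time=i * frame_dt_ns,
            )
        )
    return frames


def write_frames_pdb(frames: Sequence[Frame], path: PathLike) -> None:
    """Write frames as concatenated PDB MODEL blocks."""
    if not frames:
        raise InvalidArgumentError("no frames to write")
    with open(path, "w") as fh:
        if frames[0].box is not None:
            lx, ly, lz = frames[0].box
            fh.write(
                f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for imodel, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {imodel:4d}\n")
            serial = 1
            for name, resname, resid, segid, (x, y, z) in zip(
                frame.atom_names,
                frame.resnames,
                frame.resids,
                frame.segids,
                frame.xyz,
            ):
                nm = str(name)
                pad_name = f" {nm:<3s}" if len(nm) < 4 else nm[:4]
                fh.write(
                    f"ATOM  {serial % 100000:5d} {pad_name} {str(resname)[:4]:<4s}"
                    f"{'A'}{int(resid) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"      {str(segid)[:4]:<4s}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_poses_csv(path: PathLike) -> PoseSet:
    """Read docking-pose reference points (columns run_id, x, y, z)."""
    _, df = _read_commented_csv(path)
    if not {"x", "y", "z"}.issubset(df.columns):
        raise ConfigurationError("pose CSV needs columns x, y, z")
    labels = (
        tuple(df["run_id"].tolist()) if "run_id" in df.columns else None
    )
    return PoseSet(
        positions=df[["x", "y", "z"]].to_numpy(dtype=float), run_labels=labels
    )


def write_poses_csv(poses: PoseSet, path: PathLike) -> None:
    labels = poses.run_labels or tuple(range(poses.n_poses))
    with open(path, "w") as fh:
        fh.write("run_id,x,y,z\n")
        for lab, (x, y, z) in zip(labels, poses.positions):
            fh.write(f"{lab},{float(x)!r},{float(y)!r},{float(z)!r}\n")


def load_sites_yaml(path: PathLike) -> list[SiteDefinition]:
    """Site definitions: ``{sites: {name: [resid, ...], ...}}``."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "sites" not in data:
        raise ConfigurationError("sites YAML must contain a 'sites' mapping")
    out = []
    for name, resids in data["sites"].items():
        out.append(SiteDefinition(str(name), tuple(int(r) for r in resids)))
    return out


def load_config(path: PathLike) -> dict:
    """Load a YAML key-value configuration file."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a key-value mapping")
    return data
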