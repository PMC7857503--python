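"""End-to-end orchestration: config -> staged analyses -> run report.

A run is described by a single YAML config selecting stages and inputs;
the report collects every numeric result together with the constants
actually used, the seed and a config hash, and can be rendered as JSON,
TSV tables, or a markdown summary using the conventional table formats
(K_x as value x 10^-6 at 2 significant figures, dG at one decimal).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .docking import DEFAULT_SITES, cluster_poses, tabulate_site_occupancy
from .errors import ConfigurationError, InvalidArgumentError, LipbindError
from .geometry import (
    ContactCriteria,
    ContactSeries,
    HeadgroupSpec,
    basic_residue_contact_total,
    contact_time_statistics,
    interloop_angle,
    DEFAULT_LOOPS,
    phosphate_plane_z,
    protein_com_height,
)
from .io import (
    load_sites_yaml,
    read_frames_pdb,
    read_poses_csv,
    read_titration_csv,
    read_trace_csv,
)
from .kinetics import (
    association_rate_constant,
    average_replicate_traces,
    fit_association,
    fit_dissociation,
)
from .titration import (
    PartitioningInputs,
    analyze_titration,
    apply_titration_controls,
    fit_competition_titration,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "render_report",
    "format_kx_millions",
    "format_delta_g",
]


def format_kx_millions(kx: float) -> str:
    """K_x rendered as value x 10^-6 at 2 significant figures ('300')."""
    millions = kx / 1e6
    if millions == 0:
        return "0"
    exponent = math.floor(math.log10(abs(millions)))
    quantum = 10.0 ** (exponent - 1)
    rounded = round(millions / quantum) * quantum
    if rounded >= 10 or float(rounded).is_integer():
        return f"{rounded:.0f}"
    return f"{rounded:.1f}"


def format_delta_g(delta_g: float) -> str:
    """dG at one decimal place, kcal/mol."""
    return f"{delta_g:.1f}"


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    stages: tuple[str, ...]
    inputs: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: Optional[str] = None

    KNOWN_STAGES = ("titration", "kinetics", "membrane", "poses")

    def __post_init__(self):
        unknown = set(self.stages) - set(self.KNOWN_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ConfigurationError(f"input {key}={path} does not exist")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            stages=tuple(data.get("stages", [])),
            inputs=dict(data.get("inputs", {})),
            constants=dict(data.get("constants", {})),
            seed=int(data.get("seed", 0)),
            out_dir=data.get("out_dir"),
        )

    def partitioning_inputs(self, **overrides) -> PartitioningInputs:
        kwargs = dict(
            k_i=self.constants.get("k_i_uM", 1.8),
            water_molarity=self.constants.get("water_molarity_M", 55.5),
            temperature=self.constants.get("temperature_K", 298.15),
        )
        kwargs.update(overrides)
        return PartitioningInputs(**kwargs)


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    results: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "results": self.results,
            "tables": {
                name: df.to_dict(orient="records")
                for name, df in self.tables.items()
            },
            "warnings": list(self.warnings),
            "provenance": self.provenance,
        }


def _stage_titration(config: RunConfig, report: RunReport) -> None:
    curve = read_titration_csv(config.inputs["titration_csv"])
    if "titration_control_csv" in config.inputs:
        control = read_titration_csv(config.inputs["titration_control_csv"])
        curve = apply_titration_controls(curve, control)
    fit = fit_competition_titration(curve)
    accessible = config.constants.get(
        "accessible_lipid_uM", curve.total_lipid_conc / 2.0
    )
    inputs = config.partitioning_inputs(accessible_lipid=accessible)
    part = analyze_titration(fit.ic50, inputs)
    report.results["titration"] = {
        "composition_label": curve.composition_label,
        "ic50_uM": fit.ic50,
        "ic50_stderr_uM": fit.stderr.get("ic50"),
        "delta_f_max": fit.delta_f_max,
        "offset_c": fit.offset_c,
        "kx": part.kx,
        "kx_millions_printed": format_kx_millions(part.kx),
        "delta_g_kcal_mol": part.delta_g,
        "delta_g_printed": format_delta_g(part.delta_g),
        "constants": {
            "k_i_uM": inputs.k_i,
            "water_molarity_M": inputs.water_molarity,
            "accessible_lipid_uM": inputs.accessible_lipid,
            "temperature_K": inputs.temperature,
        },
    }


def _stage_kinetics(config: RunConfig, report: RunReport) -> None:
    out: dict = {}
    accessible = config.constants.get("accessible_lipid_uM", 37.5)
    inputs = config.partitioning_inputs(accessible_lipid=accessible)
    if "association_csv" in config.inputs:
        traces = read_trace_csv(config.inputs["association_csv"])
        trace = average_replicate_traces(traces) if len(traces) > 1 else traces[0]
        fit = fit_association(trace)
        out["association"] = {
            "k_obs_per_s": fit.k_obs,
            "delta_f_max": fit.delta_f_max,
            "offset_c": fit.offset_c,
            "n_replicates": trace.n_replicates_averaged,
        }
    if "dissociation_csv" in config.inputs:
        traces = read_trace_csv(config.inputs["dissociation_csv"])
        trace = average_replicate_traces(traces) if len(traces) > 1 else traces[0]
        model = config.constants.get("dissociation_model", "auto")
        fit = fit_dissociation(trace, model=model)
        out["dissociation"] = {
            "model": fit.model,
            "rates_per_s": list(fit.rates),
            "amplitude_fractions_pct": list(fit.amplitude_fractions),
            "offset_c": fit.offset_c,
            "aicc": fit.information_criterion,
        }
    if "association" in out and "dissociation" in out:
        which = config.constants.get("koff_component", "fast")
        rates = out["dissociation"]["rates_per_s"]
        fracs = out["dissociation"]["amplitude_fractions_pct"]
        if which == "fast":
            k_off = rates[0]
        elif which == "slow":
            k_off = rates[-1]
        elif which == "amplitude_weighted":
            k_off = float(
                sum(r * f for r, f in zip(rates, fracs)) / sum(fracs)
            )
        else:
            raise ConfigurationError(f"unknown koff_component {which!r}")
        rate = association_rate_constant(
            out["association"]["k_obs_per_s"], k_off, inputs
        )
        out["kon_x"] = {
            "kon_x_per_s": rate.kon_x,
            "kon_x_millions": rate.kon_x / 1e6,
            "koff_component": which,
            "accessible_lipid_uM": inputs.accessible_lipid,
        }
    if not out:
        raise ConfigurationError("kinetics stage needs association/dissociation CSVs")
    report.results["kinetics"] = out


def _stage_membrane(config: RunConfig, report: RunReport) -> None:
    frames = read_frames_pdb(config.inputs["frames_pdb"])
    criteria = ContactCriteria(
        lys_cutoff=config.constants.get("lys_cutoff_A", 5.0),
        arg_cutoff=config.constants.get("arg_cutoff_A", 6.3),
        his_cutoff=config.constants.get("his_cutoff_A", 6.1),
    )
    headgroups = (
        HeadgroupSpec(config.constants["headgroup_atoms"])
        if "headgroup_atoms" in config.constants
        else HeadgroupSpec()
    )
    heights, angles_a, angles_b = [], [], []
    for frame in frames:
        plane = phosphate_plane_z(frame, "protein_facing")
        heights.append(protein_com_height(frame, plane))
        angles_a.append(
            interloop_angle(
                frame, DEFAULT_LOOPS["beta2-beta3"], DEFAULT_LOOPS["beta6-beta7"]
            )
        )
        angles_b.append(
            interloop_angle(
                frame, DEFAULT_LOOPS["beta6-beta7"], DEFAULT_LOOPS["beta3-beta4"]
            )
        )
    series = ContactSeries.from_trajectory(frames, criteria, headgroups)
    window = config.constants.get("window", {"last_fraction": 0.5})
    stats = contact_time_statistics(series, window)
    totals = basic_residue_contact_total(series)
    report.results["membrane"] = {
        "n_frames": len(frames),
        "com_height_mean_A": float(np.mean(heights)),
        "com_height_sd_A": float(np.std(heights)),
        "alpha_deg_mean": float(np.mean(angles_a)),
        "beta_deg_mean": float(np.mean(angles_b)),
    }
    report.tables["contact_statistics"] = stats
    report.tables["basic_residue_totals"] = totals


def _stage_poses(config: RunConfig, report: RunReport) -> None:
    poses = read_poses_csv(config.inputs["poses_csv"])
    protein = read_frames_pdb(config.inputs["protein_pdb"])[0]
    sites = (
        load_sites_yaml(config.inputs["sites_yaml"])
        if "sites_yaml" in config.inputs
        else list(DEFAULT_SITES)
    )
    cutoff = config.constants.get("linkage_cutoff_A", 5.0)
    radius = config.constants.get("assign_radius_A", 8.0)
    labels = cluster_poses(poses, cutoff)
    fractions = tabulate_site_occupancy(labels, poses, sites, protein, radius)
    report.results["poses"] = {
        "n_poses": poses.n_poses,
        "n_clusters": int(labels.max()) + 1,
        "largest_cluster_fraction": float(np.mean(labels == 0)),
        "site_fractions": fractions,
        "linkage_cutoff_A": cutoff,
        "assign_radius_A": radius,
    }


_STAGE_FUNCS = {
    "titration": _stage_titration,
    "kinetics": _stage_kinetics,
    "membrane": _stage_membrane,
    "poses": _stage_poses,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the selected stages; identical config+seed gives an
    identical numeric payload."""
    blob = json.dumps(
        {
            "stages": list(config.stages),
            "inputs": config.inputs,
            "constants": config.constants,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    report = RunReport(
        provenance={
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": config.seed,
            "package_version": __version__,
        }
    )
    for stage in config.stages:
        try:
            _STAGE_FUNCS[stage](config, report)
        except LipbindError as exc:
            report.warnings.append(f"stage {stage} failed: {exc}")
            report.results.setdefault("errors", {})[stage] = str(exc)
    return report


def render_report(report: RunReport, out_dir, formats=("json",)) -> list[Path]:
    """Write the report as JSON (lossless), TSV tables, and/or markdown."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt == "json":
            path = out_dir / "report.json"
            path.write_text(json.dumps(report.to_jsonable(), indent=2, default=float))
            written.append(path)
        elif fmt == "tsv":
            for name, df in report.tables.items():
                path = out_dir / f"{name}.tsv"
                df.to_csv(path, sep="\t", index=False)
                written.append(path)
            if not report.tables:
                path = out_dir / "tables.tsv"
                path.write_text("table\tnote\n")
                written.append(path)
        elif fmt == "markdown":
            path = out_dir / "report.md"
            path.write_text(_markdown_summary(report))
            written.append(path)
        else:
            raise InvalidArgumentError(f"unsupported format {fmt!r}")
    return written


def _markdown_summary(report: RunReport) -> str:
    lines = ["# Run summary", ""]
    tit = report.results.get("titration")
    if tit:
        lines += [
            "| composition | IC50 (uM) | Kx x 10^-6 | dG (kcal/mol) |",
            "|---|---|---|---|",
            "| {} | {:.0f} | {} | {} |".format(
                tit["composition_label"] or "-",
                tit["ic50_uM"],
                tit["kx_millions_printed"],
                tit["delta_g_printed"],
            ),
            "",
        ]
    kin = report.results.get("kinetics")
    if kin:
        lines.append("## Kinetics")
        for key, block in kin.items():
            lines.append(f"- **{key}**: {json.dumps(block, default=float)}")
        lines.append("")
    mem = report.results.get("membrane")
    if mem:
        lines.append("## Membrane metrics")
        lines.append(f"- {json.dumps(mem, default=float)}")
        lines.append("")
    pos = report.results.get("poses")
    if pos:
        lines.append("## Docking-site occupancy")
        for name, frac in pos["site_fractions"].items():
            lines.append(f"- {name}: {100 * frac:.1f}%")
        lines.append("")
    if report.warnings:
        lines.append("## Warnings")
        lines += [f"- {w}" for w in report.warnings]
        lines.append("")
    return "\n".join(lines)
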