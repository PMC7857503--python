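"""Synthetic data generators with recorded ground truth.

Raw titrations, stopped-flow shots, MD trajectories and docking outputs
for this system are not publicly deposited, so every analysis module is
exercised against synthetic inputs whose generating parameters — and,
for coordinate fixtures, the per-frame analytic values of every geometric
metric — are recorded in a :class:`GroundTruth` object. Analysis code
never reads the ground truth; tests compare against it.

Defaults mirror the study conditions: 1 uM protein premixed with 125 uM
total lipid for titrations; >= 8 averaged stopped-flow shots with a 1.4 ms
dead time; bilayer frames saved every 0.1 ns with the protein centre of
mass ~23 A above the phosphate plane; 510 docking poses.

All noise is additive Gaussian; every generator is bit-reproducible from
its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_DEAD_TIME_S
from .errors import GenerationError, InvalidArgumentError
from .geometry import Frame, HIS_RING_ATOMS
from .kinetics import KineticTrace
from .docking import PoseSet
from .titration import TitrationCurve, competition_model

__all__ = [
    "GroundTruth",
    "simulate_titration",
    "simulate_kinetic_trace",
    "simulate_replicate_traces",
    "build_membrane_protein_frames",
    "sample_pose_cloud",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters plus analytic expected values."""

    params: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)


def default_titrant_grid(n_points: int = 20, lo: float = 1.0, hi: float = 1e4):
    """Log-spaced IP6 grid (uM) with an explicit zero point prepended."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, n_points - 1)])


def simulate_titration(
    ic50: float = 620.0,
    delta_f_max: float = 1.0,
    offset: float = 0.0,
    grid: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    **curve_kwargs,
) -> tuple[TitrationCurve, GroundTruth]:
    """Competition titration on a hyperbolic displacement curve.

    ``noise_sd`` is the absolute SD of the additive Gaussian noise (for
    the conventional "2% of amplitude", pass ``0.02 * delta_f_max``).
    """
    if grid is None:
        grid = default_titrant_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidArgumentError("empty titrant grid")
    if np.any(np.diff(grid) <= 0):
        raise InvalidArgumentError("grid must be strictly ascending")
    clean = competition_model(grid, delta_f_max, ic50, offset)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=grid.shape) if noise_sd else clean
    curve_kwargs.setdefault("composition_label", "synthetic")
    curve = TitrationCurve.from_arrays(grid, noisy, **curve_kwargs)
    truth = GroundTruth(
        params={
            "ic50": ic50,
            "delta_f_max": delta_f_max,
            "offset": offset,
            "noise_sd": noise_sd,
            "seed": seed,
        },
        values={"clean_signal": clean},
    )
    return curve, truth


def simulate_kinetic_trace(
    model: str = "association",
    rates: Sequence[float] = (30.0,),
    amplitudes: Sequence[float] = (1.0,),
    offset: float = 0.0,
    dt: float = 1e-3,
    duration: float = 0.3,
    dead_time: float = DEFAULT_DEAD_TIME_S,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[KineticTrace, GroundTruth]:
    """A stopped-flow trace on a half-open grid [0, duration).

    ``model`` is ``"association"`` (rising single exponential; one rate)
    or ``"dissociation"`` (sum of falling exponentials; one or two rates).
    Points before ``dead_time`` are generated from the same closed form
    but flagged for exclusion through the trace's dead time.
    """
    rates = tuple(float(r) for r in rates)
    amplitudes = tuple(float(a) for a in amplitudes)
    if any(r <= 0 for r in rates):
        raise InvalidArgumentError("rates must be > 0")
    if len(rates) != len(amplitudes):
        raise InvalidArgumentError("rates/amplitudes length mismatch")
    if duration <= dead_time:
        raise InvalidArgumentError("duration must exceed dead_time")
    t = np.arange(0.0, duration, dt)
    if model == "association":
        if len(rates) != 1:
            raise InvalidArgumentError("association uses exactly one rate")
        clean = amplitudes[0] * (1.0 - np.exp(-rates[0] * t)) + offset
    elif model == "dissociation":
        clean = np.full_like(t, offset)
        for a, k in zip(amplitudes, rates):
            clean = clean + a * np.exp(-k * t)
    else:
        raise InvalidArgumentError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    signal = clean + rng.normal(0.0, noise_sd, size=t.shape) if noise_sd else clean
    trace = KineticTrace(time=t, signal=signal, dead_time=dead_time)
    truth = GroundTruth(
        params={
            "model": model,
            "rates": rates,
            "amplitudes": amplitudes,
            "offset": offset,
            "noise_sd": noise_sd,
            "dead_time": dead_time,
            "seed": seed,
        },
        values={
            "clean_signal": clean,
            "amplitude_fractions": tuple(
                100.0 * a / sum(amplitudes) for a in amplitudes
            ),
        },
    )
    return trace, truth


def simulate_replicate_traces(
    n_replicates: int = 8, seed: int = 0, **kwargs
) -> tuple[list[KineticTrace], GroundTruth]:
    """Replicate shots differing only in their noise stream."""
    if n_replicates < 2:
        raise InvalidArgumentError("need >= 2 replicates")
    traces = []
    truth = None
    for i in range(n_replicates):
        tr, truth = simulate_kinetic_trace(seed=seed + i, **kwargs)
        traces.append(tr)
    return traces, truth


# ---------------------------------------------------------------------------
# Coordinate fixtures


def _tip_triplet(center: np.ndarray, spread: float = 1.5) -> list[np.ndarray]:
    """Three points with centroid exactly at ``center``."""
    offsets = np.array(
        [[spread, 0.0, 0.0], [-spread, spread, 0.0], [0.0, -spread, 0.0]]
    )
    # Make offsets sum to exactly zero so the centroid is exact.
    offsets[2] = -(offsets[0] + offsets[1])
    return [center + o for o in offsets]


def _unit(theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    return np.array([math.sin(th), 0.0, math.cos(th)])


@dataclass
class _AtomBuffer:
    names: list = field(default_factory=list)
    resnames: list = field(default_factory=list)
    resids: list = field(default_factory=list)
    segids: list = field(default_factory=list)
    xyz: list = field(default_factory=list)
    masses: list = field(default_factory=list)

    def add(self, name, resname, resid, segid, pos, mass):
        self.names.append(name)
        self.resnames.append(resname)
        self.resids.append(resid)
        self.segids.append(segid)
        self.xyz.append(np.asarray(pos, dtype=float))
        self.masses.append(mass)


_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}


def _add_lipid(buf: _AtomBuffer, resname: str, resid: int, p_pos: np.ndarray):
    """Minimal lipid: phosphorus plus two headgroup oxygens at the same z."""
    buf.add("P", resname, resid, "MEMB", p_pos, _MASS["P"])
    buf.add("O13", resname, resid, "MEMB", p_pos + np.array([0.8, 0.0, 0.0]), _MASS["O"])
    buf.add("O14", resname, resid, "MEMB", p_pos + np.array([-0.8, 0.0, 0.0]), _MASS["O"])


def build_membrane_protein_frames(
    n_frames: int = 20,
    frame_dt_ns: float = 0.1,
    leaflet_z: float = 20.0,
    lattice_spacing: float = 8.0,
    n_lipids_per_type: Optional[dict] = None,
    com_height: float = 23.0,
    tip_radius: float = 15.0,
    alpha_deg: float = 35.0,
    beta_deg: float = 76.0,
    contact_schedule: Optional[dict] = None,
    height_schedule: Optional[Sequence[float]] = None,
    anchor_dip_distance: float = 2.0,
    seed: int = 0,
) -> tuple[list[Frame], GroundTruth]:
    """Planar two-leaflet bilayer plus a pseudo-protein, with exact truth.

    Geometry
    --------
    Lipid phosphorus atoms sit exactly at z = +/-``leaflet_z`` on a square
    lattice, so the upper phosphate plane is exactly ``leaflet_z``. The
    pseudo-protein is built mirror-symmetric about its centre of mass —
    every residue has a twin at the point-reflected position — so the COM
    is exact by construction; it is placed ``com_height`` above the upper
    plane (optionally modulated per frame by ``height_schedule``). Loop
    tips for the three membrane-binding loops are placed on rays from the
    COM at the prescribed ``alpha_deg`` (beta2-beta3 vs beta6-beta7) and
    ``beta_deg`` (beta6-beta7 vs beta3-beta4) angles.

    Contacts
    --------
    ``contact_schedule`` maps ``(resid, lipid_type) -> per-frame counts``
    (a sequence of ints, length ``n_frames``). For every scheduled pair a
    dedicated set of lipids of that type is laid out around the residue's
    side-chain anchor; in frames where the scheduled count is k, exactly k
    of them are placed within ``anchor_dip_distance`` (< the class cutoff)
    of the anchor and the rest are parked far away. Anchor displacements
    are mirrored on the twin residue so the protein COM never moves.

    Ground truth ``values``: ``plane_z``, per-frame ``com_height``,
    ``angles`` (alpha, beta), per-frame ``contacts`` (the schedule,
    including zeros for unscheduled basic residues), per-residue ``depth``
    of every C-alpha in the first frame.
    """
    if n_lipids_per_type is None:
        n_lipids_per_type = {"POPC": 36, "POPS": 12, "PIP2": 2}
    if contact_schedule is None:
        contact_schedule = {}
    if height_schedule is None:
        height_schedule = [0.0] * n_frames
    height_schedule = list(height_schedule)
    if len(height_schedule) != n_frames:
        raise InvalidArgumentError("height_schedule length must equal n_frames")
    for key, counts in contact_schedule.items():
        if len(counts) != n_frames:
            raise InvalidArgumentError(
                f"contact schedule for {key} must have {n_frames} entries"
            )

    rng = np.random.default_rng(seed)

    # --- static protein layout (local coordinates, COM at origin) -------
    com_local = np.zeros(3)
    tip_dirs = {
        "beta2-beta3": _unit(0.0),
        "beta6-beta7": _unit(alpha_deg),
        "beta3-beta4": _unit(alpha_deg + beta_deg),
    }
    tip_resids = {
        "beta2-beta3": (388, 389, 390),
        "beta6-beta7": (450, 451, 452),
        "beta3-beta4": (406, 407, 408),
    }
    tip_resnames = {
        "beta2-beta3": ("GLU", "ALA", "LYS"),
        "beta6-beta7": ("GLY", "ARG", "PHE"),
        "beta3-beta4": ("SER", "ARG", "GLN"),
    }

    # Basic residues that can take part in contact schedules: anchors at
    # fixed local positions on the membrane-facing side of the protein.
    anchor_residues = {
        398: "LYS",
        410: "LYS",
        412: "LYS",
        392: "ARG",
        449: "HSD",
    }

    protein_atoms: list[tuple] = []  # (name, resname, resid, local_pos, mass)

    def add_res_pair(resid, resname, atoms):
        """A residue and its point-mirrored twin (resid + 1000)."""
        for name, pos, mass in atoms:
            protein_atoms.append((name, resname, resid, np.asarray(pos, float), mass))
        for name, pos, mass in atoms:
            protein_atoms.append(
                (name, resname, resid + 1000, -np.asarray(pos, float), mass)
            )

    for loop, direction in tip_dirs.items():
        tip_center = com_local + tip_radius * direction
        for resid, resname, ca in zip(
            tip_resids[loop], tip_resnames[loop], _tip_triplet(tip_center)
        ):
            atoms = [("CA", ca, _MASS["C"])]
            # basic tip residues need their side-chain anchor atom so the
            # contact scan can resolve them (they stay far from any lipid)
            if resname == "LYS":
                atoms.append(("NZ", ca + np.array([0.0, 0.0, 3.0]), _MASS["N"]))
            elif resname == "ARG":
                atoms.append(("CZ", ca + np.array([0.0, 0.0, 3.0]), _MASS["C"]))
            add_res_pair(resid, resname, atoms)

    # Spread anchor residues along y so their xy positions are >= 40 A
    # apart and far from the loop tips (which lie in the x-z plane).
    anchor_base: dict[int, np.ndarray] = {}
    for i, (resid, resname) in enumerate(sorted(anchor_residues.items())):
        base = np.array([0.0, 40.0 * (i + 1), -com_height + 8.0])
        anchor_base[resid] = base
        atoms = [("CA", base + np.array([0.0, 0.0, 2.0]), _MASS["C"])]
        if resname == "LYS":
            atoms.append(("NZ", base, _MASS["N"]))
        elif resname == "ARG":
            atoms.append(("CZ", base, _MASS["C"]))
        else:  # histidine ring, centroid exactly at base
            ring_offsets = np.array(
                [
                    [1.2, 0.0, 0.0],
                    [0.37, 1.14, 0.0],
                    [-0.97, 0.7, 0.0],
                    [-0.97, -0.7, 0.0],
                    [0.37, -1.14, 0.0],
                ]
            )
            ring_offsets[4] = -ring_offsets[:4].sum(axis=0)
            for name, off in zip(HIS_RING_ATOMS, ring_offsets):
                mass = _MASS["N"] if name.startswith("N") else _MASS["C"]
                atoms.append((name, base + off, mass))
        add_res_pair(resid, resname, atoms)

    # --- static membrane lattice ----------------------------------------
    buf_static = _AtomBuffer()
    order = [t for t, n in n_lipids_per_type.items() for _ in range(n)]
    side = max(1, math.ceil(math.sqrt(len(order))))
    resid_counter = 1
    for leaf_sign in (+1, -1):
        shuffled = list(order)
        rng.shuffle(shuffled)
        for idx, lipid in enumerate(shuffled):
            ix, iy = divmod(idx, side)
            p = np.array(
                [ix * lattice_spacing, iy * lattice_spacing, leaf_sign * leaflet_z]
            )
            _add_lipid(buf_static, lipid, resid_counter, p)
            resid_counter += 1

    # Dedicated contact lipids: per scheduled (resid, type), allocate the
    # maximum simultaneous count. Park position is far from every anchor.
    contact_pool: dict[tuple, list[int]] = {}
    pool_home: dict[int, np.ndarray] = {}
    lipid_types_present = set(n_lipids_per_type)
    for (resid, lipid), counts in contact_schedule.items():
        if resid not in anchor_residues:
            raise GenerationError(f"no anchor residue {resid} in the layout")
        lipid_types_present.add(lipid)
        n_needed = max(counts)
        ids = []
        for j in range(n_needed):
            ids.append(resid_counter)
            pool_home[resid_counter] = np.array(
                [-200.0 - 20.0 * len(pool_home), -200.0, leaflet_z]
            )
            resid_counter += 1
        contact_pool[(resid, lipid)] = ids

    # --- assemble frames --------------------------------------------------
    frames: list[Frame] = []
    com_heights = []
    contacts_truth: dict[tuple, list[int]] = {
        key: list(counts) for key, counts in contact_schedule.items()
    }
    protein_shift_xy = np.array([-120.0, 0.0])  # keep protein clear of lattice

    for f in range(n_frames):
        buf = _AtomBuffer()
        # static lipids
        for name, resname, resid, segid, pos, mass in zip(
            buf_static.names,
            buf_static.resnames,
            buf_static.resids,
            buf_static.segids,
            buf_static.xyz,
            buf_static.masses,
        ):
            buf.add(name, resname, resid, segid, pos, mass)

        h = com_height + height_schedule[f]
        com_world = np.array(
            [protein_shift_xy[0], protein_shift_xy[1], leaflet_z + h]
        )

        # per-frame anchor displacements (mirrored on the twin)
        disp: dict[int, np.ndarray] = {}
        for (resid, lipid), counts in contact_schedule.items():
            if counts[f] > 0:
                target_z = leaflet_z + anchor_dip_distance / 2.0
                base_world = com_world + anchor_base[resid]
                disp.setdefault(resid, np.zeros(3))
                disp[resid] = np.array(
                    [0.0, 0.0, target_z - base_world[2]]
                )

        for name, resname, resid, local, mass in protein_atoms:
            base_resid = resid if resid < 1000 else resid - 1000
            d = disp.get(base_resid, None)
            pos = com_world + local
            if d is not None and resname in ("LYS", "ARG", "HSD", "HSE", "HIS"):
                # move only side-chain anchor atoms, mirrored on the twin
                side_chain = name in ("NZ", "CZ") or name in HIS_RING_ATOMS
                if side_chain:
                    pos = pos + (d if resid < 1000 else -d)
            buf.add(name, resname, resid, "PROT", pos, mass)

        # contact lipids: within dip distance when on, parked when off
        for (resid, lipid), ids in contact_pool.items():
            k = contact_schedule[(resid, lipid)][f]
            anchor_world = com_world + anchor_base[resid]
            if (resid, lipid) in contact_schedule and k > 0:
                anchor_world = anchor_world + disp.get(resid, np.zeros(3))
            for j, lid in enumerate(ids):
                if j < k:
                    angle = 2 * math.pi * j / max(len(ids), 1)
                    offset = np.array(
                        [
                            anchor_dip_distance * math.cos(angle) * 0.7,
                            anchor_dip_distance * math.sin(angle) * 0.7,
                            0.0,
                        ]
                    )
                    p = np.array(
                        [
                            anchor_world[0] + offset[0],
                            anchor_world[1] + offset[1],
                            leaflet_z,
                        ]
                    )
                else:
                    p = pool_home[lid]
                _add_lipid(buf, lipid, lid, p)

        frames.append(
            Frame(
                atom_names=np.array(buf.names, dtype=object),
                resnames=np.array(buf.resnames, dtype=object),
                resids=np.array(buf.resids, dtype=int),
                segids=np.array(buf.segids, dtype=object),
                xyz=np.vstack(buf.xyz),
                masses=np.array(buf.masses, dtype=float),
                time=f * frame_dt_ns,
            )
        )
        com_heights.append(h)

    # first-frame C-alpha depths, from construction
    depths = {}
    com0 = np.array(
        [protein_shift_xy[0], protein_shift_xy[1], leaflet_z + com_heights[0]]
    )
    for name, resname, resid, local, mass in protein_atoms:
        if name == "CA" and resid < 1000:
            depths[resid] = float(com0[2] + local[2] - leaflet_z)

    truth = GroundTruth(
        params={
            "n_frames": n_frames,
            "leaflet_z": leaflet_z,
            "com_height": com_height,
            "alpha_deg": alpha_deg,
            "beta_deg": beta_deg,
            "seed": seed,
            "n_lipids_per_type": dict(n_lipids_per_type),
        },
        values={
            "plane_z": leaflet_z,
            "com_height": com_heights,
            "angles": {"alpha": alpha_deg, "beta": beta_deg},
            "contacts": contacts_truth,
            "ca_depth_frame0": depths,
        },
    )
    return frames, truth


def sample_pose_cloud(
    centers: Sequence[Sequence[float]],
    weights: Sequence[float],
    sd: float = 1.5,
    n: int = 510,
    seed: int = 0,
) -> tuple[PoseSet, GroundTruth]:
    """Poses drawn from a Gaussian mixture around named site centres."""
    centers = np.asarray(centers, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise InvalidArgumentError("centers must be (k, 3)")
    if weights.shape[0] != centers.shape[0]:
        raise InvalidArgumentError("weights/centers length mismatch")
    if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise InvalidArgumentError("weights must be non-negative and sum to 1")
    if sd <= 0:
        raise InvalidArgumentError("sd must be > 0")
    rng = np.random.default_rng(seed)
    labels = rng.choice(centers.shape[0], size=n, p=weights)
    positions = centers[labels] + rng.normal(0.0, sd, size=(n, 3))
    poses = PoseSet(positions=positions, run_labels=tuple(range(n)))
    truth = GroundTruth(
        params={"weights": tuple(weights), "sd": sd, "n": n, "seed": seed},
        values={"labels": labels},
    )
    return poses, truth
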