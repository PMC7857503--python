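"""Membrane-interaction geometry from coordinate frames.

Given snapshots of a peripheral protein above (or inserted into) a lipid
bilayer whose normal is the z axis, this module computes:

* the phosphate plane — mean z of lipid phosphorus atoms in a leaflet;
* protein centre-of-mass height above that plane;
* per-residue insertion depth (C-alpha or a named atom) relative to the
  plane, negative meaning below the plane (inserted);
* loop-tip positions (centroid of three consecutive C-alpha atoms) and the
  angles between loop tips subtended at the protein centre of mass;
* residue-resolved electrostatic contacts between basic side chains and
  anionic lipid headgroups, counted per distinct lipid molecule, plus
  windowed time statistics over a trajectory.

Contacts use side-chain anchors: the lysine amine nitrogen NZ (cutoff
5.0 A), the arginine guanidino carbon CZ (6.3 A), and the centre of mass
of the five histidine imidazole ring heavy atoms (6.1 A). A lipid within
the cutoff through any number of its headgroup heavy atoms counts once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import ARG_CUTOFF_A, HIS_CUTOFF_A, LYS_CUTOFF_A
from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    EmptyWindowError,
    InvalidArgumentError,
    MissingAtomError,
    MissingSelectionError,
)

__all__ = [
    "Frame",
    "Trajectory",
    "ContactCriteria",
    "HeadgroupSpec",
    "LoopDefinition",
    "ContactSeries",
    "DEFAULT_LOOPS",
    "phosphate_plane_z",
    "protein_com_height",
    "residue_depth",
    "loop_tip_position",
    "interloop_angle",
    "lipid_contacts",
    "contact_time_statistics",
    "basic_residue_contact_total",
]

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP",
}
HIS_RESNAMES = {"HIS", "HSD", "HSE", "HSP"}
HIS_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")

# Approximate atomic masses for element inference from atom names.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098, "CL": 35.45, "NA": 22.990,
}


def element_from_atom_name(name: str) -> str:
    """Best-effort element from a PDB/CHARMM atom name (e.g. 'NZ' -> N)."""
    stripped = name.strip()
    if not stripped:
        raise InvalidArgumentError("empty atom name")
    two = stripped[:2].upper()
    if two in ("CL", "NA") and not stripped[0].isdigit():
        return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise InvalidArgumentError(f"cannot infer element from {name!r}")


@dataclass
class Frame:
    """One coordinate snapshot as parallel numpy arrays.

    ``segids`` distinguishes protein segments from lipid molecules when
    residue numbers alone are ambiguous; lipid molecule identity is the
    (segid, residue_number) pair.
    """

    atom_names: np.ndarray  # str
    resnames: np.ndarray  # str
    resids: np.ndarray  # int
    segids: np.ndarray  # str
    xyz: np.ndarray  # (n, 3) float, Angstrom
    masses: Optional[np.ndarray] = None  # amu
    box: Optional[tuple[float, float, float]] = None
    time: float = 0.0  # ns

    def __post_init__(self):
        n = len(self.atom_names)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.segids = np.asarray(self.segids, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (n, 3):
            raise InvalidArgumentError("xyz must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise InvalidArgumentError("coordinates must be finite")
        if self.masses is None:
            self.masses = np.array(
                [
                    _ELEMENT_MASSES.get(element_from_atom_name(a), 12.011)
                    for a in self.atom_names
                ]
            )
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if np.any(self.masses <= 0):
                raise InvalidArgumentError("masses must be > 0")
        if self.box is not None and any(b <= 0 for b in self.box):
            raise InvalidArgumentError("box lengths must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def is_protein(self) -> np.ndarray:
        return np.isin(self.resnames.astype(str), list(PROTEIN_RESNAMES))

    def protein_com(self) -> np.ndarray:
        """Mass-weighted centre of mass of all protein atoms."""
        mask = self.is_protein()
        if not mask.any():
            raise MissingSelectionError("no protein atoms in frame")
        m = self.masses[mask]
        return (self.xyz[mask] * m[:, None]).sum(axis=0) / m.sum()


Trajectory = list  # a trajectory is simply a list of Frame


@dataclass(frozen=True)
class ContactCriteria:
    """Anchor atoms and cutoffs per basic residue class (Angstrom)."""

    lys_cutoff: float = LYS_CUTOFF_A
    arg_cutoff: float = ARG_CUTOFF_A
    his_cutoff: float = HIS_CUTOFF_A

    def __post_init__(self):
        if min(self.lys_cutoff, self.arg_cutoff, self.his_cutoff) <= 0:
            raise InvalidArgumentError("cutoffs must be > 0")

    def cutoff_for(self, resname: str) -> float:
        if resname == "LYS":
            return self.lys_cutoff
        if resname == "ARG":
            return self.arg_cutoff
        if resname in HIS_RESNAMES:
            return self.his_cutoff
        raise ConfigurationError(f"no contact criteria for residue {resname!r}")


# Default CHARMM36-flavoured headgroup heavy-atom names. The anionic
# headgroups are counted from the phosphodiester linkage outward; PC from
# the glycerol backbone outward. Naming is force-field dependent, so these
# lists are fully overrideable.
DEFAULT_HEADGROUPS: dict[str, tuple[str, ...]] = {
    "POPC": (
        "C1", "C2", "C3", "O21", "O31",
        "P", "O11", "O12", "O13", "O14",
        "C11", "C12", "N", "C13", "C14", "C15",
    ),
    "POPS": (
        "P", "O11", "O12", "O13", "O14",
        "C11", "C12", "C13", "N", "O13A", "O13B",
    ),
    "PIP2": (
        "P", "O11", "O12", "O13", "O14",
        "C11", "C12", "C13", "C14", "C15", "C16",
        "O2", "O3", "O4", "O5", "O6",
        "P4", "OP42", "OP43", "OP44",
        "P5", "OP52", "OP53", "OP54",
    ),
}
# Short aliases used by synthetic fixtures and generic inputs.
DEFAULT_HEADGROUPS["PC"] = DEFAULT_HEADGROUPS["POPC"]
DEFAULT_HEADGROUPS["PS"] = DEFAULT_HEADGROUPS["POPS"]
DEFAULT_HEADGROUPS["SAPI"] = DEFAULT_HEADGROUPS["PIP2"]


@dataclass(frozen=True)
class HeadgroupSpec:
    """Headgroup heavy-atom names per lipid residue name."""

    atoms_by_lipid: dict = field(
        default_factory=lambda: dict(DEFAULT_HEADGROUPS)
    )

    def __post_init__(self):
        for lipid, atoms in self.atoms_by_lipid.items():
            if not atoms:
                raise InvalidArgumentError(
                    f"empty headgroup atom list for {lipid!r}"
                )

    @property
    def lipid_types(self) -> tuple[str, ...]:
        return tuple(self.atoms_by_lipid)


@dataclass(frozen=True)
class LoopDefinition:
    """A loop tip: three consecutive residues whose C-alpha centroid is
    taken as the tip position."""

    name: str
    tip_residues: tuple[int, int, int]

    def __post_init__(self):
        if len(self.tip_residues) != 3:
            raise InvalidArgumentError("a loop tip is exactly 3 residues")


#: Loop-tip definitions for the Slp-4 C2A domain (human numbering).
DEFAULT_LOOPS = {
    "beta2-beta3": LoopDefinition("beta2-beta3", (388, 389, 390)),
    "beta6-beta7": LoopDefinition("beta6-beta7", (450, 451, 452)),
    "beta3-beta4": LoopDefinition("beta3-beta4", (406, 407, 408)),
}


def _lipid_phosphorus_mask(frame: Frame) -> np.ndarray:
    is_lipid = ~frame.is_protein()
    is_p = np.array(
        [element_from_atom_name(a) == "P" for a in frame.atom_names]
    )
    return is_lipid & is_p


def phosphate_plane_z(frame: Frame, leaflet: str = "protein_facing") -> float:
    """Mean z of lipid phosphorus atoms in the selected leaflet.

    Leaflet assignment: phosphorus atoms above the bilayer midpoint (the
    mean of all lipid P z coordinates) form the upper leaflet; the
    protein-facing leaflet is the one whose mean P z lies nearer the
    protein centre of mass.
    """
    if leaflet not in ("protein_facing", "upper", "lower"):
        raise InvalidArgumentError(f"unknown leaflet {leaflet!r}")
    mask = _lipid_phosphorus_mask(frame)
    if not mask.any():
        raise MissingSelectionError("no lipid phosphorus atoms in frame")
    z = frame.xyz[mask, 2]
    # A bilayer has two P populations separated by tens of Angstroms; a
    # z-spread below the splitting threshold means a single leaflet.
    if z.max() - z.min() < 15.0:
        upper = lower = z
    else:
        mid = z.mean()
        upper, lower = z[z >= mid], z[z < mid]
        if lower.size == 0:
            lower = upper
    if leaflet == "upper":
        sel = upper
    elif leaflet == "lower":
        sel = lower
    else:
        com_z = frame.protein_com()[2]
        sel = upper if abs(upper.mean() - com_z) <= abs(lower.mean() - com_z) else lower
    if sel.size == 0:
        raise MissingSelectionError(f"no phosphorus atoms in {leaflet} leaflet")
    return float(sel.mean())


def protein_com_height(frame: Frame, plane_z: float) -> float:
    """Height of the protein centre of mass above the phosphate plane."""
    return float(frame.protein_com()[2] - plane_z)


def _residue_mask(frame: Frame, residue_number: int) -> np.ndarray:
    mask = frame.is_protein() & (frame.resids == residue_number)
    if not mask.any():
        raise MissingSelectionError(f"protein residue {residue_number} not found")
    return mask


def residue_depth(
    frame: Frame,
    residue_number: int,
    plane_z: float,
    representation: str = "c_alpha",
    atom_name: Optional[str] = None,
) -> float:
    """z(representative atom) - plane_z; negative means inserted below the
    phosphate plane."""
    if representation == "c_alpha":
        atom = "CA"
    elif representation == "named_atom":
        if not atom_name:
            raise InvalidArgumentError("named_atom representation needs atom_name")
        atom = atom_name
    else:
        raise InvalidArgumentError(f"unknown representation {representation!r}")
    mask = _residue_mask(frame, residue_number) & (
        frame.atom_names.astype(str) == atom
    )
    if not mask.any():
        raise MissingAtomError(
            f"atom {atom!r} absent from residue {residue_number}"
        )
    return float(frame.xyz[mask, 2][0] - plane_z)


def loop_tip_position(frame: Frame, loop: LoopDefinition) -> np.ndarray:
    """Mass-weighted centre of the three tip C-alpha atoms (equal masses,
    so the centroid)."""
    coords, weights = [], []
    for resid in loop.tip_residues:
        mask = _residue_mask(frame, resid) & (frame.atom_names.astype(str) == "CA")
        if not mask.any():
            raise MissingAtomError(f"C-alpha absent from residue {resid}")
        coords.append(frame.xyz[mask][0])
        weights.append(frame.masses[mask][0])
    coords = np.array(coords)
    weights = np.array(weights)
    return (coords * weights[:, None]).sum(axis=0) / weights.sum()


def interloop_angle(
    frame: Frame, loop_a: LoopDefinition, loop_b: LoopDefinition
) -> float:
    """Angle (degrees) at the protein COM between the two loop tips."""
    com = frame.protein_com()
    va = loop_tip_position(frame, loop_a) - com
    vb = loop_tip_position(frame, loop_b) - com
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise DegenerateGeometryError("loop tip coincides with protein COM")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _min_image_dxy(delta: np.ndarray, box) -> np.ndarray:
    """Minimum-image displacement in x-y; z left non-periodic (bilayer
    normal)."""
    if box is not None:
        for axis in (0, 1):
            delta[:, axis] -= box[axis] * np.round(delta[:, axis] / box[axis])
    return delta


def _anchor_point(frame: Frame, resid: int, resname: str) -> np.ndarray:
    mask = _residue_mask(frame, resid)
    names = frame.atom_names[mask].astype(str)
    coords = frame.xyz[mask]
    if resname == "LYS":
        sel = names == "NZ"
        if not sel.any():
            raise MissingAtomError(f"NZ absent from LYS {resid}")
        return coords[sel][0]
    if resname == "ARG":
        sel = names == "CZ"
        if not sel.any():
            raise MissingAtomError(f"CZ absent from ARG {resid}")
        return coords[sel][0]
    # histidine: imidazole ring heavy-atom COM
    sel = np.isin(names, HIS_RING_ATOMS)
    if not sel.any():
        raise MissingAtomError(f"imidazole ring atoms absent from residue {resid}")
    m = frame.masses[mask][sel]
    return (coords[sel] * m[:, None]).sum(axis=0) / m.sum()


def basic_residues(frame: Frame) -> list[tuple[int, str]]:
    """(residue_number, canonical resname) for every Lys/Arg/His residue."""
    mask = frame.is_protein()
    out = []
    seen = set()
    for resid, resname in zip(frame.resids[mask], frame.resnames[mask].astype(str)):
        if resid in seen:
            continue
        seen.add(resid)
        if resname == "LYS" or resname == "ARG":
            out.append((int(resid), resname))
        elif resname in HIS_RESNAMES:
            out.append((int(resid), "HIS"))
    return out


def lipid_contacts(
    frame: Frame,
    criteria: ContactCriteria = ContactCriteria(),
    headgroups: HeadgroupSpec = HeadgroupSpec(),
) -> pd.DataFrame:
    """Distinct-lipid contact counts per basic residue and lipid type.

    Returns a DataFrame with columns ``residue`` (e.g. ``K398``),
    ``resid``, ``lipid_type`` and ``count``. A lipid molecule within the
    residue-class cutoff through one or more headgroup heavy atoms counts
    exactly once.
    """
    lipid_mask = ~frame.is_protein()
    lipid_resnames = set(frame.resnames[lipid_mask].astype(str))
    unknown = lipid_resnames - set(headgroups.atoms_by_lipid)
    if unknown:
        raise ConfigurationError(
            f"lipid types without headgroup definition: {sorted(unknown)}"
        )

    # Collect headgroup atoms per lipid type with molecule ids.
    per_type: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    resnames = frame.resnames.astype(str)
    atom_names = frame.atom_names.astype(str)
    for lipid in sorted(lipid_resnames):
        sel = (
            lipid_mask
            & (resnames == lipid)
            & np.isin(atom_names, headgroups.atoms_by_lipid[lipid])
        )
        mol_ids = np.array(
            [f"{s}:{r}" for s, r in zip(frame.segids[sel], frame.resids[sel])],
            dtype=object,
        )
        # types with no headgroup atoms in the frame still report count 0
        per_type[lipid] = (frame.xyz[sel], mol_ids)

    one_letter = {"LYS": "K", "ARG": "R", "HIS": "H"}
    rows = []
    for resid, resname in basic_residues(frame):
        anchor = _anchor_point(frame, resid, resname)
        cutoff = criteria.cutoff_for(resname)
        label = f"{one_letter[resname]}{resid}"
        for lipid, (coords, mol_ids) in per_type.items():
            delta = coords - anchor[None, :]
            delta = _min_image_dxy(delta, frame.box)
            dist = np.linalg.norm(delta, axis=1)
            contacted = np.unique(mol_ids[dist <= cutoff])
            rows.append(
                {
                    "residue": label,
                    "resid": resid,
                    "lipid_type": lipid,
                    "count": int(contacted.size),
                }
            )
    return pd.DataFrame(rows, columns=["residue", "resid", "lipid_type", "count"])


@dataclass
class ContactSeries:
    """Per-frame contact counts over a trajectory.

    ``table`` columns: time (ns), frame index, residue, resid, lipid_type,
    count.
    """

    table: pd.DataFrame

    @classmethod
    def from_trajectory(
        cls,
        frames: Iterable[Frame],
        criteria: ContactCriteria = ContactCriteria(),
        headgroups: HeadgroupSpec = HeadgroupSpec(),
    ) -> "ContactSeries":
        parts = []
        for i, frame in enumerate(frames):
            df = lipid_contacts(frame, criteria, headgroups)
            df.insert(0, "frame", i)
            df.insert(0, "time", frame.time)
            parts.append(df)
        if not parts:
            raise InvalidArgumentError("empty trajectory")
        return cls(pd.concat(parts, ignore_index=True))

    @property
    def time_span(self) -> tuple[float, float]:
        return float(self.table["time"].min()), float(self.table["time"].max())


def _window_mask(series: ContactSeries, window) -> pd.Series:
    t = series.table["time"]
    t0, t1 = series.time_span
    if window is None:
        window = {"last_fraction": 0.5}
    if isinstance(window, dict) and "last_fraction" in window:
        frac = float(window["last_fraction"])
        if not 0 < frac <= 1:
            raise InvalidArgumentError("last_fraction must be in (0, 1]")
        start = t1 - frac * (t1 - t0)
        mask = t >= start - 1e-12
    else:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise EmptyWindowError("window selects no frames")
    return mask


def contact_time_statistics(
    series: ContactSeries, window=None
) -> pd.DataFrame:
    """Windowed mean and SD of contact counts per residue and lipid type.

    ``window`` is either ``{'last_fraction': f}`` (default: last half of
    the trajectory, mirroring 'averaged over the last 100 ns' of a 200 ns
    run) or an explicit ``(t_start, t_end)`` range in ns. SD is computed
    across saved frames (population SD).
    """
    mask = _window_mask(series, window)
    sub = series.table[mask]
    out = (
        sub.groupby(["residue", "resid", "lipid_type"], sort=True)["count"]
        .agg(mean="mean", sd=lambda s: float(np.std(s, ddof=0)))
        .reset_index()
    )
    return out


def basic_residue_contact_total(series: ContactSeries) -> pd.DataFrame:
    """Per frame, the number of distinct basic residues with >= 1 contact,
    split by lipid type (residues are counted, not contacts)."""
    tab = series.table
    if tab.empty:
        raise InvalidArgumentError("empty contact series")
    touched = tab[tab["count"] >= 1]
    grouped = (
        touched.groupby(["time", "frame", "lipid_type"])["residue"]
        .nunique()
        .reset_index(name="n_residues")
    )
    # Re-insert explicit zeros for frame/type combinations with no contacts.
    frames = tab[["time", "frame"]].drop_duplicates()
    types = tab["lipid_type"].drop_duplicates()
    full = frames.merge(types, how="cross")
    out = full.merge(grouped, on=["time", "frame", "lipid_type"], how="left")
    out["n_residues"] = out["n_residues"].fillna(0).astype(int)
    return out.sort_values(["frame", "lipid_type"]).reset_index(drop=True)
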