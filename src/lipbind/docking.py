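"""Docked-pose clustering and binding-site occupancy tabulation.

Docking runs started from many ligand placements around the protein yield
one final ligand reference point (heavy-atom centroid) per run. Poses are
clustered by single-linkage agglomeration — clusters are the connected
components of the graph joining poses closer than the linkage cutoff —
and each cluster is assigned to the nearest named binding site (e.g. the
conserved lysine cluster, or the membrane-binding loops region) when its
centroid lies within the assignment radius, otherwise to "other". The
output is the fraction of all poses landing in each site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import InvalidArgumentError, MissingSelectionError
from .geometry import Frame, _anchor_point, _residue_mask

__all__ = [
    "PoseSet",
    "SiteDefinition",
    "cluster_poses",
    "cluster_sizes",
    "tabulate_site_occupancy",
    "DEFAULT_SITES",
]


@dataclass(frozen=True)
class PoseSet:
    """Final ligand reference points, one per docking run."""

    positions: np.ndarray  # (n, 3) Angstrom
    run_labels: Optional[tuple] = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise InvalidArgumentError("positions must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        if self.run_labels is not None and len(self.run_labels) != pos.shape[0]:
            raise InvalidArgumentError("run_labels length mismatch")

    @property
    def n_poses(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SiteDefinition:
    """A named binding site centred on the anchor atoms of its residues.

    Anchors follow the contact conventions (Lys NZ, Arg CZ, His ring COM);
    other residues use their C-alpha.
    """

    name: str
    anchor_residues: tuple[int, ...]

    def __post_init__(self):
        if len(self.anchor_residues) < 1:
            raise InvalidArgumentError("a site needs >= 1 anchor residue")

    def center(self, protein_frame: Frame) -> np.ndarray:
        points = []
        resnames = protein_frame.resnames.astype(str)
        for resid in self.anchor_residues:
            mask = _residue_mask(protein_frame, resid)
            resname = str(resnames[mask][0])
            try:
                points.append(_anchor_point(protein_frame, resid, resname))
            except Exception:
                ca = mask & (protein_frame.atom_names.astype(str) == "CA")
                if not ca.any():
                    raise MissingSelectionError(
                        f"no anchor or C-alpha for residue {resid}"
                    )
                points.append(protein_frame.xyz[ca][0])
        return np.mean(points, axis=0)


#: Site definitions for the Slp-4 C2A domain: the conserved lysine cluster
#: (K398/K410/K412) and the tips of the two membrane-binding loops.
DEFAULT_SITES = (
    SiteDefinition("lysine_cluster", (398, 410, 412)),
    SiteDefinition("loops", (388, 389, 390, 450, 451, 452)),
)


def cluster_poses(poses: PoseSet, linkage_cutoff: float = 5.0) -> np.ndarray:
    """Single-linkage cluster labels, 0-based, sorted by descending size.

    Labels are deterministic given input order: clusters of equal size are
    ordered by the first pose index they contain.
    """
    if linkage_cutoff <= 0:
        raise InvalidArgumentError("linkage_cutoff must be > 0")
    n = poses.n_poses
    if n == 1:
        return np.zeros(1, dtype=int)
    raw = fcluster(
        linkage(pdist(poses.positions), method="single"),
        t=linkage_cutoff,
        criterion="distance",
    )
    # Relabel by (descending size, first-seen index).
    order = {}
    for idx, lab in enumerate(raw):
        order.setdefault(lab, [0, idx])
        order[lab][0] += 1
    ranked = sorted(order.items(), key=lambda kv: (-kv[1][0], kv[1][1]))
    remap = {lab: rank for rank, (lab, _) in enumerate(ranked)}
    return np.array([remap[lab] for lab in raw], dtype=int)


def cluster_sizes(labels: np.ndarray) -> np.ndarray:
    """Cluster sizes indexed by label."""
    labels = np.asarray(labels, dtype=int)
    return np.bincount(labels)


def tabulate_site_occupancy(
    labels: np.ndarray,
    poses: PoseSet,
    sites: Sequence[SiteDefinition],
    protein_frame: Frame,
    assign_radius: float = 8.0,
) -> dict[str, float]:
    """Fraction of poses per named site, plus "other"; fractions sum to 1.

    Each cluster is assigned as a whole: its centroid goes to the nearest
    site centre if that lies within ``assign_radius``, else to "other".
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != poses.n_poses:
        raise InvalidArgumentError("labels/poses length mismatch")
    centers = {site.name: site.center(protein_frame) for site in sites}
    fractions = {name: 0.0 for name in centers}
    fractions["other"] = 0.0
    n = poses.n_poses
    for lab in np.unique(labels):
        members = labels == lab
        centroid = poses.positions[members].mean(axis=0)
        best_name, best_dist = "other", np.inf
        for name, center in centers.items():
            d = float(np.linalg.norm(centroid - center))
            if d < best_dist:
                best_name, best_dist = name, d
        if best_dist > assign_radius:
            best_name = "other"
        fractions[best_name] += members.sum() / n
    return fractions
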