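"""Shared fixtures: random coordinate fixtures and assay constants."""

import numpy as np
import pytest
from hypothesis import settings

from lipbind.geometry import (
    DEFAULT_HEADGROUPS,
    HIS_RING_ATOMS,
    Frame,
)
from lipbind.titration import PartitioningInputs

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def pm_inputs():
    """Partitioning constants for the equilibrium titration assay
    (125 uM total lipid -> 62.5 uM accessible)."""
    return PartitioningInputs(
        k_i=1.8, water_molarity=55.5, accessible_lipid=62.5, temperature=298.15
    )


def make_random_contact_frame(rng, n_lipids=40, with_box=False):
    """A disordered frame of lipids plus basic residues for oracle tests.

    Lipid atoms mix headgroup and non-headgroup names; residues carry the
    side-chain anchor atoms the contact definitions require.
    """
    names, resnames, resids, segids, xyz, masses = [], [], [], [], [], []
    box = (60.0, 60.0, 120.0) if with_box else None
    span = np.array(box[:2] + (40.0,)) if with_box else np.array([50.0, 50.0, 40.0])

    resid = 1
    lipid_types = ["POPC", "POPS", "PIP2"]
    for _ in range(n_lipids):
        lipid = lipid_types[rng.integers(len(lipid_types))]
        center = rng.uniform(0, 1, 3) * span
        pool = list(DEFAULT_HEADGROUPS[lipid]) + ["C21", "C31", "C22"]
        n_atoms = rng.integers(3, 7)
        chosen = rng.choice(len(pool), size=n_atoms, replace=False)
        for ai in chosen:
            names.append(pool[ai])
            resnames.append(lipid)
            resids.append(resid)
            segids.append("MEMB")
            xyz.append(center + rng.normal(0, 1.5, 3))
            masses.append(15.999)
        resid += 1

    protein_kinds = ["LYS", "ARG", "HSD", "LYS", "ARG"]
    for kind in protein_kinds:
        center = rng.uniform(0, 1, 3) * span
        names.append("CA")
        resnames.append(kind)
        resids.append(resid)
        segids.append("PROT")
        xyz.append(center)
        masses.append(12.011)
        if kind == "LYS":
            names.append("NZ")
            xyz.append(center + rng.normal(0, 2.0, 3))
            masses.append(14.007)
            resnames.append(kind), resids.append(resid), segids.append("PROT")
        elif kind == "ARG":
            names.append("CZ")
            xyz.append(center + rng.normal(0, 2.0, 3))
            masses.append(12.011)
            resnames.append(kind), resids.append(resid), segids.append("PROT")
        else:
            for ring_name in HIS_RING_ATOMS:
                names.append(ring_name)
                xyz.append(center + rng.normal(0, 1.0, 3))
                masses.append(14.007 if ring_name.startswith("N") else 12.011)
                resnames.append(kind), resids.append(resid), segids.append("PROT")
        resid += 1

    return Frame(
        atom_names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        segids=np.array(segids, dtype=object),
        xyz=np.vstack(xyz),
        masses=np.array(masses),
        box=box,
    )


def brute_force_contacts(frame, criteria, headgroups):
    """All-pairs pure-python contact oracle (no neighbor optimisation).

    Returns {(residue_label, lipid_type): count} using the same anchor and
    cutoff definitions but an independent O(N^2) scan.
    """
    import math

    one_letter = {"LYS": "K", "ARG": "R", "HIS": "H", "HSD": "H", "HSE": "H",
                  "HSP": "H"}
    atoms = list(
        zip(
            frame.atom_names.astype(str),
            frame.resnames.astype(str),
            frame.resids,
            frame.segids.astype(str),
            frame.xyz,
            frame.masses,
        )
    )
    protein_resnames = {"LYS", "ARG", "HSD", "HSE", "HSP", "HIS"}

    # anchors
    anchors = {}
    for name, resname, resid, segid, pos, mass in atoms:
        if resname not in protein_resnames or segid == "MEMB":
            continue
        key = (int(resid), resname)
        anchors.setdefault(key, [])
        if resname == "LYS" and name == "NZ":
            anchors[key].append((pos, 1.0))
        elif resname == "ARG" and name == "CZ":
            anchors[key].append((pos, 1.0))
        elif resname not in ("LYS", "ARG") and name in HIS_RING_ATOMS:
            anchors[key].append((pos, mass))

    out = {}
    for (resid, resname), pts in anchors.items():
        if not pts:
            continue
        total_m = sum(m for _, m in pts)
        anchor = sum(p * m for p, m in pts) / total_m
        if resname == "LYS":
            cutoff = criteria.lys_cutoff
        elif resname == "ARG":
            cutoff = criteria.arg_cutoff
        else:
            cutoff = criteria.his_cutoff
        label = f"{one_letter[resname]}{resid}"
        for lipid, head_atoms in headgroups.atoms_by_lipid.items():
            touched = set()
            for name, rn, rid, segid, pos, _ in atoms:
                if rn != lipid or name not in head_atoms:
                    continue
                d = math.dist(anchor, pos)
                if d <= cutoff:
                    touched.add((segid, int(rid)))
            out[(label, lipid)] = len(touched)
    return out
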