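"""Peptide and modification mass arithmetic for lysine-modification MS.

Covers the computational side of identifying non-enzymatic lysine adducts
on a polybasic protein surface: modification masses from elemental
composition (e.g. phosphogluconoylation, the +258 Da adduct of bacterial
6-phosphogluconolactone, C6H11O9P; phosphorylation, +80 Da, HPO3),
monoisotopic peptide masses, singly-charged b/y fragment-ion ladders with
site-resolved modification shifts, intact-protein mass-shift assignment
at Dalton-level tolerance, and ppm matching for peptide/fragment masses.

Residue and elemental masses come from pyteomics; ladder construction and
shift bookkeeping are implemented here.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from pyteomics import mass as pmass

from .constants import PROTON_MASS_DA
from .errors import InvalidArgumentError, MassLookupError, SequenceError

__all__ = [
    "ModificationSpec",
    "ModifiedPeptide",
    "TolerancePolicy",
    "ShiftMatch",
    "BUILTIN_MODIFICATIONS",
    "modification_mass",
    "peptide_monoisotopic_mass",
    "fragment_ladder",
    "match_intact_mass_shift",
    "ppm_match",
    "parse_lowercase_peptide",
    "tryptic_peptides",
    "enumerate_site_assignments",
]

WATER_MONO = pmass.calculate_mass(formula="H2O")
STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ModificationSpec:
    """A named covalent modification with an elemental composition.

    Counts may be negative for loss-type modifications (deamidation is
    H-1 N-1 O+1); an all-zero composition is forbidden.
    """

    name: str
    elemental_composition: dict
    target_residues: str = ""
    variable: bool = True

    def __post_init__(self):
        comp = dict(self.elemental_composition)
        if not comp or all(v == 0 for v in comp.values()):
            raise InvalidArgumentError("composition must not be (all) zero")
        object.__setattr__(self, "elemental_composition", comp)

    def applies_to(self, residue: str) -> bool:
        return not self.target_residues or residue in self.target_residues


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with positional modifications (1-based positions)."""

    sequence: str
    site_modifications: dict = field(default_factory=dict)

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise SequenceError("empty sequence")
        bad = set(seq) - STANDARD_RESIDUES
        if bad:
            raise SequenceError(f"unknown residues: {sorted(bad)}")
        for pos, spec in self.site_modifications.items():
            if not 1 <= pos <= len(seq):
                raise SequenceError(f"modification position {pos} out of range")
            if not spec.applies_to(seq[pos - 1]):
                raise SequenceError(
                    f"{spec.name} does not target residue "
                    f"{seq[pos - 1]} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "site_modifications", dict(self.site_modifications))


@dataclass(frozen=True)
class TolerancePolicy:
    """Mass-matching tolerances: ppm for peptide precursors and fragments,
    Daltons for deconvoluted intact-protein shifts."""

    precursor_ppm: float = 20.0
    fragment_ppm: float = 50.0
    intact_tolerance_da: float = 1.0

    def __post_init__(self):
        if min(self.precursor_ppm, self.fragment_ppm, self.intact_tolerance_da) <= 0:
            raise InvalidArgumentError("tolerances must be > 0")


BUILTIN_MODIFICATIONS: dict[str, ModificationSpec] = {
    "phosphogluconoyl": ModificationSpec(
        "phosphogluconoyl", {"C": 6, "H": 11, "O": 9, "P": 1}, target_residues="K"
    ),
    "phospho": ModificationSpec(
        "phospho", {"H": 1, "P": 1, "O": 3}, target_residues="STYK"
    ),
    "oxidation": ModificationSpec("oxidation", {"O": 1}, target_residues="M"),
    "carbamidomethyl": ModificationSpec(
        "carbamidomethyl", {"C": 2, "H": 3, "N": 1, "O": 1},
        target_residues="C", variable=False,
    ),
    "deamidated": ModificationSpec(
        "deamidated", {"H": -1, "N": -1, "O": 1}, target_residues="NQ"
    ),
}


def _composition_mass(comp: dict, average: bool) -> float:
    total = 0.0
    for element, count in comp.items():
        try:
            if average:
                # Abundance-weighted average over natural isotopes.
                isotopes = pmass.nist_mass[element]
                avg = sum(
                    m * ab for iso, (m, ab) in isotopes.items() if iso != 0
                )
            else:
                avg = pmass.nist_mass[element][0][0]
        except KeyError as exc:
            raise MassLookupError(f"unknown element {element!r}") from exc
        total += count * avg
    return total


def modification_mass(spec: ModificationSpec) -> tuple[float, float]:
    """(monoisotopic, average) mass of the modification in Da."""
    return (
        _composition_mass(spec.elemental_composition, average=False),
        _composition_mass(spec.elemental_composition, average=True),
    )


def _residue_masses(sequence: str) -> list[float]:
    out = []
    for aa in sequence:
        try:
            out.append(pmass.std_aa_mass[aa])
        except KeyError as exc:
            raise SequenceError(f"unknown residue {aa!r}") from exc
    return out


def peptide_monoisotopic_mass(peptide: ModifiedPeptide) -> float:
    """Sum of residue monoisotopic masses + water + modification masses."""
    total = sum(_residue_masses(peptide.sequence)) + WATER_MONO
    for spec in peptide.site_modifications.values():
        total += modification_mass(spec)[0]
    return total


def fragment_ladder(peptide: ModifiedPeptide, charge: int = 1) -> dict:
    """Singly-charged (by default) b- and y-ion m/z ladders.

    Returns ``{"b": [b1..b_{n-1}], "y": [y1..y_{n-1}]}``. A modification
    at position i shifts b_k for k >= i and y_k for k > n - i.
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise SequenceError("fragment ladder needs >= 2 residues")
    if charge < 1:
        raise InvalidArgumentError("charge must be >= 1")
    res = _residue_masses(seq)
    mod_at = [0.0] * n
    for pos, spec in peptide.site_modifications.items():
        mod_at[pos - 1] += modification_mass(spec)[0]
    per_res = [r + m for r, m in zip(res, mod_at)]

    b_ions, y_ions = [], []
    prefix = 0.0
    for k in range(n - 1):
        prefix += per_res[k]
        b_ions.append((prefix + charge * PROTON_MASS_DA) / charge)
    suffix = 0.0
    for k in range(n - 1):
        suffix += per_res[n - 1 - k]
        y_ions.append((suffix + WATER_MONO + charge * PROTON_MASS_DA) / charge)
    return {"b": b_ions, "y": y_ions}


def ppm_match(theoretical: float, observed: float, ppm: float) -> bool:
    """Symmetric ppm window: |observed - theoretical|/theoretical <= ppm."""
    if theoretical <= 0:
        raise InvalidArgumentError("theoretical mass must be > 0")
    return abs(observed - theoretical) / theoretical * 1e6 <= ppm


@dataclass(frozen=True)
class ShiftMatch:
    """One candidate explanation of an intact-protein mass shift."""

    modifications: tuple[str, ...]
    total_mass: float
    error: float  # observed - total


def match_intact_mass_shift(
    observed_shift: float,
    candidates: Sequence[ModificationSpec],
    policy: TolerancePolicy = TolerancePolicy(),
    max_modifications: int = 2,
) -> list[ShiftMatch]:
    """Explain a deconvoluted intact-protein mass shift.

    Considers single modifications and combinations up to
    ``max_modifications`` (with repetition), keeps those whose summed
    monoisotopic mass falls within the intact tolerance, and ranks by
    absolute error. An empty list is a valid outcome.
    """
    if not candidates:
        raise InvalidArgumentError("candidate list must be non-empty")
    matches = []
    for r in range(1, max_modifications + 1):
        for combo in itertools.combinations_with_replacement(candidates, r):
            total = sum(modification_mass(spec)[0] for spec in combo)
            err = observed_shift - total
            if abs(err) <= policy.intact_tolerance_da:
                matches.append(
                    ShiftMatch(
                        modifications=tuple(s.name for s in combo),
                        total_mass=total,
                        error=err,
                    )
                )
    matches.sort(key=lambda m: (abs(m.error), len(m.modifications)))
    return matches


def parse_lowercase_peptide(
    text: str, lowercase_map: Optional[dict] = None
) -> ModifiedPeptide:
    """Parse ``SNPYVkTYLLPD``-style notation: lowercase letters mark
    modified residues, mapped to modifications via ``lowercase_map``
    (default: lowercase k -> phosphogluconoyl)."""
    if lowercase_map is None:
        lowercase_map = {"k": BUILTIN_MODIFICATIONS["phosphogluconoyl"]}
    mods = {}
    for i, ch in enumerate(text, start=1):
        if ch.islower():
            if ch not in lowercase_map:
                raise SequenceError(f"no modification mapped to {ch!r}")
            mods[i] = lowercase_map[ch]
    return ModifiedPeptide(sequence=text.upper(), site_modifications=mods)


def tryptic_peptides(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Simple trypsin rule: cleave after K/R except before P."""
    sequence = sequence.upper()
    if not sequence:
        raise SequenceError("empty sequence")
    pieces = re.split(r"(?<=[KR])(?!P)", sequence)
    out = []
    for i in range(len(pieces)):
        for j in range(i, min(i + missed_cleavages + 1, len(pieces))):
            out.append("".join(pieces[i : j + 1]))
    return out


def enumerate_site_assignments(
    sequence: str,
    candidate_sites: Sequence[int],
    spec: ModificationSpec,
    observed_shift: float,
    policy: TolerancePolicy = TolerancePolicy(),
) -> list[tuple[int, ...]]:
    """Site-assignment sets consistent with an intact mass shift.

    Because the whole-protein spectrum constrains the *total* added mass,
    assignments are enumerated so that the summed modification mass
    matches the observed shift: a single +258 Da shift makes modification
    of two candidate lysines mutually exclusive — each single-site
    assignment is returned, never the pair.
    """
    mono = modification_mass(spec)[0]
    seq = sequence.upper()
    for pos in candidate_sites:
        if not 1 <= pos <= len(seq):
            raise SequenceError(f"site {pos} out of range")
        if not spec.applies_to(seq[pos - 1]):
            raise SequenceError(f"{spec.name} does not target position {pos}")
    out = []
    for r in range(1, len(candidate_sites) + 1):
        if abs(observed_shift - r * mono) <= policy.intact_tolerance_da:
            out.extend(itertools.combinations(candidate_sites, r))
    return out
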